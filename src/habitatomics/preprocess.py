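"""Image standardization and voxel-wise DCE kinetic parameter maps.

Covers the steps applied to every scan before habitat clustering and
feature extraction: resampling to isotropic voxels, z-score intensity
normalization, empirical-Bayes batch harmonization (ComBat) of extracted
feature tables, and the four-voxel-wise kinetic summaries of the
enhancement curve: wash-in slope (WIS), wash-out slope (WOS), signal
enhancement ratio (SER) and percentage enhancement (PE).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import SimpleITK as sitk

log = logging.getLogger(__name__)

#: denominator clamp for SER
SER_EPS = 1e-8


@dataclass
class DCESeries:
    """A dynamic contrast-enhanced time series.

    Parameters
    ----------
    data
        4D array indexed (x, y, z, t) of signal intensities.
    spacing_mm
        Voxel size along (x, y, z) in millimetres.
    times_s
        Acquisition time of each frame in seconds, strictly increasing.
    baseline_index
        Index of the last pre-contrast frame (default 0).
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    times_s: np.ndarray
    baseline_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DCESeries.data must be 4D (x, y, z, t)")
        nt = self.data.shape[3]
        if nt < 3:
            raise ValueError("DCE series needs at least 3 timepoints")
        if len(self.times_s) != nt:
            raise ValueError("times_s length must match number of frames")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times_s must be strictly increasing")
        if not 0 <= self.baseline_index < nt - 1:
            raise ValueError("baseline_index must precede the last frame")


@dataclass
class KineticMaps:
    """Voxel-wise kinetic parameter maps over a tumor mask.

    WIS/WOS are in intensity per second, SER is dimensionless, PE is in
    percent. Values outside the mask are zero.
    """

    WIS: np.ndarray
    WOS: np.ndarray
    SER: np.ndarray
    PE: np.ndarray
    mask: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    names: tuple[str, ...] = field(default=("WIS", "WOS", "SER", "PE"), init=False)

    def stack(self) -> np.ndarray:
        """Masked voxels as an (n_voxels, 4) array in ``names`` order."""
        m = self.mask.astype(bool)
        return np.column_stack([getattr(self, n)[m] for n in self.names])


def _to_sitk(volume: np.ndarray, spacing: tuple[float, float, float]) -> sitk.Image:
    # numpy (x,y,z) -> sitk expects (z,y,x) array ordering
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.T))
    img.SetSpacing(tuple(float(s) for s in spacing))
    return img


def _from_sitk(img: sitk.Image) -> np.ndarray:
    return sitk.GetArrayFromImage(img).T


def resample_isotropic(
    volume: np.ndarray,
    spacing_mm,
    target_spacing: float = 1.0,
    interpolation: str = "bspline",
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Resample a 3D (or frame-wise 4D) volume to isotropic spacing.

    B-spline interpolation for intensity images; nearest-neighbour for
    masks so binary volumes stay binary.

    Returns the resampled array and its new spacing.
    """
    spacing_mm = tuple(float(s) for s in spacing_mm)
    if any(s <= 0 for s in spacing_mm):
        raise ValueError("voxel spacings must be positive")
    volume = np.asarray(volume)
    if not np.all(np.isfinite(volume)):
        raise ValueError("non-finite voxels in input volume")
    if volume.ndim == 4:
        frames = [
            resample_isotropic(volume[..., t], spacing_mm, target_spacing, interpolation)[0]
            for t in range(volume.shape[3])
        ]
        out_spacing = (target_spacing,) * 3
        return np.stack(frames, axis=-1), out_spacing
    if volume.ndim != 3:
        raise ValueError("expected a 3D or 4D volume")

    if spacing_mm == (target_spacing,) * 3:
        return volume.astype(float, copy=True), spacing_mm

    interp = {
        "bspline": sitk.sitkBSpline,
        "linear": sitk.sitkLinear,
        "nearest": sitk.sitkNearestNeighbor,
    }[interpolation]
    img = _to_sitk(volume.astype(float), spacing_mm)
    new_size = [
        int(round(sz * sp / target_spacing))
        for sz, sp in zip(volume.shape, spacing_mm)
    ]
    res = sitk.Resample(
        img,
        new_size,
        sitk.Transform(),
        interp,
        img.GetOrigin(),
        (target_spacing,) * 3,
        img.GetDirection(),
        0.0,
        sitk.sitkFloat64,
        True,  # nearest-neighbour extrapolation at the FOV edge
    )
    out = _from_sitk(res)
    if interpolation == "nearest":
        out = (out > 0.5).astype(volume.dtype)
    return out, (target_spacing,) * 3


def zscore_normalize(image: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Z-score an image over all voxels or over a mask.

    Raises ``ValueError`` for constant input (zero variance).
    """
    image = np.asarray(image, dtype=float)
    scope = image[np.asarray(mask, dtype=bool)] if mask is not None else image.ravel()
    if scope.size < 2:
        raise ValueError("need at least 2 voxels to normalize")
    mu = scope.mean()
    sd = scope.std()
    if sd == 0:
        raise ValueError("zero variance: constant image cannot be z-scored")
    return (image - mu) / sd


def combat_harmonize(
    features: pd.DataFrame,
    batch: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Remove batch (center) location/scale effects from a feature table.

    Parametric empirical-Bayes harmonization: per-batch feature means are
    shrunk toward a normal prior and per-batch variances toward an
    inverse-gamma prior before the adjustment, which preserves biological
    covariates supplied in ``covariates``.

    A single batch is passed through unchanged. Features with zero
    variance inside some batch are passed through with a warning.
    """
    batch = np.asarray(batch)
    if len(batch) != len(features):
        raise ValueError("batch labels must match feature-table rows")
    levels, batch_idx = np.unique(batch, return_inverse=True)
    n_batch = len(levels)
    if n_batch < 2:
        return features.copy()
    counts = np.bincount(batch_idx)
    if np.any(counts < 2):
        raise ValueError("each batch needs at least 2 subjects")

    X = features.to_numpy(dtype=float)
    n, g = X.shape

    # design: batch indicators + optional covariates
    B = np.zeros((n, n_batch))
    B[np.arange(n), batch_idx] = 1.0
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        design = np.column_stack([B, C])
    else:
        C = None
        design = B

    ok = np.ones(g, dtype=bool)
    for b in range(n_batch):
        ok &= X[batch_idx == b].std(axis=0) > 0
    if not ok.all():
        warnings.warn(
            f"{(~ok).sum()} feature(s) constant within a batch; passed through unharmonized"
        )

    out = X.copy()
    Xg = X[:, ok]
    beta, *_ = np.linalg.lstsq(design, Xg, rcond=None)
    grand_mean = (counts / n) @ beta[:n_batch]
    resid = Xg - design @ beta
    pooled_var = (resid**2).sum(axis=0) / n

    stand_mean = np.tile(grand_mean, (n, 1))
    if C is not None:
        stand_mean = stand_mean + C @ beta[n_batch:]
    Z = (Xg - stand_mean) / np.sqrt(pooled_var)

    # batch effect estimates on standardized data
    gamma_hat = np.stack([Z[batch_idx == b].mean(axis=0) for b in range(n_batch)])
    delta_hat = np.stack([Z[batch_idx == b].var(axis=0, ddof=1) for b in range(n_batch)])

    # EB hyperpriors (method of moments, per batch); with a single usable
    # feature there is nothing to pool across, fall back to no shrinkage
    gamma_bar = gamma_hat.mean(axis=1)
    if gamma_hat.shape[1] < 2:
        tau2 = np.full(n_batch, 1e6)
        d_var = np.full(n_batch, 1e-12)
    else:
        tau2 = gamma_hat.var(axis=1, ddof=1)
        d_var = delta_hat.var(axis=1, ddof=1)
    d_mean = delta_hat.mean(axis=1)
    lam = (2 * d_var + d_mean**2) / np.maximum(d_var, 1e-12)
    theta = (d_mean * d_var + d_mean**3) / np.maximum(d_var, 1e-12)

    Zadj = np.empty_like(Z)
    for b in range(n_batch):
        nb = counts[b]
        zb = Z[batch_idx == b]
        # iterate gamma*/delta* to convergence (Johnson's parametric EB)
        g_star = gamma_hat[b].copy()
        d_star = delta_hat[b].copy()
        for _ in range(100):
            g_new = (nb * tau2[b] * gamma_hat[b] + d_star * gamma_bar[b]) / (
                nb * tau2[b] + d_star
            )
            ss = ((zb - g_new) ** 2).sum(axis=0)
            d_new = (theta[b] + 0.5 * ss) / (nb / 2 + lam[b] - 1)
            if np.allclose(g_new, g_star, atol=1e-10) and np.allclose(
                d_new, d_star, atol=1e-10
            ):
                g_star, d_star = g_new, d_new
                break
            g_star, d_star = g_new, d_new
        Zadj[batch_idx == b] = (zb - g_star) / np.sqrt(np.maximum(d_star, 1e-12))

    out[:, ok] = Zadj * np.sqrt(pooled_var) + stand_mean
    return pd.DataFrame(out, index=features.index, columns=features.columns)


def compute_kinetic_maps(dce: DCESeries, mask: np.ndarray) -> KineticMaps:
    """Voxel-wise WIS, WOS, SER and PE from a DCE series.

    With ``S0`` the baseline frame, ``Speak`` the post-baseline maximum at
    time ``tpeak``, ``Searly`` the first post-baseline frame and ``Slast``
    the final frame::

        PE  = 100 * (Speak - S0) / S0
        WIS = (Speak - S0) / (tpeak - t0)
        WOS = (Slast - Speak) / (tlast - tpeak)   (0 when tpeak == tlast)
        SER = (Searly - S0) / (Slast - S0)        (0 when |denominator| <= eps)
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dce.data.shape[:3]:
        raise ValueError("mask shape does not match DCE grid")
    b = dce.baseline_index
    S = dce.data[mask]  # (n_voxels, t)
    S0 = S[:, b]
    if np.any(S0 <= 0):
        raise ValueError("non-positive baseline signal inside mask (un-normalized input?)")
    post = S[:, b + 1 :]
    t_post = dce.times_s[b + 1 :]
    peak_j = np.argmax(post, axis=1)
    Speak = post[np.arange(post.shape[0]), peak_j]
    tpeak = t_post[peak_j]
    Searly = post[:, 0]
    Slast = post[:, -1]
    tlast = t_post[-1]
    t0 = dce.times_s[b]

    pe = 100.0 * (Speak - S0) / S0
    wis = (Speak - S0) / (tpeak - t0)
    dt_wash = tlast - tpeak
    wos = np.where(dt_wash > 0, (Slast - Speak) / np.where(dt_wash > 0, dt_wash, 1.0), 0.0)
    denom = Slast - S0
    ser = np.where(np.abs(denom) > SER_EPS, (Searly - S0) / np.where(np.abs(denom) > SER_EPS, denom, 1.0), 0.0)

    def full(vals: np.ndarray) -> np.ndarray:
        out = np.zeros(mask.shape)
        out[mask] = vals
        return out

    return KineticMaps(
        WIS=full(wis), WOS=full(wos), SER=full(ser), PE=full(pe),
        mask=mask, spacing_mm=dce.spacing_mm,
    )
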
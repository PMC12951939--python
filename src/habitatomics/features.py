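"""IBSI-style radiomic feature extraction.

Feature classes: 14 3D shape/morphology features, 18 first-order
statistics, and 75 texture features from five gray-level matrices
(GLCM 24, GLRLM 16, GLSZM 16, GLDM 14, NGTDM 5), optionally repeated on
the 8 sub-bands of a single-level stationary wavelet decomposition.

Conventions frozen here:

* gray-level discretization by fixed bin width (default) or fixed bin
  count, levels 1..L;
* texture matrices over 26-connected 3D neighbourhoods — GLCM and GLRLM
  per 13 unique directions at distance 1 with feature values averaged
  over directions; GLSZM zones and GLDM dependencies use full
  26-connectivity;
* feature names are the field's bare names (``MeshVolume``,
  ``ClusterShade``); the few names shared by several texture families
  (``Contrast``, ``GrayLevelVariance``, ...) carry a lowercase family
  prefix (``glcm_Contrast``) so that every name in a table is unique.

Full column names follow the grammar
``<timepoint>_<sequence>_<region>_<FeatureName>`` with an optional
``wavelet-XXX`` filter tag before the feature name, e.g.
``delta_dce_mps_MeshVolume`` or ``pre_dce_tumor_wavelet-HHH_Entropy``.
"""

from __future__ import annotations

import warnings
from itertools import product

import numpy as np
import pywt
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

EPS = np.spacing(1.0)

#: 13 unique direction offsets of the 26-neighbourhood (distance 1)
DIRECTIONS: tuple[tuple[int, int, int], ...] = tuple(
    off for off in product((0, 1, -1), repeat=3) if off > (0, 0, 0)
)
assert len(DIRECTIONS) == 13

ALL_OFFSETS: tuple[tuple[int, int, int], ...] = tuple(
    off for off in product((-1, 0, 1), repeat=3) if off != (0, 0, 0)
)

SHAPE_FEATURES = (
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "MajorAxisLength",
    "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness",
)

FIRSTORDER_FEATURES = (
    "Mean", "Median", "Minimum", "Maximum", "Range", "Variance",
    "Skewness", "Kurtosis", "Energy", "TotalEnergy", "Entropy",
    "Uniformity", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "InterquartileRange", "10Percentile", "90Percentile",
)

GLCM_FEATURES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "Id", "Idm", "Idmn", "Idn",
    "Imc1", "Imc2", "InverseVariance", "JointAverage", "JointEnergy",
    "JointEntropy", "MCC", "MaximumProbability", "SumAverage",
    "SumEntropy", "SumSquares",
)

GLRLM_FEATURES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage",
    "GrayLevelVariance", "RunVariance", "RunEntropy",
    "LowGrayLevelRunEmphasis", "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis", "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis", "LongRunHighGrayLevelEmphasis",
)

GLSZM_FEATURES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage",
    "GrayLevelVariance", "ZoneVariance", "ZoneEntropy",
    "LowGrayLevelZoneEmphasis", "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis", "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis", "LargeAreaHighGrayLevelEmphasis",
)

GLDM_FEATURES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

NGTDM_FEATURES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

TEXTURE_FAMILIES = {
    "glcm": GLCM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "glszm": GLSZM_FEATURES,
    "gldm": GLDM_FEATURES,
    "ngtdm": NGTDM_FEATURES,
}


def _ambiguous_names() -> set[str]:
    seen: dict[str, int] = {}
    for feats in TEXTURE_FAMILIES.values():
        for f in feats:
            seen[f] = seen.get(f, 0) + 1
    return {f for f, c in seen.items() if c > 1}


AMBIGUOUS = _ambiguous_names()


def qualified_name(family: str, feature: str) -> str:
    """Unique feature name: bare when unambiguous, family-prefixed otherwise."""
    return f"{family}_{feature}" if feature in AMBIGUOUS else feature


def full_name(
    feature: str, timepoint: str, sequence: str, region: str, image_filter: str = "original"
) -> str:
    """Column name per the naming grammar ``<tp>_<seq>_<region>_<Feature>``."""
    if image_filter == "original":
        return f"{timepoint}_{sequence}_{region}_{feature}"
    return f"{timepoint}_{sequence}_{region}_{image_filter}_{feature}"


# ---------------------------------------------------------------------------
# discretization


def discretize(
    image: np.ndarray,
    mask: np.ndarray,
    mode: str = "fixed_bin_width",
    bin_width: float = 25.0,
    bin_count: int = 32,
) -> tuple[np.ndarray, int]:
    """Map masked intensities to integer gray levels 1..L (monotone).

    ``fixed_bin_width``: level = floor((x - min)/w) + 1, so
    L = floor((max - min)/w) + 1. ``fixed_bin_count``: the range is split
    into ``bin_count`` equal bins (a constant image yields one level).
    Voxels outside the mask get level 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    x = np.asarray(image, dtype=float)
    vals = x[mask]
    lo, hi = vals.min(), vals.max()
    lv = np.zeros(x.shape, dtype=np.int64)
    if mode == "fixed_bin_width":
        if bin_width <= 0:
            raise ValueError("bin width must be positive")
        lv[mask] = np.floor((vals - lo) / bin_width).astype(np.int64) + 1
        L = int(np.floor((hi - lo) / bin_width)) + 1
    elif mode == "fixed_bin_count":
        if bin_count < 2:
            raise ValueError("bin count must be >= 2")
        if hi == lo:
            lv[mask] = 1
            L = 1
        else:
            lv[mask] = np.minimum(
                np.floor((vals - lo) / ((hi - lo) / bin_count)).astype(np.int64) + 1,
                bin_count,
            )
            L = bin_count
    else:
        raise ValueError(f"unknown discretization mode {mode!r}")
    return lv, L


# ---------------------------------------------------------------------------
# shape


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 400:
        try:
            points = points[ConvexHull(points).vertices]
        except Exception:  # degenerate (coplanar) sets
            pass
    return float(pdist(points).max())


def shape_features(mask: np.ndarray, spacing_mm) -> dict[str, float]:
    """The 14 IBSI 3D morphology features of a binary mask.

    MeshVolume and SurfaceArea come from a closed marching-cubes surface;
    axis lengths from PCA of voxel centers (physical coordinates). A mask
    confined to a single slice along any axis is planar-degenerate: the
    mesh-based features are returned NaN with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    spacing = np.asarray(spacing_mm, dtype=float)
    out: dict[str, float] = {}

    n = int(mask.sum())
    voxel_vol = float(np.prod(spacing))
    out["VoxelVolume"] = n * voxel_vol

    idx = np.argwhere(mask)
    coords = idx * spacing  # physical voxel centers
    extent = idx.max(axis=0) - idx.min(axis=0) + 1
    planar = bool((extent < 2).any())

    if planar:
        warnings.warn("single-slice mask: mesh-based shape features set to NaN")
        for k in ("MeshVolume", "SurfaceArea", "SurfaceVolumeRatio", "Sphericity"):
            out[k] = float("nan")
    else:
        padded = np.pad(mask.astype(np.uint8), 1)
        verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
        a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
        cross = np.cross(b - a, c - a)
        area = 0.5 * np.linalg.norm(cross, axis=1).sum()
        vol = abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum()) / 6.0
        out["MeshVolume"] = float(vol)
        out["SurfaceArea"] = float(area)
        out["SurfaceVolumeRatio"] = float(area / vol)
        out["Sphericity"] = float((36 * np.pi * vol**2) ** (1 / 3) / area)

    # maximum diameters from boundary voxel centers
    eroded = ndimage.binary_erosion(mask)
    boundary = coords if planar else (np.argwhere(mask & ~eroded) * spacing)
    if len(boundary) == 0:
        boundary = coords
    out["Maximum3DDiameter"] = _max_pairwise(boundary)
    # 2D diameters: per-plane maxima, ignoring one axis at a time
    bidx = np.argwhere(mask & ~eroded) if not planar else idx
    if len(bidx) == 0:
        bidx = idx
    for name, drop_ax in (
        ("Maximum2DDiameterSlice", 2),
        ("Maximum2DDiameterColumn", 1),
        ("Maximum2DDiameterRow", 0),
    ):
        best = 0.0
        for plane in np.unique(bidx[:, drop_ax]):
            pts = bidx[bidx[:, drop_ax] == plane]
            keep = [ax for ax in range(3) if ax != drop_ax]
            best = max(best, _max_pairwise(pts[:, keep] * spacing[keep]))
        out[name] = best

    # principal axes
    centered = coords - coords.mean(axis=0)
    if n > 1:
        cov = centered.T @ centered / n
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0, None)
    else:
        eig = np.zeros(3)
    out["MajorAxisLength"] = float(4 * np.sqrt(eig[0]))
    out["MinorAxisLength"] = float(4 * np.sqrt(eig[1]))
    out["LeastAxisLength"] = float(4 * np.sqrt(eig[2]))
    out["Elongation"] = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else float("nan")
    out["Flatness"] = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else float("nan")
    return out


# ---------------------------------------------------------------------------
# first order


def firstorder_features(
    image: np.ndarray,
    mask: np.ndarray,
    voxel_volume: float = 1.0,
    bin_width: float | None = None,
) -> dict[str, float]:
    """The 18 standard first-order intensity statistics.

    Entropy and Uniformity are computed on a histogram of the masked
    intensities: discretized at ``bin_width`` when given, else over the
    distinct observed values. Variance/Skewness/Kurtosis are population
    moments; Kurtosis is not excess-corrected (a Gaussian scores 3).
    """
    mask = np.asarray(mask, dtype=bool)
    x = np.asarray(image, dtype=float)[mask]
    if x.size == 0:
        raise ValueError("empty mask")
    mu = x.mean()
    var = x.var()
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])

    if bin_width is not None:
        lv = np.floor((x - x.min()) / bin_width)
        _, counts = np.unique(lv, return_counts=True)
    else:
        _, counts = np.unique(x, return_counts=True)
    p = counts / counts.sum()

    robust = x[(x >= p10) & (x <= p90)]
    m2 = var
    m3 = ((x - mu) ** 3).mean()
    m4 = ((x - mu) ** 4).mean()
    return {
        "Mean": float(mu),
        "Median": float(p50),
        "Minimum": float(x.min()),
        "Maximum": float(x.max()),
        "Range": float(x.max() - x.min()),
        "Variance": float(var),
        "Skewness": float(m3 / m2**1.5) if m2 > 0 else 0.0,
        "Kurtosis": float(m4 / m2**2) if m2 > 0 else 0.0,
        "Energy": float((x**2).sum()),
        "TotalEnergy": float(voxel_volume * (x**2).sum()),
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Uniformity": float((p**2).sum()),
        "MeanAbsoluteDeviation": float(np.abs(x - mu).mean()),
        "RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean())
        if robust.size
        else 0.0,
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "InterquartileRange": float(p75 - p25),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
    }


# ---------------------------------------------------------------------------
# texture helpers


def _shifted_views(shape, off):
    """Slice pairs (src, dst) such that arr_dst[v] = arr_src[v + off]."""
    src, dst = [], []
    for d, s in zip(off, shape):
        if d == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif d > 0:
            src.append(slice(d, None))
            dst.append(slice(None, s - d))
        else:
            src.append(slice(None, d))
            dst.append(slice(-d, None))
    return tuple(src), tuple(dst)


def _shift(arr: np.ndarray, off, fill=0) -> np.ndarray:
    """Array b with b[v] = arr[v + off] (fill outside)."""
    out = np.full_like(arr, fill)
    src, dst = _shifted_views(arr.shape, off)
    out[dst] = arr[src]
    return out


def glcm_matrix(levels: np.ndarray, mask: np.ndarray, L: int, off) -> np.ndarray:
    """Symmetric gray-level co-occurrence matrix for one direction offset."""
    src, dst = _shifted_views(levels.shape, off)
    a = levels[dst]
    b = levels[src]
    valid = mask[dst] & mask[src]
    i, j = a[valid] - 1, b[valid] - 1
    P = np.zeros((L, L))
    np.add.at(P, (i, j), 1.0)
    return P + P.T


def glcm_features_single(P: np.ndarray) -> dict[str, float]:
    """GLCM feature vector from one (symmetric, unnormalized) matrix."""
    L = P.shape[0]
    s = P.sum()
    if s == 0:
        return {k: float("nan") for k in GLCM_FEATURES}
    p = P / s
    i = np.arange(1, L + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux = (i * px).sum()
    muy = (i * py).sum()
    sigx = np.sqrt(((i - mux) ** 2 * px).sum())
    sigy = np.sqrt(((i - muy) ** 2 * py).sum())

    k_sum = np.arange(2, 2 * L + 1)
    p_sum = np.array([p[(I + J) == k].sum() for k in k_sum])
    k_diff = np.arange(0, L)
    p_diff = np.array([p[np.abs(I - J) == k].sum() for k in k_diff])

    nz = p > 0
    HXY = -(p[nz] * np.log2(p[nz])).sum()
    pxpy = np.outer(px, py)
    both = nz & (pxpy > 0)
    HXY1 = -(p[both] * np.log2(pxpy[both])).sum()
    nz2 = pxpy > 0
    HXY2 = -(pxpy[nz2] * np.log2(pxpy[nz2])).sum()
    HX = -(px[px > 0] * np.log2(px[px > 0])).sum()
    HY = -(py[py > 0] * np.log2(py[py > 0])).sum()

    da = (k_diff * p_diff).sum()
    nzs = p_sum > 0
    nzd = p_diff > 0

    # MCC: second largest eigenvalue of Q
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = px[:, None] * py[None, :]
        pq = np.where(denom > 0, p / np.where(denom > 0, denom, 1.0), 0.0)
    Q = pq @ p.T  # Q[i,j] = sum_k p(i,k) p(j,k) / (px(i) py(k))
    try:
        ev = np.sort(np.real(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(max(ev[-2], 0.0))) if L > 1 else 1.0
    except np.linalg.LinAlgError:
        mcc = float("nan")

    mu_t = mux + muy
    off_ij = I + J - mu_t
    denom_iv = (I - J).astype(float) ** 2
    iv_mask = I != J

    corr = ((I * J * p).sum() - mux * muy) / (sigx * sigy) if sigx * sigy > 0 else 1.0
    imc1 = (HXY - HXY1) / max(HX, HY) if max(HX, HY) > 0 else 0.0
    imc2 = float(np.sqrt(1 - np.exp(-2.0 * max(HXY2 - HXY, 0.0))))

    return {
        "Autocorrelation": float((I * J * p).sum()),
        "ClusterProminence": float((off_ij**4 * p).sum()),
        "ClusterShade": float((off_ij**3 * p).sum()),
        "ClusterTendency": float((off_ij**2 * p).sum()),
        "Contrast": float((((I - J) ** 2) * p).sum()),
        "Correlation": float(corr),
        "DifferenceAverage": float(da),
        "DifferenceEntropy": float(-(p_diff[nzd] * np.log2(p_diff[nzd])).sum()),
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "Id": float((p / (1.0 + np.abs(I - J))).sum()),
        "Idm": float((p / (1.0 + (I - J) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((I - J) / L) ** 2)).sum()),
        "Idn": float((p / (1.0 + np.abs(I - J) / L)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": float((p[iv_mask] / denom_iv[iv_mask]).sum()),
        "JointAverage": float(mux),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": float(HXY),
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": float(-(p_sum[nzs] * np.log2(p_sum[nzs])).sum()),
        "SumSquares": float(((I - mux) ** 2 * p).sum()),
    }


def glrlm_matrix(levels: np.ndarray, mask: np.ndarray, L: int, off) -> np.ndarray:
    """Gray-level run-length matrix (L x max_run) for one direction."""
    mask = mask.astype(bool)
    eq_next = (_shift(levels, off) == levels) & _shift(mask, off, fill=False) & mask
    neg = tuple(-d for d in off)
    eq_prev = (_shift(levels, neg) == levels) & _shift(mask, neg, fill=False) & mask
    starts = mask & ~eq_prev

    # remaining run length R[v] = 1 + R[v+off] if continuation
    R = mask.astype(np.int64)
    for _ in range(max(levels.shape)):
        nxt = mask * (1 + eq_next * _shift(R, off))
        if np.array_equal(nxt, R):
            break
        R = nxt
    runs = R[starts]
    lvls = levels[starts]
    max_run = int(runs.max()) if runs.size else 1
    P = np.zeros((L, max_run))
    np.add.at(P, (lvls - 1, runs - 1), 1.0)
    return P


def _run_zone_features(P: np.ndarray, n_voxels: int, kind: str) -> dict[str, float]:
    """Shared feature formulas for run-length (kind='run') and size-zone matrices."""
    Nr = P.sum()
    if Nr == 0:
        names = GLRLM_FEATURES if kind == "run" else GLSZM_FEATURES
        return {k: float("nan") for k in names}
    L, M = P.shape
    i = np.arange(1, L + 1, dtype=float)
    j = np.arange(1, M + 1, dtype=float)
    I, J = np.meshgrid(i, j, indexing="ij")
    p = P / Nr
    ri = P.sum(axis=1)
    rj = P.sum(axis=0)
    mu_i = (I * p).sum()
    mu_j = (J * p).sum()
    nz = p > 0
    ent = -(p[nz] * np.log2(p[nz])).sum()

    vals = {
        "SRE": float((p / J**2).sum()),
        "LRE": float((p * J**2).sum()),
        "GLN": float((ri**2).sum() / Nr),
        "GLNN": float((ri**2).sum() / Nr**2),
        "RLN": float((rj**2).sum() / Nr),
        "RLNN": float((rj**2).sum() / Nr**2),
        "RP": float(Nr / n_voxels),
        "GLV": float(((I - mu_i) ** 2 * p).sum()),
        "RV": float(((J - mu_j) ** 2 * p).sum()),
        "RE": float(ent),
        "LGLE": float((p / I**2).sum()),
        "HGLE": float((p * I**2).sum()),
        "SRLGLE": float((p / (I**2 * J**2)).sum()),
        "SRHGLE": float((p * I**2 / J**2).sum()),
        "LRLGLE": float((p * J**2 / I**2).sum()),
        "LRHGLE": float((p * I**2 * J**2).sum()),
    }
    if kind == "run":
        keys = (
            "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
            "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
            "RunLengthNonUniformityNormalized", "RunPercentage",
            "GrayLevelVariance", "RunVariance", "RunEntropy",
            "LowGrayLevelRunEmphasis", "HighGrayLevelRunEmphasis",
            "ShortRunLowGrayLevelEmphasis", "ShortRunHighGrayLevelEmphasis",
            "LongRunLowGrayLevelEmphasis", "LongRunHighGrayLevelEmphasis",
        )
    else:
        keys = (
            "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
            "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
            "SizeZoneNonUniformityNormalized", "ZonePercentage",
            "GrayLevelVariance", "ZoneVariance", "ZoneEntropy",
            "LowGrayLevelZoneEmphasis", "HighGrayLevelZoneEmphasis",
            "SmallAreaLowGrayLevelEmphasis", "SmallAreaHighGrayLevelEmphasis",
            "LargeAreaLowGrayLevelEmphasis", "LargeAreaHighGrayLevelEmphasis",
        )
    order = (
        "SRE", "LRE", "GLN", "GLNN", "RLN", "RLNN", "RP", "GLV", "RV", "RE",
        "LGLE", "HGLE", "SRLGLE", "SRHGLE", "LRLGLE", "LRHGLE",
    )
    return dict(zip(keys, (vals[o] for o in order)))


def glszm_matrix(levels: np.ndarray, mask: np.ndarray, L: int) -> np.ndarray:
    """Gray-level size-zone matrix: 26-connected zones of equal level."""
    structure = np.ones((3, 3, 3), dtype=int)
    sizes_per_level: list[np.ndarray] = []
    max_size = 1
    for lev in range(1, L + 1):
        comp, ncomp = ndimage.label((levels == lev) & mask, structure=structure)
        if ncomp == 0:
            sizes_per_level.append(np.empty(0, dtype=np.int64))
            continue
        sizes = np.bincount(comp.ravel())[1:]
        sizes_per_level.append(sizes)
        max_size = max(max_size, int(sizes.max()))
    P = np.zeros((L, max_size))
    for lev, sizes in enumerate(sizes_per_level):
        if sizes.size:
            np.add.at(P, (lev, sizes - 1), 1.0)
    return P


def gldm_matrix(levels: np.ndarray, mask: np.ndarray, L: int, alpha: int = 0) -> np.ndarray:
    """Gray-level dependence matrix with 26-neighbourhood, tolerance alpha.

    The dependence size of a voxel is 1 + the number of in-mask neighbours
    whose gray level differs by at most ``alpha``.
    """
    mask = mask.astype(bool)
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in ALL_OFFSETS:
        nb = _shift(levels, off)
        nb_in = _shift(mask, off, fill=False)
        dep += (np.abs(nb - levels) <= alpha) & nb_in & mask
    size = dep[mask] + 1
    lv = levels[mask]
    P = np.zeros((L, int(size.max())))
    np.add.at(P, (lv - 1, size - 1), 1.0)
    return P


def gldm_features_from_matrix(P: np.ndarray) -> dict[str, float]:
    Nz = P.sum()
    if Nz == 0:
        return {k: float("nan") for k in GLDM_FEATURES}
    L, M = P.shape
    i = np.arange(1, L + 1, dtype=float)
    j = np.arange(1, M + 1, dtype=float)
    I, J = np.meshgrid(i, j, indexing="ij")
    p = P / Nz
    ri = P.sum(axis=1)
    rj = P.sum(axis=0)
    mu_i = (I * p).sum()
    mu_j = (J * p).sum()
    nz = p > 0
    return {
        "SmallDependenceEmphasis": float((p / J**2).sum()),
        "LargeDependenceEmphasis": float((p * J**2).sum()),
        "GrayLevelNonUniformity": float((ri**2).sum() / Nz),
        "DependenceNonUniformity": float((rj**2).sum() / Nz),
        "DependenceNonUniformityNormalized": float((rj**2).sum() / Nz**2),
        "GrayLevelVariance": float(((I - mu_i) ** 2 * p).sum()),
        "DependenceVariance": float(((J - mu_j) ** 2 * p).sum()),
        "DependenceEntropy": float(-(p[nz] * np.log2(p[nz])).sum()),
        "LowGrayLevelEmphasis": float((p / I**2).sum()),
        "HighGrayLevelEmphasis": float((p * I**2).sum()),
        "SmallDependenceLowGrayLevelEmphasis": float((p / (I**2 * J**2)).sum()),
        "SmallDependenceHighGrayLevelEmphasis": float((p * I**2 / J**2).sum()),
        "LargeDependenceLowGrayLevelEmphasis": float((p * J**2 / I**2).sum()),
        "LargeDependenceHighGrayLevelEmphasis": float((p * I**2 * J**2).sum()),
    }


def ngtdm_table(levels: np.ndarray, mask: np.ndarray, L: int):
    """NGTDM components: per-level counts n_i and summed deviations s_i."""
    mask = mask.astype(bool)
    nb_sum = np.zeros(levels.shape, dtype=float)
    nb_cnt = np.zeros(levels.shape, dtype=np.int64)
    for off in ALL_OFFSETS:
        nb_in = _shift(mask, off, fill=False)
        nb_sum += np.where(nb_in, _shift(levels, off), 0)
        nb_cnt += nb_in
    valid = mask & (nb_cnt > 0)
    dev = np.abs(levels[valid] - nb_sum[valid] / nb_cnt[valid])
    lv = levels[valid]
    n_i = np.bincount(lv - 1, minlength=L).astype(float)
    s_i = np.bincount(lv - 1, weights=dev, minlength=L)
    return n_i, s_i


def ngtdm_features_from_table(n_i: np.ndarray, s_i: np.ndarray) -> dict[str, float]:
    Nvp = n_i.sum()
    if Nvp == 0:
        return {k: float("nan") for k in NGTDM_FEATURES}
    L = len(n_i)
    i = np.arange(1, L + 1, dtype=float)
    p_i = n_i / Nvp
    present = p_i > 0
    Ngp = int(present.sum())
    ip = i[present]
    pp = p_i[present]
    sp = s_i[present]

    coarse_den = (pp * sp).sum()
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6

    if Ngp > 1:
        Pi, Pj = np.meshgrid(pp, pp, indexing="ij")
        Ii, Ij = np.meshgrid(ip, ip, indexing="ij")
        contrast = (Pi * Pj * (Ii - Ij) ** 2).sum() / (Ngp * (Ngp - 1)) * (s_i.sum() / Nvp)
        busy_den = np.abs(np.subtract.outer(ip * pp, ip * pp)).sum()
        busyness = coarse_den / busy_den if busy_den > 0 else 0.0
        Si, Sj = np.meshgrid(sp, sp, indexing="ij")
        complexity = (
            np.abs(Ii - Ij) * (Pi * Si + Pj * Sj) / (Pi + Pj)
        ).sum() / Nvp
        s_sum = s_i.sum()
        strength = ((Pi + Pj) * (Ii - Ij) ** 2).sum() / s_sum if s_sum > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0
    return {
        "Coarseness": float(coarseness),
        "Contrast": float(contrast),
        "Busyness": float(busyness),
        "Complexity": float(complexity),
        "Strength": float(strength),
    }


def _average_over_directions(per_dir: list[dict[str, float]]) -> dict[str, float]:
    keys = per_dir[0].keys()
    return {k: float(np.nanmean([d[k] for d in per_dir])) for k in keys}


def texture_features(
    levels: np.ndarray,
    mask: np.ndarray,
    L: int,
    family: str,
) -> dict[str, float]:
    """Texture features of one family from a discretized volume.

    GLCM and GLRLM are evaluated per direction (13 unique offsets) and the
    feature values averaged; GLSZM/GLDM/NGTDM use full 26-connectivity.
    Names are disambiguated across families via :func:`qualified_name`.
    """
    mask = np.asarray(mask, dtype=bool)
    if family == "glcm":
        feats = _average_over_directions(
            [glcm_features_single(glcm_matrix(levels, mask, L, off)) for off in DIRECTIONS]
        )
    elif family == "glrlm":
        n = int(mask.sum())
        feats = _average_over_directions(
            [
                _run_zone_features(glrlm_matrix(levels, mask, L, off), n, "run")
                for off in DIRECTIONS
            ]
        )
    elif family == "glszm":
        feats = _run_zone_features(glszm_matrix(levels, mask, L), int(mask.sum()), "zone")
    elif family == "gldm":
        feats = gldm_features_from_matrix(gldm_matrix(levels, mask, L))
    elif family == "ngtdm":
        feats = ngtdm_features_from_table(*ngtdm_table(levels, mask, L))
    else:
        raise ValueError(f"unknown texture family {family!r}")
    return {qualified_name(family, k): v for k, v in feats.items()}


# ---------------------------------------------------------------------------
# wavelet bank


WAVELET = "coif1"


def wavelet_bank(image: np.ndarray, wavelet: str = WAVELET) -> dict[str, np.ndarray]:
    """Single-level stationary 3D wavelet decomposition into 8 sub-bands.

    Returns sub-bands named LLL..HHH (low/high-pass per axis, axis order
    x, y, z), each the same shape as the input. Input dims must be at
    least the filter length; odd dims are edge-padded to even internally
    and the sub-bands cropped back (exact inverse reconstruction is only
    guaranteed for even-shaped input).
    """
    image = np.asarray(image, dtype=float)
    w = pywt.Wavelet(wavelet)
    if any(s < w.dec_len for s in image.shape):
        raise ValueError("volume too small for the wavelet filter length")
    pad = [(0, s % 2) for s in image.shape]
    padded = np.pad(image, pad, mode="edge") if any(p[1] for p in pad) else image
    coeffs = pywt.swtn(padded, wavelet, level=1)[0]
    out = {}
    for key, arr in coeffs.items():
        name = key.replace("a", "L").replace("d", "H").upper()
        crop = tuple(slice(0, s) for s in image.shape)
        out[name] = arr[crop]
    assert len(out) == 8
    return out


def wavelet_reconstruct(bands: dict[str, np.ndarray], wavelet: str = WAVELET) -> np.ndarray:
    """Invert :func:`wavelet_bank` (even-shaped volumes)."""
    coeffs = {
        name.replace("L", "a").replace("H", "d").lower(): arr
        for name, arr in bands.items()
    }
    return pywt.iswtn([coeffs], wavelet)


# ---------------------------------------------------------------------------
# region extraction and delta features


def extract_region_features(
    image: np.ndarray,
    mask: np.ndarray,
    spacing_mm=(1.0, 1.0, 1.0),
    families: tuple[str, ...] = ("shape", "firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm"),
    discretization: str = "fixed_bin_width",
    bin_width: float = 25.0,
    bin_count: int = 32,
    wavelets: bool = False,
) -> dict[str, float]:
    """All requested feature families for one ROI on one image.

    Shape features are computed once from the mask; intensity and texture
    features are computed on the original image and, when ``wavelets`` is
    on, repeated on each of the 8 stationary-wavelet sub-bands (names
    prefixed ``wavelet-XXX_``).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    voxel_volume = float(np.prod(spacing_mm))
    out: dict[str, float] = {}
    if "shape" in families:
        out.update(shape_features(mask, spacing_mm))

    intensity_fams = [f for f in families if f != "shape"]

    def one_image(img: np.ndarray, prefix: str = "") -> None:
        if "firstorder" in intensity_fams:
            fo = firstorder_features(img, mask, voxel_volume=voxel_volume)
            out.update({prefix + k: v for k, v in fo.items()})
        tex = [f for f in intensity_fams if f in TEXTURE_FAMILIES]
        if tex:
            lv, L = discretize(img, mask, discretization, bin_width=bin_width, bin_count=bin_count)
            for fam in tex:
                feats = texture_features(lv, mask, L, fam)
                out.update({prefix + k: v for k, v in feats.items()})

    if intensity_fams:
        one_image(np.asarray(image, dtype=float))
        if wavelets:
            for band, vol in wavelet_bank(np.asarray(image, dtype=float)).items():
                one_image(vol, prefix=f"wavelet-{band}_")
    return out


def delta_features(pre: dict[str, float], post: dict[str, float]) -> dict[str, float]:
    """Longitudinal change: post-treatment minus pre-treatment, per feature.

    Both inputs must carry identical feature-name sets.
    """
    if set(pre) != set(post):
        missing = sorted(set(pre) ^ set(post))
        raise ValueError(f"feature name mismatch between pre and post: {missing}")
    return {k: post[k] - pre[k] for k in pre}
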
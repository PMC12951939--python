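"""Tumor subregion construction: perfusion habitats, cellularity split, peritumoral ring.

Perfusion habitats come from k-means clustering of the four voxel-wise
kinetic parameters (WIS, WOS, SER, PE) inside the tumor; clusters are
relabeled by descending mean PE so label 1 is always the high-perfusion
subregion. Cellularity subregions split the tumor at its mean ADC. The
peritumoral ring is the shell of tissue within a fixed physical distance
outside the tumor boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .preprocess import KineticMaps

#: label used for the peritumoral ring
PERI_LABEL = 9


@dataclass
class HabitatMask:
    """Integer label volume assigning voxels to subregions.

    ``scheme`` is one of ``perfusion3`` (1 = high-, 2 = moderate-,
    3 = poor-perfusion), ``cellularity2`` (1 = high-, 2 = low-cellularity)
    or ``peritumoral`` (9 = ring). Label 0 is outside every subregion.
    """

    labels: np.ndarray
    scheme: str
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def region(self, label: int) -> np.ndarray:
        return self.labels == label


def cluster_perfusion(
    kmaps: KineticMaps,
    k: int = 3,
    n_init: int = 10,
    seed: int = 0,
    zscore_inputs: bool = True,
) -> HabitatMask:
    """Partition the tumor into perfusion habitats by k-means on (WIS, WOS, SER, PE).

    Lloyd's algorithm with k-means++ initialization, best of ``n_init``
    restarts by within-cluster SSE. Kinetic features are z-scored within
    the tumor before clustering. Clusters are relabeled by descending mean
    PE: label 1 = high perfusion, ``k`` = poor perfusion.
    """
    mask = kmaps.mask.astype(bool)
    X = kmaps.stack()
    if X.shape[0] < k:
        raise ValueError("degenerate clustering: fewer tumor voxels than clusters")
    if np.unique(X, axis=0).shape[0] < k:
        raise ValueError("degenerate clustering: fewer distinct voxel profiles than clusters")
    if zscore_inputs:
        sd = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    km = KMeans(n_clusters=k, n_init=n_init, init="k-means++", random_state=seed)
    assign = km.fit_predict(X)

    pe = kmaps.PE[mask]
    order = np.argsort([-pe[assign == c].mean() for c in range(k)])
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)

    labels = np.zeros(mask.shape, dtype=int)
    labels[mask] = relabel[assign]
    return HabitatMask(labels=labels, scheme="perfusion3", spacing_mm=kmaps.spacing_mm)


def threshold_cellularity(
    adc: np.ndarray,
    mask: np.ndarray,
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> HabitatMask:
    """Split the tumor into high-/low-cellularity classes at the mean ADC.

    ADC is inversely related to cellularity: voxels strictly below the
    tumor-mean ADC become label 1 (high cellularity), the rest label 2.
    A constant ADC yields a single-class (label 2) mask with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    adc = np.asarray(adc, dtype=float)
    vals = adc[mask]
    if vals.size == 0:
        raise ValueError("empty tumor mask")
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite ADC inside mask")
    thr = vals.mean()
    labels = np.zeros(mask.shape, dtype=int)
    labels[mask] = np.where(adc[mask] < thr, 1, 2)
    if vals.min() == vals.max():
        warnings.warn("constant ADC in tumor: single-class cellularity mask")
    return HabitatMask(labels=labels, scheme="cellularity2", spacing_mm=spacing_mm)


def tumor_surface_distance(
    mask: np.ndarray,
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Euclidean distance from each outside voxel center to the tumor boundary.

    The Euclidean distance transform to the nearest inside voxel *center*
    systematically overestimates the distance to the digitized tumor
    boundary by about a quarter voxel on smooth surfaces; that offset is
    subtracted here. The result still upper-bounds the distance to the
    tumor considered as a union of voxel cubes (which lies at least half
    a voxel closer than the nearest center), so thresholding it at r mm
    never includes tissue farther than r from the tumor. Inside voxels
    get 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty tumor mask")
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing_mm)
    offset = 0.25 * float(min(spacing_mm))
    return np.where(mask, 0.0, np.maximum(dist - offset, 1e-9))


def peritumoral_ring(
    mask: np.ndarray,
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    radius_mm: float = 5.0,
) -> HabitatMask:
    """Construct the peritumoral ring by expanding the tumor boundary outward.

    The ring is the set of voxels whose Euclidean distance to the tumor
    boundary (see :func:`tumor_surface_distance`; voxel centers, physical
    spacing) is in ``(0, radius_mm]``, excluding the tumor itself. Rings
    touching the image border are clipped with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty tumor mask")
    dist = tumor_surface_distance(mask, spacing_mm)
    ring = (dist > 0) & (dist <= radius_mm) & ~mask

    # border clipping check: would the ring extend past the array edge?
    pad = tuple(int(np.ceil(radius_mm / s)) for s in spacing_mm)
    edges = [
        mask.take(range(p), axis=ax).any() or mask.take(range(-p, 0), axis=ax).any()
        for ax, p in enumerate(pad)
    ]
    if any(edges):
        warnings.warn("peritumoral ring clipped at image border")

    labels = np.where(ring, PERI_LABEL, 0)
    return HabitatMask(labels=labels, scheme="peritumoral", spacing_mm=spacing_mm)
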
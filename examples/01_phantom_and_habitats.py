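"""Build a DCE/ADC phantom and partition it into perfusion habitats.

Creates a spherical tumor with three planted perfusion habitats (fast
wash-in rim, plateau mid-zone, slowly enhancing core), computes the four
voxel-wise kinetic maps (WIS, WOS, SER, PE), clusters them with k-means,
and builds the 5 mm peritumoral ring. The adjusted Rand index measures
how well clustering recovers the planted habitat labels (1.0 = perfect).
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

from habitatomics import (
    HabitatChange,
    PhantomSpec,
    cluster_perfusion,
    compute_kinetic_maps,
    peritumoral_ring,
    simulate_imaging_pair,
)

spec = PhantomSpec(seed=0, noise_sd=2.0)
pre, post = simulate_imaging_pair(spec, HabitatChange(volume_scale=(0.7, 0.5, 0.9)))

kmaps = compute_kinetic_maps(pre.dce, pre.mask)
habitats = cluster_perfusion(kmaps, k=3, seed=0)
ring = peritumoral_ring(pre.mask, spec.spacing_mm, radius_mm=5.0)

m = pre.mask
ari = adjusted_rand_score(pre.truth_perfusion.labels[m], habitats.labels[m])
print(f"tumor voxels: {int(m.sum())} (pre), {int(post.mask.sum())} (post)")
for lab, name in ((1, "high-perfusion"), (2, "moderate"), (3, "poor")):
    n = int((habitats.labels == lab).sum())
    pe = kmaps.PE[habitats.labels == lab].mean()
    print(f"  habitat {lab} ({name:>14}): {n:5d} voxels, mean PE {pe:6.1f}%")
print(f"peritumoral ring: {int((ring.labels == 9).sum())} voxels within 5 mm")
print(f"adjusted Rand index vs planted habitats: {ari:.3f}")
# ARI near 1 means the clustering recovered the planted perfusion structure
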
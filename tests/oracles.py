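"""Independent brute-force oracles for the texture-matrix constructions.

Everything here is written as naive voxel-by-voxel enumeration with
explicit Python loops, deliberately sharing no code with the package's
vectorized implementations.
"""

from __future__ import annotations

from itertools import product

import numpy as np

OFFSETS_26 = [o for o in product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]


def _inside(shape, v):
    return all(0 <= v[a] < shape[a] for a in range(3))


def glcm_brute(levels, mask, L, off):
    """Symmetric co-occurrence counts by enumerating every voxel pair."""
    P = np.zeros((L, L))
    shape = levels.shape
    for v in product(*(range(s) for s in shape)):
        if not mask[v]:
            continue
        w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
        if _inside(shape, w) and mask[w]:
            P[levels[v] - 1, levels[w] - 1] += 1
            P[levels[w] - 1, levels[v] - 1] += 1
    return P


def glrlm_brute(levels, mask, L, off):
    """Run-length counts by walking every maximal run start."""
    shape = levels.shape
    runs = []
    for v in product(*(range(s) for s in shape)):
        if not mask[v]:
            continue
        prev = (v[0] - off[0], v[1] - off[1], v[2] - off[2])
        if _inside(shape, prev) and mask[prev] and levels[prev] == levels[v]:
            continue  # not a run start
        length = 1
        w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
        while _inside(shape, w) and mask[w] and levels[w] == levels[v]:
            length += 1
            w = (w[0] + off[0], w[1] + off[1], w[2] + off[2])
        runs.append((levels[v], length))
    max_run = max((r for _, r in runs), default=1)
    P = np.zeros((L, max_run))
    for lev, r in runs:
        P[lev - 1, r - 1] += 1
    return P


def glszm_brute(levels, mask, L):
    """Size-zone counts by flood fill (26-connectivity) per gray level."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for v in product(*(range(s) for s in shape)):
        if not mask[v] or seen[v]:
            continue
        lev = levels[v]
        stack = [v]
        seen[v] = True
        size = 0
        while stack:
            u = stack.pop()
            size += 1
            for off in OFFSETS_26:
                w = (u[0] + off[0], u[1] + off[1], u[2] + off[2])
                if _inside(shape, w) and mask[w] and not seen[w] and levels[w] == lev:
                    seen[w] = True
                    stack.append(w)
        zones.append((lev, size))
    max_size = max((s for _, s in zones), default=1)
    P = np.zeros((L, max_size))
    for lev, s in zones:
        P[lev - 1, s - 1] += 1
    return P


def gldm_brute(levels, mask, L, alpha=0):
    """Dependence counts: 1 + number of similar 26-neighbours per voxel."""
    shape = levels.shape
    entries = []
    for v in product(*(range(s) for s in shape)):
        if not mask[v]:
            continue
        dep = 0
        for off in OFFSETS_26:
            w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if _inside(shape, w) and mask[w] and abs(int(levels[w]) - int(levels[v])) <= alpha:
                dep += 1
        entries.append((levels[v], dep + 1))
    max_dep = max(d for _, d in entries)
    P = np.zeros((L, max_dep))
    for lev, d in entries:
        P[lev - 1, d - 1] += 1
    return P


def ngtdm_brute(levels, mask, L):
    """Per-level counts and summed deviations from the neighbourhood mean."""
    shape = levels.shape
    n_i = np.zeros(L)
    s_i = np.zeros(L)
    for v in product(*(range(s) for s in shape)):
        if not mask[v]:
            continue
        nb = []
        for off in OFFSETS_26:
            w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if _inside(shape, w) and mask[w]:
                nb.append(int(levels[w]))
        if not nb:
            continue
        lev = int(levels[v])
        n_i[lev - 1] += 1
        s_i[lev - 1] += abs(lev - sum(nb) / len(nb))
    return n_i, s_i


def cindex_brute(risk, time, event):
    """All-pairs Harrell concordance with explicit loops."""
    conc = disc = ties = 0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if i == j or event[i] != 1:
                continue
            comparable = time[j] > time[i] or (time[j] == time[i] and event[j] == 0)
            if not comparable:
                continue
            if risk[i] > risk[j]:
                conc += 1
            elif risk[i] < risk[j]:
                disc += 1
            else:
                ties += 1
    return (conc + 0.5 * ties) / (conc + disc + ties)


def wilcoxon_exact_brute(a, b):
    """Two-sided exact rank-sum p by enumerating all group assignments."""
    from itertools import combinations

    pooled = list(a) + list(b)
    n = len(a)
    ranks = {}
    srt = sorted(pooled)
    # midranks for ties
    for i, v in enumerate(srt):
        ranks.setdefault(v, []).append(i + 1)
    rank_of = {v: sum(r) / len(r) for v, r in ranks.items()}
    obs = sum(rank_of[v] for v in a)
    stats = [
        sum(rank_of[pooled[i]] for i in comb)
        for comb in combinations(range(len(pooled)), n)
    ]
    mean = sum(stats) / len(stats)
    extreme = sum(1 for s in stats if abs(s - mean) >= abs(obs - mean) - 1e-12)
    return extreme / len(stats)
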
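"""Synthetic multiparametric MRI phantoms, cohorts, outcomes and expression data.

Generates everything the analysis pipeline consumes, with known planted
structure so that every downstream stage is testable without patient
data:

* spherical tumors whose voxels belong to three concentric perfusion
  habitats with distinct enhancement kinetics (perfused rim, plateau
  mid-zone, poorly perfused core);
* a two-level ADC cellularity structure (low-ADC high-cellularity core);
* paired pre-/post-treatment volumes with planted per-habitat volume
  change and a concentric or non-concentric shrinkage pattern;
* binary pCR outcomes from a logistic link on emitted summary features,
  with the intercept calibrated by bisection to a target prevalence;
* disease-free-survival times from a Weibull proportional-hazards model
  with independent (exponential + administrative) censoring;
* a log2 expression matrix with planted differentially expressed gene
  programs tied to the risk groups.

All generators are deterministic given their seed; per-subject RNG
streams derive from (cohort seed, subject index).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .habitats import HabitatMask
from .preprocess import DCESeries
from .radiogenomics import ExpressionStudy, GeneSetCollection

#: enhancement-curve parameters per perfusion habitat, in acquisition order
#: high perfusion (fast wash-in, net washout), moderate (plateau),
#: poor (slow persistent rise; peak beyond the acquisition window)
DEFAULT_ARCHETYPES = (
    {"baseline": 100.0, "amplitude": 120.0, "time_to_peak_s": 60.0, "washout_rate": 0.0015},
    {"baseline": 100.0, "amplitude": 80.0, "time_to_peak_s": 150.0, "washout_rate": 0.0},
    {"baseline": 100.0, "amplitude": 50.0, "time_to_peak_s": 600.0, "washout_rate": 0.0},
)


@dataclass
class PhantomSpec:
    """Geometry, kinetics and noise of one synthetic tumor phantom."""

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_radius_mm: float = 8.0
    habitat_fractions: tuple[float, float, float] = (0.40, 0.35, 0.25)
    kinetic_archetypes: tuple[dict, ...] = DEFAULT_ARCHETYPES
    adc_levels: tuple[float, float] = (0.8, 1.6)  # x1e-3 mm^2/s (low=high cellularity)
    high_cellularity_fraction: float = 0.5
    noise_sd: float = 4.0
    adc_noise_sd: float = 0.04
    n_timepoints: int = 6
    frame_interval_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.habitat_fractions, dtype=float)
        if np.any(f < 0) or abs(f.sum() - 1) > 1e-9:
            raise ValueError("habitat_fractions must be nonnegative and sum to 1")
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 DCE timepoints")
        half_extent = min(
            s * n / 2 for s, n in zip(self.spacing_mm, self.grid_shape)
        )
        if self.tumor_radius_mm >= half_extent:
            raise ValueError("tumor does not fit inside the grid")


@dataclass
class HabitatChange:
    """Planted longitudinal change applied between pre and post imaging.

    ``volume_scale`` multiplies each habitat's voxel count (1 = no
    change, 0.5 = halved, 0 = habitat vanishes). ``non_concentric``
    shifts the residual lesion off-center, emulating a non-concentric
    shrinkage pattern.
    """

    volume_scale: tuple[float, float, float] = (0.6, 0.6, 0.6)
    non_concentric: bool = False

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.volume_scale):
            raise ValueError("volume_scale entries must be >= 0")


@dataclass
class SubjectImaging:
    """One timepoint's synthetic images for one subject."""

    dce: DCESeries
    adc: np.ndarray
    mask: np.ndarray
    truth_perfusion: HabitatMask
    truth_cellularity: HabitatMask


def _sphere_voxels(spec: PhantomSpec, radius_mm: float, center: np.ndarray):
    """Sorted (by center distance) voxel indices of a digital sphere."""
    grid = np.indices(spec.grid_shape).reshape(3, -1).T
    phys = grid * np.asarray(spec.spacing_mm)
    d = np.linalg.norm(phys - center, axis=1)
    inside = d <= radius_mm
    idx = grid[inside]
    dist = d[inside]
    order = np.argsort(dist, kind="mergesort")
    return idx[order], dist[order]


def _partition_habitats(n_voxels: int, fractions: np.ndarray) -> np.ndarray:
    """Habitat label (1..3) per sorted voxel: rim = 1, core = 3."""
    counts = np.floor(fractions * n_voxels).astype(int)
    while counts.sum() < n_voxels:
        counts[np.argmax(fractions * n_voxels - counts)] += 1
    labels = np.empty(n_voxels, dtype=int)
    # innermost voxels are poor perfusion (3), outermost high (1)
    stop3 = counts[2]
    stop2 = counts[2] + counts[1]
    labels[:stop3] = 3
    labels[stop3:stop2] = 2
    labels[stop2:] = 1
    return labels


def _build_timepoint(
    spec: PhantomSpec,
    radius_mm: float,
    fractions: np.ndarray,
    center: np.ndarray,
    rng: np.random.Generator,
) -> SubjectImaging:
    idx, _ = _sphere_voxels(spec, radius_mm, center)
    n = len(idx)
    if n == 0:
        raise ValueError("degenerate post lesion: no tumor voxels remain")
    mask = np.zeros(spec.grid_shape, dtype=bool)
    mask[tuple(idx.T)] = True

    hab = _partition_habitats(n, fractions)
    labels = np.zeros(spec.grid_shape, dtype=int)
    labels[tuple(idx.T)] = hab
    truth_perf = HabitatMask(labels=labels, scheme="perfusion3", spacing_mm=spec.spacing_mm)

    times = np.arange(spec.n_timepoints) * spec.frame_interval_s
    data = np.zeros(spec.grid_shape + (spec.n_timepoints,), dtype=float)
    # breast background: weakly enhancing tissue
    bg = 50.0 + 5.0 * (1 - np.exp(-times / 300.0))
    data[...] = bg
    for h, arch in enumerate(spec.kinetic_archetypes, start=1):
        sel = idx[hab == h]
        if len(sel) == 0:
            continue
        ttp = arch["time_to_peak_s"]
        rise = np.clip(times / ttp, 0, 1)
        decay = 1.0 - arch["washout_rate"] * np.clip(times - ttp, 0, None)
        curve = arch["baseline"] + arch["amplitude"] * rise * np.clip(decay, 0, None)
        data[sel[:, 0], sel[:, 1], sel[:, 2], :] = curve
    if spec.noise_sd > 0:
        data = data + rng.normal(0, spec.noise_sd, size=data.shape)
        data = np.clip(data, 1.0, None)
    dce = DCESeries(data=data, spacing_mm=spec.spacing_mm, times_s=times, baseline_index=0)

    # two-level cellularity: low-ADC (high cellularity) core by voxel count
    n_high = int(round(spec.high_cellularity_fraction * n))
    cell = np.zeros(spec.grid_shape, dtype=int)
    cell[tuple(idx[:n_high].T)] = 1  # innermost voxels: high cellularity
    cell[tuple(idx[n_high:].T)] = 2
    truth_cell = HabitatMask(labels=cell, scheme="cellularity2", spacing_mm=spec.spacing_mm)

    adc = np.full(spec.grid_shape, spec.adc_levels[1] + 0.4)  # normal tissue
    adc[cell == 1] = spec.adc_levels[0]
    adc[cell == 2] = spec.adc_levels[1]
    if spec.adc_noise_sd > 0:
        adc = adc + rng.normal(0, spec.adc_noise_sd, size=adc.shape)
    adc = np.clip(adc, 1e-4, None)  # ADC is physically nonnegative

    return SubjectImaging(
        dce=dce, adc=adc, mask=mask, truth_perfusion=truth_perf, truth_cellularity=truth_cell
    )


def simulate_imaging_pair(
    spec: PhantomSpec, change: HabitatChange
) -> tuple[SubjectImaging, SubjectImaging]:
    """Voxel-aligned pre/post phantom pair with planted habitat change.

    The post lesion's per-habitat voxel counts are the pre counts scaled
    by ``change.volume_scale``; its radius is chosen to match the new
    total volume and its fractions renormalized accordingly. Raises when
    every habitat is removed ("degenerate post lesion").
    """
    rng = np.random.default_rng(spec.seed)
    center = np.array(
        [s * (n - 1) / 2 for s, n in zip(spec.spacing_mm, spec.grid_shape)]
    )
    fractions = np.asarray(spec.habitat_fractions, dtype=float)
    pre = _build_timepoint(spec, spec.tumor_radius_mm, fractions, center, rng)

    n_pre = int(pre.mask.sum())
    pre_counts = fractions * n_pre
    post_counts = pre_counts * np.asarray(change.volume_scale, dtype=float)
    n_post = post_counts.sum()
    if n_post < 1:
        raise ValueError("degenerate post lesion: requested change removes the tumor")
    post_fractions = post_counts / n_post
    # radius matching the target voxel count under the pre-lesion density
    post_radius = spec.tumor_radius_mm * (n_post / n_pre) ** (1 / 3)
    post_center = center.copy()
    if change.non_concentric:
        shift = (spec.tumor_radius_mm - post_radius) * 0.8
        post_center[0] += shift
    post = _build_timepoint(spec, post_radius, post_fractions, post_center, rng)
    return pre, post


#: planted response effects of the effectful study condition: pCR is more
#: likely with a larger high-perfusion share and a smaller tumor, more
#: likely under high Ki-67 and less likely with diffuse breast edema
EFFECTFUL_PCR_COEFFICIENTS = {
    "hps_fraction": 30.0,
    "tumor_volume_mm3": -0.003,
    "ki67_high": 1.0,
    "edema_diffuse": -1.0,
}

#: planted prognosis effects: recurrence hazard grows with on-treatment
#: expansion of the moderate-perfusion subregion, high Ki-67 and a
#: non-concentric shrinkage pattern
EFFECTFUL_DFS_COEFFICIENTS = {
    "delta_mps_volume_mm3": 0.006,
    "ki67_high": 0.6,
    "nonconcentric_shrinkage": 0.7,
}


@dataclass
class CohortSpec:
    """Population structure of a synthetic cohort."""

    n_subjects: int = 300
    pcr_prevalence: float = 0.15
    pcr_coefficients: dict = field(default_factory=dict)
    dfs_coefficients: dict = field(default_factory=dict)
    baseline_hazard_shape: float = 1.2  # Weibull shape
    baseline_hazard_scale: float = 12.0  # Weibull scale, years
    censoring_rate: float = 0.7
    followup_years: float = 7.0
    covariate_scheme: dict = field(
        default_factory=lambda: {
            "edema_diffuse": 0.25,
            "nonconcentric_shrinkage": 0.4,
            "t_stage_high": 0.8,
            "n_stage_high": 0.8,
            "ki67_high": 0.17,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.pcr_prevalence < 1:
            raise ValueError("pcr_prevalence must be in (0, 1)")
        if not 0 <= self.censoring_rate <= 1:
            raise ValueError("censoring_rate must be in [0, 1]")


def _calibrate_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Bisection on b0 so that mean(sigmoid(b0 + eta)) == prevalence."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if np.mean(1 / (1 + np.exp(-(mid + eta)))) < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _linear_predictor(features: pd.DataFrame, coefficients: dict) -> np.ndarray:
    missing = [k for k in coefficients if k not in features.columns]
    if missing:
        raise ValueError(f"coefficient(s) reference missing feature column(s): {missing}")
    eta = np.zeros(len(features))
    for name, beta in coefficients.items():
        eta += beta * features[name].to_numpy(dtype=float)
    return eta


def simulate_outcomes(features: pd.DataFrame, spec: CohortSpec) -> pd.DataFrame:
    """pCR labels and DFS times from planted effects on feature columns.

    pCR ~ Bernoulli(logistic(b0 + X beta)) with b0 calibrated by
    bisection to the target prevalence. DFS event times follow a Weibull
    proportional-hazards model; censoring combines an exponential
    censoring process (rate calibrated to the target censored fraction)
    with administrative censoring at ``followup_years``.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(features)

    eta_p = _linear_predictor(features, spec.pcr_coefficients)
    b0 = _calibrate_intercept(eta_p, spec.pcr_prevalence)
    p = 1 / (1 + np.exp(-(b0 + eta_p)))
    pcr = rng.binomial(1, p)

    eta_h = _linear_predictor(features, spec.dfs_coefficients)
    u = rng.uniform(size=n)
    shape, scale = spec.baseline_hazard_shape, spec.baseline_hazard_scale
    T = scale * (-np.log(u) / np.exp(eta_h)) ** (1 / shape)

    if spec.censoring_rate >= 1.0:
        time = rng.uniform(0.1, spec.followup_years, size=n)
        event = np.zeros(n, dtype=int)
    else:
        uc = rng.uniform(size=n)
        admin_frac = np.mean(T > spec.followup_years)

        def censored_fraction(lam: float) -> float:
            C = np.minimum(-np.log(uc) / lam if lam > 0 else np.inf, spec.followup_years)
            return float(np.mean(C < T))

        if spec.censoring_rate <= admin_frac or spec.censoring_rate == 0:
            lam = 0.0
        else:
            lo, hi = 1e-6, 50.0
            for _ in range(100):
                mid = np.sqrt(lo * hi)
                if censored_fraction(mid) < spec.censoring_rate:
                    lo = mid
                else:
                    hi = mid
            lam = np.sqrt(lo * hi)
        C = np.minimum(-np.log(uc) / lam if lam > 0 else np.inf, spec.followup_years)
        time = np.minimum(T, C)
        event = (T <= C).astype(int)
    time = np.maximum(time, 1e-6)
    return pd.DataFrame(
        {"pcr": pcr, "time": time, "event": event}, index=features.index
    )


def simulate_expression(
    risk_labels: np.ndarray,
    gene_sets: dict[str, list[str]],
    n_genes: int = 2000,
    planted: dict[str, float] | None = None,
    seed: int = 0,
    noise_sd: float = 0.5,
) -> tuple[ExpressionStudy, GeneSetCollection]:
    """Log2 expression matrix with planted gene-program shifts.

    Background genes share a log-normal intensity model (gene-level mean
    ~ N(7, 1) on the log2 scale, sample noise ``noise_sd``); genes in a
    planted set gain the stated log2 shift in high-risk samples.
    """
    risk = np.asarray(risk_labels).astype(int)
    if len(np.unique(risk)) < 2:
        raise ValueError("degenerate contrast: all samples share one risk label")
    planted = planted or {}
    for s in planted:
        if s not in gene_sets:
            raise ValueError(f"planted shift references unknown gene set {s!r}")
    set_genes: list[str] = []
    seen = set()
    for genes in gene_sets.values():
        for g in genes:
            if g not in seen:
                seen.add(g)
                set_genes.append(g)
    if n_genes < len(set_genes):
        raise ValueError("n_genes smaller than the union of gene-set members")
    background = [f"bg{i:05d}" for i in range(n_genes - len(set_genes))]
    genes = set_genes + background

    rng = np.random.default_rng(seed)
    n_samples = len(risk)
    mu = rng.normal(7.0, 1.0, size=n_genes)
    X = mu[:, None] + rng.normal(0, noise_sd, size=(n_genes, n_samples))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for set_name, shift in planted.items():
        rows = [gene_pos[g] for g in gene_sets[set_name]]
        X[np.ix_(rows, np.flatnonzero(risk == 1))] += shift
    expr = pd.DataFrame(X, index=genes, columns=[f"s{j:04d}" for j in range(n_samples)])
    study = ExpressionStudy(expr=expr, group=risk)
    coll = GeneSetCollection(sets=dict(gene_sets), universe=genes)
    return study, coll


# ---------------------------------------------------------------------------
# cohort-level generation


def study_phantom_spec(seed: int = 0) -> PhantomSpec:
    """Phantom geometry used by the cohort studies (28 mm grid, 7 mm tumor)."""
    return PhantomSpec(grid_shape=(28, 28, 28), tumor_radius_mm=7.0, seed=seed)


def effectful_cohort_spec(n_subjects: int = 300, seed: int = 0) -> CohortSpec:
    """Study condition with the planted habitat and temporal effects."""
    return CohortSpec(
        n_subjects=n_subjects,
        pcr_prevalence=0.15,
        pcr_coefficients=dict(EFFECTFUL_PCR_COEFFICIENTS),
        dfs_coefficients=dict(EFFECTFUL_DFS_COEFFICIENTS),
        seed=seed,
    )


def null_cohort_spec(n_subjects: int = 300, seed: int = 0) -> CohortSpec:
    """Study condition with no planted effects (calibration runs)."""
    return CohortSpec(
        n_subjects=n_subjects,
        pcr_prevalence=0.15,
        pcr_coefficients={},
        dfs_coefficients={},
        seed=seed,
    )


def _subject_rng(seed: int, subject: int) -> np.random.Generator:
    return np.random.default_rng([seed, subject])


def simulate_subject(
    pspec: PhantomSpec, cspec: CohortSpec, subject: int
) -> tuple[SubjectImaging, SubjectImaging, dict]:
    """One subject's pre/post imaging plus emitted summary features.

    Subject-level variability: lognormal tumor radius, Dirichlet habitat
    fractions around the phantom spec, and an independent per-habitat
    response multiplier driving the planted longitudinal change.
    """
    rng = _subject_rng(cspec.seed, subject)
    radius = float(pspec.tumor_radius_mm * np.exp(rng.normal(0, 0.10)))
    half_extent = min(s * n / 2 for s, n in zip(pspec.spacing_mm, pspec.grid_shape))
    radius = min(radius, 0.95 * half_extent - 5.0 / 2)  # leave ring headroom
    fractions = rng.dirichlet(np.asarray(pspec.habitat_fractions) * 25.0)

    cov = {}
    for name, prob in cspec.covariate_scheme.items():
        cov[name] = int(rng.uniform() < prob)

    overall = rng.uniform(0.35, 1.05)
    per_hab = overall * rng.uniform(0.6, 1.4, size=3)
    change = HabitatChange(
        volume_scale=tuple(np.clip(per_hab, 0.05, None)),
        non_concentric=bool(cov.get("nonconcentric_shrinkage", 0)),
    )
    sspec = PhantomSpec(
        grid_shape=pspec.grid_shape,
        spacing_mm=pspec.spacing_mm,
        tumor_radius_mm=radius,
        habitat_fractions=tuple(fractions),
        kinetic_archetypes=pspec.kinetic_archetypes,
        adc_levels=pspec.adc_levels,
        high_cellularity_fraction=pspec.high_cellularity_fraction,
        noise_sd=pspec.noise_sd,
        adc_noise_sd=pspec.adc_noise_sd,
        n_timepoints=pspec.n_timepoints,
        frame_interval_s=pspec.frame_interval_s,
        seed=int(rng.integers(2**31)),
    )
    pre, post = simulate_imaging_pair(sspec, change)

    vvol = float(np.prod(pspec.spacing_mm))
    row: dict[str, float] = {}
    n_pre = int(pre.mask.sum())
    n_post = int(post.mask.sum())
    row["tumor_volume_mm3"] = n_pre * vvol
    for lab, name in ((1, "hps"), (2, "mps"), (3, "pps")):
        pre_v = int((pre.truth_perfusion.labels == lab).sum()) * vvol
        post_v = int((post.truth_perfusion.labels == lab).sum()) * vvol
        row[f"{name}_fraction"] = pre_v / (n_pre * vvol)
        row[f"{name}_volume_mm3"] = pre_v
        row[f"delta_{name}_volume_mm3"] = post_v - pre_v
    row["delta_tumor_volume_mm3"] = (n_post - n_pre) * vvol
    row.update(cov)
    return pre, post, row


def simulate_cohort_tables(
    pspec: PhantomSpec, cspec: CohortSpec, keep_images: bool = True
):
    """Generate a full in-memory cohort.

    Returns (subjects, clinical, outcomes): ``subjects`` is a list of
    (pre, post) :class:`SubjectImaging` pairs (or None when
    ``keep_images`` is off), ``clinical`` the emitted summary-feature +
    covariate table and ``outcomes`` the planted pCR/DFS table.
    """
    subjects = []
    rows = []
    for i in range(cspec.n_subjects):
        pre, post, row = simulate_subject(pspec, cspec, i)
        subjects.append((pre, post) if keep_images else None)
        rows.append(row)
    clinical = pd.DataFrame(rows, index=[f"sub{i:04d}" for i in range(cspec.n_subjects)])
    outcomes = simulate_outcomes(clinical, cspec)
    return subjects, clinical, outcomes


def simulate_cohort(
    pspec: PhantomSpec, cspec: CohortSpec, out_dir, overwrite: bool = False
) -> Path:
    """Write a complete synthetic cohort to disk (NIfTI + CSV + manifest).

    Refuses to clobber an existing manifest unless ``overwrite`` is set.
    Returns the manifest path.
    """
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True to replace")

    subjects, clinical, outcomes = simulate_cohort_tables(pspec, cspec)
    records = []
    affine = np.diag(list(pspec.spacing_mm) + [1.0])
    for sid, (pre, post) in zip(clinical.index, subjects):
        rec = {"subject": sid}
        for tp, img in (("pre", pre), ("post", post)):
            paths = {
                "dce": out / f"{sid}_{tp}_dce.nii.gz",
                "adc": out / f"{sid}_{tp}_adc.nii.gz",
                "mask": out / f"{sid}_{tp}_mask.nii.gz",
                "habitats": out / f"{sid}_{tp}_habitats.nii.gz",
            }
            nib.save(nib.Nifti1Image(img.dce.data.astype(np.float32), affine), paths["dce"])
            nib.save(nib.Nifti1Image(img.adc.astype(np.float32), affine), paths["adc"])
            nib.save(nib.Nifti1Image(img.mask.astype(np.uint8), affine), paths["mask"])
            nib.save(
                nib.Nifti1Image(img.truth_perfusion.labels.astype(np.uint8), affine),
                paths["habitats"],
            )
            rec[tp] = {k: str(v.name) for k, v in paths.items()}
        rec["times_s"] = [float(t) for t in pre.dce.times_s]
        records.append(rec)

    clinical.to_csv(out / "clinical.csv")
    outcomes.to_csv(out / "outcomes.csv")
    manifest = {
        "n_subjects": cspec.n_subjects,
        "spacing_mm": list(pspec.spacing_mm),
        "clinical": "clinical.csv",
        "outcomes": "outcomes.csv",
        "subjects": records,
        "phantom_spec": {
            **{k: v for k, v in asdict(pspec).items() if k != "kinetic_archetypes"},
        },
        "cohort_seed": cspec.seed,
    }
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def load_cohort(manifest_path):
    """Round-trip reader for :func:`simulate_cohort` output."""
    import nibabel as nib

    manifest_path = Path(manifest_path)
    man = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    clinical = pd.read_csv(root / man["clinical"], index_col=0)
    outcomes = pd.read_csv(root / man["outcomes"], index_col=0)
    spacing = tuple(man["spacing_mm"])
    subjects = []
    for rec in man["subjects"]:
        pair = []
        for tp in ("pre", "post"):
            p = rec[tp]
            data = np.asarray(nib.load(root / p["dce"]).dataobj, dtype=float)
            adc = np.asarray(nib.load(root / p["adc"]).dataobj, dtype=float)
            mask = np.asarray(nib.load(root / p["mask"]).dataobj).astype(bool)
            hab = np.asarray(nib.load(root / p["habitats"]).dataobj).astype(int)
            dce = DCESeries(
                data=data,
                spacing_mm=spacing,
                times_s=np.asarray(rec["times_s"], dtype=float),
            )
            cell = HabitatMask(labels=np.zeros_like(hab), scheme="cellularity2", spacing_mm=spacing)
            pair.append(
                SubjectImaging(
                    dce=dce,
                    adc=adc,
                    mask=mask,
                    truth_perfusion=HabitatMask(hab, "perfusion3", spacing),
                    truth_cellularity=cell,
                )
            )
        subjects.append(tuple(pair))
    return subjects, clinical, outcomes
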
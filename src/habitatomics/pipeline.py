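"""End-to-end studies: response (pCR) and prognosis (DFS) on a cohort.

``run_response_study`` executes kinetics -> habitat clustering ->
subregion/peritumoral feature extraction (pre-treatment only) ->
selection -> SMOTE + boosted fit -> held-out evaluation -> RadScore-
adjusted multivariable logistic regression.

``run_prognosis_study`` restricts to non-pCR subjects, extracts pre,
post and delta features, fits four radiomic variants (pre-only,
post-only, delta-only, multitemporal) under the Cox objective, and
reports C-indices, Kaplan-Meier/log-rank stratification by RadScore
group and the RadScore-adjusted multivariable Cox model.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as ft
from .habitats import cluster_perfusion, peritumoral_ring, threshold_cellularity
from .models import (
    ModelBundle,
    evaluate,
    fit_boosted,
    km_logrank,
    multivariable_adjusted,
    smote_oversample,
    youden_cutoff,
)
from .preprocess import compute_kinetic_maps
from .selection import (
    SelectionConfig,
    cox_score_filter,
    spearman_prune,
    stability_select,
    univariable_screen,
    wilcoxon_filter,
)
from .synth import SubjectImaging

__version__ = "0.1.0"

#: covariate columns treated as clinical/conventional-MRI variables
DEFAULT_COVARIATES = (
    "edema_diffuse",
    "nonconcentric_shrinkage",
    "t_stage_high",
    "n_stage_high",
    "ki67_high",
)


@dataclass
class StudyConfig:
    """Resolved configuration of one study run (serialized for provenance)."""

    seed: int = 0
    test_fraction: float = 0.4
    families: tuple[str, ...] = ("shape", "firstorder", "glcm", "glszm", "gldm")
    dce_regions: tuple[str, ...] = ("tumor", "hps", "mps", "pps", "peri")
    adc_regions: tuple[str, ...] = ("tumor", "highcell", "lowcell")
    bin_width_dce: float = 25.0
    bin_width_adc: float = 0.05  # ADC in x1e-3 mm^2/s units
    ring_radius_mm: float = 5.0
    kmeans_n_init: int = 10
    min_region_voxels: int = 10
    min_signature_size: int = 7
    n_boot: int = 200
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    covariates: tuple[str, ...] = DEFAULT_COVARIATES

    def to_json(self) -> dict:
        d = asdict(self)
        return d


def _region_masks(img: SubjectImaging, config: StudyConfig, seed: int):
    """Named subregion masks computed from the images (never from truth)."""
    kmaps = compute_kinetic_maps(img.dce, img.mask)
    perf = cluster_perfusion(kmaps, k=3, n_init=config.kmeans_n_init, seed=seed)
    cell = threshold_cellularity(img.adc, img.mask, img.dce.spacing_mm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ring = peritumoral_ring(img.mask, img.dce.spacing_mm, config.ring_radius_mm)
    dce_regions = {
        "tumor": img.mask,
        "hps": perf.labels == 1,
        "mps": perf.labels == 2,
        "pps": perf.labels == 3,
        "peri": ring.labels == ring.labels.max() if ring.labels.any() else ring.labels > 0,
    }
    adc_regions = {
        "tumor": img.mask,
        "highcell": cell.labels == 1,
        "lowcell": cell.labels == 2,
    }
    return dce_regions, adc_regions


def extract_subject_features(
    img: SubjectImaging, timepoint: str, config: StudyConfig, seed: int = 0
) -> dict[str, float]:
    """Radiomic features of one subject at one timepoint, fully named.

    DCE features are taken from the first post-contrast frame; ADC
    features from the ADC map. Regions smaller than
    ``config.min_region_voxels`` yield NaN (dropped cohort-wide later).
    """
    dce_img = img.dce.data[..., img.dce.baseline_index + 1]
    spacing = img.dce.spacing_mm
    dce_regions, adc_regions = _region_masks(img, config, seed)
    out: dict[str, float] = {}
    jobs = [("dce", dce_img, config.bin_width_dce, config.dce_regions, dce_regions)]
    if config.adc_regions:
        jobs.append(("adc", img.adc, config.bin_width_adc, config.adc_regions, adc_regions))
    tumor_vox = max(int(img.mask.sum()), 1)
    for seq, image, bw, wanted, masks in jobs:
        for region in wanted:
            mask = masks[region]
            if mask.sum() < config.min_region_voxels:
                continue  # cohort-wide column alignment fills NaN
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vals = ft.extract_region_features(
                    image, mask, spacing,
                    families=config.families,
                    bin_width=bw,
                )
            if region != "tumor":
                # canonical habitat-analysis summary: subregion volume share
                vals["VolumeFraction"] = float(mask.sum()) / tumor_vox
            for name, v in vals.items():
                out[ft.full_name(name, timepoint, seq, region)] = v
    return out


def build_feature_table(
    subjects: list,
    config: StudyConfig,
    timepoints: tuple[str, ...] = ("pre",),
    with_delta: bool = False,
) -> pd.DataFrame:
    """Cohort feature table over the requested timepoints (+ delta).

    Delta columns are post minus pre for every matched feature name.
    Columns with any missing or non-finite value are dropped (no silent
    NaN propagation into the models).
    """
    rows = []
    for i, pair in enumerate(subjects):
        pre, post = pair
        row: dict[str, float] = {}
        if "pre" in timepoints:
            row.update(extract_subject_features(pre, "pre", config, seed=config.seed))
        if "post" in timepoints:
            if post is None:
                raise ValueError(f"subject index {i}: missing post-treatment imaging")
            row.update(extract_subject_features(post, "post", config, seed=config.seed))
        rows.append(row)
    table = pd.DataFrame(rows)
    if with_delta:
        deltas = {}
        for c in table.columns:
            if not c.startswith("pre_"):
                continue
            pc = "post_" + c[len("pre_"):]
            if pc in table.columns:
                deltas["delta_" + c[len("pre_"):]] = table[pc] - table[c]
        table = pd.concat([table, pd.DataFrame(deltas)], axis=1)
    bad = table.columns[~np.isfinite(table).all(axis=0)]
    if len(bad):
        table = table.drop(columns=bad)
    return table


def stratified_split(labels: np.ndarray, test_fraction: float, seed: int):
    """Stratified train/test indices (fixed-seed shuffle within class)."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    train, test = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_test = int(round(test_fraction * len(idx)))
        test.extend(idx[:n_test])
        train.extend(idx[n_test:])
    return np.sort(np.array(train)), np.sort(np.array(test))


def _zscore_by_train(table: pd.DataFrame, train_idx: np.ndarray) -> pd.DataFrame:
    mu = table.iloc[train_idx].mean()
    sd = table.iloc[train_idx].std().replace(0, 1.0)
    return (table - mu) / sd


def _pad_signature(selected: list[str], freq: pd.Series, k: int) -> list[str]:
    """Stability-selected features padded to a minimum signature size.

    Radiomic signatures in this setting typically carry 5-10 features; a
    too-small stability-selected set is extended by descending selection
    frequency so the boosted model is not starved of signal.
    """
    if len(selected) >= k:
        return list(selected)
    ranked = [c for c in freq.sort_values(ascending=False, kind="mergesort").index]
    out = list(selected)
    for c in ranked:
        if len(out) >= k:
            break
        if c not in out and freq[c] > 0:
            out.append(c)
    return out


def _most_separated(radscore, covariates: pd.DataFrame, y) -> str:
    """Covariate whose unpenalized logistic coefficient diverges hardest."""
    import statsmodels.api as sm

    X = covariates.copy()
    X.insert(0, "radscore", np.asarray(radscore, dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(np.asarray(y, dtype=float), sm.add_constant(X)).fit(
                disp=0, maxiter=200
            )
            coefs = res.params.drop(["const", "radscore"], errors="ignore").abs()
        except Exception:
            return covariates.columns[0]
    return str(coefs.idxmax())


def run_response_study(
    subjects: list,
    clinical: pd.DataFrame,
    outcomes: pd.DataFrame,
    config: StudyConfig | None = None,
    split: tuple[np.ndarray, np.ndarray] | None = None,
    feature_table: pd.DataFrame | None = None,
) -> dict:
    """Pre-treatment response (pCR) study; returns the full report dict.

    ``split`` overrides the stratified 60/40 train/test split (useful for
    leakage audits); ``feature_table`` short-circuits extraction when the
    caller already holds one for these subjects.
    """
    config = config or StudyConfig()
    y = outcomes["pcr"].to_numpy().astype(int)
    if feature_table is None:
        feature_table = build_feature_table(subjects, config, timepoints=("pre",))
    table = feature_table
    if split is None:
        train_idx, test_idx = stratified_split(y, config.test_fraction, config.seed)
    else:
        train_idx, test_idx = split

    tz = _zscore_by_train(table, train_idx)
    Xtr, ytr = tz.iloc[train_idx], y[train_idx]

    kept_w, pvals = wilcoxon_filter(Xtr, ytr, config.selection.wilcoxon_alpha)
    if not kept_w:
        kept_w = list(pvals.sort_values().head(10).index)
    priority = -pvals[kept_w]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kept_s = spearman_prune(Xtr[kept_w], config.selection.spearman_threshold, priority)
    sel_cfg = config.selection
    selected, freq = stability_select(Xtr[kept_s], ytr, "binary", sel_cfg)
    selected = _pad_signature(selected, freq, config.min_signature_size)
    if not selected:
        selected = list(freq.sort_values(ascending=False).head(3).index)

    Xb, yb = smote_oversample(Xtr[selected], ytr, k=5, seed=config.seed)
    bundle = fit_boosted(Xb, yb, "binary", seed=config.seed)

    rad_train = bundle.radscore(tz.iloc[train_idx][selected])
    rad_test = bundle.radscore(tz.iloc[test_idx][selected])

    # out-of-fold training RadScores: in-sample boosted scores separate the
    # training labels almost perfectly, which would make the adjusted
    # logistic model degenerate and the cutoff meaningless
    from sklearn.model_selection import StratifiedKFold

    rad_train_oof = np.empty(len(train_idx))
    skf = StratifiedKFold(5, shuffle=True, random_state=config.seed)
    for tr2, va2 in skf.split(Xtr[selected], ytr):
        Xf, yf = smote_oversample(Xtr[selected].iloc[tr2], ytr[tr2], k=5, seed=config.seed)
        bf = fit_boosted(Xf, yf, "binary", seed=config.seed, tune=False)
        rad_train_oof[va2] = bf.radscore(Xtr[selected].iloc[va2])

    cutoff, youden = youden_cutoff(rad_train_oof, ytr)
    bundle.radscore_cutoff = cutoff

    auc_train = evaluate(rad_train, ytr, "auc", n_boot=config.n_boot, seed=config.seed)
    auc_train_cv = evaluate(rad_train_oof, ytr, "auc", n_boot=config.n_boot, seed=config.seed)
    auc_test = evaluate(rad_test, y[test_idx], "auc", n_boot=config.n_boot, seed=config.seed)

    covars = [c for c in config.covariates if c in clinical.columns]
    cov_train = clinical.iloc[train_idx][covars].astype(float)
    cov_test = clinical.iloc[test_idx][covars].astype(float)
    screened, cov_p = univariable_screen(cov_train, ytr, "binary", config.selection.clinical_screen_alpha)
    adj_covars = screened or covars[:2]
    auc_comb = None
    try:
        mv = None
        while True:
            try:
                mv = multivariable_adjusted(rad_train_oof, cov_train[adj_covars], ytr, "binary")
                break
            except ValueError:
                # quasi-separated covariate (e.g. a zero-count cell): drop the
                # worst offender and refit; keep RadScore always
                if not adj_covars:
                    raise
                drop = _most_separated(rad_train_oof, cov_train[adj_covars], ytr)
                adj_covars = [c for c in adj_covars if c != drop]
        mv_report = {
            "radscore_OR": float(mv.loc["radscore", "OR"]),
            "radscore_p": float(mv.loc["radscore", "p"]),
            "table": mv.to_dict(),
        }
        # combined model: linear predictor of the adjusted logistic fit
        import statsmodels.api as sm

        Xc_tr = sm.add_constant(
            pd.concat(
                [pd.Series(rad_train_oof, name="radscore", index=cov_train.index), cov_train[adj_covars]],
                axis=1,
            )
        )
        fit = sm.Logit(ytr.astype(float), Xc_tr).fit(disp=0, maxiter=200)
        Xc_te = sm.add_constant(
            pd.concat(
                [pd.Series(rad_test, name="radscore", index=cov_test.index), cov_test[adj_covars]],
                axis=1,
            ),
            has_constant="add",
        )[Xc_tr.columns]
        pred_comb = np.asarray(fit.predict(Xc_te))
        auc_comb = evaluate(pred_comb, y[test_idx], "auc", n_boot=config.n_boot, seed=config.seed)
    except Exception as exc:  # separation / singular design on small cohorts
        mv_report = {"error": str(exc)}

    report = {
        "task": "response",
        "package_version": __version__,
        "config": config.to_json(),
        "n_subjects": len(table),
        "n_train": int(len(train_idx)),
        "n_test": int(len(test_idx)),
        "n_features_extracted": int(table.shape[1]),
        "n_after_wilcoxon": len(kept_w),
        "n_after_spearman": len(kept_s),
        "selected_features": selected,
        "selection_frequency": {k: float(freq[k]) for k in selected},
        "radscore_cutoff": float(cutoff),
        "youden_index": float(youden),
        "auc_train": auc_train,
        "auc_train_cv": auc_train_cv,
        "auc_test": auc_test,
        "auc_test_combined": auc_comb,
        "covariate_screen_p": {k: float(v) for k, v in cov_p.items()},
        "multivariable": mv_report,
        "feature_table_sha256": hashlib.sha256(
            table.round(10).to_csv().encode()
        ).hexdigest(),
    }
    report["_bundle"] = bundle
    report["_radscores"] = {"train": rad_train, "test": rad_test}
    report["_split"] = (train_idx, test_idx)
    return report


def _fit_cox_variant(
    table: pd.DataFrame,
    cols: list[str],
    surv: pd.DataFrame,
    train_idx,
    test_idx,
    config: StudyConfig,
    preselected: list[str] | None = None,
) -> tuple[ModelBundle, dict, np.ndarray, np.ndarray]:
    tz = _zscore_by_train(table[cols], np.asarray(train_idx))
    Xtr = tz.iloc[train_idx]
    str_ = surv.iloc[train_idx]
    if preselected is not None:
        selected = list(preselected)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kept_u, pvals = cox_score_filter(Xtr, str_, config.selection.wilcoxon_alpha)
            if not kept_u:
                kept_u = list(pvals.sort_values().head(10).index)
            kept = spearman_prune(
                Xtr[kept_u], config.selection.spearman_threshold, -pvals[kept_u]
            )
            selected, freq = stability_select(Xtr[kept], str_, "cox", config.selection)
            selected = _pad_signature(selected, freq, config.min_signature_size)
        if not selected:
            selected = list(freq.sort_values(ascending=False).head(3).index)
    bundle = fit_boosted(Xtr[selected], str_, "cox", seed=config.seed)
    rad_te = bundle.radscore(tz.iloc[test_idx][selected])

    # out-of-fold training RadScores (in-sample Cox risks overfit and would
    # inflate the adjusted hazard ratio and the KM cutoff)
    from sklearn.model_selection import StratifiedKFold

    rad_tr_oof = np.empty(len(train_idx))
    skf = StratifiedKFold(5, shuffle=True, random_state=config.seed)
    ev_tr = str_["event"].to_numpy()
    for tr2, va2 in skf.split(Xtr[selected], ev_tr):
        if ev_tr[tr2].sum() == 0:
            rad_tr_oof[va2] = 0.5
            continue
        bf = fit_boosted(
            Xtr[selected].iloc[tr2], str_.iloc[tr2], "cox", seed=config.seed, tune=False
        )
        rad_tr_oof[va2] = bf.radscore(Xtr[selected].iloc[va2])
    ste = surv.iloc[test_idx]
    ci = evaluate(rad_te, ste, "cindex", n_boot=config.n_boot, seed=config.seed)
    return bundle, {"cindex_test": ci, "selected_features": selected}, rad_tr_oof, rad_te


def run_prognosis_study(
    subjects: list,
    clinical: pd.DataFrame,
    outcomes: pd.DataFrame,
    config: StudyConfig | None = None,
    feature_table: pd.DataFrame | None = None,
) -> dict:
    """Prognosis (DFS) study on the non-pCR subset; returns the report dict.

    Fits pre-only, post-only, delta-only and multitemporal Cox-objective
    boosted models, stratifies subjects by the training-median RadScore
    for Kaplan-Meier/log-rank, and adjusts the multitemporal RadScore for
    clinical covariates in a multivariable Cox model.
    """
    config = config or StudyConfig()
    pcr = outcomes["pcr"].to_numpy().astype(int)
    keep = np.flatnonzero(pcr == 0)
    n_dropped = int((pcr == 1).sum())
    if n_dropped:
        warnings.warn(f"excluded {n_dropped} pCR subject(s) from prognosis modelling")
    subjects = [subjects[i] for i in keep]
    clinical = clinical.iloc[keep].reset_index(drop=True)
    surv = outcomes.iloc[keep][["time", "event"]].reset_index(drop=True)
    if surv["event"].sum() < 1:
        raise ValueError("no events among non-pCR subjects")

    if feature_table is None:
        feature_table = build_feature_table(
            subjects, config, timepoints=("pre", "post"), with_delta=True
        )
    table = feature_table
    train_idx, test_idx = stratified_split(
        surv["event"].to_numpy(), config.test_fraction, config.seed
    )

    variants = {
        "pre": [c for c in table.columns if c.startswith("pre_")],
        "post": [c for c in table.columns if c.startswith("post_")],
        "delta": [c for c in table.columns if c.startswith("delta_")],
    }
    results = {}
    radscores = {}
    for name, cols in variants.items():
        bundle, res, rad_tr, rad_te = _fit_cox_variant(
            table, cols, surv, train_idx, test_idx, config
        )
        results[name] = res
        radscores[name] = (rad_tr, rad_te)
    # multitemporal model: re-run stability selection over the pooled
    # per-timepoint signatures so the strongest temporal features dominate
    union = sorted(
        set().union(*(results[v]["selected_features"] for v in variants))
    )
    bundle, res, rad_tr, rad_te = _fit_cox_variant(
        table, union, surv, train_idx, test_idx, config
    )
    results["multitemporal"] = res
    radscores["multitemporal"] = (rad_tr, rad_te)

    # Kaplan-Meier stratification over the whole non-pCR cohort: training
    # subjects enter with their out-of-fold RadScores, test subjects with
    # the fitted model's scores, split at the training-median cutoff
    rad_tr, rad_te = radscores["multitemporal"]
    cutoff = float(np.median(rad_tr))
    rad_all = np.empty(len(surv))
    rad_all[np.asarray(train_idx)] = rad_tr
    rad_all[np.asarray(test_idx)] = rad_te
    groups_all = (rad_all >= cutoff).astype(int)
    try:
        km = km_logrank(surv["time"], surv["event"], groups_all)
        km_report = {"chi2": km["chi2"], "p": km["p"]}
        km_te = km_logrank(
            surv.iloc[test_idx]["time"],
            surv.iloc[test_idx]["event"],
            (rad_te >= cutoff).astype(int),
        )
        km_report["p_test"] = km_te["p"]
    except ValueError as exc:
        km_report = {"error": str(exc)}

    covars = [c for c in config.covariates if c in clinical.columns]
    cov_train = clinical.iloc[train_idx][covars].astype(float)
    screened, cov_p = univariable_screen(
        cov_train, surv.iloc[train_idx], "cox", config.selection.clinical_screen_alpha
    )
    adj = screened or covars[:2]
    try:
        mv = multivariable_adjusted(
            rad_tr, cov_train[adj], surv.iloc[train_idx], "cox"
        )
        mv_report = {
            "radscore_HR": float(mv.loc["radscore", "HR"]),
            "radscore_p": float(mv.loc["radscore", "p"]),
            "table": mv.to_dict(),
        }
    except Exception as exc:  # small-sample Cox fits can fail to converge
        mv_report = {"error": str(exc)}

    report = {
        "task": "prognosis",
        "package_version": __version__,
        "config": config.to_json(),
        "n_subjects": len(table),
        "n_excluded_pcr": n_dropped,
        "n_events": int(surv["event"].sum()),
        "variants": results,
        "cindex_by_variant": {
            k: results[k]["cindex_test"]["estimate"] for k in results
        },
        "radscore_cutoff": cutoff,
        "km_logrank_test": km_report,
        "multivariable": mv_report,
    }
    report["_radscores"] = radscores
    report["_split"] = (train_idx, test_idx)
    return report


def write_report(report: dict, out_dir) -> Path:
    """Serialize a study report (minus in-memory handles) to JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    clean = {k: v for k, v in report.items() if not k.startswith("_")}
    path = out / f"{report.get('task', 'study')}_report.json"
    path.write_text(json.dumps(clean, indent=1, sort_keys=True, default=float))
    return path
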
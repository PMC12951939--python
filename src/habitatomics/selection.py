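"""Feature-selection pipeline: reproducibility, redundancy, univariate and stability filters.

The fixed filter order is ICC -> Spearman redundancy pruning ->
univariate screen -> gradient-boosting stability selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy import stats


@dataclass
class SelectionConfig:
    """Thresholds and resampling parameters of the selection pipeline.

    Defaults mirror the analysis conventions: ICC >= 0.80 kept, Spearman
    |rho| >= 0.9 pruned, Wilcoxon p < 0.05 kept, clinical screen at
    P < 0.10; stability selection over 20 inner resamples (50%
    subsampling, the canonical choice that decorrelates resamples), top
    10 features by gain per resample, frequency threshold 0.7.
    """

    icc_threshold: float = 0.80
    spearman_threshold: float = 0.9
    wilcoxon_alpha: float = 0.05
    clinical_screen_alpha: float = 0.10
    n_outer_folds: int = 5
    n_inner_repeats: int = 20
    subsample_fraction: float = 0.5
    top_m: int = 10
    stability_frequency_threshold: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.stability_frequency_threshold <= 1:
            raise ValueError("stability_frequency_threshold must be in (0, 1]")
        for name in ("icc_threshold", "spearman_threshold"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


def icc_single(a: np.ndarray, b: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``a`` and ``b`` are the two raters' measurements of the same subjects.
    Returns NaN when the between-subject mean square is degenerate.
    """
    Y = np.column_stack([a, b]).astype(float)
    n, k = Y.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    grand = Y.mean()
    row_m = Y.mean(axis=1)
    col_m = Y.mean(axis=0)
    ss_rows = k * ((row_m - grand) ** 2).sum()
    ss_cols = n * ((col_m - grand) ** 2).sum()
    ss_tot = ((Y - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or (msr == 0 and mse == 0):
        return float("nan")
    return float((msr - mse) / denom)


def icc_filter(
    ratings_a: pd.DataFrame,
    ratings_b: pd.DataFrame,
    threshold: float = 0.80,
) -> tuple[list[str], pd.Series]:
    """Retain features whose inter-rater ICC(2,1) meets the threshold.

    Features with undefined ICC (no between-subject variance) are dropped
    with a warning. Returns (retained names, ICC per feature).
    """
    if list(ratings_a.columns) != list(ratings_b.columns) or len(ratings_a) != len(ratings_b):
        raise ValueError("the two rating tables must share subjects and features")
    iccs = {}
    for c in ratings_a.columns:
        iccs[c] = icc_single(ratings_a[c].to_numpy(), ratings_b[c].to_numpy())
    icc_s = pd.Series(iccs)
    undefined = icc_s.index[icc_s.isna()]
    if len(undefined):
        warnings.warn(f"ICC undefined for {len(undefined)} feature(s); dropped")
    kept = [c for c in ratings_a.columns if np.isfinite(icc_s[c]) and icc_s[c] >= threshold]
    return kept, icc_s


def spearman_prune(
    table: pd.DataFrame,
    threshold: float = 0.9,
    priority: pd.Series | None = None,
) -> list[str]:
    """Greedy redundancy pruning at |Spearman rho| >= threshold.

    Features are visited in descending ``priority`` (default: table
    order); a feature correlated at or above the threshold with an
    already-kept feature is dropped. Constant columns are dropped with a
    warning. The kept set is invariant to input column order given fixed
    priorities.
    """
    cols = list(table.columns)
    if len(table) < 3:
        raise ValueError("need at least 3 subjects")
    const = [c for c in cols if table[c].nunique() <= 1]
    if const:
        warnings.warn(f"{len(const)} constant column(s) dropped (undefined correlation)")
    cols = [c for c in cols if c not in const]
    if priority is not None:
        order = sorted(cols, key=lambda c: (-priority[c], c))
    else:
        order = cols
    ranks = table[cols].rank()
    corr = ranks.corr(method="pearson")  # Spearman = Pearson on ranks
    kept: list[str] = []
    for c in order:
        if all(abs(corr.loc[c, k]) < threshold for k in kept):
            kept.append(c)
    return kept


def wilcoxon_filter(
    table: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    alpha: float = 0.05,
) -> tuple[list[str], pd.Series]:
    """Two-sided Wilcoxon rank-sum screen; keep features with p < alpha.

    The exact null distribution is used when the smaller group has at
    most 10 subjects and the feature has no ties; otherwise the normal
    approximation with tie correction.
    """
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    pvals = {}
    for c in table.columns:
        x = table[c].to_numpy(dtype=float)
        a, b = x[y == 1], x[y == 0]
        has_ties = len(np.unique(x)) < len(x)
        method = "exact" if (min(len(a), len(b)) <= 10 and not has_ties) else "asymptotic"
        pvals[c] = stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    p_s = pd.Series(pvals)
    kept = [c for c in table.columns if p_s[c] < alpha]
    return kept, p_s


def cox_score_filter(
    table: pd.DataFrame,
    surv,
    alpha: float = 0.05,
) -> tuple[list[str], pd.Series]:
    """Univariate Cox score (log-rank trend) screen; keep features with p < alpha.

    For each feature the score statistic U = sum over events of
    (x_i - risk-set mean) with its hypergeometric-style variance gives a
    1-df chi-square p-value. Vectorized over features; Breslow handling
    of tied event times.
    """
    t = np.asarray(surv["time"], dtype=float)
    e = np.asarray(surv["event"]).astype(int)
    if e.sum() == 0:
        raise ValueError("no events")
    X = table.to_numpy(dtype=float)
    U = np.zeros(X.shape[1])
    V = np.zeros(X.shape[1])
    for i in np.flatnonzero(e == 1):
        at_risk = t >= t[i]
        R = X[at_risk]
        mu = R.mean(axis=0)
        U += X[i] - mu
        V += R.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(V > 0, U**2 / np.where(V > 0, V, 1.0), 0.0)
    p = stats.chi2.sf(chi2, df=1)
    p_s = pd.Series(p, index=table.columns)
    kept = [c for c in table.columns if p_s[c] < alpha]
    return kept, p_s


def _gain_ranking(
    X: pd.DataFrame, outcome, objective: str, seed: int, n_rounds: int = 60
) -> pd.Series:
    """Total split gain per feature from one boosted fit."""
    params = {
        "max_depth": 3,
        "eta": 0.1,
        "subsample": 0.9,
        "seed": int(seed) % (2**31),
        "nthread": 1,
        "verbosity": 0,
    }
    if objective == "binary":
        params["objective"] = "binary:logistic"
        dtrain = xgb.DMatrix(X, label=np.asarray(outcome, dtype=float))
    elif objective == "cox":
        params["objective"] = "survival:cox"
        time = np.asarray(outcome["time"], dtype=float)
        event = np.asarray(outcome["event"], dtype=int)
        y = np.where(event == 1, time, -time)
        dtrain = xgb.DMatrix(X, label=y)
    else:
        raise ValueError(f"unknown objective {objective!r}")
    booster = xgb.train(params, dtrain, num_boost_round=n_rounds)
    gains = booster.get_score(importance_type="total_gain")
    return pd.Series({c: gains.get(c, 0.0) for c in X.columns})


def stability_select(
    table: pd.DataFrame,
    outcome,
    objective: str = "binary",
    config: SelectionConfig | None = None,
) -> tuple[list[str], pd.Series]:
    """Stability selection with a gradient-boosting feature ranker.

    In each of ``n_inner_repeats`` resamples (subsampling without
    replacement), a boosted model is fit under the given objective
    (``binary`` label vector or ``cox`` DataFrame with ``time``/``event``
    columns), features are ranked by total split gain, and the top-m are
    marked selected. The final set contains features whose selection
    frequency reaches ``stability_frequency_threshold``. Deterministic
    given ``config.seed``.

    Returns (selected names, per-feature selection frequency).
    """
    cfg = config or SelectionConfig()
    rng = np.random.default_rng(cfg.seed)
    n = len(table)
    n_sub = max(2, int(round(cfg.subsample_fraction * n)))
    counts = pd.Series(0.0, index=table.columns)
    any_gain = False
    for r in range(cfg.n_inner_repeats):
        idx = rng.choice(n, size=n_sub, replace=False)
        Xs = table.iloc[idx]
        if objective == "binary":
            ys = np.asarray(outcome)[idx]
            if len(np.unique(ys)) < 2:
                continue
        else:
            ys = outcome.iloc[idx] if hasattr(outcome, "iloc") else outcome[idx]
            if np.asarray(ys["event"]).sum() == 0:
                continue
        gains = _gain_ranking(Xs, ys, objective, seed=int(rng.integers(2**31)))
        if gains.sum() <= 0:
            continue
        any_gain = True
        top = gains[gains > 0].sort_values(ascending=False).head(cfg.top_m)
        counts[top.index] += 1
    freq = counts / cfg.n_inner_repeats
    if not any_gain:
        warnings.warn("no splits with positive gain in any resample; empty selection")
        return [], freq
    selected = [c for c in table.columns if freq[c] >= cfg.stability_frequency_threshold]
    return selected, freq


def univariable_screen(
    covariates: pd.DataFrame,
    outcome,
    objective: str = "binary",
    alpha: float = 0.10,
) -> tuple[list[str], pd.Series]:
    """Clinical/conventional-imaging covariate screen at P < alpha.

    Univariable logistic (response task) or Cox (prognosis task) score
    tests per covariate; covariates below the relaxed alpha pass to
    multivariable modelling.
    """
    import statsmodels.api as sm
    from lifelines import CoxPHFitter

    pvals = {}
    for c in covariates.columns:
        x = covariates[[c]].astype(float)
        if x[c].nunique() <= 1:
            pvals[c] = 1.0
            continue
        if objective == "binary":
            y = np.asarray(outcome, dtype=float)
            if x[c].nunique() == 2:
                # binary covariate: Fisher's exact test is robust to separation
                hi = x[c] == x[c].max()
                tab = [
                    [int((y[hi.to_numpy()] == 1).sum()), int((y[hi.to_numpy()] == 0).sum())],
                    [int((y[~hi.to_numpy()] == 1).sum()), int((y[~hi.to_numpy()] == 0).sum())],
                ]
                from scipy.stats import fisher_exact

                pvals[c] = float(fisher_exact(tab)[1])
                continue
            model = sm.Logit(y, sm.add_constant(x))
            try:
                res = model.fit(disp=0)
                pvals[c] = float(res.pvalues[c])
            except Exception:
                pvals[c] = 1.0
        else:
            df = x.copy()
            df["time"] = np.asarray(outcome["time"], dtype=float)
            df["event"] = np.asarray(outcome["event"], dtype=int)
            try:
                cph = CoxPHFitter().fit(df, duration_col="time", event_col="event")
                pvals[c] = float(cph.summary.loc[c, "p"])
            except Exception:
                pvals[c] = 1.0
    p_s = pd.Series(pvals)
    return [c for c in covariates.columns if p_s[c] < alpha], p_s
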
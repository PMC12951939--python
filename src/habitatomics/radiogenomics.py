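"""Radiogenomic validation statistics.

Subjects are dichotomized by a RadScore cutoff learned on the training
cohort, and the resulting high-/low-risk groups are contrasted on
matched expression data: moderated (empirical-Bayes) differential
expression, Benjamini-Hochberg adjustment, hypergeometric gene-set
over-representation, and ssGSEA signature scoring with group
comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma


@dataclass
class ExpressionStudy:
    """A genes x samples log2 expression matrix with a binary risk label."""

    expr: pd.DataFrame  # genes x samples
    group: np.ndarray  # 1 = high risk

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group).astype(int)
        if len(self.group) != self.expr.shape[1]:
            raise ValueError("group labels must match sample count")
        if not np.all(np.isfinite(self.expr.to_numpy())):
            raise ValueError("non-finite expression values")
        if self.expr.index.duplicated().any():
            raise ValueError("duplicate gene ids")


@dataclass
class GeneSetCollection:
    """Named gene sets over a measured-gene universe."""

    sets: dict[str, list[str]]
    universe: list[str]

    def filtered(self, min_size: int = 2) -> "GeneSetCollection":
        """Intersect sets with the universe; drop sets that become too small."""
        uni = set(self.universe)
        out = {}
        for name, genes in self.sets.items():
            g = [x for x in genes if x in uni]
            if len(g) >= min_size:
                out[name] = g
            else:
                warnings.warn(f"gene set {name!r} has <{min_size} measured genes; skipped")
        return GeneSetCollection(sets=out, universe=self.universe)


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file (name, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def dichotomize_risk(radscores: np.ndarray, cutoff: float) -> np.ndarray:
    """High-risk (1) when score >= cutoff, else low-risk (0).

    The cutoff must come from the training cohort; boundary scores are
    assigned high-risk.
    """
    scores = np.asarray(radscores, dtype=float)
    groups = (scores >= cutoff).astype(int)
    if len(np.unique(groups)) < 2:
        warnings.warn("all subjects fall in one risk group; downstream contrasts will fail")
    return groups


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration (vectorized)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1 - tri / x) / polygamma(2, y)
        y += dif
        if np.all(np.abs(dif) < 1e-10 * y):
            break
    return y


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Empirical-Bayes inverse-chi-square prior (d0, s0^2) for gene variances.

    Method-of-moments fit on log s^2 (the scaled F-distribution fit used
    by moderated-t pipelines). Returns (d0, s0sq); d0 = inf when the
    observed log-variance spread is at or below the sampling spread.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - digamma(df / 2) + np.log(df / 2)
    emean = e.mean()
    evar = e.var(ddof=1) * (1 - 1 / ok.sum())  # limma's finite-sample nudge
    evar = evar - polygamma(1, df / 2)
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2 * _trigamma_inverse(np.array(evar))[()]
    s0sq = float(np.exp(emean + digamma(d0 / 2) - np.log(d0 / 2)))
    return float(d0), s0sq


def moderated_de(
    study: ExpressionStudy,
    lfc_min: float = 2.0,
    q_max: float = 0.05,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Two-group moderated-t differential expression with BH adjustment.

    Per gene, the group-difference in means (log2FC) is tested with a t
    statistic whose residual variance is shrunk toward an empirical-Bayes
    prior: s_tilde^2 = (d0*s0^2 + d*s^2)/(d0 + d) on d0 + d degrees of
    freedom. ``prior_df`` overrides the estimated d0 (0 recovers the
    ordinary t; inf collapses all variances to s0^2).

    Returns a per-gene table with log2FC, t, p, q and a ``deg`` flag
    (|log2FC| >= lfc_min and q < q_max).
    """
    g = study.group
    n1 = int((g == 1).sum())
    n0 = int((g == 0).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("need at least 2 samples per risk group")
    X = study.expr.to_numpy(dtype=float)
    hi = X[:, g == 1]
    lo = X[:, g == 0]
    lfc = hi.mean(axis=1) - lo.mean(axis=1)
    df = n1 + n0 - 2
    s2 = (hi.var(axis=1, ddof=1) * (n1 - 1) + lo.var(axis=1, ddof=1) * (n0 - 1)) / df

    zero = s2 <= 0
    if zero.any():
        warnings.warn(f"{zero.sum()} zero-variance gene(s): p set to 1")

    if prior_df is None:
        d0, s0sq = fit_variance_prior(s2[~zero] if zero.any() else s2, df)
    else:
        d0 = prior_df
        _, s0sq = fit_variance_prior(s2[~zero] if zero.any() else s2, df)

    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0sq)
        df_total = np.inf
    elif d0 == 0:
        s2_tilde = s2.copy()
        df_total = df
    else:
        s2_tilde = (d0 * s0sq + df * s2) / (d0 + df)
        df_total = d0 + df

    se = np.sqrt(s2_tilde * (1 / n1 + 1 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    p = np.where(zero, 1.0, p)
    q = bh_adjust(p)
    res = pd.DataFrame(
        {"log2FC": lfc, "t": t, "p": p, "q": q},
        index=study.expr.index,
    )
    res["deg"] = (np.abs(res["log2FC"]) >= lfc_min) & (res["q"] < q_max)
    res.attrs["d0"] = d0
    res.attrs["s0sq"] = s0sq
    return res


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    NaN inputs propagate to NaN with a warning and are excluded from the
    ranking.
    """
    p = np.asarray(pvals, dtype=float)
    nan = np.isnan(p)
    if nan.any():
        warnings.warn("NaN p-values propagated through BH adjustment")
    ok = ~nan
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    pv = p[ok]
    m = pv.size
    if m:
        order = np.argsort(pv, kind="mergesort")
        ranked = pv[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        qq = np.empty(m)
        qq[order] = np.minimum(ranked, 1.0)
        q[ok] = qq
    return q


def ora_hypergeometric(deg: list[str], collection: GeneSetCollection) -> pd.DataFrame:
    """Gene-set over-representation by the one-sided hypergeometric tail.

    For each set: P(X >= k) with N = |universe|, K = |set|, n = |DEG
    list|, k = |overlap|; q from BH across sets. An empty DEG list gives
    p = 1 everywhere.
    """
    coll = collection.filtered()
    uni = set(coll.universe)
    degs = [g for g in deg if g in uni]
    N = len(uni)
    n = len(degs)
    rows = []
    for name, genes in coll.sets.items():
        K = len(genes)
        k = len(set(genes) & set(degs))
        p = 1.0 if n == 0 else float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "overlap": k, "set_size": K, "p": p})
    res = pd.DataFrame(rows).set_index("set")
    res["q"] = bh_adjust(res["p"].to_numpy()) if len(res) else []
    return res


def ssgsea(
    expr: pd.DataFrame,
    collection: GeneSetCollection,
    weight_exponent: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """Single-sample gene-set enrichment scores (samples x sets).

    Per sample, genes are ranked by expression; the score integrates the
    difference between the rank-weighted (rank^alpha) in-set ECDF and the
    uniform out-of-set ECDF over the full ranking. Rank-based, hence
    invariant to monotone transforms of a sample's values. Sets covering
    every measured gene are degenerate and skipped.
    """
    genes = list(expr.index)
    N = len(genes)
    coll = GeneSetCollection(collection.sets, genes).filtered()
    usable = {}
    for name, members in coll.sets.items():
        if len(members) >= N:
            warnings.warn(f"gene set {name!r} covers all measured genes; skipped")
            continue
        usable[name] = np.asarray([g in set(members) for g in genes])
    if not usable:
        raise ValueError("no usable gene sets after filtering")

    scores = np.zeros((expr.shape[1], len(usable)))
    X = expr.to_numpy(dtype=float)
    for s in range(expr.shape[1]):
        ranks = stats.rankdata(X[:, s])  # 1 = lowest
        order = np.argsort(-X[:, s], kind="mergesort")  # descending
        w = ranks**weight_exponent
        for t, (name, member) in enumerate(usable.items()):
            mem_sorted = member[order]
            w_sorted = w[order]
            win = np.where(mem_sorted, w_sorted, 0.0)
            p_in = np.cumsum(win)
            p_in /= p_in[-1]
            p_out = np.cumsum(~mem_sorted) / (N - member.sum())
            scores[s, t] = (p_in - p_out).sum()
    out = pd.DataFrame(scores, index=expr.columns, columns=list(usable))
    if normalize:
        rng = out.to_numpy().max() - out.to_numpy().min()
        if rng > 0:
            out = (out - out.to_numpy().min()) / rng
    return out


def ssgsea_group_test(scores: pd.DataFrame, group: np.ndarray) -> pd.DataFrame:
    """Wilcoxon rank-sum per signature between risk groups, BH-adjusted."""
    group = np.asarray(group).astype(int)
    rows = {}
    for c in scores.columns:
        x = scores[c].to_numpy()
        rows[c] = stats.mannwhitneyu(x[group == 1], x[group == 0], alternative="two-sided").pvalue
    res = pd.DataFrame({"p": pd.Series(rows)})
    res["q"] = bh_adjust(res["p"].to_numpy())
    return res
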
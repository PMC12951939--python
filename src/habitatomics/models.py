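"""Response and prognosis models, RadScore construction and evaluation statistics.

The response model is a gradient-boosted tree classifier for pCR
(RadScore = predicted probability); the prognosis model is boosted under
the Cox partial-likelihood objective (RadScore = within-cohort
rank-normalized risk in [0, 1]). Evaluation is by AUC / Harrell's
C-index with percentile-bootstrap 95% CIs, Kaplan-Meier curves with the
log-rank test, and RadScore-adjusted multivariable logistic / Cox
regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy import stats


@dataclass
class ModelBundle:
    """A fitted boosted model plus everything needed to apply it."""

    objective: str  # "binary" or "cox"
    booster: xgb.Booster
    feature_names: list[str]
    seed: int
    radscore_cutoff: float | None = None
    metrics: dict = field(default_factory=dict)
    train_risk: np.ndarray | None = None  # reference scores for cox rank scaling

    def predict_raw(self, X: pd.DataFrame) -> np.ndarray:
        if list(X.columns) != self.feature_names:
            X = X[self.feature_names]
        d = xgb.DMatrix(X)
        return self.booster.predict(d)

    def radscore(self, X: pd.DataFrame) -> np.ndarray:
        """Scalar radiomic score per subject.

        Binary objective: predicted pCR probability. Cox objective: risk
        rank-normalized to [0, 1] against the training risks.
        """
        raw = self.predict_raw(X)
        if self.objective == "binary":
            return raw
        ref = self.train_risk if self.train_risk is not None else raw
        return np.searchsorted(np.sort(ref), raw, side="right") / len(ref)


def smote_oversample(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """SMOTE: balance classes by interpolated synthetic minority samples.

    Each synthetic row is x + u * (neighbor - x) for a random minority
    point x, one of its k nearest minority neighbours, and u ~ U(0, 1).
    Must be applied inside training folds only.
    """
    cols = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE requires a binary outcome")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min < 2:
        raise ValueError("minority class needs at least 2 samples")
    k_eff = min(k, n_min - 1)
    Xm = Xa[y == minority]
    need = n_maj - n_min
    rng = np.random.default_rng(seed)

    d = np.linalg.norm(Xm[:, None, :] - Xm[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    nn = np.argsort(d, axis=1)[:, :k_eff]

    synth = np.empty((need, Xa.shape[1]))
    for i in range(need):
        j = rng.integers(n_min)
        nb = nn[j, rng.integers(k_eff)]
        u = rng.uniform()
        synth[i] = Xm[j] + u * (Xm[nb] - Xm[j])
    X_out = np.vstack([Xa, synth])
    y_out = np.concatenate([y, np.full(need, minority)])
    if cols is not None:
        X_out = pd.DataFrame(X_out, columns=cols)
    return X_out, y_out


_DEFAULT_GRID = {
    "max_depth": (2, 3),
    "eta": (0.05, 0.1),
}


def _train(params, dtrain, n_rounds):
    return xgb.train(params, dtrain, num_boost_round=n_rounds)


def fit_boosted(
    X: pd.DataFrame,
    outcome,
    objective: str = "binary",
    hyperparams: dict | None = None,
    seed: int = 0,
    tune: bool = True,
    n_rounds: int = 150,
) -> ModelBundle:
    """Fit a gradient-boosted tree ensemble for response or prognosis.

    ``binary``: outcome is a 0/1 vector, logistic deviance objective.
    ``cox``: outcome is a DataFrame with ``time``/``event`` columns;
    the negative Cox partial likelihood is minimized. A small inner
    3-fold cross-validation over depth x learning rate picks
    hyperparameters by AUC (binary) or Harrell's C (cox) unless
    ``hyperparams`` pins them.
    """
    if not np.all(np.isfinite(X.to_numpy(dtype=float))):
        raise ValueError("non-finite feature values")
    seed = int(seed) % (2**31)
    base = {
        "subsample": 0.8,
        "colsample_bytree": 0.8,
        "min_child_weight": 3,
        "seed": seed,
        "nthread": 1,
        "verbosity": 0,
    }
    if objective == "binary":
        y = np.asarray(outcome).astype(float)
        if len(np.unique(y)) < 2:
            raise ValueError("binary outcome has a single class")
        base["objective"] = "binary:logistic"
        label = y
    elif objective == "cox":
        time = np.asarray(outcome["time"], dtype=float)
        event = np.asarray(outcome["event"], dtype=int)
        if event.sum() == 0:
            raise ValueError("no events in survival outcome")
        base["objective"] = "survival:cox"
        label = np.where(event == 1, time, -time)
    else:
        raise ValueError(f"unknown objective {objective!r}")

    dtrain = xgb.DMatrix(X, label=label)

    if hyperparams is not None:
        params = {**base, **hyperparams}
    elif tune and len(X) >= 30:
        params = {**base, **_tune(X, outcome, objective, base, seed, n_rounds)}
    else:
        params = {**base, "max_depth": 2, "eta": 0.05}

    booster = _train(params, dtrain, n_rounds)
    bundle = ModelBundle(
        objective=objective,
        booster=booster,
        feature_names=list(X.columns),
        seed=seed,
    )
    if objective == "cox":
        bundle.train_risk = bundle.predict_raw(X)
    return bundle


def _tune(X, outcome, objective, base, seed, n_rounds) -> dict:
    """Small grid search (depth x eta) by 3-fold CV metric."""
    from sklearn.model_selection import KFold, StratifiedKFold

    best, best_score = None, -np.inf
    for depth in _DEFAULT_GRID["max_depth"]:
        for eta in _DEFAULT_GRID["eta"]:
            params = {**base, "max_depth": depth, "eta": eta}
            scores = []
            if objective == "binary":
                y = np.asarray(outcome).astype(float)
                splitter = StratifiedKFold(3, shuffle=True, random_state=seed)
                splits = splitter.split(X, y)
            else:
                splitter = KFold(3, shuffle=True, random_state=seed)
                splits = splitter.split(X)
            for tr, te in splits:
                Xtr, Xte = X.iloc[tr], X.iloc[te]
                if objective == "binary":
                    ytr, yte = y[tr], y[te]
                    if len(np.unique(ytr)) < 2 or len(np.unique(yte)) < 2:
                        continue
                    bst = _train(params, xgb.DMatrix(Xtr, label=ytr), n_rounds // 2)
                    pred = bst.predict(xgb.DMatrix(Xte))
                    scores.append(auc_mann_whitney(pred, yte))
                else:
                    t = np.asarray(outcome["time"], dtype=float)
                    e = np.asarray(outcome["event"], dtype=int)
                    if e[tr].sum() == 0 or e[te].sum() == 0:
                        continue
                    lab = np.where(e[tr] == 1, t[tr], -t[tr])
                    bst = _train(params, xgb.DMatrix(Xtr, label=lab), n_rounds // 2)
                    pred = bst.predict(xgb.DMatrix(Xte))
                    scores.append(harrell_cindex(pred, t[te], e[te]))
            if scores and np.mean(scores) > best_score:
                best_score = float(np.mean(scores))
                best = {"max_depth": depth, "eta": eta}
    return best or {"max_depth": 3, "eta": 0.1}


# ---------------------------------------------------------------------------
# evaluation statistics


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U statistic (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC needs both outcome classes")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (len(pos) * len(neg)))


def harrell_cindex(risk: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Harrell's concordance: concordant / (concordant + discordant) pairs.

    A pair is comparable when the earlier time is an event; it is
    concordant when the earlier-failing subject has the higher predicted
    risk; risk ties count 1/2.
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    # comparable (i, j): i fails first (ties in time only against censored j)
    ev_i = event[:, None] == 1
    later = time[None, :] > time[:, None]
    tied_cens = (time[None, :] == time[:, None]) & (event[None, :] == 0)
    comparable = ev_i & (later | tied_cens)
    np.fill_diagonal(comparable, False)
    total = comparable.sum()
    if total == 0:
        raise ValueError("no comparable pairs")
    higher = risk[:, None] > risk[None, :]
    tied_r = risk[:, None] == risk[None, :]
    conc = (comparable & higher).sum()
    ties = (comparable & tied_r).sum()
    return float((conc + 0.5 * ties) / total)


def evaluate(
    scores: np.ndarray,
    outcome,
    metric: str = "auc",
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Point estimate with percentile-bootstrap 95% CI over subjects.

    ``metric='auc'`` expects a binary label vector; ``metric='cindex'``
    expects a DataFrame/dict with ``time`` and ``event``.
    """
    scores = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(scores)

    if metric == "auc":
        y = np.asarray(outcome).astype(int)
        est = auc_mann_whitney(scores, y)

        def stat(idx):
            if len(np.unique(y[idx])) < 2:
                return None
            return auc_mann_whitney(scores[idx], y[idx])

    elif metric == "cindex":
        t = np.asarray(outcome["time"], dtype=float)
        e = np.asarray(outcome["event"]).astype(int)
        est = harrell_cindex(scores, t, e)

        def stat(idx):
            try:
                return harrell_cindex(scores[idx], t[idx], e[idx])
            except ValueError:
                return None

    else:
        raise ValueError(f"unknown metric {metric!r}")

    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        v = stat(idx)
        if v is not None:
            boots.append(v)
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan))
    return {"estimate": est, "ci_lower": float(lo), "ci_upper": float(hi), "n_boot": n_boot}


def km_logrank(time, event, group) -> dict:
    """Kaplan-Meier curves per group and the two-group log-rank test."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    curves = {}
    for g in levels:
        m = group == g
        if m.sum() == 0:
            raise ValueError(f"group {g} has no subjects")
        kmf = KaplanMeierFitter().fit(time[m], event[m])
        curves[g] = kmf.survival_function_
    if event.sum() == 0:
        # no events anywhere: S(t) = 1 and the test carries no information
        return {"curves": curves, "chi2": 0.0, "p": 1.0}
    res = multivariate_logrank_test(time, group, event)
    return {
        "curves": curves,
        "chi2": float(res.test_statistic),
        "p": float(res.p_value),
    }


def youden_cutoff(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Score cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are the observed score values (score >= cutoff is called
    positive); ties in J are broken toward the smaller cutoff. Returns
    (cutoff, J). A constant score vector yields J = 0 with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class")
    cands = np.unique(scores)
    if len(cands) == 1:
        warnings.warn("constant scores: Youden index is 0")
        return float(cands[0]), 0.0
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    best_c, best_j = cands[0], -np.inf
    for c in cands:
        called = scores >= c
        sens = (called & (labels == 1)).sum() / n_pos
        spec = (~called & (labels == 0)).sum() / n_neg
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_j, best_c = j, c
    return float(best_c), float(best_j)


def multivariable_adjusted(
    radscore: np.ndarray,
    covariates: pd.DataFrame,
    outcome,
    objective: str = "binary",
) -> pd.DataFrame:
    """RadScore-adjusted multivariable regression.

    Logistic (IRLS via statsmodels) for binary response, Cox proportional
    hazards (Efron ties via lifelines) for survival. Returns a table of
    coefficients, OR/HR with Wald 95% CIs and p-values, indexed by
    covariate with ``radscore`` first (pass ``radscore=None`` for a
    covariate-only model). Raises on separation (diverging logistic
    coefficients).
    """
    X = covariates.copy()
    if radscore is not None:
        X.insert(0, "radscore", np.asarray(radscore, dtype=float))
    if objective == "binary":
        import statsmodels.api as sm

        y = np.asarray(outcome).astype(float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, sm.add_constant(X.astype(float))).fit(disp=0, maxiter=200)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "separation detected (singular information matrix); penalize or simplify"
            ) from exc
        coefs = res.params.drop("const")
        if np.any(np.abs(coefs) > 15):
            raise ValueError("separation detected (diverging coefficient); penalize or simplify")
        ci = res.conf_int().drop(index="const")
        out = pd.DataFrame(
            {
                "coef": coefs,
                "OR": np.exp(coefs),
                "ci_lower": np.exp(ci[0]),
                "ci_upper": np.exp(ci[1]),
                "p": res.pvalues.drop("const"),
            }
        )
        return out
    elif objective == "cox":
        from lifelines import CoxPHFitter

        df = X.astype(float).copy()
        df["time"] = np.asarray(outcome["time"], dtype=float)
        df["event"] = np.asarray(outcome["event"]).astype(int)
        n_events = int(df["event"].sum())
        if n_events < X.shape[1]:
            warnings.warn("fewer events than covariates: unstable Cox fit")
        cph = CoxPHFitter().fit(df, duration_col="time", event_col="event")
        s = cph.summary
        return pd.DataFrame(
            {
                "coef": s["coef"],
                "HR": s["exp(coef)"],
                "ci_lower": s["exp(coef) lower 95%"],
                "ci_upper": s["exp(coef) upper 95%"],
                "p": s["p"],
            }
        )
    raise ValueError(f"unknown objective {objective!r}")


def attribution(bundle: ModelBundle, X: pd.DataFrame) -> pd.DataFrame:
    """Per-subject additive feature contributions (TreeSHAP).

    Contributions per subject sum to the raw model output minus the
    background expectation (efficiency property). Global importance is
    the mean absolute contribution per feature.
    """
    if list(X.columns) != bundle.feature_names:
        missing = set(bundle.feature_names) ^ set(X.columns)
        raise ValueError(f"feature set mismatch: {sorted(missing)}")
    d = xgb.DMatrix(X)
    contrib = bundle.booster.predict(d, pred_contribs=True)
    cols = bundle.feature_names + ["bias"]
    return pd.DataFrame(contrib, columns=cols, index=X.index)
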
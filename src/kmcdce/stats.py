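"""Group comparisons, logistic pCR prediction and bootstrap ROC machinery.

Cohort-level analysis mirrors a standard apparent-performance workflow:

* pCR vs non-pCR group differences: Wilcoxon rank-sum for continuous
  features (exact enumeration when the combined sample is small and
  tie-free, normal approximation with tie correction otherwise) and a
  Pearson chi-square without continuity correction for categorical ones.
* Logistic regression on standardized features with a small ridge term for
  separation stability; an exhaustive search over all feature subsets of
  size 1-3 inside each model family selects the subset with the highest
  in-sample ROC AUC (ties to fewer features, then lexicographic order).
* ROC AUC is the Mann-Whitney probability that a random positive outscores
  a random negative, ties counted half.
* Uncertainty: patients are resampled with replacement, the already
  selected model is refit on each resample and scored on it, and the
  2.5/97.5 percentiles of the resample AUCs give a 95% CI. Feature
  selection is not repeated inside the bootstrap (an optimism-prone but
  conventional choice for apparent performance). Two models sharing the
  same resample indices are compared by a z-test on the mean paired AUC
  difference. The operating point reported with each model maximizes the
  Youden index (sensitivity + specificity - 1).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_core import DataError

logger = logging.getLogger(__name__)

RIDGE = 1e-4          # L2 penalty on standardized coefficients (not intercept)
MAX_FEATURES = 3

#: model families: which candidate-feature pools each family may draw from
FAMILIES = {
    "i": ("clinical",),
    "ii": ("kT",),
    "iii": ("kBPE_IC",),
    "iv": ("clinical", "kT"),
    "v": ("clinical", "kBPE_IC"),
    "vi": ("kT", "kBPE_IC"),
    "vii": ("clinical", "kT", "kBPE_IC"),
}


@dataclass
class GroupComparison:
    feature: str
    kind: str                       # "continuous" | "categorical"
    mean_nonpcr: float
    sd_nonpcr: float
    mean_pcr: float
    sd_pcr: float
    test: str
    statistic: float
    p_value: float
    auc: float = float("nan")
    auc_ci: tuple[float, float] = (float("nan"), float("nan"))
    degenerate: bool = False


@dataclass
class ModelReport:
    family: str
    features: tuple[str, ...]
    coefficients: dict[str, float]
    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float
    specificity: float
    accuracy: float
    threshold: float
    n_bootstrap: int
    leaderboard: pd.DataFrame = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# elementary statistics

def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5*P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == 0
    n1, n0 = int(pos.sum()), int(neg.sum())
    if n1 == 0 or n0 == 0:
        raise DataError("both classes must be present for ROC AUC")
    ranks = sps.rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided rank-sum test; exact for tie-free combined n <= 20."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(np.concatenate([x, y])) == 0:
        return float("nan"), 1.0
    combined = np.concatenate([x, y])
    exact = combined.size <= 20 and np.unique(combined).size == combined.size
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)


def chi_square(table) -> tuple[float, float]:
    """Pearson chi-square on a contingency table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.min() < 0 or table.sum() == 0:
        raise DataError("invalid contingency table")
    stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def youden_operating_point(scores, labels) -> tuple[float, float, float, float]:
    """Threshold maximizing sensitivity + specificity - 1 (ties: lowest
    threshold); returns (threshold, sensitivity, specificity, accuracy).
    A score >= threshold predicts the positive class."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == 0
    if not pos.any() or not neg.any():
        raise DataError("both classes must be present")
    best = None
    for thr in np.unique(scores):
        pred = scores >= thr
        sens = float(pred[pos].mean())
        spec = float((~pred[neg]).mean())
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            acc = float((pred == pos).mean())
            best = (j, thr, sens, spec, acc)
    _, thr, sens, spec, acc = best
    return float(thr), sens, spec, acc


# ---------------------------------------------------------------------------
# logistic model

class LogisticModel:
    """Ridge-stabilized maximum-likelihood logistic regression.

    Features are standardized with full-cohort mean/SD (consistent with
    apparent in-sample evaluation); a small L2 penalty on the standardized
    coefficients keeps separated data finite. Newton-Raphson iterations,
    deterministic.
    """

    def __init__(self, features: tuple[str, ...], ridge: float = RIDGE):
        self.features = tuple(features)
        self.ridge = ridge
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None
        self.coef_: np.ndarray | None = None   # [intercept, b1..bd]

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LogisticModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.mean_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0, ddof=0)
        if np.any(self.sd_ == 0):
            bad = [f for f, s in zip(self.features, self.sd_) if s == 0]
            raise DataError(f"constant feature(s) after standardization: {bad}")
        Z = (X - self.mean_) / self.sd_
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise DataError(f"collinear features: {list(self.features)}")
        D = np.column_stack([np.ones(len(Z)), Z])
        beta = np.zeros(D.shape[1])
        pen = np.full(D.shape[1], self.ridge)
        pen[0] = 0.0
        sign = 2.0 * y - 1.0

        def pnll(b):
            # penalized negative log-likelihood, overflow-safe
            return float(np.logaddexp(0.0, -sign * (D @ b)).sum()
                         + 0.5 * np.sum(pen * b * b))

        f = pnll(beta)
        for _ in range(100):
            eta = np.clip(D @ beta, -35.0, 35.0)
            p = 1.0 / (1.0 + np.exp(-eta))
            w = np.clip(p * (1.0 - p), 1e-10, None)
            grad = D.T @ (y - p) - pen * beta
            H = (D * w[:, None]).T @ D + np.diag(pen)
            step = np.linalg.solve(H, grad)
            # backtracking keeps separated designs from diverging
            t = 1.0
            for _ in range(40):
                f_new = pnll(beta + t * step)
                if f_new <= f + 1e-14:
                    break
                t *= 0.5
            beta = beta + t * step
            if f - f_new < 1e-12 or np.max(np.abs(t * step)) < 1e-10:
                f = f_new
                break
            f = f_new
        self.coef_ = beta
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.mean_) / self.sd_
        eta = np.clip(self.coef_[0] + Z @ self.coef_[1:], -500.0, 500.0)
        return 1.0 / (1.0 + np.exp(-eta))


def fit_logistic(cohort: pd.DataFrame, features) -> tuple[LogisticModel, np.ndarray]:
    """Fit on complete cases of ``features``; returns model + in-sample
    predicted probabilities (aligned to the retained rows)."""
    features = tuple(features)
    if len(features) > MAX_FEATURES:
        raise DataError(f"at most {MAX_FEATURES} features, got {len(features)}")
    sub = cohort[list(features) + ["outcome"]].dropna()
    dropped = len(cohort) - len(sub)
    if dropped:
        logger.info("dropped %d patients with missing features", dropped)
    X = sub[list(features)].to_numpy(dtype=float)
    y = sub["outcome"].to_numpy(dtype=float)
    model = LogisticModel(features).fit(X, y)
    return model, model.predict_proba(X)


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap_indices(n: int, n_boot: int, seed: int,
                      labels=None, stratified: bool = False) -> np.ndarray:
    """(n_boot, n) resample index matrix; deterministic given seed. With
    ``stratified`` each class is resampled within itself."""
    rng = np.random.default_rng(seed)
    if not stratified:
        return rng.integers(0, n, size=(n_boot, n))
    labels = np.asarray(labels)
    idx_pos = np.flatnonzero(labels == 1)
    idx_neg = np.flatnonzero(labels == 0)
    out = np.empty((n_boot, n), dtype=np.int64)
    for b in range(n_boot):
        out[b] = np.concatenate([
            rng.choice(idx_pos, size=idx_pos.size, replace=True),
            rng.choice(idx_neg, size=idx_neg.size, replace=True)])
    return out


def bootstrap_auc(cohort: pd.DataFrame, features, indices: np.ndarray
                  ) -> np.ndarray:
    """Refit the selected model on each resample and score it on the same
    resample. Single-class or degenerate resamples yield NaN (logged)."""
    features = tuple(features)
    sub = cohort[list(features) + ["outcome"]].dropna().reset_index(drop=True)
    X = sub[list(features)].to_numpy(dtype=float)
    y = sub["outcome"].to_numpy(dtype=float)
    aucs = np.full(indices.shape[0], np.nan)
    for b, idx in enumerate(indices):
        yb = y[idx]
        if yb.min() == yb.max():
            continue
        try:
            m = LogisticModel(features).fit(X[idx], yb)
        except DataError:
            continue
        aucs[b] = roc_auc(m.predict_proba(X[idx]), yb)
    n_bad = int(np.isnan(aucs).sum())
    if n_bad:
        logger.info("%d/%d degenerate bootstrap resamples skipped",
                    n_bad, len(aucs))
    if n_bad > 0.5 * len(aucs):
        raise DataError("more than half of bootstrap resamples degenerate")
    return aucs


def bootstrap_auc_ci(cohort: pd.DataFrame, features, n_boot: int = 1000,
                     seed: int = 0, stratified: bool = False
                     ) -> tuple[tuple[float, float], np.ndarray]:
    """95% percentile bootstrap CI of the apparent AUC of one model."""
    sub = cohort[list(features) + ["outcome"]].dropna()
    y = sub["outcome"].to_numpy()
    indices = bootstrap_indices(len(sub), n_boot, seed, labels=y,
                                stratified=stratified)
    aucs = bootstrap_auc(cohort, features, indices)
    valid = aucs[np.isfinite(aucs)]
    lo, hi = np.percentile(valid, [2.5, 97.5])
    return (float(lo), float(hi)), aucs


def compare_models_z(aucs_a: np.ndarray, aucs_b: np.ndarray
                     ) -> tuple[float, float]:
    """z-test on the mean paired AUC difference across shared resamples."""
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if a.shape != b.shape:
        raise DataError("paired AUC vectors must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    d = a[ok] - b[ok]
    if d.size < 2:
        raise DataError("too few paired resamples")
    dbar = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        return (0.0, 1.0) if dbar == 0.0 else (float("inf"), 0.0)
    z = dbar / (sd / np.sqrt(d.size))
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# cohort-level drivers

def compare_groups(cohort: pd.DataFrame, feature: str,
                   categorical: bool | None = None,
                   n_boot: int = 1000, seed: int = 0) -> GroupComparison:
    """pCR vs non-pCR comparison of one feature, with single-feature AUC."""
    sub = cohort[[feature, "outcome"]].dropna()
    y = sub["outcome"].to_numpy()
    v = sub[feature]
    g_pcr = v[y == 1]
    g_non = v[y == 0]
    if len(g_pcr) < 2 or len(g_non) < 2:
        raise DataError(f"{feature}: need >= 2 patients per group")
    if categorical is None:
        categorical = (v.dtype == object or str(v.dtype) == "category"
                       or v.nunique() <= 2)

    if categorical:
        table = pd.crosstab(v, y).to_numpy()
        degenerate = table.shape[0] < 2
        if degenerate:
            stat, p = float("nan"), 1.0
        else:
            stat, p = chi_square(table)
        return GroupComparison(
            feature=feature, kind="categorical",
            mean_nonpcr=float(pd.to_numeric(g_non, errors="coerce").mean()),
            sd_nonpcr=float(pd.to_numeric(g_non, errors="coerce").std()),
            mean_pcr=float(pd.to_numeric(g_pcr, errors="coerce").mean()),
            sd_pcr=float(pd.to_numeric(g_pcr, errors="coerce").std()),
            test="chi-square", statistic=stat, p_value=p,
            degenerate=degenerate)

    x_non = g_non.to_numpy(dtype=float)
    x_pcr = g_pcr.to_numpy(dtype=float)
    degenerate = np.ptp(np.concatenate([x_non, x_pcr])) == 0
    stat, p = wilcoxon_rank_sum(x_non, x_pcr)
    if degenerate:
        auc, ci = float("nan"), (float("nan"), float("nan"))
    else:
        auc = roc_auc(sub[feature].to_numpy(dtype=float), y)
        auc = max(auc, 1.0 - auc)   # direction-free discrimination
        ci, _ = bootstrap_auc_ci(cohort, (feature,), n_boot=n_boot, seed=seed)
    return GroupComparison(
        feature=feature, kind="continuous",
        mean_nonpcr=float(x_non.mean()), sd_nonpcr=float(np.std(x_non, ddof=1)),
        mean_pcr=float(x_pcr.mean()), sd_pcr=float(np.std(x_pcr, ddof=1)),
        test="wilcoxon-rank-sum", statistic=stat, p_value=p,
        auc=auc, auc_ci=ci, degenerate=bool(degenerate))


def enumerate_subsets(pools: dict[str, list[str]], family: str
                      ) -> list[tuple[str, ...]]:
    """All feature subsets of size 1..3 for a family. Single-pool families
    enumerate every subset of the pool; multi-pool families require at
    least one feature from each constituent pool (subsets that ignore a
    pool belong to a simpler family)."""
    pool_names = FAMILIES[family]
    union = [f for p in pool_names for f in pools[p]]
    subsets = []
    for r in range(1, MAX_FEATURES + 1):
        for combo in itertools.combinations(union, r):
            if len(pool_names) > 1:
                covered = {p for p in pool_names
                           if any(f in pools[p] for f in combo)}
                if covered != set(pool_names):
                    continue
            subsets.append(combo)
    return subsets


def exhaustive_model_search(cohort: pd.DataFrame, pools: dict[str, list[str]],
                            family: str, n_boot: int = 1000, seed: int = 0
                            ) -> ModelReport:
    """Fit every admissible <=3-feature logistic model of a family and keep
    the one with the highest apparent AUC (ties: fewer features, then
    lexicographic feature order). The full leaderboard is retained."""
    if family not in FAMILIES:
        raise DataError(f"unknown family {family!r}")
    rows = []
    fitted = 0
    for combo in enumerate_subsets(pools, family):
        try:
            _, probs = fit_logistic(cohort, combo)
        except (DataError, np.linalg.LinAlgError):
            continue
        sub = cohort[list(combo) + ["outcome"]].dropna()
        auc = roc_auc(probs, sub["outcome"].to_numpy())
        rows.append({"features": combo, "n_features": len(combo), "auc": auc})
        fitted += 1
    if fitted == 0:
        raise DataError(f"family {family}: all candidate fits degenerate")
    board = pd.DataFrame(rows).sort_values(
        ["auc", "n_features", "features"],
        ascending=[False, True, True], kind="stable").reset_index(drop=True)
    best = tuple(board.iloc[0]["features"])

    model, probs = fit_logistic(cohort, best)
    sub = cohort[list(best) + ["outcome"]].dropna()
    y = sub["outcome"].to_numpy()
    auc = roc_auc(probs, y)
    ci, _ = bootstrap_auc_ci(cohort, best, n_boot=n_boot, seed=seed)
    thr, sens, spec, acc = youden_operating_point(probs, y)
    coefs = {"intercept": float(model.coef_[0])}
    coefs.update({f: float(b) for f, b in zip(best, model.coef_[1:])})
    return ModelReport(family=family, features=best, coefficients=coefs,
                       auc=auc, auc_ci=ci, sensitivity=sens,
                       specificity=spec, accuracy=acc, threshold=thr,
                       n_bootstrap=n_boot, leaderboard=board)
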
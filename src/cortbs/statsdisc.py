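"""Precision, rank statistics, PLS discrimination and ROC metrics.

Implements the statistical toolbox of the fracture-discrimination study:

* short-term precision (root-mean-square of within-subject SDs over repeated
  measurements, absolute and as a coefficient of variation),
* Wilcoxon rank-sum group comparisons and Spearman rank correlations,
* PLS1 regression by NIPALS on autoscaled data, used both for regression
  (predicting X-ray parameters from backscatter parameters) and, with +-1
  coded labels, for discrimination (PLS-DA),
* leave-one-out / stratified k-fold cross-validation,
* subwindow permutation analysis (SPA): Monte-Carlo subset resampling for
  variable selection,
* ROC analysis with the rank-based AUC, the Hanley-McNeil standard error,
  Youden-optimal operating points, odds ratios with Woolf confidence
  intervals, and the Hanley-McNeil z-test comparing two AUCs.

The discrimination entry point follows the Model/Results pattern:
``DiscriminationModel(X, y).fit(seed)`` runs variable selection plus
PLS-LOOCV scoring and returns a results object with ROC metrics, the
confusion matrix at the operating point and the odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PrecisionResult",
    "short_term_precision",
    "wilcoxon_rank_sum",
    "spearman_rho",
    "PLSModel",
    "pls_fit",
    "cross_validated_pls",
    "spa_select",
    "ROCMetrics",
    "ConfusionMatrix",
    "roc_metrics",
    "odds_ratio",
    "compare_auc",
    "DiscriminationModel",
    "DiscriminationResults",
]


# ---------------------------------------------------------------------------
# short-term precision
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrecisionResult:
    """Absolute (parameter units) and relative (%) short-term precision."""

    absolute: float
    relative_pct: float
    n_subjects: int
    n_repeats: int
    relative_defined: bool = True

    def __str__(self) -> str:
        rel = f"{self.relative_pct:.2f}" if self.relative_defined else "undef"
        return f"{self.absolute:.2f} ({rel})"


def short_term_precision(repeats) -> PrecisionResult:
    """RMS within-subject precision of repeated measurements.

    ``repeats`` is (m subjects x k repeats), array or DataFrame.  Absolute
    precision is sqrt(mean_j SD_j^2); relative precision is
    100 * sqrt(mean_j (SD_j / mean_j)^2) (the RMS coefficient of variation).
    """
    x = np.asarray(repeats, dtype=float)
    if x.ndim != 2 or x.shape[0] < 1 or x.shape[1] < 2:
        raise ValueError("need m >= 1 subjects with k >= 2 repeats")
    sd = np.std(x, axis=1, ddof=1)
    mean = np.mean(x, axis=1)
    absolute = float(np.sqrt(np.mean(sd**2)))
    ok = not np.any(mean == 0)
    rel = float(100.0 * np.sqrt(np.mean((sd / mean) ** 2))) if ok else np.nan
    return PrecisionResult(
        absolute=absolute,
        relative_pct=rel,
        n_subjects=x.shape[0],
        n_repeats=x.shape[1],
        relative_defined=ok,
    )


# ---------------------------------------------------------------------------
# rank statistics
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(x, y):
    """Two-sided rank-sum test with midrank ties.

    Exact null when both groups have n <= 10 and no ties; normal
    approximation with tie correction otherwise.  Returns (statistic, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples must have at least 2 observations")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= 10 and y.size <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def spearman_rho(x, y, seed: int = 0, n_perm: int = 10_000):
    """Spearman rank correlation with pairwise-complete missing handling.

    Permutation p-value for n <= 9 (exact enumeration up to n = 7, seeded
    Monte-Carlo otherwise); t-approximation for larger n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("zero rank variance: correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        import itertools

        def corr(perm):
            return np.corrcoef(rx, ry[list(perm)])[0, 1]

        if n <= 7:
            perms = itertools.permutations(range(n))
            vals = np.array([corr(p) for p in perms])
        else:
            rng = np.random.default_rng(seed)
            vals = np.array([corr(rng.permutation(n)) for _ in range(n_perm)])
        p = float(np.mean(np.abs(vals) >= abs(rho) - 1e-12))
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


# ---------------------------------------------------------------------------
# PLS (NIPALS)
# ---------------------------------------------------------------------------


class PLSModel:
    """PLS1 regression fitted by NIPALS on autoscaled columns.

    For discrimination, code class labels +1/-1 and threshold the predicted
    score.  ``coef_`` is on the original (unscaled) X scale; successive
    score vectors are mutually orthogonal.
    """

    def __init__(self, ncomp: int = 3, balanced: bool = False):
        self.ncomp = ncomp
        #: balanced centering for discrimination: center y (and X) on the
        #: midpoint of the class means so that the fitted offset does not
        #: depend on the class composition of the training fold -- removes
        #: the small-sample pessimism of LOOCV scores under the null
        self.balanced = balanced

    def fit(self, X, y, column_names=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        names = list(column_names) if column_names is not None else [f"x{j}" for j in range(p)]
        if self.balanced and np.unique(y).size == 2:
            pos = y == np.max(y)
            self.x_mean_ = (X[pos].mean(axis=0) + X[~pos].mean(axis=0)) / 2.0
            self.y_mean_ = (y[pos].mean() + y[~pos].mean()) / 2.0
        else:
            self.x_mean_ = X.mean(axis=0)
            self.y_mean_ = y.mean()
        self.x_std_ = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(self.x_std_ == 0)
        if zero.size:
            raise ValueError(f"zero-variance column(s): {[names[j] for j in zero]}")
        self.y_std_ = y.std(ddof=1) or 1.0
        Xa = (X - self.x_mean_) / self.x_std_
        ya = (y - self.y_mean_) / self.y_std_

        a = min(self.ncomp, n - 1, p)
        W = np.zeros((p, a))
        P = np.zeros((p, a))
        T = np.zeros((n, a))
        q = np.zeros(a)
        for k in range(a):
            w = Xa.T @ ya
            nw = np.linalg.norm(w)
            if nw < 1e-12:
                a = k
                break
            w /= nw
            t = Xa @ w
            tt = t @ t
            pk = Xa.T @ t / tt
            qk = ya @ t / tt
            Xa = Xa - np.outer(t, pk)
            ya = ya - qk * t
            W[:, k], P[:, k], T[:, k], q[k] = w, pk, t, qk
        W, P, T, q = W[:, :a], P[:, :a], T[:, :a], q[:a]
        self.n_components_ = a
        self.x_weights_, self.x_loadings_, self.x_scores_, self.y_loadings_ = W, P, T, q
        # b_scaled maps autoscaled X to autoscaled y
        b_scaled = W @ np.linalg.solve(P.T @ W, q) if a else np.zeros(p)
        self.coef_ = b_scaled * self.y_std_ / self.x_std_
        self.intercept_ = self.y_mean_ - self.x_mean_ @ self.coef_
        self.column_names_ = names
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_

    def score(self, X, y):
        """Training R^2."""
        y = np.asarray(y, dtype=float).ravel()
        resid = y - self.predict(X)
        return 1.0 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))


def pls_fit(X, y, ncomp: int = 3, column_names=None) -> PLSModel:
    """Convenience wrapper: fit a PLS1 model and return it."""
    return PLSModel(ncomp=ncomp).fit(X, y, column_names=column_names)


def cross_validated_pls(
    X,
    y,
    ncomp: int = 3,
    scheme: str = "loocv",
    k: int = 3,
    seed: int = 0,
    stratify: bool = None,
    balanced: bool = None,
):
    """Out-of-fold PLS predictions with Spearman rho and RMSE vs truth.

    ``scheme`` is "loocv" or "kfold" (k=3 default, label-stratified for
    binary targets).  Returns ``(predictions, rho, rmse)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    binary = np.unique(y).size == 2
    if stratify is None:
        stratify = binary
    if balanced is None:
        balanced = binary

    if scheme == "loocv":
        folds = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    elif scheme == "kfold":
        rng = np.random.default_rng(seed)
        fold_id = np.empty(n, dtype=int)
        if stratify:
            for lab in np.unique(y):
                idx = rng.permutation(np.flatnonzero(y == lab))
                fold_id[idx] = np.arange(idx.size) % k
        else:
            fold_id[rng.permutation(n)] = np.arange(n) % k
        folds = [
            (np.flatnonzero(fold_id != f), np.flatnonzero(fold_id == f)) for f in range(k)
        ]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    preds = np.empty(n)
    for train, test in folds:
        if binary and np.unique(y[train]).size < 2:
            raise ValueError("degenerate fold: training set contains one class only")
        m = PLSModel(ncomp=ncomp, balanced=balanced).fit(X[train], y[train])
        preds[test] = m.predict(X[test])
    rho = float(stats.spearmanr(preds, y).statistic)
    rmse = float(np.sqrt(np.mean((preds - y) ** 2)))
    return preds, rho, rmse


# ---------------------------------------------------------------------------
# SPA variable selection
# ---------------------------------------------------------------------------


def _spa_round_errors(X, y, active, n_mc, n_sub, subject_frac, ncomp, rng):
    """One batch of subwindow Monte-Carlo rounds: per-round out-of-subset
    misclassification error and the variable-inclusion mask."""
    n = y.size
    pa = active.size
    errors = np.empty(n_mc)
    included = np.zeros((n_mc, pa), dtype=bool)
    cls = [np.flatnonzero(y < 0), np.flatnonzero(y > 0)]
    for r in range(n_mc):
        train = np.concatenate([
            rng.permutation(c)[: max(2, int(round(subject_frac * c.size)))] for c in cls
        ])
        test = np.setdiff1d(np.arange(n), train)
        vsub = rng.permutation(pa)[:n_sub]
        included[r, vsub] = True
        cols = active[vsub]
        try:
            m = PLSModel(ncomp=min(ncomp, n_sub), balanced=True).fit(
                X[np.ix_(train, cols)], y[train])
            pred = m.predict(X[np.ix_(test, cols)])
            errors[r] = np.mean(np.sign(pred) != np.sign(y[test]))
        except ValueError:
            errors[r] = np.nan
    return errors, included


def _spa_importance(errors, included):
    """Per-variable importance: mean error excluding minus mean including."""
    ok = np.isfinite(errors)
    pa = included.shape[1]
    imp = np.full(pa, -np.inf)
    for j in range(pa):
        e_in = errors[ok & included[:, j]]
        e_out = errors[ok & ~included[:, j]]
        if e_in.size >= 5 and e_out.size >= 5:
            imp[j] = e_out.mean() - e_in.mean()
    return imp


def spa_select(
    X,
    y,
    n_mc: int = 10_000,
    seed: int = 0,
    subject_frac: float = 0.7,
    var_frac: float = 0.5,
    alpha: float = 0.05,
    ncomp: int = 3,
    max_outer: int = 10,
    n_null_perm: int = 10,
    column_names=None,
):
    """Subwindow permutation analysis for PLS-DA variable selection.

    Each Monte-Carlo round trains a PLS-DA model on a random subject subset
    (stratified, ``subject_frac``) and a random variable subwindow (at least
    2, at most all-but-one variables) and records the out-of-subset
    misclassification error.  A variable's importance is the mean error of
    rounds excluding it minus the mean error of rounds including it.

    Significance is judged against a dataset-level permutation null: the
    same subwindow procedure is repeated on label-permuted copies of the
    data (``n_null_perm`` permutations, a reduced round count each), and a
    variable is selected when its importance exceeds the ``1 - alpha``
    quantile of the pooled null importances.  This keeps the per-variable
    false-selection rate at ~alpha across datasets, which a round-level
    include/exclude rank test does not (within one dataset a lucky noise
    variable is genuinely, reproducibly "helpful", so round-level p-values
    saturate as the number of rounds grows).

    The procedure repeats on the selected set until two successive passes
    agree (capped at ``max_outer``).  Returns the selected names (possibly
    empty).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 candidate variables")
    names = list(column_names) if column_names is not None else [f"x{j}" for j in range(p)]
    rng = np.random.default_rng(seed)
    active = np.arange(p)

    for _ in range(max_outer):
        pa = active.size
        if pa <= 2:
            break  # a subwindow must exclude something for the importance
        n_sub = min(max(2, int(round(var_frac * pa))), pa - 1)
        errors, included = _spa_round_errors(
            X, y, active, n_mc, n_sub, subject_frac, ncomp, rng)
        imp = _spa_importance(errors, included)

        # dataset-level null: label permutations, pooled importances
        n_mc_null = max(50, n_mc // 5)
        null_imp = []
        for _ in range(n_null_perm):
            y_perm = y[rng.permutation(n)]
            e0, inc0 = _spa_round_errors(
                X, y_perm, active, n_mc_null, n_sub, subject_frac, ncomp, rng)
            ni = _spa_importance(e0, inc0)
            null_imp.extend(ni[np.isfinite(ni)])
        thresh = float(np.quantile(null_imp, 1.0 - alpha)) if null_imp else np.inf

        keep = [active[j] for j in range(pa) if imp[j] > thresh]
        new_active = np.array(sorted(keep), dtype=int)
        if new_active.size == active.size and np.array_equal(new_active, active):
            break
        if new_active.size == 0:
            import warnings

            warnings.warn("SPA selected no variables", stacklevel=2)
            return []
        active = new_active
    return [names[j] for j in active]


# ---------------------------------------------------------------------------
# ROC / odds ratio
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def n_pos(self):
        return self.tp + self.fn

    @property
    def n_neg(self):
        return self.tn + self.fp

    @property
    def sensitivity(self):
        return self.tp / self.n_pos if self.n_pos else np.nan

    @property
    def specificity(self):
        return self.tn / self.n_neg if self.n_neg else np.nan

    @property
    def accuracy(self):
        n = self.n_pos + self.n_neg
        return (self.tp + self.tn) / n if n else np.nan


@dataclass(frozen=True)
class ROCMetrics:
    auc: float
    se: float  # Hanley-McNeil standard error
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Standard error of the AUC with Q1 = A/(2-A), Q2 = 2A^2/(1+A)."""
    a = auc
    q1 = a / (2 - a)
    q2 = 2 * a**2 / (1 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a**2) + (n_neg - 1) * (q2 - a**2)) / (
        n_pos * n_neg
    )
    return float(np.sqrt(max(var, 0.0)))


def roc_metrics(scores, labels):
    """Rank-based AUC plus the Youden-optimal operating point.

    ``labels`` are boolean/0-1 (positive = fractured); higher scores are
    assumed to indicate the positive class.  The operating point maximizes
    Youden's J; ties prefer the higher specificity.  Returns
    ``(ROCMetrics, ConfusionMatrix)``.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels).astype(bool)
    n_pos = int(lab.sum())
    n_neg = int((~lab).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    auc = (ranks[lab].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    se = hanley_mcneil_se(auc, n_pos, n_neg)

    # candidate thresholds: midpoints between consecutive unique scores
    uniq = np.unique(s)
    cand = np.concatenate([[uniq[0] - 1.0], (uniq[1:] + uniq[:-1]) / 2.0, [uniq[-1] + 1.0]])
    best = None
    for thr in cand:
        pred = s >= thr
        tp = int(np.sum(pred & lab))
        fp = int(np.sum(pred & ~lab))
        sens = tp / n_pos
        spec = 1.0 - fp / n_neg
        j = sens + spec - 1.0
        key = (round(j, 12), round(spec, 12))
        if best is None or key > best[0]:
            best = (key, thr, tp, fp)
    _, thr, tp, fp = best
    cm = ConfusionMatrix(tp=tp, fn=n_pos - tp, tn=n_neg - fp, fp=fp)
    roc = ROCMetrics(
        auc=float(auc),
        se=se,
        threshold=float(thr),
        sensitivity=cm.sensitivity,
        specificity=cm.specificity,
        accuracy=cm.accuracy,
    )
    return roc, cm


def odds_ratio(cm: ConfusionMatrix, haldane: bool = True):
    """Diagnostic odds ratio with a Woolf log-normal 95% CI.

    The Haldane-Anscombe +0.5 correction is applied to every cell when any
    cell is zero.  Returns ``(or, (ci_lo, ci_hi))``.
    """
    a, b, c, d = cm.tp, cm.fn, cm.fp, cm.tn
    if haldane and min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = float(np.exp(np.log(orr) - 1.96 * se))
    hi = float(np.exp(np.log(orr) + 1.96 * se))
    return float(orr), (lo, hi)


def compare_auc(roc1: ROCMetrics, roc2: ROCMetrics, r: float = 0.0):
    """Hanley-McNeil z-test between two AUCs with correlation ``r``."""
    if not 0.0 <= r <= 1.0:
        raise ValueError("correlation must lie in [0, 1]")
    denom = roc1.se**2 + roc2.se**2 - 2 * r * roc1.se * roc2.se
    if denom <= 0:
        if roc1.auc == roc2.auc:
            return 0.0, 1.0
        raise ZeroDivisionError("zero variance in AUC difference")
    z = (roc1.auc - roc2.auc) / np.sqrt(denom)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# discrimination model (PLS-LOOCV with SPA)
# ---------------------------------------------------------------------------

FEATURE_SETS = {
    "cortbs": [
        "Ct.alpha0", "Ct.alphaf", "Ct.Po.Dm.D_Peak", "Ct.Po.Dm.D_Q10",
        "Ct.Po.Dm.D_Q90", "Ct.Po.Dm.D_FWHM", "Ct.Po.Dm.D_FWHM_min",
        "Ct.Po.Dm.D_FWHM_max",
    ],
    "dxa": ["T_score_Femur", "T_score_Spine", "T_score_Total"],
    "hrpqct": [
        "Ct.Th_ROI", "Ct.Po_BH_ROI", "Ct.Po.D_SD_ROI", "Ct.Po.D_skewness_Full",
        "Ct.Po.D_kurtosis_Full", "Ct.Po.Dm.D_Mean_ROI", "Ct.Po.Dm.D_Q90_ROI",
    ],
    "attenuation": ["Ct.alpha0", "Ct.alphaf"],
}
ANTHROPOMETRIC = ["Age", "Height", "Weight", "BMI"]


class DiscriminationModel:
    """PLS-DA fracture discrimination with LOOCV scoring.

    Parameters
    ----------
    X : DataFrame or array
        Candidate predictor columns.
    y : array of bool
        Fracture endpoint labels (True = fractured).
    ncomp : int
        PLS components of the final model (three by default).
    select : bool
        Run SPA variable selection before the final LOOCV model.
    """

    def __init__(self, X, y, ncomp: int = 3, select: bool = False,
                 spa_n_mc: int = 1000, column_names=None):
        if isinstance(X, pd.DataFrame):
            self.names = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.names = list(column_names) if column_names else [
                f"x{j}" for j in range(X.shape[1])
            ]
        keep = np.all(np.isfinite(X), axis=1)  # listwise deletion
        self.X = X[keep]
        self.y = np.asarray(y).astype(bool)[keep]
        self.n_dropped = int((~keep).sum())
        self.ncomp = ncomp
        self.select = select
        self.spa_n_mc = spa_n_mc

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame, endpoint: str = "all",
                    features: str = "cortbs", anthropometric: bool = False,
                    **kw) -> "DiscriminationModel":
        cols = list(FEATURE_SETS[features])
        if anthropometric:
            cols = cols + ANTHROPOMETRIC
        if endpoint == "all":
            y = cohort["group"] == "Fx"
        elif endpoint == "vertebral":
            y = cohort["fracture_vertebral"]
            mask = y | (cohort["group"] == "nFx")
            cohort = cohort[mask]
            y = y[mask]
        elif endpoint == "other":
            y = cohort["fracture_other"]
            mask = y | (cohort["group"] == "nFx")
            cohort = cohort[mask]
            y = y[mask]
        else:
            raise ValueError(f"unknown endpoint {endpoint!r}")
        return cls(cohort[cols], y.to_numpy(), **kw)

    def fit(self, seed: int = 0) -> "DiscriminationResults":
        ycode = np.where(self.y, 1.0, -1.0)
        names = self.names
        X = self.X
        if self.select:
            sel = spa_select(X, ycode, n_mc=self.spa_n_mc, seed=seed,
                             column_names=names)
            if len(sel) >= 2:
                idx = [names.index(s) for s in sel]
                X = X[:, idx]
                names = sel
        scores, _, _ = cross_validated_pls(X, ycode, ncomp=min(self.ncomp, X.shape[1]),
                                           scheme="loocv")
        roc, cm = roc_metrics(scores, self.y)
        orr, ci = odds_ratio(cm)
        return DiscriminationResults(
            model=self, scores=scores, selected=names, roc=roc,
            confusion=cm, odds_ratio=orr, or_ci=ci,
        )


@dataclass
class DiscriminationResults:
    """LOOCV discrimination scores and the derived operating metrics."""

    model: DiscriminationModel
    scores: np.ndarray
    selected: list
    roc: ROCMetrics
    confusion: ConfusionMatrix
    odds_ratio: float
    or_ci: tuple

    def summary_row(self) -> dict:
        """Row shaped like the study's discrimination-performance table."""
        return {
            "n_fx": self.confusion.n_pos,
            "n_nfx": self.confusion.n_neg,
            "sensitivity": round(self.roc.sensitivity, 2),
            "specificity": round(self.roc.specificity, 2),
            "AUC": round(self.roc.auc, 2),
            "SE": round(self.roc.se, 3),
            "accuracy": round(self.roc.accuracy, 2),
            "OR": round(self.odds_ratio, 2),
            "OR_CI": (round(self.or_ci[0], 1), round(self.or_ci[1], 1)),
            "variables": " ".join(self.selected),
        }

    def summary(self) -> str:
        r = self.summary_row()
        lines = ["PLS-LOOCV fracture discrimination", "-" * 34]
        for k, v in r.items():
            lines.append(f"  {k:>12s} : {v}")
        return "\n".join(lines)
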
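"""Cohort-level diagnostic statistics for response prediction.

The analysis layer mirrors common clinical-imaging practice:

* paired and unpaired location comparisons gated on a Shapiro-Wilk
  normality check (parametric t tests when normal, rank tests when
  not; Levene's test additionally gates the pooled-variance t);
* chi-square / continuity-corrected / Fisher tests for categorical
  tables, chosen by expected-count rules;
* a logistic-regression combination of several markers into a single
  predicted-probability score (PRE);
* empirical ROC analysis with a Youden-optimal cutoff, DeLong
  confidence intervals, likelihood ratios and predictive values at the
  cohort prevalence, and the paired DeLong test for comparing two
  correlated ROC curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression

__all__ = [
    "GroupComparison",
    "RocResult",
    "DiagnosticMetrics",
    "LogisticCombination",
    "compare_paired",
    "compare_unpaired",
    "t_from_summary",
    "compare_categorical",
    "logistic_combine",
    "roc_analysis",
    "diagnostic_metrics",
    "delong_compare",
]


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    test: str
    statistic: float
    p_value: float
    summary_1: dict
    summary_2: dict

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Operating-point metrics at a given prevalence.

    Predictive values are computed from integer confusion counts
    reconstructed at the cohort prevalence (TP = round(sens * n_pos)
    etc.), the convention of clinical ROC software; they are reported
    as percentages.
    """

    youden: float
    plr: float
    nlr: float
    ppv_pct: float
    npv_pct: float
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass(frozen=True)
class RocResult:
    marker: str
    orientation: str  # "higher" or "lower" predicts the positive class
    auc: float
    ci95: tuple[float, float]
    youden: float
    cutoff: float
    sensitivity: float
    specificity: float
    plr: float
    nlr: float
    ppv_pct: float
    npv_pct: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class LogisticCombination:
    scores: np.ndarray  # fitted probability of the positive class
    coefficients: np.ndarray
    intercept: float
    feature_names: tuple
    separation: bool


def _mean_sd(x: np.ndarray) -> dict:
    return {"mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1))}


def _median_iqr(x: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {"median": float(med), "iqr": float(q3 - q1)}


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return stats.shapiro(x).pvalue > alpha


def compare_paired(pre, post, alpha_normality: float = 0.05,
                   variable: str = "") -> GroupComparison:
    """Paired location comparison with a normality gate on differences.

    Shapiro-Wilk on the paired differences selects the paired t test
    (normal) or the Wilcoxon signed-rank test (non-normal); summaries
    are mean +/- SD or median (IQR) accordingly.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.size < 3:
        raise ValueError("paired samples must have equal length >= 3")
    diffs = post - pre
    if np.all(diffs == 0):
        return GroupComparison(variable, "paired t", 0.0, 1.0,
                               _mean_sd(pre), _mean_sd(post))
    if _is_normal(diffs, alpha_normality):
        res = stats.ttest_rel(post, pre)
        return GroupComparison(variable, "paired t", float(res.statistic),
                               float(res.pvalue), _mean_sd(pre), _mean_sd(post))
    res = stats.wilcoxon(post, pre)
    return GroupComparison(variable, "Wilcoxon signed-rank", float(res.statistic),
                           float(res.pvalue), _median_iqr(pre), _median_iqr(post))


def compare_unpaired(g1, g2, alpha_normality: float = 0.05,
                     variable: str = "") -> GroupComparison:
    """Two-sample comparison gated on normality and variance homogeneity.

    Pooled-variance Student t when both groups pass Shapiro-Wilk and
    Levene's test finds homogeneous variances; Mann-Whitney U (two
    sided, tie-corrected) otherwise.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.size < 3 or g2.size < 3:
        raise ValueError("both groups need n >= 3")
    normal = _is_normal(g1, alpha_normality) and _is_normal(g2, alpha_normality)
    if normal:
        homoscedastic = stats.levene(g1, g2).pvalue > alpha_normality
        if homoscedastic:
            res = stats.ttest_ind(g1, g2, equal_var=True)
            return GroupComparison(variable, "Student t", float(res.statistic),
                                   float(res.pvalue), _mean_sd(g1), _mean_sd(g2))
    res = stats.mannwhitneyu(g1, g2, alternative="two-sided")
    return GroupComparison(variable, "Mann-Whitney U", float(res.statistic),
                           min(float(res.pvalue), 1.0), _median_iqr(g1), _median_iqr(g2))


def t_from_summary(mean1: float, sd1: float, n1: int,
                   mean2: float, sd2: float, n2: int) -> float:
    """|t| of the pooled-variance Student t test from group summaries."""
    if n1 < 2 or n2 < 2 or sd1 <= 0 or sd2 <= 0:
        raise ValueError("need n >= 2 and positive SDs in both groups")
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    return float(abs(mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2)))


def compare_categorical(table, variable: str = "") -> GroupComparison:
    """Association test on a contingency table by expected-count rules.

    Plain chi-square when every expected count is >= 5; for a 2x2
    table, Yates continuity correction when an expected count falls in
    [1, 5), and Fisher's exact test when any expected count is below 1
    or the total sample is small (n < 40, the classic rule).  Larger
    sparse tables fall back to the chi-square with a warning, as exact
    tests beyond 2x2 are out of scope.
    """
    table = np.asarray(table)
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("contingency table must hold non-negative integers")
    margins1 = {"counts": table[0].tolist()}
    margins2 = {"counts": table[1].tolist()} if table.shape[0] > 1 else {}
    expected = stats.contingency.expected_freq(table)
    is_2x2 = table.shape == (2, 2)
    if is_2x2 and (expected.min() < 1.0 or table.sum() < 40):
        res = stats.fisher_exact(table)
        return GroupComparison(variable, "Fisher exact", float(res.statistic),
                               float(res.pvalue), margins1, margins2)
    if is_2x2 and expected.min() < 5.0:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
        return GroupComparison(variable, "chi-square (continuity-corrected)",
                               float(chi2), float(p), margins1, margins2)
    if expected.min() < 5.0 and not is_2x2:
        warnings.warn("expected counts < 5 in a non-2x2 table; chi-square "
                      "approximation may be poor", stacklevel=2)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return GroupComparison(variable, "chi-square", float(chi2), float(p),
                           margins1, margins2)


def logistic_combine(features, labels, feature_names=None,
                     ridge_on_separation: float = 1e-6) -> LogisticCombination:
    """Combine markers into one predictive score by logistic regression.

    Fits an unpenalised maximum-likelihood logistic model with all
    features entered simultaneously; the returned score is the fitted
    probability of the positive class.  Features are centred
    internally, which keeps constant columns at a zero coefficient.
    Complete separation (which sends coefficients to infinity) is
    detected and flagged, and the model is refitted with a tiny ridge
    penalty so a usable score is still produced.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] == 1 and np.asarray(labels).size > 1:
        X = X.T
    y = np.asarray(labels).astype(int)
    if X.shape[0] != y.size:
        raise ValueError("features and labels disagree in length")
    if np.any(~np.isfinite(X)):
        raise ValueError("missing values are not supported")
    if min(np.sum(y == 1), np.sum(y == 0)) < 2:
        raise ValueError("need at least 2 patients in each class")
    if feature_names is None:
        feature_names = tuple(f"x{i}" for i in range(X.shape[1]))
    Xc = X - X.mean(axis=0)

    def fit(C):
        model = LogisticRegression(C=C, solver="lbfgs", max_iter=5000, tol=1e-10)
        return model.fit(Xc, y)

    # C = 1/lambda; near-zero penalty approximates the MLE
    model = fit(1e10)
    scores = model.predict_proba(Xc)[:, 1]
    # strictly separated fitted scores expose a separating hyperplane,
    # under which the unpenalised MLE diverges
    separation = bool(np.min(scores[y == 1]) > np.max(scores[y == 0]))
    if separation:
        model = fit(1.0 / ridge_on_separation)
        scores = model.predict_proba(Xc)[:, 1]
    return LogisticCombination(scores, model.coef_.ravel().copy(),
                               float(model.intercept_[0]),
                               tuple(feature_names), separation)


def _auc_midrank(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the Mann-Whitney statistic U/(n_pos*n_neg), ties count 1/2."""
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    m = pos.size
    u = ranks[:m].sum() - m * (m + 1) / 2.0
    return float(u / (m * neg.size))


def _delong_components(pos: np.ndarray, neg: np.ndarray):
    """DeLong structural components (V10 per positive, V01 per negative)."""
    diff_p = pos[:, None] - neg[None, :]
    psi = np.where(diff_p > 0, 1.0, np.where(diff_p == 0, 0.5, 0.0))
    return psi.mean(axis=1), psi.mean(axis=0)


def diagnostic_metrics(sensitivity: float, specificity: float,
                       n_pos: int, n_neg: int) -> DiagnosticMetrics:
    """Youden index, likelihood ratios and predictive values.

    +LR = sens/(1-spec) (infinite at perfect specificity), -LR =
    (1-sens)/spec; PPV/NPV from confusion counts reconstructed at the
    prevalence n_pos/(n_pos+n_neg).
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both classes need at least one subject")
    tp = round(sensitivity * n_pos)
    fn = n_pos - tp
    fp = round((1.0 - specificity) * n_neg)
    tn = n_neg - fp
    plr = np.inf if specificity == 1.0 else sensitivity / (1.0 - specificity)
    nlr = np.inf if specificity == 0.0 else (1.0 - sensitivity) / specificity
    ppv = 100.0 * tp / (tp + fp) if tp + fp else np.nan
    npv = 100.0 * tn / (tn + fn) if tn + fn else np.nan
    return DiagnosticMetrics(sensitivity + specificity - 1.0, float(plr),
                             float(nlr), float(ppv), float(npv), tp, fp, tn, fn)


def roc_analysis(scores, labels, marker: str = "",
                 orientation: str | None = None) -> RocResult:
    """Empirical ROC analysis with a Youden-optimal operating point.

    The AUC is the trapezoidal area, identical to the Mann-Whitney
    U/(n_pos*n_neg) with ties counted one half.  Orientation (whether
    high or low marker values predict the positive class) is chosen
    automatically so the AUC is >= 0.5, and recorded rather than
    silently hidden.  The reported cutoff maximises Youden's index over
    all empirical thresholds, is placed midway between adjacent
    observed values, and ties resolve to the smallest cutoff on the
    original marker scale.  The 95% CI uses the DeLong variance.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if scores.shape != y.shape:
        raise ValueError("scores and labels disagree in shape")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    auc_raw = _auc_midrank(scores[y], scores[~y])
    if orientation is None:
        orientation = "higher" if auc_raw >= 0.5 else "lower"
    s = scores if orientation == "higher" else -scores
    auc = _auc_midrank(s[y], s[~y])
    v10, v01 = _delong_components(s[y], s[~y])
    var = (np.var(v10, ddof=1) / n_pos if n_pos > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n_neg if n_neg > 1 else 0.0)
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    ci = (max(auc - half, 0.0), min(auc + half, 1.0))

    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    best = None
    for c in candidates:
        pred = s >= c
        sens = np.count_nonzero(pred & y) / n_pos
        spec = np.count_nonzero(~pred & ~y) / n_neg
        j = sens + spec - 1.0
        cut_orig = c if orientation == "higher" else -c
        key = (-j, cut_orig)
        if best is None or key < best[0]:
            best = (key, c, sens, spec)
    _, cut, sens, spec = best
    cutoff = float(cut if orientation == "higher" else -cut)
    dm = diagnostic_metrics(sens, spec, n_pos, n_neg)
    return RocResult(marker, orientation, auc, ci, dm.youden, cutoff,
                     sens, spec, dm.plr, dm.nlr, dm.ppv_pct, dm.npv_pct,
                     n_pos, n_neg)


def delong_compare(scores1, scores2, labels) -> tuple[float, float, float]:
    """Paired DeLong test for two correlated ROC AUCs.

    Both markers are oriented so their AUCs are >= 0.5 before the
    comparison (matching how each would be reported).  Returns
    ``(auc_difference, z, p)``; rank-preserving transforms of a marker
    leave the result unchanged.
    """
    y = np.asarray(labels).astype(bool)
    out = []
    for sc in (scores1, scores2):
        sc = np.asarray(sc, dtype=float)
        if sc.shape != y.shape:
            raise ValueError("scores and labels disagree in shape")
        if _auc_midrank(sc[y], sc[~y]) < 0.5:
            sc = -sc
        out.append(sc)
    s1, s2 = out
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    a1 = _auc_midrank(s1[y], s1[~y])
    a2 = _auc_midrank(s2[y], s2[~y])
    v10 = np.column_stack([_delong_components(s1[y], s1[~y])[0],
                           _delong_components(s2[y], s2[~y])[0]])
    v01 = np.column_stack([_delong_components(s1[y], s1[~y])[1],
                           _delong_components(s2[y], s2[~y])[1]])
    s10 = np.cov(v10, rowvar=False)
    s01 = np.cov(v01, rowvar=False)
    cov = s10 / n_pos + s01 / n_neg
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    diff = a1 - a2
    if diff == 0.0 or var_diff <= 0.0:
        z = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0.0 else 0.0
        return float(diff), float(z), float(p)
    z = diff / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(diff), float(z), float(p)
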
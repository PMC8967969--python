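"""Validation-battery statistics.

Covers the clinimetric toolkit needed to validate an ordinal-ish clinical
score against a reference standard and to characterise its test-retest
reliability:

* rank correlations — Spearman's rho and Kendall's tau-b (tie-aware),
* group differences — Mann-Whitney U and Wilcoxon signed-rank, with exact
  small-sample p-values,
* diagnostic discrimination — empirical ROC with Youden-index cutpoint and a
  stratified-bootstrap AUC confidence interval,
* reliability — ICC(2,1) (two-way random effects, absolute agreement, single
  measurement) with its F-based 95% CI, ANOVA variance components, the
  standard error of measurement SEM = sqrt(sigma_trial^2 + sigma_error^2)
  and the minimal detectable change MDC95 = SEM * sqrt(2) * 1.96,
* Bonferroni control of the family-wise error rate.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn import metrics as skmetrics

from .errors import DataError

MDC_FACTOR = float(np.sqrt(2.0) * 1.96)


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "spearman_rho" | "kendall_tau_b"
    estimate: float
    p_value: float
    n: int


@dataclass(frozen=True)
class GroupTestResult:
    method: str  # "mann_whitney_u" | "wilcoxon_signed_rank"
    statistic: float
    p_value: float
    n: int  # total n (MW) or number of pairs after zero removal (Wilcoxon)


@dataclass(frozen=True)
class RocResult:
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    n_normal: int
    n_impaired: int


@dataclass(frozen=True)
class ReliabilityResult:
    icc: float
    icc_ci_low: float
    icc_ci_high: float
    sem: float
    mdc95: float
    systematic_p: float
    n: int
    var_subject: float
    var_trial: float
    var_error: float

    def summary(self) -> str:
        return (
            f"ICC(2,1) = {self.icc:.3f} [{self.icc_ci_low:.3f}, {self.icc_ci_high:.3f}]  "
            f"SEM = {self.sem:.3f}  MDC95 = {self.mdc95:.3f}  "
            f"systematic-error p = {self.systematic_p:.3f}  (n = {self.n})"
        )


def _paired(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("paired samples must be 1-D arrays of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < min_n:
        raise DataError(f"need at least {min_n} complete pairs, got {x.size}")
    return x, y


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact p by full enumeration of rank permutations (tie-free)."""
    n = x.size
    ranks = np.arange(1, n + 1)
    denom = n * (n * n - 1)
    order_x = np.argsort(x)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        d = ranks - ranks[list(perm)]
        r = 1 - 6 * float(np.sum(d * d)) / denom
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation (midranks for ties), two-sided p.

    The p-value is exact (full permutation enumeration) for n <= 8 without
    ties, otherwise the usual t-approximation.
    """
    x, y = _paired(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("correlation undefined for a constant vector")
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    ties = (np.unique(x).size < x.size) or (np.unique(y).size < y.size)
    if x.size <= 8 and not ties:
        p = _exact_spearman_p(x, y, rho)
    else:
        p = float(res.pvalue)
    return CorrelationResult("spearman_rho", rho, p, int(x.size))


def kendall_tau_b(x, y) -> CorrelationResult:
    """Kendall's tau-b with tie corrections, two-sided p."""
    x, y = _paired(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("tau-b undefined when one variable is entirely tied")
    res = stats.kendalltau(x, y, variant="b")
    return CorrelationResult("kendall_tau_b", float(res.statistic), float(res.pvalue), int(x.size))


def mann_whitney(a, b) -> GroupTestResult:
    """Two-sided Mann-Whitney U test (midranks), U reported for sample ``a``.

    Exact p when the pooled sample is tie-free and n1*n2 <= 400; otherwise
    the tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise DataError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not ties and a.size * b.size <= 400) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupTestResult(
        "mann_whitney_u", float(res.statistic), float(res.pvalue), int(a.size + b.size)
    )


def _exact_signed_rank_p(d: np.ndarray) -> tuple[float, float]:
    """Exact two-sided p by enumerating all 2^n sign assignments.

    Uses midranks of |d|, so tied absolute differences are handled; the null
    distribution of W+ is symmetric around n(n+1)/4 and the two-sided p is
    the probability of a deviation at least as large as observed.
    """
    ranks = stats.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    n = d.size
    mu = ranks.sum() / 2.0
    count = 0
    for mask in range(2**n):
        signs = (mask >> np.arange(n)) & 1
        w = float(ranks[signs == 1].sum())
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return w_obs, count / 2**n


def wilcoxon_signed_rank(pre, post) -> GroupTestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (classic Wilcoxon rule). If every pair is
    tied the result degenerates to p = 1 with a warning. Exact p (full
    sign-flip enumeration, midranks) for n <= 12, otherwise the
    continuity-corrected normal approximation.
    """
    pre, post = _paired(pre, post, min_n=1)
    d = post - pre
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; signed-rank test is degenerate")
        return GroupTestResult("wilcoxon_signed_rank", 0.0, 1.0, 0)
    if d.size <= 12:
        w_plus, p = _exact_signed_rank_p(d)
        ranks = stats.rankdata(np.abs(d))
        statistic = min(w_plus, float(ranks.sum()) - w_plus)  # scipy's W convention
        return GroupTestResult("wilcoxon_signed_rank", statistic, p, int(d.size))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns about ties in the approximation
        res = stats.wilcoxon(d, method="approx", correction=True)
    return GroupTestResult(
        "wilcoxon_signed_rank", float(res.statistic), float(res.pvalue), int(d.size)
    )


def _empirical_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based empirical AUC (used only inside the bootstrap for speed)."""
    r = stats.rankdata(scores)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    return (r[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


def roc_youden(
    scores, labels, n_boot: int = 2000, seed: int = 0
) -> RocResult:
    """Empirical ROC with the Youden-optimal cutpoint and bootstrap AUC CI.

    ``labels`` is boolean with True = normal; higher scores indicate more
    normal patterns and a subject is classified normal when
    ``score >= cutoff``. Among cutoffs with equal Youden J the one with the
    highest sensitivity is reported. The 95% CI is a stratified bootstrap
    (resampling within each class) percentile interval.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    keep = np.isfinite(scores)
    scores, labels = scores[keep], labels[keep]
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise DataError("ROC needs at least one subject of each class")

    fpr, tpr, thresholds = skmetrics.roc_curve(labels, scores)
    auc = float(skmetrics.auc(fpr, tpr))
    j = tpr - fpr
    # drop the sklearn sentinel threshold (inf); tie-break: max J, then max tpr
    valid = np.isfinite(thresholds)
    best_j = j[valid].max()
    cand = np.flatnonzero(valid & (j >= best_j - 1e-12))
    best = cand[np.argmax(tpr[cand])]
    cutoff = float(thresholds[best])

    rng = np.random.default_rng(seed)
    pos, neg = scores[labels], scores[~labels]
    aucs = np.empty(n_boot)
    for i in range(n_boot):
        bs = np.concatenate([rng.choice(pos, n1, replace=True), rng.choice(neg, n0, replace=True)])
        bl = np.concatenate([np.ones(n1, bool), np.zeros(n0, bool)])
        aucs[i] = _empirical_auc(bs, bl)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return RocResult(
        auc=auc,
        auc_ci_low=float(lo),
        auc_ci_high=float(hi),
        cutoff=cutoff,
        sensitivity=float(tpr[best]),
        specificity=float(1 - fpr[best]),
        n_normal=n1,
        n_impaired=n0,
    )


def _anova_two_way(scores: np.ndarray) -> tuple[float, float, float, int, int]:
    """Mean squares (rows, columns, error) of the two-way crossed layout."""
    n, k = scores.shape
    grand = scores.mean()
    row_means = scores.mean(axis=1)
    col_means = scores.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((scores - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc_2_1(scores, alpha: float = 0.05) -> ReliabilityResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rating.

    ``scores`` is an (n_subjects x k_sessions) matrix, typically k = 2
    (test and retest). Returns the ICC with its F-based 95% CI, the ANOVA
    variance components (subject, trial/session, residual error) with
    negative estimates clamped to zero, the SEM/MDC95 derived from the trial
    and error components, and the p-value of a signed-rank test for a
    systematic test-retest shift.
    """
    scores = np.asarray(scores, float)
    if scores.ndim != 2 or scores.shape[1] < 2:
        raise DataError("need an (n x k>=2) score matrix")
    if not np.all(np.isfinite(scores)):
        raise DataError("reliability analysis requires a complete score matrix")
    n, k = scores.shape
    if n < 3:
        raise DataError(f"need at least 3 subjects, got {n}")
    if np.ptp(scores) == 0:
        warnings.warn("zero total variance; ICC is undefined")
        return ReliabilityResult(
            float("nan"), float("nan"), float("nan"), 0.0, 0.0, 1.0, n, 0.0, 0.0, 0.0
        )

    msr, msc, mse, n, k = _anova_two_way(scores)
    icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))

    # F-based CI for the absolute-agreement single-measure ICC
    with np.errstate(divide="ignore", invalid="ignore"):
        one_minus = np.float64(1.0 - icc)
        a = (k * icc) / (n * one_minus)
        b = 1 + (k * icc * (n - 1)) / (n * one_minus)
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
    if np.isfinite(v) and v > 0:
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        denom_l = f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        denom_u = k * msc + (k * n - k - n) * mse + n * f_u * msr
        ci_low = n * (msr - f_l * mse) / denom_l
        ci_high = n * (f_u * msr - mse) / denom_u
    else:  # perfect agreement: MSE == 0 degenerates the F machinery
        ci_low = ci_high = icc

    var_subject = (msr - mse) / k
    var_trial = (msc - mse) / n
    var_error = mse
    clamped = {}
    for name, val in (("subject", var_subject), ("trial", var_trial), ("error", var_error)):
        if val < 0:
            warnings.warn(f"negative {name} variance component ({val:.3g}) clamped to 0")
            val = 0.0
        clamped[name] = val

    sem, mdc95 = sem_mdc(clamped["trial"], clamped["error"])
    if k == 2:
        systematic = wilcoxon_signed_rank(scores[:, 0], scores[:, 1]).p_value
    else:
        systematic = float("nan")
    return ReliabilityResult(
        icc=float(icc),
        icc_ci_low=float(ci_low),
        icc_ci_high=float(ci_high),
        sem=sem,
        mdc95=mdc95,
        systematic_p=float(systematic),
        n=n,
        var_subject=clamped["subject"],
        var_trial=clamped["trial"],
        var_error=clamped["error"],
    )


def sem_mdc(
    var_trial: float, var_error: float, *, sd: float | None = None, icc: float | None = None,
    method: str = "trial_error",
) -> tuple[float, float]:
    """SEM and MDC95 from ANOVA variance components.

    Default: SEM = sqrt(sigma_trial^2 + sigma_error^2) with the trial
    (session) and residual-error variance components; MDC95 = SEM * sqrt(2)
    * 1.96. The classic ``sd * sqrt(1 - ICC)`` form is available as
    ``method="classic"`` but is never the default.
    """
    if method == "classic":
        if sd is None or icc is None:
            raise DataError("classic SEM needs sd and icc")
        sem = float(sd * np.sqrt(max(1 - icc, 0.0)))
    elif method == "trial_error":
        for name, val in (("trial", var_trial), ("error", var_error)):
            if val < 0:
                warnings.warn(f"negative {name} variance clamped to 0")
        sem = float(np.sqrt(max(var_trial, 0.0) + max(var_error, 0.0)))
    else:
        raise DataError(f"unknown SEM method {method!r}")
    return sem, sem * MDC_FACTOR


def bonferroni(p_values, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Family-wise error control: flags p < alpha/m, returns (flags, alpha/m)."""
    p = np.asarray(p_values, float)
    if p.size < 1:
        raise DataError("need at least one p-value")
    adjusted = alpha / p.size
    return p < adjusted, float(adjusted)
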
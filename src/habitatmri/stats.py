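"""Group comparisons, ROC/Youden analysis and inter-rater agreement.

Conventions chosen to match the source analyses of this kind of cohort:

* Pearson chi-square on 2x2 tables **without** continuity correction.
* Welch two-sample t-test (pooled variant available), accepting either raw
  samples or (mean, SD, n) summaries.
* Mann-Whitney U and Wilcoxon signed-rank with exact enumeration on small
  samples (combined n <= 12 / nonzero pairs <= 15, midranks on ties) and
  tie-corrected normal approximation otherwise.
* Empirical AUC with the Mann-Whitney estimator (ties count 1/2), DeLong CI,
  Youden-optimal cutoff at the midpoint between adjacent observed scores.
* ICC(2,1): two-way random effects, absolute agreement, single measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "RocSummary",
    "AgreementReport",
    "pearson_chi2",
    "two_sample_t",
    "mann_whitney",
    "wilcoxon_paired",
    "roc_youden",
    "icc",
    "shapiro_gate",
    "compare_groups",
    "median_iqr",
]


@dataclass
class TestResult:
    test: str
    statistic: float
    p: float
    df: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


@dataclass
class RocSummary:
    auc: float
    ci_low: float
    ci_high: float
    sensitivity: float
    specificity: float
    cutoff: float
    youden_j: float


@dataclass
class AgreementReport:
    icc: float
    variant: str


def pearson_chi2(table) -> TestResult:
    """Pearson chi-square on a 2x2 table, no continuity correction, df = 1."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("cell counts must be nonnegative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a margin is zero")
    chi2, p, dof, _ = sps.chi2_contingency(t, correction=False)
    return TestResult("pearson_chi2", float(chi2), float(p), float(dof))


def _is_summary(arg) -> bool:
    return isinstance(arg, tuple) and len(arg) == 3 and np.isscalar(arg[0])


def two_sample_t(x, y, equal_var: bool = False) -> TestResult:
    """Two-sided t-test (Welch by default) on samples or (mean, SD, n) summaries."""
    if _is_summary(x) != _is_summary(y):
        raise ValueError("give both groups as samples or both as summaries")
    if _is_summary(x):
        (m1, s1, n1), (m2, s2, n2) = x, y
        if n1 < 2 or n2 < 2:
            raise ValueError("need n >= 2 per group")
        if s1 <= 0 or s2 <= 0:
            raise ValueError("summary SDs must be positive")
        res = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=equal_var)
    else:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size < 2 or y.size < 2:
            raise ValueError("need n >= 2 per group")
        res = sps.ttest_ind(x, y, equal_var=equal_var)
    name = "t_pooled" if equal_var else "t_welch"
    df = float(getattr(res, "df", np.nan))
    return TestResult(name, float(res.statistic), float(res.pvalue), df)


def _rank_sum_u(ranks_x: np.ndarray, n1: int) -> float:
    return float(ranks_x.sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney(x, y, exact_max_n: int = 12) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration of all C(n1+n2, n1) group labelings (midranks, so ties
    are handled exactly) when the combined sample size is at most
    ``exact_max_n``; otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    u_obs = _rank_sum_u(ranks[:n1], n1)
    mu = n1 * n2 / 2.0
    if n1 + n2 <= exact_max_n:
        dev = abs(u_obs - mu) - 1e-12
        hits = total = 0
        for combo in combinations(range(n1 + n2), n1):
            u = _rank_sum_u(ranks[list(combo)], n1)
            hits += abs(u - mu) >= dev
            total += 1
        return TestResult("mann_whitney_exact", u_obs, hits / total)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult("mann_whitney_normal", float(res.statistic), float(res.pvalue))


def wilcoxon_paired(d, exact_max_n: int = 15) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped.  For at most ``exact_max_n`` nonzero pairs
    the null distribution is enumerated over all 2^n sign patterns on the
    midranks of |d| (exact under ties); larger samples use the normal
    approximation.
    """
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    mu = ranks.sum() / 2.0
    if n <= exact_max_n:
        dev = abs(w_obs - mu) - 1e-12
        hits = 0
        total = 2 ** n
        for signs in range(total):
            w = sum(ranks[i] for i in range(n) if signs >> i & 1)
            hits += abs(w - mu) >= dev
        return TestResult("wilcoxon_exact", w_obs, hits / total)
    res = sps.wilcoxon(d, alternative="two-sided", method="approx", correction=False)
    return TestResult("wilcoxon_normal", float(res.statistic), float(res.pvalue))


def _auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (pos.size * neg.size)


def _delong_variance(scores: np.ndarray, labels: np.ndarray, auc: float) -> float:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    # placement values
    v10 = ((pos[:, None] > neg[None, :]).sum(axis=1)
           + 0.5 * (pos[:, None] == neg[None, :]).sum(axis=1)) / n
    v01 = ((pos[None, :] > neg[:, None]).sum(axis=1)
           + 0.5 * (pos[None, :] == neg[:, None]).sum(axis=1)) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_youden(scores, labels, direction: str = "auto") -> RocSummary:
    """Empirical ROC with DeLong 95% CI and Youden-optimal cutoff.

    ``direction=">"`` treats high scores as the positive class, ``"<"`` the
    reverse; ``"auto"`` picks the orientation with AUC >= 0.5.  The cutoff is
    the midpoint between adjacent observed scores maximizing J (on J ties,
    the cutoff with the higher sensitivity); a case is called positive when
    its (oriented) score >= cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be 0/1")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")

    oriented = scores.copy()
    if direction == "<":
        oriented = -oriented
    elif direction == "auto":
        if _auc_mann_whitney(oriented, labels) < 0.5:
            oriented = -oriented
    elif direction != ">":
        raise ValueError("direction must be '>', '<' or 'auto'")

    auc = _auc_mann_whitney(oriented, labels)
    var = _delong_variance(oriented, labels, auc)
    half = 1.959963984540054 * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    uniq = np.unique(oriented)
    cuts = np.concatenate([[uniq[0] - 1.0], (uniq[1:] + uniq[:-1]) / 2.0, [uniq[-1] + 1.0]])
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    best = None
    for c in cuts:
        pred = oriented >= c
        sens = (pred & (labels == 1)).sum() / n_pos
        spec = (~pred & (labels == 0)).sum() / n_neg
        j = sens + spec - 1.0
        key = (j, sens)
        if best is None or key > best[0]:
            best = (key, float(c), float(sens), float(spec))
    (j, sens), cutoff, sens_v, spec_v = best[0], best[1], best[2], best[3]
    return RocSummary(float(auc), ci[0], ci[1], sens_v, spec_v, cutoff, float(j))


def icc(ratings, variant: str = "absolute") -> AgreementReport:
    """Single-measure two-way random-effects ICC.

    ``variant="absolute"`` is ICC(2,1) (absolute agreement);
    ``variant="consistency"`` is ICC(3,1).  ``ratings`` is subjects x raters.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 raters")
    n, k = x.shape
    if np.ptp(x) == 0:
        raise ValueError("ratings are constant; ICC undefined")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if variant == "absolute":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        value = (msr - mse) / denom
        tag = "ICC(2,1)"
    elif variant == "consistency":
        value = (msr - mse) / (msr + (k - 1) * mse)
        tag = "ICC(3,1)"
    else:
        raise ValueError("variant must be 'absolute' or 'consistency'")
    return AgreementReport(float(value), tag)


def shapiro_gate(x, alpha: float = 0.05) -> bool:
    """True when the Shapiro-Wilk test does not reject normality at alpha."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return False
    return sps.shapiro(x).pvalue >= alpha


def compare_groups(x, y, alpha: float = 0.05) -> TestResult:
    """Normality-gated group comparison used for cohort summary tables.

    Both samples Shapiro-normal at ``alpha`` -> Welch t-test; otherwise
    Mann-Whitney U.  The gate only picks the reported default; call the
    specific test directly to force one.
    """
    if shapiro_gate(x, alpha) and shapiro_gate(y, alpha):
        return two_sample_t(x, y)
    return mann_whitney(x, y)


def median_iqr(x) -> tuple[float, float, float]:
    """Median (P25, P75) with the linear-interpolation quantile convention."""
    x = np.asarray(x, dtype=float)
    q25, q50, q75 = np.percentile(x, [25, 50, 75])
    return float(q50), float(q25), float(q75)
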
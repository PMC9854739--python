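"""Binary-classification metrics and the run-comparison statistics suite.

Covers three layers of evaluation machinery:

1. **Confusion-matrix metrics** — accuracy, sensitivity (TPR),
   specificity (TNR), precision (PPV), NPV and F1 from TP/FP/TN/FN
   counts, plus a brute-force reconstruction of the smallest integer
   confusion matrix consistent with printed sensitivity/specificity
   values (a consistency oracle for published results tables).
2. **Descriptive run statistics** — the full description of a vector of
   per-run accuracies: percentiles, order-statistic median confidence
   interval with its discrete *actual* confidence level, mean/SD/SEM with
   t-intervals, coefficient of variation, geometric/harmonic/quadratic
   means with back-transformed intervals, adjusted sample skewness and
   excess kurtosis.
3. **Comparison tests** — classical one-way ANOVA (from raw data or from
   printed group means/SDs) and the exact one-sample Wilcoxon
   signed-rank test, with the exact two-tailed p-value obtained from the
   full null distribution of the signed-rank sum (equivalent to
   enumerating all 2^n sign patterns) for n <= 25 and a tie-corrected
   normal approximation with continuity correction beyond.

Undefined quantities (zero denominators, zero variance, non-positive
values under a log) are reported as flagged NaNs, never silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_from_predictions",
    "compute_metrics",
    "f1_from_precision_recall",
    "reconstruct_confusion",
    "StatDescription",
    "describe_runs",
    "MedianCI",
    "median_ci",
    "AnovaResult",
    "one_way_anova",
    "anova_from_summary",
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "load_run_matrix",
    "run_matrix_report",
]


# ---------------------------------------------------------------------------
# confusion counts and metrics
# ---------------------------------------------------------------------------


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """The six standard binary metrics; ``undefined`` names flagged NaN fields."""

    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f1: float
    undefined: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "f1": self.f1,
            "undefined": sorted(self.undefined),
        }


def confusion_from_predictions(truth, predicted) -> ConfusionCounts:
    """Count TP/FP/TN/FN with label 1 as the positive (tumor) class."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.size == 0:
        raise ValueError("empty inputs")
    if truth.shape != predicted.shape:
        raise ValueError("truth and prediction lengths differ")
    labels = set(np.unique(truth)) | set(np.unique(predicted))
    if not labels <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return ConfusionCounts(
        tp=int(np.sum((truth == 1) & (predicted == 1))),
        fp=int(np.sum((truth == 0) & (predicted == 1))),
        tn=int(np.sum((truth == 0) & (predicted == 0))),
        fn=int(np.sum((truth == 1) & (predicted == 0))),
    )


def _ratio(num: int, den: int, name: str, undefined: set[str]) -> float:
    if den == 0:
        undefined.add(name)
        return math.nan
    return num / den


def f1_from_precision_recall(ppv: float, tpr: float) -> float:
    """Harmonic mean of precision and sensitivity."""
    if ppv + tpr == 0:
        return math.nan
    return 2.0 * ppv * tpr / (ppv + tpr)


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """All six metrics from counts; zero-denominator ratios are flagged NaN."""
    if c.total == 0:
        raise ValueError("cannot compute metrics on zero total counts")
    undefined: set[str] = set()
    acc = (c.tp + c.tn) / c.total
    sens = _ratio(c.tp, c.tp + c.fn, "sensitivity", undefined)
    spec = _ratio(c.tn, c.tn + c.fp, "specificity", undefined)
    ppv = _ratio(c.tp, c.tp + c.fp, "ppv", undefined)
    npv = _ratio(c.tn, c.tn + c.fn, "npv", undefined)
    if math.isnan(ppv) or math.isnan(sens) or ppv + sens == 0:
        undefined.add("f1")
        f1 = math.nan
    else:
        f1 = f1_from_precision_recall(ppv, sens)
    return MetricsReport(acc, sens, spec, ppv, npv, f1, undefined)


def _min_fraction(target: float, decimals: int, cap: int) -> tuple[int, int]:
    """Smallest-denominator fraction num/den in [0,1] printing as ``target``."""
    half = 0.5 * 10.0 ** (-decimals)
    for den in range(1, cap + 1):
        num = int(np.floor(target * den + 0.5))
        if 0 <= num <= den and abs(num / den - target) < half:
            return num, den
    raise ValueError(
        f"no integer ratio with denominator <= {cap} rounds to {target} at {decimals} decimals"
    )


def reconstruct_confusion(
    sensitivity: float, specificity: float, decimals: int = 9, cap: int = 10000
) -> ConfusionCounts:
    """Smallest integer confusion matrix whose TPR/TNR print as the given values.

    Brute-forces denominators in increasing order independently for the
    positive (tp+fn) and negative (tn+fp) margins, which minimizes the
    total count.  Raises if no solution exists below ``cap``.
    """
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    tp, pos = _min_fraction(sensitivity, decimals, cap)
    tn, neg = _min_fraction(specificity, decimals, cap)
    return ConfusionCounts(tp=tp, fn=pos - tp, tn=tn, fp=neg - tn)


# ---------------------------------------------------------------------------
# descriptive statistics
# ---------------------------------------------------------------------------


@dataclass
class MedianCI:
    lower: float
    upper: float
    actual_level: float  # achieved coverage as a fraction
    below_target: bool
    k: int  # order statistic used (1-based from each end)


def median_ci(values, level: float = 0.95) -> MedianCI:
    """Order-statistic confidence interval for the median.

    Uses the interval (x_(k), x_(n+1-k)) with the largest k whose binomial
    coverage ``1 - 2 P(Bin(n, 1/2) <= k-1)`` still reaches ``level`` — the
    smallest achievable coverage at or above the target.  If even the full
    range (k=1) falls short, it is returned with ``below_target=True``.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 values")
    best_k = 1
    for k in range(n // 2, 0, -1):
        coverage = 1.0 - 2.0 * sps.binom.cdf(k - 1, n, 0.5)
        if coverage >= level:
            best_k = k
            break
    coverage = float(1.0 - 2.0 * sps.binom.cdf(best_k - 1, n, 0.5))
    return MedianCI(
        lower=float(x[best_k - 1]),
        upper=float(x[n - best_k]),
        actual_level=coverage,
        below_target=coverage < level,
        k=best_k,
    )


@dataclass
class StatDescription:
    """Full descriptive summary of a vector of per-run scores."""

    n: int
    minimum: float
    maximum: float
    range: float
    p10: float
    p25: float
    median: float
    p75: float
    p90: float
    median_ci_lower: float
    median_ci_upper: float
    median_ci_actual_level: float
    mean: float
    sd: float
    sem: float
    mean_ci_lower: float
    mean_ci_upper: float
    cv_percent: float
    geometric_mean: float
    geometric_ci_lower: float
    geometric_ci_upper: float
    harmonic_mean: float
    harmonic_ci_lower: float
    harmonic_ci_upper: float
    quadratic_mean: float
    quadratic_ci_lower: float
    quadratic_ci_upper: float
    skewness: float
    kurtosis: float
    sum: float
    flags: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "flags"}
        d["flags"] = sorted(self.flags)
        return d


def _t_interval(center: float, spread_sem: float, n: int) -> tuple[float, float]:
    if spread_sem == 0.0:
        return center, center
    tcrit = sps.t.ppf(0.975, n - 1)
    return center - tcrit * spread_sem, center + tcrit * spread_sem


def describe_runs(values) -> StatDescription:
    """Descriptive statistics of n >= 2 run scores.

    Percentiles use linear interpolation between closest ranks.  Skewness
    is the adjusted Fisher-Pearson sample estimator and kurtosis the
    sample-adjusted excess form; both are flagged NaN when the SD is 0.
    Geometric/harmonic means require strictly positive data (flagged NaN
    otherwise); their intervals are back-transformed t-intervals.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 values")
    flags: set[str] = set()
    mean = float(x.mean())
    # a truly constant vector has SD exactly 0 (avoid cancellation noise)
    sd = 0.0 if x.max() == x.min() else float(x.std(ddof=1))
    sem = sd / math.sqrt(n)
    lo_m, hi_m = _t_interval(mean, sem, n)
    mci = median_ci(x)

    if sd == 0.0:
        skew = kurt = math.nan
        flags |= {"skewness", "kurtosis"}
    else:
        skew = float(sps.skew(x, bias=False))
        kurt = float(sps.kurtosis(x, fisher=True, bias=False))

    if np.all(x > 0):
        logs = np.log(x)
        gm = float(np.exp(logs.mean()))
        glo, ghi = _t_interval(logs.mean(), logs.std(ddof=1) / math.sqrt(n), n)
        gm_lo, gm_hi = math.exp(glo), math.exp(ghi)
        recip = 1.0 / x
        hm = float(1.0 / recip.mean())
        hlo, hhi = _t_interval(recip.mean(), recip.std(ddof=1) / math.sqrt(n), n)
        # larger mean reciprocal -> smaller harmonic mean
        hm_lo, hm_hi = 1.0 / hhi, 1.0 / hlo
    else:
        gm = gm_lo = gm_hi = hm = hm_lo = hm_hi = math.nan
        flags |= {"geometric_mean", "harmonic_mean"}

    sq = x * x
    qm = math.sqrt(float(sq.mean()))
    qlo, qhi = _t_interval(float(sq.mean()), float(sq.std(ddof=1)) / math.sqrt(n), n)
    qm_lo = math.sqrt(max(qlo, 0.0))
    qm_hi = math.sqrt(max(qhi, 0.0))

    mean_cv = math.nan if mean == 0 else 100.0 * sd / abs(mean)
    if mean == 0:
        flags.add("cv_percent")

    return StatDescription(
        n=n,
        minimum=float(x.min()),
        maximum=float(x.max()),
        range=float(x.max() - x.min()),
        p10=float(np.percentile(x, 10)),
        p25=float(np.percentile(x, 25)),
        median=float(np.percentile(x, 50)),
        p75=float(np.percentile(x, 75)),
        p90=float(np.percentile(x, 90)),
        median_ci_lower=mci.lower,
        median_ci_upper=mci.upper,
        median_ci_actual_level=mci.actual_level,
        mean=mean,
        sd=sd,
        sem=sem,
        mean_ci_lower=lo_m,
        mean_ci_upper=hi_m,
        cv_percent=mean_cv,
        geometric_mean=gm,
        geometric_ci_lower=gm_lo,
        geometric_ci_upper=gm_hi,
        harmonic_mean=hm,
        harmonic_ci_lower=hm_lo,
        harmonic_ci_upper=hm_hi,
        quadratic_mean=qm,
        quadratic_ci_lower=qm_lo,
        quadratic_ci_upper=qm_hi,
        skewness=skew,
        kurtosis=kurt,
        sum=float(x.sum()),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# one-way ANOVA
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    ss_between: float
    ss_within: float
    ss_total: float
    df_between: int
    df_within: int
    ms_between: float
    ms_within: float
    f_stat: float
    p_value: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _anova_from_ss(ss_b: float, ss_w: float, df_b: int, df_w: int) -> AnovaResult:
    ms_b = ss_b / df_b
    degenerate = False
    if ss_w == 0.0 or df_w == 0:
        ms_w = 0.0
        f = math.inf if ms_b > 0 else math.nan
        p = 0.0 if ms_b > 0 else math.nan
        degenerate = True
    else:
        ms_w = ss_w / df_w
        f = ms_b / ms_w
        p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(
        ss_between=ss_b,
        ss_within=ss_w,
        ss_total=ss_b + ss_w,
        df_between=df_b,
        df_within=df_w,
        ms_between=ms_b,
        ms_within=ms_w,
        f_stat=f,
        p_value=p,
        degenerate=degenerate,
    )


def one_way_anova(groups: list) -> AnovaResult:
    """Classical one-way ANOVA decomposition over k groups of raw values."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrs):
        raise ValueError("every group needs at least 2 values")
    all_vals = np.concatenate(arrs)
    grand = all_vals.mean()
    ss_b = float(sum(len(a) * (a.mean() - grand) ** 2 for a in arrs))
    ss_w = float(sum(((a - a.mean()) ** 2).sum() for a in arrs))
    df_b = len(arrs) - 1
    df_w = len(all_vals) - len(arrs)
    return _anova_from_ss(ss_b, ss_w, df_b, df_w)


def anova_from_summary(means, sds, n_per_group: int) -> AnovaResult:
    """One-way ANOVA recovered from per-group means and SDs (equal group sizes).

    ``ss_between = n * sum (m_i - m̄)^2`` and ``ss_within = (n-1) * sum sd_i^2``;
    identical to :func:`one_way_anova` on any raw data with those summaries.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if means.shape != sds.shape:
        raise ValueError("means and sds must have equal length")
    if np.any(sds < 0):
        raise ValueError("standard deviations must be non-negative")
    if n_per_group < 2:
        raise ValueError("need n_per_group >= 2")
    k = len(means)
    grand = means.mean()
    ss_b = float(n_per_group * np.sum((means - grand) ** 2))
    ss_w = float((n_per_group - 1) * np.sum(sds ** 2))
    return _anova_from_ss(ss_b, ss_w, k - 1, k * (n_per_group - 1))


# ---------------------------------------------------------------------------
# exact Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

EXACT_ENUMERATION_MAX_N = 25


@dataclass
class WilcoxonResult:
    w_signed: float
    w_pos: float
    w_neg: float
    p_two_tailed: float
    exact: bool
    n_used: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _signed_rank_distribution(double_ranks: np.ndarray) -> np.ndarray:
    """Null distribution of the doubled positive-rank sum over all sign patterns.

    Convolution DP over integers; counts stay exact in float64 for n <= 25
    (total count 2^25 < 2^53).  Equivalent to enumerating all 2^n sign
    assignments.
    """
    total = int(double_ranks.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in double_ranks:
        r = int(r)
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    return dist


def wilcoxon_signed_rank(values, mu0: float = 0.0) -> WilcoxonResult:
    """One-sample Wilcoxon signed-rank test against a hypothesized median.

    Differences exactly equal to ``mu0`` are dropped before ranking (the
    classical zero policy); ties among absolute differences receive
    midranks.  For n <= 25 the two-tailed p-value is exact:
    ``P(W+ <= min(w+, w-)) + P(W+ >= max(w+, w-))`` under the full null
    distribution of sign patterns.  Beyond that, a tie-corrected normal
    approximation with continuity correction is used.
    """
    d = np.asarray(values, dtype=float) - mu0
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise ValueError("all values equal the hypothesized median; test undefined")
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w_signed = w_pos - w_neg

    if n <= EXACT_ENUMERATION_MAX_N:
        double = np.round(2.0 * ranks).astype(int)
        dist = _signed_rank_distribution(double)
        total = dist.sum()  # 2^n
        w_lo = int(round(2.0 * min(w_pos, w_neg)))
        w_hi = int(round(2.0 * max(w_pos, w_neg)))
        p = (dist[: w_lo + 1].sum() + dist[w_hi:].sum()) / total
        return WilcoxonResult(w_signed, w_pos, w_neg, float(min(p, 1.0)), True, n)

    mean = n * (n + 1) / 4.0
    tie_counts = np.unique(np.abs(d), return_counts=True)[1]
    tie_corr = float(np.sum(tie_counts ** 3 - tie_counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr
    z = (w_pos - mean - 0.5 * np.sign(w_pos - mean)) / math.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return WilcoxonResult(w_signed, w_pos, w_neg, p, False, n)


# ---------------------------------------------------------------------------
# run-matrix reporting
# ---------------------------------------------------------------------------


def load_run_matrix(path: str | Path) -> pd.DataFrame:
    """Read a per-run accuracy table (columns: method, run, accuracy)."""
    df = pd.read_csv(path)
    required = {"method", "run", "accuracy"}
    if not required <= set(df.columns):
        raise ValueError(f"run matrix needs columns {sorted(required)}")
    if df.empty:
        raise ValueError("run matrix is empty")
    return df


def run_matrix_report(df: pd.DataFrame, mu0: float = 0.0) -> dict:
    """Description + ANOVA + Wilcoxon report across methods.

    ANOVA is skipped (with a warning entry) when run counts are unequal
    across methods; descriptions and per-method Wilcoxon tests are always
    emitted.
    """
    methods = list(dict.fromkeys(df["method"]))
    groups = {m: df.loc[df["method"] == m, "accuracy"].to_numpy() for m in methods}
    report: dict = {"methods": methods, "description": {}, "wilcoxon": {}}
    for m in methods:
        report["description"][m] = describe_runs(groups[m]).to_dict()
        report["wilcoxon"][m] = wilcoxon_signed_rank(groups[m], mu0).to_dict()
    counts = {len(g) for g in groups.values()}
    if len(methods) >= 2 and len(counts) == 1:
        report["anova"] = one_way_anova([groups[m] for m in methods]).to_dict()
    else:
        report["anova"] = None
        report["anova_warning"] = "ANOVA skipped: need >= 2 methods with equal run counts"
    return report
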
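"""Statistical battery for recalibration analyses.

Nonparametric omnibus and pairwise tests with Bonferroni correction,
two-sample variance F-tests, a paired t-test on log-transformed values,
outlier-screened Pearson correlations, and the per-participant join of
the recalibration index with the Multisensory Influence score from a
companion visuo-haptic integration task.

Effect size for the Kruskal-Wallis omnibus defaults to
``eta2_H = (H - k + 1) / (n - k)``; epsilon-squared
(``H / (n - 1)``) is available as an alternative.  Rank tests use exact
enumeration for small samples without ties and the normal approximation
with tie correction otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st

__all__ = [
    "TestResult",
    "bonferroni",
    "omnibus_group_test",
    "pairwise_ranksum",
    "signed_rank",
    "variance_f_test",
    "paired_t_log",
    "ScreenedCorrelation",
    "screened_pearson",
    "correlate_with_mi",
]

#: Largest sample for which the signed-rank null is enumerated exactly
#: (2**n sign patterns; midranks make ties exact too).
SIGNED_RANK_EXACT_N = 12

#: Largest per-group sample for which the rank-sum test is exact.
RANKSUM_EXACT_N = 25


@dataclass(frozen=True)
class TestResult:
    """One test outcome in the tidy results table."""

    name: str
    label: str
    statistic: float
    df: float | tuple | None
    n: int | tuple
    p: float
    p_adjusted: float | None = None
    effect_size: float | None = None
    tail: str = "two-sided"
    extra: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "analysis": self.label,
            "statistic": self.name,
            "value": self.statistic,
            "df": str(self.df),
            "n": str(self.n),
            "p_raw": self.p,
            "p_adjusted": self.p_adjusted,
            "effect_size": self.effect_size,
            "tail": self.tail,
        }


def bonferroni(p: float, n_comparisons: int) -> float:
    """Bonferroni-adjusted p-value, capped at 1."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return min(1.0, p * n_comparisons)


def _as_groups(values_by_group) -> dict[str, np.ndarray]:
    if isinstance(values_by_group, dict):
        items = values_by_group.items()
    else:
        items = ((f"group{i + 1}", v) for i, v in enumerate(values_by_group))
    out = {}
    for name, vals in items:
        arr = np.asarray(vals, dtype=float).ravel()
        if arr.size == 0:
            raise ValueError(f"group {name!r} is empty")
        out[str(name)] = arr
    return out


def omnibus_group_test(
    values_by_group, effect: str = "eta2_h", label: str = "omnibus"
) -> TestResult:
    """Kruskal-Wallis H test (tie-corrected) across groups with effect size."""
    groups = _as_groups(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, arr in groups.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} needs >=2 values for the omnibus test")
    arrays = list(groups.values())
    h, p = _st.kruskal(*arrays)
    k = len(arrays)
    n = sum(a.size for a in arrays)
    if effect == "eta2_h":
        es = (h - k + 1) / (n - k)
    elif effect == "epsilon2":
        es = h / (n - 1)
    else:
        raise ValueError(f"unknown effect-size formula {effect!r}")
    return TestResult(
        name="Kruskal-Wallis H",
        label=label,
        statistic=float(h),
        df=k - 1,
        n=n,
        p=float(p),
        effect_size=float(es),
        extra={"effect_formula": effect, "group_ns": {g: int(a.size) for g, a in groups.items()}},
    )


def _ranksum_z(x: np.ndarray, y: np.ndarray) -> float:
    """Rank-sum z with tie-corrected variance (no continuity correction)."""
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _st.rankdata(pooled)
    w1 = ranks[:n1].sum()
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1.0))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        raise ValueError("zero rank variance: all values identical")
    return float((w1 - mu) / math.sqrt(var))


def pairwise_ranksum(
    values_by_group,
    n_comparisons: int | None = None,
    tail: str = "two-sided",
    label: str = "pairwise",
) -> list[TestResult]:
    """Bonferroni-corrected Wilcoxon rank-sum tests for every group pair.

    The reported statistic is the tie-corrected normal-approximation z;
    the p-value is exact (Mann-Whitney enumeration) when both samples
    have at most :data:`RANKSUM_EXACT_N` values and carry no ties.
    """
    groups = _as_groups(values_by_group)
    pairs = list(itertools.combinations(groups, 2))
    m = n_comparisons if n_comparisons is not None else len(pairs)
    results = []
    for g1, g2 in pairs:
        x, y = groups[g1], groups[g2]
        pooled = np.concatenate([x, y])
        has_ties = np.unique(pooled).size < pooled.size
        small = x.size <= RANKSUM_EXACT_N and y.size <= RANKSUM_EXACT_N
        method = "exact" if (small and not has_ties) else "asymptotic"
        res = _st.mannwhitneyu(x, y, alternative=tail, method=method)
        z = _ranksum_z(x, y)
        results.append(
            TestResult(
                name="rank-sum z",
                label=f"{label}: {g1} vs {g2}",
                statistic=z,
                df=None,
                n=(int(x.size), int(y.size)),
                p=float(res.pvalue),
                p_adjusted=bonferroni(float(res.pvalue), m),
                tail=tail,
                extra={"U": float(res.statistic), "method": method},
            )
        )
    return results


def _signed_rank_exact_p(
    w_plus: float, abs_ranks: np.ndarray, tail: str, sign_observed: float
) -> float:
    """Exact p by enumerating all 2**n sign assignments (midranks for ties)."""
    n = abs_ranks.size
    sums = np.zeros(1)
    for r in abs_ranks:
        sums = np.concatenate([sums, sums + r])
    mu = abs_ranks.sum() / 2.0
    eps = 1e-9
    if tail == "greater":
        count = np.sum(sums >= w_plus - eps)
    elif tail == "less":
        count = np.sum(sums <= w_plus + eps)
    elif tail == "two-sided":
        count = np.sum(np.abs(sums - mu) >= abs(w_plus - mu) - eps)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return float(count) / float(2**n)


def signed_rank(x, y=None, tail: str = "two-sided", label: str = "signed-rank") -> TestResult:
    """Wilcoxon signed-rank test of paired samples (or one sample vs 0).

    Reports the rank sum of positive differences ``W+`` as the statistic,
    with the tie-corrected normal-approximation z alongside.  Zero
    differences are dropped.  The p-value comes from exact sign-flip
    enumeration when at most :data:`SIGNED_RANK_EXACT_N` non-zero
    differences remain, otherwise from the normal approximation with
    continuity correction.
    """
    xv = np.asarray(x, dtype=float).ravel()
    d = xv - np.asarray(y, dtype=float).ravel() if y is not None else xv
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    ranks = _st.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(counts**3 - counts) / 48.0
    z = (w_plus - mu) / math.sqrt(var) if var > 0 else 0.0

    if n <= SIGNED_RANK_EXACT_N:
        p = _signed_rank_exact_p(w_plus, ranks, tail, np.sign(w_plus - mu))
        method = "exact"
    else:
        cc = 0.5 * np.sign(w_plus - mu)
        z_cc = (w_plus - mu - cc) / math.sqrt(var) if var > 0 else 0.0
        if tail == "greater":
            p = float(_st.norm.sf(z_cc))
        elif tail == "less":
            p = float(_st.norm.cdf(z_cc))
        else:
            p = float(2 * _st.norm.sf(abs(z_cc)))
        method = "normal"
    return TestResult(
        name="W+",
        label=label,
        statistic=w_plus,
        df=None,
        n=n,
        p=min(1.0, p),
        tail=tail,
        extra={"z": float(z), "method": method},
    )


def variance_f_test(x, y, tail: str = "two-sided", label: str = "variance F") -> TestResult:
    """Two-sample F-test on variances, ``F = s1^2 / s2^2``.

    One-sided p tests ``var(x) > var(y)``; the two-sided p doubles the
    smaller tail.  Unbiased (n-1) variance estimates throughout.
    """
    xv = np.asarray(x, dtype=float).ravel()
    yv = np.asarray(y, dtype=float).ravel()
    if xv.size < 2 or yv.size < 2:
        raise ValueError("both samples need >=2 values")
    s1, s2 = xv.var(ddof=1), yv.var(ddof=1)
    if s2 == 0:
        raise ValueError("zero variance in the denominator sample")
    f = s1 / s2
    df1, df2 = xv.size - 1, yv.size - 1
    sf = float(_st.f.sf(f, df1, df2))
    cdf = float(_st.f.cdf(f, df1, df2))
    if tail == "greater":
        p = sf
    elif tail == "less":
        p = cdf
    else:
        p = min(1.0, 2 * min(sf, cdf))
    return TestResult(
        name="F",
        label=label,
        statistic=float(f),
        df=(df1, df2),
        n=(int(xv.size), int(yv.size)),
        p=p,
        tail=tail,
        extra={"p_one_sided_greater": sf},
    )


def paired_t_log(pre, post, tail: str = "two-sided", label: str = "paired t (log)") -> TestResult:
    """Paired t-test on log-transformed positive values (post vs pre)."""
    pre_v = np.asarray(pre, dtype=float).ravel()
    post_v = np.asarray(post, dtype=float).ravel()
    if pre_v.shape != post_v.shape:
        raise ValueError("paired samples must have matching length")
    if np.any(pre_v <= 0) or np.any(post_v <= 0):
        raise ValueError("log transform requires strictly positive values")
    res = _st.ttest_rel(np.log10(post_v), np.log10(pre_v), alternative=tail)
    return TestResult(
        name="t",
        label=label,
        statistic=float(res.statistic),
        df=int(pre_v.size - 1),
        n=int(pre_v.size),
        p=float(res.pvalue),
        tail=tail,
    )


@dataclass(frozen=True)
class ScreenedCorrelation:
    """Pearson correlation with the 3-SD outlier screen applied."""

    r: float
    p: float
    n_used: int
    excluded_ids: tuple
    r_unscreened: float
    p_unscreened: float
    sd_limit: float


def screened_pearson(x, y, sd_limit: float = 3.0, ids=None) -> ScreenedCorrelation:
    """Pearson correlation after excluding outliers beyond ``sd_limit`` SD.

    A pair is excluded when its x or y lies more than ``sd_limit`` sample
    standard deviations from that variable's mean, with means and SDs
    computed once on the full data (pre-exclusion).  Both the screened and
    the unscreened coefficients are reported; ``sd_limit=inf`` reproduces
    the unscreened correlation exactly.
    """
    xv = np.asarray(x, dtype=float).ravel()
    yv = np.asarray(y, dtype=float).ravel()
    if xv.shape != yv.shape:
        raise ValueError("x and y must have matching length")
    id_arr = np.asarray(ids) if ids is not None else np.arange(xv.size)
    if id_arr.shape != xv.shape:
        raise ValueError("ids must match the data length")
    r_all, p_all = _st.pearsonr(xv, yv)
    if math.isinf(sd_limit):
        keep = np.ones(xv.size, dtype=bool)
    else:
        keep = np.ones(xv.size, dtype=bool)
        for arr in (xv, yv):
            sd = arr.std(ddof=1)
            if sd > 0:
                keep &= np.abs(arr - arr.mean()) <= sd_limit * sd
    if keep.sum() < 3:
        raise ValueError("fewer than 3 pairs remain after screening")
    xs, ys = xv[keep], yv[keep]
    if xs.std() == 0 or ys.std() == 0:
        raise ValueError("degenerate variance after screening")
    r, p = _st.pearsonr(xs, ys)
    return ScreenedCorrelation(
        r=float(r),
        p=float(p),
        n_used=int(keep.sum()),
        excluded_ids=tuple(id_arr[~keep].tolist()),
        r_unscreened=float(r_all),
        p_unscreened=float(p_all),
        sd_limit=sd_limit,
    )


def correlate_with_mi(
    metrics: pd.DataFrame, mi: pd.DataFrame, label: str = "i_recal vs MI"
) -> TestResult:
    """Pearson correlation of i_recal with the Multisensory Influence score.

    ``metrics`` needs columns ``participant_id`` and ``i_recal``; ``mi``
    needs ``participant_id`` and ``mi`` (0 = no integration, 1 = full
    fusion).  The inner join on participant id must be non-empty; the
    result lists unmatched ids on both sides.
    """
    joined = metrics.merge(mi, on="participant_id", how="inner")
    if joined.empty:
        raise ValueError("no participants shared between metrics and MI records")
    if len(joined) < 3:
        raise ValueError(f"only {len(joined)} joined participants; need >=3")
    r, p = _st.pearsonr(joined["i_recal"], joined["mi"])
    unmatched_metrics = sorted(set(metrics["participant_id"]) - set(joined["participant_id"]))
    unmatched_mi = sorted(set(mi["participant_id"]) - set(joined["participant_id"]))
    return TestResult(
        name="Pearson r",
        label=label,
        statistic=float(r),
        df=int(len(joined) - 2),
        n=int(len(joined)),
        p=float(p),
        extra={
            "unmatched_metrics_ids": unmatched_metrics,
            "unmatched_mi_ids": unmatched_mi,
        },
    )
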
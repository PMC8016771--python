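"""Quantitative arm: rating summaries, paired t, ANOVA, Bonferroni post-hoc.

Priority ratings live on a 3-point scale (1 = very important, 3 = less
important; a *lower* mean marks a *higher* priority). Topics are compared
within respondents by paired t-tests; groups (disease group, gender,
region) are compared per topic by one-way ANOVA followed by all-pairs
post-hoc t-tests with Bonferroni correction. All tests are two-sided and
complete-case (pairwise deletion); post-hoc tests default to Welch's
unequal-variance t because group sizes are typically highly unbalanced,
with a pooled-variance option.

Degenerate inputs (zero-variance differences, all-constant groups) are
flagged rather than raising, with the conventional p of 1 (no shift) or 0
(constant nonzero shift).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from voices.errors import DegenerateDataError
from voices.survey import ResponseRecord
from voices.synthetic import TOPICS


@dataclass
class RatingSummary:
    topic: str
    n: int
    mean: float
    sd: float


@dataclass
class StatTestResult:
    kind: str                  # paired_t | welch_t | pooled_t | anova_F
    comparison: tuple
    statistic: float
    df: float | tuple
    p_raw: float
    p_adjusted: float | None = None
    m: int = 1                 # comparisons in the family
    degenerate: bool = False


def bonferroni(p_raw: float, m: int) -> float:
    """Family-wise adjusted p: min(1, m·p_raw)."""
    return min(1.0, m * p_raw)


def summarise_ratings(records: Sequence[ResponseRecord], topic: str) -> RatingSummary:
    """Mean and sample SD (n−1 denominator) of non-missing ratings."""
    if topic not in TOPICS:
        raise KeyError(f"unknown topic: {topic!r}")
    values = np.array([r.ratings[topic] for r in records if topic in r.ratings],
                      dtype=float)
    if values.size == 0:
        raise DegenerateDataError(f"no ratings present for topic {topic!r}")
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return RatingSummary(topic, int(values.size), float(values.mean()), sd)


def paired_t(records: Sequence[ResponseRecord], topic_a: str, topic_b: str
             ) -> StatTestResult:
    """Paired-samples t-test on the complete-pairs subset.

    t = mean(d) / (sd(d)/√n) with d the within-respondent rating difference,
    df = n−1, two-sided p from Student's t.
    """
    for topic in (topic_a, topic_b):
        if topic not in TOPICS:
            raise KeyError(f"unknown topic: {topic!r}")
    pairs = [(r.ratings[topic_a], r.ratings[topic_b]) for r in records
             if topic_a in r.ratings and topic_b in r.ratings]
    if len(pairs) < 2:
        raise DegenerateDataError(
            f"fewer than 2 complete pairs for ({topic_a}, {topic_b})")
    d = np.diff(np.array(pairs, dtype=float), axis=1).ravel() * -1  # a - b
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return StatTestResult("paired_t", (topic_a, topic_b), 0.0,
                                  float(n - 1), 1.0, degenerate=True)
        stat = math.copysign(math.inf, d.mean())
        return StatTestResult("paired_t", (topic_a, topic_b), stat,
                              float(n - 1), 0.0, degenerate=True)
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return StatTestResult("paired_t", (topic_a, topic_b), float(t),
                          float(n - 1), float(p))


def _constant(x: np.ndarray) -> bool:
    return float(np.ptp(x)) == 0.0


def two_sample_t(a: Sequence[float], b: Sequence[float], labels: tuple,
                 variance: str = "welch") -> StatTestResult:
    """Two-sided two-sample t-test (Welch by default, pooled optional)."""
    x, y = np.asarray(a, float), np.asarray(b, float)
    if x.size < 2 or y.size < 2:
        raise DegenerateDataError(f"need >= 2 observations per group: {labels}")
    kind = "welch_t" if variance == "welch" else "pooled_t"
    if _constant(x) and _constant(y):
        if x.mean() == y.mean():
            return StatTestResult(kind, labels, 0.0, float(x.size + y.size - 2),
                                  1.0, degenerate=True)
        stat = math.copysign(math.inf, x.mean() - y.mean())
        return StatTestResult(kind, labels, stat, float(x.size + y.size - 2),
                              0.0, degenerate=True)
    res = sps.ttest_ind(x, y, equal_var=(variance == "pooled"))
    return StatTestResult(kind, labels, float(res.statistic), float(res.df),
                          float(res.pvalue))


def one_way_anova(groups: dict[str, Sequence[float]]) -> StatTestResult:
    """One-way ANOVA: F = MS_between / MS_within, df = (g−1, N−g)."""
    labels = tuple(sorted(groups))
    if len(labels) < 2:
        raise DegenerateDataError("ANOVA needs at least 2 groups")
    arrays = [np.asarray(groups[lab], float) for lab in labels]
    if any(a.size < 2 for a in arrays):
        raise DegenerateDataError("every group needs at least 2 observations")
    g = len(arrays)
    n_total = sum(a.size for a in arrays)
    df = (float(g - 1), float(n_total - g))
    if all(_constant(a) for a in arrays):
        means = [a.mean() for a in arrays]
        if len(set(means)) == 1:
            return StatTestResult("anova_F", labels, 0.0, df, 1.0,
                                  degenerate=True)
        return StatTestResult("anova_F", labels, math.inf, df, 0.0,
                              degenerate=True)
    res = sps.f_oneway(*arrays)
    return StatTestResult("anova_F", labels, float(res.statistic), df,
                          float(res.pvalue))


def posthoc_pairwise(groups: dict[str, Sequence[float]],
                     variance: str = "welch",
                     m: int | None = None) -> list[StatTestResult]:
    """All g·(g−1)/2 pairwise t-tests with Bonferroni adjustment.

    ``m`` defaults to the number of pairs; results are ordered by comparison
    label. Degenerate pairs (both groups constant) keep their flag and get
    the same adjustment.
    """
    labels = sorted(groups)
    pairs = list(itertools.combinations(labels, 2))
    if m is None:
        m = len(pairs)
    results = []
    for a, b in pairs:
        res = two_sample_t(groups[a], groups[b], (a, b), variance=variance)
        res.m = m
        res.p_adjusted = bonferroni(res.p_raw, m)
        results.append(res)
    return results


def ratings_by_group(records: Sequence[ResponseRecord], topic: str,
                     group_of) -> dict[str, list[float]]:
    """Collect non-missing ratings for one topic keyed by a grouping
    function over records (e.g. ``lambda r: r.mtg``)."""
    groups: dict[str, list[float]] = {}
    for record in records:
        if topic in record.ratings:
            groups.setdefault(group_of(record), []).append(
                float(record.ratings[topic]))
    return groups


def rank_topics(summaries: Sequence[RatingSummary]) -> tuple[list[str], bool]:
    """Order topics by priority: ascending mean (lower = more important).

    Ties are broken lexicographically and flagged via the second return
    value. Permutation-invariant in the input order.
    """
    ordered = sorted(summaries, key=lambda s: (s.mean, s.topic))
    means = [s.mean for s in ordered]
    tie = len(means) != len(set(means))
    return [s.topic for s in ordered], tie
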
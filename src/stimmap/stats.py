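"""Two-group outcome statistics: summaries, t-tests, confidence intervals.

These are the comparisons applied to WAB language scores and tract metrics:
independent-samples t-tests (Welch by default, pooled-variance optionally)
computable directly from (mean, SD, n) summaries, the paired t-test for
within-subject modality comparisons, and the standard t-based confidence
interval.  All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError, InsufficientDataError


@dataclass
class GroupSummary:
    """(mean, SD, n) triplet; SD uses the n-1 denominator."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise InsufficientDataError("a group summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("SD must be non-negative")


@dataclass
class TestResult:
    statistic: float
    df: float
    p: float
    kind: str


def summarize(samples) -> GroupSummary:
    """Sample mean, SD (ddof=1) and size."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("need at least two samples to summarize")
    return GroupSummary(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=int(x.size))


def t_test_from_summaries(a: GroupSummary, b: GroupSummary, kind: str = "welch") -> TestResult:
    """Independent two-sample t-test from group summaries.

    ``kind="welch"`` uses the unequal-variance statistic with Satterthwaite
    degrees of freedom (the default: robust to unequal variances);
    ``kind="pooled"`` the classical equal-variance form.
    """
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            raise DegenerateDataError("zero variance in both groups with equal means")
        return TestResult(statistic=float("inf"), df=a.n + b.n - 2, p=0.0, kind=kind)
    if kind == "welch":
        se = np.sqrt(va + vb)
        t = (a.mean - b.mean) / se
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    elif kind == "pooled":
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
        t = (a.mean - b.mean) / np.sqrt(sp2 * (1 / a.n + 1 / b.n))
        df = a.n + b.n - 2
    else:
        raise ValueError(f"unknown test kind {kind!r}")
    p = 2 * sps.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=float(df), p=float(p), kind=kind)


def t_test(x, y, kind: str = "welch") -> TestResult:
    """Independent two-sample t-test on raw samples (via their summaries)."""
    return t_test_from_summaries(summarize(x), summarize(y), kind=kind)


def paired_t_test(x, y) -> TestResult:
    """One-sample t-test on the within-pair differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InsufficientDataError("paired samples must have equal lengths")
    if x.size < 2:
        raise InsufficientDataError("need at least two pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero variance of paired differences; statistic undefined")
    t = d.mean() / (sd / np.sqrt(d.size))
    df = d.size - 1
    p = 2 * sps.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=float(df), p=float(p), kind="paired")


def confidence_interval(samples, level: float = 0.95) -> tuple[float, float]:
    """mean +/- t_{(1+level)/2, n-1} * SD / sqrt(n)."""
    s = summarize(samples)
    half = sps.t.ppf((1 + level) / 2, s.n - 1) * s.sd / np.sqrt(s.n)
    return (s.mean - half, s.mean + half)


def permutation_p_value(x, y, n_perm: int = 10_000, seed: int = 0) -> float:
    """Two-sided permutation p for the Welch statistic (Monte-Carlo reference).

    Used as an independent cross-check of the closed-form Welch p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n = x.size
    obs = abs(t_test(x, y).statistic)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        try:
            stat = abs(t_test(perm[:n], perm[n:]).statistic)
        except DegenerateDataError:
            stat = 0.0
        if stat >= obs:
            hits += 1
    return (hits + 1) / (n_perm + 1)
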
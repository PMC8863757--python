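"""The statistical battery for multi-trial gaze-pattern studies.

Three pieces, applied to novice groups only (experts are a reference, not an
inference population): Levene's test of equal variances as the precondition
check, a paired t-test of first-vs-last-trial pattern counts within each group
with the effect size r = sqrt(t^2 / (t^2 + df)), and a two-group one-way ANOVA
comparing per-participant learning slopes and centred intercepts between
groups. All p-values are two-sided; the conventional alpha is 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError


@dataclass
class LeveneResult:
    W: float
    df_between: int
    df_within: int
    p: float


@dataclass
class PairedTestResult:
    t: float
    df: int
    p: float
    r: float
    n: int
    mean_first: float
    sem_first: float
    mean_last: float
    sem_last: float


@dataclass
class AnovaResult:
    """One-way fixed-effects ANOVA table row (df, SS, MS, F, p)."""

    df_between: int
    df_within: int
    ss_between: float
    ss_within: float
    ms_between: float
    ms_within: float
    F: float
    p: float


def _sem(v: np.ndarray) -> float:
    return float(v.std(ddof=1) / math.sqrt(len(v))) if len(v) > 1 else float("nan")


def levene(*groups: Sequence[float], center: str = "mean") -> LeveneResult:
    """Levene's test of equal variances across two or more groups.

    The classic test ANOVAs the absolute deviations from each group's mean;
    ``center='median'`` gives the Brown-Forsythe variant.
    """
    if len(groups) < 2:
        raise ValueError("levene needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if len(g) < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
    W, p = sps.levene(*arrays, center=center)
    n_total = sum(len(g) for g in arrays)
    return LeveneResult(
        W=float(W),
        df_between=len(arrays) - 1,
        df_within=n_total - len(arrays),
        p=float(p),
    )


def effect_size_r(t: float, df: int) -> float:
    """Effect size r = sqrt(t^2 / (t^2 + df)).

    Sign-insensitive, strictly increasing in |t|, in [0, 1). This converts a
    paired-t statistic into a correlation-scale effect size, with r = 0.3
    conventionally a large effect in individual-differences research.
    """
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    t2 = float(t) * float(t)
    return math.sqrt(t2 / (t2 + df))


def truncate(x: float, digits: int = 3) -> float:
    """Truncate (not round) towards zero at the given number of decimals."""
    factor = 10**digits
    return math.trunc(x * factor) / factor


def paired_first_last(
    first: Sequence[float], last: Sequence[float]
) -> PairedTestResult:
    """Paired t-test of first-trial vs last-trial values, by participant.

    t = mean(d) / (SD(d)/sqrt(n)) on d = first - last, df = n - 1, two-sided
    p, and effect size r. Zero spread in the differences leaves t undefined
    and raises DegenerateDataError.
    """
    f = np.asarray(first, dtype=float)
    l = np.asarray(last, dtype=float)
    if f.shape != l.shape:
        raise ValueError("first and last must pair up elementwise")
    n = len(f)
    if n < 2:
        raise ValueError(f"need >= 2 pairs, got {n}")
    d = f - l
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("all paired differences equal; t undefined")
    df = n - 1
    t = float(d.mean() / (sd / math.sqrt(n)))
    p = float(2 * sps.t.sf(abs(t), df))
    return PairedTestResult(
        t=t,
        df=df,
        p=p,
        r=effect_size_r(t, df),
        n=n,
        mean_first=float(f.mean()),
        sem_first=_sem(f),
        mean_last=float(l.mean()),
        sem_last=_sem(l),
    )


def anova_two_group(a: Sequence[float], b: Sequence[float]) -> AnovaResult:
    """One-way fixed-effects ANOVA between two groups.

    Emits the full table (df, sums of squares, mean squares, F, p). For two
    groups F equals the square of the pooled-variance independent t statistic.
    Zero within-group variance with equal group means leaves F undefined and
    raises DegenerateDataError.
    """
    ga = np.asarray(a, dtype=float)
    gb = np.asarray(b, dtype=float)
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each group needs >= 2 values")
    grand = np.concatenate([ga, gb]).mean()
    ss_between = float(
        len(ga) * (ga.mean() - grand) ** 2 + len(gb) * (gb.mean() - grand) ** 2
    )
    ss_within = float(((ga - ga.mean()) ** 2).sum() + ((gb - gb.mean()) ** 2).sum())
    df_between = 1
    df_within = len(ga) + len(gb) - 2
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        if ss_between == 0:
            raise DegenerateDataError(
                "zero within-group variance and equal means; F undefined"
            )
        F = float("inf")
        p = 0.0
    else:
        F = ms_between / ms_within
        p = float(sps.f.sf(F, df_between, df_within))
    return AnovaResult(
        df_between=df_between,
        df_within=df_within,
        ss_between=ss_between,
        ss_within=ss_within,
        ms_between=ms_between,
        ms_within=ms_within,
        F=float(F),
        p=p,
    )
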
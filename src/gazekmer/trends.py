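"""Per-participant pattern-frequency trends across repeated trials.

For each participant and pattern, the per-trial occurrence counts form a
series; an ordinary least-squares line on the mean-centred trial index gives
the learning slope (counts per trial) and the centred intercept, which under
OLS equals the participant's average count and so measures how often the
pattern occurs overall. Group learning curves are the per-trial mean and SEM
across participants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FitError
from .kmer import KmerTable


@dataclass
class TrialSeries:
    """One pattern's per-trial counts for one participant."""

    pattern: str
    k: int
    participant_id: str
    group: str
    trials: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.trials.shape != self.counts.shape:
            raise DataError("trials and counts must have equal length")
        if len(self.trials) > 1 and not np.all(np.diff(self.trials) > 0):
            raise DataError("trial indices must be strictly increasing")
        if np.any(self.counts < 0):
            raise DataError("counts must be non-negative")


@dataclass
class TrendFit:
    """OLS slope and centred intercept of one TrialSeries."""

    pattern: str
    participant_id: str
    slope: float
    centered_intercept: float
    residual_variance: float


def build_series(
    tables_by_trial: Mapping[int, KmerTable],
    pattern: str,
    *,
    participant_id: str = "",
    group: str = "",
) -> TrialSeries:
    """Assemble the per-trial count series of one pattern.

    Trials where the pattern was never observed contribute count 0, so the
    series always covers every trial present in the mapping.
    """
    if not tables_by_trial:
        raise LookupError(f"no trials available for participant {participant_id!r}")
    trials = sorted(tables_by_trial)
    ks = {tables_by_trial[t].k for t in trials}
    if len(ks) != 1:
        raise DataError(f"tables mix k values {sorted(ks)}")
    counts = [tables_by_trial[t].counts.get(pattern, 0) for t in trials]
    return TrialSeries(
        pattern=pattern,
        k=ks.pop(),
        participant_id=participant_id,
        group=group,
        trials=np.array(trials, dtype=float),
        counts=np.array(counts, dtype=float),
    )


def fit_trend(series: TrialSeries) -> TrendFit:
    """OLS of counts on the mean-centred trial index.

    slope = Σ x~ y / Σ x~², with x~ = trial - mean(trial); the centred
    intercept is the fitted value at the mean trial index, which for OLS is
    exactly mean(counts). Residual variance uses n - 2 denominator (0 when
    n = 2, where the line interpolates).
    """
    n = len(series.trials)
    if n < 2:
        raise FitError(f"need >= 2 trials to fit a trend, got {n}")
    x = series.trials - series.trials.mean()
    y = series.counts
    sxx = float(np.dot(x, x))
    slope = float(np.dot(x, y) / sxx)
    intercept = float(y.mean())
    resid = y - (intercept + slope * x)
    residual_variance = float(np.dot(resid, resid) / (n - 2)) if n > 2 else 0.0
    return TrendFit(
        pattern=series.pattern,
        participant_id=series.participant_id,
        slope=slope,
        centered_intercept=intercept,
        residual_variance=residual_variance,
    )


def group_curve(series_list: Sequence[TrialSeries]) -> pd.DataFrame:
    """Per-trial mean and SEM across participants of one group and pattern.

    SEM is sample SD / sqrt(n) over the participants contributing that trial;
    with a single participant the sample SD is undefined and SEM is NaN.
    Returns a DataFrame with columns trial, mean, sem, n.
    """
    if not series_list:
        raise DataError("group_curve needs at least one series")
    values: dict[float, list[float]] = {}
    for s in series_list:
        for t, c in zip(s.trials, s.counts):
            values.setdefault(float(t), []).append(float(c))
    rows = []
    for t in sorted(values):
        v = np.array(values[t])
        n = len(v)
        sem = float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        rows.append({"trial": t, "mean": float(v.mean()), "sem": sem, "n": n})
    return pd.DataFrame(rows)
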
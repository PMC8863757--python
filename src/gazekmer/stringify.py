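"""Collapsed dwell strings and the traditional AOI metrics.

Successive fixations on the same AOI form a *dwell*; collapsing each dwell to
a single letter gives the trial's string representation, in which no letter
neighbours itself. The traditional metrics — mean fixation duration, per-AOI
dwell time and dwell count, and AOI transition counts — are the k = 1 and
k = 2 views of that same string.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import DataError
from .ingest import TrialRecord


@dataclass(frozen=True)
class Dwell:
    letter: str
    dwell_time: float  # ms, sum of member fixation durations
    fixation_count: int


@dataclass
class DwellString:
    """A trial's collapsed AOI letter sequence with per-dwell aggregates."""

    letters: str
    dwells: list[Dwell] = field(default_factory=list)
    participant_id: str = ""
    group: str = ""
    trial_index: int = 1

    def __post_init__(self) -> None:
        if len(self.letters) != len(self.dwells):
            raise DataError("letters and dwells must align")
        for a, b in zip(self.letters, self.letters[1:]):
            if a == b:
                raise DataError(f"adjacent equal letters {a!r} in collapsed string")

    def __len__(self) -> int:
        return len(self.letters)


def collapse(
    labels_with_durations: Iterable[tuple[str, float]],
    *,
    participant_id: str = "",
    group: str = "",
    trial_index: int = 1,
) -> DwellString:
    """Collapse a labeled fixation stream into a DwellString.

    Maximal runs of equal letters become one position whose dwell_time and
    fixation_count aggregate the run. Empty input yields an empty DwellString.
    """
    letters: list[str] = []
    dwells: list[Dwell] = []
    for letter, duration in labels_with_durations:
        if letters and letters[-1] == letter:
            prev = dwells[-1]
            dwells[-1] = Dwell(
                letter=letter,
                dwell_time=prev.dwell_time + duration,
                fixation_count=prev.fixation_count + 1,
            )
        else:
            letters.append(letter)
            dwells.append(Dwell(letter=letter, dwell_time=duration, fixation_count=1))
    return DwellString(
        letters="".join(letters),
        dwells=dwells,
        participant_id=participant_id,
        group=group,
        trial_index=trial_index,
    )


def from_trial(trial: TrialRecord) -> DwellString:
    """DwellString of a labeled trial (raises DataError on unlabeled fixations)."""
    pairs = []
    for i, fix in enumerate(trial.fixations):
        if fix.label is None:
            raise DataError(f"fixation {i} of trial {trial.trial_index} is unlabeled")
        pairs.append((fix.label, fix.duration))
    return collapse(
        pairs,
        participant_id=trial.participant_id,
        group=trial.group,
        trial_index=trial.trial_index,
    )


@dataclass
class TrialMetrics:
    """Traditional per-trial AOI metrics.

    dwell_time is in ms per AOI letter; transitions maps ordered letter pairs
    (two-character strings) to counts.
    """

    mean_fixation_duration: float
    dwell_time: dict[str, float]
    dwell_count: dict[str, int]
    transitions: dict[str, int]


def trial_metrics(
    trial: TrialRecord,
    dwell: DwellString | None = None,
    *,
    exclude_letter: str | None = None,
) -> TrialMetrics:
    """Compute mean fixation duration, per-AOI dwell time/count and transitions.

    The mean fixation duration averages over all fixations, whitespace
    included; pass ``exclude_letter`` to drop one letter (e.g. 'W') from that
    average. Transition counts are the adjacent ordered letter pairs of the
    collapsed string and always sum to len(letters) - 1.
    """
    if dwell is None:
        dwell = from_trial(trial)
    durations = [
        f.duration
        for f in trial.fixations
        if exclude_letter is None or f.label != exclude_letter
    ]
    mean_dur = sum(durations) / len(durations) if durations else 0.0

    dwell_time: dict[str, float] = {}
    dwell_count: dict[str, int] = {}
    for d in dwell.dwells:
        dwell_time[d.letter] = dwell_time.get(d.letter, 0.0) + d.dwell_time
        dwell_count[d.letter] = dwell_count.get(d.letter, 0) + 1

    transitions = dict(
        Counter(a + b for a, b in zip(dwell.letters, dwell.letters[1:]))
    )
    return TrialMetrics(
        mean_fixation_duration=mean_dur,
        dwell_time=dwell_time,
        dwell_count=dwell_count,
        transitions=transitions,
    )


def dwell_strings(trials: Sequence[TrialRecord]) -> list[DwellString]:
    """Collapse every labeled trial of a cohort."""
    return [from_trial(t) for t in trials]
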
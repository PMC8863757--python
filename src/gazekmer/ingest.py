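"""Reading gaze/fixation tables and velocity-threshold (I-VT) fixation detection.

Mobile eye trackers deliver either raw gaze samples (time, x, y, validity) or
vendor-detected fixation events. This module reads both in delimited-text form
and, for raw samples, provides an I-VT classifier: consecutive samples whose
point-to-point velocity stays below a threshold form a candidate fixation, and
candidates shorter than a minimum duration are discarded. The defaults (50 ms
minimum duration, 40 deg/s peak velocity) are the standard mobile-tracker
event-detector settings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

#: canonical column names of the fixation-table external format
CANONICAL_COLUMNS = (
    "participant",
    "group",
    "trial",
    "start_ms",
    "duration_ms",
    "x",
    "y",
    "label",
)

#: default mapping from logical field -> column name in the file
DEFAULT_MAPPING: dict[str, str] = {
    "participant": "participant",
    "group": "group",
    "trial": "trial",
    "start": "start_ms",
    "duration": "duration_ms",
    "x": "x",
    "y": "y",
    "label": "label",
}

_REQUIRED_FIELDS = ("participant", "trial", "start", "duration")


@dataclass(frozen=True)
class GazeSample:
    """One raw gaze sample.

    t is in milliseconds; x/y are scene coordinates (pixels, origin top-left,
    y down, unless the caller declares degrees). Invalid samples carry no
    usable position.
    """

    t: float
    x: float = float("nan")
    y: float = float("nan")
    valid: bool = True


@dataclass
class FixationEvent:
    """A detected fixation: start and duration in ms, centroid position and/or AOI letter."""

    start: float
    duration: float
    x: float | None = None
    y: float | None = None
    label: str | None = None


@dataclass
class TrialRecord:
    """All fixations of one participant in one trial, time-ordered."""

    participant_id: str
    group: str
    trial_index: int
    fixations: list[FixationEvent] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trial_index < 1:
            raise DataError(f"trial_index must be >= 1, got {self.trial_index}")


def read_fixation_table(
    path,
    mapping: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> list[TrialRecord]:
    """Read a delimited fixation table into one TrialRecord per (participant, trial).

    ``mapping`` maps the logical fields participant/group/trial/start/duration/
    x/y/label to column names in the file; omitted entries fall back to the
    canonical names. The file must provide participant, trial, start and
    duration, plus either x and y or a label column. Rows are grouped by
    (participant, trial) and time-sorted within each trial; columns not
    consumed by the mapping are preserved in TrialRecord.metadata.
    """
    m = dict(DEFAULT_MAPPING)
    if mapping:
        m.update(mapping)

    df = pd.read_csv(path, sep=sep, engine="python")

    for field_name in _REQUIRED_FIELDS:
        if m[field_name] not in df.columns:
            raise ConfigurationError(
                f"required column {m[field_name]!r} (field {field_name!r}) "
                f"not found in {path}"
            )
    has_label = m["label"] in df.columns
    has_xy = m["x"] in df.columns and m["y"] in df.columns
    if not (has_label or has_xy):
        raise ConfigurationError(
            f"need either column {m['label']!r} or columns "
            f"{m['x']!r}/{m['y']!r} in {path}"
        )

    for field_name in ("start", "duration"):
        col = m[field_name]
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header is line 1
            raise DataError(
                f"non-numeric value {df[col][bad.idxmax()]!r} in column "
                f"{col!r} at line {row} of {path}"
            )
        df[col] = numeric

    mapped_cols = {m[f] for f in m if m[f] in df.columns}
    extra_cols = [c for c in df.columns if c not in mapped_cols]

    records: list[TrialRecord] = []
    for (pid, trial), sub in df.groupby([m["participant"], m["trial"]], sort=True):
        sub = sub.sort_values(m["start"], kind="stable")
        group = ""
        if m["group"] in sub.columns:
            group = str(sub[m["group"]].iloc[0])
        fixations = [
            FixationEvent(
                start=float(r[m["start"]]),
                duration=float(r[m["duration"]]),
                x=float(r[m["x"]]) if has_xy and pd.notna(r[m["x"]]) else None,
                y=float(r[m["y"]]) if has_xy and pd.notna(r[m["y"]]) else None,
                label=(
                    str(r[m["label"]])
                    if has_label and pd.notna(r[m["label"]])
                    else None
                ),
            )
            for _, r in sub.iterrows()
        ]
        metadata = {c: sub[c].iloc[0] for c in extra_cols}
        records.append(
            TrialRecord(
                participant_id=str(pid),
                group=group,
                trial_index=int(trial),
                fixations=fixations,
                metadata=metadata,
            )
        )
    return records


def write_fixation_table(trials: Iterable[TrialRecord], path) -> None:
    """Write TrialRecords in the canonical fixation CSV format."""
    rows = [
        {
            "participant": t.participant_id,
            "group": t.group,
            "trial": t.trial_index,
            "start_ms": f.start,
            "duration_ms": f.duration,
            "x": f.x,
            "y": f.y,
            "label": f.label,
        }
        for t in trials
        for f in t.fixations
    ]
    pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS)).to_csv(path, index=False)


def detect_fixations(
    samples: Sequence[GazeSample],
    velocity_threshold: float = 40.0,
    min_duration: float = 50.0,
    *,
    smooth_window: int = 0,
    px_per_degree: float | None = None,
) -> list[FixationEvent]:
    """I-VT fixation classification of a raw sample stream.

    Velocity between consecutive valid samples is Euclidean displacement over
    Δt (per second), in the units of the input; ``px_per_degree`` converts
    pixel velocities to deg/s when given. Runs of sub-threshold velocities
    form candidate fixations; a candidate's duration is last-minus-first
    member time plus one sample period (median Δt of the recording), and
    candidates shorter than ``min_duration`` are dropped. Invalid samples
    split candidates (blinks are never bridged). ``smooth_window`` applies an
    optional centred moving average to the velocity trace before
    classification (off by default).

    Fewer than two valid samples yield an empty list; non-monotone timestamps
    raise DataError.
    """
    if velocity_threshold <= 0:
        raise ConfigurationError("velocity_threshold must be > 0")

    times = np.asarray([s.t for s in samples], dtype=float)
    if len(times) >= 2 and not np.all(np.diff(times) > 0):
        raise DataError("sample timestamps must be strictly increasing")

    valid = [s for s in samples if s.valid]
    if len(valid) < 2:
        return []

    # sample period from the full valid stream
    period = float(np.median(np.diff([s.t for s in valid])))

    # segments of consecutive valid samples (invalid samples split them)
    segments: list[list[GazeSample]] = []
    current: list[GazeSample] = []
    for s in samples:
        if s.valid:
            current.append(s)
        elif current:
            segments.append(current)
            current = []
    if current:
        segments.append(current)

    out: list[FixationEvent] = []
    for seg in segments:
        if len(seg) < 2:
            continue
        t = np.array([s.t for s in seg])
        x = np.array([s.x for s in seg])
        y = np.array([s.y for s in seg])
        dt = np.diff(t) / 1000.0  # s
        v = np.hypot(np.diff(x), np.diff(y)) / dt
        if px_per_degree is not None:
            v = v / px_per_degree
        if smooth_window > 1:
            kernel = np.ones(smooth_window) / smooth_window
            v = np.convolve(v, kernel, mode="same")
        below = v < velocity_threshold
        # maximal runs of sub-threshold velocities -> candidate sample spans
        i = 0
        while i < len(below):
            if not below[i]:
                i += 1
                continue
            j = i
            while j < len(below) and below[j]:
                j += 1
            first, last = i, j  # samples first..last inclusive
            duration = (t[last] - t[first]) + period
            if duration >= min_duration:
                out.append(
                    FixationEvent(
                        start=float(t[first]),
                        duration=float(duration),
                        x=float(np.mean(x[first : last + 1])),
                        y=float(np.mean(y[first : last + 1])),
                    )
                )
            i = j
    return out


def replace_fixation(fix: FixationEvent, **changes) -> FixationEvent:
    """Return a copy of ``fix`` with the given fields replaced."""
    return dataclasses.replace(fix, **changes)
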
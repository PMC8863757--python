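"""Areas of interest: named screen regions mapped to single-letter codes.

A scheme lists regions in priority order, each carrying one uppercase letter
(e.g. A = building area, B = bricks, C = manual). Every fixation falling in no
region is assigned the whitespace letter (default 'W'). Rectangle membership
is half-open ([x0, x1) x [y0, y1)) so shared edges cannot be double-assigned;
polygon membership counts the boundary as inside.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import yaml
from shapely.geometry import Point, Polygon

from .errors import ConfigurationError, DataError
from .ingest import FixationEvent, TrialRecord, replace_fixation


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle, half-open on the right/bottom edges."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ConfigurationError(f"degenerate rectangle {self}")

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1


class PolygonGeom:
    """Simple polygon; membership includes the boundary."""

    def __init__(self, vertices) -> None:
        if len(vertices) < 3:
            raise ConfigurationError("polygon needs at least 3 vertices")
        self._poly = Polygon(vertices)
        if self._poly.area <= 0:
            raise ConfigurationError("degenerate polygon (zero area)")
        self.vertices = [tuple(map(float, v)) for v in vertices]

    def contains(self, x: float, y: float) -> bool:
        return bool(self._poly.covers(Point(x, y)))

    def __repr__(self) -> str:  # pragma: no cover
        return f"PolygonGeom({self.vertices!r})"


@dataclass(frozen=True)
class Region:
    letter: str
    name: str
    geometry: Rect | PolygonGeom


@dataclass(frozen=True)
class AOIScheme:
    """Ordered regions plus the whitespace fallback letter."""

    regions: tuple[Region, ...]
    whitespace_letter: str = "W"

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))
        letters = [r.letter for r in self.regions]
        for letter in letters + [self.whitespace_letter]:
            if len(letter) != 1 or letter not in string.ascii_uppercase:
                raise ConfigurationError(
                    f"AOI letters must be single uppercase A-Z, got {letter!r}"
                )
        if len(set(letters)) != len(letters):
            raise ConfigurationError(f"duplicate AOI letters in {letters}")
        if self.whitespace_letter in letters:
            raise ConfigurationError(
                f"whitespace letter {self.whitespace_letter!r} also used by a region"
            )

    @property
    def alphabet(self) -> str:
        """All letters a labeled fixation can carry, whitespace last."""
        return "".join(r.letter for r in self.regions) + self.whitespace_letter


def load_scheme(path) -> AOIScheme:
    """Load an AOI scheme from YAML or JSON.

    Expected shape::

        whitespace: W
        regions:
          - {letter: A, name: building area, rect: [x0, y0, x1, y1]}
          - {letter: C, name: manual, polygon: [[x, y], [x, y], [x, y]]}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "regions" not in raw:
        raise ConfigurationError(f"AOI scheme {path} must define 'regions'")
    regions = []
    for entry in raw["regions"]:
        if "rect" in entry:
            geom: Rect | PolygonGeom = Rect(*map(float, entry["rect"]))
        elif "polygon" in entry:
            geom = PolygonGeom(entry["polygon"])
        else:
            raise ConfigurationError(
                f"region {entry.get('letter', '?')!r} has neither 'rect' nor 'polygon'"
            )
        regions.append(
            Region(
                letter=str(entry["letter"]),
                name=str(entry.get("name", entry["letter"])),
                geometry=geom,
            )
        )
    return AOIScheme(
        regions=tuple(regions), whitespace_letter=str(raw.get("whitespace", "W"))
    )


def assign_aoi(fix: FixationEvent, scheme: AOIScheme) -> str:
    """Letter of the first region containing the fixation, else whitespace.

    A fixation already carrying a label keeps it.
    """
    if fix.label is not None:
        return fix.label
    if fix.x is None or fix.y is None:
        raise DataError("fixation has neither a position nor a label")
    for region in scheme.regions:
        if region.geometry.contains(fix.x, fix.y):
            return region.letter
    return scheme.whitespace_letter


def label_trial(trial: TrialRecord, scheme: AOIScheme) -> TrialRecord:
    """Return the trial with every fixation labeled, order preserved.

    A fully pre-labeled trial is returned unchanged.
    """
    if all(f.label is not None for f in trial.fixations):
        return trial
    labeled = []
    for i, fix in enumerate(trial.fixations):
        try:
            labeled.append(replace_fixation(fix, label=assign_aoi(fix, scheme)))
        except DataError as exc:
            raise DataError(f"fixation {i}: {exc}") from exc
    return TrialRecord(
        participant_id=trial.participant_id,
        group=trial.group,
        trial_index=trial.trial_index,
        fixations=labeled,
        metadata=dict(trial.metadata),
    )
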
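"""Overlapping k-mer extraction over collapsed dwell strings.

A k-mer is a length-k contiguous window of the collapsed AOI string, counted
at every offset (stride 1). On collapsed strings k = 1 counts coincide with
per-AOI dwell counts and k = 2 counts with AOI transition counts, so the
traditional metrics are the small-k special cases of the same machinery.

Relative frequency of a pattern is its mean count across the analysed trials
divided by the sum of mean counts over all same-k patterns; patterns whose
relative frequency strictly exceeds the relevance threshold (default 1%) are
the "relevant" gaze patterns carried into trend and group analysis.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence


@dataclass
class KmerTable:
    """Pattern -> count map for one string (or one pooled unit) at one k."""

    k: int
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def rel_freq(self) -> dict[str, float]:
        """Counts normalised to fractions; empty when no window was observed."""
        total = self.total
        if total == 0:
            return {}
        return {p: c / total for p, c in self.counts.items()}


def extract_kmers(letters: str, k: int) -> KmerTable:
    """Count all overlapping length-k windows of ``letters``.

    Patterns absent from the string are absent from the map. A string shorter
    than k has no windows and yields an empty table.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    counts = Counter(letters[i : i + k] for i in range(len(letters) - k + 1))
    return KmerTable(k=k, counts=dict(counts))


def relative_frequency(tables: Sequence[KmerTable]) -> dict[str, float]:
    """Mean count per pattern across trials, normalised over all patterns.

    All tables must share k. When every count is zero the map is empty rather
    than raising a division error.
    """
    tables = list(tables)
    if not tables:
        return {}
    ks = {t.k for t in tables}
    if len(ks) != 1:
        raise ValueError(f"tables mix k values {sorted(ks)}")
    mean_counts: dict[str, float] = {}
    for t in tables:
        for p, c in t.counts.items():
            mean_counts[p] = mean_counts.get(p, 0.0) + c
    n = len(tables)
    mean_counts = {p: c / n for p, c in mean_counts.items()}
    total = sum(mean_counts.values())
    if total == 0:
        return {}
    return {p: c / total for p, c in mean_counts.items()}


def pooled_relative_frequency(
    tables_by_unit: Mapping[str, Sequence[KmerTable]],
) -> dict[str, float]:
    """Group-level relative frequency: per-participant mean counts are
    averaged over participants, then normalised."""
    per_unit_means: list[dict[str, float]] = []
    for unit_tables in tables_by_unit.values():
        unit_tables = list(unit_tables)
        if not unit_tables:
            continue
        means: dict[str, float] = {}
        for t in unit_tables:
            for p, c in t.counts.items():
                means[p] = means.get(p, 0.0) + c
        per_unit_means.append({p: c / len(unit_tables) for p, c in means.items()})
    if not per_unit_means:
        return {}
    pooled: dict[str, float] = {}
    for means in per_unit_means:
        for p, c in means.items():
            pooled[p] = pooled.get(p, 0.0) + c
    pooled = {p: c / len(per_unit_means) for p, c in pooled.items()}
    total = sum(pooled.values())
    if total == 0:
        return {}
    return {p: c / total for p, c in pooled.items()}


def relevant_patterns(
    rel_freq: Mapping[str, float], threshold: float = 0.01
) -> set[str]:
    """Patterns whose relative frequency strictly exceeds the threshold."""
    return {p for p, f in rel_freq.items() if f > threshold}


def count_possible_patterns(n_aoi: int, k: int, collapsed: bool = True) -> int:
    """Size of the k-mer pattern space over an alphabet of ``n_aoi`` letters.

    Uncollapsed strings admit n^k patterns. A collapsed dwell string can never
    repeat a letter adjacently, so only n * (n-1)^(k-1) patterns can occur
    (e.g. 108 length-4 patterns over 4 AOIs).
    """
    if n_aoi < 1 or k < 1:
        raise ValueError(f"n_aoi and k must be >= 1, got {n_aoi}, {k}")
    if not collapsed:
        return n_aoi**k
    return n_aoi * (n_aoi - 1) ** (k - 1)


def iter_possible_patterns(
    alphabet: str, k: int, collapsed: bool = True
) -> Iterator[str]:
    """Enumerate every pattern the space admits, in lexicographic product order."""
    for tup in itertools.product(sorted(alphabet), repeat=k):
        if collapsed and any(a == b for a, b in zip(tup, tup[1:])):
            continue
        yield "".join(tup)


def restrict_alphabet(table: KmerTable, keep: Iterable[str]) -> KmerTable:
    """Drop every pattern containing a letter outside ``keep``.

    Supports result tables restricted to the task AOIs (e.g. A/B/C without
    whitespace). Relative frequencies renormalise automatically over the
    survivors since ``rel_freq`` derives from the counts.
    """
    keep = set(keep)
    if not keep:
        raise ValueError("keep must name at least one letter")
    counts = {
        p: c for p, c in table.counts.items() if all(ch in keep for ch in p)
    }
    return KmerTable(k=table.k, counts=counts)
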
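"""Synthetic multi-trial cohorts of labeled fixation sequences.

The generator emulates a repeated-assembly eye-tracking study: each trial is a
collapsed AOI sequence sampled from a first-order Markov chain with zero
diagonal (a collapsed string never repeats a letter adjacently). Two chains
describe the behavioural extremes — a novice chain that routes attention
through the manual (A→C→B cycles, giving frequent ACB/BAC/CBA/CAC patterns)
and an expert chain that alternates between bricks and building area (A↔B,
giving dominant ABAB/BABA patterns). Learning is an exponential-saturation
mix: on trial t the transition matrix is a convex combination with expert
weight w(t) = 1 - exp(-λ (t - 1)), so trial 1 is pure novice behaviour and
the chain converges to the expert reference as practice accumulates. String
lengths shrink along the same schedule (novices produce longer, more
meandering sequences early on) and per-fixation durations are lognormal.

The default cohort mirrors a 30-participant study: two novice groups of 14
(the simpler-stimulus group learning faster than the complex-stimulus group)
plus 2 trained experts, 8 trials each — 240 gaze sequences in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ingest import FixationEvent, TrialRecord
from .kmer import iter_possible_patterns

ALPHABET = "ABCW"

_ROW_TOL = 1e-9


@dataclass(frozen=True)
class MarkovKernel:
    """First-order chain over AOI letters with zero self-transitions."""

    alphabet: str
    transition: np.ndarray  # row-stochastic, zero diagonal
    start: np.ndarray

    def __post_init__(self) -> None:
        trans = np.asarray(self.transition, dtype=float)
        start = np.asarray(self.start, dtype=float)
        object.__setattr__(self, "transition", trans)
        object.__setattr__(self, "start", start)
        n = len(self.alphabet)
        if trans.shape != (n, n):
            raise ValueError(f"transition must be {n}x{n}")
        if not np.allclose(trans.sum(axis=1), 1.0, atol=_ROW_TOL):
            raise ValueError("transition rows must sum to 1")
        if np.any(np.abs(np.diag(trans)) > _ROW_TOL):
            raise ValueError("transition diagonal must be 0 (collapsed strings)")
        if not np.isclose(start.sum(), 1.0, atol=_ROW_TOL):
            raise ValueError("start distribution must sum to 1")

    def index(self, letter: str) -> int:
        return self.alphabet.index(letter)

    def stationary(self) -> np.ndarray:
        """Stationary distribution π with π P = π (left unit eigenvector)."""
        vals, vecs = np.linalg.eig(self.transition.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()

    def expected_pattern_freq(self, k: int) -> dict[str, float]:
        """Expected relative frequency of every collapsed k-mer under
        stationarity: P(a0..a_{k-1}) = π(a0) · Π P(a_i → a_{i+1})."""
        pi = self.stationary()
        out: dict[str, float] = {}
        for pattern in iter_possible_patterns(self.alphabet, k, collapsed=True):
            p = pi[self.index(pattern[0])]
            for a, b in zip(pattern, pattern[1:]):
                p *= self.transition[self.index(a), self.index(b)]
            out[pattern] = float(p)
        return out


def mix_kernel(
    novice: MarkovKernel, expert: MarkovKernel, t: int, lam: float
) -> MarkovKernel:
    """Trial-t kernel on the learning curve: expert weight w(t) = 1 - e^{-λ(t-1)}.

    w(1) = 0 (pure novice), w → 1 as practice accumulates; λ = 0 freezes the
    novice kernel for all trials.
    """
    if lam < 0:
        raise ValueError(f"learning rate must be >= 0, got {lam}")
    if novice.alphabet != expert.alphabet:
        raise ValueError("kernels must share an alphabet")
    w = 1.0 - np.exp(-lam * (t - 1))
    return MarkovKernel(
        alphabet=novice.alphabet,
        transition=(1 - w) * novice.transition + w * expert.transition,
        start=(1 - w) * novice.start + w * expert.start,
    )


def sample_trial(
    kernel: MarkovKernel,
    length: int,
    rng: np.random.Generator,
    *,
    duration_mu: float = 5.7,
    duration_sigma: float = 0.55,
    saccade_gap_ms: float = 30.0,
) -> list[FixationEvent]:
    """Sample one labeled fixation sequence of the given collapsed length.

    Letters follow the chain (start distribution, then transitions); the zero
    diagonal guarantees the output is already collapsed. Durations are
    lognormal (ms) and start times cumulate with a fixed inter-fixation gap.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    n = len(kernel.alphabet)
    idx = np.empty(length, dtype=int)
    idx[0] = rng.choice(n, p=kernel.start)
    for i in range(1, length):
        idx[i] = rng.choice(n, p=kernel.transition[idx[i - 1]])
    durations = rng.lognormal(duration_mu, duration_sigma, size=length)
    out: list[FixationEvent] = []
    t = 0.0
    for i in range(length):
        out.append(
            FixationEvent(
                start=round(t, 3),
                duration=round(float(durations[i]), 3),
                label=kernel.alphabet[idx[i]],
            )
        )
        t += durations[i] + saccade_gap_ms
    return out


# Default behavioural kernels (rows/columns ordered A, B, C, W): the expert
# alternates bricks <-> building area with rare manual glances; the novice
# routes through the manual, producing ACB/BAC/CBA cycles and CAC checks.
EXPERT_KERNEL = MarkovKernel(
    alphabet=ALPHABET,
    transition=np.array(
        [
            [0.00, 0.90, 0.04, 0.06],
            [0.92, 0.00, 0.03, 0.05],
            [0.80, 0.15, 0.00, 0.05],
            [0.50, 0.40, 0.10, 0.00],
        ]
    ),
    start=np.array([0.35, 0.55, 0.02, 0.08]),
)

NOVICE_KERNEL = MarkovKernel(
    alphabet=ALPHABET,
    transition=np.array(
        [
            [0.00, 0.28, 0.60, 0.12],
            [0.55, 0.00, 0.35, 0.10],
            [0.35, 0.55, 0.00, 0.10],
            [0.40, 0.25, 0.35, 0.00],
        ]
    ),
    start=np.array([0.25, 0.25, 0.40, 0.10]),
)


@dataclass(frozen=True)
class GroupSpec:
    """One participant group: its kernels, learning rate and string lengths."""

    name: str
    n_participants: int
    novice_kernel: MarkovKernel
    expert_kernel: MarkovKernel
    learning_rate: float
    novice_length: float = 100.0
    expert_length: float = 55.0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")


@dataclass(frozen=True)
class SynthSpec:
    """Full cohort specification: groups, trial count, durations, seed."""

    groups: tuple[GroupSpec, ...]
    n_trials: int = 8
    duration_mu: float = 5.7
    duration_sigma: float = 0.55
    seed: int = 0
    ground_truth_ks: tuple[int, ...] = (1, 2, 3, 4)

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2")
        alphabets = {g.novice_kernel.alphabet for g in self.groups} | {
            g.expert_kernel.alphabet for g in self.groups
        }
        if len(alphabets) > 1:
            raise ValueError("all kernels must share one alphabet")


def default_spec(
    seed: int = 0,
    *,
    n_novices_per_group: int = 14,
    n_experts: int = 2,
    n_trials: int = 8,
) -> SynthSpec:
    """The study-mirroring default cohort: 14 + 14 novices on two stimulus
    complexities (the simpler one learned faster) plus 2 trained experts."""
    groups = [
        GroupSpec(
            name="NOV BC",
            n_participants=n_novices_per_group,
            novice_kernel=NOVICE_KERNEL,
            expert_kernel=EXPERT_KERNEL,
            learning_rate=0.40,
        ),
        GroupSpec(
            name="NOV MC",
            n_participants=n_novices_per_group,
            novice_kernel=NOVICE_KERNEL,
            expert_kernel=EXPERT_KERNEL,
            learning_rate=0.25,
            novice_length=110.0,
        ),
    ]
    if n_experts > 0:
        groups.append(
            GroupSpec(
                name="EXP",
                n_participants=n_experts,
                novice_kernel=EXPERT_KERNEL,
                expert_kernel=EXPERT_KERNEL,
                learning_rate=0.0,
                novice_length=55.0,
                expert_length=55.0,
            )
        )
    return SynthSpec(groups=tuple(groups), n_trials=n_trials, seed=seed)


def generate_cohort(spec: SynthSpec) -> tuple[list[TrialRecord], dict]:
    """Sample every participant x trial sequence and record the ground truth.

    Each participant gets a deterministic substream seeded from
    (spec.seed, group index, participant index), so a fixed spec reproduces
    byte-identical cohorts. The ground-truth record carries the per-trial
    mixed kernels and the chain-derived expected k-mer relative frequencies.
    """
    trials: list[TrialRecord] = []
    truth: dict = {"seed": spec.seed, "n_trials": spec.n_trials, "groups": {}}
    for gi, group in enumerate(spec.groups):
        group_truth: dict = {
            "learning_rate": group.learning_rate,
            "n_participants": group.n_participants,
            "alphabet": group.novice_kernel.alphabet,
            "novice_transition": group.novice_kernel.transition.tolist(),
            "expert_transition": group.expert_kernel.transition.tolist(),
            "trials": {},
        }
        for t in range(1, spec.n_trials + 1):
            kernel = mix_kernel(
                group.novice_kernel, group.expert_kernel, t, group.learning_rate
            )
            w = 1.0 - np.exp(-group.learning_rate * (t - 1))
            group_truth["trials"][t] = {
                "expert_weight": float(w),
                "transition": kernel.transition.tolist(),
                "mean_length": float(
                    (1 - w) * group.novice_length + w * group.expert_length
                ),
                "expected_rel_freq": {
                    k: kernel.expected_pattern_freq(k)
                    for k in spec.ground_truth_ks
                },
            }
        truth["groups"][group.name] = group_truth

        prefix = "".join(c for c in group.name if c.isalnum())[:4] or f"G{gi}"
        for pi in range(group.n_participants):
            rng = np.random.default_rng([spec.seed, gi, pi])
            pid = f"{prefix}{pi + 1:02d}"
            for t in range(1, spec.n_trials + 1):
                kernel = mix_kernel(
                    group.novice_kernel, group.expert_kernel, t, group.learning_rate
                )
                w = 1.0 - np.exp(-group.learning_rate * (t - 1))
                mean_len = (1 - w) * group.novice_length + w * group.expert_length
                length = max(2, int(rng.poisson(mean_len)))
                fixations = sample_trial(
                    kernel,
                    length,
                    rng,
                    duration_mu=spec.duration_mu,
                    duration_sigma=spec.duration_sigma,
                )
                trials.append(
                    TrialRecord(
                        participant_id=pid,
                        group=group.name,
                        trial_index=t,
                        fixations=fixations,
                    )
                )
    return trials, truth
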
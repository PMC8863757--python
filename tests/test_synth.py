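import numpy as np
import pytest

from gazekmer.errors import DegenerateDataError
from gazekmer.kmer import extract_kmers
from gazekmer.stats import paired_first_last
from gazekmer.stringify import from_trial
from gazekmer.synth import (
    ALPHABET,
    EXPERT_KERNEL,
    NOVICE_KERNEL,
    GroupSpec,
    MarkovKernel,
    SynthSpec,
    default_spec,
    generate_cohort,
    mix_kernel,
    sample_trial,
)
from gazekmer.trends import build_series, fit_trend


class TestKernelValidation:
    def test_rows_must_be_stochastic(self):
        with pytest.raises(ValueError):
            MarkovKernel("AB", np.array([[0, 0.5], [1, 0]]), np.array([0.5, 0.5]))

    def test_diagonal_must_be_zero(self):
        with pytest.raises(ValueError):
            MarkovKernel("AB", np.array([[0.5, 0.5], [1, 0]]), np.array([0.5, 0.5]))

    def test_stationary_is_invariant_under_the_chain(self):
        for kernel in (NOVICE_KERNEL, EXPERT_KERNEL):
            pi = kernel.stationary()
            assert pi @ kernel.transition == pytest.approx(pi, abs=1e-12)
            assert pi.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_expected_pattern_freqs_sum_to_one(self, k):
        freqs = NOVICE_KERNEL.expected_pattern_freq(k)
        assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-12)


class TestMixKernel:
    def test_trial_one_is_pure_novice(self):
        mixed = mix_kernel(NOVICE_KERNEL, EXPERT_KERNEL, t=1, lam=2.0)
        assert np.allclose(mixed.transition, NOVICE_KERNEL.transition)

    def test_zero_rate_freezes_novice_kernel(self):
        for t in (1, 4, 8):
            mixed = mix_kernel(NOVICE_KERNEL, EXPERT_KERNEL, t=t, lam=0.0)
            assert np.allclose(mixed.transition, NOVICE_KERNEL.transition)

    def test_large_rate_converges_to_expert(self):
        mixed = mix_kernel(NOVICE_KERNEL, EXPERT_KERNEL, t=8, lam=5.0)
        assert np.allclose(mixed.transition, EXPERT_KERNEL.transition, atol=1e-6)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            mix_kernel(NOVICE_KERNEL, EXPERT_KERNEL, t=1, lam=-0.1)


class TestSampleTrial:
    def test_deterministic_alternation_chain(self):
        kernel = MarkovKernel(
            "AB", np.array([[0.0, 1.0], [1.0, 0.0]]), np.array([1.0, 0.0])
        )
        fixations = sample_trial(kernel, 9, np.random.default_rng(0))
        letters = "".join(f.label for f in fixations)
        assert letters == "ABABABABA"
        assert extract_kmers(letters, 4).counts == {"ABAB": 3, "BABA": 3}

    def test_length_one_draws_from_start(self):
        kernel = MarkovKernel(
            "AB", np.array([[0.0, 1.0], [1.0, 0.0]]), np.array([0.0, 1.0])
        )
        fixations = sample_trial(kernel, 1, np.random.default_rng(0))
        assert [f.label for f in fixations] == ["B"]

    def test_fixed_seed_reproduces(self):
        a = sample_trial(NOVICE_KERNEL, 50, np.random.default_rng(42))
        b = sample_trial(NOVICE_KERNEL, 50, np.random.default_rng(42))
        assert [(f.start, f.duration, f.label) for f in a] == [
            (f.start, f.duration, f.label) for f in b
        ]

    def test_output_is_collapsed_and_time_ordered(self):
        fixations = sample_trial(NOVICE_KERNEL, 200, np.random.default_rng(1))
        letters = [f.label for f in fixations]
        assert all(a != b for a, b in zip(letters, letters[1:]))
        starts = [f.start for f in fixations]
        assert starts == sorted(starts)


class TestGenerateCohort:
    def test_default_cohort_has_240_sequences(self):
        trials, truth = generate_cohort(default_spec(seed=3))
        assert len(trials) == 240
        assert len({t.participant_id for t in trials}) == 30
        assert truth["n_trials"] == 8

    def test_minimal_cohort(self):
        spec = SynthSpec(
            groups=(
                GroupSpec("G", 1, NOVICE_KERNEL, EXPERT_KERNEL, learning_rate=0.3),
            ),
            n_trials=2,
        )
        trials, _ = generate_cohort(spec)
        assert len(trials) == 2

    def test_cohort_reproducible_for_fixed_seed(self):
        spec = default_spec(seed=9, n_novices_per_group=2, n_experts=1, n_trials=3)
        a, _ = generate_cohort(spec)
        b, _ = generate_cohort(spec)
        assert [(t.participant_id, t.trial_index) for t in a] == [
            (t.participant_id, t.trial_index) for t in b
        ]
        assert all(
            fa.label == fb.label and fa.start == fb.start
            for ta, tb in zip(a, b)
            for fa, fb in zip(ta.fixations, tb.fixations)
        )

    def test_ground_truth_records_mixed_kernels(self):
        spec = default_spec(seed=0, n_novices_per_group=2, n_experts=0, n_trials=3)
        _, truth = generate_cohort(spec)
        bc = truth["groups"]["NOV BC"]
        assert np.allclose(bc["trials"][1]["transition"], NOVICE_KERNEL.transition)
        for t in (1, 2, 3):
            for k, freqs in bc["trials"][t]["expected_rel_freq"].items():
                assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_trial_count_rejected(self):
        with pytest.raises(ValueError):
            default_spec(n_trials=1)


def test_empirical_2mer_frequencies_match_chain_expectation():
    """Long sampled trials reproduce pi(a) P(a->b) within 3 Monte-Carlo SEs."""
    kernel = MarkovKernel(ALPHABET, EXPERT_KERNEL.transition, EXPERT_KERNEL.stationary())
    expected = kernel.expected_pattern_freq(2)
    rng = np.random.default_rng(7)
    n_trials, length = 200, 400
    per_trial = {p: [] for p in expected}
    for _ in range(n_trials):
        fixations = sample_trial(kernel, length, rng)
        letters = "".join(f.label for f in fixations)
        table = extract_kmers(letters, 2)
        for p in expected:
            per_trial[p].append(table.counts.get(p, 0) / (length - 1))
    for p, exp_freq in expected.items():
        vals = np.array(per_trial[p])
        se = vals.std(ddof=1) / np.sqrt(n_trials)
        assert abs(vals.mean() - exp_freq) <= 3 * se + 1e-4, p


def test_frozen_learning_rate_gives_slopes_centered_on_zero():
    """With lam = 0 trials are exchangeable, so fitted slopes centre on 0."""
    spec = SynthSpec(
        groups=(
            GroupSpec("FLAT", 60, NOVICE_KERNEL, EXPERT_KERNEL, learning_rate=0.0),
        ),
        n_trials=8,
        seed=11,
    )
    trials, _ = generate_cohort(spec)
    for pattern in ("ACB", "BAB"):
        slopes = []
        by_pid: dict[str, dict[int, object]] = {}
        for t in trials:
            dw = from_trial(t)
            by_pid.setdefault(t.participant_id, {})[t.trial_index] = extract_kmers(
                dw.letters, len(pattern)
            )
        for pid, tables in by_pid.items():
            slopes.append(fit_trend(build_series(tables, pattern)).slope)
        slopes = np.array(slopes)
        sem = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean()) <= 3 * sem, pattern


def test_expert_cohorts_show_plateau_not_learning():
    """Pure-expert cohorts rarely show a significant first-vs-last change."""
    pattern = "BABA"
    significant = 0
    n_seeds = 20
    for seed in range(n_seeds):
        spec = SynthSpec(
            groups=(
                GroupSpec(
                    "EXP", 10, EXPERT_KERNEL, EXPERT_KERNEL, learning_rate=0.0,
                    novice_length=55.0, expert_length=55.0,
                ),
            ),
            n_trials=8,
            seed=100 + seed,
        )
        trials, _ = generate_cohort(spec)
        firsts, lasts = [], []
        for t in trials:
            if t.trial_index not in (1, 8):
                continue
            dw = from_trial(t)
            count = extract_kmers(dw.letters, 4).counts.get(pattern, 0)
            (firsts if t.trial_index == 1 else lasts).append(count)
        try:
            res = paired_first_last(firsts, lasts)
            if res.p < 0.05:
                significant += 1
        except DegenerateDataError:
            pass
    assert significant <= 0.10 * n_seeds + 1e-9
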
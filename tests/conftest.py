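import numpy as np
import pytest

from gazekmer.ingest import FixationEvent, TrialRecord


def make_trial(labels, durations=None, participant="P1", group="NOV", trial=1):
    """Build a labeled TrialRecord with contiguous fixation timing."""
    if durations is None:
        durations = [100.0] * len(labels)
    fixations, t = [], 0.0
    for letter, dur in zip(labels, durations):
        fixations.append(FixationEvent(start=t, duration=dur, label=letter))
        t += dur + 30.0
    return TrialRecord(
        participant_id=participant, group=group, trial_index=trial,
        fixations=fixations,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_collapsed_string(rng, alphabet="ABCW", length=30):
    """Random string with no adjacent repeats (what a dwell string looks like)."""
    letters = [rng.choice(list(alphabet))]
    while len(letters) < length:
        nxt = rng.choice([c for c in alphabet if c != letters[-1]])
        letters.append(nxt)
    return "".join(letters)
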
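import numpy as np
import pytest

from slfreqtag.preprocess import EpochSet
from slfreqtag.streams import build_lexicon, generate_stream


@pytest.fixture(scope="session")
def lexicon_a():
    return build_lexicon("A")


@pytest.fixture(scope="session")
def stream400(lexicon_a):
    """Canonical exposure stream: 4 words x 100 repetitions at 300 ms/syllable."""
    return generate_stream(lexicon_a, reps_per_word=100, syllable_duration=0.3, seed=7)


def make_phase_epochs(
    phases, freq=4.0, sfreq=64.0, n_samp=256, amp=1.0, ch_names=("Cz",)
) -> EpochSet:
    """Epochs of a single sinusoid with a given phase per epoch.

    The FFT phase of cos(2 pi f t + phi) at the bin of f equals phi, so these
    epochs have an analytically known ITC: the resultant length of the phase
    draws.
    """
    t = np.arange(n_samp) / sfreq
    data = np.stack(
        [
            np.tile(amp * np.cos(2 * np.pi * freq * t + p), (len(ch_names), 1))
            for p in np.atleast_1d(phases)
        ]
    )
    return EpochSet(
        epochs=data,
        epoch_onsets=np.arange(len(data)) * (n_samp / sfreq),
        sfreq=sfreq,
        ch_names=list(ch_names),
    )
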
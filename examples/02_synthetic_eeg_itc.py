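"""Simulate an entrained EEG recording and measure ITC and the WLI.

The generator injects a syllable-rate (3.333 Hz) and a word-rate (1.111 Hz)
component whose phase consistency across 12-word epochs is controlled by von
Mises concentrations; ITC recovers that phase consistency from the data.
"""

from slfreqtag import (
    SyntheticEEGConfig,
    build_lexicon,
    epoch_by_words,
    generate_stream,
    participant_summary,
    rereference_mastoids,
    simulate_recording,
)

stream = generate_stream(build_lexicon("A"), 100, 0.3, seed=7)
config = SyntheticEEGConfig(kappa_word_start=1.0, kappa_word_end=4.0,
                            kappa_syllable=8.0, seed=1)
rec, truth = simulate_recording(stream, config)
print(f"recording: {len(rec.ch_names)} channels x {rec.duration:.0f} s at {rec.sfreq:.0f} Hz")

rec = rereference_mastoids(rec)
epochs = epoch_by_words(rec, stream.word_onsets)
print(f"{epochs.n_epochs} word-locked epochs of {epochs.epoch_duration:.1f} s")

roi = rec.meta["roi_channels"]
summary = participant_summary(epochs, roi, participant_id="sim01")
print(f"ITC_word     = {summary.itc_word:.3f}  (bin {summary.word_bin_hz:.3f} Hz)")
print(f"ITC_syllable = {summary.itc_syllable:.3f}  (bin {summary.syllable_bin_hz:.3f} Hz)")
print(f"WLI          = {summary.wli:.3f}")
print(f"injected syllable-phase resultant R(kappa=8) = {truth.expected_r_syllable:.3f}")
# ITC_syllable lands near the analytic von Mises resultant (minus a little
# noise); ITC_word averages over the rising kappa schedule. A WLI well above
# the jittered-onset null indicates sensitivity to the hidden word structure.
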
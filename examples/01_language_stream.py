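"""Build the artificial-language exposure stream and inspect its statistics.

The stream concatenates four trisyllabic nonsense words, 100 repetitions
each at 300 ms per syllable, with no immediate word repeats. The only cue to
word boundaries is statistical: within-word syllable transitions are fully
predictable, boundary transitions are not.
"""

from slfreqtag import build_lexicon, generate_stream, transitional_probabilities

lexicon = build_lexicon("A")
print("words:", ", ".join(lexicon.word_labels))

stream = generate_stream(lexicon, reps_per_word=100, syllable_duration=0.3, seed=7)
print(f"{len(stream.tokens)} word tokens, {stream.total_duration:.0f} s of speech")

tp = transitional_probabilities(stream, lexicon)
print(f"mean TP within words:   {tp.within_word_mean:.2f}")
print(f"mean TP across boundaries: {tp.between_word_mean:.2f}")
# Within-word TP is exactly 1.0 (the next syllable is determined); the
# boundary TP sits near 1/3 because each word is followed uniformly by one
# of the three other words. That 1.0 vs 0.33 contrast is what listeners --
# and the downstream EEG analysis -- latch onto.
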
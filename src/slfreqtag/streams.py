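"""Artificial-language speech streams with controlled transitional-probability structure.

The exposure language consists of four trisyllabic nonsense words built from an
inventory of 12 unique syllables. Words are concatenated into a continuous
isochronous stream (one syllable every 300 ms by default) with the single
constraint that a word never immediately repeats. Within-word syllable
transitions are therefore fully predictable (TP = 1.0) while word-boundary
transitions are not (TP = 1/3 under uniform choice among the three
non-repeating successors) — the statistical cue listeners use to segment words.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Lexicon",
    "SpeechStream",
    "TPTable",
    "DetectionStream",
    "build_lexicon",
    "generate_stream",
    "transitional_probabilities",
    "generate_detection_streams",
    "write_events_tsv",
    "GenerationError",
]


class GenerationError(RuntimeError):
    """Raised when no valid token arrangement exists within the retry budget."""


#: The three language versions. Each word is an ordered triple of syllables.
_LEXICONS: dict[str, tuple[tuple[str, str, str], ...]] = {
    "A": (("pau", "to", "ne"), ("nu", "ra", "fi"), ("ga", "ba", "lu"), ("mai", "lo", "ki")),
    "B": (("pau", "to", "ki"), ("nu", "ra", "fi"), ("ga", "ba", "lu"), ("mai", "lo", "ne")),
    "C": (("pau", "to", "ne"), ("nu", "ra", "fi"), ("ga", "mi", "lu"), ("mai", "pu", "ki")),
}


@dataclass(frozen=True)
class Lexicon:
    """Four trisyllabic words over a 12-syllable inventory."""

    version: str
    words: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        if len(self.words) != 4:
            raise ValueError(f"a lexicon has exactly 4 words, got {len(self.words)}")
        inv = self.syllable_inventory
        if len(inv) != 12:
            raise ValueError(f"a lexicon has 12 distinct syllables, got {len(inv)}")

    @property
    def syllable_inventory(self) -> frozenset[str]:
        return frozenset(s for w in self.words for s in w)

    @property
    def word_labels(self) -> tuple[str, ...]:
        return tuple("".join(w) for w in self.words)

    def syllables_of(self, label: str) -> tuple[str, str, str]:
        for w in self.words:
            if "".join(w) == label:
                return w
        raise KeyError(label)

    def within_word_bigrams(self) -> frozenset[tuple[str, str]]:
        """All syllable pairs that are adjacent inside a word."""
        return frozenset(
            (w[i], w[i + 1]) for w in self.words for i in range(2)
        )


def build_lexicon(version: str = "A") -> Lexicon:
    """Return one of the three language versions (A, B or C)."""
    try:
        words = _LEXICONS[version.upper()]
    except KeyError:
        raise ValueError(
            f"unknown lexicon version {version!r}; expected one of {sorted(_LEXICONS)}"
        ) from None
    return Lexicon(version=version.upper(), words=words)


@dataclass
class SpeechStream:
    """A concrete exposure stream: word tokens plus nominal onset times.

    Onsets are stimulus-nominal (stream starts at t = 0) and lie on an exact
    grid of ``syllable_duration`` seconds; they are not sample-aligned.
    """

    tokens: list[str]
    syllables: list[str]
    syllable_onsets: np.ndarray
    word_onsets: np.ndarray
    syllable_duration: float
    total_duration: float
    seed: int
    lexicon_version: str = "A"


def _no_repeat_sequence(
    n_words: int, reps_per_word: int, rng: np.random.Generator, max_retries: int
) -> list[int]:
    """Sample word indices with exact per-word quotas and no immediate repeats.

    At each step the successor is drawn uniformly from the words that still have
    remaining quota, excluding the previous word. Dead ends (only the previous
    word left) abort the attempt; the whole sequence is resampled up to
    ``max_retries`` times.
    """
    for _ in range(max_retries):
        remaining = [reps_per_word] * n_words
        seq: list[int] = []
        prev = -1
        ok = True
        for _ in range(n_words * reps_per_word):
            choices = [i for i in range(n_words) if remaining[i] > 0 and i != prev]
            if not choices:
                ok = False
                break
            # weight by remaining quota to steer away from dead ends
            weights = np.array([remaining[i] for i in choices], dtype=float)
            nxt = int(rng.choice(choices, p=weights / weights.sum()))
            seq.append(nxt)
            remaining[nxt] -= 1
            prev = nxt
        if ok:
            return seq
    raise GenerationError(
        f"no valid no-repeat arrangement found in {max_retries} attempts"
    )


def generate_stream(
    lexicon: Lexicon,
    reps_per_word: int = 100,
    syllable_duration: float = 0.3,
    seed: int = 0,
    max_retries: int = 1000,
) -> SpeechStream:
    """Generate a pseudorandom exposure stream.

    Each word appears exactly ``reps_per_word`` times; the same word never
    occurs twice in a row. Defaults give the canonical 400-word, six-minute
    stream (100 repetitions x 4 words at 300 ms per syllable).
    """
    if reps_per_word < 1:
        raise ValueError("reps_per_word must be >= 1")
    if syllable_duration <= 0:
        raise ValueError("syllable_duration must be positive")
    rng = np.random.default_rng(seed)
    idx = _no_repeat_sequence(len(lexicon.words), reps_per_word, rng, max_retries)
    tokens = [lexicon.word_labels[i] for i in idx]
    syllables = [s for i in idx for s in lexicon.words[i]]
    n_syll = len(syllables)
    syllable_onsets = np.arange(n_syll) * syllable_duration
    word_onsets = syllable_onsets[::3].copy()
    return SpeechStream(
        tokens=tokens,
        syllables=syllables,
        syllable_onsets=syllable_onsets,
        word_onsets=word_onsets,
        syllable_duration=syllable_duration,
        total_duration=3 * syllable_duration * len(tokens),
        seed=seed,
        lexicon_version=lexicon.version,
    )


@dataclass
class TPTable:
    """Empirical syllable-to-syllable transitional probabilities.

    ``probs[(a, b)]`` is the conditional probability P(next = b | current = a)
    estimated from bigram counts over the syllable sequence. The within- and
    between-word means are averaged over transition *instances* (token-weighted),
    so the between-word mean on a long stream approaches 1/3.
    """

    probs: dict[tuple[str, str], float]
    within_word_mean: float
    between_word_mean: float
    n_transitions: int


def transitional_probabilities(stream: SpeechStream, lexicon: Lexicon) -> TPTable:
    """Tally bigram counts over the syllable sequence and form conditional TPs."""
    syl = stream.syllables
    if not syl:
        raise ValueError("empty stream")
    if not set(stream.tokens) <= set(lexicon.word_labels):
        raise ValueError("stream tokens are not drawn from the given lexicon")
    bigrams = list(zip(syl[:-1], syl[1:]))
    pair_counts = Counter(bigrams)
    first_counts = Counter(a for a, _ in bigrams)
    probs = {pair: c / first_counts[pair[0]] for pair, c in pair_counts.items()}

    within_bigrams = lexicon.within_word_bigrams()
    within_vals, between_vals = [], []
    for i, pair in enumerate(bigrams):
        p = probs[pair]
        # positions 0,1 within a word; position 2 is a word boundary
        if i % 3 == 2:
            between_vals.append(p)
        else:
            within_vals.append(p)
            assert pair in within_bigrams
    return TPTable(
        probs=probs,
        within_word_mean=float(np.mean(within_vals)),
        between_word_mean=float(np.mean(between_vals)) if between_vals else float("nan"),
        n_transitions=len(bigrams),
    )


@dataclass
class DetectionStream:
    """One target-detection trial stream: 16 word tokens and a target syllable."""

    tokens: list[str]
    target_word: str
    target_syllable: str
    target_position: int  # 1-based syllable position within the word
    syllable_duration: float
    syllable_onsets: np.ndarray
    target_onsets: np.ndarray


_MODE_SYLLABLE_DURATION = {"child": 0.35, "adult": 0.30}


def generate_detection_streams(
    lexicon: Lexicon,
    n_streams: int,
    mode: str = "adult",
    seed: int = 0,
) -> list[DetectionStream]:
    """Build target-detection streams with counterbalanced targets.

    Each stream presents the four words four times each (16 tokens, no
    immediate repeats). The (word, position) target pairs are assigned
    round-robin over the 12 combinations, so with n_streams divisible by 12
    every syllable position receives ``n_streams * 4 / 3`` targets
    (24 streams -> 32 per position; 36 -> 48). Child mode slows the syllable
    rate to 350 ms.
    """
    if n_streams < 1:
        raise ValueError("n_streams must be >= 1")
    if mode not in _MODE_SYLLABLE_DURATION:
        raise ValueError(f"mode must be 'child' or 'adult', got {mode!r}")
    dur = _MODE_SYLLABLE_DURATION[mode]
    rng = np.random.default_rng(seed)

    combos = list(itertools.product(range(4), range(3)))  # (word, position)
    assignments = [combos[i % 12] for i in range(n_streams)]
    # leftover block (n_streams % 12) already covered by the modular walk;
    # shuffle stream order so versions differ by seed
    rng.shuffle(assignments)

    streams = []
    for word_i, pos_i in assignments:
        idx = _no_repeat_sequence(4, 4, rng, max_retries=1000)
        tokens = [lexicon.word_labels[i] for i in idx]
        onsets = np.arange(len(idx) * 3) * dur
        target_word = lexicon.word_labels[word_i]
        target_syll = lexicon.words[word_i][pos_i]
        target_onsets = np.array(
            [onsets[3 * k + pos_i] for k, t in enumerate(tokens) if t == target_word]
        )
        streams.append(
            DetectionStream(
                tokens=tokens,
                target_word=target_word,
                target_syllable=target_syll,
                target_position=pos_i + 1,
                syllable_duration=dur,
                syllable_onsets=onsets,
                target_onsets=target_onsets,
            )
        )
    return streams


def write_events_tsv(stream: SpeechStream, path: str | Path) -> pd.DataFrame:
    """Write word and syllable events as a BIDS-style TSV and return the table."""
    rows = []
    for w, (token, onset) in enumerate(zip(stream.tokens, stream.word_onsets)):
        rows.append(
            dict(onset=onset, duration=3 * stream.syllable_duration,
                 trial_type="word", label=token, word_index=w, syllable_position="")
        )
    for i, (syl, onset) in enumerate(zip(stream.syllables, stream.syllable_onsets)):
        rows.append(
            dict(onset=onset, duration=stream.syllable_duration,
                 trial_type="syllable", label=syl, word_index=i // 3,
                 syllable_position=i % 3 + 1)
        )
    df = pd.DataFrame(rows).sort_values(["onset", "trial_type"], kind="stable")
    df.to_csv(path, sep="\t", index=False)
    return df
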
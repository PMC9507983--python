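"""Synthetic EEG and behavioural data with known ground truth.

The EEG generator emulates the statistical structure the entrainment analysis
assumes rather than biophysics: a syllable-rate (1/0.3 s = 3.333 Hz) and a
word-rate (1/0.9 s = 1.111 Hz) sinusoid whose phase offsets are drawn per
12-word analysis epoch from von Mises distributions, on top of 1/f^alpha
Gaussian background noise. The von Mises concentration kappa controls phase
consistency across epochs, hence the downstream ITC: the expected resultant
length is R(kappa) = I1(kappa) / I0(kappa). Ramping kappa_word across epochs
injects a known learning trajectory. ROI channels carry the signal at gain 1,
other scalp channels at gain 0.3 (frontocentral topography), and the two
mastoid channels carry noise only.

Behavioural tables are generated from a single latent learning strength
L in [0, 1]: 2AFC accuracy is p = 0.5 + 0.4 L, familiarity-rating category
means separate linearly in L, and detection reaction times speed up with
syllable position in proportion to L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .preprocess import EEGRecording
from .streams import DetectionStream, Lexicon, SpeechStream, generate_detection_streams

__all__ = [
    "SyntheticEEGConfig",
    "GroundTruth",
    "BehaviourSimConfig",
    "BehaviourTables",
    "FoilSet",
    "simulate_recording",
    "simulate_behaviour",
    "make_partwords_nonwords",
    "attested_bigrams",
    "vonmises_resultant",
    "STANDARD_32",
    "FRONTOCENTRAL_ROI_32",
]

#: 32-channel 10-20 scalp montage used as the default child-style layout.
STANDARD_32 = [
    "Fp1", "AF3", "F7", "F3", "FC1", "FC5", "T7", "C3", "CP1", "CP5", "P7",
    "P3", "Pz", "PO3", "O1", "Oz", "O2", "PO4", "P4", "P8", "CP6", "CP2",
    "C4", "T8", "FC6", "FC2", "F4", "F8", "AF4", "Fp2", "Fz", "Cz",
]

#: 18 frontocentral electrodes of the 32-channel layout (signal-maximal ROI).
FRONTOCENTRAL_ROI_32 = [
    "Fp1", "Fp2", "AF3", "AF4", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
]

MASTOIDS = ["M1", "M2"]


def _montage(n_channels: int) -> tuple[list[str], list[str]]:
    """Scalp labels and a default frontocentral ROI for a given channel count."""
    if n_channels == 32:
        return list(STANDARD_32), list(FRONTOCENTRAL_ROI_32)
    labels = [f"Ch{i + 1:02d}" for i in range(n_channels)]
    return labels, labels[: max(1, n_channels // 2)]


def vonmises_resultant(kappa: float) -> float:
    """Expected resultant length R(kappa) = I1(kappa)/I0(kappa) of a von Mises phase."""
    if np.isinf(kappa):
        return 1.0
    if kappa == 0:
        return 0.0
    return float(special.i1e(kappa) / special.i0e(kappa))


@dataclass
class SyntheticEEGConfig:
    sampling_rate: float = 512.0
    n_channels: int = 32
    roi_channels: list[str] | None = None
    syllable_amp: float = 2.0  # µV
    word_amp: float = 1.0  # µV
    kappa_syllable: float = 8.0
    kappa_word_start: float = 0.5
    kappa_word_end: float = 4.0
    noise_sigma: float = 5.0  # µV per channel
    noise_exponent: float = 1.0  # 1/f^alpha
    non_roi_gain: float = 0.3
    pad_post: float = 1.5  # noise-only tail, seconds (room for onset jitter)
    words_per_epoch: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 2 * 3.34:
            raise ValueError("sampling rate must exceed twice the syllable rate")
        for k in (self.kappa_syllable, self.kappa_word_start, self.kappa_word_end):
            if k < 0:
                raise ValueError("kappa must be >= 0")
        if self.syllable_amp < 0 or self.word_amp < 0:
            raise ValueError("amplitudes must be >= 0")


@dataclass
class GroundTruth:
    """Injected per-epoch phase concentrations and their expected resultants."""

    kappa_word: np.ndarray
    kappa_syllable: float
    expected_r_word: np.ndarray
    expected_r_syllable: float
    wli_slope_sign: int
    seed: int


def _one_over_f_noise(
    n_samples: int, n_channels: int, sigma: float, alpha: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise spectrally shaped to 1/f^alpha, RMS-normalised per channel."""
    if sigma == 0:
        return np.zeros((n_channels, n_samples))
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-alpha / 2.0)
    scale[0] = 0.0  # no DC
    shaped = np.fft.irfft(spec * scale[None, :], n=n_samples, axis=1)
    shaped /= shaped.std(axis=1, keepdims=True)
    return sigma * shaped


def _draw_phase(kappa: float, rng: np.random.Generator) -> float:
    if np.isinf(kappa):
        return 0.0
    if kappa == 0:
        return float(rng.uniform(-np.pi, np.pi))
    return float(rng.vonmises(0.0, kappa))


def simulate_recording(
    stream: SpeechStream, config: SyntheticEEGConfig
) -> tuple[EEGRecording, GroundTruth]:
    """Synthesise a continuous EEG recording entrained to the speech stream.

    Word- and syllable-rate components restart at each 12-word epoch onset with
    a fresh von Mises phase offset; kappa_word interpolates linearly from
    ``kappa_word_start`` to ``kappa_word_end`` across epochs so the injected
    word-level phase locking (and hence ITC_word) grows over exposure.
    """
    fs = config.sampling_rate
    rng = np.random.default_rng(config.seed)
    scalp, default_roi = _montage(config.n_channels)
    roi = list(config.roi_channels) if config.roi_channels is not None else default_roi
    if not roi:
        raise ValueError("ROI channel list is empty")
    ch_names = scalp + MASTOIDS

    n_samp = int(round((stream.total_duration + config.pad_post) * fs))
    word_dur = 3 * stream.syllable_duration
    f_word = 1.0 / word_dur
    f_syll = 1.0 / stream.syllable_duration
    wpe = config.words_per_epoch
    n_epochs = len(stream.word_onsets) // wpe
    epoch_len = int(round(wpe * word_dur * fs))

    if np.isinf(config.kappa_word_start) and np.isinf(config.kappa_word_end):
        kappa_word = np.full(max(n_epochs, 1), np.inf)
    elif n_epochs > 1:
        kappa_word = np.linspace(config.kappa_word_start, config.kappa_word_end, n_epochs)
    else:
        kappa_word = np.full(max(n_epochs, 1), config.kappa_word_start)

    signal = np.zeros(n_samp)
    for n in range(n_epochs):
        t0 = stream.word_onsets[wpe * n]
        start = int(round(t0 * fs))
        stop = min(start + epoch_len, n_samp)
        t_local = np.arange(stop - start) / fs
        phi_w = _draw_phase(kappa_word[n], rng)
        phi_s = _draw_phase(config.kappa_syllable, rng)
        signal[start:stop] = (
            config.word_amp * np.cos(2 * np.pi * f_word * t_local + phi_w)
            + config.syllable_amp * np.cos(2 * np.pi * f_syll * t_local + phi_s)
        )

    gains = np.array(
        [1.0 if c in set(roi) else config.non_roi_gain for c in scalp] + [0.0, 0.0]
    )
    data = gains[:, None] * signal[None, :]
    data += _one_over_f_noise(
        n_samp, len(ch_names), config.noise_sigma, config.noise_exponent, rng
    )

    events = pd.DataFrame(
        dict(onset=stream.word_onsets, duration=word_dur,
             trial_type="word", label=stream.tokens)
    )
    rec = EEGRecording(
        data=data,
        sfreq=fs,
        ch_names=ch_names,
        reference="raw",
        events=events,
        meta=dict(
            synthetic=True, seed=config.seed, roi_channels=roi,
            kappa_word_start=config.kappa_word_start,
            kappa_word_end=config.kappa_word_end,
            kappa_syllable=config.kappa_syllable,
            noise_sigma=config.noise_sigma,
            noise_exponent=config.noise_exponent,
        ),
    )
    truth = GroundTruth(
        kappa_word=kappa_word,
        kappa_syllable=config.kappa_syllable,
        expected_r_word=np.array([vonmises_resultant(k) for k in kappa_word]),
        expected_r_syllable=vonmises_resultant(config.kappa_syllable),
        wli_slope_sign=(
            0 if config.kappa_word_end == config.kappa_word_start
            else int(np.sign(config.kappa_word_end - config.kappa_word_start))
        ),
        seed=config.seed,
    )
    return rec, truth


# --------------------------------------------------------------------------
# foils


@dataclass(frozen=True)
class FoilSet:
    partwords: tuple[tuple[str, str, str], ...]
    nonwords: tuple[tuple[str, str, str], ...]


def attested_bigrams(lexicon: Lexicon) -> frozenset[tuple[str, str]]:
    """Every syllable pair that can occur adjacently in an exposure stream:
    within-word pairs plus all (word-final, other-word-initial) boundary pairs."""
    within = lexicon.within_word_bigrams()
    between = frozenset(
        (w[2], v[0]) for w in lexicon.words for v in lexicon.words if w != v
    )
    return within | between


def make_partwords_nonwords(lexicon: Lexicon, seed: int = 0) -> FoilSet:
    """Build 4 partword and 4 nonword foils.

    Partwords keep exactly one within-word syllable pair and span a word
    boundary: either the final syllable of word X prepended to the first two
    syllables of word Y, or the last two syllables of Y followed by the first
    syllable of X. Nonwords chain syllables (position 2, position 1,
    position 3 of three distinct words) so that no adjacent pair ever occurs
    in the stream.
    """
    rng = np.random.default_rng(seed)
    words = lexicon.words
    within = lexicon.within_word_bigrams()
    attested = attested_bigrams(lexicon)

    pairs = [(x, y) for x in range(4) for y in range(4) if x != y]
    partwords: list[tuple[str, str, str]] = []
    rng.shuffle(pairs)
    for x, y in pairs:
        cand = (words[x][2], words[y][0], words[y][1])  # X3 Y1 Y2
        if cand not in partwords:
            partwords.append(cand)
        if len(partwords) == 2:
            break
    for x, y in pairs:
        cand = (words[y][1], words[y][2], words[x][0])  # Y2 Y3 X1
        if cand not in partwords:
            partwords.append(cand)
        if len(partwords) == 4:
            break
    for pw in partwords:
        n_within = sum(b in within for b in zip(pw[:-1], pw[1:]))
        assert n_within == 1, pw

    nonwords: list[tuple[str, str, str]] = []
    triples = [
        (a, b, c)
        for a in range(4) for b in range(4) for c in range(4)
        if len({a, b, c}) == 3
    ]
    rng.shuffle(triples)
    for a, b, c in triples:
        cand = (words[a][1], words[b][0], words[c][2])  # pos2, pos1, pos3
        if cand in nonwords:
            continue
        if any(b2 in attested for b2 in zip(cand[:-1], cand[1:])):
            continue
        nonwords.append(cand)
        if len(nonwords) == 4:
            break
    assert len(nonwords) == 4
    return FoilSet(partwords=tuple(partwords), nonwords=tuple(nonwords))


# --------------------------------------------------------------------------
# behaviour


@dataclass
class BehaviourSimConfig:
    n_participants: int = 24
    learning_strength: float = 0.5  # L in [0, 1]
    mode: str = "adult"  # detection task version
    rating_base: float = 2.5
    rating_word_gain: float = 1.2  # word mean = base + gain * L
    rating_partword_gain: float = 0.3
    rating_nonword_gain: float = -0.6
    rating_noise_sd: float = 0.8
    rt_baseline: float = 520.0  # ms
    rt_facilitation: float = 120.0  # ms speed-up per later position at L = 1
    rt_noise_sd: float = 60.0  # ms
    miss_rate: float = 0.12
    fa_rate: float = 0.1  # false alarms per target
    tasks: tuple[str, ...] = ("rating", "afc", "detection")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.learning_strength <= 1.0:
            raise ValueError("learning_strength must lie in [0, 1]")
        if self.rt_baseline <= 0:
            raise ValueError("rt_baseline must be positive")
        if self.mode not in ("child", "adult"):
            raise ValueError("mode must be 'child' or 'adult'")

    @property
    def afc_accuracy(self) -> float:
        """2AFC success probability p(L) = 0.5 + 0.4 L."""
        return 0.5 + 0.4 * self.learning_strength


@dataclass
class BehaviourTables:
    rating: pd.DataFrame
    afc: pd.DataFrame
    detection_targets: pd.DataFrame
    detection_presses: pd.DataFrame
    mode: str


def _discrete_rating(mean: float, sd: float, rng: np.random.Generator) -> int:
    return int(np.clip(round(rng.normal(mean, sd)), 1, 4))


def simulate_behaviour(
    config: BehaviourSimConfig, lexicon: Lexicon
) -> BehaviourTables:
    """Generate rating, 2AFC and target-detection trial tables.

    Ratings: 12 trials per participant (4 words, 4 partwords, 4 nonwords) on a
    1-4 scale. 2AFC: 16 trials, each word paired exhaustively with two
    partwords and two nonwords; success probability 0.5 + 0.4 L. Detection:
    hits occur with probability 1 - miss_rate; RTs shorten linearly with
    syllable position in proportion to L; false alarms are uniform stray
    presses at ``fa_rate`` per target.
    """
    rng = np.random.default_rng(config.seed)
    L = config.learning_strength
    foils = make_partwords_nonwords(lexicon, seed=config.seed)
    cat_means = {
        "word": config.rating_base + config.rating_word_gain * L,
        "partword": config.rating_base + config.rating_partword_gain * L,
        "nonword": config.rating_base + config.rating_nonword_gain * L,
    }
    n_streams = 24 if config.mode == "child" else 36
    window_ms = 1400.0 if config.mode == "child" else 1200.0

    rating_rows, afc_rows, target_rows, press_rows = [], [], [], []
    for i in range(config.n_participants):
        pid = f"P{i + 1:03d}"
        items = (
            [("word", w) for w in lexicon.word_labels]
            + [("partword", "".join(p)) for p in foils.partwords]
            + [("nonword", "".join(nw)) for nw in foils.nonwords]
        )
        for cat, item in items if "rating" in config.tasks else []:
            rating_rows.append(
                dict(participant_id=pid, item=item, category=cat,
                     rating=_discrete_rating(cat_means[cat], config.rating_noise_sd, rng))
            )

        for w in lexicon.word_labels if "afc" in config.tasks else []:
            pw_pick = rng.choice(len(foils.partwords), size=2, replace=False)
            nw_pick = rng.choice(len(foils.nonwords), size=2, replace=False)
            foil_items = [("partword", "".join(foils.partwords[j])) for j in pw_pick]
            foil_items += [("nonword", "".join(foils.nonwords[j])) for j in nw_pick]
            for foil_type, foil in foil_items:
                correct = bool(rng.random() < config.afc_accuracy)
                afc_rows.append(
                    dict(participant_id=pid, word=w, foil=foil,
                         foil_type=foil_type, choice=w if correct else foil,
                         correct=correct)
                )

        if "detection" not in config.tasks:
            continue
        streams = generate_detection_streams(
            lexicon, n_streams, mode=config.mode,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        for s_i, st in enumerate(streams):
            stream_dur = len(st.tokens) * 3 * st.syllable_duration
            for onset in st.target_onsets:
                target_rows.append(
                    dict(participant_id=pid, stream=s_i, onset=float(onset),
                         position=st.target_position)
                )
                if rng.random() < config.miss_rate:
                    continue
                rt = rng.normal(
                    config.rt_baseline
                    - config.rt_facilitation * L * (st.target_position - 1),
                    config.rt_noise_sd,
                )
                rt = float(np.clip(rt, 80.0, window_ms - 1.0))
                press_rows.append(
                    dict(participant_id=pid, stream=s_i, time=float(onset) + rt / 1000.0)
                )
            n_fa = rng.binomial(len(st.target_onsets), config.fa_rate)
            for _ in range(n_fa):
                press_rows.append(
                    dict(participant_id=pid, stream=s_i,
                         time=float(rng.uniform(0, stream_dur)))
                )

    press_cols = ["participant_id", "stream", "time"]
    presses = pd.DataFrame(press_rows, columns=press_cols).sort_values(
        press_cols, ignore_index=True
    )
    return BehaviourTables(
        rating=pd.DataFrame(rating_rows, columns=["participant_id", "item", "category", "rating"]),
        afc=pd.DataFrame(afc_rows, columns=["participant_id", "word", "foil", "foil_type", "choice", "correct"]),
        detection_targets=pd.DataFrame(
            target_rows, columns=["participant_id", "stream", "onset", "position"]
        ),
        detection_presses=presses,
        mode=config.mode,
    )
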
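"""EEG preprocessing: filtering, mastoid re-referencing, word-locked epoching,
and amplitude-based artifact screening.

The epoching convention follows the frequency-tagging design: the continuous
recording is cut into nonoverlapping epochs time-locked to every 12th word
onset, each spanning 12 words (10.8 s at the 900 ms word rate). Because the
stimulus grid is not sample-aligned, onsets map to the nearest sample and all
epochs share one fixed length of round(12 * word_duration * fs) samples
(5530 at 512 Hz), which keeps the maximum timing error below 1 ms and the
FFT bin grid identical across epochs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

import mne

logger = logging.getLogger(__name__)

__all__ = [
    "EEGRecording",
    "EpochSet",
    "filter_recording",
    "rereference_mastoids",
    "epoch_by_words",
    "reject_artifacts",
]


@dataclass
class EEGRecording:
    """Continuous multi-channel EEG in microvolts.

    ``data`` is channels x samples; ``events`` (optional) is an onset-sorted
    table with at least ``onset`` (s) and ``trial_type`` columns.
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str]
    reference: str = "raw"  # 'raw' | 'mastoid_avg'
    events: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.ch_names):
            raise ValueError("data must be channels x samples matching ch_names")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite samples in recording")
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel labels must be unique")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    def copy(self) -> "EEGRecording":
        return EEGRecording(
            data=self.data.copy(),
            sfreq=self.sfreq,
            ch_names=list(self.ch_names),
            reference=self.reference,
            events=None if self.events is None else self.events.copy(),
            meta=dict(self.meta),
        )


def filter_recording(
    rec: EEGRecording,
    band: tuple[float, float] = (0.1, 20.0),
    notch: float | None = 60.0,
) -> EEGRecording:
    """Zero-phase band-pass (FIR, forward-backward) plus optional notch filter.

    Zero-phase filtering matters here because the downstream statistic is
    phase-based; a causal filter would rotate phases differently across
    frequencies.
    """
    low, high = band
    nyq = rec.sfreq / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band {band} must satisfy 0 < low < high < Nyquist ({nyq})")
    out = rec.copy()
    data = out.data
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if notch is not None:
            if not (0 < notch < nyq):
                raise ValueError(f"notch {notch} outside (0, Nyquist)")
            data = mne.filter.notch_filter(
                data, rec.sfreq, freqs=notch, phase="zero", verbose="error"
            )
        data = mne.filter.filter_data(
            data, rec.sfreq, l_freq=low, h_freq=high, phase="zero", verbose="error"
        )
    out.data = data
    out.meta.update(filter_band=band, filter_notch=notch, filter_phase="zero")
    return out


def rereference_mastoids(
    rec: EEGRecording, mastoid_labels: tuple[str, str] = ("M1", "M2")
) -> EEGRecording:
    """Subtract the mean of the left/right mastoid channels from every channel."""
    if rec.reference != "raw":
        raise ValueError(f"recording already re-referenced ({rec.reference})")
    missing = [m for m in mastoid_labels if m not in rec.ch_names]
    if missing:
        raise ValueError(f"mastoid channel(s) not found: {missing}")
    out = rec.copy()
    idx = [rec.ch_names.index(m) for m in mastoid_labels]
    ref = rec.data[idx].mean(axis=0)
    out.data = rec.data - ref[None, :]
    out.reference = "mastoid_avg"
    out.meta.update(reference_channels=list(mastoid_labels))
    return out


@dataclass
class EpochSet:
    """Fixed-length word-locked epochs: n_epochs x channels x samples."""

    epochs: np.ndarray
    epoch_onsets: np.ndarray  # seconds, nominal stimulus time of epoch start
    sfreq: float
    ch_names: list[str]
    words_per_epoch: int = 12
    retained_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.retained_mask is None:
            self.retained_mask = np.ones(len(self.epochs), dtype=bool)
        self.retained_mask = np.asarray(self.retained_mask, dtype=bool)
        if len(self.retained_mask) != len(self.epochs):
            raise ValueError("retained_mask length must equal n_epochs")

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    @property
    def n_retained(self) -> int:
        return int(self.retained_mask.sum())

    @property
    def epoch_duration(self) -> float:
        return self.epochs.shape[2] / self.sfreq

    def retained(self) -> np.ndarray:
        return self.epochs[self.retained_mask]

    def subset(self, indices: Sequence[int]) -> "EpochSet":
        idx = np.asarray(indices, dtype=int)
        return EpochSet(
            epochs=self.epochs[idx],
            epoch_onsets=self.epoch_onsets[idx],
            sfreq=self.sfreq,
            ch_names=list(self.ch_names),
            words_per_epoch=self.words_per_epoch,
            retained_mask=self.retained_mask[idx],
        )


def epoch_by_words(
    rec: EEGRecording,
    word_onsets: np.ndarray,
    words_per_epoch: int = 12,
    word_duration: float = 0.9,
) -> EpochSet:
    """Cut nonoverlapping epochs starting at every ``words_per_epoch``-th word onset.

    Epoch k starts at word onset index ``words_per_epoch * k`` mapped to the
    nearest sample; every epoch has round(words_per_epoch * word_duration * fs)
    samples. Epochs that would run past either end of the recording (possible
    after onset jittering) are dropped with a log entry.
    """
    onsets = np.asarray(word_onsets, dtype=float)
    if np.any(np.diff(onsets) < 0):
        raise ValueError("word onsets must be sorted")
    n_full = len(onsets) // words_per_epoch
    n_samp = int(round(words_per_epoch * word_duration * rec.sfreq))
    if n_full == 0:
        warnings.warn(
            f"fewer than {words_per_epoch} word onsets; no epochs extracted",
            stacklevel=2,
        )
        return EpochSet(
            epochs=np.empty((0, len(rec.ch_names), n_samp)),
            epoch_onsets=np.empty(0),
            sfreq=rec.sfreq,
            ch_names=list(rec.ch_names),
            words_per_epoch=words_per_epoch,
        )
    epochs, kept_onsets, dropped = [], [], 0
    for k in range(n_full):
        t0 = onsets[words_per_epoch * k]
        start = int(round(t0 * rec.sfreq))
        if start < 0 or start + n_samp > rec.n_samples:
            dropped += 1
            continue
        epochs.append(rec.data[:, start : start + n_samp])
        kept_onsets.append(t0)
    if dropped:
        logger.info("epoch_by_words: dropped %d epoch(s) outside recording bounds", dropped)
    return EpochSet(
        epochs=np.stack(epochs) if epochs else np.empty((0, len(rec.ch_names), n_samp)),
        epoch_onsets=np.array(kept_onsets),
        sfreq=rec.sfreq,
        ch_names=list(rec.ch_names),
        words_per_epoch=words_per_epoch,
    )


def reject_artifacts(
    epochs: EpochSet,
    peak_to_peak_threshold: float = 150.0,
    channels: Sequence[str] | None = None,
) -> EpochSet:
    """Flag epochs whose peak-to-peak amplitude exceeds the threshold (in µV).

    An automated stand-in for manual artifact screening: any epoch whose
    maximum peak-to-peak range over the screened channels exceeds the
    threshold is marked not-retained. Returns a new EpochSet; data unchanged.
    """
    if peak_to_peak_threshold <= 0:
        raise ValueError("threshold must be positive")
    if channels is None:
        ch_idx = np.arange(len(epochs.ch_names))
    else:
        ch_idx = np.array([epochs.ch_names.index(c) for c in channels])
    data = epochs.epochs[:, ch_idx, :]
    ptp = data.max(axis=2) - data.min(axis=2)  # n_epochs x channels
    bad = ptp.max(axis=1) > peak_to_peak_threshold if len(data) else np.zeros(0, bool)
    mask = epochs.retained_mask & ~bad
    n_rej = int(bad.sum())
    if n_rej:
        logger.info("reject_artifacts: rejected %d / %d epochs", n_rej, epochs.n_epochs)
    if epochs.n_epochs and not mask.any():
        warnings.warn("all epochs rejected by peak-to-peak screening", stacklevel=2)
    return EpochSet(
        epochs=epochs.epochs,
        epoch_onsets=epochs.epoch_onsets,
        sfreq=epochs.sfreq,
        ch_names=list(epochs.ch_names),
        words_per_epoch=epochs.words_per_epoch,
        retained_mask=mask,
    )
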
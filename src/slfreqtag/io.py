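"""Reading/writing recordings, event tables and run configurations.

Continuous EEG travels in one of two forms: EDF (read via mne) for interchange
with standard acquisition pipelines, or the package's internal container — a
`.npz` array archive (data, sampling rate, labels, reference, JSON-encoded
metadata) with a companion ``<stem>.events.tsv`` table. Event tables are
BIDS-style TSVs with an ``onset`` column in seconds.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import EEGRecording

__all__ = ["read_eeg", "write_eeg", "read_events", "write_events", "RunConfig"]


def _events_path(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".events.tsv")


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "onset" not in df.columns:
        raise ValueError(f"events file {path} lacks an 'onset' column")
    if not df["onset"].is_monotonic_increasing:
        warnings.warn(f"events in {path} were not onset-sorted; sorting", stacklevel=2)
        df = df.sort_values("onset", kind="stable", ignore_index=True)
    return df


def write_eeg(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording to the internal npz container plus events TSV."""
    path = Path(path).with_suffix(".npz")
    np.savez_compressed(
        path,
        data=rec.data.astype(np.float32),
        sfreq=rec.sfreq,
        ch_names=np.array(rec.ch_names),
        reference=rec.reference,
        meta=json.dumps(rec.meta, default=str),
    )
    if rec.events is not None:
        write_events(rec.events, _events_path(path))
    return path


def read_eeg(path: str | Path) -> EEGRecording:
    """Read a recording from EDF (.edf) or the internal npz container."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # mne stores volts; package convention is µV
        rec = EEGRecording(
            data=data, sfreq=float(raw.info["sfreq"]),
            ch_names=list(raw.ch_names), reference="raw",
        )
    elif path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            rec = EEGRecording(
                data=np.asarray(z["data"], dtype=float),
                sfreq=float(z["sfreq"]),
                ch_names=[str(c) for c in z["ch_names"]],
                reference=str(z["reference"]),
                meta=json.loads(str(z["meta"])),
            )
    else:
        raise ValueError(f"unsupported EEG format: {path.suffix!r}")
    ev = _events_path(path)
    if ev.exists():
        rec.events = read_events(ev)
    return rec


@dataclass
class RunConfig:
    """Everything needed to reproduce one end-to-end synthetic analysis run."""

    lexicon_version: str = "A"
    reps_per_word: int = 100
    syllable_duration: float = 0.3
    n_participants: int = 6
    learning_strength: float = 0.5
    mode: str = "adult"
    # synthetic EEG
    sampling_rate: float = 512.0
    n_channels: int = 32
    roi_channels: list[str] | None = None
    kappa_word_start: float = 0.5
    kappa_word_end: float = 4.0
    kappa_syllable: float = 8.0
    word_amp: float = 1.0
    syllable_amp: float = 2.0
    noise_sigma: float = 5.0
    # preprocessing
    apply_filter: bool = True
    band: tuple[float, float] = (0.1, 20.0)
    notch: float | None = 60.0
    ptp_threshold: float = 150.0
    words_per_epoch: int = 12
    # entrainment / time course
    word_freq: float = 1.1
    syllable_freq: float = 3.3
    freq_range: tuple[float, float] = (0.6, 5.0)
    jitter_range_ms: tuple[int, int] = (-900, 900)
    bundle_size: int = 5
    missing_threshold: float = 0.5
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        cfg = cls(**raw)
        # JSON has no tuples; restore declared tuple fields
        for name in ("band", "jitter_range_ms", "freq_range"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg
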
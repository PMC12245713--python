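"""EDF and hypnogram text I/O.

Recordings are single-channel EEG traces stored in European Data Format
(EDF); stage labels live in plain CSV files with one row per fixed-length
epoch.  Three vigilance states are used throughout the package:
``P`` (REM/paradoxical sleep), ``S`` (NREM/slow-wave sleep) and ``W``
(wake), with the sentinel ``X`` marking artifact/unscored epochs in
reference label tracks.  Class index order is alphabetical: P=0, S=1, W=2.

EDF reading is delegated to MNE; writing uses a minimal 16-bit EDF encoder
(one data record per second) sufficient for single-channel traces.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: canonical vigilance states, in class-index order
STAGES: tuple[str, ...] = ("P", "S", "W")
#: artifact / unscored sentinel
ARTIFACT: str = "X"
STAGE_TO_INDEX: dict[str, int] = {s: i for i, s in enumerate(STAGES)}
VALID_SYMBOLS = frozenset(STAGES) | {ARTIFACT}


class ChannelNotFoundError(KeyError):
    """Requested EDF channel is absent; carries the available channel names."""

    def __init__(self, requested: str, available: Sequence[str]):
        super().__init__(
            f"channel {requested!r} not found; available channels: {list(available)}"
        )
        self.requested = requested
        self.available = list(available)


@dataclass
class Recording:
    """One subject's single-channel EEG trace in physical units (microvolts)."""

    subject_id: str
    samples: np.ndarray
    sampling_rate: float
    session_id: str = ""
    channel_name: str = "EEG"
    start_time: Optional[str] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.sampling_rate > 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain NaN/Inf")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class Hypnogram:
    """Per-epoch vigilance-state sequence at a fixed epoch length."""

    subject_id: str
    epoch_length_s: float
    stages: np.ndarray  # array of single-character strings over {P,S,W,X}

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype="U1")
        if not self.epoch_length_s > 0:
            raise ValueError("epoch_length_s must be positive")
        bad = set(np.unique(self.stages)) - VALID_SYMBOLS
        if bad:
            raise ValueError(f"unknown stage symbols {sorted(bad)}; allowed {sorted(VALID_SYMBOLS)}")

    def __len__(self) -> int:
        return int(self.stages.size)

    @property
    def duration_s(self) -> float:
        return len(self) * self.epoch_length_s

    @property
    def has_artifacts(self) -> bool:
        return bool(np.any(self.stages == ARTIFACT))

    def indices(self) -> np.ndarray:
        """Integer class indices (P=0, S=1, W=2); artifact epochs map to -1."""
        out = np.full(len(self), -1, dtype=np.int64)
        for sym, idx in STAGE_TO_INDEX.items():
            out[self.stages == sym] = idx
        return out


def read_edf(path, channel: str | int = 0) -> Recording:
    """Read one channel of an EDF/EDF+ file into a :class:`Recording`.

    Parameters
    ----------
    path
        EDF file path.
    channel
        Channel name or zero-based index.  Other channels (EMG etc.) are
        ignored: the classifier is single-channel by design.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EDF file not found: {path}")
    raw = mne.io.read_raw_edf(str(path), preload=False, verbose="error")
    names = list(raw.ch_names)
    if isinstance(channel, int):
        if not 0 <= channel < len(names):
            raise ChannelNotFoundError(str(channel), names)
        ch_name = names[channel]
    else:
        if channel not in names:
            raise ChannelNotFoundError(channel, names)
        ch_name = channel
    raw = raw.pick([ch_name]).load_data(verbose="error")
    # MNE stores signals in SI units (volts for EEG); convert back to µV.
    data = raw.get_data(units={"eeg": "uV"} if raw.get_channel_types()[0] == "eeg" else None)
    samples = np.asarray(data[0], dtype=np.float64)
    if raw.get_channel_types()[0] != "eeg":
        samples = samples * 1e6  # MNE read misc channels scaled to SI
    if samples.size == 0:
        raise ValueError(f"zero-length signal in {path}")
    if not np.all(np.isfinite(samples)):
        raise ValueError(f"non-finite samples in {path}")
    return Recording(
        subject_id=path.stem,
        samples=samples,
        sampling_rate=float(raw.info["sfreq"]),
        channel_name=ch_name,
    )


def _ascii_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path) -> Path:
    """Write a single-channel 16-bit EDF file.

    The signal is quantized to the int16 range over a symmetric physical
    range covering the data, one data record per second.  The sample count
    must be a whole number of seconds (trailing remainder is truncated with
    a warning, mirroring the epoching rule).
    """
    path = Path(path)
    fs = recording.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    x = recording.samples
    n_records = x.size // fs
    if n_records == 0:
        raise ValueError("recording shorter than one second")
    if x.size % fs:
        logger.warning(
            "truncating %d trailing samples (partial final second)", x.size % fs
        )
        x = x[: n_records * fs]

    phys_max = max(1.0, float(math.ceil(np.abs(x).max()))) if x.size else 1.0
    dig_max = 32767
    scale = dig_max / phys_max
    digital = np.clip(np.rint(x * scale), -dig_max, dig_max).astype("<i2")

    header = b"".join(
        [
            _ascii_field("0", 8),                       # version
            _ascii_field(recording.subject_id[:80], 80),  # patient id
            _ascii_field(recording.session_id[:80] or "recording", 80),
            _ascii_field("01.01.00", 8),                # start date
            _ascii_field("00.00.00", 8),                # start time
            _ascii_field(256 + 256, 8),                 # header bytes (1 signal)
            _ascii_field("", 44),                       # reserved
            _ascii_field(n_records, 8),
            _ascii_field(1, 8),                         # record duration (s)
            _ascii_field(1, 4),                         # number of signals
            # per-signal header fields
            _ascii_field(recording.channel_name[:16], 16),
            _ascii_field("", 80),                       # transducer
            _ascii_field("uV", 8),                      # physical dimension
            _ascii_field(int(-phys_max), 8),
            _ascii_field(int(phys_max), 8),
            _ascii_field(-dig_max, 8),
            _ascii_field(dig_max, 8),
            _ascii_field("", 80),                       # prefiltering
            _ascii_field(fs, 8),                        # samples per record
            _ascii_field("", 32),                       # reserved
        ]
    )
    with open(path, "wb") as f:
        f.write(header)
        f.write(digital.tobytes())
    return path


def read_labels(path, epoch_length_s: float) -> Hypnogram:
    """Read an epoch-label CSV into a :class:`Hypnogram`.

    Accepted dialects:

    * headerless two-column ``epoch_index,stage`` (canonical);
    * headered CSV containing at least ``stage`` plus either ``epoch_index``
      or ``onset_s`` (onsets are divided by ``epoch_length_s``) — this is
      what :func:`write_hypnogram` emits.

    Rows must form a contiguous, ascending, 0-based epoch index sequence.
    """
    path = Path(path)
    with open(path, newline="") as f:
        rows = [r for r in csv.reader(f) if r and any(c.strip() for c in r)]
    if not rows:
        raise ValueError(f"empty label file: {path}")

    first = rows[0]
    idx_col, stage_col = 0, 1
    start_row = 0
    if not first[0].strip().lstrip("-").replace(".", "", 1).isdigit():
        header = [c.strip() for c in first]
        if "stage" not in header:
            raise ValueError(f"label file header lacks a 'stage' column: {header}")
        stage_col = header.index("stage")
        if "epoch_index" in header:
            idx_col = header.index("epoch_index")
            onset_based = False
        elif "onset_s" in header:
            idx_col = header.index("onset_s")
            onset_based = True
        else:
            raise ValueError("label file needs an 'epoch_index' or 'onset_s' column")
        start_row = 1
    else:
        onset_based = False

    stages: list[str] = []
    for row_no, row in enumerate(rows[start_row:], start=start_row + 1):
        raw_idx = float(row[idx_col])
        idx = raw_idx / epoch_length_s if onset_based else raw_idx
        if abs(idx - round(idx)) > 1e-9:
            raise ValueError(f"row {row_no}: onset {raw_idx} is not a multiple of epoch length")
        idx = int(round(idx))
        expected = len(stages)
        if idx < expected:
            raise ValueError(f"row {row_no}: duplicate epoch index {idx}")
        if idx > expected:
            raise ValueError(f"gap in epoch index at {expected} (row {row_no} has {idx})")
        sym = row[stage_col].strip()
        if sym not in VALID_SYMBOLS:
            raise ValueError(
                f"row {row_no}: unknown stage symbol {sym!r}; allowed {sorted(VALID_SYMBOLS)}"
            )
        stages.append(sym)
    return Hypnogram(subject_id=path.stem, epoch_length_s=epoch_length_s,
                     stages=np.array(stages, dtype="U1"))


def write_hypnogram(h: Hypnogram, path, probabilities=None) -> Path:
    """Write a hypnogram (and optional per-epoch class probabilities) as CSV.

    Columns: ``epoch_index, onset_s, stage`` plus ``p_P, p_S, p_W`` when
    probabilities are supplied.  Each probability triple must sum to one
    and its argmax must agree with the written stage.
    """
    path = Path(path)
    if probabilities is not None:
        probabilities = np.asarray(probabilities, dtype=np.float64)
        if probabilities.shape != (len(h), 3):
            raise ValueError(
                f"probabilities shape {probabilities.shape} does not match "
                f"{len(h)} epochs x 3 classes"
            )
        if np.any(np.abs(probabilities.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("probability triples must sum to 1 within 1e-6")
        argmax = probabilities.argmax(axis=1)
        for i, sym in enumerate(h.stages):
            if sym in STAGE_TO_INDEX and argmax[i] != STAGE_TO_INDEX[sym]:
                raise ValueError(
                    f"epoch {i}: stage {sym} is not the argmax of its probability triple"
                )
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        head = ["epoch_index", "onset_s", "stage"]
        if probabilities is not None:
            head += [f"p_{s}" for s in STAGES]
        w.writerow(head)
        for i, sym in enumerate(h.stages):
            row = [i, format(i * h.epoch_length_s, "g"), sym]
            if probabilities is not None:
                row += [format(p, ".6f") for p in probabilities[i]]
            w.writerow(row)
    return path
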
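"""Resampling, epoching, and context-window construction.

The classifier operates on 10 s epochs at 500 Hz (5,000 samples per epoch)
and predicts the stage of the center epoch of a 9-epoch moving window
(stride 1).  Recordings at other rates are resampled in the frequency
domain first.  Each recording is zero-padded with (k-1)/2 all-zero epochs
on both ends so that every real epoch is a window center exactly once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from scipy.signal import resample as _fourier_resample

from .io_edf import Hypnogram, Recording

logger = logging.getLogger(__name__)

NATIVE_RATE = 500.0
NATIVE_EPOCH_S = 10.0


def resample_recording(r: Recording, target_rate: float = NATIVE_RATE) -> Recording:
    """Resample a recording to ``target_rate`` using the Fourier method.

    The output has ``round(n * target / original)`` samples.  When the rates
    already match the input samples are returned unchanged (bitwise).
    """
    if not target_rate > 0:
        raise ValueError("target_rate must be positive")
    if r.n_samples == 0:
        raise ValueError("cannot resample an empty signal")
    if r.sampling_rate == target_rate:
        return r
    n_out = int(round(r.n_samples * target_rate / r.sampling_rate))
    resampled = _fourier_resample(r.samples, n_out)
    return Recording(
        subject_id=r.subject_id,
        session_id=r.session_id,
        samples=np.asarray(resampled, dtype=np.float64),
        sampling_rate=float(target_rate),
        channel_name=r.channel_name,
        start_time=r.start_time,
    )


@dataclass
class EpochedRecording:
    """A recording partitioned into fixed-length scoring epochs."""

    subject_id: str
    epochs: np.ndarray  # (n_epochs, samples_per_epoch)
    epoch_length_s: float = NATIVE_EPOCH_S
    sampling_rate: float = NATIVE_RATE

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs)
        if self.epochs.ndim != 2:
            raise ValueError("epochs must be a 2-D array (n_epochs, samples)")
        expected = self.epoch_length_s * self.sampling_rate
        if abs(self.epochs.shape[1] - expected) > 1e-9:
            raise ValueError(
                f"each epoch must hold epoch_length_s*sampling_rate="
                f"{expected:g} samples, got {self.epochs.shape[1]}"
            )

    @property
    def n_epochs(self) -> int:
        return int(self.epochs.shape[0])

    @property
    def samples_per_epoch(self) -> int:
        return int(self.epochs.shape[1])


def epoch_signal(r: Recording, epoch_length_s: float = NATIVE_EPOCH_S) -> EpochedRecording:
    """Partition a recording into fixed-length epochs.

    A trailing partial epoch (recording length not a multiple of the epoch)
    is dropped with a logged warning: partial epochs are never scored.
    """
    spe_f = epoch_length_s * r.sampling_rate
    if abs(spe_f - round(spe_f)) > 1e-9:
        raise ValueError(
            f"epoch_length_s*sampling_rate must be integral, got {spe_f}"
        )
    spe = int(round(spe_f))
    n_epochs = r.n_samples // spe
    if n_epochs == 0:
        raise ValueError(
            f"recording of {r.duration_s:.1f} s is shorter than one "
            f"{epoch_length_s:g} s epoch"
        )
    remainder = r.n_samples - n_epochs * spe
    if remainder:
        logger.warning(
            "%s: discarding trailing partial epoch (%.3g s)",
            r.subject_id, remainder / r.sampling_rate,
        )
    segments = r.samples[: n_epochs * spe].reshape(n_epochs, spe)
    return EpochedRecording(
        subject_id=r.subject_id,
        epochs=segments,
        epoch_length_s=epoch_length_s,
        sampling_rate=r.sampling_rate,
    )


class Window(NamedTuple):
    context: np.ndarray   # (k, samples_per_epoch), zero-padded at the edges
    center_index: int
    label: Optional[str]


@dataclass
class WindowedDataset:
    """Stride-1 moving windows of ``k`` epochs over one recording.

    Window ``i`` holds epochs ``i-(k-1)/2 .. i+(k-1)/2`` of the zero-padded
    epoch sequence, with the real epoch ``i`` at the center position; its
    label (if labels were supplied) is the center epoch's stage.  There are
    exactly ``n_epochs`` windows.  Contexts are assembled on demand so the
    epoched signal is never duplicated nine-fold in memory.
    """

    epochs: np.ndarray           # (n_epochs, samples_per_epoch)
    k: int = 9
    labels: Optional[np.ndarray] = None  # (n_epochs,) int class indices, or None
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.k % 2 == 0 or self.k < 1:
            raise ValueError(f"window length k must be odd and positive, got {self.k}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape[0] != self.epochs.shape[0]:
                raise ValueError(
                    f"label count {self.labels.shape[0]} does not match "
                    f"epoch count {self.epochs.shape[0]}"
                )

    @property
    def pad(self) -> int:
        return (self.k - 1) // 2

    @property
    def n_windows(self) -> int:
        return int(self.epochs.shape[0])

    def __len__(self) -> int:
        return self.n_windows

    def __getitem__(self, i: int) -> Window:
        if not 0 <= i < self.n_windows:
            raise IndexError(i)
        ctx = self.batch(np.array([i]))[0]
        label = None
        if self.labels is not None and self.labels[i] >= 0:
            from .io_edf import STAGES
            label = STAGES[self.labels[i]]
        return Window(context=ctx, center_index=i, label=label)

    def batch(self, indices: np.ndarray) -> np.ndarray:
        """Assemble contexts for the given window indices: (B, k, spe) float32."""
        indices = np.asarray(indices, dtype=np.int64)
        n, spe = self.epochs.shape
        out = np.zeros((indices.size, self.k, spe), dtype=np.float32)
        for j in range(self.k):
            src = indices + j - self.pad
            ok = (src >= 0) & (src < n)
            out[ok, j, :] = self.epochs[src[ok]]
        return out


def make_windows(
    e: EpochedRecording,
    labels: Optional[Hypnogram] = None,
    k: int = 9,
    standardize: bool = False,
) -> WindowedDataset:
    """Build the stride-1, zero-padded k-epoch window dataset for a recording.

    ``standardize`` optionally z-scores the whole recording (single mean/std
    over all epochs) before windowing; default off — the classifier is fed
    raw physical units.
    """
    if k % 2 == 0 or k < 1:
        raise ValueError(f"window length k must be odd and positive, got {k}")
    label_idx = None
    if labels is not None:
        if len(labels) != e.n_epochs:
            raise ValueError(
                f"hypnogram has {len(labels)} epochs but recording has {e.n_epochs}"
            )
        if abs(labels.epoch_length_s - e.epoch_length_s) > 1e-9:
            raise ValueError(
                f"epoch length mismatch: labels {labels.epoch_length_s} s "
                f"vs recording {e.epoch_length_s} s"
            )
        label_idx = labels.indices()
    epochs = e.epochs
    if standardize:
        mu = float(epochs.mean())
        sd = float(epochs.std()) or 1.0
        epochs = (epochs - mu) / sd
    return WindowedDataset(epochs=epochs, k=k, labels=label_idx,
                           subject_id=e.subject_id)
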
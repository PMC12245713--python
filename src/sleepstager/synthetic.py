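"""Synthetic single-channel rodent EEG cohorts with known stage structure.

Vigilance-state sequences follow a semi-Markov chain: each stage dwells
for a geometrically distributed number of 10 s epochs (explicit mean dwell
per stage) and then transitions to a *different* stage drawn from a
row-stochastic transition matrix with zero diagonal.  The EEG is
band-limited noise whose band and amplitude depend on the current stage —
slow-wave sleep is dominated by high-amplitude delta (0.5–4 Hz),
paradoxical sleep by theta (5–8 Hz), wake by low-amplitude fast activity
(8–30 Hz) — superimposed on a 1/f background.  Stage changes are smoothed
with a 0.5 s crossfade so the trace is continuous at epoch joins.

This emulates the statistical structure a sleep stager exploits (stage-
dependent spectral content and bout dynamics), not real electrophysiology:
there are no spindles, K-complexes, phasic theta events, or artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, sosfiltfilt

from .io_edf import Hypnogram, Recording, STAGES, write_edf, write_hypnogram

#: default mean dwell times, in epochs (W 2 min, S 3 min, P 1 min at 10 s epochs)
DEFAULT_DWELL = {"W": 12.0, "S": 18.0, "P": 6.0}
#: default per-stage spectral recipes: (band_low_hz, band_high_hz, relative_amplitude)
DEFAULT_BANDS = {"W": (8.0, 30.0, 1.0), "S": (0.5, 4.0, 3.0), "P": (5.0, 8.0, 1.5)}
#: default stage-to-stage transition probabilities (self-transitions excluded;
#: dwell is handled by the geometric sojourn, not the matrix), class order P,S,W
DEFAULT_TRANSITION = np.array(
    [
        [0.00, 0.20, 0.80],  # from P: mostly awakenings, some back to S
        [0.35, 0.00, 0.65],  # from S
        [0.05, 0.95, 0.00],  # from W: sleep onset is almost always NREM
    ]
)


@dataclass
class SynthParams:
    """Generator settings; defaults give well-separated ("easy") stage spectra.

    ``hardness`` in [0, 1] scales the amplitude contrast between stages:
    1.0 keeps the full recipe, 0 collapses every stage to equal amplitude.
    """

    transition: np.ndarray = field(default_factory=lambda: DEFAULT_TRANSITION.copy())
    mean_dwell_epochs: dict = field(default_factory=lambda: dict(DEFAULT_DWELL))
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    background_amplitude: float = 1.0
    base_amplitude_uv: float = 20.0
    sampling_rate: float = 500.0
    epoch_length_s: float = 10.0
    hardness: float = 1.0

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=np.float64)
        if self.transition.shape != (3, 3):
            raise ValueError("transition matrix must be 3x3 over (P, S, W)")
        if np.any(self.transition < 0):
            raise ValueError("transition probabilities must be nonnegative")
        if np.any(np.abs(self.transition.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(np.diag(self.transition) != 0):
            raise ValueError(
                "transition diagonal must be zero: dwell is modeled explicitly"
            )
        nyq = self.sampling_rate / 2
        for stage, (lo, hi, amp) in self.bands.items():
            if not (0 < lo < hi < nyq):
                raise ValueError(
                    f"stage {stage}: need 0 < band_low < band_high < {nyq} Hz, "
                    f"got ({lo}, {hi})"
                )
            if amp < 0:
                raise ValueError(f"stage {stage}: amplitude must be nonnegative")
        for stage in STAGES:
            if self.mean_dwell_epochs.get(stage, 0) < 1:
                raise ValueError(f"mean dwell for stage {stage} must be >= 1 epoch")

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.epoch_length_s * self.sampling_rate))

    def effective_amplitude(self, stage: str) -> float:
        lo, hi, amp = self.bands[stage]
        return 1.0 + (amp - 1.0) * self.hardness


def sample_stage_sequence(params: SynthParams, n_epochs: int, seed: int,
                          initial_stage: str = "W", subject_id: str = "synthetic") -> Hypnogram:
    """Draw a semi-Markov vigilance-state sequence of ``n_epochs`` epochs."""
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    rng = np.random.default_rng(seed)
    stages: list[str] = []
    current = initial_stage
    while len(stages) < n_epochs:
        mean = params.mean_dwell_epochs[current]
        dwell = int(rng.geometric(1.0 / mean))
        stages.extend([current] * min(dwell, n_epochs - len(stages)))
        row = params.transition[STAGES.index(current)]
        current = STAGES[int(rng.choice(3, p=row))]
    return Hypnogram(subject_id=subject_id, epoch_length_s=params.epoch_length_s,
                     stages=np.array(stages, dtype="U1"))


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f-amplitude background noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz] / freqs[nz][0])
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd else x


def synthesize_eeg(h: Hypnogram, params: SynthParams, seed: int) -> Recording:
    """Render a hypnogram into a continuous single-channel EEG trace (µV)."""
    spe = params.samples_per_epoch
    n = len(h) * spe
    fs = params.sampling_rate
    rng = np.random.default_rng(seed)

    signal = params.background_amplitude * _pink_noise(rng, n)

    # per-stage band-limited noise streams, unit variance before scaling
    streams = {}
    for stage in STAGES:
        lo, hi, _ = params.bands[stage]
        sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        x = sosfiltfilt(sos, rng.standard_normal(n))
        sd = x.std()
        streams[stage] = x / sd if sd else x

    # smooth per-stage indicator masks: two box filters of 0.25 s give a
    # continuous 0.5 s crossfade at stage changes while masks still sum to 1
    ramp = max(2, int(round(0.25 * fs)))
    for stage in STAGES:
        mask = np.repeat((h.stages == stage).astype(np.float64), spe)
        mask = uniform_filter1d(uniform_filter1d(mask, ramp), ramp)
        signal += mask * params.effective_amplitude(stage) * streams[stage]

    signal *= params.base_amplitude_uv
    return Recording(subject_id=h.subject_id, samples=signal, sampling_rate=fs)


def generate_subject(params: SynthParams, n_epochs: int, seed: int,
                     subject_id: str = "synthetic") -> tuple[Recording, Hypnogram]:
    """Sample a stage sequence and render its EEG with derived sub-seeds."""
    ss = np.random.SeedSequence(seed)
    s_seq, s_eeg = (int(s) & 0x7FFFFFFF for s in ss.generate_state(2))
    hyp = sample_stage_sequence(params, n_epochs, s_seq, subject_id=subject_id)
    rec = synthesize_eeg(hyp, params, s_eeg)
    return rec, hyp


def make_cohort(n_subjects: int, hours_per_subject: float, params: SynthParams,
                seed: int, out_dir, materialize: bool = True) -> pd.DataFrame:
    """Generate a cohort of EDF + label-CSV pairs plus a manifest.

    With ``materialize=False`` only the manifest (subject ids, epoch counts,
    sub-seeds) is written — useful for planning full-scale cohorts without
    rendering hours of signal.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_epochs = int(round(hours_per_subject * 3600.0 / params.epoch_length_s))
    if n_epochs < 1:
        raise ValueError("cohort recordings must span at least one epoch")
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    rows = []
    for i, child in enumerate(children):
        sid = f"synth{i + 1:02d}"
        sub_seed = int(child.generate_state(1)[0]) & 0x7FFFFFFF
        edf_path, label_path = "", ""
        if materialize:
            rec, hyp = generate_subject(params, n_epochs, sub_seed, subject_id=sid)
            edf_path = str(out_dir / f"{sid}.edf")
            label_path = str(out_dir / f"{sid}_labels.csv")
            write_edf(rec, edf_path)
            write_hypnogram(hyp, label_path)
        rows.append({"subject": sid, "edf": edf_path, "labels": label_path,
                     "n_epochs": n_epochs, "seed": sub_seed})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
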
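"""Sleep-architecture analytics on hypnograms.

A *bout* is a maximal run of consecutive epochs in the same vigilance
state.  The summaries computed here — per-stage total bout duration, bout
count, mean bout duration, and stage proportion of recording time,
optionally broken into fixed time bins (1 h Zeitgeber-time bins by
default) — are the standard endpoints of rodent sleep studies.

Binning conventions: a bout straddling a bin boundary has its *duration*
apportioned to bins by overlap (so per-bin durations are exact and sum to
the bin length across stages) but is *counted* once, in the bin containing
its onset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_edf import ARTIFACT, Hypnogram, STAGES

PARAMETERS = ("total_duration_s", "bout_count", "mean_bout_duration_s")


@dataclass
class BoutRecord:
    """One maximal same-stage run."""

    stage: str
    start_epoch: int
    length_epochs: int
    epoch_length_s: float

    @property
    def duration_s(self) -> float:
        return self.length_epochs * self.epoch_length_s

    @property
    def onset_s(self) -> float:
        return self.start_epoch * self.epoch_length_s


def detect_bouts(h: Hypnogram, artifact_policy: str = "error") -> list[BoutRecord]:
    """Run-length segmentation of a hypnogram into maximal same-stage bouts.

    ``artifact_policy``: ``"error"`` rejects hypnograms containing ``X``;
    ``"break"`` treats ``X`` epochs as run-breaking gaps that belong to no
    bout (bout durations then no longer tile the full recording).
    """
    if len(h) == 0:
        raise ValueError("empty hypnogram")
    if h.has_artifacts:
        if artifact_policy == "error":
            raise ValueError(
                "hypnogram contains artifact epochs (X); "
                "use artifact_policy='break' to segment around them"
            )
        if artifact_policy != "break":
            raise ValueError(f"unknown artifact_policy {artifact_policy!r}")
    stages = h.stages
    # run boundaries wherever the symbol changes
    change = np.flatnonzero(stages[1:] != stages[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(stages)]])
    bouts = []
    for s, e in zip(starts, ends):
        if stages[s] == ARTIFACT:
            continue
        bouts.append(BoutRecord(stage=str(stages[s]), start_epoch=int(s),
                                length_epochs=int(e - s),
                                epoch_length_s=h.epoch_length_s))
    return bouts


@dataclass
class ArchitectureSummary:
    """Per-stage architecture statistics, optionally per time bin."""

    subject_id: str
    totals: pd.DataFrame           # index: stage; columns: PARAMETERS + proportion
    bins: Optional[pd.DataFrame]   # long: bin, stage, parameter columns; or None
    bin_length_s: Optional[float] = None


def summarize_architecture(
    bouts: Sequence[BoutRecord],
    hypnogram: Hypnogram,
    bin_length_s: Optional[float] = None,
) -> ArchitectureSummary:
    """Aggregate bouts into per-stage totals and optional fixed-bin breakdowns.

    Per-bin mean bout duration is the bin's apportioned duration divided by
    its onset-based bout count (0 when the bin holds no bout onsets).
    """
    total_s = hypnogram.duration_s
    rows = {}
    for stage in STAGES:
        sb = [b for b in bouts if b.stage == stage]
        dur = float(sum(b.duration_s for b in sb))
        count = len(sb)
        rows[stage] = {
            "total_duration_s": dur,
            "bout_count": float(count),
            "mean_bout_duration_s": dur / count if count else 0.0,
            "proportion": dur / total_s,
        }
    totals = pd.DataFrame(rows).T.loc[list(STAGES)]

    bins_frame = None
    if bin_length_s is not None:
        ratio = bin_length_s / hypnogram.epoch_length_s
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"bin length {bin_length_s} s must be a multiple of the "
                f"epoch length {hypnogram.epoch_length_s} s"
            )
        n_bins = int(np.ceil(total_s / bin_length_s))
        dur = np.zeros((n_bins, 3))
        cnt = np.zeros((n_bins, 3))
        sidx = {s: i for i, s in enumerate(STAGES)}
        for b in bouts:
            j = sidx[b.stage]
            onset_bin = int(b.onset_s // bin_length_s)
            cnt[onset_bin, j] += 1
            t0, t1 = b.onset_s, b.onset_s + b.duration_s
            first, last = int(t0 // bin_length_s), int((t1 - 1e-9) // bin_length_s)
            for bi in range(first, last + 1):
                lo = max(t0, bi * bin_length_s)
                hi = min(t1, (bi + 1) * bin_length_s)
                dur[bi, j] += hi - lo
        rows = []
        for bi in range(n_bins):
            for j, stage in enumerate(STAGES):
                rows.append({
                    "bin": bi, "stage": stage,
                    "total_duration_s": dur[bi, j],
                    "bout_count": cnt[bi, j],
                    "mean_bout_duration_s": dur[bi, j] / cnt[bi, j] if cnt[bi, j] else 0.0,
                })
        bins_frame = pd.DataFrame(rows)

    return ArchitectureSummary(subject_id=hypnogram.subject_id, totals=totals,
                               bins=bins_frame, bin_length_s=bin_length_s)


def analyze_hypnogram(h: Hypnogram, bin_length_s: Optional[float] = None,
                      artifact_policy: str = "error") -> ArchitectureSummary:
    """Convenience: detect bouts then summarize in one call."""
    return summarize_architecture(detect_bouts(h, artifact_policy), h, bin_length_s)


def compare_scorers(
    a: Mapping[str, ArchitectureSummary],
    b: Mapping[str, ArchitectureSummary],
    scorer_names: tuple = ("model", "human"),
) -> pd.DataFrame:
    """Paired long-format table of binned architecture parameters per scorer.

    Both mappings must cover the same subjects with identical bin grids.
    Output columns: subject, bin, stage, parameter, value_<scorer_a>,
    value_<scorer_b>, difference (a − b) — the tidy table consumed by
    external statistics software (e.g. repeated-measures ANOVA).
    """
    if set(a) != set(b):
        raise ValueError(
            f"subject mismatch between scorers: {sorted(set(a) ^ set(b))}"
        )
    rows = []
    for subject in sorted(a):
        sa, sb = a[subject], b[subject]
        if (sa.bins is None) or (sb.bins is None):
            raise ValueError(f"subject {subject}: both scorers need binned summaries")
        if sorted(sa.bins["bin"].unique()) != sorted(sb.bins["bin"].unique()):
            raise ValueError(f"subject {subject}: bin grids differ between scorers")
        fa = sa.bins.set_index(["bin", "stage"])
        fb = sb.bins.set_index(["bin", "stage"])
        for (bi, stage), ra in fa.iterrows():
            rb = fb.loc[(bi, stage)]
            for param in PARAMETERS:
                rows.append({
                    "subject": subject, "bin": bi, "stage": stage, "parameter": param,
                    f"value_{scorer_names[0]}": float(ra[param]),
                    f"value_{scorer_names[1]}": float(rb[param]),
                    "difference": float(ra[param]) - float(rb[param]),
                })
    return pd.DataFrame(rows)


def plot_hypnogram(h: Hypnogram, path) -> None:
    """Step plot of stage vs time, the standard hypnogram visualization."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = {"W": 2, "S": 1, "P": 0, ARTIFACT: -1}
    y = np.array([order[s] for s in h.stages])
    t = np.arange(len(h)) * h.epoch_length_s / 3600.0
    fig, ax = plt.subplots(figsize=(10, 2.5))
    ax.step(t, y, where="post", linewidth=0.8)
    ax.set_yticks([0, 1, 2], ["P", "S", "W"])
    ax.set_xlabel("time (h)")
    ax.set_ylabel("stage")
    ax.set_title(h.subject_id)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
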
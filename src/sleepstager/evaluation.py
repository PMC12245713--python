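"""Confusion matrices, per-class precision/recall/F1, macro F1, confidence
summaries, and the cross-resolution (10 s predictions vs 4 s reference)
comparison.

Per-class metrics follow the usual one-vs-rest definitions

    precision_C = TP_C / (TP_C + FP_C)
    recall_C    = TP_C / (TP_C + FN_C)
    F1_C        = 2 * precision_C * recall_C / (precision_C + recall_C)

with macro F1 the unweighted mean of F1_C over the three classes.  A zero
denominator yields a metric of 0 with the class recorded in
``undefined_metrics`` so that macro F1 stays defined on degenerate folds.

Reference epochs labeled ``X`` (artifact/unscored) are masked out of all
tallies.  In cross-resolution mode each 4 s reference epoch that straddles
two 10 s predictions contributes fractional weight 0.5 against each, so the
total confusion mass always equals the number of scored reference epochs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io_edf import Hypnogram, STAGES


@dataclass
class ConfusionMatrix:
    """Class-agreement mass: rows = reference class, columns = predicted."""

    matrix: np.ndarray  # (3, 3) nonnegative reals; fractional in cross-resolution mode
    labels: tuple = STAGES

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (len(self.labels), len(self.labels)):
            raise ValueError("confusion matrix must be square over the class labels")
        if np.any(self.matrix < 0):
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total_mass(self) -> float:
        return float(self.matrix.sum())

    @property
    def support(self) -> np.ndarray:
        """Reference-class row sums."""
        return self.matrix.sum(axis=1)

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.matrix) / self.matrix.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix,
                            index=[f"ref_{s}" for s in self.labels],
                            columns=[f"pred_{s}" for s in self.labels])


@dataclass
class MetricsReport:
    """Per-class precision/recall/F1 with supports and the macro average."""

    precision: dict
    recall: dict
    f1: dict
    support: dict
    macro_f1: float
    undefined_metrics: tuple = ()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"class": c, "precision": self.precision[c], "recall": self.recall[c],
             "f1": self.f1[c], "support": self.support[c]}
            for c in STAGES
        ]
        return pd.DataFrame(rows)


def _check_comparable(pred: Hypnogram, ref: Hypnogram) -> None:
    if abs(pred.epoch_length_s - ref.epoch_length_s) > 1e-9:
        raise ValueError(
            f"epoch length mismatch: pred {pred.epoch_length_s} s vs ref "
            f"{ref.epoch_length_s} s (use cross_resolution_confusion)"
        )
    if len(pred) != len(ref):
        raise ValueError(f"length mismatch: pred {len(pred)} vs ref {len(ref)} epochs")


def confusion_matrix(pred: Hypnogram, ref: Hypnogram) -> ConfusionMatrix:
    """Tally predicted vs reference stages at equal epoch resolution.

    Reference ``X`` epochs are masked out (contribute no mass); predictions
    must be over {P,S,W} only.
    """
    _check_comparable(pred, ref)
    p = pred.indices()
    r = ref.indices()
    if np.any(p < 0):
        raise ValueError("predicted hypnogram contains artifact symbols")
    keep = r >= 0
    m = np.zeros((3, 3), dtype=np.float64)
    np.add.at(m, (r[keep], p[keep]), 1.0)
    return ConfusionMatrix(m)


def class_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Precision, recall and F1 per class plus macro F1 from a confusion matrix."""
    m = cm.matrix
    tp = np.diag(m)
    fp = m.sum(axis=0) - tp
    fn = m.sum(axis=1) - tp
    precision, recall, f1 = {}, {}, {}
    undefined = []
    for i, c in enumerate(cm.labels):
        if tp[i] + fp[i] > 0:
            prec = tp[i] / (tp[i] + fp[i])
        else:
            prec = 0.0
            undefined.append(f"precision_{c}")
        if tp[i] + fn[i] > 0:
            rec = tp[i] / (tp[i] + fn[i])
        else:
            rec = 0.0
            undefined.append(f"recall_{c}")
        if prec + rec > 0:
            f = 2 * prec * rec / (prec + rec)
        else:
            f = 0.0
            if f"precision_{c}" not in undefined or f"recall_{c}" not in undefined:
                undefined.append(f"f1_{c}")
        precision[c], recall[c], f1[c] = float(prec), float(rec), float(f)
    macro = float(np.mean([f1[c] for c in cm.labels]))
    return MetricsReport(
        precision=precision, recall=recall, f1=f1,
        support={c: float(cm.support[i]) for i, c in enumerate(cm.labels)},
        macro_f1=macro, undefined_metrics=tuple(undefined),
    )


def cross_resolution_confusion(pred_10s: Hypnogram, ref_4s: Hypnogram) -> ConfusionMatrix:
    """Score 10 s predictions against an unaligned 4 s reference track.

    Over each 20 s block (two 10 s predictions vs five 4 s reference
    epochs) the first two reference epochs score against the first
    prediction and the last two against the second, each with weight 1; the
    straddling reference epoch [8 s, 12 s) contributes weight 0.5 against
    *each* prediction — the mean-of-the-metric rule expressed as fractional
    confusion mass.  Total mass equals the number of scored 4 s epochs.
    """
    pl, rl = pred_10s.epoch_length_s, ref_4s.epoch_length_s
    if abs(pl - 10.0) > 1e-9 or abs(rl - 4.0) > 1e-9:
        raise ValueError(
            f"expected 10 s predictions and 4 s reference, got {pl} s and {rl} s"
        )
    if abs(len(pred_10s) * pl - len(ref_4s) * rl) > 1e-6:
        raise ValueError(
            f"span mismatch: predictions cover {len(pred_10s) * pl:g} s but "
            f"reference covers {len(ref_4s) * rl:g} s"
        )
    p = pred_10s.indices()
    r = ref_4s.indices()
    if np.any(p < 0):
        raise ValueError("predicted hypnogram contains artifact symbols")
    m = np.zeros((3, 3), dtype=np.float64)
    for j in range(len(r)):
        if r[j] < 0:  # masked reference artifact
            continue
        start, end = j * rl, (j + 1) * rl
        i1 = int(start // pl)
        i2 = int((end - 1e-9) // pl)
        if i1 == i2:
            m[r[j], p[i1]] += 1.0
        else:
            m[r[j], p[i1]] += 0.5
            m[r[j], p[i2]] += 0.5
    return ConfusionMatrix(m)


def confidence_summary(probabilities) -> dict:
    """Mean and minimum per-epoch confidence (max softmax probability).

    Accepts one ``(n, 3)`` probability array or a mapping of recording id
    to such arrays; returns overall mean/min plus a per-recording table.
    """
    if isinstance(probabilities, Mapping):
        per_rec = {k: np.asarray(v, dtype=np.float64) for k, v in probabilities.items()}
    else:
        per_rec = {"recording": np.asarray(probabilities, dtype=np.float64)}
    if not per_rec or any(v.size == 0 for v in per_rec.values()):
        raise ValueError("confidence_summary needs at least one prediction")
    rows = []
    all_conf = []
    for rec, probs in per_rec.items():
        conf = probs.max(axis=1)
        all_conf.append(conf)
        rows.append({"recording": rec, "mean_confidence": float(conf.mean()),
                     "min_confidence": float(conf.min()), "n_epochs": int(conf.size)})
    conf = np.concatenate(all_conf)
    return {
        "mean_confidence": float(conf.mean()),
        "min_confidence": float(conf.min()),
        "per_recording": pd.DataFrame(rows),
    }


# ------------------------------------------------------------- reporting


def fold_metrics_frame(reports: Mapping[str, MetricsReport]) -> pd.DataFrame:
    """Long-format per-fold metrics table (fold, class, precision, recall, f1, support)."""
    rows = []
    for fold, rep in reports.items():
        for c in STAGES:
            rows.append({"fold": fold, "class": c, "precision": rep.precision[c],
                         "recall": rep.recall[c], "f1": rep.f1[c],
                         "support": rep.support[c]})
    return pd.DataFrame(rows)


def write_metrics(reports: Mapping[str, MetricsReport], out_dir) -> dict:
    """Write per-fold metrics CSV and a JSON summary; returns the summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = fold_metrics_frame(reports)
    frame.to_csv(out_dir / "metrics_per_fold.csv", index=False)
    summary = {
        "mean_macro_f1": float(np.mean([r.macro_f1 for r in reports.values()])),
        "per_fold_macro_f1": {k: r.macro_f1 for k, r in reports.items()},
        "n_folds": len(reports),
    }
    with open(out_dir / "metrics_summary.json", "w") as f:
        json.dump(summary, f, indent=2)
    return summary


def write_confusion(cm: ConfusionMatrix, path) -> Path:
    path = Path(path)
    cm.to_frame().to_csv(path)
    return path
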
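"""Patient-level splitting, diagnostic metrics, ROC/AUC, and reports.

Splitting is done at the patient level: a seeded uniform shuffle of the
patient ids followed by contiguous assignment in the requested ratio
(largest-remainder rounding), so all spectra from one patient — and hence
from one sample — land in one partition.  The two-way mode (classical
models) merges train and validation of the three-way split, leaving the
test partition identical across modes for a given seed.

Metrics are computed at the spectrum level (each spectrum is one unit):

    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    accuracy    = (TP + TN) / (TP + TN + FP + FN)

with malignant as the positive class.  A patient-level majority-vote
summary is available separately (:func:`patient_level_votes`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .core import SpectrumDataset
from .errors import UndefinedMetricError, ValidationError

Partition = Literal["train", "validation", "test"]

DEFAULT_RATIO = (10, 3, 5)


@dataclass
class SplitAssignment:
    assignment: dict[str, Partition]
    mode: Literal["three_way", "two_way"]
    ratio: tuple[int, int, int]
    seed: int

    def patients(self, partition: Partition) -> list[str]:
        return [p for p, part in self.assignment.items() if part == partition]

    def partition_of(self, patient_id: str) -> Partition:
        return self.assignment[patient_id]

    def to_dict(self) -> dict:
        return {"mode": self.mode, "ratio": list(self.ratio), "seed": self.seed,
                "assignment": dict(self.assignment)}


def _largest_remainder(n: int, ratio: tuple[int, int, int]) -> list[int]:
    total = sum(ratio)
    quotas = [n * r / total for r in ratio]
    counts = [int(np.floor(q)) for q in quotas]
    remainders = sorted(range(3), key=lambda i: quotas[i] - counts[i], reverse=True)
    for i in remainders[: n - sum(counts)]:
        counts[i] += 1
    return counts


def split_patients(
    patient_ids: list[str],
    ratio: tuple[int, int, int] = DEFAULT_RATIO,
    mode: Literal["three_way", "two_way"] = "three_way",
    seed: int = 0,
) -> SplitAssignment:
    """Seeded shuffle + contiguous assignment of patients to partitions.

    With 18 patients and the default 10:3:5 ratio this gives exactly
    10/3/5; two-way mode folds validation into train (13/5) while keeping
    the same test patients as the three-way split at the same seed.
    """
    if any(r < 0 for r in ratio) or sum(ratio) == 0:
        raise ValidationError(f"invalid ratio {ratio}")
    if len(set(patient_ids)) != len(patient_ids):
        raise ValidationError("duplicate patient ids")
    order = list(np.random.default_rng(seed).permutation(list(patient_ids)))
    counts = _largest_remainder(len(order), tuple(ratio))
    for part, r, c in zip(("train", "validation", "test"), ratio, counts):
        if r > 0 and c == 0:
            raise ValidationError(f"partition {part!r} received 0 patients for ratio {ratio}")
    assignment: dict[str, Partition] = {}
    bounds = np.cumsum(counts)
    for i, pid in enumerate(order):
        part = "train" if i < bounds[0] else ("validation" if i < bounds[1] else "test")
        if mode == "two_way" and part == "validation":
            part = "train"
        assignment[str(pid)] = part
    return SplitAssignment(assignment, mode, tuple(ratio), seed)


def apply_split(dataset: SpectrumDataset, split: SplitAssignment) -> dict[str, SpectrumDataset]:
    """Partition a dataset by the split; empty partitions are omitted."""
    out = {}
    for part in ("train", "validation", "test"):
        pats = split.patients(part)
        if pats:
            out[part] = dataset.subset_patients(pats)
    return out


# ------------------------------------------------------------------ metrics


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValidationError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def confusion(labels: np.ndarray, scores: np.ndarray, threshold: float) -> ConfusionMatrix:
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    if len(labels) == 0:
        raise ValidationError("cannot build a confusion matrix from no spectra")
    if len(labels) != len(scores):
        raise ValidationError("labels and scores differ in length")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValidationError("labels must be binary (malignant=1, benign=0)")
    pred = scores >= threshold
    pos, neg = labels == 1, labels == 0
    return ConfusionMatrix(
        tp=int((pred & pos).sum()), fn=int((~pred & pos).sum()),
        tn=int((~pred & neg).sum()), fp=int((pred & neg).sum()),
    )


def metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) from confusion counts."""
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive (malignant) spectra")
    if cm.tn + cm.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative (benign) spectra")
    sensitivity = cm.tp / (cm.tp + cm.fn)
    specificity = cm.tn / (cm.tn + cm.fp)
    accuracy = (cm.tp + cm.tn) / cm.total
    return sensitivity, specificity, accuracy


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> RocCurve:
    """ROC by threshold sweep + trapezoidal AUC.

    Ties are handled so the AUC equals P(score_mal > score_ben) + 0.5 *
    P(tie) — the Mann–Whitney statistic.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if (labels == 1).sum() == 0 or (labels == 0).sum() == 0:
        raise ValidationError("ROC needs both classes present")
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return RocCurve(fpr, tpr, float(np.trapezoid(tpr, fpr)))


@dataclass
class EvaluationReport:
    model_kind: str
    threshold: float
    confusion: ConfusionMatrix
    sensitivity: float
    specificity: float
    accuracy: float
    roc: RocCurve
    n_spectra: int

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "threshold": self.threshold,
            "confusion": asdict(self.confusion),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auc": self.roc.auc,
            "roc_points": np.column_stack([self.roc.fpr, self.roc.tpr]).tolist(),
            "n_spectra": self.n_spectra,
        }


def evaluate_model(model, test: SpectrumDataset, threshold: float | None = None) -> EvaluationReport:
    """Score a test dataset and assemble the spectrum-level report."""
    if len(test) == 0:
        raise ValidationError("test dataset is empty")
    thr = model.threshold if threshold is None else threshold
    scores = model.score_dataset(test)
    labels = test.labels
    cm = confusion(labels, scores, thr)
    sens, spec, acc = metrics(cm)
    roc = roc_auc(labels, scores)
    return EvaluationReport(model.model_kind, thr, cm, sens, spec, acc, roc, len(test))


def patient_level_votes(model, test: SpectrumDataset, threshold: float | None = None):
    """Supplementary patient-level summary: majority vote over each
    sample's spectrum labels, reported per sample.  Clearly an aggregate —
    the primary report is spectrum-level."""
    thr = model.threshold if threshold is None else threshold
    pred = model.score_dataset(test) >= thr
    rows = []
    m = test.manifest
    for sample_id, grp in m.groupby("sample_id", sort=True):
        votes = pred[grp.index.to_numpy()]
        rows.append({
            "sample_id": str(sample_id),
            "patient_id": str(grp["patient_id"].iloc[0]),
            "class_label": str(grp["class_label"].iloc[0]),
            "malignant_vote_fraction": float(votes.mean()),
            "predicted_label": "malignant" if votes.mean() >= 0.5 else "benign",
        })
    return rows
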
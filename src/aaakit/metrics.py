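"""Evaluation metrics for boundary detection and surrogate-volume agreement.

Implements the interval Dice coefficient, the coefficient of determination
R^2 = 1 - RSS/TSS, MAE/MSE, binary cross-entropy, the unit-less surrogate
volume (sum of segmented pixels between the aneurysm boundaries), the
interpolated-baseline enlargement statistic, confusion-matrix
classification metrics, and cohort-level report assembly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .profiles import BoundaryAnnotation, Cohort, SliceProfile

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "interval_dice",
    "r_squared",
    "mae_mse",
    "bce",
    "volume_surrogate",
    "enlargement_surrogate",
    "classification_metrics",
    "evaluate_cohort",
    "save_report",
    "load_report",
]

PathLike = Union[str, Path]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion matrix with aneurysm as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")
        if self.tp + self.fp + self.fn + self.tn < 1:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class EvalReport:
    """Cohort-level boundary and volume agreement summary.

    Metric fields are ``None`` when not computable (e.g. no patient had a
    positive prediction).  ``n_predicted + n_missed`` equals the number of
    annotated patients evaluated.
    """

    mean_dice: Optional[float] = None
    r2_start: Optional[float] = None
    r2_end: Optional[float] = None
    r2_volume: Optional[float] = None
    mae_start: Optional[float] = None
    mae_end: Optional[float] = None
    mse_start: Optional[float] = None
    mse_end: Optional[float] = None
    n_predicted: int = 0
    n_missed: int = 0
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# elementary metrics
# ---------------------------------------------------------------------------

def interval_dice(pred: BoundaryAnnotation, truth: BoundaryAnnotation) -> float:
    """Dice = 2TP / (2TP + FP + FN) on the two slice-index intervals.

    Both absent counts as perfect agreement (1.0); exactly one absent is a
    complete miss (0.0).
    """
    if not pred.present and not truth.present:
        return 1.0
    if pred.present != truth.present:
        return 0.0
    a, b = pred.slice_set(), truth.slice_set()
    tp = len(a & b)
    return 2.0 * tp / (len(a) + len(b))


def r_squared(truth: Sequence[float], pred: Sequence[float]) -> float:
    """Coefficient of determination 1 - RSS/TSS of predictions vs truth."""
    yt = np.asarray(truth, dtype=float)
    yp = np.asarray(pred, dtype=float)
    if yt.shape != yp.shape:
        raise ValueError("truth and pred must have equal length")
    if yt.size < 2:
        raise ValueError("r_squared needs at least two observations")
    tss = float(np.sum((yt - yt.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("r_squared undefined for constant truth (TSS = 0)")
    rss = float(np.sum((yt - yp) ** 2))
    return 1.0 - rss / tss


def mae_mse(truth: Sequence[float], pred: Sequence[float]) -> tuple[float, float]:
    """Mean absolute and mean squared error between paired vectors."""
    yt = np.asarray(truth, dtype=float)
    yp = np.asarray(pred, dtype=float)
    if yt.shape != yp.shape:
        raise ValueError("truth and pred must have equal length")
    if yt.size == 0:
        raise ValueError("mae_mse needs at least one observation")
    diff = yt - yp
    return float(np.mean(np.abs(diff))), float(np.mean(diff**2))


def bce(
    truth: Sequence[float], probs: Sequence[float], clip_eps: float = 1e-7
) -> float:
    """Binary cross-entropy: negative mean log-likelihood of binary targets.

    Probabilities are clipped to ``[clip_eps, 1 - clip_eps]`` before taking
    logs so the value stays finite at saturated predictions.
    """
    yt = np.asarray(truth, dtype=float)
    yp = np.asarray(probs, dtype=float)
    if yt.shape != yp.shape:
        raise ValueError("truth and probs must have equal length")
    if np.any((yp < 0) | (yp > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    yp = np.clip(yp, clip_eps, 1.0 - clip_eps)
    return float(-np.mean(yt * np.log(yp) + (1.0 - yt) * np.log(1.0 - yp)))


def volume_surrogate(profile: SliceProfile, ann: BoundaryAnnotation) -> int:
    """Unit-less surrogate volume: sum of pixel counts over [start, end]."""
    if not ann.present:
        raise ValueError("volume_surrogate requires a present annotation")
    if ann.end >= profile.slice_count:
        raise ValueError("annotation extends beyond profile")
    return int(sum(profile.counts[ann.start : ann.end + 1]))


def enlargement_surrogate(profile: SliceProfile, ann: BoundaryAnnotation) -> float:
    """Excess area above the linearly interpolated normal-caliber baseline.

    The normal baseline inside the aneurysm is estimated by linear
    interpolation between the counts at the start and end boundary slices;
    the statistic sums the positive excess of each slice over that
    baseline (dips below baseline contribute zero).
    """
    if not ann.present:
        raise ValueError("enlargement_surrogate requires a present annotation")
    if ann.end >= profile.slice_count:
        raise ValueError("annotation extends beyond profile")
    if ann.start == ann.end:
        return 0.0
    idx = np.arange(ann.start, ann.end + 1)
    c0, c1 = profile.counts[ann.start], profile.counts[ann.end]
    baseline = c0 + (c1 - c0) * (idx - ann.start) / (ann.end - ann.start)
    counts = np.asarray(profile.counts[ann.start : ann.end + 1], dtype=float)
    return float(np.sum(np.maximum(0.0, counts - baseline)))


def classification_metrics(cm: ConfusionMatrix) -> dict[str, Optional[float]]:
    """Accuracy, precision, recall, specificity, F1 as one-decimal percentages.

    A metric whose denominator is zero is reported as ``None``.
    """

    def pct(num: int, den: int) -> Optional[float]:
        if den == 0:
            return None
        return round(100.0 * num / den, 1)

    return {
        "accuracy": pct(cm.tp + cm.tn, cm.total),
        "precision": pct(cm.tp, cm.tp + cm.fp),
        "recall": pct(cm.tp, cm.tp + cm.fn),
        "specificity": pct(cm.tn, cm.tn + cm.fp),
        "f1": pct(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn),
    }


# ---------------------------------------------------------------------------
# cohort-level evaluation
# ---------------------------------------------------------------------------

def _safe_r2(truth: list[float], pred: list[float]) -> Optional[float]:
    try:
        return r_squared(truth, pred)
    except ValueError:
        return None


def evaluate_cohort(
    cohort: Cohort, predictions: Mapping[str, BoundaryAnnotation]
) -> EvalReport:
    """Score predicted boundaries against a cohort's annotations.

    Every annotated patient contributes to the mean Dice (a missing or
    absent prediction for an aneurysmal patient scores 0).  Boundary
    R^2/MAE/MSE and volume R^2 are computed over the patients where both
    prediction and truth mark an aneurysm; they are ``None`` when fewer
    than the required number of such pairs exist.
    """
    unknown = set(predictions) - set(cohort.profiles)
    if unknown:
        raise ValueError(f"predictions for unknown patients: {sorted(unknown)}")

    ids = cohort.annotated_ids()
    if not ids:
        return EvalReport(n_predicted=0, n_missed=0)

    dices: list[float] = []
    t_start: list[float] = []
    t_end: list[float] = []
    p_start: list[float] = []
    p_end: list[float] = []
    t_vol: list[float] = []
    p_vol: list[float] = []
    n_predicted = 0

    for pid in ids:
        truth = cohort.annotations[pid]
        pred = predictions.get(pid, BoundaryAnnotation(patient_id=pid, present=False))
        dices.append(interval_dice(pred, truth))
        if pred.present:
            n_predicted += 1
        if pred.present and truth.present:
            profile = cohort.profiles[pid]
            t_start.append(truth.start)
            t_end.append(truth.end)
            p_start.append(pred.start)
            p_end.append(pred.end)
            t_vol.append(volume_surrogate(profile, truth))
            p_vol.append(volume_surrogate(profile, pred))

    report = EvalReport(
        mean_dice=float(np.mean(dices)),
        n_predicted=n_predicted,
        n_missed=len(ids) - n_predicted,
    )
    if t_start:
        report.mae_start, report.mse_start = mae_mse(t_start, p_start)
        report.mae_end, report.mse_end = mae_mse(t_end, p_end)
        report.r2_start = _safe_r2(t_start, p_start)
        report.r2_end = _safe_r2(t_end, p_end)
        report.r2_volume = _safe_r2(t_vol, p_vol)
    return report


# ---------------------------------------------------------------------------
# report I/O
# ---------------------------------------------------------------------------

def save_report(report: EvalReport, path: PathLike) -> None:
    """Serialize an :class:`EvalReport` to JSON (nulls preserved)."""
    payload = asdict(report)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_report(path: PathLike) -> EvalReport:
    """Read a JSON report written by :func:`save_report`."""
    with open(path) as fh:
        payload = json.load(fh)
    return EvalReport(**payload)
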
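"""Bidirectional LSTM slice labeler for aneurysm boundary detection.

The labeler reads a patient's normalized pixel-count sequence (padded to a
fixed number of timesteps), passes it through stacked bidirectional LSTM
layers, maps each timestep's concatenated forward/backward state through a
shared fully connected ReLU stack to a single sigmoid score, and
thresholds the per-slice probabilities.  The longest run of supra-threshold
slices is decoded into start/end boundaries, mirroring the
largest-abnormality-region principle of the rule-based detector.

Training minimizes binary cross-entropy plus a soft-Jaccard overlap term
with Adam, early-stopping on validation loss.  Patient-level k-fold
cross-validation with a leakage guard evaluates generalization.
"""

from __future__ import annotations

import json
import logging
from copy import deepcopy
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from . import nn
from .metrics import EvalReport, evaluate_cohort
from .profiles import BoundaryAnnotation, Cohort, SliceProfile

__all__ = [
    "DetectorSpec",
    "TrainingConfig",
    "TrainedDetector",
    "encode_labels",
    "prepare_input",
    "train_detector",
    "predict_boundaries",
    "decode_probabilities",
    "assign_folds",
    "cross_validate",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


@dataclass(frozen=True)
class DetectorSpec:
    """Architecture of the slice labeler.

    Defaults follow the reference architecture: two stacked bidirectional
    LSTM layers with 600 hidden units per direction, a fully connected
    ReLU stack (widths 256, 64) shared across the 200 output timesteps,
    and a fixed 0.5 decision threshold.
    """

    recurrent_layers: int = 2
    hidden_units: int = 600
    fc_hidden: tuple[int, ...] = (256, 64)
    output_len: int = 200
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.recurrent_layers < 1:
            raise ValueError("recurrent_layers must be >= 1")
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.output_len < 1:
            raise ValueError("output_len must be >= 1")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization hyperparameters (Adam, BCE + Jaccard loss)."""

    learning_rate: float = 3e-4
    batch_size: int = 10
    max_epochs: int = 1000
    jaccard_weight: float = 1.0
    early_stop_patience: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.jaccard_weight < 0:
            raise ValueError("jaccard_weight must be >= 0")


@dataclass
class TrainedDetector:
    """A trained labeler: spec, weights, and the recorded loss curves."""

    spec: DetectorSpec
    params: dict
    loss_history: dict[str, list[float]]
    best_epoch: int = 0

    def __post_init__(self) -> None:
        nt, nv = len(self.loss_history["train"]), len(self.loss_history["val"])
        if nt != nv:
            raise ValueError("train/val loss histories must have equal length")
        for key in ("train", "val"):
            if not all(np.isfinite(self.loss_history[key])):
                raise ValueError(f"non-finite {key} loss encountered")


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def encode_labels(ann: BoundaryAnnotation, length: int) -> np.ndarray:
    """Per-slice binary target: 1 inside [start, end], 0 elsewhere."""
    if ann.present and ann.end >= length:
        raise ValueError(
            f"annotation {ann.patient_id!r}: end {ann.end} >= length {length}"
        )
    y = np.zeros(length)
    if ann.present:
        y[ann.start : ann.end + 1] = 1.0
    return y


def prepare_input(
    profile: SliceProfile, length: int = 200
) -> tuple[np.ndarray, float]:
    """Normalize a profile by its maximum count and pad/truncate to ``length``.

    Returns the fixed-length vector and the scale factor (max count; 1 for
    an all-zero profile) needed to reconstruct counts.  Profiles longer
    than ``length`` are truncated at the distal end with a warning.
    """
    counts = profile.as_array()
    scale = float(counts.max())
    if scale == 0.0:
        scale = 1.0
    x = counts / scale
    if x.size > length:
        logger.warning(
            "profile %s: %d slices truncated to %d", profile.patient_id,
            x.size, length,
        )
        x = x[:length]
    elif x.size < length:
        x = np.concatenate([x, np.zeros(length - x.size)])
    return x, scale


# ---------------------------------------------------------------------------
# model forward/backward
# ---------------------------------------------------------------------------

def _init_params(spec: DetectorSpec, rng: np.random.Generator) -> dict:
    params: dict = {}
    n_in = 1
    for l in range(spec.recurrent_layers):
        params[f"fwd{l}"] = nn.init_lstm(rng, n_in, spec.hidden_units)
        params[f"bwd{l}"] = nn.init_lstm(rng, n_in, spec.hidden_units)
        n_in = 2 * spec.hidden_units
    widths = list(spec.fc_hidden) + [1]
    for j, w in enumerate(widths):
        params[f"fc{j}"] = nn.init_dense(rng, n_in, w)
        n_in = w
    return params


def _forward(spec: DetectorSpec, params: dict, x: np.ndarray):
    """x: (B, T, 1) -> probs (B, T) plus caches for backprop."""
    B, T, _ = x.shape
    caches = []
    h = x
    for l in range(spec.recurrent_layers):
        hf, cf = nn.lstm_forward(params[f"fwd{l}"], h)
        hb_rev, cb = nn.lstm_forward(params[f"bwd{l}"], h[:, ::-1])
        h = np.concatenate([hf, hb_rev[:, ::-1]], axis=2)
        caches.append((cf, cb))
    acts = [h.reshape(B * T, -1)]
    n_fc = len(spec.fc_hidden) + 1
    a = acts[0]
    for j in range(n_fc):
        p = params[f"fc{j}"]
        z = a @ p["W"] + p["b"]
        a = np.maximum(z, 0.0) if j < n_fc - 1 else z
        acts.append(a)
    logits = acts[-1].reshape(B, T)
    probs = nn.sigmoid(logits)
    return probs, (caches, acts, B, T)


def _backward(spec: DetectorSpec, params: dict, cache, dlogits: np.ndarray) -> dict:
    caches, acts, B, T = cache
    grads: dict = {}
    n_fc = len(spec.fc_hidden) + 1
    da = dlogits.reshape(B * T, 1)
    for j in range(n_fc - 1, -1, -1):
        p = params[f"fc{j}"]
        a_in = acts[j]
        if j < n_fc - 1:  # ReLU was applied to this layer's output
            da = da * (acts[j + 1] > 0)
        grads[f"fc{j}"] = {"W": a_in.T @ da, "b": da.sum(axis=0)}
        da = da @ p["W"].T
    dh = da.reshape(B, T, -1)
    H = spec.hidden_units
    for l in range(spec.recurrent_layers - 1, -1, -1):
        cf, cb = caches[l]
        gf, dxf = nn.lstm_backward(params[f"fwd{l}"], cf, np.ascontiguousarray(dh[:, :, :H]))
        gb, dxb = nn.lstm_backward(
            params[f"bwd{l}"], cb, np.ascontiguousarray(dh[:, ::-1, H:])
        )
        grads[f"fwd{l}"] = gf
        grads[f"bwd{l}"] = gb
        dh = dxf + dxb[:, ::-1]
    return grads


def _loss_and_dlogits(
    probs: np.ndarray, y: np.ndarray, jaccard_weight: float, eps: float = 1e-7
):
    """Mean over samples of BCE (per-position mean) + w * (1 - soft Jaccard)."""
    B, T = probs.shape
    p = np.clip(probs, eps, 1.0 - eps)
    bce_val = float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
    dlogits = (probs - y) / (B * T)

    if jaccard_weight > 0:
        inter = np.sum(p * y, axis=1)
        union = np.sum(p, axis=1) + np.sum(y, axis=1) - inter
        union = np.maximum(union, eps)
        jac_val = float(np.mean(1.0 - inter / union))
        # d(1 - I/U)/dp = -(y*U - I*(1-y)) / U^2, then through the sigmoid
        dp = -(y * union[:, None] - inter[:, None] * (1.0 - y)) / union[:, None] ** 2
        dlogits = dlogits + jaccard_weight * dp * probs * (1.0 - probs) / B
        return bce_val + jaccard_weight * jac_val, dlogits
    return bce_val, dlogits


def _param_keys(spec: DetectorSpec) -> list[tuple[str, str]]:
    keys = []
    for l in range(spec.recurrent_layers):
        for d in ("fwd", "bwd"):
            for w in ("Wx", "Wh", "b"):
                keys.append((f"{d}{l}", w))
    for j in range(len(spec.fc_hidden) + 1):
        for w in ("W", "b"):
            keys.append((f"fc{j}", w))
    return keys


# ---------------------------------------------------------------------------
# training / prediction / cross-validation
# ---------------------------------------------------------------------------

def _cohort_arrays(cohort: Cohort, length: int):
    ids = cohort.annotated_ids()
    X = np.stack([prepare_input(cohort.profiles[pid], length)[0] for pid in ids])
    Y = np.stack([encode_labels(cohort.annotations[pid], length) for pid in ids])
    return ids, X[:, :, None], Y


def train_detector(
    train: Cohort,
    validation: Cohort,
    spec: DetectorSpec = DetectorSpec(),
    cfg: TrainingConfig = TrainingConfig(),
) -> TrainedDetector:
    """Train the labeler with Adam on BCE + Jaccard loss, early stopping.

    Both cohorts must be annotated and patient-disjoint (leakage guard).
    The parameters achieving the best validation loss are restored.
    """
    overlap = set(train.profiles) & set(validation.profiles)
    if overlap:
        raise ValueError(f"patient leakage between train and validation: "
                         f"{sorted(overlap)}")
    if not train.annotations or not validation.annotations:
        raise ValueError("train and validation cohorts must be annotated")

    _, Xtr, Ytr = _cohort_arrays(train, spec.output_len)
    _, Xva, Yva = _cohort_arrays(validation, spec.output_len)

    rng = np.random.default_rng(cfg.seed)
    params = _init_params(spec, rng)
    keys = _param_keys(spec)
    flat = [params[k][w] for k, w in keys]
    adam = nn.AdamState(flat, lr=cfg.learning_rate)

    n = Xtr.shape[0]
    history: dict[str, list[float]] = {"train": [], "val": []}
    best_val = np.inf
    best_params = deepcopy(params)
    best_epoch = 0
    stale = 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        batch_losses = []
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            probs, cache = _forward(spec, params, Xtr[idx])
            loss, dlogits = _loss_and_dlogits(probs, Ytr[idx], cfg.jaccard_weight)
            grads = _backward(spec, params, cache, dlogits)
            adam.step([grads[k][w] for k, w in keys])
            batch_losses.append(loss)

        probs_va, _ = _forward(spec, params, Xva)
        val_loss, _ = _loss_and_dlogits(probs_va, Yva, cfg.jaccard_weight)
        history["train"].append(float(np.mean(batch_losses)))
        history["val"].append(float(val_loss))

        if val_loss < best_val:
            best_val = val_loss
            best_params = deepcopy(params)
            best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= cfg.early_stop_patience:
                logger.info("early stop at epoch %d (best %d)", epoch, best_epoch)
                break

    return TrainedDetector(
        spec=spec, params=best_params, loss_history=history, best_epoch=best_epoch
    )


def decode_probabilities(
    probs: Sequence[float], threshold: float, patient_id: str = ""
) -> BoundaryAnnotation:
    """Decode per-slice probabilities into the longest supra-threshold run.

    Ties between equally long runs break toward the earliest; with no
    slice at or above the threshold the annotation is absent.
    """
    p = np.asarray(probs, dtype=float)
    above = p >= threshold
    best: Optional[tuple[int, int]] = None
    start: Optional[int] = None
    for i in range(p.size + 1):
        val = bool(above[i]) if i < p.size else False
        if val and start is None:
            start = i
        elif not val and start is not None:
            if best is None or (i - start) > (best[1] - best[0] + 1):
                best = (start, i - 1)
            start = None
    if best is None:
        return BoundaryAnnotation(patient_id=patient_id, present=False)
    return BoundaryAnnotation(
        patient_id=patient_id, present=True, start=best[0], end=best[1]
    )


def predict_boundaries(
    model: TrainedDetector, profile: SliceProfile
) -> tuple[BoundaryAnnotation, np.ndarray]:
    """Per-slice probabilities and the decoded longest supra-threshold run.

    Padding positions are excluded; the returned probability vector covers
    the analyzed slices of the profile (at most ``output_len``).
    """
    x, _ = prepare_input(profile, model.spec.output_len)
    probs, _ = _forward(model.spec, model.params, x[None, :, None])
    true_len = min(profile.slice_count, model.spec.output_len)
    p = probs[0, :true_len]
    ann = decode_probabilities(p, model.spec.threshold, profile.patient_id)
    return ann, p


def assign_folds(ids: Sequence[str], k: int, seed: int) -> list[list[str]]:
    """Seeded partition of patient ids into k disjoint test folds."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds {len(ids)} patients")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    return [list(f) for f in np.array_split(perm, k)]


def cross_validate(
    cohort: Cohort,
    k: int = 5,
    spec: DetectorSpec = DetectorSpec(),
    cfg: TrainingConfig = TrainingConfig(),
    val_fraction: float = 0.1,
) -> tuple[list[EvalReport], EvalReport]:
    """Patient-level k-fold cross-validation of the labeler.

    Patients are partitioned once (seeded) into k disjoint test folds; for
    each fold the remaining patients are split into a training set and a
    small early-stopping validation set.  Per-fold reports come from
    :func:`aaakit.metrics.evaluate_cohort`; the pooled report averages the
    fold metrics (ignoring folds where a metric is undefined) and sums the
    prediction counts.
    """
    ids = cohort.annotated_ids()
    folds = assign_folds(ids, k, cfg.seed)

    # leakage guard: the folds partition the patients
    flat = [pid for f in folds for pid in f]
    assert len(flat) == len(set(flat)) == len(ids)

    reports: list[EvalReport] = []
    order = [pid for f in folds for pid in f]
    for fi, test_ids in enumerate(folds):
        rest = [pid for pid in order if pid not in set(test_ids)]
        n_val = max(1, int(round(val_fraction * len(rest))))
        if n_val >= len(rest):
            raise ValueError("fold too small to carve out a validation set")
        val_ids, train_ids = rest[:n_val], rest[n_val:]

        model = train_detector(
            cohort.subset(train_ids),
            cohort.subset(val_ids),
            spec,
            replace(cfg, seed=cfg.seed + fi),
        )
        test_cohort = cohort.subset(test_ids)
        preds = {
            pid: predict_boundaries(model, test_cohort.profiles[pid])[0]
            for pid in test_ids
        }
        reports.append(evaluate_cohort(test_cohort, preds))

    pooled = EvalReport(
        n_predicted=sum(r.n_predicted for r in reports),
        n_missed=sum(r.n_missed for r in reports),
    )
    for name in ("mean_dice", "r2_start", "r2_end", "r2_volume",
                 "mae_start", "mae_end", "mse_start", "mse_end"):
        vals = [getattr(r, name) for r in reports if getattr(r, name) is not None]
        setattr(pooled, name, float(np.mean(vals)) if vals else None)
    return reports, pooled


# ---------------------------------------------------------------------------
# model archive
# ---------------------------------------------------------------------------

def save_model(model: TrainedDetector, path: PathLike) -> None:
    """Save spec, weights, and loss history to a single ``.npz`` archive."""
    arrays = {}
    for group, name in _param_keys(model.spec):
        arrays[f"{group}.{name}"] = model.params[group][name]
    header = json.dumps(
        {
            "spec": asdict(model.spec),
            "best_epoch": model.best_epoch,
            "loss_history": model.loss_history,
        }
    )
    np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8), **arrays)


def load_model(path: PathLike) -> TrainedDetector:
    """Load a model archive written by :func:`save_model`."""
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        spec_d = header["spec"]
        spec_d["fc_hidden"] = tuple(spec_d["fc_hidden"])
        spec = DetectorSpec(**spec_d)
        params: dict = {}
        for group, name in _param_keys(spec):
            params.setdefault(group, {})[name] = data[f"{group}.{name}"]
    return TrainedDetector(
        spec=spec,
        params=params,
        loss_history={k: list(v) for k, v in header["loss_history"].items()},
        best_epoch=header["best_epoch"],
    )
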
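"""Training loop, 80/20 split protocol and the evaluation metric suite.

Splitting defaults to whole-gait-cycle grouping: analysis windows overlap, so
a purely random window split would place near-duplicate windows on both sides
and inflate test scores.  Classification is scored with per-class precision,
overall accuracy and the macro/micro averaged precision and sensitivity suite
(PMAP, PMIP, PMAS, PMIS); for single-label multiclass problems the micro
averages both equal the accuracy.  Angle regression is scored per joint with
RMSE (degrees), the zero-lag Pearson cross-correlation coefficient and a
relative error, RMSE as a percentage of the observed true range of motion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import ConfigurationError, DataError
from .features import FeatureSet
from .model import ModelConfig, MultiBranchNet, multitask_loss

__all__ = [
    "SplitSpec", "TrainConfig", "EvalReport", "split", "train",
    "confusion_matrix", "classification_metrics", "regression_metrics",
    "evaluate",
]

N_CLASSES = 4


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partition: 80/20, grouped by gait cycle by default."""

    train_fraction: float = 0.8
    stratify_by_gait: bool = False
    group_by_cycle: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ConfigurationError("train_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 40
    batch_size: int = 64
    learning_rate: float = 1e-3
    loss_lambda: float = 0.1
    #: fraction of the training side carved out for the per-epoch validation curve
    val_fraction: float = 0.1
    seed: int = 0


@dataclass
class EvalReport:
    """Confusion-derived classification metrics plus per-joint regression metrics.

    Percentages are on the 0-100 scale; RMSE in degrees; cross-correlation in
    [-1, 1]."""

    confusion: np.ndarray
    per_class_precision: np.ndarray
    per_class_sensitivity: np.ndarray
    accuracy: float
    pmap: float
    pmip: float
    pmas: float
    pmis: float
    per_joint_rmse: np.ndarray
    per_joint_xcorr: np.ndarray
    per_joint_relative_error: np.ndarray
    traces: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "per_class_precision_pct": self.per_class_precision.tolist(),
            "per_class_sensitivity_pct": self.per_class_sensitivity.tolist(),
            "accuracy_pct": self.accuracy,
            "pmap_pct": self.pmap,
            "pmip_pct": self.pmip,
            "pmas_pct": self.pmas,
            "pmis_pct": self.pmis,
            "per_joint_rmse_deg": self.per_joint_rmse.tolist(),
            "per_joint_xcorr": self.per_joint_xcorr.tolist(),
            "per_joint_relative_error_pct": self.per_joint_relative_error.tolist(),
        }


# ---------------------------------------------------------------------------
# splitting


def split(dataset: FeatureSet, spec: SplitSpec = SplitSpec()
          ) -> tuple[FeatureSet, FeatureSet]:
    """Disjoint, exhaustive train/test split of the window set.

    With ``group_by_cycle`` whole gait cycles are assigned to one side, so no
    overlapping windows straddle the split.  With ``stratify_by_gait`` (window
    -level splits only) class proportions are preserved within one window per
    class.
    """
    spec.validate()
    n = len(dataset)
    if n < 2:
        raise DataError("need at least two windows to split")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF, 7]))
    if spec.group_by_cycle:
        groups = np.unique(dataset.cycle_index)
        order = rng.permutation(groups)
        n_train_groups = int(round(spec.train_fraction * groups.size))
        n_train_groups = min(max(n_train_groups, 1), groups.size - 1)
        train_groups = set(order[:n_train_groups].tolist())
        mask = np.array([c in train_groups for c in dataset.cycle_index])
        train_idx = np.flatnonzero(mask)
        test_idx = np.flatnonzero(~mask)
    elif spec.stratify_by_gait:
        train_parts, test_parts = [], []
        for cls in np.unique(dataset.gait):
            idx = rng.permutation(np.flatnonzero(dataset.gait == cls))
            k = int(round(spec.train_fraction * idx.size))
            train_parts.append(idx[:k])
            test_parts.append(idx[k:])
        train_idx = np.sort(np.concatenate(train_parts))
        test_idx = np.sort(np.concatenate(test_parts))
    else:
        order = rng.permutation(n)
        k = int(round(spec.train_fraction * n))
        train_idx = np.sort(order[:k])
        test_idx = np.sort(order[k:])
    return dataset.subset(train_idx), dataset.subset(test_idx)


# ---------------------------------------------------------------------------
# training


def _forward_batched(net: MultiBranchNet, ds: FeatureSet, batch_size: int = 256
                     ) -> tuple[np.ndarray, np.ndarray]:
    logits = np.empty((len(ds), N_CLASSES))
    angles = np.empty((len(ds), 3))
    for s in range(0, len(ds), batch_size):
        sl = slice(s, min(s + batch_size, len(ds)))
        lg, an = net.forward(ds.raw[sl], ds.spec[sl], ds.td[sl])
        logits[sl], angles[sl] = lg, an
    return logits, angles


def train(net: MultiBranchNet, train_set: FeatureSet,
          cfg: TrainConfig = TrainConfig(), verbose: bool = False
          ) -> dict:
    """Train in place with Adam; returns the learning curves.

    A ``val_fraction`` carve-out of the training windows is scored every epoch
    (total loss and gait accuracy — the standard training-progress curves);
    the weights with the best validation loss are restored at the end.
    """
    if len(train_set) < 2 * cfg.batch_size and len(train_set) < 10:
        raise DataError("training set too small")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 11]))
    n = len(train_set)
    order = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n)))
    val_idx, fit_idx = order[:n_val], order[n_val:]
    val = train_set.subset(val_idx)
    fit = train_set.subset(fit_idx)
    opt = nn.Adam(net.parameters(), lr=cfg.learning_rate)
    history = {"epoch": [], "train_loss": [], "val_loss": [], "val_accuracy": []}
    best = (np.inf, net.state_dict())
    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(fit))
        losses = []
        for s in range(0, len(fit), cfg.batch_size):
            idx = perm[s: s + cfg.batch_size]
            opt.zero_grad()
            logits, ang = net.forward(fit.raw[idx], fit.spec[idx], fit.td[idx])
            loss, gl, ga, _ = multitask_loss(
                logits, ang, fit.gait[idx].astype(int), fit.angles[idx],
                lam=cfg.loss_lambda,
            )
            net.backward(gl, ga)
            opt.step()
            losses.append(loss)
        v_logits, v_ang = _forward_batched(net, val)
        v_loss, _, _, _ = multitask_loss(
            v_logits, v_ang, val.gait.astype(int), val.angles, lam=cfg.loss_lambda
        )
        v_acc = float(np.mean(v_logits.argmax(axis=1) == val.gait))
        history["epoch"].append(epoch)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(float(v_loss))
        history["val_accuracy"].append(v_acc)
        if v_loss < best[0]:
            best = (v_loss, net.state_dict())
        if verbose:
            print(f"epoch {epoch:3d}  train_loss {np.mean(losses):.4f}  "
                  f"val_loss {v_loss:.4f}  val_acc {v_acc:.3f}")
        if not np.isfinite(np.mean(losses)):
            raise DataError("training diverged (non-finite loss)")
    net.load_state_dict(best[1])
    return history


# ---------------------------------------------------------------------------
# metrics


def confusion_matrix(true: np.ndarray, pred: np.ndarray,
                     n_classes: int = N_CLASSES) -> np.ndarray:
    """Counts with rows = true class, columns = predicted class."""
    true = np.asarray(true, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if true.shape != pred.shape:
        raise DataError("true/pred length mismatch")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (true, pred), 1)
    return cm


def classification_metrics(confusion: np.ndarray) -> dict:
    """Precision/sensitivity per class plus the macro/micro suite, in percent.

    A class with zero predicted (resp. true) positives has undefined precision
    (resp. sensitivity); it is reported as 0 with a warning.  Macro averages
    run over classes that appear in the truth.
    """
    cm = np.asarray(confusion, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise DataError("confusion matrix must be square")
    tp = np.diag(cm)
    pred_pos = cm.sum(axis=0)
    true_pos = cm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_pos > 0, tp / pred_pos, 0.0)
        sensitivity = np.where(true_pos > 0, tp / true_pos, 0.0)
    if np.any((pred_pos == 0) & (true_pos > 0)):
        warnings.warn("class with zero predicted positives: precision reported as 0",
                      stacklevel=2)
    total = cm.sum()
    if total == 0:
        raise DataError("empty confusion matrix")
    accuracy = tp.sum() / total
    present = true_pos > 0
    pmap = precision[present].mean()
    pmas = sensitivity[present].mean()
    # micro: pooled counts; for single-label multiclass FP total == FN total,
    # so micro precision == micro sensitivity == accuracy
    pmip = tp.sum() / pred_pos.sum()
    pmis = tp.sum() / true_pos.sum()
    return {
        "per_class_precision": precision * 100.0,
        "per_class_sensitivity": sensitivity * 100.0,
        "accuracy": accuracy * 100.0,
        "pmap": pmap * 100.0,
        "pmip": pmip * 100.0,
        "pmas": pmas * 100.0,
        "pmis": pmis * 100.0,
    }


def regression_metrics(pred_angles: np.ndarray, true_angles: np.ndarray) -> dict:
    """Per-joint RMSE (deg), zero-lag Pearson cross-correlation, and relative
    error = RMSE / observed true range x 100."""
    pred = np.asarray(pred_angles, dtype=float)
    true = np.asarray(true_angles, dtype=float)
    if pred.shape != true.shape or pred.ndim != 2:
        raise DataError("angle arrays must be matching (n, joints)")
    rmse = np.sqrt(np.mean((pred - true) ** 2, axis=0))
    xcorr = np.empty(pred.shape[1])
    for j in range(pred.shape[1]):
        pj, tj = pred[:, j] - pred[:, j].mean(), true[:, j] - true[:, j].mean()
        denom = np.sqrt((pj**2).sum() * (tj**2).sum())
        xcorr[j] = (pj * tj).sum() / denom if denom > 0 else 0.0
    rng_true = true.max(axis=0) - true.min(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(rng_true > 0, rmse / rng_true * 100.0, np.nan)
    return {"rmse": rmse, "xcorr": xcorr, "relative_error": rel}


def evaluate(net: MultiBranchNet, test_set: FeatureSet) -> EvalReport:
    """Score a trained model on held-out windows and emit the full report,
    including the predicted-vs-true gait sequence and angle traces."""
    if len(test_set) == 0:
        raise DataError("empty test set")
    logits, pred_angles = _forward_batched(net, test_set)
    pred_gait = logits.argmax(axis=1)
    cm = confusion_matrix(test_set.gait, pred_gait)
    cls = classification_metrics(cm)
    reg = regression_metrics(pred_angles, test_set.angles)
    order = np.argsort(test_set.window_start)
    traces = {
        "window_start": test_set.window_start[order].tolist(),
        "true_gait": test_set.gait[order].astype(int).tolist(),
        "pred_gait": pred_gait[order].astype(int).tolist(),
        "true_angles": test_set.angles[order].tolist(),
        "pred_angles": pred_angles[order].tolist(),
    }
    return EvalReport(
        confusion=cm,
        per_class_precision=cls["per_class_precision"],
        per_class_sensitivity=cls["per_class_sensitivity"],
        accuracy=cls["accuracy"],
        pmap=cls["pmap"], pmip=cls["pmip"], pmas=cls["pmas"], pmis=cls["pmis"],
        per_joint_rmse=reg["rmse"],
        per_joint_xcorr=reg["xcorr"],
        per_joint_relative_error=reg["relative_error"],
        traces=traces,
    )
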
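"""Training loop, repetition-based split protocols, and evaluation metrics.

Two split protocols are provided, matching the benchmark conventions for the
supported databases: a fixed 7-train / 3-test repetition split (train on
repetitions {1, 3, 4, 6, 8, 9, 10}, test on {2, 5, 7}) and an odd/even trial
split.  A fresh model is trained per subject and metrics are averaged across
subjects, unweighted.

Metrics are accuracy, macro F1 and micro F1 (percent), all derived from the
confusion matrix.  For single-label classification where every item receives
exactly one prediction, micro F1 equals accuracy identically; macro F1
averages per-class F1 with classes absent from both truth and prediction
contributing 0 (the strictest convention, which matters on imbalanced sets).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .matrix import MatrixSignal, augment
from .transformer import SignalTransformer, split_patches

__all__ = [
    "TrainConfig", "EvalReport", "AdamW",
    "split_by_repetition", "split_odd_even",
    "train", "evaluate", "cross_subject_report",
    "NINAPRO_TRAIN_REPS", "NINAPRO_TEST_REPS", "stack_patches",
]

NINAPRO_TRAIN_REPS = frozenset({1, 3, 4, 6, 8, 9, 10})
NINAPRO_TEST_REPS = frozenset({2, 5, 7})


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults match the full-scale runs)."""

    batch_size: int = 55
    epochs: int = 8
    eval_steps: int = 100
    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    seed: int = 0
    augment: bool = False
    flip_p: float = 0.5
    max_rot: float = 15.0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.epochs, self.eval_steps) < 1:
            raise ValueError("batch_size, epochs and eval_steps must be positive")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("learning_rate must be > 0 and weight_decay >= 0")


@dataclass
class EvalReport:
    """Metrics for one train/test split (percentages)."""

    accuracy: float
    f1_macro: float
    f1_micro: float
    confusion: np.ndarray
    n_test: int
    subject_id: str = ""

    def as_dict(self) -> dict:
        return {"subject_id": self.subject_id, "accuracy": self.accuracy,
                "f1_macro": self.f1_macro, "f1_micro": self.f1_micro,
                "n_test": self.n_test, "confusion": self.confusion.tolist()}


# ---------------------------------------------------------------------------
# splits

def split_by_repetition(data: list[MatrixSignal], train_reps, test_reps
                        ) -> tuple[list[MatrixSignal], list[MatrixSignal]]:
    """Assign every item by its trial index; the two sets must be disjoint.

    Items whose repetition is in neither set (e.g. rest windows, trial 0)
    belong to neither split.
    """
    train_reps, test_reps = set(train_reps), set(test_reps)
    if train_reps & test_reps:
        raise ValueError(f"train and test repetitions overlap: {train_reps & test_reps}")
    if not test_reps:
        raise ValueError("test repetition set is empty")
    train = [d for d in data if d.repetition in train_reps]
    test = [d for d in data if d.repetition in test_reps]
    return train, test


def split_odd_even(data: list[MatrixSignal]
                   ) -> tuple[list[MatrixSignal], list[MatrixSignal]]:
    """Odd-numbered trials train, even-numbered trials test."""
    reps = {d.repetition for d in data if d.repetition > 0}
    return split_by_repetition(data,
                               {r for r in reps if r % 2 == 1},
                               {r for r in reps if r % 2 == 0})


# ---------------------------------------------------------------------------
# optimization

class AdamW:
    """Adam with decoupled weight decay; decay applies to 2-D weights only."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-4):
        self.params = params
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            if p.ndim >= 2:
                p -= self.lr * self.weight_decay * p
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# training and evaluation

def stack_patches(data: list[MatrixSignal], patch_size: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Batch a list of matrix signals into (patches, labels) arrays."""
    X = np.stack([split_patches(d, patch_size) for d in data])
    y = np.array([d.label for d in data], dtype=np.int64)
    return X, y


def train(model: SignalTransformer, train_data: list[MatrixSignal],
          cfg: TrainConfig, eval_data: list[MatrixSignal] | None = None
          ) -> tuple[SignalTransformer, dict]:
    """Minimize cross-entropy with AdamW; reproducible given cfg.seed.

    Every ``cfg.eval_steps`` optimizer steps an evaluation snapshot on
    ``eval_data`` (when given) is appended to the log.  Augmentation, when
    enabled, is applied to the training split only, re-drawn each epoch.
    """
    if not train_data:
        raise ValueError("empty training data")
    rng = np.random.default_rng(cfg.seed)
    p = model.config.patch_size
    opt = AdamW(model.params, lr=cfg.learning_rate,
                weight_decay=cfg.weight_decay)
    log = {"loss": [], "eval": []}
    step = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(len(train_data))
        epoch_data = [train_data[i] for i in order]
        if cfg.augment:
            epoch_data = [augment(d, rng, cfg.flip_p, cfg.max_rot)
                          for d in epoch_data]
        X, y = stack_patches(epoch_data, p)
        for i in range(0, len(epoch_data), cfg.batch_size):
            xb, yb = X[i:i + cfg.batch_size], y[i:i + cfg.batch_size]
            loss, grads = model.loss_and_grads(xb, yb, train=True, rng=rng)
            opt.step(grads)
            log["loss"].append(float(loss))
            step += 1
            if eval_data is not None and step % cfg.eval_steps == 0:
                log["eval"].append((step, evaluate(model, eval_data).accuracy))
    return model, log


def _metrics_from_confusion(conf: np.ndarray) -> tuple[float, float, float]:
    n = conf.sum()
    tp = np.diag(conf).astype(np.float64)
    fp = conf.sum(axis=0) - tp
    fn = conf.sum(axis=1) - tp
    accuracy = tp.sum() / n
    denom = 2 * tp + fp + fn
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(denom > 0, 2 * tp / np.where(denom > 0, denom, 1), 0.0)
    f1_macro = per_class.mean()
    micro_denom = 2 * tp.sum() + fp.sum() + fn.sum()
    f1_micro = 2 * tp.sum() / micro_denom if micro_denom else 0.0
    return 100.0 * accuracy, 100.0 * f1_macro, 100.0 * f1_micro


def evaluate(model: SignalTransformer, test_data: list[MatrixSignal]
             ) -> EvalReport:
    """Accuracy, macro F1 and micro F1 on a held-out split."""
    if not test_data:
        raise ValueError("empty test data")
    X, y = stack_patches(test_data, model.config.patch_size)
    pred = model.predict(X)
    return report_from_predictions(y, pred, model.config.n_classes,
                                   subject_id=test_data[0].subject_id)


def report_from_predictions(y_true, y_pred, n_classes: int,
                            subject_id: str = "") -> EvalReport:
    """Build an EvalReport from raw label/prediction arrays."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    conf = _sk_confusion(y_true, y_pred, labels=np.arange(n_classes))
    acc, f1m, f1u = _metrics_from_confusion(conf)
    return EvalReport(accuracy=acc, f1_macro=f1m, f1_micro=f1u,
                      confusion=conf, n_test=int(y_true.size),
                      subject_id=subject_id)


def cross_subject_report(reports: list[EvalReport]) -> dict:
    """Unweighted per-subject averages plus the per-subject table."""
    if not reports:
        raise ValueError("no subject reports")
    return {
        "accuracy": float(np.mean([r.accuracy for r in reports])),
        "f1_macro": float(np.mean([r.f1_macro for r in reports])),
        "f1_micro": float(np.mean([r.f1_micro for r in reports])),
        "n_subjects": len(reports),
        "per_subject": [r.as_dict() for r in reports],
    }
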
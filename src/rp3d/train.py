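"""Training loop, metrics and the five-fold cross-validation driver.

Hyperparameter defaults follow the reference protocol: Adam with
learning rate 0.001 and batch size 64, categorical cross-entropy on
the softmax head, early stopping on validation loss with the best
checkpoint restored. Evaluation reports per-class precision, recall
and F1 (one-vs-rest from the confusion matrix), their unweighted
macro averages, and the confusion matrix itself; metrics are
conventionally rounded to 4 decimals when printed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .records import RhythmClass, CLASS_ORDER
from .nn.model import Classifier, ModelConfig, build_model, predict, softmax

__all__ = [
    "TrainConfig", "EvalReport", "Adam", "train", "evaluate", "run_cv",
    "run_cv_records", "f1_from_precision_recall", "metrics_from_confusion",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 64
    max_epochs: int = 50
    patience: int = 10          # early-stop patience on val loss
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("learning_rate > 0, batch_size >= 1, max_epochs >= 1 required")


class Adam:
    """Adam with the usual defaults (beta1 0.9, beta2 0.999, eps 1e-8)."""

    def __init__(self, lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1 ** self.t
        corr2 = 1 - b2 ** self.t
        for name, value, grad in params:
            if name not in self.m:
                self.m[name] = np.zeros_like(value)
                self.v[name] = np.zeros_like(value)
            m, v = self.m[name], self.v[name]
            m[...] = b1 * m + (1 - b1) * grad
            v[...] = b2 * v + (1 - b2) * grad * grad
            value -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


def _cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = len(y)
    eps = 1e-12
    loss = -float(np.mean(np.log(p[np.arange(n), y] + eps)))
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


def _epoch_loss(model: Classifier, x: np.ndarray, y: np.ndarray,
                batch_size: int) -> tuple[float, float]:
    """Eval-mode loss and accuracy over a dataset."""
    losses, correct = [], 0
    for i in range(0, len(x), batch_size):
        logits = model.forward(x[i:i + batch_size], training=False)
        loss, _ = _cross_entropy(logits, y[i:i + batch_size])
        losses.append(loss * len(logits))
        correct += int((logits.argmax(axis=1) == y[i:i + batch_size]).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def train(model: Classifier, x_train: np.ndarray, y_train: np.ndarray,
          x_val: np.ndarray | None = None, y_val: np.ndarray | None = None,
          cfg: TrainConfig = TrainConfig()) -> dict:
    """Fit in place; returns the history dict.

    The model is restored to its best-validation-loss checkpoint
    (best train loss if no validation set is given). Fully seeded:
    shuffling and dropout derive from ``cfg.seed``, so identical
    (model seed, cfg) pairs give identical final weights. Aborts on a
    non-finite loss with a diagnostic.
    """
    if len(x_train) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    model.set_rng(np.random.default_rng(rng.integers(2**31)))
    opt = Adam(lr=cfg.learning_rate)
    y_train = np.asarray(y_train, dtype=int)
    has_val = x_val is not None and len(x_val) > 0
    if has_val:
        y_val = np.asarray(y_val, dtype=int)

    history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    best_loss, best_state, bad_epochs = np.inf, None, 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(x_train))
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            logits = model.forward(x_train[idx], training=True)
            loss, grad = _cross_entropy(logits, y_train[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, batch {i // cfg.batch_size}")
            model.backward(grad.astype(model.net_dtype))
            opt.step(model.parameters())
        tr_loss, tr_acc = _epoch_loss(model, x_train, y_train, cfg.batch_size)
        history["train_loss"].append(tr_loss)
        history["train_acc"].append(tr_acc)
        if has_val:
            va_loss, va_acc = _epoch_loss(model, x_val, y_val, cfg.batch_size)
            history["val_loss"].append(va_loss)
            history["val_acc"].append(va_acc)
            monitor = va_loss
        else:
            monitor = tr_loss
        if monitor < best_loss:
            best_loss = monitor
            best_state = copy.deepcopy(model.state_dict())
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > cfg.patience:
                break
    if best_state is not None:
        model.load_state(best_state)
    history["best_loss"] = best_loss
    history["epochs_run"] = len(history["train_loss"])
    return history


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def metrics_from_confusion(cm: np.ndarray) -> dict:
    """Per-class one-vs-rest precision/recall/F1 and macro averages.

    ``cm[i, j]`` counts samples with true class i predicted as j.
    Empty denominators yield 0 for the affected metric.
    """
    cm = np.asarray(cm, dtype=float)
    tp = np.diag(cm)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
    f1 = np.array([f1_from_precision_recall(p, r) for p, r in zip(precision, recall)])
    return {
        "tp": tp.astype(int), "fp": fp.astype(int), "fn": fn.astype(int),
        "precision": precision, "recall": recall, "f1": f1,
        "macro_precision": float(precision.mean()),
        "macro_recall": float(recall.mean()),
        "macro_f1": float(f1.mean()),
    }


@dataclass
class EvalReport:
    """Confusion matrix plus the derived per-class and macro metrics.

    Class axes follow the fixed rhythm-class order (NSR, AF, LBBB,
    IAVB); row = true class, column = predicted class.
    """

    confusion: np.ndarray
    class_names: tuple[str, ...] = field(
        default_factory=lambda: tuple(c.name for c in CLASS_ORDER))

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=int)
        m = metrics_from_confusion(self.confusion)
        self.tp, self.fp, self.fn = m["tp"], m["fp"], m["fn"]
        self.precision, self.recall, self.f1 = m["precision"], m["recall"], m["f1"]
        self.macro_precision = m["macro_precision"]
        self.macro_recall = m["macro_recall"]
        self.macro_f1 = m["macro_f1"]

    @property
    def n_evaluated(self) -> int:
        return int(self.confusion.sum())

    def as_dict(self, ndigits: int = 4) -> dict:
        return {
            "classes": list(self.class_names),
            "confusion": self.confusion.tolist(),
            "precision": [round(float(v), ndigits) for v in self.precision],
            "recall": [round(float(v), ndigits) for v in self.recall],
            "f1": [round(float(v), ndigits) for v in self.f1],
            "macro_precision": round(self.macro_precision, ndigits),
            "macro_recall": round(self.macro_recall, ndigits),
            "macro_f1": round(self.macro_f1, ndigits),
            "n": self.n_evaluated,
        }


def evaluate(model: Classifier, x: np.ndarray, y: np.ndarray,
             batch_size: int = 64, n_classes: int | None = None) -> EvalReport:
    """Predict and score a labelled set."""
    y = np.asarray(y, dtype=int)
    k = n_classes if n_classes is not None else model.cfg.n_classes
    _, pred = predict(model, x, batch_size)
    cm = np.zeros((k, k), dtype=int)
    np.add.at(cm, (y, pred), 1)
    names = tuple(c.name for c in CLASS_ORDER) if k == len(CLASS_ORDER) \
        else tuple(f"class{i}" for i in range(k))
    return EvalReport(confusion=cm, class_names=names)


def run_cv(x: np.ndarray, y: np.ndarray, folds, model_cfg: ModelConfig,
           train_cfg: TrainConfig = TrainConfig(),
           x_test: np.ndarray | None = None, y_test: np.ndarray | None = None
           ) -> dict:
    """Five-fold (or k-fold) cross-validation driver.

    ``folds`` is a list of (train_idx, val_idx) index arrays over
    ``x``/``y`` (build them with ``dataset.make_cv_folds`` to keep the
    record grouping). Each fold trains a fresh model from the same
    seed family; the aggregate reports mean and sd of the fold
    macro-F1 on validation, per-fold test reports when a test set is
    supplied, and the best fold (lowest validation loss).
    """
    fold_val_reports: list[EvalReport] = []
    fold_test_reports: list[EvalReport] = []
    histories = []
    best = (np.inf, None)
    for f, (tr_idx, va_idx) in enumerate(folds):
        model = build_model(model_cfg, seed=train_cfg.seed + f)
        hist = train(model, x[tr_idx], y[tr_idx], x[va_idx], y[va_idx],
                     cfg=train_cfg)
        histories.append(hist)
        fold_val_reports.append(evaluate(model, x[va_idx], y[va_idx],
                                         train_cfg.batch_size))
        if x_test is not None:
            fold_test_reports.append(evaluate(model, x_test, y_test,
                                              train_cfg.batch_size))
        if hist["best_loss"] < best[0]:
            best = (hist["best_loss"], f)
    val_f1 = np.array([r.macro_f1 for r in fold_val_reports])
    out = {
        "fold_val_reports": fold_val_reports,
        "histories": histories,
        "val_macro_f1_mean": float(val_f1.mean()),
        "val_macro_f1_sd": float(val_f1.std(ddof=1)) if len(val_f1) > 1 else 0.0,
        "best_fold": best[1],
    }
    if fold_test_reports:
        test_f1 = np.array([r.macro_f1 for r in fold_test_reports])
        out["fold_test_reports"] = fold_test_reports
        out["test_macro_f1_mean"] = float(test_f1.mean())
        out["best_fold_test_report"] = fold_test_reports[best[1]]
    return out


def run_cv_records(records, mode: str = "vcg3",
                   model_cfg: ModelConfig | None = None,
                   train_cfg: TrainConfig = TrainConfig(), k: int = 5,
                   rp=None, split_seed: int = 0) -> dict:
    """Record-level front end to :func:`run_cv`.

    Splits the cohort (inter-patient test draw), builds recurrence
    volumes once, groups the train+val segments into k record-grouped
    folds and runs the cross-validation driver against the held-out
    test set.
    """
    from .dataset import RPConfig, build_volumes, make_cv_folds, make_split

    rp = rp if rp is not None else RPConfig(side=64)
    split = make_split(records, seed=split_seed)
    trainval = split.train + split.val
    vols_tv = build_volumes(records, trainval, mode, rp)
    vols_te = build_volumes(records, split.test, mode, rp)
    x = np.stack([v.values for v in vols_tv])
    y = np.array([v.label.index for v in vols_tv])
    x_test = np.stack([v.values for v in vols_te]) if vols_te else None
    y_test = np.array([v.label.index for v in vols_te]) if vols_te else None
    seg_index = {seg: i for i, seg in enumerate(trainval)}
    folds = [(np.array([seg_index[s] for s in tr]),
              np.array([seg_index[s] for s in va]))
             for tr, va in make_cv_folds(trainval, k=k, seed=split_seed)]
    if model_cfg is None:
        c, h, w = x.shape[1:]
        from .nn.model import tiny_config
        model_cfg = tiny_config(input_shape=(c, h, w))
    out = run_cv(x, y, folds, model_cfg, train_cfg, x_test, y_test)
    out["split"] = split
    return out
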
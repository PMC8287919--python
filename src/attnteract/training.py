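"""Training, evaluation, confident-example selection, hyperparameter search.

Optimization is plain Adam with early stopping on validation loss.  All
randomness (shuffling, initialization) flows from explicit seeds, so two
runs with the same seed give bitwise-identical loss histories.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from sklearn.metrics import roc_auc_score

from .model import Model, ModelConfig
from .seqdata import LabeledDataset, encode_batch

logger = logging.getLogger(__name__)

__all__ = [
    "ConfidenceThresholds", "TrainResult", "train", "evaluate_auc",
    "predict_probabilities", "select_confident_examples", "random_search",
]


@dataclasses.dataclass
class ConfidenceThresholds:
    """Cutoffs used when choosing which examples to interpret.

    - ``confidence`` (p): binary positives with predicted probability
      > p enter the foreground; negatives scoring < 1 - p form the
      background.
    - ``precision``: multi-label examples qualify when the precision of
      their thresholded predictions against the true labels exceeds this.
    - ``attention``: pairs whose maximum attention never reaches this are
      dropped (0.10 default; 0.08 was the more sensitive promoter setting).
    - ``min_ic``: motifs kept for TF mapping need at least this
      information content, in bits.
    """

    confidence: float = 0.70
    precision: float = 0.50
    attention: float = 0.10
    min_ic: float = 3.0
    prob_cutoff: float = 0.50   # binarization cutoff inside the precision rule

    def __post_init__(self):
        for name in ("confidence", "precision", "attention", "prob_cutoff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclasses.dataclass
class TrainResult:
    model: Model
    history: list[dict]         # per epoch: train_loss, val_loss, val_auc

    def write_log(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch\ttrain_loss\tval_loss\tval_auc\n")
            for row in self.history:
                fh.write(f"{row['epoch']}\t{row['train_loss']:.6f}\t"
                         f"{row['val_loss']:.6f}\t{row['val_auc']:.6f}\n")


class _Adam:
    def __init__(self, params: dict, lr: float):
        self.params = params
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * p.grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * p.grad ** 2
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _encode_split(ds: LabeledDataset, tag: str, seq_len: int):
    sub = ds.split_subset(tag)
    if len(sub) == 0:
        return None, None
    return encode_batch(sub.sequences, seq_len), sub.labels


def train(config: ModelConfig, ds: LabeledDataset, *, epochs: int = 20,
          batch_size: int = 16, lr: float = 3e-3, patience: int = 5,
          seed: int = 0) -> TrainResult:
    """Train a model on the ``train`` split, early-stopping on ``val`` loss.

    The dataset must already carry split tags.  Raises ``RuntimeError``
    if the loss turns non-finite (diverged run).
    """
    if not np.any(ds.split == "train"):
        raise ValueError("dataset has no 'train' split tag; run split_dataset first")
    model = Model(config, seed=seed)
    x_train, y_train = _encode_split(ds, "train", config.seq_len)
    x_val, y_val = _encode_split(ds, "val", config.seq_len)
    opt = _Adam(model.params, lr)
    rng = np.random.default_rng(seed)
    history: list[dict] = []
    best_val = np.inf
    best_state = None
    bad_epochs = 0
    n = len(y_train)
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            result = model.forward(x_train[idx])
            loss = model.loss(result, y_train[idx])
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}")
            model.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * len(idx)
        epoch_loss /= n
        if x_val is not None:
            val_res = model.forward(x_val)
            val_loss = model.loss(val_res, y_val).item()
            try:
                val_auc = evaluate_auc(model, ds, "val")["median"]
            except ValueError:
                val_auc = float("nan")
        else:
            val_loss, val_auc = epoch_loss, float("nan")
        history.append({"epoch": epoch, "train_loss": epoch_loss,
                        "val_loss": val_loss, "val_auc": val_auc})
        logger.info("epoch %d train %.4f val %.4f auc %.4f",
                    epoch, epoch_loss, val_loss, val_auc)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = {k: p.data.copy() for k, p in model.params.items()}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= patience:
                logger.info("early stopping at epoch %d", epoch)
                break
    if best_state is not None:
        for k, p in model.params.items():
            p.data = best_state[k]
    return TrainResult(model, history)


def predict_probabilities(model: Model, ds: LabeledDataset,
                          batch_size: int = 256) -> np.ndarray:
    """Predicted probabilities for every example of ``ds`` (in order)."""
    out = []
    x = encode_batch(ds.sequences, model.config.seq_len)
    for start in range(0, len(ds), batch_size):
        res = model.forward(x[start:start + batch_size])
        out.append(res.probabilities(model.config.task))
    return np.concatenate(out)


def evaluate_auc(model: Model, ds: LabeledDataset, split: str = "test",
                 batch_size: int = 256) -> dict:
    """Rank-based ROC AUC on a split; per task plus the median.

    A task whose split contains a single class has no defined AUC and is
    reported as NaN (and excluded from the median).
    """
    sub = ds.split_subset(split)
    if len(sub) == 0:
        raise ValueError(f"split {split!r} is empty")
    probs = predict_probabilities(model, sub, batch_size)
    y = sub.labels
    if y.ndim == 1:
        y2, p2 = y[:, None], probs[:, None]
    else:
        y2, p2 = y, probs
    aucs = []
    for c in range(y2.shape[1]):
        if len(np.unique(y2[:, c])) < 2:
            aucs.append(float("nan"))
        else:
            aucs.append(float(roc_auc_score(y2[:, c], p2[:, c])))
    finite = [a for a in aucs if np.isfinite(a)]
    if not finite:
        raise ValueError(f"no task in split {split!r} has both classes present")
    return {"per_task": aucs, "median": float(np.median(finite))}


def _prediction_precision(y_true: np.ndarray, probs: np.ndarray,
                          cutoff: float) -> float:
    """Precision of the thresholded multi-label prediction for one example."""
    pred = probs > cutoff
    if pred.sum() == 0:
        return 0.0
    return float((y_true[pred] == 1).mean())


def select_confident_examples(model: Model, ds: LabeledDataset,
                              thresholds: ConfidenceThresholds | None = None,
                              split: str = "test"
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Foreground / background example indices (into ``ds``) to interpret.

    Binary task: foreground = positives with P(positive) > p, background
    = negatives with P(positive) < 1 - p.  Multi-label: foreground =
    examples whose prediction precision exceeds the precision threshold;
    the background is empty (built separately by dinucleotide shuffling).
    """
    thresholds = thresholds or ConfidenceThresholds()
    idx = np.flatnonzero(ds.split == split)
    sub = ds.subset(idx)
    probs = predict_probabilities(model, sub)
    if model.config.task == "binary":
        p = thresholds.confidence
        fg = idx[(sub.labels == 1) & (probs > p)]
        bg = idx[(sub.labels == 0) & (probs < 1.0 - p)]
    else:
        prec = np.array([
            _prediction_precision(sub.labels[i], probs[i], thresholds.prob_cutoff)
            for i in range(len(sub))])
        fg = idx[prec > thresholds.precision]
        bg = np.array([], dtype=np.int64)
    if len(fg) == 0:
        logger.warning("no examples passed the confidence threshold")
    return fg, bg


def random_search(base_config: ModelConfig, ds: LabeledDataset,
                  space: dict[str, list], budget: int, seed: int = 0,
                  **train_kwargs) -> tuple[ModelConfig, float, list[dict]]:
    """Uniform random hyperparameter search maximizing validation AUC.

    ``space`` maps ModelConfig field names (filter length, filter count,
    pooling window, attention feature sizes, ...) to candidate value
    lists.  Returns (best config, its val AUC, full trial log).
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if not space or any(len(v) == 0 for v in space.values()):
        raise ValueError("search space must be non-empty")
    rng = np.random.default_rng(seed)
    trials = []
    best = (None, -np.inf)
    for trial in range(budget):
        overrides = {k: v[int(rng.integers(len(v)))] for k, v in space.items()}
        cfg = dataclasses.replace(base_config, **overrides)
        try:
            result = train(cfg, ds, seed=seed + trial, **train_kwargs)
            auc = evaluate_auc(result.model, ds, "val")["median"]
        except (RuntimeError, ValueError) as exc:
            logger.warning("trial %d failed: %s", trial, exc)
            auc = -np.inf
        trials.append({"trial": trial, "config": overrides, "val_auc": auc})
        if auc > best[1]:
            best = (cfg, auc)
    return best[0], best[1], trials
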
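"""Training, fine-tuning and cross-validation of per-organ HN-Net models.

Optimization follows the published recipe: Adam (beta1 = 0.9,
beta2 = 0.999), initial learning rate 0.01 decayed by a factor of 0.8
on a fixed epoch schedule, and the soft "1 - Dice" loss.  Everything is
deterministic given the seed: parameter initialization, the per-epoch
shuffling of the training slices, and batch statistics all derive from
it, so two runs with the same (seed, config, dataset) produce
bit-identical histories and weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, BatchNorm2d, Tensor
from .model import HNNet, ModelConfig, build_model

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TrainingHistory",
    "soft_dice_loss",
    "learning_rate_at",
    "train",
    "fine_tune",
    "crossvalidate",
]

DICE_EPS = 1e-6


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.999
    lr_decay_factor: float = 0.8
    lr_decay_every: int = 10
    epochs: int = 20
    batch_size: int = 8
    drop_empty_slices: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("beta1 and beta2 must lie in (0, 1)")
        if not (0 < self.lr_decay_factor <= 1):
            raise ValueError("lr_decay_factor must lie in (0, 1]")
        if self.lr_decay_every < 1 or self.batch_size < 1:
            raise ValueError("lr_decay_every and batch_size must be >= 1")


@dataclass
class TrainingHistory:
    losses: list[float] = field(default_factory=list)
    learning_rates: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)


def soft_dice_loss(pred: Tensor | np.ndarray, target: np.ndarray,
                   eps: float = DICE_EPS) -> Tensor | float:
    """1 - soft Dice over a batch: 1 - (2*sum(p*t) + eps)/(sum p + sum t + eps).

    Accepts an autodiff Tensor (training path) or a plain array
    (evaluation path); the smoothing constant keeps the loss defined
    when both prediction and target are empty.
    """
    if isinstance(pred, Tensor):
        if pred.shape != target.shape:
            raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
        t = Tensor(np.asarray(target, dtype=np.float64))
        inter = (pred * t).sum()
        return 1.0 - (2.0 * inter + eps) / (pred.sum() + t.sum() + eps)
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    inter = float((pred * target).sum())
    return 1.0 - (2.0 * inter + eps) / (pred.sum() + target.sum() + eps)


def learning_rate_at(epoch: int, config: TrainConfig) -> float:
    """Stepwise-decayed learning rate in force during `epoch` (0-based)."""
    return config.learning_rate * config.lr_decay_factor ** (
        epoch // config.lr_decay_every)


def _stack_dataset(dataset, drop_empty: bool):
    if len(dataset) == 0:
        raise ValueError("dataset must be non-empty")
    slices, masks = [], []
    for sl, mk in dataset:
        mk = np.asarray(mk, dtype=np.float64)
        if drop_empty and mk.sum() == 0:
            continue
        slices.append(np.asarray(sl, dtype=np.float64))
        masks.append(mk)
    if not slices:
        raise ValueError("all slices were empty and drop_empty_slices is set")
    return np.stack(slices), np.stack(masks)


def _run_epochs(model: HNNet, x: np.ndarray, y: np.ndarray,
                config: TrainConfig, optimizer: Adam,
                history: TrainingHistory, rng: np.random.Generator) -> None:
    n = x.shape[0]
    model.train()
    for epoch in range(config.epochs):
        optimizer.lr = learning_rate_at(epoch, config)
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            pred = model(Tensor(x[idx][:, None]))
            loss = soft_dice_loss(pred, y[idx][:, None])
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        mean_loss = epoch_loss / n_batches
        history.losses.append(mean_loss)
        history.learning_rates.append(optimizer.lr)
        logger.info("epoch %d lr %.5f loss %.4f",
                    len(history.losses), optimizer.lr, mean_loss)
    recalibrate_batchnorm(model, x, config.batch_size)
    model.eval()


def recalibrate_batchnorm(model: HNNet, x: np.ndarray,
                          batch_size: int) -> None:
    """Replace batch-norm running statistics with exact statistics of
    the training set ("precise BN").

    Exponential running estimates lag the activations when training is
    short, which degrades inference-mode predictions; one extra
    forward sweep over the data fixes the statistics exactly and keeps
    inference deterministic.
    """
    bns = [m for m in model.modules() if isinstance(m, BatchNorm2d)]
    for bn in bns:
        bn.start_calibration()
    model.train()
    for start in range(0, x.shape[0], batch_size):
        model(Tensor(x[start:start + batch_size][:, None]))
    for bn in bns:
        bn.finish_calibration()
    model.eval()


def train(model: HNNet, dataset, config: TrainConfig):
    """Train on a list of (preprocessed slice, binary mask) pairs.

    Returns (model, TrainingHistory); the model is optimized in place.
    """
    x, y = _stack_dataset(dataset, config.drop_empty_slices)
    optimizer = Adam(model.parameters(), lr=config.learning_rate,
                     beta1=config.beta1, beta2=config.beta2)
    history = TrainingHistory()
    _run_epochs(model, x, y, config, optimizer, history,
                np.random.default_rng(config.seed))
    return model, history


def fine_tune(model: HNNet, base_dataset, added_samples, config: TrainConfig):
    """Continue optimizing trained weights on base data plus new samples.

    Weights are NOT re-initialized; a fresh Adam moment state is created
    for the fine-tuning phase.  Each added sample must carry a mask.
    """
    for item in added_samples:
        if len(item) != 2 or item[1] is None:
            raise ValueError("added samples must be labeled (slice, mask) pairs")
    combined = list(base_dataset) + list(added_samples)
    history = TrainingHistory()
    if config.epochs == 0:
        return model, history
    x, y = _stack_dataset(combined, config.drop_empty_slices)
    optimizer = Adam(model.parameters(), lr=config.learning_rate,
                     beta1=config.beta1, beta2=config.beta2)
    _run_epochs(model, x, y, config, optimizer, history,
                np.random.default_rng(config.seed))
    return model, history


def make_folds(case_ids: list[str], k: int, seed: int) -> list[list[str]]:
    """Deterministic case-level partition into k folds."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(case_ids) < k:
        raise ValueError(f"need at least {k} cases for {k}-fold CV")
    order = list(np.random.default_rng(seed).permutation(sorted(case_ids)))
    return [order[i::k] for i in range(k)]


def crossvalidate(cases: dict, model_config: ModelConfig,
                  train_config: TrainConfig, k: int = 5,
                  threshold: float = 0.5):
    """k-fold cross-validation with case-level splits.

    `cases` maps case_id -> (slices (S, H, W), masks (S, H, W)).  Folds
    never split a case across train and validation, so no slice of a
    validation case leaks into training.  Returns a list of per-fold
    dicts with the fold's case ids and mean validation metrics, plus a
    pooled summary.
    """
    from .metrics import evaluate_case  # local import: avoid cycle

    folds = make_folds(list(cases.keys()), k, train_config.seed)
    fold_reports = []
    for i, val_ids in enumerate(folds):
        train_ids = [cid for f in folds for cid in f if f is not folds[i]]
        dataset = [(sl, mk) for cid in train_ids
                   for sl, mk in zip(*cases[cid])]
        model = build_model(model_config)
        model, history = train(model, dataset, train_config)
        reports = []
        for cid in val_ids:
            slices, masks = cases[cid]
            probs = model.forward_array(np.asarray(slices, dtype=np.float64))
            reports.append(evaluate_case(probs >= threshold,
                                         np.asarray(masks) > 0.5,
                                         case_id=cid))
        fold_reports.append({
            "fold": i,
            "val_cases": list(val_ids),
            "mean_dice": float(np.mean([r.dice for r in reports])),
            "reports": reports,
            "history": history,
        })
    pooled = [r for f in fold_reports for r in f["reports"]]
    summary = {"mean_dice": float(np.mean([r.dice for r in pooled])),
               "n_cases": len(pooled)}
    return fold_reports, summary
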
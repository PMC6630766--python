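"""Training protocol: Dice loss, SGD schedule, folds, best-epoch selection.

The loss is the negative soft Dice coefficient between the predicted
probability map and the binary reference, with a small epsilon in the
denominator so the empty-mask case is defined. Optimisation is SGD with
momentum 0.9 starting at learning rate 0.1, decayed per epoch as
``lr = lr0 / (1 + decay * epoch)`` with ``decay = lr0 / epochs``. Weights
are Xavier-initialised. After every epoch the model is evaluated on the
held-out fold by mean DSC at threshold 0.5, and the best-scoring epoch's
weights are the returned checkpoint (selection on the held-out fold, as in
the original protocol; pass a separate validation set for an unbiased
variant). Five-fold cross-validation shuffles identifiers once, partitions
them into near-equal folds, and averages the fold results.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .metrics import dsc
from .network import NetworkConfig, build_network, predict_proba
from .nn import autodiff as ad
from .records import ImageRecord


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 60
    batch_size: int = 4
    momentum: float = 0.9
    lr0: float = 0.1
    folds: int = 5
    seed: int = 0
    smooth_eps: float = 1e-6
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not self.lr0 > 0:
            raise ValueError("lr0 must be positive")


def dice_loss(p: np.ndarray, g: np.ndarray, smooth_eps: float = 1e-6) -> float:
    """Negative Dice of one probability map against a binary mask.

    ``-2*sum(p*g) / (sum(p) + sum(g) + smooth_eps)``, in [-1, 0].
    """
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    return float(-2.0 * (p * g).sum() / (p.sum() + g.sum() + smooth_eps))


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Closed-form decay ``lr0 / (1 + (lr0/epochs) * epoch)``."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    decay = cfg.lr0 / cfg.epochs
    return cfg.lr0 / (1.0 + decay * epoch)


@dataclass(frozen=True)
class FoldSplit:
    fold_index: int
    test_ids: tuple[str, ...]
    train_ids: tuple[str, ...]


def make_folds(ids: list[str], folds: int, seed: int) -> list[FoldSplit]:
    """Deterministic shuffled partition into near-equal folds.

    Fold sizes differ by at most one (the remainder goes to the first
    folds); each round holds one fold out as the test set.
    """
    ids = list(ids)
    if folds > len(ids):
        raise ValueError(f"cannot make {folds} folds from {len(ids)} ids")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    parts = np.array_split(shuffled, folds)
    splits = []
    for k, part in enumerate(parts):
        test = tuple(part.tolist())
        train = tuple(x for j, p in enumerate(parts) if j != k for x in p.tolist())
        splits.append(FoldSplit(fold_index=k, test_ids=test, train_ids=train))
    return splits


@dataclass
class TrainResult:
    best_state: dict[str, np.ndarray]
    best_epoch: int
    best_dsc: float
    log: pd.DataFrame   # epoch, lr, train_loss, test_dsc
    network_config: NetworkConfig


def _stack(records: list[ImageRecord], target: str) -> tuple[np.ndarray, np.ndarray]:
    imgs = np.stack([r.image for r in records]).astype(nn.DTYPE)
    masks = np.stack([r.mask(target) for r in records]).astype(nn.DTYPE)
    return imgs, masks[:, None]


def evaluate_mean_dsc(model, records: list[ImageRecord], target: str,
                      threshold: float = 0.5, batch_size: int = 4) -> float:
    imgs, masks = _stack(records, target)
    probs = predict_proba(model, imgs, batch_size=batch_size)
    return float(np.mean([dsc(probs[i, 0] >= threshold, masks[i, 0])
                          for i in range(len(records))]))


def train_fold(model, train_records: list[ImageRecord],
               test_records: list[ImageRecord], cfg: TrainConfig,
               target: str = "mf", verbose: bool = False,
               epoch_checkpoint_dir=None) -> TrainResult:
    """Train one model on one fold; return the best-epoch checkpoint + log.

    When ``epoch_checkpoint_dir`` is given, the model state is additionally
    written to ``epoch_<n>.npz`` after every epoch (the per-epoch record
    from which the best model is selected); otherwise only the best state
    is kept, in memory.
    """
    if not train_records:
        raise ValueError("empty training set")
    if epoch_checkpoint_dir is not None:
        from pathlib import Path
        epoch_checkpoint_dir = Path(epoch_checkpoint_dir)
        epoch_checkpoint_dir.mkdir(parents=True, exist_ok=True)
    imgs, masks = _stack(train_records, target)
    opt = nn.SGD(model.parameters(), momentum=cfg.momentum)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    best = (-1.0, -1, None)
    for epoch in range(cfg.epochs):
        lr = lr_schedule(epoch, cfg)
        model.train()
        order = rng.permutation(len(train_records))
        losses = []
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            opt.zero_grad()
            p = model(imgs[idx])
            loss = ad.soft_dice_loss(p, masks[idx], cfg.smooth_eps)
            loss.backward()
            opt.step(lr)
            losses.append(float(loss.data))
        test_dsc = (evaluate_mean_dsc(model, test_records, target,
                                      cfg.threshold, cfg.batch_size)
                    if test_records else float("nan"))
        rows.append({"epoch": epoch, "lr": lr,
                     "train_loss": float(np.mean(losses)),
                     "test_dsc": test_dsc})
        if verbose:
            print(f"epoch {epoch:3d}  lr {lr:.4f}  loss {rows[-1]['train_loss']:+.4f}"
                  f"  test DSC {test_dsc:.4f}")
        if epoch_checkpoint_dir is not None:
            from .io import save_checkpoint
            save_checkpoint(epoch_checkpoint_dir / f"epoch_{epoch:03d}.npz",
                            model.state_dict(), model.cfg.to_dict(),
                            extra={"epoch": epoch, "test_dsc": test_dsc})
        score = test_dsc if test_records else -rows[-1]["train_loss"]
        if score > best[0]:
            best = (score, epoch, copy.deepcopy(model.state_dict()))
    best_state = best[2] if best[2] is not None else model.state_dict()
    return TrainResult(best_state=best_state, best_epoch=best[1],
                       best_dsc=best[0] if test_records else float("nan"),
                       log=pd.DataFrame(rows), network_config=model.cfg)


@dataclass
class CrossValReport:
    fold_results: list[TrainResult]
    fold_dscs: list[float]
    mean_dsc: float
    splits: list[FoldSplit]


def cross_validate(records: list[ImageRecord], net_cfg: NetworkConfig,
                   train_cfg: TrainConfig, target: str = "mf",
                   verbose: bool = False) -> CrossValReport:
    """k-fold cross-validation; one fresh model per round, results averaged.

    No data augmentation and no post-processing are applied.
    """
    by_id = {r.identifier: r for r in records}
    if len(by_id) != len(records):
        raise ValueError("record identifiers must be unique")
    splits = make_folds(list(by_id), train_cfg.folds, train_cfg.seed)
    results, fold_dscs = [], []
    for split in splits:
        model = build_network(net_cfg, seed=train_cfg.seed + split.fold_index)
        res = train_fold(model,
                         [by_id[i] for i in split.train_ids],
                         [by_id[i] for i in split.test_ids],
                         train_cfg, target=target, verbose=verbose)
        results.append(res)
        fold_dscs.append(res.best_dsc)
    return CrossValReport(fold_results=results, fold_dscs=fold_dscs,
                          mean_dsc=float(np.mean(fold_dscs)), splits=splits)
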
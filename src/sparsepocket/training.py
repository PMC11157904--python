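"""Optimization: AdamW, ligand-grouped splitting, the training loop and a
pluggable hyperparameter search driver.

Training minimizes a class-imbalance loss (focal by default, Dice as the
alternative) with AdamW.  Early stopping watches the validation loss;
model selection returns the checkpoint with the best validation PRC-AUC —
the two criteria the published optimization procedure states.  All
randomness (weight init, batch order, the search sampler) flows from one
named seed, so histories reproduce bit-for-bit on a single thread.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol, Sequence

import numpy as np
import pandas as pd

from .losses import dice_loss_with_grad, f1_at_threshold, focal_loss_with_grad, prc_auc
from .network import NetworkSpec, SparseUNet
from .sparse import Parameter, Tape
from .tensorize import SparseProteinTensor, batch

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "AdamW",
    "grouped_split",
    "train",
    "TrainResult",
    "SearchSpace",
    "Sampler",
    "RandomSampler",
    "tune",
]


@dataclass
class TrainingConfig:
    batch_size: int = 2
    learning_rate: float = 1e-3
    loss: str = "focal"  # "focal" or "dice"
    focal_gamma: float = 1.0
    focal_alpha: float = 0.15
    dice_smooth: float = 1.0
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 0.01
    f1_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.loss not in ("focal", "dice"):
            raise ValueError(f"unknown loss {self.loss!r}; choose 'focal' or 'dice'")
        if self.focal_gamma < 0:
            raise ValueError("focal gamma must be non-negative")
        if not 0.0 < self.focal_alpha < 1.0:
            raise ValueError("focal alpha must lie in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be at least 1 epoch")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be positive")

    def loss_fn(self) -> Callable[[np.ndarray, np.ndarray], tuple[float, np.ndarray]]:
        if self.loss == "focal":
            g, a = self.focal_gamma, self.focal_alpha
            return lambda z, y: focal_loss_with_grad(z, y, g, a)
        s = self.dice_smooth
        return lambda z, y: dice_loss_with_grad(z, y, s)


class AdamW:
    """Decoupled weight-decay Adam over a flat parameter list."""

    def __init__(
        self,
        params: Sequence[Parameter],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        weight_decay: float = 0.01,
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr, self.beta1, self.beta2 = lr, beta1, beta2
        self.weight_decay, self.eps = weight_decay, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.data -= self.lr * (
                (m / b1c) / (np.sqrt(v / b2c) + self.eps) + self.weight_decay * p.data
            )

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[:] = 0.0


def grouped_split(
    ligand_ids: dict[str, Sequence[str]],
    fraction: float = 0.8,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Split structures so no ligand id appears on both sides.

    ``ligand_ids`` maps structure id → its ligand identifier(s).  Structures
    sharing any ligand are merged into one group (union-find), groups are
    shuffled deterministically by ``seed`` and assigned greedily so the train
    side lands as close to ``fraction`` as group sizes allow.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    items = sorted(ligand_ids)
    parent = {s: s for s in items}

    def find(a: str) -> str:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    owner: dict[str, str] = {}
    for sid in items:
        for lig in ligand_ids[sid]:
            if lig in owner:
                parent[find(sid)] = find(owner[lig])
            else:
                owner[lig] = sid
    groups: dict[str, list[str]] = {}
    for sid in items:
        groups.setdefault(find(sid), []).append(sid)
    group_list = [groups[k] for k in sorted(groups)]
    if len(group_list) < 2:
        raise ValueError("all structures share one ligand group; split impossible")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(group_list))
    target = fraction * len(items)
    train: list[str] = []
    val: list[str] = []
    for gi in order:
        g = group_list[gi]
        if len(train) < target:
            train.extend(g)
        else:
            val.extend(g)
    if not val:  # greedy overshoot ate everything; move the last group over
        val = group_list[order[-1]]
        train = [s for s in train if s not in set(val)]
    return train, val


@dataclass
class TrainResult:
    best_state: dict[str, np.ndarray]
    history: pd.DataFrame
    best_epoch: int
    best_val_prc_auc: float


def _evaluate(net: SparseUNet, tensors, loss_fn, f1_threshold: float):
    logits_all, labels_all = [], []
    for t in tensors:
        lg = net.forward_logits(t, training=False)
        logits_all.append(lg.feats[:, 0])
        labels_all.append(t.labels.astype(float))
    z = np.concatenate(logits_all)
    y = np.concatenate(labels_all)
    loss, _ = loss_fn(z, y)
    probs = 1.0 / (1.0 + np.exp(-z))
    auc = prc_auc(probs, y) if y.sum() > 0 else 0.0
    return loss, auc, f1_at_threshold(probs, y, f1_threshold)


def train(
    net: SparseUNet,
    train_tensors: Sequence[SparseProteinTensor],
    val_tensors: Sequence[SparseProteinTensor],
    config: TrainingConfig,
) -> TrainResult:
    """Optimize ``net``; returns the best-PRC-AUC checkpoint and the history.

    Per-epoch history records train loss, validation loss, validation
    PRC-AUC and validation F1 (probability threshold ``f1_threshold``).
    Stops after ``patience`` epochs without validation-loss improvement.
    """
    if not train_tensors:
        raise ValueError("empty training set")
    if not val_tensors:
        raise ValueError("empty validation set")
    rng = np.random.default_rng(config.seed)
    loss_fn = config.loss_fn()
    optimizer = AdamW(
        net.parameters(),
        lr=config.learning_rate,
        beta1=config.beta1,
        beta2=config.beta2,
        weight_decay=config.weight_decay,
    )
    rows = []
    best_val_loss = np.inf
    best_auc = -np.inf
    best_state = copy.deepcopy(net.state_arrays())
    best_epoch = 0
    stale = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_tensors))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            tensor = (
                train_tensors[idx[0]]
                if len(idx) == 1
                else batch([train_tensors[i] for i in idx])
            )
            tape = Tape()
            logits = net.forward_logits(tensor, training=True, tape=tape)
            loss, grad = loss_fn(logits.feats[:, 0], tensor.labels.astype(float))
            optimizer.zero_grad()
            tape.backward(logits, grad.reshape(-1, 1))
            optimizer.step()
            epoch_losses.append(loss)
        val_loss, val_auc, val_f1 = _evaluate(
            net, val_tensors, loss_fn, config.f1_threshold
        )
        rows.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)),
                "val_loss": val_loss,
                "val_prc_auc": val_auc,
                "val_f1": val_f1,
            }
        )
        if val_auc > best_auc:
            best_auc = val_auc
            best_state = copy.deepcopy(net.state_arrays())
            best_epoch = epoch
        if val_loss < best_val_loss - 1e-12:
            best_val_loss = val_loss
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                logger.info("early stop at epoch %d (patience %d)", epoch, config.patience)
                break
    return TrainResult(
        best_state=best_state,
        history=pd.DataFrame(rows),
        best_epoch=best_epoch,
        best_val_prc_auc=float(best_auc),
    )


# ---------------------------------------------------------------------------
# hyperparameter search
# ---------------------------------------------------------------------------

@dataclass
class SearchSpace:
    """Ranges explored by the search; the objective is validation PRC-AUC."""

    batch_sizes: tuple[int, ...] = (1, 2, 4)
    learning_rates: tuple[float, float] = (1e-4, 1e-2)  # log-uniform bounds
    widths: tuple[int, ...] = (8, 12, 16)
    block_counts: tuple[int, ...] = (1, 2)
    losses: tuple[str, ...] = ("focal", "dice")
    focal_gammas: tuple[float, ...] = (1.0, 2.0)
    focal_alphas: tuple[float, ...] = (0.1, 0.15, 0.25)

    def __post_init__(self) -> None:
        for name in ("batch_sizes", "widths", "block_counts", "losses"):
            if not getattr(self, name):
                raise ValueError(f"search space field {name} is empty")


class Sampler(Protocol):
    """Suggestion strategy contract: propose configs, observe results."""

    def suggest(self, trial_index: int, space: SearchSpace) -> dict: ...

    def report(self, trial_index: int, config: dict, objective: float) -> None: ...


class RandomSampler:
    """Seeded uniform sampler; the default search strategy."""

    def __init__(self, seed: int = 0):
        self.rng = np.random.default_rng(seed)

    def suggest(self, trial_index: int, space: SearchSpace) -> dict:
        lo, hi = space.learning_rates
        return {
            "batch_size": int(self.rng.choice(space.batch_sizes)),
            "learning_rate": float(np.exp(self.rng.uniform(np.log(lo), np.log(hi)))),
            "width": int(self.rng.choice(space.widths)),
            "blocks": int(self.rng.choice(space.block_counts)),
            "loss": str(self.rng.choice(space.losses)),
            "focal_gamma": float(self.rng.choice(space.focal_gammas)),
            "focal_alpha": float(self.rng.choice(space.focal_alphas)),
        }

    def report(self, trial_index: int, config: dict, objective: float) -> None:
        pass


def tune(
    space: SearchSpace,
    train_tensors: Sequence[SparseProteinTensor],
    val_tensors: Sequence[SparseProteinTensor],
    trials: int,
    sampler: Optional[Sampler] = None,
    epochs_per_trial: int = 10,
    seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Run scaled-down train/eval cycles; return (best config, trial log)."""
    if trials < 1:
        raise ValueError("at least one trial is required")
    sampler = sampler or RandomSampler(seed)
    log = []
    best: tuple[float, dict] = (-np.inf, {})
    for i in range(trials):
        cfg = sampler.suggest(i, space)
        spec = NetworkSpec.reduced(width=cfg["width"], blocks=cfg["blocks"])
        net = SparseUNet(spec, seed=seed + i)
        tconf = TrainingConfig(
            batch_size=cfg["batch_size"],
            learning_rate=cfg["learning_rate"],
            loss=cfg["loss"],
            focal_gamma=cfg["focal_gamma"],
            focal_alpha=cfg["focal_alpha"],
            max_epochs=epochs_per_trial,
            patience=max(1, epochs_per_trial),
            seed=seed + i,
        )
        result = train(net, train_tensors, val_tensors, tconf)
        objective = result.best_val_prc_auc
        sampler.report(i, cfg, objective)
        log.append({**cfg, "trial": i, "val_prc_auc": objective})
        if objective > best[0]:
            best = (objective, cfg)
    return best[1], pd.DataFrame(log)
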
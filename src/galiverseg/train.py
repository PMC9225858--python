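"""Training: logistic cost with weight decay, piecewise learning-rate
schedule, stochastic gradient descent with momentum, and the epoch loop.

Defaults are the reference recipe: 70 epochs, mini-batch 64, momentum 0.9,
L2 regularization 1e-4, initial learning rate 0.01 dropped by a factor of
0.1 every 20 epochs, weights initialized from a zero-mean Gaussian with
sigma = 1e-4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError, DataError
from .network import GaCNN, init_gaussian
from .patches import PatchSet

__all__ = ["TrainConfig", "TrainHistory", "cost", "lr_at", "sgdm_step", "fit"]

logger = logging.getLogger("galiverseg.train")

_EPS = 1e-12


@dataclass(frozen=True)
class TrainConfig:
    max_epochs: int = 70
    batch_size: int = 64
    momentum: float = 0.9
    weight_decay: float = 1e-4
    lr_initial: float = 0.01
    lr_drop_factor: float = 0.1
    lr_drop_period: int = 20
    sigma_init: float = 1e-4
    seed: int = 0
    validation_fraction: float = 0.1

    def validate(self) -> None:
        if self.lr_initial <= 0:
            raise ConfigError("lr_initial must be > 0")
        if not 0.0 <= self.momentum < 1.0:
            raise ConfigError("momentum must lie in [0, 1)")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.max_epochs < 0:
            raise ConfigError("max_epochs must be >= 0")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ConfigError("validation_fraction must lie in (0, 1)")
        if self.lr_drop_period < 1 or not 0 < self.lr_drop_factor <= 1:
            raise ConfigError("invalid learning-rate schedule")


@dataclass
class TrainHistory:
    """One record per completed epoch."""

    records: list[dict] = field(default_factory=list)

    def append(self, **kwargs) -> None:
        self.records.append(dict(kwargs))

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.records)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def cost(probabilities: np.ndarray, labels: np.ndarray,
         model_weights=None, weight_decay: float = 0.0) -> float:
    """Mean negative log-likelihood of the liver class plus an L2 penalty.

    -(1/m) * sum_i [y_i log p1_i + (1 - y_i) log(1 - p1_i)]
    + (weight_decay / 2) * sum w^2, with p1 clipped away from {0, 1}.

    ``model_weights`` may be a mapping or iterable of weight arrays, a
    precomputed sum of squares, or None.
    """
    probabilities = np.asarray(probabilities, dtype=np.float64)
    labels = np.asarray(labels)
    if probabilities.ndim != 2 or probabilities.shape[1] != 2:
        raise DataError("probabilities must be (N, 2)")
    if labels.shape != (probabilities.shape[0],):
        raise DataError("labels must be (N,)")
    if not np.all(np.isin(labels, (0, 1))):
        raise DataError("labels must be in {0, 1}")
    p1 = np.clip(probabilities[:, 1], _EPS, 1.0 - _EPS)
    nll = -np.mean(labels * np.log(p1) + (1 - labels) * np.log(1.0 - p1))
    penalty = 0.0
    if weight_decay and model_weights is not None:
        if np.isscalar(model_weights):
            sq = float(model_weights)
        else:
            arrays = (model_weights.values() if hasattr(model_weights, "values")
                      else model_weights)
            sq = float(sum((np.asarray(w, dtype=np.float64) ** 2).sum()
                           for w in arrays))
        penalty = 0.5 * weight_decay * sq
    return float(nll + penalty)


def lr_at(epoch: int, config: TrainConfig) -> float:
    """Piecewise-constant schedule: lr_initial * factor^floor((e-1)/period)."""
    config.validate()
    if not 1 <= epoch <= config.max_epochs:
        raise ConfigError(f"epoch {epoch} outside [1, {config.max_epochs}]")
    drops = (epoch - 1) // config.lr_drop_period
    return config.lr_initial * config.lr_drop_factor ** drops


def sgdm_step(params: dict, grads: dict, velocity: dict, lr: float,
              momentum: float, weight_decay: float = 0.0) -> tuple[dict, dict]:
    """One SGDM update, in place on the parameter arrays.

    v <- momentum * v - lr * (grad + weight_decay * param); param <- param + v.
    Biases (keys ending '.bias') are excluded from weight decay.
    """
    for name, p in params.items():
        g = grads[name]
        if g.shape != p.shape:
            raise ConfigError(f"gradient/parameter shape mismatch for {name}")
        if not np.all(np.isfinite(g)):
            raise DataError(f"non-finite gradient in {name}")
        effective = g if (weight_decay == 0.0 or name.endswith(".bias")) \
            else g + weight_decay * p
        v = velocity.get(name)
        if v is None:
            v = np.zeros_like(p)
        v = momentum * v - lr * effective
        velocity[name] = v.astype(p.dtype, copy=False)
        p += velocity[name]
    return params, velocity


def _stratified_split(labels: np.ndarray, fraction: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        members = rng.permutation(members)
        n_val = max(1, int(round(fraction * len(members))))
        val_idx.append(members[:n_val])
        train_idx.append(members[n_val:])
    return np.concatenate(train_idx), np.concatenate(val_idx)


def _evaluate(model: GaCNN, patches: np.ndarray, labels: np.ndarray,
              batch: int = 256) -> tuple[float, float]:
    costs, correct = [], 0
    for start in range(0, len(labels), batch):
        probs = model.forward(patches[start:start + batch], train=False)
        y = labels[start:start + batch]
        costs.append(cost(probs, y) * len(y))
        correct += int(np.sum((probs[:, 1] >= 0.5).astype(int) == y))
    return float(np.sum(costs) / len(labels)), correct / len(labels)


def fit(model: GaCNN, patchset: PatchSet, config: TrainConfig,
        checkpoint_dir=None, checkpoint_every: int | None = None
        ) -> tuple[GaCNN, TrainHistory]:
    """Train ``model`` on a labeled patch set under the SGDM recipe.

    Per-epoch shuffling, the validation split and dropout are all
    deterministic in ``config.seed``; two runs from the same initial model
    yield identical parameters and history.
    """
    config.validate()
    if len(patchset) == 0:
        raise DataError("cannot fit on an empty patch set")
    history = TrainHistory()
    if config.max_epochs == 0:
        return model, history

    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 0xF17])
    )
    train_idx, val_idx = _stratified_split(patchset.labels,
                                           config.validation_fraction, rng)
    x_train = patchset.patches[train_idx]
    y_train = patchset.labels[train_idx]
    x_val = patchset.patches[val_idx]
    y_val = patchset.labels[val_idx]

    params = model.parameters()
    velocity: dict = {}
    model.mode = "train"
    for epoch in range(1, config.max_epochs + 1):
        lr = lr_at(epoch, config)
        order = rng.permutation(len(y_train))
        batch_costs = []
        for start in range(0, len(order), config.batch_size):
            sel = order[start:start + config.batch_size]
            xb, yb = x_train[sel], y_train[sel]
            logits = model.forward_logits(xb, train=True)
            shifted = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(shifted)
            probs = e / e.sum(axis=1, keepdims=True)
            batch_costs.append(cost(probs, yb) * len(yb))
            onehot = np.zeros_like(probs)
            onehot[np.arange(len(yb)), yb] = 1.0
            model.backward((probs - onehot) / len(yb))
            params, velocity = sgdm_step(params, model.gradients(), velocity,
                                         lr, config.momentum, config.weight_decay)
        train_cost = float(np.sum(batch_costs) / len(order))
        if config.weight_decay:
            train_cost += 0.5 * config.weight_decay * model.weight_square_sum()
        model.mode = "eval"
        val_cost, val_acc = _evaluate(model, x_val, y_val)
        model.mode = "train"
        ckpt_path = ""
        if checkpoint_dir is not None and checkpoint_every and (
                epoch % checkpoint_every == 0 or epoch == config.max_epochs):
            ckpt_path = str(Path(checkpoint_dir) / f"epoch_{epoch:03d}.npz")
            model.save(ckpt_path, extra={"epoch": epoch, "seed": config.seed})
        logger.info(
            "epoch %d lr=%.6g train_cost=%.6f val_cost=%.6f val_acc=%.4f",
            epoch, lr, train_cost, val_cost, val_acc,
        )
        history.append(epoch=epoch, lr=lr, train_cost=train_cost,
                       val_cost=val_cost, val_acc=val_acc,
                       checkpoint=ckpt_path)
    model.mode = "eval"
    return model, history


def train_from_scratch(patchset: PatchSet, config: TrainConfig,
                       spec=None, **fit_kwargs) -> tuple[GaCNN, TrainHistory]:
    """Initialize a Gaussian-weight GaCNN and fit it in one call."""
    from .network import default_spec

    model = init_gaussian(spec or default_spec(), sigma=config.sigma_init,
                          seed=config.seed)
    return fit(model, patchset, config, **fit_kwargs)
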
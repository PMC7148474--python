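"""Contrastive metric learning for the Siamese network.

The objective on a labeled pair with embedding distance d = D_w(x1, x2) is

    L(d, y) = (y/2) d^2 + ((1-y)/2) max(0, m - d)^2

with margin m > 0: same-species pairs (y=1) are pulled together
quadratically, different-species pairs (y=0) are pushed apart but stop
contributing once their distance exceeds the margin.  The batch loss is
the mean over pairs.  Both twins are the same network object, so a single
backward pass through the concatenated pair batch updates the shared
weights exactly once.

Validation thresholds the learned distance at ``tol`` (0.5 by default):
a pair is predicted same-species when d <= tol, and pair accuracy is the
fraction of agreements with the true labels.  Validation batches are drawn
by the training sampler but without affine augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .model import NetworkHandle, embed_batch
from .pairs import AugmentationConfig, SamplingConfig, as_class_index, augment, make_pair_batch

__all__ = [
    "TrainingConfig",
    "TrainingHistory",
    "contrastive_loss",
    "contrastive_loss_grad",
    "validate_pairs",
    "train_csn",
    "margin_sweep",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the Siamese training loop.

    Defaults follow the reference protocol: margin 1.0, Adam with
    lr = 1e-5, beta1 = 0.9, beta2 = 0.999, 500 epochs, pair batches of 32
    with p_same = 0.3, validation threshold 0.5 over 10 clean batches
    every epoch.  ``batches_per_epoch=None`` means ceil(|T| / batch_size),
    so one epoch sees roughly as many images as the training set holds.
    """

    margin: float = 1.0
    epochs: int = 500
    learning_rate: float = 1e-5
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 32
    p_same: float = 0.3
    batches_per_epoch: int | None = None
    validation_tol: float = 0.5
    validation_batches: int = 10
    validate_every: int = 1
    augmentation: AugmentationConfig | None = field(default_factory=AugmentationConfig)
    seed: int = 0

    def __post_init__(self):
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        if self.validation_tol <= 0:
            raise ValueError("validation_tol must be positive")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("bad epoch or batch count")


@dataclass
class TrainingHistory:
    """Per-epoch training losses and per-validation pair accuracies."""

    train_loss: list[float] = field(default_factory=list)
    val_epochs: list[int] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int | None = None
    best_val_accuracy: float | None = None


def contrastive_loss(d, y, m: float):
    """Elementwise contrastive loss; accepts scalars or arrays.

    Raises on negative distances or a non-positive margin.
    """
    d = np.asarray(d, dtype=np.float64)
    y = np.asarray(y)
    if m <= 0:
        raise ValueError("margin must be positive")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    loss = y / 2.0 * d ** 2 + (1.0 - y) / 2.0 * np.maximum(0.0, m - d) ** 2
    return float(loss) if loss.ndim == 0 else loss


def contrastive_loss_grad(d, y, m: float):
    """dL/dd of the contrastive loss: y*d - (1-y)*max(0, m-d)."""
    d = np.asarray(d, dtype=np.float64)
    y = np.asarray(y)
    g = y * d - (1.0 - y) * np.maximum(0.0, m - d)
    return float(g) if g.ndim == 0 else g


def pair_distances(net: NetworkHandle, batch, train: bool = False):
    """Forward a pair batch through the shared trunk; returns (d, y, e1-e2).

    Both sides of every pair go through the network as one stack, which is
    how the twins share weights by construction.
    """
    x1 = np.stack([p.x1 for p in batch])
    x2 = np.stack([p.x2 for p in batch])
    y = np.array([p.y for p in batch], dtype=np.float64)
    emb = embed_batch(net, np.concatenate([x1, x2]), train=train)
    n = len(batch)
    diff = emb[:n].astype(np.float64) - emb[n:].astype(np.float64)
    d = np.linalg.norm(diff, axis=1)
    return d, y, diff


def pair_accuracy(distances, labels, tol: float) -> float:
    """Fraction of pairs where thresholding d <= tol reproduces the label."""
    d = np.asarray(distances, dtype=np.float64)
    y = np.asarray(labels)
    if d.shape != y.shape or d.size == 0:
        raise ValueError("distances and labels must be equal-length and non-empty")
    return float(((d <= tol).astype(int) == y).mean())


def validate_pairs(net: NetworkHandle, validation_set, tol: float,
                   n_batches: int, rng: np.random.Generator,
                   batch_size: int = 32, p_same: float = 0.3) -> float:
    """Pair accuracy on clean (unaugmented) batches from the validation set.

    Predict same-species when the learned distance is <= tol.
    """
    index = as_class_index(validation_set)
    if not any(index.values()):
        raise ValueError("empty validation set")
    cfg = SamplingConfig(batch_size=batch_size, p_same=p_same)
    accs = []
    for _ in range(n_batches):
        batch = make_pair_batch(index, cfg, rng)
        d, y, _ = pair_distances(net, batch)
        accs.append(pair_accuracy(d, y.astype(int), tol))
    return float(np.mean(accs))


def _train_step(net: NetworkHandle, batch, margin: float, opt: nn.Adam) -> float:
    d, y, diff = pair_distances(net, batch, train=True)
    loss = contrastive_loss(d, y, margin).mean()
    if not np.isfinite(loss):
        raise FloatingPointError(f"non-finite contrastive loss: {loss}")
    n = len(batch)
    coeff = contrastive_loss_grad(d, y, margin) / np.maximum(d, 1e-12) / n
    demb = coeff[:, None] * diff
    dtype = net.trunk.params()[0].dtype
    dout = np.concatenate([demb, -demb]).astype(dtype)
    net.trunk.zero_grad()
    net.trunk.backward(dout)
    opt.step()
    return float(loss)


def train_csn(net: NetworkHandle, train_set, val_set,
              cfg: TrainingConfig) -> tuple[NetworkHandle, TrainingHistory]:
    """Run the Siamese training loop and restore the best-validation weights.

    ``train_set`` and ``val_set`` are class-indexed collections (or lists
    of ImageSamples); they must be disjoint, which the caller guarantees
    through the split protocol.
    """
    train_index = as_class_index(train_set)
    n_train = sum(len(v) for v in train_index.values())
    batches = cfg.batches_per_epoch or max(1, int(np.ceil(n_train / cfg.batch_size)))
    rng = np.random.default_rng(cfg.seed)
    sampling = SamplingConfig(batch_size=cfg.batch_size, p_same=cfg.p_same)
    opt = nn.Adam(net.trunk.params(), net.trunk.grads(), lr=cfg.learning_rate,
                  beta1=cfg.beta1, beta2=cfg.beta2)
    history = TrainingHistory()
    best_state = None
    for epoch in range(cfg.epochs):
        losses = []
        for _ in range(batches):
            batch = make_pair_batch(train_index, sampling, rng)
            if cfg.augmentation is not None:
                for p in batch:
                    p.x1 = augment(p.x1, cfg.augmentation, rng)
                    p.x2 = augment(p.x2, cfg.augmentation, rng)
            losses.append(_train_step(net, batch, cfg.margin, opt))
        history.train_loss.append(float(np.mean(losses)))
        if (epoch + 1) % cfg.validate_every == 0:
            acc = validate_pairs(net, val_set, cfg.validation_tol,
                                 cfg.validation_batches, rng,
                                 batch_size=cfg.batch_size, p_same=cfg.p_same)
            history.val_epochs.append(epoch)
            history.val_accuracy.append(acc)
            if history.best_val_accuracy is None or acc > history.best_val_accuracy:
                history.best_val_accuracy = acc
                history.best_epoch = epoch
                best_state = net.state_dict()
    if best_state is not None:
        net.load_state_dict(best_state)
    return net, history


def margin_sweep(candidates, train_set, val_set, epochs: int,
                 cfg: TrainingConfig, builder=None):
    """Train one CSN per candidate margin and pick the best by pair accuracy.

    Every candidate trains from the same seeded initial weights on the same
    data stream.  Ties break toward the smaller margin.  ``builder`` is a
    zero-argument callable returning a fresh network; it is required so each
    margin starts from identical initialization.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no margin candidates")
    if builder is None:
        raise ValueError("margin_sweep needs a network builder")
    table = []
    for m in candidates:
        net = builder()
        run_cfg = replace(cfg, margin=float(m), epochs=epochs)
        _, hist = train_csn(net, train_set, val_set, run_cfg)
        acc = hist.val_accuracy[-1] if hist.val_accuracy else 0.0
        table.append((float(m), float(acc)))
    best = max(table, key=lambda t: (t[1], -t[0]))[0]
    return best, table
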
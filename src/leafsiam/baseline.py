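"""The softmax CNN baseline the Siamese network is compared against.

Architecturally this is the same trunk as one Siamese twin with a softmax
head over the species, trained with cross-entropy under the same Adam
settings and the same augmentation policy, so the comparison isolates the
learning objective.  Against novel species the baseline must be retrained
with an enlarged head, which is exactly the cost the metric-learning
approach avoids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .model import ArchitectureSpec, NetworkHandle, build_embedding_network, embed_batch
from .pairs import AugmentationConfig, augment
from .training import TrainingHistory

__all__ = [
    "ClassifierConfig",
    "train_classifier",
    "predict_proba",
    "classifier_topk",
    "retrain_with_novel",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Training settings for the softmax baseline.

    Defaults mirror the Siamese run (Adam, lr = 1e-5) except the epoch
    budget, 2000 by default.  No early stopping: the best-validation
    weights are restored after the full run.
    """

    epochs: int = 2000
    learning_rate: float = 1e-5
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 32
    augmentation: AugmentationConfig | None = field(default_factory=AugmentationConfig)
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("bad epoch or batch count")


def _encode(samples, class_labels):
    lut = {c: i for i, c in enumerate(class_labels)}
    bad = {s.species_id for s in samples} - set(lut)
    if bad:
        raise ValueError(f"labels outside the classifier head: {sorted(bad)}")
    x = np.stack([s.image for s in samples])
    y = np.array([lut[s.species_id] for s in samples])
    return x, y


def _forward_logits(net: NetworkHandle, x, train=False):
    if net.head is None:
        raise ValueError("network has no softmax head")
    emb = embed_batch(net, x, train=train)
    return net.head.forward(emb, train=train)


def predict_proba(net: NetworkHandle, images) -> np.ndarray:
    """Class probabilities (softmax over the head) for a stack of images."""
    return nn.softmax(_forward_logits(net, images))


def train_classifier(net: NetworkHandle, train_set, val_set,
                     cfg: ClassifierConfig) -> tuple[NetworkHandle, TrainingHistory]:
    """Minimize cross-entropy over species labels; restore best-val weights."""
    if net.head is None:
        raise ValueError("classifier training needs a network with a softmax head")
    class_labels = net.class_labels or sorted({s.species_id for s in train_set})
    if len(class_labels) != net.head.W.shape[1]:
        raise ValueError(f"head emits {net.head.W.shape[1]} classes but "
                         f"{len(class_labels)} labels were provided")
    net.class_labels = list(class_labels)
    x_train, y_train = _encode(train_set, class_labels)
    x_val, y_val = _encode(val_set, class_labels)
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(net.params(), net.grads(), lr=cfg.learning_rate,
                  beta1=cfg.beta1, beta2=cfg.beta2)
    history = TrainingHistory()
    best_state = None
    n = len(x_train)
    dtype = net.trunk.params()[0].dtype
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = x_train[idx]
            if cfg.augmentation is not None:
                xb = np.stack([augment(img, cfg.augmentation, rng) for img in xb])
            logits = _forward_logits(net, xb, train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, y_train[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite cross-entropy: {loss}")
            net.zero_grad()
            demb = net.head.backward(dlogits.astype(dtype))
            net.trunk.backward(demb)
            opt.step()
            losses.append(loss)
        history.train_loss.append(float(np.mean(losses)))
        probs = predict_proba(net, x_val)
        acc = float((probs.argmax(axis=1) == y_val).mean())
        history.val_epochs.append(epoch)
        history.val_accuracy.append(acc)
        if history.best_val_accuracy is None or acc > history.best_val_accuracy:
            history.best_val_accuracy = acc
            history.best_epoch = epoch
            best_state = net.state_dict()
    if best_state is not None:
        net.load_state_dict(best_state)
    return net, history


def classifier_topk(net: NetworkHandle, test_set, k: int = 1) -> float:
    """Fraction of test images whose label is among the k most probable."""
    if net.class_labels is None:
        raise ValueError("classifier has not been trained (no class labels)")
    test_set = list(test_set)
    x, y = _encode(test_set, net.class_labels)
    probs = predict_proba(net, x)
    topk = np.argsort(-probs, axis=1)[:, :k]
    return float(np.mean([y[i] in topk[i] for i in range(len(y))]))


def retrain_with_novel(net: NetworkHandle, old_train_set, novel_species,
                       cfg: ClassifierConfig, old_val_set=()) -> NetworkHandle:
    """Extend the head to cover novel species and retrain the classifier.

    ``novel_species`` is a list of ``(species_id, images)`` with exactly 3
    images each, split 2 for training / 1 for validation.  The trunk keeps
    its weights; the head is rebuilt (fresh, seeded init) at the enlarged
    class count.
    """
    from .data_io import ImageSample

    old_labels = net.class_labels or sorted({s.species_id for s in old_train_set})
    novel_labels = [sp for sp, _ in novel_species]
    if set(novel_labels) & set(old_labels):
        raise ValueError("novel species overlap the trained classes")
    for sp, imgs in novel_species:
        if len(imgs) != 3:
            raise ValueError(f"novel species {sp} must have exactly 3 images, "
                             f"got {len(imgs)}")
    all_labels = sorted(list(old_labels) + novel_labels)
    spec = replace(net.spec, n_classes=len(all_labels))
    rng = np.random.default_rng(cfg.seed)
    head = nn.Dense(spec.embedding_dim, len(all_labels), rng,
                    dtype=net.trunk.params()[0].dtype)
    net.spec, net.head, net.class_labels = spec, head, all_labels
    train = list(old_train_set)
    val = list(old_val_set)
    for sp, imgs in novel_species:
        train.append(ImageSample(imgs[0], sp, f"novel/{sp}/0"))
        train.append(ImageSample(imgs[1], sp, f"novel/{sp}/1"))
        val.append(ImageSample(imgs[2], sp, f"novel/{sp}/2"))
    if not val:
        raise ValueError("retraining needs at least one validation image")
    net, _ = train_classifier(net, train, val, cfg)
    return net
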
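"""The embedding CNN shared by the Siamese network and the softmax baseline.

The trunk is three convolutional blocks — conv 32@11x11 + ReLU + maxpool,
conv 64@8x8 + ReLU + maxpool, conv 128@5x5 + ReLU — followed by global
average pooling to a 128-vector and a fully connected layer of 1024 ReLU
units.  The 1024-vector is the embedding F_w(x) whose pairwise Euclidean
distances the Siamese training shapes.  A softmax head over ``n_classes``
is attached only for the baseline classifier; the metric-learning model
never has one.

Both Siamese twins are the same ``NetworkHandle``: weight sharing is by
identity, so "mirrored" updates are structural rather than synchronized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn

__all__ = [
    "ArchitectureSpec",
    "NetworkHandle",
    "build_embedding_network",
    "embed",
    "embed_batch",
    "distance",
    "count_trainable_parameters",
    "save_network",
    "load_network",
]

#: conv blocks as (n_filters, kernel_size, has_pool)
DEFAULT_CONV_BLOCKS = ((32, 11, True), (64, 8, True), (128, 5, False))


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of the network, serializable to JSON/YAML."""

    input_height: int = 224
    input_width: int = 224
    input_channels: int = 1
    conv_blocks: tuple[tuple[int, int, bool], ...] = DEFAULT_CONV_BLOCKS
    pool_size: int = 2
    pool_stride: int = 2
    embedding_dim: int = 1024
    n_classes: int | None = None

    def __post_init__(self):
        counts = [self.input_height, self.input_width, self.input_channels,
                  self.pool_size, self.pool_stride, self.embedding_dim]
        if any(int(c) <= 0 for c in counts):
            raise ValueError("all sizes must be positive")
        if self.n_classes is not None and self.n_classes < 1:
            raise ValueError("n_classes must be positive when present")
        if not self.conv_blocks:
            raise ValueError("at least one conv block required")
        for nf, k, _ in self.conv_blocks:
            if nf <= 0 or k <= 0:
                raise ValueError("filter counts and kernel sizes must be positive")
        # normalize to tuples so specs hash/compare by value
        object.__setattr__(self, "conv_blocks",
                           tuple((int(nf), int(k), bool(p)) for nf, k, p in self.conv_blocks))

    def feature_map_sizes(self) -> list[tuple[int, int]]:
        """Spatial size after each block; raises if any kernel/pool does not fit."""
        h, w = self.input_height, self.input_width
        sizes = []
        for nf, k, has_pool in self.conv_blocks:
            if h < k or w < k:
                raise ValueError(
                    f"feature map {h}x{w} too small for {k}x{k} kernel "
                    f"(input {self.input_height}x{self.input_width})")
            h, w = h - k + 1, w - k + 1
            if has_pool:
                h, w = h // self.pool_size, w // self.pool_stride
                if h == 0 or w == 0:
                    raise ValueError("feature map vanished under pooling")
            sizes.append((h, w))
        return sizes

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conv_blocks"] = [list(b) for b in self.conv_blocks]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        d = dict(d)
        d["conv_blocks"] = tuple(tuple(b) for b in d["conv_blocks"])
        return cls(**d)


@dataclass
class NetworkHandle:
    """An instantiated network: shared trunk plus optional softmax head.

    ``class_labels`` records the label order of the softmax head once a
    classifier has been trained, so probabilities map back to species.
    """

    spec: ArchitectureSpec
    trunk: nn.Sequential
    head: nn.Dense | None = None
    class_labels: list | None = None

    def params(self):
        ps = self.trunk.params()
        if self.head is not None:
            ps = ps + self.head.params()
        return ps

    def grads(self):
        gs = self.trunk.grads()
        if self.head is not None:
            gs = gs + self.head.grads()
        return gs

    def zero_grad(self):
        for g in self.grads():
            g[...] = 0

    def state_dict(self):
        return {f"p{i}": p.copy() for i, p in enumerate(self.params())}

    def load_state_dict(self, state):
        params = self.params()
        for i, p in enumerate(params):
            p[...] = state[f"p{i}"]


def build_embedding_network(spec: ArchitectureSpec, seed: int,
                            dtype=np.float32) -> NetworkHandle:
    """Instantiate the CNN described by ``spec`` with seeded He initialization.

    Raises ``ValueError`` when the input is too small for the stacked
    kernels and pools.
    """
    spec.feature_map_sizes()  # validates geometry
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    channels = spec.input_channels
    for nf, k, has_pool in spec.conv_blocks:
        layers.append(nn.Conv2D(channels, nf, k, rng, dtype=dtype))
        layers.append(nn.ReLU())
        if has_pool:
            layers.append(nn.MaxPool2D(spec.pool_size, spec.pool_stride))
        channels = nf
    layers.append(nn.GlobalAvgPool())
    layers.append(nn.Dense(channels, spec.embedding_dim, rng, dtype=dtype))
    layers.append(nn.ReLU())
    head = None
    if spec.n_classes is not None:
        head = nn.Dense(spec.embedding_dim, spec.n_classes, rng, dtype=dtype)
    return NetworkHandle(spec=spec, trunk=nn.Sequential(layers), head=head)


def _as_batch(net: NetworkHandle, images) -> np.ndarray:
    x = np.asarray(images)
    if x.ndim == 2:
        x = x[None]
    if x.ndim == 3:
        x = x[..., None]
    s = net.spec
    if x.shape[1:] != (s.input_height, s.input_width, s.input_channels):
        raise ValueError(
            f"image shape {x.shape[1:]} does not match spec "
            f"({s.input_height}, {s.input_width}, {s.input_channels})")
    return x.astype(net.trunk.params()[0].dtype, copy=False)


def embed_batch(net: NetworkHandle, images, train: bool = False) -> np.ndarray:
    """Embeddings for a stack of images, shape (n, embedding_dim)."""
    return net.trunk.forward(_as_batch(net, images), train=train)


def embed(net: NetworkHandle, image: np.ndarray) -> np.ndarray:
    """F_w(x): the 1024-dim (by default) feature vector of one image."""
    if np.asarray(image).ndim not in (2, 3):
        raise ValueError("embed expects a single image")
    return embed_batch(net, image)[0]


def distance(e1: np.ndarray, e2: np.ndarray) -> float:
    """Euclidean distance between two embeddings, D_w = ||F_w(x1) - F_w(x2)||."""
    e1, e2 = np.asarray(e1), np.asarray(e2)
    if e1.shape != e2.shape:
        raise ValueError(f"embedding length mismatch: {e1.shape} vs {e2.shape}")
    return float(np.linalg.norm(e1.astype(np.float64) - e2.astype(np.float64)))


def count_trainable_parameters(net: NetworkHandle) -> int:
    """Total number of weight and bias entries (conv + FC + optional head)."""
    return int(sum(p.size for p in net.params()))


def save_network(net: NetworkHandle, path) -> None:
    """Checkpoint as ``.npz`` with the architecture spec embedded as JSON."""
    meta = {"spec": net.spec.to_dict(), "class_labels": net.class_labels}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **net.state_dict())


def load_network(path) -> NetworkHandle:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    net = build_embedding_network(ArchitectureSpec.from_dict(meta["spec"]), seed=0)
    net.load_state_dict(state)
    net.class_labels = meta.get("class_labels")
    return net
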
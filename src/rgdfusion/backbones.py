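"""The five convolutional feature extractors.

Each family keeps its defining motif -- AlexNet a plain conv stack with large
first-layer receptive field and dense layers, VGG deep 3x3 stacks, ResNet
residual skips, AttentionNet attention-masked residual trunks, GoogLeNet
multi-scale inception branches -- and every network ends in a learned linear
projection to a common ``feature_dim`` so the GCN sees dimension-aligned node
features.  The 8-slice depth is absorbed by a 3D convolution in the first
block (kernel and stride cover the full depth), after which the maps are
planar.

``scale="tiny"`` is the desk-scale default used throughout the tests;
``scale="full"`` widens and deepens every family.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._seeding import derive_seed, rng_for
from .heads import FocalParams, focal_loss_tensor
from .nn import (
    Adam,
    Conv3d,
    Dense,
    Flatten,
    GlobalAvgPool,
    MaxPool2d,
    Module,
    Sequential,
    Tensor,
    concat,
    relu,
    sigmoid,
)

__all__ = [
    "BACKBONE_NAMES",
    "BackboneSpec",
    "BackboneOutput",
    "OptimizerConfig",
    "Backbone",
    "build_backbone",
    "train_backbone",
]

BACKBONE_NAMES = ("alexnet", "vgg13", "resnet34", "attention56", "googlenet")

INPUT_SHAPE = (8, 128, 128)  # (z, y, x)


@dataclass(frozen=True)
class BackboneSpec:
    name: str = "resnet34"
    scale: str = "tiny"
    feature_dim: int = 256
    input_shape: tuple[int, int, int] = INPUT_SHAPE

    def validate(self) -> None:
        if self.name not in BACKBONE_NAMES:
            raise KeyError(
                f"unknown backbone {self.name!r}; registry: {BACKBONE_NAMES}"
            )
        if self.scale not in ("tiny", "full"):
            raise ValueError("scale must be 'tiny' or 'full'")
        if self.feature_dim < 8:
            raise ValueError("feature_dim must be >= 8")


@dataclass
class BackboneOutput:
    """Per-sample backbone products: feature vector, probability, hard call."""

    features: np.ndarray
    probability: np.ndarray
    hard_prediction: np.ndarray


@dataclass(frozen=True)
class OptimizerConfig:
    """Adam settings; defaults follow the training recipe (lr 1e-4,
    weight decay 1e-4, at most 100 epochs)."""

    lr: float = 1e-4
    weight_decay: float = 1e-4
    max_epochs: int = 100
    batch_size: int = 32


class _ResBlock(Module):
    def __init__(self, c: int, rng):
        self.c1 = Conv3d(c, c, (1, 3, 3), rng, padding=(0, 1, 1))
        self.c2 = Conv3d(c, c, (1, 3, 3), rng, padding=(0, 1, 1))

    def forward(self, x):
        h = relu(self.c1(x))
        h = self.c2(h)
        return relu(h + x)


class _Inception(Module):
    """Parallel 1x1 / 3x3 / 5x5 / projection branches, channel-concatenated."""

    def __init__(self, c_in: int, b1: int, b3: int, b5: int, bp: int, rng):
        self.p1 = Conv3d(c_in, b1, (1, 1, 1), rng)
        self.p3a = Conv3d(c_in, max(b3 // 2, 2), (1, 1, 1), rng)
        self.p3b = Conv3d(max(b3 // 2, 2), b3, (1, 3, 3), rng, padding=(0, 1, 1))
        self.p5a = Conv3d(c_in, max(b5 // 2, 2), (1, 1, 1), rng)
        self.p5b = Conv3d(max(b5 // 2, 2), b5, (1, 5, 5), rng, padding=(0, 2, 2))
        self.pp = Conv3d(c_in, bp, (1, 1, 1), rng)
        self.out_channels = b1 + b3 + b5 + bp

    def forward(self, x):
        a = relu(self.p1(x))
        b = relu(self.p3b(relu(self.p3a(x))))
        c = relu(self.p5b(relu(self.p5a(x))))
        d = relu(self.pp(x))
        return concat([a, b, c, d], axis=1)


class _AttentionBlock(Module):
    """Residual trunk modulated by a learned soft mask: out = trunk * (1+M)."""

    def __init__(self, c: int, rng):
        self.trunk = _ResBlock(c, rng)
        self.mask = Conv3d(c, c, (1, 3, 3), rng, padding=(0, 1, 1))

    def forward(self, x):
        t = self.trunk(x)
        m = sigmoid(self.mask(x))
        return t * (1.0 + m)


class Backbone(Module):
    """body -> feature projection (F_i) -> linear classifier (probability)."""

    def __init__(self, spec: BackboneSpec, body: Module, body_out: int, rng):
        self.spec = spec
        self.body = body
        self.proj = Dense(body_out, spec.feature_dim, rng)
        self.classifier = Dense(spec.feature_dim, 1, rng)

    def forward_features(self, x: Tensor) -> Tensor:
        return relu(self.proj(self.body(x)))

    def forward(self, x: Tensor) -> Tensor:
        """Malignancy probability, shape (B,)."""
        f = self.forward_features(x)
        logit = self.classifier(f)
        return sigmoid(logit.reshape(logit.shape[0]))

    # -- inference-mode numpy API ------------------------------------------

    def apply(self, volumes: np.ndarray, batch_size: int = 32) -> BackboneOutput:
        """Run the extractor on (n, 8, 128, 128) volumes without tracking
        gradients; deterministic."""
        volumes = _as_batch(volumes)
        feats, probs = [], []
        for i in range(0, volumes.shape[0], batch_size):
            x = Tensor(volumes[i : i + batch_size, None])
            f = self.forward_features(x)
            p = sigmoid(self.classifier(f).reshape(f.shape[0]))
            feats.append(f.data.copy())
            probs.append(p.data.copy())
        features = np.concatenate(feats)
        probability = np.concatenate(probs)
        return BackboneOutput(
            features=features,
            probability=probability,
            hard_prediction=(probability >= 0.5).astype(int),
        )


def _as_batch(volumes) -> np.ndarray:
    if isinstance(volumes, (list, tuple)):
        volumes = np.stack(
            [v.voxels if hasattr(v, "voxels") else np.asarray(v) for v in volumes]
        )
    volumes = np.asarray(volumes, dtype=np.float32)
    if volumes.ndim == 3:
        volumes = volumes[None]
    return volumes


def _widths(scale: str) -> dict:
    if scale == "tiny":
        return {
            "stem": {"alexnet": 12, "vgg13": 8, "resnet34": 16,
                     "attention56": 16, "googlenet": 16},
            "mult": 1,
        }
    return {
        "stem": {"alexnet": 48, "vgg13": 32, "resnet34": 64,
                 "attention56": 64, "googlenet": 64},
        "mult": 4,
    }


def build_backbone(spec: BackboneSpec, seed: int = 0) -> Backbone:
    """Instantiate a trainable extractor with deterministic initialisation."""
    spec.validate()
    rng = rng_for(seed, "backbone", spec.name, spec.scale, spec.feature_dim)
    w = _widths(spec.scale)
    c0 = w["stem"][spec.name]
    m = w["mult"]
    stem = [
        Conv3d(1, c0, (8, 8, 8), rng, stride=(8, 8, 8)),  # (B,c0,1,16,16)
        relu,
    ]
    if spec.name == "alexnet":
        body = Sequential(
            *stem,
            Conv3d(c0, 24 * m, (1, 3, 3), rng, padding=(0, 1, 1)),
            relu,
            MaxPool2d(),
            Conv3d(24 * m, 32 * m, (1, 3, 3), rng, padding=(0, 1, 1)),
            relu,
            MaxPool2d(),
            Flatten(),
            Dense(32 * m * 16, 64 * m, rng),
            relu,
        )
        body_out = 64 * m
    elif spec.name == "vgg13":
        body = Sequential(
            *stem,
            Conv3d(c0, 16 * m, (1, 3, 3), rng, padding=(0, 1, 1)),
            relu,
            Conv3d(16 * m, 16 * m, (1, 3, 3), rng, padding=(0, 1, 1)),
            relu,
            MaxPool2d(),
            Conv3d(16 * m, 24 * m, (1, 3, 3), rng, padding=(0, 1, 1)),
            relu,
            Conv3d(24 * m, 24 * m, (1, 3, 3), rng, padding=(0, 1, 1)),
            relu,
            MaxPool2d(),
            Flatten(),
        )
        body_out = 24 * m * 16
    elif spec.name == "resnet34":
        body = Sequential(
            *stem,
            _ResBlock(c0, rng),
            MaxPool2d(),
            Conv3d(c0, 24 * m, (1, 1, 1), rng),
            relu,
            _ResBlock(24 * m, rng),
            MaxPool2d(),
            GlobalAvgPool(),
        )
        body_out = 24 * m
    elif spec.name == "attention56":
        body = Sequential(
            *stem,
            _AttentionBlock(c0, rng),
            MaxPool2d(),
            _ResBlock(c0, rng),
            MaxPool2d(),
            GlobalAvgPool(),
        )
        body_out = c0
    else:  # googlenet
        inc1 = _Inception(c0, 6 * m, 10 * m, 4 * m, 4 * m, rng)
        inc2 = _Inception(inc1.out_channels, 8 * m, 14 * m, 6 * m, 4 * m, rng)
        body = Sequential(
            *stem,
            inc1,
            MaxPool2d(),
            inc2,
            MaxPool2d(),
            GlobalAvgPool(),
        )
        body_out = inc2.out_channels
    return Backbone(spec, body, body_out, rng)


def train_backbone(
    extractor: Backbone,
    volumes,
    labels,
    loss: FocalParams = FocalParams(),
    optimizer: OptimizerConfig = OptimizerConfig(),
    epochs: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Train with focal loss + Adam; returns training-set hard predictions.

    ``epochs`` overrides ``optimizer.max_epochs`` (0 leaves the model at its
    initialisation).  Requires both classes in the training set.
    """
    X = _as_batch(volumes)
    y = np.asarray(labels, dtype=np.float32)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    n_epochs = optimizer.max_epochs if epochs is None else epochs
    opt = Adam(
        extractor.parameters(),
        lr=optimizer.lr,
        weight_decay=optimizer.weight_decay,
    )
    rng = rng_for(seed, "train-backbone", extractor.spec.name)
    n = X.shape[0]
    for _ in range(n_epochs):
        order = rng.permutation(n)
        for i in range(0, n, optimizer.batch_size):
            idx = order[i : i + optimizer.batch_size]
            xb = Tensor(X[idx, None])
            prob = extractor.forward(xb)
            L = focal_loss_tensor(y[idx], prob, loss)
            opt.zero_grad()
            L.backward()
            opt.step()
    return extractor.apply(X).hard_prediction
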
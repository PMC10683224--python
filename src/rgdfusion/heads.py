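"""Focal loss, fusion heads and the accuracy-weighted ensemble.

After the five backbones are trained, each model gets a *fusion head*: a
classifier over the concatenation of its own feature vector F_i, the
radiomics vector FR and the GCN-fused vector FG.  The heads and the shared
GCN weights are optimised jointly with focal loss (backbone trunks stay
frozen).  The per-head probabilities are finally combined with weights
proportional to each fused model's validation accuracy:
W_i = Acc_i / sum_j Acc_j and P = sum_i W_i * P_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeding import rng_for
from .graph_fusion import GCNParams, gcn_forward_t, normalize_adjacency
from .nn import Adam, Dense, Module, Tensor, concat, sigmoid

__all__ = [
    "FocalParams",
    "focal_loss",
    "focal_loss_tensor",
    "EnsembleWeights",
    "ensemble_weights",
    "ensemble_predict",
    "FusionModel",
    "finetune_heads",
]

_EPS = 1e-7


@dataclass(frozen=True)
class FocalParams:
    """Focal-loss hyperparameters; alpha 0.25, gamma 2 by default."""

    alpha: float = 0.25
    gamma: float = 2.0

    def validate(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


def focal_loss(y, y_prob, params: FocalParams = FocalParams()) -> float:
    """Mean focal loss (natural log) over a batch.

    y = 1: -alpha * (1 - p)^gamma * log(p);
    y = 0: -(1 - alpha) * p^gamma * log(1 - p).
    Probabilities are clamped to [1e-7, 1 - 1e-7].
    """
    params.validate()
    y = np.atleast_1d(np.asarray(y, dtype=np.float64))
    p = np.clip(np.atleast_1d(np.asarray(y_prob, dtype=np.float64)), _EPS, 1 - _EPS)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must have equal length")
    if np.any((y != 0) & (y != 1)):
        raise ValueError("labels must be 0 or 1")
    a, g = params.alpha, params.gamma
    pos = -a * (1 - p) ** g * np.log(p)
    neg = -(1 - a) * p**g * np.log(1 - p)
    return float(np.mean(y * pos + (1 - y) * neg))


def focal_loss_tensor(y: np.ndarray, prob: Tensor,
                      params: FocalParams = FocalParams()) -> Tensor:
    """Differentiable focal loss on a probability Tensor (training path)."""
    from .nn import clip

    params.validate()
    y = np.asarray(y, dtype=np.float32)
    p = clip(prob, _EPS, 1.0 - _EPS)
    a, g = params.alpha, params.gamma
    one_m_p = 1.0 - p
    pos = -a * one_m_p.pow_const(g) * p.log()
    neg = -(1.0 - a) * p.pow_const(g) * one_m_p.log()
    return (Tensor(y) * pos + Tensor(1.0 - y) * neg).mean()


# ---------------------------------------------------------------------------
# ensemble


@dataclass(frozen=True)
class EnsembleWeights:
    weights: tuple[float, ...]
    accuracies: tuple[float, ...]


def ensemble_weights(accuracies) -> EnsembleWeights:
    """Accuracy-proportional weights W_i = Acc_i / sum_j Acc_j."""
    acc = np.asarray(accuracies, dtype=np.float64)
    if acc.size < 1:
        raise ValueError("need at least one accuracy")
    if np.any((acc < 0) | (acc > 1)):
        raise ValueError("accuracies must lie in [0, 1]")
    total = acc.sum()
    if total <= 0:
        raise ValueError("accuracies must not all be zero")
    w = acc / total
    return EnsembleWeights(weights=tuple(w.tolist()), accuracies=tuple(acc.tolist()))


def ensemble_predict(probs, weights: EnsembleWeights):
    """Weighted-average probability P = sum_i W_i * P_i.

    ``probs`` is (n_models,) for one sample or (n_models, n) for a batch.
    """
    p = np.asarray(probs, dtype=np.float64)
    w = np.asarray(weights.weights)
    if p.shape[0] != w.size:
        raise ValueError("probability/weight length mismatch")
    out = np.tensordot(w, p, axes=(0, 0))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# fusion heads


class FusionModel(Module):
    """Shared GCN weights plus one linear head per backbone.

    The radiomics block is z-scored with training-set statistics (constant
    columns pass through as zeros) before entering the heads.
    """

    def __init__(self, n_models: int, feature_dim: int, fr_dim: int,
                 gcn_hidden: int, gcn_out: int, adjacency: np.ndarray,
                 seed: int = 0):
        rng = rng_for(seed, "fusion-heads")
        self.n_models = n_models
        self.feature_dim = feature_dim
        self.S = normalize_adjacency(adjacency).astype(np.float32)
        self.w0 = Tensor(
            rng.normal(0, np.sqrt(2.0 / feature_dim),
                       (feature_dim, gcn_hidden)).astype(np.float32),
            requires_grad=True,
        )
        self.w1 = Tensor(
            rng.normal(0, np.sqrt(2.0 / gcn_hidden),
                       (gcn_hidden, gcn_out)).astype(np.float32),
            requires_grad=True,
        )
        fg_dim = n_models * gcn_out
        self.heads = [
            Dense(feature_dim + fr_dim + fg_dim, 1, rng) for _ in range(n_models)
        ]
        self.fr_mean = np.zeros(fr_dim, dtype=np.float32)
        self.fr_std = np.ones(fr_dim, dtype=np.float32)

    def fit_fr_scaler(self, fr: np.ndarray) -> None:
        self.fr_mean = fr.mean(axis=0).astype(np.float32)
        sd = fr.std(axis=0)
        sd[sd < 1e-12] = 1.0
        self.fr_std = sd.astype(np.float32)

    def _scale_fr(self, fr: np.ndarray) -> np.ndarray:
        return (np.asarray(fr, dtype=np.float32) - self.fr_mean) / self.fr_std

    def gcn_params(self) -> GCNParams:
        return GCNParams(w0=self.w0.data.astype(np.float64),
                         w1=self.w1.data.astype(np.float64))

    def forward_probs(self, features: np.ndarray, fr: np.ndarray) -> list[Tensor]:
        """Per-head probability tensors for a batch.

        ``features`` is (n, n_models, feature_dim); ``fr`` is (n, fr_dim).
        """
        h0 = Tensor(np.asarray(features, dtype=np.float32))
        fg = gcn_forward_t(h0, self.S, self.w0, self.w1)
        fr_t = Tensor(self._scale_fr(fr))
        probs = []
        for i, head in enumerate(self.heads):
            f_i = Tensor(np.ascontiguousarray(features[:, i, :], dtype=np.float32))
            inp = concat([f_i, fr_t, fg], axis=1)
            logit = head(inp)
            probs.append(sigmoid(logit.reshape(logit.shape[0])))
        return probs

    def predict(self, features: np.ndarray, fr: np.ndarray) -> np.ndarray:
        """(n_models, n) fused per-model probabilities, inference mode."""
        probs = self.forward_probs(np.asarray(features), np.asarray(fr))
        return np.stack([p.data.copy() for p in probs])


def finetune_heads(
    features: np.ndarray,
    fr: np.ndarray,
    adjacency: np.ndarray,
    labels,
    loss: FocalParams = FocalParams(),
    gcn_hidden: int = 64,
    gcn_out: int = 32,
    epochs: int = 30,
    lr: float = 1e-3,
    weight_decay: float = 1e-4,
    batch_size: int = 64,
    seed: int = 0,
) -> FusionModel:
    """Jointly optimise the N fusion heads and the shared GCN weights.

    ``features`` is (n, n_models, feature_dim) of frozen backbone features,
    ``fr`` the (n, fr_dim) radiomics block (may be all-zero, which reduces
    each head to a probe on [F_i, FG]).
    """
    features = np.asarray(features, dtype=np.float32)
    fr = np.asarray(fr, dtype=np.float32)
    y = np.asarray(labels, dtype=np.float32)
    if features.ndim != 3:
        raise ValueError("features must be (n, n_models, feature_dim)")
    if fr.shape[0] != features.shape[0] or y.shape[0] != features.shape[0]:
        raise ValueError("features, radiomics and labels must align")
    n, n_models, feature_dim = features.shape
    model = FusionModel(
        n_models, feature_dim, fr.shape[1], gcn_hidden, gcn_out,
        adjacency, seed=seed,
    )
    model.fit_fr_scaler(fr)
    opt = Adam(model.parameters(), lr=lr, weight_decay=weight_decay)
    rng = rng_for(seed, "finetune-heads")
    for _ in range(epochs):
        order = rng.permutation(n)
        for i in range(0, n, batch_size):
            idx = order[i : i + batch_size]
            probs = model.forward_probs(features[idx], fr[idx])
            losses = [focal_loss_tensor(y[idx], p, loss) for p in probs]
            total = losses[0]
            for L in losses[1:]:
                total = total + L
            total = total * (1.0 / len(losses))
            opt.zero_grad()
            total.backward()
            opt.step()
    return model
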
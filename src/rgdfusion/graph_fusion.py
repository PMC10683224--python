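"""Model-divergence graph and GCN feature fusion.

The five backbone feature vectors of one nodule are the nodes of a small
graph.  The edge weight between models i and j is their *divergence*
1 - similarity(i, j), where similarity is the fraction of training samples on
which the two models emit the same hard prediction.  A two-layer GCN with the
symmetrically normalised propagation matrix D^{-1/2} (A + I) D^{-1/2} mixes
the node features; the fused vector FG concatenates the five node outputs of
the last layer.

Adjacency variants (ablation):

* ``a1s`` (default) - divergence weights, zero diagonal;
* ``as``  - similarity weights, zero diagonal;
* ``a1``  - all-ones (complete graph);
* ``a0``  - all-zeros off-diagonal (no message passing beyond self-loops).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeding import rng_for
from .nn import Tensor

__all__ = [
    "ADJACENCY_VARIANTS",
    "GCNParams",
    "ModelGraph",
    "model_similarity",
    "build_adjacency",
    "normalize_adjacency",
    "gcn_forward",
    "init_gcn_params",
]

ADJACENCY_VARIANTS = ("a0", "a1", "as", "a1s")
_ALIASES = {"a-0": "a0", "a-1": "a1", "a-s": "as", "a-1-s": "a1s"}


def _canon_variant(variant: str) -> str:
    v = variant.lower()
    v = _ALIASES.get(v, v)
    if v not in ADJACENCY_VARIANTS:
        raise ValueError(f"unknown adjacency variant {variant!r}; "
                         f"choose from {ADJACENCY_VARIANTS}")
    return v


def model_similarity(preds_i, preds_j) -> float:
    """Agreement fraction of two models' hard predictions on the train set."""
    a = np.asarray(preds_i)
    b = np.asarray(preds_j)
    if a.size == 0 or a.shape != b.shape:
        raise ValueError("prediction lists must be nonempty and equal length")
    return float((a == b).mean())


def build_adjacency(all_preds, variant: str = "a1s") -> np.ndarray:
    """Adjacency over models from their training-set hard predictions.

    ``all_preds`` is a sequence of N equal-length prediction arrays, one per
    model.  Returned matrix is symmetric with entries in [0, 1] and zero
    diagonal for the ``as`` / ``a1s`` variants.
    """
    variant = _canon_variant(variant)
    n = len(all_preds)
    if n < 2:
        raise ValueError("need at least two models")
    if variant == "a0":
        return np.zeros((n, n))
    if variant == "a1":
        return np.ones((n, n))
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = model_similarity(all_preds[i], all_preds[j])
            A[i, j] = A[j, i] = s if variant == "as" else 1.0 - s
    return A


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric GCN propagation matrix D^{-1/2} (A + I) D^{-1/2}.

    Self-loops are added before degree normalisation, so the all-zero
    adjacency maps to the identity.
    """
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if np.any(A < 0):
        raise ValueError("adjacency entries must be nonnegative")
    At = A + np.eye(A.shape[0])
    d = At.sum(axis=1)
    dinv = 1.0 / np.sqrt(d)
    return dinv[:, None] * At * dinv[None, :]


@dataclass
class GCNParams:
    """Two-layer GCN weights; widths default 256 -> 256 -> 128."""

    w0: np.ndarray
    w1: np.ndarray

    @property
    def widths(self) -> tuple[int, int, int]:
        return (self.w0.shape[0], self.w0.shape[1], self.w1.shape[1])


def init_gcn_params(
    feature_dim: int = 256,
    hidden: int = 256,
    out: int = 128,
    seed: int = 0,
) -> GCNParams:
    rng = rng_for(seed, "gcn-init")
    w0 = rng.normal(0, np.sqrt(2.0 / feature_dim), (feature_dim, hidden))
    w1 = rng.normal(0, np.sqrt(2.0 / hidden), (hidden, out))
    return GCNParams(w0=w0.astype(np.float64), w1=w1.astype(np.float64))


@dataclass
class ModelGraph:
    """Per-sample node features plus the fold-level adjacency.

    ``node_features`` is (n_models, feature_dim) for a single sample or
    (batch, n_models, feature_dim) for a batch.
    """

    node_features: np.ndarray
    adjacency: np.ndarray
    variant: str = "a1s"


def gcn_forward(graph: ModelGraph, params: GCNParams) -> np.ndarray:
    """Fused features FG: two propagation layers, ReLU after each, node rows
    of the last layer concatenated.

    Returns (n_models * out_width,) for a single sample, or a batch thereof.
    """
    H0 = np.asarray(graph.node_features, dtype=np.float64)
    single = H0.ndim == 2
    if single:
        H0 = H0[None]
    n_models = H0.shape[1]
    if graph.adjacency.shape != (n_models, n_models):
        raise ValueError("adjacency and node feature dimensions disagree")
    if H0.shape[2] != params.w0.shape[0]:
        raise ValueError("node feature width does not match W0")
    S = normalize_adjacency(graph.adjacency)
    H1 = np.maximum(S @ H0 @ params.w0, 0.0)
    H2 = np.maximum(S @ H1 @ params.w1, 0.0)
    fg = H2.reshape(H2.shape[0], -1)
    return fg[0] if single else fg


def gcn_forward_t(h0: Tensor, S: np.ndarray, w0: Tensor, w1: Tensor) -> Tensor:
    """Differentiable GCN forward used during joint head/GCN training.

    ``h0`` is (batch, n_models, feature_dim); ``S`` the fixed propagation
    matrix.  Returns FG as (batch, n_models * out_width).
    """
    from .nn import relu

    St = Tensor(S.astype(np.float32))
    h1 = relu(St @ h0 @ w0)
    h2 = relu(St @ h1 @ w1)
    return h2.reshape(h2.shape[0], -1)
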
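"""Graph convolutional coordinate regressor.

One consolidate-update graph convolution followed by a four-layer MLP
maps node embeddings and the balanced contact graph to xyz coordinates:

    C(x_i) = sum_{j in N(i)} e_ij x_j / sum_{j in N(i)} e_ij      (consolidate)
    x'_i   = W1 x_i + W2 C(x_i)                                   (update)

then x'_i passes through ReLU and a ReLU-MLP with a linear 3-unit
output.  Every parameter is shared across nodes, so a trained parameter
set applies to a graph of any node count — this N-independence is what
makes stored models transferable across maps.  The neighborhood N(i)
is {j != i : e_ij > 0} on the balanced matrix; self-information enters
only through the W1 x_i term.

The network is small enough that forward and backward passes are
written directly in numpy; :func:`backward` returns exact analytic
gradients used by the Adam loop in :mod:`hicstruct.train`.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .embedding import EmbeddingMatrix
from .io import Structure
from .preprocess import NormalizedMap

__all__ = [
    "GCNNParams",
    "init_params",
    "consolidate",
    "consolidate_all",
    "update",
    "forward",
    "forward_coords",
    "backward",
    "aggregation_matrix",
    "save_params",
    "load_params",
]


@dataclasses.dataclass
class GCNNParams:
    """Learnable parameters: graph-layer matrices plus MLP weights/biases.

    ``w1`` and ``w2`` are E x E and bias-free; the MLP has layer widths
    E -> h1 -> h2 -> h3 -> 3 with biases.  Layer matrices are stored
    row-as-output (``h = relu(W @ x + b)`` per node).
    """

    w1: np.ndarray
    w2: np.ndarray
    mlp_w: list  # four matrices: h1xE, h2xh1, h3xh2, 3xh3
    mlp_b: list  # four bias vectors
    graph_relu: bool = True

    @property
    def e_dim(self) -> int:
        return self.w1.shape[0]

    def copy(self) -> "GCNNParams":
        return GCNNParams(
            self.w1.copy(),
            self.w2.copy(),
            [w.copy() for w in self.mlp_w],
            [b.copy() for b in self.mlp_b],
            self.graph_relu,
        )

    def as_dict(self) -> dict:
        d = {"w1": self.w1, "w2": self.w2}
        for k, (w, b) in enumerate(zip(self.mlp_w, self.mlp_b)):
            d[f"mw{k}"] = w
            d[f"mb{k}"] = b
        return d


def init_params(
    e_dim: int, hidden: tuple = (256, 128, 64), seed: int = 0, graph_relu: bool = True
) -> GCNNParams:
    """Seeded Glorot-uniform initialization; biases start at zero."""
    if len(hidden) != 3:
        raise ValueError("the MLP has exactly three hidden layers")
    rng = np.random.default_rng(seed)

    def glorot(fan_out, fan_in):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_out, fan_in))

    widths = [e_dim, *hidden, 3]
    mlp_w = [glorot(widths[k + 1], widths[k]) for k in range(4)]
    mlp_b = [np.zeros(widths[k + 1]) for k in range(4)]
    return GCNNParams(
        w1=glorot(e_dim, e_dim),
        w2=glorot(e_dim, e_dim),
        mlp_w=mlp_w,
        mlp_b=mlp_b,
        graph_relu=graph_relu,
    )


def _as_weights(w) -> np.ndarray:
    if isinstance(w, NormalizedMap):
        return w.weights
    return np.asarray(w, dtype=float)


def _as_features(x) -> np.ndarray:
    if isinstance(x, EmbeddingMatrix):
        return x.u
    return np.asarray(x, dtype=float)


def aggregation_matrix(w) -> np.ndarray:
    """Row-normalized adjacency S with zero diagonal: C = S @ X.

    Rows whose off-diagonal weights sum to zero (isolated nodes) stay
    all-zero, so their consolidated feature is the zero vector.
    """
    W = _as_weights(w).copy()
    np.fill_diagonal(W, 0.0)
    rowsum = W.sum(axis=1)
    S = np.zeros_like(W)
    nz = rowsum > 0
    S[nz] = W[nz] / rowsum[nz, None]
    return S


def consolidate(x, w, i: int) -> np.ndarray:
    """Weighted mean of neighbor features of node i (the consolidate step)."""
    X = _as_features(x)
    S = aggregation_matrix(w)
    return S[i] @ X


def consolidate_all(x, w) -> np.ndarray:
    """Consolidated features for every node at once."""
    return aggregation_matrix(w) @ _as_features(x)


def update(x_i: np.ndarray, c_i: np.ndarray, p: GCNNParams) -> np.ndarray:
    """Graph-layer update W1 x_i + W2 c_i (no bias, no activation)."""
    x_i = np.asarray(x_i, dtype=float)
    c_i = np.asarray(c_i, dtype=float)
    if x_i.shape[-1] != p.e_dim or c_i.shape[-1] != p.e_dim:
        raise ValueError(
            f"feature dimension {x_i.shape[-1]} does not match parameter size {p.e_dim}"
        )
    return x_i @ p.w1.T + c_i @ p.w2.T


def forward_coords(X: np.ndarray, S: np.ndarray, p: GCNNParams, want_cache: bool = False):
    """Coordinates for all nodes; optionally return the backprop cache.

    ``S`` is the precomputed aggregation matrix of the balanced map.
    """
    if X.shape[1] != p.e_dim:
        raise ValueError(
            f"embedding dimension {X.shape[1]} does not match parameter size {p.e_dim}"
        )
    C = S @ X
    A0 = X @ p.w1.T + C @ p.w2.T
    H = np.maximum(A0, 0.0) if p.graph_relu else A0
    acts = []
    h = H
    for k in range(3):
        a = h @ p.mlp_w[k].T + p.mlp_b[k]
        acts.append(a)
        h = np.maximum(a, 0.0)
        if not np.all(np.isfinite(h)):
            raise FloatingPointError(f"non-finite activation in MLP hidden layer {k + 1}")
    Y = h @ p.mlp_w[3].T + p.mlp_b[3]
    if not np.all(np.isfinite(Y)):
        raise FloatingPointError("non-finite activation in MLP output layer")
    if not want_cache:
        return Y
    cache = {"X": X, "C": C, "A0": A0, "H": H, "acts": acts}
    return Y, cache


def backward(dY: np.ndarray, cache: dict, p: GCNNParams) -> dict:
    """Exact gradients of the loss w.r.t. every parameter given dL/dY."""
    grads = {}
    h3 = np.maximum(cache["acts"][2], 0.0)
    h2 = np.maximum(cache["acts"][1], 0.0)
    h1 = np.maximum(cache["acts"][0], 0.0)
    hs = [cache["H"], h1, h2, h3]

    grads["mw3"] = dY.T @ hs[3]
    grads["mb3"] = dY.sum(axis=0)
    dh = dY @ p.mlp_w[3]
    for k in (2, 1, 0):
        da = dh * (cache["acts"][k] > 0)
        grads[f"mw{k}"] = da.T @ hs[k]
        grads[f"mb{k}"] = da.sum(axis=0)
        dh = da @ p.mlp_w[k]
    dA0 = dh * (cache["A0"] > 0) if p.graph_relu else dh
    grads["w1"] = dA0.T @ cache["X"]
    grads["w2"] = dA0.T @ cache["C"]
    return grads


def forward(x, w, p: GCNNParams, bin_size: int = 1, bin_start_bp=None, chromosome_label: str = "chr"):
    """Full forward pass returning a :class:`~hicstruct.io.Structure`."""
    X = _as_features(x)
    S = aggregation_matrix(w)
    if X.shape[0] != S.shape[0]:
        raise ValueError(
            f"embeddings have {X.shape[0]} nodes but the graph has {S.shape[0]}"
        )
    Y = forward_coords(X, S, p)
    return Structure(
        Y, bin_size=bin_size, bin_start_bp=bin_start_bp, chromosome_label=chromosome_label
    )


def save_params(p: GCNNParams, path, extra: dict | None = None) -> None:
    """Serialize parameters (and optional metadata) to a single .npz checkpoint."""
    meta = {"graph_relu": p.graph_relu, "hidden": [w.shape[0] for w in p.mlp_w[:3]]}
    if extra:
        meta.update(extra)
    np.savez(path, __meta__=json.dumps(meta), **p.as_dict())


def load_params(path) -> tuple[GCNNParams, dict]:
    """Load a checkpoint written by :func:`save_params`."""
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        p = GCNNParams(
            w1=z["w1"],
            w2=z["w2"],
            mlp_w=[z[f"mw{k}"] for k in range(4)],
            mlp_b=[z[f"mb{k}"] for k in range(4)],
            graph_relu=bool(meta.get("graph_relu", True)),
        )
    return p, meta
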
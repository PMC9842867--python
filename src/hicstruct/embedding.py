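"""Weighted node embeddings of the contact graph (LINE, second-order).

The contact map is an adjacency matrix of an edge-weighted undirected
graph over loci, but the nodes themselves carry no features.  Static
node features are created with the LINE objective: the model conditional

    p2(v_j | v_i) = exp(u'_j . u_i) / sum_{k in N(v_i)} exp(u'_k . u_i)

is fitted to the empirical edge-weight distribution by minimizing their
KL divergence with edge-sampling stochastic gradient descent.  Edges
are drawn with probability proportional to their weight and negative
contexts from the weighted-degree^(3/4) noise distribution, so heavier
contacts shape the representation more.  Training is fully seeded and
reproducible.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import ContactMap
from .preprocess import NormalizedMap

__all__ = ["EmbeddingMatrix", "line_embed", "second_order_conditional"]


@dataclasses.dataclass
class EmbeddingMatrix:
    """N x E node representations plus the second-order context vectors."""

    u: np.ndarray
    context: np.ndarray
    e_dim: int
    graph: np.ndarray | None = None
    metadata: dict = dataclasses.field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.u.shape[0]


def _as_weight_matrix(g) -> np.ndarray:
    if isinstance(g, ContactMap):
        return g.counts
    if isinstance(g, NormalizedMap):
        return g.weights
    return np.asarray(g, dtype=float)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def line_embed(
    g,
    e_dim: int = 512,
    epochs: int = 10,
    negative_samples: int = 5,
    seed: int = 0,
    samples_per_epoch: int | None = None,
    initial_lr: float = 0.025,
    batch_size: int | None = None,
    order: int = 2,
) -> EmbeddingMatrix:
    """Train second-order LINE embeddings of a weighted graph.

    Parameters
    ----------
    g
        ContactMap, NormalizedMap or dense weight matrix.
    e_dim
        Embedding dimensionality E.
    epochs, samples_per_epoch
        Edge samples are drawn with probability proportional to edge
        weight; per epoch, ``samples_per_epoch`` samples are processed
        (default: 200 x number of edges, capped at 200,000).
    negative_samples
        Negative contexts per positive edge, drawn from the
        weighted-degree^(3/4) noise distribution.
    seed
        Seeds initialization and all sampling; identical inputs and
        seed give bitwise-identical embeddings.
    order
        Proximity order: 2 (default) trains separate context vectors
        for the conditional neighborhood distribution; 1 scores node
        pairs directly through their own vectors.
    """
    if e_dim <= 0:
        raise ValueError("embedding dimension must be positive")
    if order not in (1, 2):
        raise ValueError("proximity order must be 1 or 2")
    W = _as_weight_matrix(g)
    n = W.shape[0]
    if n < 2:
        raise ValueError("graph must have at least 2 nodes")
    iu, ju = np.nonzero(np.triu(W, k=1))
    if len(iu) == 0:
        raise ValueError("graph must have at least one positive-weight edge")
    # undirected edge -> two directed samples
    src = np.concatenate([iu, ju])
    dst = np.concatenate([ju, iu])
    ew = np.concatenate([W[iu, ju], W[iu, ju]])
    edge_p = ew / ew.sum()

    degree = W.sum(axis=1)
    isolated = np.flatnonzero(degree == 0)
    noise = degree ** 0.75
    noise_p = noise / noise.sum()

    rng = np.random.default_rng(seed)
    u = (rng.random((n, e_dim)) - 0.5) / e_dim
    ctx = np.zeros((n, e_dim))

    if samples_per_epoch is None:
        samples_per_epoch = int(min(200 * len(iu), 100_000))
    if batch_size is None:
        # keep the expected per-node occupancy of a batch small so the
        # summed within-batch updates stay close to sequential SGD
        batch_size = int(min(4096, max(64, 4 * n)))
    total = epochs * samples_per_epoch
    K = int(negative_samples)
    loss_history = []
    done = 0
    for _ in range(epochs):
        epoch_loss = 0.0
        epoch_n = 0
        remaining = samples_per_epoch
        while remaining > 0:
            B = min(batch_size, remaining)
            remaining -= B
            eidx = rng.choice(len(src), size=B, p=edge_p)
            i = src[eidx]
            j = dst[eidx]
            neg = rng.choice(n, size=(B, K), p=noise_p)
            lr = initial_lr * max(1e-4, 1.0 - done / total)
            done += B

            ctx_side = ctx if order == 2 else u
            ui = u[i]                     # B x E
            cj = ctx_side[j]              # B x E
            cneg = ctx_side[neg]          # B x K x E
            s_pos = np.einsum("be,be->b", ui, cj)
            s_neg = np.einsum("be,bke->bk", ui, cneg)
            g_pos = _sigmoid(s_pos) - 1.0          # d/ds of -log sigma(s)
            g_neg = _sigmoid(s_neg)                # d/ds of -log sigma(-s)

            grad_ui = g_pos[:, None] * cj + np.einsum("bk,bke->be", g_neg, cneg)
            grad_cj = g_pos[:, None] * ui
            grad_cneg = g_neg[:, :, None] * ui[:, None, :]

            np.add.at(u, i, -lr * grad_ui)
            np.add.at(ctx_side, j, -lr * grad_cj)
            np.add.at(ctx_side, neg.ravel(), -lr * grad_cneg.reshape(B * K, e_dim))

            with np.errstate(over="ignore"):
                epoch_loss += float(
                    np.sum(np.logaddexp(0.0, -s_pos)) + np.sum(np.logaddexp(0.0, s_neg))
                )
            epoch_n += B
        loss_history.append(epoch_loss / max(epoch_n, 1))

    if order == 1:
        ctx = u.copy()
    meta = {
        "epochs": epochs,
        "seed": seed,
        "order": order,
        "negative_samples": K,
        "samples_per_epoch": samples_per_epoch,
        "loss_history": loss_history,
        "isolated_nodes": isolated.tolist(),
    }
    return EmbeddingMatrix(u=u, context=ctx, e_dim=e_dim, graph=W, metadata=meta)


def second_order_conditional(emb: EmbeddingMatrix, i: int, j: int) -> float:
    """Model probability p2(v_j | v_i) over the neighborhood of v_i."""
    if emb.graph is None:
        raise ValueError("embedding carries no graph; cannot define neighborhoods")
    W = emb.graph
    nbrs = np.flatnonzero((W[i] > 0) & (np.arange(W.shape[0]) != i))
    if len(nbrs) == 0:
        raise ValueError(f"node {i} has no neighbors; conditional undefined")
    if j not in nbrs:
        return 0.0
    scores = emb.context[nbrs] @ emb.u[i]
    scores -= scores.max()
    ex = np.exp(scores)
    probs = ex / ex.sum()
    return float(probs[np.searchsorted(nbrs, j)])
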
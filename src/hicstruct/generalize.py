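"""Applying a stored model to a different map of the same chromosome.

Because the regressor's parameters are shared across nodes, a model
trained on one contact map can run inference on another map of the
same chromosome — a different resolution, restriction enzyme, cell
population, or coverage level — without retraining.  Two pieces of
machinery make this work:

* **Row expansion** — across resolutions the embedding matrices have
  different row counts (a 1 mb map has half the loci of a 500 kb map of
  the same region).  Each low-resolution row is repeated k consecutive
  times so that corresponding rows of the two matrices describe the
  same genomic region.  Zero-contact bins must be retained at read
  time for the row counts to be exact multiples.
* **Procrustes alignment** — node embeddings of two maps of the same
  chromosome are assumed approximately equivalent up to rotation,
  translation and scaling.  The orthogonal transform minimizing the
  Frobenius distance between the two embedding matrices has a closed
  form via SVD, so aligning the target embeddings into the space the
  model was trained in requires no additional training.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import gcnn
from .embedding import EmbeddingMatrix
from .io import ContactMap, Structure
from .preprocess import kr_balance, wish_distances
from .train import TrainedModel

__all__ = [
    "AlignmentResult",
    "expand_embeddings",
    "procrustes_align",
    "generalized_predict",
    "GeneralizationResult",
]


@dataclasses.dataclass
class AlignmentResult:
    """Outcome of an orthogonal Procrustes alignment of two embeddings."""

    aligned: np.ndarray
    transform: np.ndarray
    residual: float
    scale: float = 1.0
    expansion_factor: int = 1
    side: str = "feature"


def expand_embeddings(a: EmbeddingMatrix, n_target: int) -> EmbeddingMatrix:
    """Repeat each row of a low-resolution embedding k times to reach n_target rows.

    ``n_target`` must be an integer multiple k * N of the input row
    count; output row r equals input row floor(r / k), so both rows
    describe the same chromosomal region at the two resolutions.
    """
    n = a.n_nodes
    if n_target % n != 0:
        raise ValueError(
            f"target row count {n_target} is not a multiple of {n}; re-read the maps "
            "keeping zero-contact bins so resolutions stay exact multiples"
        )
    k = n_target // n
    return EmbeddingMatrix(
        u=np.repeat(a.u, k, axis=0),
        context=np.repeat(a.context, k, axis=0),
        e_dim=a.e_dim,
        graph=None,
        metadata={**a.metadata, "expansion_factor": k},
    )


def _as_matrix(x) -> np.ndarray:
    return x.u if isinstance(x, EmbeddingMatrix) else np.asarray(x, dtype=float)


def procrustes_align(
    a,
    b,
    scale: bool = True,
    center: bool = True,
    side: str = "feature",
) -> AlignmentResult:
    """Align embedding matrix ``a`` onto ``b`` by orthogonal Procrustes.

    With ``side="feature"`` (default) an E x E orthogonal T minimizing
    ||A T - B||_F is solved from the SVD of A^T B and applied on the
    right; this is robust to the node count and is the standard
    orthogonal-Procrustes reading.  ``side="node"`` solves the literal
    N x N left transform from the SVD of B A^T (shapes permitting).
    Optional mean-centering and a single uniform scale factor account
    for translation and scaling between the embedding spaces.
    """
    A = _as_matrix(a)
    B = _as_matrix(b)
    if A.shape != B.shape:
        raise ValueError(
            f"embedding shapes {A.shape} and {B.shape} differ; expand the "
            "lower-resolution embeddings first (expand_embeddings)"
        )
    mu_a = A.mean(axis=0) if center else np.zeros(A.shape[1])
    mu_b = B.mean(axis=0) if center else np.zeros(B.shape[1])
    Ac = A - mu_a
    Bc = B - mu_b
    norm_a = np.linalg.norm(Ac)
    if norm_a == 0:
        raise ValueError("degenerate (rank-0) embedding matrix; nothing to align")

    if side == "feature":
        U, sv, Vt = np.linalg.svd(Ac.T @ Bc)
        T = U @ Vt
        mapped = Ac @ T
    elif side == "node":
        U, sv, Vt = np.linalg.svd(Bc @ Ac.T)
        T = U @ Vt
        mapped = T @ Ac
    else:
        raise ValueError(f"unknown side {side!r}")

    s = float(sv.sum() / (norm_a ** 2)) if scale else 1.0
    aligned = s * mapped + mu_b
    residual = float(np.linalg.norm(aligned - B))
    return AlignmentResult(
        aligned=aligned, transform=T, residual=residual, scale=s, side=side
    )


@dataclasses.dataclass
class GeneralizationResult:
    """Structure predicted by a stored model on a new map, with its dSCC."""

    structure: Structure
    dscc: float
    alignment: AlignmentResult | None = None


def generalized_predict(
    model: TrainedModel,
    target_map: ContactMap,
    target_emb: EmbeddingMatrix,
    source_emb: EmbeddingMatrix | None = None,
    align: bool = True,
    gamma: float = 1.0,
) -> GeneralizationResult:
    """Run a stored model on a different map of the same chromosome.

    If ``align`` is set, the target embeddings are transformed into the
    source embedding space the model was trained in (after expanding
    the lower-resolution source embeddings row-wise when the node
    counts differ).  No parameter update occurs.  The returned dSCC is
    computed against the target map's wish distances at ``gamma``
    (default 1: the rank correlation does not depend on the conversion
    factor, since changing gamma only applies a monotone transform).
    """
    from .evaluate import dscc as _dscc

    if target_emb.e_dim != model.params.e_dim:
        raise ValueError(
            f"embedding dimension {target_emb.e_dim} does not match the stored "
            f"model's {model.params.e_dim}"
        )
    alignment = None
    X = target_emb.u
    if align:
        if source_emb is None:
            raise ValueError("alignment requested but no source embeddings given")
        src = source_emb
        if src.n_nodes != target_emb.n_nodes:
            src = expand_embeddings(src, target_emb.n_nodes)
        alignment = procrustes_align(target_emb, src)
        alignment.expansion_factor = target_emb.n_nodes // source_emb.n_nodes
        X = alignment.aligned

    normalized = kr_balance(target_map)
    if len(normalized.kept_indices) != target_map.n_loci:
        raise ValueError(
            "target map contains all-zero rows; drop them before generalized inference"
        )
    S = gcnn.aggregation_matrix(normalized)
    Y = gcnn.forward_coords(X, S, model.params)
    structure = Structure(
        Y,
        bin_size=target_map.bin_size,
        bin_start_bp=target_map.bin_start_bp,
        chromosome_label=target_map.chromosome_label,
    )
    wd = wish_distances(target_map, gamma)
    return GeneralizationResult(structure=structure, dscc=_dscc(structure, wd), alignment=alignment)
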
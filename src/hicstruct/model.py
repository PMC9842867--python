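"""Model/Results front-end over the reconstruction pipeline.

:class:`HiCStructureModel` is built from a contact map (embeddings are
computed lazily if not supplied); ``fit()`` runs the gamma-grid
training and returns a :class:`HiCStructureResults` carrying the
selected structure, the per-gamma selection record, metrics and a
``summary()`` table.  Generalized inference on a second map of the
same chromosome hangs off the results object.
"""

from __future__ import annotations


from . import train as _train
from .embedding import EmbeddingMatrix, line_embed
from .evaluate import evaluate_structure
from .generalize import GeneralizationResult, generalized_predict
from .io import ContactMap, Structure, write_structure
from .preprocess import wish_distances
from .train import TrainConfig, TrainedModel

__all__ = ["HiCStructureModel", "HiCStructureResults"]


class HiCStructureModel:
    """3D structure model of one chromosome from its Hi-C contact map.

    Parameters
    ----------
    contact_map
        The cis-chromosomal map to reconstruct.
    embeddings
        Precomputed node embeddings; computed from the raw map with
        seeded LINE if omitted.
    config
        Training configuration (:class:`~hicstruct.train.TrainConfig`).
    embed_kwargs
        Forwarded to :func:`~hicstruct.embedding.line_embed` when
        embeddings are computed here (e.g. ``e_dim``, ``epochs``).
    """

    def __init__(
        self,
        contact_map: ContactMap,
        embeddings: EmbeddingMatrix | None = None,
        config: TrainConfig | None = None,
        **embed_kwargs,
    ):
        self.contact_map = contact_map
        self.config = config or TrainConfig()
        self._embed_kwargs = embed_kwargs
        self._embeddings = embeddings

    @classmethod
    def from_file(cls, path, bin_size="infer", **kwargs) -> "HiCStructureModel":
        """Build a model from a coordinate-list or dense-matrix text file."""
        from .io import read_coordinate_list, read_square_matrix

        try:
            cmap = read_coordinate_list(path, bin_size=bin_size)
        except ValueError:
            cmap = read_square_matrix(path, bin_size=1 if bin_size == "infer" else bin_size)
        return cls(cmap, **kwargs)

    @property
    def embeddings(self) -> EmbeddingMatrix:
        if self._embeddings is None:
            kw = dict(self._embed_kwargs)
            kw.setdefault("seed", self.config.seed)
            self._embeddings = line_embed(self.contact_map, **kw)
        return self._embeddings

    def fit(self, gammas=None) -> "HiCStructureResults":
        """Train over the gamma grid and return the best-dSCC results."""
        trained = _train.fit(self.contact_map, self.embeddings, self.config, gammas=gammas)
        return HiCStructureResults(self, trained)


class HiCStructureResults:
    """Fitted reconstruction: structure, selection record and metrics."""

    def __init__(self, model: HiCStructureModel, trained: TrainedModel):
        self.model = model
        self.trained = trained

    @property
    def structure(self) -> Structure:
        return self.trained.structure

    @property
    def gamma_star(self) -> float:
        return self.trained.gamma_star

    @property
    def dscc(self) -> float:
        return self.trained.dscc_by_gamma[self.trained.gamma_star]

    @property
    def dscc_by_gamma(self) -> dict:
        return self.trained.dscc_by_gamma

    def metrics(self, rescale: bool = True):
        wd = wish_distances(self.model.contact_map, self.gamma_star)
        return evaluate_structure(self.structure, wd, rescale=rescale)

    def generalize(
        self,
        target_map: ContactMap,
        target_embeddings: EmbeddingMatrix | None = None,
        align: bool = True,
        **embed_kwargs,
    ) -> GeneralizationResult:
        """Apply the stored parameters to another map of the same chromosome."""
        if target_embeddings is None:
            kw = dict(self.model._embed_kwargs)
            kw.update(embed_kwargs)
            kw.setdefault("seed", self.model.config.seed)
            kw.setdefault("e_dim", self.model.embeddings.e_dim)
            target_embeddings = line_embed(target_map, **kw)
        return generalized_predict(
            self.trained,
            target_map,
            target_embeddings,
            source_emb=self.model.embeddings,
            align=align,
        )

    def save(self, path) -> None:
        self.trained.save(path)

    def save_structure(self, path, format: str = "xyz") -> None:
        write_structure(self.structure, path, format=format)

    def summary(self) -> str:
        """Human-readable fit report."""
        t = self.trained
        m = self.model.contact_map
        lines = [
            "HiC structure reconstruction results",
            "=" * 44,
            f"chromosome:            {m.chromosome_label}",
            f"loci (N):              {m.n_loci}",
            f"bin size:              {m.bin_size}",
            f"embedding size (E):    {self.model.embeddings.e_dim}",
            f"selected gamma:        {t.gamma_star:g}",
            f"dSCC at gamma*:        {self.dscc:.4f}",
            f"final training MSE:    {t.final_loss:.3e}",
            f"epochs run:            {t.epochs_run}"
            + ("" if t.converged else "  (epoch cap reached)"),
            "",
            "gamma     dSCC",
            "-" * 16,
        ]
        for g in sorted(t.dscc_by_gamma):
            v = t.dscc_by_gamma[g]
            mark = "  *" if g == t.gamma_star else ""
            lines.append(f"{g:5.2f}   {v: .4f}{mark}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<HiCStructureResults N={self.model.contact_map.n_loci} "
            f"gamma*={self.gamma_star:g} dSCC={self.dscc:.3f}>"
        )
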
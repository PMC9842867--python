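"""Structure evaluation: dSCC, dRMSD, baselines and compartment calls.

dSCC is the Spearman rank correlation between the pairwise distances
of a predicted structure and the wish distances of the contact map it
came from.  Being rank-based it is invariant to rigid motion and
uniform scaling of the structure — appropriate, since the absolute
scale of a reconstructed chromosome is unidentifiable from contacts.
dRMSD is the root-mean-square deviation of the same two distance
vectors, optionally after a single closed-form rescaling of the
structure.  A/B compartments are called from the sign pattern of the
principal eigenvector of the Pearson correlation matrix of the
balanced contact map.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import stats

from .io import ContactMap, Structure
from .preprocess import WishDistances, kr_balance

logger = logging.getLogger(__name__)

__all__ = [
    "MetricReport",
    "CompartmentCalls",
    "dscc",
    "drmsd",
    "interpolate_structure",
    "call_compartments",
    "region_distance_compare",
    "evaluate_structure",
]


@dataclasses.dataclass
class MetricReport:
    """dSCC and dRMSD of one structure against one map's wish distances."""

    dscc: float
    drmsd: float
    n_pairs: int
    gamma_used: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _masked_distance_pairs(s, wd: WishDistances) -> tuple[np.ndarray, np.ndarray]:
    coords = s.coords if isinstance(s, Structure) else np.asarray(s, dtype=float)
    iu, ju, d = wd.condensed()
    if len(iu) < 3:
        raise ValueError("need at least 3 masked pairs to evaluate a structure")
    dist = np.linalg.norm(coords[iu] - coords[ju], axis=1)
    return dist, d


def dscc(s, wd: WishDistances) -> float:
    """Spearman rank correlation between structure and wish distances.

    Ranks are averaged over ties (standard Spearman).  Raises if either
    distance vector is constant, where rank correlation is undefined.
    """
    dist, d = _masked_distance_pairs(s, wd)
    if np.ptp(dist) == 0 or np.ptp(d) == 0:
        raise ValueError("rank correlation undefined: constant distance vector")
    rho = stats.spearmanr(dist, d).statistic
    return float(rho)


def drmsd(s, wd: WishDistances, rescale: bool = False) -> float:
    """Root-mean-square deviation between structure and wish distances.

    With ``rescale`` the single scalar s* = sum(d * dist) / sum(dist^2)
    minimizing sum((s * dist - d)^2) is applied to the structure
    distances first, removing the arbitrary overall scale.
    """
    dist, d = _masked_distance_pairs(s, wd)
    if rescale:
        denom = float(np.sum(dist ** 2))
        if denom > 0:
            dist = dist * (float(np.sum(d * dist)) / denom)
    return float(np.sqrt(np.mean((dist - d) ** 2)))


def interpolate_structure(s: Structure, k: int, target_n: int | None = None) -> Structure:
    """Linear-interpolation baseline for cross-resolution comparison.

    Inserts k - 1 equally spaced points on the segment between each
    pair of consecutive coordinates, giving k * (N - 1) + 1 points — a
    structure with the spatial configuration of the coarse model but
    the point count of a finer map.  If ``target_n`` differs from that
    count, the final coordinate is repeated (or the tail truncated) to
    match, and the mismatch is logged.
    """
    if k < 1:
        raise ValueError("interpolation factor must be >= 1")
    coords = s.coords
    n = len(coords)
    if n < 2:
        raise ValueError("need at least 2 points to interpolate")
    if k == 1:
        out = coords.copy()
    else:
        segs = []
        for a, b in zip(coords[:-1], coords[1:]):
            t = np.arange(k) / k
            segs.append(a[None, :] * (1 - t)[:, None] + b[None, :] * t[:, None])
        segs.append(coords[-1][None, :])
        out = np.vstack(segs)
    if target_n is not None and target_n != len(out):
        logger.info(
            "interpolated length %d != target %d; padding/truncating", len(out), target_n
        )
        if target_n > len(out):
            pad = np.repeat(out[-1][None, :], target_n - len(out), axis=0)
            out = np.vstack([out, pad])
        else:
            out = out[:target_n]
    return Structure(out, bin_size=max(s.bin_size // k, 1), chromosome_label=s.chromosome_label)


@dataclasses.dataclass
class CompartmentCalls:
    """A/B labels for the retained loci plus the eigenvector behind them."""

    labels: np.ndarray  # array of "A"/"B", length = len(kept_indices)
    kept_indices: np.ndarray
    eigenvector: np.ndarray


def call_compartments(m: ContactMap, normalization: str = "kr") -> CompartmentCalls:
    """Call A/B compartments from the principal correlation eigenvector.

    The balanced (or raw, with ``normalization="raw"``) map's Pearson
    correlation matrix is eigendecomposed; loci with positive entries
    in the leading eigenvector form one compartment and negative
    entries the other.  The eigenvector sign is fixed so that the
    larger compartment is labeled A; exact zeros go to B with a note.
    Constant rows (undefined correlation) are dropped and reported via
    ``kept_indices``.
    """
    if m.n_loci < 3:
        raise ValueError("need at least 3 loci to call compartments")
    if normalization == "kr":
        norm = kr_balance(m)
        W = norm.weights
        kept = norm.kept_indices
    elif normalization == "raw":
        trimmed, kept = m.drop_empty()
        W = trimmed.counts
    else:
        raise ValueError(f"unknown normalization {normalization!r}")

    sd = W.std(axis=1)
    ok = sd > 0
    if not np.all(ok):
        logger.info("dropping %d constant rows before correlation", int(np.sum(~ok)))
        W = W[np.ix_(ok, ok)]
        kept = kept[ok]
    if W.shape[0] < 3:
        raise ValueError("fewer than 3 loci with defined correlation")
    corr = np.corrcoef(W)
    evals, evecs = np.linalg.eigh(corr)
    v = evecs[:, -1]
    if np.sum(v > 0) < np.sum(v < 0):
        v = -v
    labels = np.where(v > 0, "A", "B")
    if np.any(v == 0):
        logger.info("%d zero eigenvector entries assigned to compartment B", int(np.sum(v == 0)))
    return CompartmentCalls(labels=labels, kept_indices=kept, eigenvector=v)


def compartments_to_bed(calls: CompartmentCalls, m: ContactMap, path) -> None:
    """Write compartment labels as BED-like text (chrom, start, end, label)."""
    with open(path, "w") as fh:
        for idx, lab in zip(calls.kept_indices, calls.labels):
            start = m.bin_start_bp[idx]
            fh.write(f"{m.chromosome_label}\t{start}\t{start + m.bin_size}\t{lab}\n")


def region_distance_compare(s: Structure, set1, set2):
    """Compare structure distances of two sets of locus pairs.

    Returns ((mean1, mean2), p) where p is the two-sided Mann-Whitney
    rank-sum p-value.  Used to check, e.g., that experimentally looped
    regions sit closer in the model than non-looped regions.
    """
    set1 = np.asarray(set1, dtype=int)
    set2 = np.asarray(set2, dtype=int)
    if len(set1) == 0 or len(set2) == 0:
        raise ValueError("both pair sets must be non-empty")
    d1 = np.linalg.norm(s.coords[set1[:, 0]] - s.coords[set1[:, 1]], axis=1)
    d2 = np.linalg.norm(s.coords[set2[:, 0]] - s.coords[set2[:, 1]], axis=1)
    if np.array_equal(np.sort(d1), np.sort(d2)):
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(d1, d2, alternative="two-sided").pvalue)
    return (float(d1.mean()), float(d2.mean())), p


def evaluate_structure(s: Structure, wd: WishDistances, rescale: bool = True) -> MetricReport:
    """Convenience bundle of dSCC and dRMSD for one structure."""
    return MetricReport(
        dscc=dscc(s, wd),
        drmsd=drmsd(s, wd, rescale=rescale),
        n_pairs=wd.n_pairs,
        gamma_used=wd.gamma,
    )
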
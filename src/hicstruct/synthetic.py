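"""Synthetic ground-truth structures and derived Hi-C maps.

Real chromosome structures are unknown, so validation relies on
instances where they are not: a known 3D curve is sampled at N loci
and contacts are generated through the same inverse power law the
reconstruction assumes, CF_ij = d(i,j)^(-1/gamma), optionally
perturbed by multiplicative log-normal noise (Hi-C counts are positive
and heavy-tailed).  At zero noise the wish-distance conversion at the
generating gamma recovers the true pairwise distances exactly, which
makes parameter-recovery experiments sharp.  Coarsening a map by
block-summing k x k bins emulates lower resolution; binomial thinning
emulates reduced sequencing coverage.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io import ContactMap, Structure

__all__ = [
    "SyntheticInstance",
    "make_structure",
    "structure_to_map",
    "coarsen_map",
    "split_coverage",
    "make_instance",
]

DEFAULT_BIN_SIZE = 1_000_000


@dataclasses.dataclass
class SyntheticInstance:
    """A planted structure with the contact maps generated from it."""

    true_structure: Structure
    maps: list
    gamma_true: float
    noise_alpha: float
    seed: int


def make_structure(n: int, kind: str = "helix", seed: int = 0) -> Structure:
    """Generate a planted 3D curve of n loci.

    kinds:
      - ``helix``: regular helix (radius 1, fixed pitch) — equal
        consecutive spacing, smooth curvature.
      - ``random_walk``: smoothed cumulative-sum curve, a stand-in for
        a disordered polymer conformation.
      - ``two_domain``: two compact clusters joined by a linker, for
        compartment-style tests.
    """
    if n < 10:
        raise ValueError("need at least 10 loci")
    rng = np.random.default_rng(seed)
    if kind == "helix":
        t = np.arange(n)
        theta = t * (2 * np.pi / 10.0)
        coords = np.column_stack([np.cos(theta), np.sin(theta), 0.3 * t])
    elif kind == "random_walk":
        steps = rng.standard_normal((n + 8, 3))
        kernel = np.ones(9) / 9.0
        smooth = np.column_stack([np.convolve(steps[:, k], kernel, mode="valid") for k in range(3)])
        # renormalize steps so consecutive loci are ~unit spaced
        norms = np.linalg.norm(smooth, axis=1)
        smooth = smooth / np.maximum(norms, 1e-12)[:, None]
        coords = np.vstack([np.zeros(3), np.cumsum(smooth[: n - 1], axis=0)])
    elif kind == "two_domain":
        n1 = n // 2
        c1 = np.zeros(3)
        c2 = np.array([8.0, 0.0, 0.0])
        blob1 = c1 + rng.standard_normal((n1, 3)) * 1.0
        blob2 = c2 + rng.standard_normal((n - n1, 3)) * 1.0
        coords = np.vstack([blob1, blob2])
    else:
        raise ValueError(f"unknown structure kind {kind!r}")
    # guard against coincident loci, which would give infinite contacts
    dmin = pdist(coords).min()
    if dmin < 1e-9:
        coords = coords + rng.standard_normal(coords.shape) * 1e-6
    return Structure(coords, bin_size=DEFAULT_BIN_SIZE)


def structure_to_map(
    s: Structure,
    gamma: float = 1.0,
    noise_alpha: float = 0.0,
    seed: int = 0,
    bin_size: int | None = None,
) -> ContactMap:
    """Generate contacts CF_ij = d(i,j)^(-1/gamma) from a planted structure.

    ``noise_alpha`` is the log-scale spread of multiplicative
    log-normal noise (0 gives the exact power law).  The diagonal is
    zero and the matrix symmetric by construction.
    """
    if not (0.1 <= gamma <= 2.0):
        raise ValueError("gamma must lie in [0.1, 2]")
    if noise_alpha < 0:
        raise ValueError("noise_alpha must be non-negative")
    d = pdist(s.coords)
    if d.min() <= 0:
        raise ValueError("structure has coincident loci; distances must be positive")
    cf = d ** (-1.0 / gamma)
    if noise_alpha > 0:
        rng = np.random.default_rng(seed)
        cf = cf * rng.lognormal(mean=0.0, sigma=noise_alpha, size=cf.shape)
    counts = squareform(cf)
    return ContactMap(
        counts,
        bin_size=int(bin_size or s.bin_size),
        chromosome_label=s.chromosome_label,
    )


def coarsen_map(m: ContactMap, k: int) -> ContactMap:
    """Lower the resolution by summing counts over k x k bin blocks."""
    if k < 1:
        raise ValueError("coarsening factor must be >= 1")
    if k == 1:
        return ContactMap(
            m.counts.copy(), bin_size=m.bin_size, bin_start_bp=m.bin_start_bp,
            chromosome_label=m.chromosome_label,
        )
    n = m.n_loci
    pad = (-n) % k
    counts = m.counts
    if pad:
        counts = np.pad(counts, ((0, pad), (0, pad)))
    nc = counts.shape[0] // k
    coarse = counts.reshape(nc, k, nc, k).sum(axis=(1, 3))
    start0 = int(m.bin_start_bp[0])
    return ContactMap(
        coarse,
        bin_size=m.bin_size * k,
        bin_start_bp=start0 + np.arange(nc, dtype=np.int64) * (m.bin_size * k),
        chromosome_label=m.chromosome_label,
    )


def split_coverage(m: ContactMap, fraction: float, seed: int = 0) -> ContactMap:
    """Emulate reduced sequencing coverage by binomial thinning.

    Counts are rounded to integers and each count c is replaced by a
    Binomial(c, fraction) draw, applied symmetrically, so the expected
    total equals fraction times the original total.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    n = m.n_loci
    counts = np.rint(m.counts).astype(np.int64)
    iu, ju = np.triu_indices(n)
    thinned = rng.binomial(counts[iu, ju], fraction)
    out = np.zeros_like(m.counts)
    out[iu, ju] = thinned
    out[ju, iu] = thinned
    return ContactMap(
        out, bin_size=m.bin_size, bin_start_bp=m.bin_start_bp, chromosome_label=m.chromosome_label
    )


def make_instance(
    n: int,
    kind: str = "helix",
    gamma: float = 1.0,
    noise_alpha: float = 0.0,
    coarsen_factors: tuple = (),
    seed: int = 0,
) -> SyntheticInstance:
    """Planted structure plus its map(s), optionally at coarser resolutions."""
    s = make_structure(n, kind=kind, seed=seed)
    base = structure_to_map(s, gamma=gamma, noise_alpha=noise_alpha, seed=seed + 1)
    maps = [base] + [coarsen_map(base, k) for k in coarsen_factors]
    return SyntheticInstance(
        true_structure=s, maps=maps, gamma_true=gamma, noise_alpha=noise_alpha, seed=seed
    )
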
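"""Reading and writing Hi-C contact maps and 3D structures.

Two plain-text contact dialects are supported: a coordinate list
(``pos_i pos_j count`` per line, positions in base pairs or bin
indices) and a dense whitespace-separated square matrix.  Structures
are written as bare ``x y z`` lines or as PDB ATOM records for
visualization in standard molecular viewers.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ContactMap",
    "Structure",
    "read_coordinate_list",
    "read_square_matrix",
    "read_xyz",
    "write_structure",
    "write_matrix",
    "write_coordinate_list",
]


@dataclasses.dataclass
class ContactMap:
    """A symmetric cis-chromosomal contact matrix with bin metadata.

    Parameters
    ----------
    counts
        N x N non-negative matrix of raw contact frequencies.
    bin_size
        Genomic span of one bin in base pairs (the map resolution).
    bin_start_bp
        Genomic start position of each bin.
    chromosome_label
        Free-text chromosome name carried through the pipeline.
    """

    counts: np.ndarray
    bin_size: int = 1
    bin_start_bp: np.ndarray | None = None
    chromosome_label: str = "chr"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("contact matrix must be square")
        if np.max(np.abs(self.counts - self.counts.T), initial=0.0) > 1e-9:
            raise ValueError("contact matrix must be symmetric within 1e-9")
        if np.any(self.counts < 0):
            raise ValueError("contact counts must be non-negative")
        if self.bin_start_bp is None:
            self.bin_start_bp = np.arange(self.n_loci, dtype=np.int64) * int(self.bin_size)
        else:
            self.bin_start_bp = np.asarray(self.bin_start_bp, dtype=np.int64)
            if len(self.bin_start_bp) != self.n_loci:
                raise ValueError("bin_start_bp length must equal the number of loci")
            if np.any(np.diff(self.bin_start_bp) <= 0):
                raise ValueError("bin_start_bp must be strictly increasing")

    @property
    def n_loci(self) -> int:
        return self.counts.shape[0]

    def drop_empty(self) -> tuple["ContactMap", np.ndarray]:
        """Remove all-zero rows/columns; returns the trimmed map and kept indices."""
        keep = np.flatnonzero(self.counts.sum(axis=1) > 0)
        trimmed = ContactMap(
            self.counts[np.ix_(keep, keep)],
            bin_size=self.bin_size,
            bin_start_bp=self.bin_start_bp[keep],
            chromosome_label=self.chromosome_label,
        )
        return trimmed, keep


@dataclasses.dataclass
class Structure:
    """Predicted 3D coordinates of chromosome loci (arbitrary units)."""

    coords: np.ndarray
    bin_size: int = 1
    bin_start_bp: np.ndarray | None = None
    chromosome_label: str = "chr"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("structure coordinates must be an N x 3 array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("structure coordinates must be finite")
        if self.bin_start_bp is None:
            self.bin_start_bp = np.arange(self.n_loci, dtype=np.int64) * int(self.bin_size)
        else:
            self.bin_start_bp = np.asarray(self.bin_start_bp, dtype=np.int64)

    @property
    def n_loci(self) -> int:
        return self.coords.shape[0]

    def pairwise_distances(self) -> np.ndarray:
        """Full N x N Euclidean distance matrix of the coordinates."""
        return squareform(pdist(self.coords))


def _parse_records(path) -> list[tuple[float, float, float, int]]:
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: expected at least 3 columns, got {len(parts)}")
            try:
                pi, pj, c = float(parts[0]), float(parts[1]), float(parts[2])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-numeric field") from exc
            if c < 0:
                raise ValueError(f"line {lineno}: negative count {c}")
            records.append((pi, pj, c, lineno))
    if not records:
        raise ValueError(f"empty contact file: {path}")
    return records


def _infer_bin_size(positions: np.ndarray) -> int:
    uniq = np.unique(positions)
    if len(uniq) < 2:
        raise ValueError("cannot infer bin size from a single distinct position")
    diffs = np.diff(uniq)
    step = int(diffs.min())
    if step <= 0:
        raise ValueError("cannot infer bin size: repeated positions")
    offsets = (uniq - uniq.min()) % step
    if np.any(offsets != 0):
        raise ValueError("non-constant inferred bin size: positions are not on a regular grid")
    return step


def read_coordinate_list(path, bin_size="infer", positions: str = "auto") -> ContactMap:
    """Read a 3-column coordinate-list contact file into a dense :class:`ContactMap`.

    Each non-comment line is ``pos_i pos_j count``.  Positions may be
    genomic base-pair coordinates on a regular grid or bin indices;
    ``positions`` selects the interpretation ("bp", "bins" or "auto").
    Duplicate records for the same unordered pair are summed, and bins
    with no records inside the observed coordinate range are retained
    as all-zero rows so that row counts across resolutions of the same
    chromosome stay exact scalar multiples.
    """
    records = _parse_records(path)
    pos = np.array([[r[0], r[1]] for r in records], dtype=float)
    allpos = pos.ravel()

    if bin_size == "infer":
        bs = _infer_bin_size(allpos)
        mode = "bp"
    else:
        bs = int(bin_size)
        if bs <= 0:
            raise ValueError("bin_size must be positive")
        if positions == "bp":
            mode = "bp"
        elif positions == "bins":
            mode = "bins"
        elif positions == "auto":
            # bp mode only if every position sits on the bin grid
            mode = "bp" if np.all(np.mod(allpos, bs) == 0) else "bins"
        else:
            raise ValueError(f"unknown positions mode {positions!r}")

    if mode == "bp":
        origin = allpos.min()
        bins = np.floor((pos - origin) / bs).astype(np.int64)
        start0 = int(origin)
    else:
        if np.any(allpos != np.round(allpos)) or np.any(allpos < 0):
            raise ValueError("bin-index positions must be non-negative integers")
        bins = pos.astype(np.int64)
        bins -= bins.min()
        start0 = int(allpos.min()) * bs

    n = int(bins.max()) + 1
    counts = np.zeros((n, n), dtype=float)
    for (bi, bj), (_, _, c, _) in zip(bins, records):
        if bi == bj:
            counts[bi, bi] += c
        else:
            counts[bi, bj] += c
            counts[bj, bi] += c
    starts = start0 + np.arange(n, dtype=np.int64) * bs
    return ContactMap(counts, bin_size=bs, bin_start_bp=starts)


def read_square_matrix(path, bin_size: int = 1) -> ContactMap:
    """Read a dense whitespace-separated square contact matrix."""
    m = np.loadtxt(path, dtype=float, ndmin=2)
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"matrix not square: shape {m.shape}")
    if np.any(np.isnan(m)):
        raise ValueError("matrix contains NaN entries")
    asym = np.max(np.abs(m - m.T), initial=0.0)
    scale = np.max(np.abs(m), initial=0.0)
    if asym > 1e-6 * max(scale, 1e-300):
        raise ValueError(f"matrix asymmetry {asym:g} exceeds tolerance")
    m = (m + m.T) / 2.0
    return ContactMap(m, bin_size=int(bin_size))


def write_matrix(m: ContactMap, path) -> None:
    """Write the dense counts matrix as whitespace-separated text."""
    np.savetxt(path, m.counts)


def write_coordinate_list(m: ContactMap, path, include_zeros: bool = False) -> None:
    """Write a map as ``pos_i pos_j count`` lines (upper triangle, bp positions)."""
    with open(path, "w") as fh:
        fh.write(f"# chromosome={m.chromosome_label} bin_size={m.bin_size}\n")
        n = m.n_loci
        for i in range(n):
            for j in range(i, n):
                c = m.counts[i, j]
                if c > 0 or include_zeros:
                    fh.write(f"{m.bin_start_bp[i]} {m.bin_start_bp[j]} {c:.10g}\n")


def read_xyz(path) -> Structure:
    """Read a bare ``x y z`` per-line structure file."""
    coords = np.loadtxt(path, dtype=float, ndmin=2)
    if coords.shape[1] != 3:
        raise ValueError("xyz file must have exactly 3 columns")
    return Structure(coords)


def _write_pdb(s: Structure, fh) -> None:
    # scale into the fixed-width 8.3 coordinate fields
    span = np.max(np.abs(s.coords), initial=0.0)
    scale = 100.0 / span if span > 0 else 1.0
    xyz = s.coords * scale
    fh.write("REMARK generated by hicstruct; coordinates in arbitrary units\n")
    for i, (x, y, z) in enumerate(xyz, start=1):
        fh.write(
            f"ATOM  {i:>5d}  CA  GLY A{i % 10000:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
        )
    fh.write("END\n")


def write_structure(s: Structure, path, format: str = "xyz") -> None:
    """Write a structure as xyz text or PDB ATOM records."""
    if not np.all(np.isfinite(s.coords)):
        raise ValueError("cannot write non-finite coordinates")
    with open(path, "w") as fh:
        if format == "xyz":
            for x, y, z in s.coords:
                fh.write(f"{x:.10g} {y:.10g} {z:.10g}\n")
        elif format == "pdb":
            _write_pdb(s, fh)
        else:
            raise ValueError(f"unknown structure format {format!r}")
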
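"""Contact-map preprocessing: KR balancing and wish-distance conversion.

Raw contact counts are often in the hundreds of thousands; before they
feed the graph convolution they are balanced to a doubly stochastic
matrix with the Knight-Ruiz algorithm, which both bounds the edge
weights in [0, 1] and removes per-locus coverage biases.  Target
distances for the regression ("wish distances") come from the standard
inverse power law d(i,j) = (1/CF_ij)^gamma; the conversion factor
gamma is unknown a priori and is grid-searched over [0.1, 2].
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .io import ContactMap

__all__ = [
    "NormalizedMap",
    "WishDistances",
    "kr_balance",
    "wish_distances",
    "gamma_grid",
]


@dataclasses.dataclass
class NormalizedMap:
    """Doubly stochastic edge-weight matrix produced by KR balancing.

    ``weights`` is N' x N' where N' counts the loci retained after
    all-zero rows were removed; ``kept_indices`` maps the retained rows
    back to the rows of the source :class:`~hicstruct.io.ContactMap`.
    """

    weights: np.ndarray
    kept_indices: np.ndarray
    note: str = ""

    @property
    def n_loci(self) -> int:
        return self.weights.shape[0]


@dataclasses.dataclass
class WishDistances:
    """Target pairwise distances d(i,j) = (1/CF_ij)^gamma on observed pairs.

    Pairs with zero contacts (and the diagonal) are excluded from the
    ``mask`` rather than mapped to an infinite distance; they simply do
    not constrain the structure.
    """

    gamma: float
    d: np.ndarray
    mask: np.ndarray

    @property
    def n_pairs(self) -> int:
        """Number of unordered masked pairs."""
        return int(np.count_nonzero(np.triu(self.mask, k=1)))

    def condensed(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Upper-triangle (i, j, d) arrays of the masked pairs."""
        iu, ju = np.nonzero(np.triu(self.mask, k=1))
        return iu, ju, self.d[iu, ju]


def _kr_newton(A: np.ndarray, tol: float, max_outer: int) -> np.ndarray:
    """Inner-outer Newton iteration for the KR scaling vector x with x*(Ax)=1."""
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, Delta = 0.1, 3.0
    g = 0.9
    etamax = 0.1
    eta = etamax
    stop_tol = tol * 0.5
    rt = tol * tol
    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rout = rho_km1
    rold = rout
    outer = 0
    while rout > rt:
        outer += 1
        if outer > max_outer:
            raise RuntimeError(
                f"KR balancing failed to converge in {max_outer} outer iterations "
                f"(residual {np.sqrt(rout):.3e})"
            )
        k = 0
        y = e.copy()
        innertol = max(eta * eta * rout, rt)
        rho_km2 = rho_km1
        Z = np.empty(n)
        p = np.empty(n)
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            if k > 10 * n + 50:
                break
            w = x * (A @ (x * p)) + v * p
            denom = p @ w
            if denom <= 0 or not np.isfinite(denom):
                raise FloatingPointError("KR inner iteration lost positive definiteness")
            alpha = rho_km1 / denom
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                ind = ap < 0
                gamma_step = np.min((delta - y[ind]) / ap[ind])
                y = y + gamma_step * ap
                break
            if ynew.max() >= Delta:
                ind = ynew > Delta
                gamma_step = np.min((Delta - y[ind]) / ap[ind])
                y = y + gamma_step * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
        x = x * y
        if np.any(x <= 0) or not np.all(np.isfinite(x)):
            raise FloatingPointError("KR scaling vector left the positive cone")
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        rat = rout / rold
        rold = rout
        res_norm = np.sqrt(rout)
        eta_o = eta
        eta = g * rat
        if g * eta_o * eta_o > 0.1:
            eta = max(eta, g * eta_o * eta_o)
        eta = max(min(eta, etamax), stop_tol / max(res_norm, 1e-300))
    return x


def _sinkhorn(A: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    """Damped symmetric Sinkhorn-Knopp fixed point for x with x*(Ax)=1."""
    x = 1.0 / np.sqrt(np.maximum(A.sum(axis=1), 1e-300))
    for _ in range(max_iter):
        Ax = A @ x
        if np.any(Ax <= 0):
            raise RuntimeError(
                "matrix is not balanceable (zero row after removal); "
                "re-read the map with drop_empty"
            )
        x = np.sqrt(x / Ax)
        resid = np.max(np.abs(x * (A @ x) - 1.0))
        if resid < tol:
            return x
    raise RuntimeError(f"Sinkhorn fallback failed to converge (residual {resid:.3e})")


def kr_balance(m: ContactMap | np.ndarray, tol: float = 1e-6, max_iter: int = 1000) -> NormalizedMap:
    """Balance a contact map to a doubly stochastic matrix in [0, 1].

    All-zero rows are removed first and reported through
    ``kept_indices``.  A Knight-Ruiz Newton iteration is attempted; if
    it leaves the positive cone (matrices that are not fully
    indecomposable, or numerically hard) a damped Sinkhorn-Knopp
    iteration is used instead and noted in the provenance string.
    """
    if isinstance(m, ContactMap):
        counts = m.counts
    else:
        counts = np.asarray(m, dtype=float)
        if np.max(np.abs(counts - counts.T), initial=0.0) > 1e-9 or np.any(counts < 0):
            raise ValueError("kr_balance needs a symmetric non-negative matrix")
    keep = np.flatnonzero(counts.sum(axis=1) > 0)
    A = counts[np.ix_(keep, keep)]
    if A.shape[0] == 0:
        raise ValueError("contact map has no non-empty rows")
    # scale invariance: normalize once so the Newton iteration sees O(1) entries
    A = A / A.sum(axis=1).mean()
    note = "kr-newton"
    try:
        x = _kr_newton(A, tol, max_outer=max_iter)
    except (RuntimeError, FloatingPointError) as exc:
        note = f"sinkhorn-fallback ({exc})"
        try:
            x = _sinkhorn(A, tol, max_iter=100000)
        except RuntimeError as exc2:
            raise RuntimeError(
                f"KR balancing failed: {exc2}; if the map has near-empty rows, "
                "re-read it with drop_empty"
            ) from exc2
    W = A * np.outer(x, x)
    W = (W + W.T) / 2.0
    return NormalizedMap(weights=W, kept_indices=keep, note=note)


def wish_distances(m: ContactMap | np.ndarray, gamma: float) -> WishDistances:
    """Convert contact frequencies to target distances d = (1/CF)^gamma.

    Zero-contact pairs and the diagonal carry no wish distance and are
    excluded from the mask.  Values of gamma outside the empirical
    [0.1, 2] range trigger a warning but are accepted.
    """
    counts = m.counts if isinstance(m, ContactMap) else np.asarray(m, dtype=float)
    if not (0.1 <= gamma <= 2.0):
        warnings.warn(
            f"conversion factor gamma={gamma} is outside the empirical range [0.1, 2]",
            stacklevel=2,
        )
    mask = counts > 0
    np.fill_diagonal(mask, False)
    d = np.zeros_like(counts, dtype=float)
    with np.errstate(divide="ignore"):
        d[mask] = (1.0 / counts[mask]) ** gamma
    return WishDistances(gamma=float(gamma), d=d, mask=mask)


def gamma_grid() -> list[float]:
    """The 20-value conversion-factor grid {0.1, 0.2, ..., 2.0}."""
    return [round(0.1 * k, 10) for k in range(1, 21)]
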
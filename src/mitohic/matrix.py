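"""Contact-matrix container, Knight-Ruiz balancing and expected-value machinery.

All analyses in this package run on per-chromosome symmetric raw-count
matrices. The container stores the upper triangle sparsely; balancing weights
and a per-bin validity mask are attached by :func:`kr_balance`. Balanced
values are ``w_i * w_j * count_ij``, scaled so that unmasked balanced row
sums equal one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

log = logging.getLogger("mitohic.matrix")


@dataclass
class ContactMatrix:
    """Symmetric binned raw contact counts for one chromosome.

    ``counts`` holds the upper triangle (i <= j) only; queries through
    :meth:`dense` return the full symmetric matrix.
    """

    chrom: str
    bin_size: int
    counts: sp.csr_matrix  # upper triangle, raw counts
    weights: np.ndarray | None = None
    mask: np.ndarray | None = None  # True = usable bin
    balancing_converged: bool = True
    _dense_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @classmethod
    def from_dense(cls, chrom: str, bin_size: int, dense: np.ndarray) -> "ContactMatrix":
        if dense.shape[0] != dense.shape[1]:
            raise ValueError("contact matrix must be square")
        upper = sp.csr_matrix(np.triu(dense))
        return cls(chrom, bin_size, upper)

    @classmethod
    def from_triplets(
        cls, chrom: str, bin_size: int, n_bins: int, rows, cols, vals
    ) -> "ContactMatrix":
        rows = np.asarray(rows, dtype=np.int64)
        cols = np.asarray(cols, dtype=np.int64)
        vals = np.asarray(vals, dtype=np.float64)
        if np.any(vals < 0):
            raise ValueError("contact counts must be non-negative")
        lo = np.minimum(rows, cols)
        hi = np.maximum(rows, cols)
        m = sp.coo_matrix((vals, (lo, hi)), shape=(n_bins, n_bins)).tocsr()
        m.sum_duplicates()
        return cls(chrom, bin_size, m)

    def dense(self) -> np.ndarray:
        """Full symmetric raw-count matrix (cached)."""
        if self._dense_cache is None:
            upper = self.counts.toarray()
            full = upper + np.triu(upper, 1).T
            self._dense_cache = full
        return self._dense_cache

    def get(self, i: int, j: int) -> float:
        lo, hi = (i, j) if i <= j else (j, i)
        return float(self.counts[lo, hi])

    def triplets(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        coo = self.counts.tocoo()
        keep = coo.data != 0
        return coo.row[keep], coo.col[keep], coo.data[keep]

    def marginals(self) -> np.ndarray:
        """Symmetric row sums of the raw matrix (diagonal counted once)."""
        return np.asarray(self.dense().sum(axis=1))

    def total(self) -> float:
        d = self.dense()
        return float(np.triu(d).sum())

    def balanced_dense(self) -> np.ndarray:
        """Full symmetric balanced matrix; masked rows/cols are NaN."""
        if self.weights is None:
            raise ValueError("matrix is not balanced; call kr_balance first")
        w = self.weights
        b = self.dense() * np.outer(w, w)
        bad = ~self.mask
        b[bad, :] = np.nan
        b[:, bad] = np.nan
        return b

    def coarsen(self, new_bin_size: int) -> "ContactMatrix":
        """Re-bin raw counts onto a coarser grid by genomic start coordinate.

        Works for any coarser bin size (not only integer multiples): fine bin
        ``i`` maps to coarse bin ``(i * bin_size) // new_bin_size``.
        """
        if new_bin_size < self.bin_size:
            raise ValueError("can only coarsen to a larger bin size")
        n = self.n_bins
        length = n * self.bin_size
        n_new = -(-length // new_bin_size)
        idx = (np.arange(n, dtype=np.int64) * self.bin_size) // new_bin_size
        coo = self.counts.tocoo()
        m = sp.coo_matrix(
            (coo.data, (idx[coo.row], idx[coo.col])), shape=(n_new, n_new)
        ).tocsr()
        m.sum_duplicates()
        # re-fold below-diagonal mass (mapping preserves row<=col ordering, so none)
        return ContactMatrix(self.chrom, new_bin_size, m)


def default_mask(matrix: ContactMatrix, low_quantile: float = 0.02) -> np.ndarray:
    """Bins usable for balancing: nonzero marginal above the low-coverage tail.

    Bins whose raw marginal is zero or in the lowest ``low_quantile`` of the
    nonzero marginals are masked out; KR is unstable on such rows.
    """
    marg = matrix.marginals()
    mask = marg > 0
    if mask.any() and low_quantile > 0:
        cut = np.quantile(marg[mask], low_quantile)
        mask &= marg > cut * (1 - 1e-12)
    return mask


def _kr_weights(A: np.ndarray, tol: float, max_iter: int) -> tuple[np.ndarray, bool]:
    """Knight-Ruiz balancing of a symmetric non-negative matrix.

    Returns x with rowsums(diag(x) A diag(x)) = 1 to within ||.||_2 <= tol.
    Inner-outer Newton iteration with conjugate-gradient inner solves.
    """
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    g, etamax = 0.9, 0.1
    eta = etamax
    stop_tol = tol * 0.5
    rt = tol**2
    delta, Delta = 0.1, 3.0

    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rout = rold = rho_km1
    mvp = 0
    while rout > rt and mvp < max_iter:
        k = 0
        y = e.copy()
        innertol = max(eta**2 * rout, rt)
        rho_km2 = rho_km1
        Z = p = None
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            denom = p @ w
            if denom <= 0:
                break
            alpha = rho_km1 / denom
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                neg = ap < 0
                gamma = ((delta - y[neg]) / ap[neg]).min()
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                pos = ynew >= Delta
                gamma = ((Delta - y[pos]) / ap[pos]).min()
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
            mvp += 1
            if mvp > max_iter:
                break
        x = x * y
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        mvp += 1
        rat = rout / rold
        rold = rout
        eta = g * rat
        eta = min(eta, etamax)
        eta = max(eta, stop_tol / max(np.sqrt(rout), 1e-300))
    return x, bool(rout <= rt)


def kr_balance(
    matrix: ContactMatrix,
    tol: float = 1e-6,
    max_iter: int = 1000,
    mask: np.ndarray | None = None,
    low_quantile: float = 0.02,
) -> np.ndarray:
    """Balance a contact matrix in place; returns the per-bin weights.

    Unmasked balanced row sums equal one to within ``tol``. On
    non-convergence a square-root-of-marginal fallback is used and flagged
    via ``matrix.balancing_converged``.
    """
    if mask is None:
        mask = default_mask(matrix, low_quantile)
    n = matrix.n_bins
    weights = np.full(n, np.nan)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        matrix.weights = weights
        matrix.mask = mask
        matrix.balancing_converged = True
        return weights
    A = matrix.dense()[np.ix_(idx, idx)].astype(float)
    # scale to O(1) so the Newton iteration starts near the solution
    scale = A.sum(axis=1).mean()
    x, converged = _kr_weights(A / scale, tol, max_iter)
    if not converged or not np.all(np.isfinite(x)) or np.any(x <= 0):
        log.warning(
            "%s: KR did not converge after %d matvecs; falling back to sqrt scaling",
            matrix.chrom,
            max_iter,
        )
        rs = A.sum(axis=1)
        x = 1.0 / np.sqrt(rs)
        converged = False
    weights[idx] = x / np.sqrt(scale)
    matrix.weights = weights
    matrix.mask = mask
    matrix.balancing_converged = converged
    return weights


def expected_profile(matrix: ContactMatrix) -> np.ndarray:
    """Per-distance mean balanced value over unmasked pixels.

    Entry ``d`` is the mean balanced contact at separation ``d`` bins; NaN for
    distances with no unmasked pixel.
    """
    b = matrix.balanced_dense()
    n = matrix.n_bins
    out = np.full(n, np.nan)
    for d in range(n):
        diag = np.diagonal(b, offset=d)
        good = ~np.isnan(diag)
        if good.any():
            out[d] = diag[good].mean()
    return out


def expected_surface(matrix: ContactMatrix, profile: np.ndarray | None = None) -> np.ndarray:
    """Dense expected matrix E[i, j] = profile[|i - j|], NaN on masked bins."""
    if profile is None:
        profile = expected_profile(matrix)
    n = matrix.n_bins
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    surf = profile[d]
    bad = ~matrix.mask
    surf[bad, :] = np.nan
    surf[:, bad] = np.nan
    return surf


def observed_over_expected(
    matrix: ContactMatrix, profile: np.ndarray | None = None
) -> np.ndarray:
    """Observed/expected matrix of balanced values.

    By construction the mean over every unmasked diagonal equals one; masked
    pixels and zero-expected diagonals propagate as NaN.
    """
    b = matrix.balanced_dense()
    e = expected_surface(matrix, profile)
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = b / e
    oe[~np.isfinite(oe)] = np.nan
    return oe


def decay_curve(matrix: ContactMatrix, max_distance_bins: int | None = None) -> np.ndarray:
    """Contact-probability decay: per-distance raw contact fraction.

    Normalised so the returned probabilities sum to one over the grid.
    """
    d_raw = matrix.dense()
    n = matrix.n_bins
    kmax = n if max_distance_bins is None else min(n, max_distance_bins + 1)
    sums = np.array([np.diagonal(d_raw, offset=k).sum() for k in range(kmax)], dtype=float)
    total = sums.sum()
    if total > 0:
        sums /= total
    return sums


def compare_decay(curves: dict[str, np.ndarray]) -> "pd.DataFrame":
    """Per-distance log2 ratio of every curve against the first one."""
    import pandas as pd

    names = list(curves)
    ref = curves[names[0]]
    n = min(len(c) for c in curves.values())
    rows = {"distance_bin": np.arange(n)}
    with np.errstate(divide="ignore", invalid="ignore"):
        for name in names:
            rows[f"log2_{name}_vs_{names[0]}"] = np.log2(curves[name][:n] / ref[:n])
    return pd.DataFrame(rows)
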
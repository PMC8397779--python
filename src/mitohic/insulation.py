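"""Insulation scores, boundary strength and candidate-domain detection.

The insulation score of a bin is the log2-normalised sum of balanced contacts
in a square window that slides along the diagonal one bin off it: low scores
mark positions that few contacts cross, i.e. domain boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .matrix import ContactMatrix

log = logging.getLogger("mitohic.insulation")


@dataclass
class InsulationTrack:
    chrom: str
    bin_size: int
    values: np.ndarray  # log2 insulation; NaN where masked
    window_sums: np.ndarray  # balanced window sums (diagnostic)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)


def _window_sums(mat: np.ndarray, w: int, offset: int) -> np.ndarray:
    """Sum of mat[b-w : b, b+offset : b+offset+w] for every bin b (else NaN)."""
    n = mat.shape[0]
    out = np.full(n, np.nan)
    z = np.nan_to_num(mat, nan=0.0)
    # summed-area table for O(1) rectangle sums
    sat = np.zeros((n + 1, n + 1))
    sat[1:, 1:] = z.cumsum(axis=0).cumsum(axis=1)

    def rect(r0, r1, c0, c1):  # rows [r0, r1), cols [c0, c1)
        return sat[r1, c1] - sat[r0, c1] - sat[r1, c0] + sat[r0, c0]

    for b in range(w, n - w - offset + 1):
        out[b] = rect(b - w, b, b + offset, b + offset + w)
    return out


def insulation_score(
    matrix: ContactMatrix,
    window_bins: int = 12,
    offset_bins: int = 1,
    min_counts: float = 12.0,
    pseudo_count: float = 1.0,
) -> InsulationTrack:
    """Per-bin insulation from a balanced matrix.

    The window for bin b covers rows [b-w, b) x cols [b+offset, b+offset+w);
    the score is log2((window sum + 1) / (chromosomal mean + 1)). Bins whose
    window is truncated by a chromosome end, or whose raw window count sum
    falls below ``min_counts``, are masked.
    """
    w, off = window_bins, offset_bins
    n = matrix.n_bins
    values = np.full(n, np.nan)
    if n < 2 * w + off:
        log.warning("%s shorter than insulation window; all bins masked", matrix.chrom)
        return InsulationTrack(matrix.chrom, matrix.bin_size, values, np.full(n, np.nan))
    bal = matrix.balanced_dense()
    raw = matrix.dense().astype(float)
    bad = ~matrix.mask
    raw[bad, :] = np.nan
    raw[:, bad] = np.nan
    sums = _window_sums(bal, w, off)
    raw_sums = _window_sums(raw, w, off)
    usable = np.isfinite(sums) & np.isfinite(raw_sums) & (raw_sums >= min_counts)
    # bins sitting on masked rows carry no signal of their own
    usable &= matrix.mask
    if usable.any():
        mean = sums[usable].mean()
        values[usable] = np.log2((sums[usable] + pseudo_count) / (mean + pseudo_count))
    return InsulationTrack(matrix.chrom, matrix.bin_size, values, sums)


def boundary_strength(
    track: InsulationTrack, boundary_bin: int, window_bp: float = 120_000
) -> float:
    """Boundary strength dIS = 2^(max IS in +-window) - 2^(IS at boundary).

    Computed on the unlogged insulation values so dIS >= 0 by construction;
    NaN when the window (or the boundary itself) is fully masked.
    """
    wb = int(window_bp // track.bin_size)
    lo = max(0, boundary_bin - wb)
    hi = min(len(track.values), boundary_bin + wb + 1)
    window = track.values[lo:hi]
    at = track.values[boundary_bin] if 0 <= boundary_bin < len(track.values) else np.nan
    if not np.isfinite(at) or not np.any(np.isfinite(window)):
        return np.nan
    return float(2 ** np.nanmax(window) - 2**at)


def candidate_domains(
    matrix: ContactMatrix | None = None,
    track: InsulationTrack | None = None,
    mode: str = "standin",
    imported: "pd.DataFrame | None" = None,
    prominence: float = 0.2,
    sub_prominence: float = 0.1,
    sub_cap_bp: int = 500_000,
    max_span_bp: int = 2_000_000,
) -> "pd.DataFrame":
    """Candidate domains between consecutive insulation local minima.

    ``mode='standin'`` is the internal caller: local minima of the insulation
    track (peak prominence >= ``prominence``) delimit domains, capped at
    ``max_span_bp``; a second, more sensitive sweep (``sub_prominence``)
    contributes additional sub-domains no larger than ``sub_cap_bp``.
    ``mode='import'`` passes an external domain table through unchanged.
    """
    import pandas as pd

    if mode == "import":
        if imported is None:
            raise ValueError("import mode requires a domain table")
        return imported.copy()
    if track is None:
        if matrix is None:
            raise ValueError("stand-in mode requires a matrix or a track")
        track = insulation_score(matrix)
    bs = track.bin_size
    vals = np.where(track.valid, track.values, np.nan)
    filled = np.nan_to_num(vals, nan=np.nanmax(vals) if np.any(track.valid) else 0.0)

    def minima(prom):
        peaks, _ = find_peaks(-filled, prominence=prom)
        return peaks[track.valid[peaks]]

    def domains_from(mins, cap_bp):
        out = []
        for a, b in zip(mins[:-1], mins[1:]):
            span = (b - a) * bs
            if 0 < span <= cap_bp:
                out.append((track.chrom, int(a) * bs, int(b) * bs))
        return out

    rows = domains_from(minima(prominence), max_span_bp)
    rows += domains_from(minima(sub_prominence), sub_cap_bp)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"]).drop_duplicates(
        ignore_index=True
    )
    return df.sort_values(["chrom", "start", "end"], ignore_index=True)
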
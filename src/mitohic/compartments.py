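"""A/B compartment calling and compartment-level statistics.

Compartments are read from the first eigenvector (EV1) of the Pearson
correlation matrix of the per-chromosome observed/expected map, with the
global sign oriented so that EV1 correlates positively with gene density
(A = active = gene rich). On top of EV1 the module computes saddle matrices
and the genome-wide compartment strength, the distance-resolved
compartmentalisation curve R(s), and tiered local B-B / A-A interaction
strengths with length-preserving shuffled controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger("mitohic.compartments")


@dataclass
class CompartmentProfile:
    """Per-bin EV1 values and A/B labels for one chromosome of one sample."""

    chrom: str
    bin_size: int
    ev1: np.ndarray  # NaN on masked bins
    labels: np.ndarray  # 'A', 'B' or '' (undefined)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.ev1)


def call_compartments(
    oe: np.ndarray, gene_density: np.ndarray, chrom: str, bin_size: int
) -> CompartmentProfile:
    """EV1 of the Pearson correlation of O/E, sign-fixed by gene density.

    Masked bins (NaN rows in the O/E matrix) get EV1 = NaN and an undefined
    label. Labels: A where EV1 > 0, B where EV1 < 0.
    """
    n = oe.shape[0]
    valid = np.flatnonzero(~np.all(np.isnan(oe), axis=1))
    ev1 = np.full(n, np.nan)
    labels = np.array([""] * n, dtype=object)
    if valid.size < 3:
        raise ValueError(f"{chrom}: too few usable bins for compartment calling")
    sub = oe[np.ix_(valid, valid)]
    # column pairs can still contain isolated NaNs (zero-expected diagonals)
    sub = np.where(np.isfinite(sub), sub, 1.0)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub)
    corr = np.where(np.isfinite(corr), corr, 0.0)
    if not np.any(corr):
        raise ValueError(f"{chrom}: degenerate correlation matrix")
    evals, evecs = np.linalg.eigh(corr)
    vec = evecs[:, -1]
    gd = np.asarray(gene_density, float)[valid]
    if gd.std() > 0 and np.corrcoef(vec, gd)[0, 1] < 0:
        vec = -vec
    ev1[valid] = vec
    labels[valid] = np.where(vec > 0, "A", "B")
    labels[valid[vec == 0]] = ""
    return CompartmentProfile(chrom, bin_size, ev1, labels)


# ---------------------------------------------------------------------------
# saddle and compartment strength
# ---------------------------------------------------------------------------

def saddle_matrix(oe: np.ndarray, reference: CompartmentProfile, sections: int = 50) -> np.ndarray:
    """Saddle: O/E reordered by reference EV1 ascending, averaged in sections.

    Top-left corner collects B-B interactions, bottom-right A-A.
    """
    valid = np.flatnonzero(reference.valid & ~np.all(np.isnan(oe), axis=1))
    if valid.size < sections:
        raise ValueError(f"{reference.chrom}: fewer usable bins than saddle sections")
    order = valid[np.argsort(reference.ev1[valid], kind="stable")]
    sub = oe[np.ix_(order, order)]
    groups = np.array_split(np.arange(order.size), sections)
    out = np.full((sections, sections), np.nan)
    for a, ga in enumerate(groups):
        for b, gb in enumerate(groups):
            block = sub[np.ix_(ga, gb)]
            good = np.isfinite(block)
            if good.any():
                out[a, b] = block[good].mean()
    return out


def compartment_strength(
    oe_by_chrom: dict[str, np.ndarray],
    reference: dict[str, CompartmentProfile],
    top_fraction: float = 0.2,
    sections: int = 50,
) -> tuple[float, dict[str, float]]:
    """Genome-wide compartment strength (log2) plus the per-chromosome ratios.

    Per chromosome: (median AA + median BB) / (median AB + median BA) over
    the pixels linking the top/bottom ``top_fraction`` of bins ranked by the
    reference EV1; the genome value is log2 of the chromosome mean.
    Chromosomes with fewer usable bins than saddle sections are skipped.
    """
    per_chrom: dict[str, float] = {}
    for chrom, oe in oe_by_chrom.items():
        prof = reference[chrom]
        valid = np.flatnonzero(prof.valid & ~np.all(np.isnan(oe), axis=1))
        if valid.size < sections:
            log.warning("%s: <%d usable bins, skipped for compartment strength", chrom, sections)
            continue
        order = valid[np.argsort(prof.ev1[valid], kind="stable")]
        k = max(1, int(round(top_fraction * order.size)))
        bot, top = order[:k], order[-k:]

        def med(rows, cols):
            block = oe[np.ix_(rows, cols)]
            vals = block[np.isfinite(block)]
            return np.median(vals) if vals.size else np.nan

        aa, bb = med(top, top), med(bot, bot)
        ab, ba = med(bot, top), med(top, bot)
        denom = ab + ba
        if denom > 0 and np.isfinite(aa + bb + denom):
            per_chrom[chrom] = (aa + bb) / denom
    if not per_chrom:
        raise ValueError("no chromosome usable for compartment strength")
    genome = float(np.log2(np.mean(list(per_chrom.values()))))
    return genome, per_chrom


# ---------------------------------------------------------------------------
# R(s) compartmentalisation expansion curve
# ---------------------------------------------------------------------------

def rs_curve(
    oe: np.ndarray,
    profile: CompartmentProfile,
    max_distance: int = 125_000_000,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Spearman R between EV1 products and O/E at each separation s.

    Distances run from one bin up to ``max_distance``; separations with fewer
    than ``min_pairs`` informative pairs are reported missing.
    """
    n = oe.shape[0]
    bs = profile.bin_size
    smax = min(n - 1, max_distance // bs)
    ev = profile.ev1
    rows = []
    for s in range(1, smax + 1):
        i = np.arange(n - s)
        j = i + s
        prod = ev[i] * ev[j]
        vals = oe[i, j]
        good = np.isfinite(prod) & np.isfinite(vals)
        if good.sum() < min_pairs:
            rows.append((s * bs, np.nan, int(good.sum())))
            continue
        r = sps.spearmanr(prod[good], vals[good]).statistic
        rows.append((s * bs, float(r), int(good.sum())))
    return pd.DataFrame(rows, columns=["s", "R", "n_pairs"])


def average_rs_curves(curves: list[pd.DataFrame]) -> pd.DataFrame:
    """Average per-chromosome R(s) curves on the common distance grid."""
    merged = pd.concat(curves)
    return (
        merged.groupby("s", as_index=False)
        .agg(R=("R", "mean"), n_pairs=("n_pairs", "sum"))
        .sort_values("s", ignore_index=True)
    )


# ---------------------------------------------------------------------------
# tiered local B-B / A-A interactions
# ---------------------------------------------------------------------------

def compartment_domains(profile: CompartmentProfile) -> pd.DataFrame:
    """Maximal same-label runs of bins: the compartment-domain segmentation."""
    rows = []
    labels = profile.labels
    n = len(labels)
    i = 0
    while i < n:
        lab = labels[i]
        j = i
        while j + 1 < n and labels[j + 1] == lab:
            j += 1
        if lab in ("A", "B"):
            rows.append(
                (profile.chrom, i * profile.bin_size, (j + 1) * profile.bin_size, lab)
            )
        i = j + 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])


def _rect_mean(oe: np.ndarray, rows: slice, cols: slice) -> float:
    block = oe[rows, cols]
    vals = block[np.isfinite(block)]
    return float(vals.mean()) if vals.size else np.nan


def tier_interactions(
    oe: np.ndarray,
    domains: pd.DataFrame,
    bin_size: int,
    chrom_length: int,
    tiers: tuple[int, ...] = (1, 2, 3, 4),
    flank: int = 250_000,
) -> pd.DataFrame:
    """Tiered pair strengths: mean O/E between 250-kb flanks around runs of
    opposite-type compartment domains.

    A tier-k B-B pair spans k consecutive A domains: the rectangle between the
    flank upstream of the first A start and the flank downstream of the k-th A
    end. Pairs whose flank leaves the chromosome are skipped.
    """
    fbins = flank // bin_size
    n = oe.shape[0]
    dom = domains.reset_index(drop=True)
    rows = []
    for pair_type, inner in (("BB", "A"), ("AA", "B")):
        idx = dom.index[dom["label"] == inner].to_numpy()
        for k in tiers:
            for m in range(len(idx) - k + 1):
                run = idx[m : m + k]
                # require k inner-type domains strictly alternating with the
                # opposite type (full-frame index step of exactly 2)
                if k > 1 and not np.all(np.diff(run) == 2):
                    continue
                start_bin = dom.loc[run[0], "start"] // bin_size
                end_bin = dom.loc[run[-1], "end"] // bin_size
                r0, r1 = start_bin - fbins, start_bin
                c0, c1 = end_bin, end_bin + fbins
                if r0 < 0 or c1 > n or c1 * bin_size > chrom_length:
                    log.debug("tier pair skipped at chromosome edge")
                    continue
                strength = _rect_mean(oe, slice(r0, r1), slice(c0, c1))
                rows.append(
                    (pair_type, k, r0 * bin_size, r1 * bin_size, c0 * bin_size,
                     c1 * bin_size, strength)
                )
    return pd.DataFrame(
        rows,
        columns=["pair_type", "tier", "up_start", "up_end", "down_start",
                 "down_end", "strength"],
    )


def shuffled_tier_control(
    oe: np.ndarray,
    domains: pd.DataFrame,
    bin_size: int,
    chrom_length: int,
    n: int = 500,
    seed: int = 0,
    flank: int = 250_000,
) -> pd.DataFrame:
    """Distance-matched random control: length-preserving shuffled intervals.

    Randomly selects ``n`` compartment domains, relocates each uniformly on
    the chromosome keeping its length, and computes the same flank-rectangle
    strength as the tier-1 statistic.
    """
    rng = np.random.default_rng(seed)
    fbins = flank // bin_size
    nb = oe.shape[0]
    lens = (domains["end"] - domains["start"]).to_numpy()
    if lens.size == 0:
        return pd.DataFrame(columns=["pair_type", "tier", "strength"])
    rows = []
    picks = rng.integers(0, lens.size, size=n)
    for p in picks:
        length = int(lens[p])
        max_start = chrom_length - length - flank
        if max_start <= flank:
            continue
        start = int(rng.integers(flank, max_start))
        sb, eb = start // bin_size, (start + length) // bin_size
        r0, r1 = sb - fbins, sb
        c0, c1 = eb, eb + fbins
        if r0 < 0 or c1 > nb:
            continue
        rows.append(("shuffled", 1, _rect_mean(oe, slice(r0, r1), slice(c0, c1))))
    return pd.DataFrame(rows, columns=["pair_type", "tier", "strength"])
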
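"""Donut-filtered loop calling and downstream loop analyses.

The caller follows the HICCUPS idea restricted to the donut filter: the local
expected value of a pixel is estimated from a square annulus around it
(excluding the row/column cross), rescaled by the distance-decay expectation;
significance is a Poisson upper tail on the raw count with
Benjamini-Hochberg correction inside lambda chunks. Significant pixels from
all samples are merged, cleaned of ubiquitous artifacts, clustered into
loops by the two-pass growing-radius rule, complemented by a replicate-based
false-negative recovery step, categorised by CTCF/cohesin and CRE occupancy
at their anchors, and quantified per sample as the mean observed/donut-
expected over the 3x3 summit neighbourhood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.signal import fftconvolve

from .matrix import ContactMatrix, expected_profile
from .stats import bh_adjust, kmeans_labels, zscore_rows

log = logging.getLogger("mitohic.loops")

LAMBDA_CHUNK_BASE = 2 ** (1.0 / 3.0)  # HICCUPS-style lambda chunking


# ---------------------------------------------------------------------------
# donut statistics
# ---------------------------------------------------------------------------

def donut_kernel(inner_diam: int, outer_diam: int) -> np.ndarray:
    """Square annulus between the two diameters, excluding the centre cross."""
    r_out = outer_diam // 2
    r_in = inner_diam // 2
    size = 2 * r_out + 1
    di = np.abs(np.arange(size) - r_out)
    cheb = np.maximum.outer(di, di)
    k = (cheb <= r_out) & (cheb > r_in)
    k &= (di[:, None] != 0) & (di[None, :] != 0)
    return k.astype(float)


@dataclass
class DonutResult:
    """Band-stored per-pixel donut statistics for one chromosome/sample.

    Arrays are indexed ``[i, d]`` for the pixel (i, i + d); NaN marks pixels
    where the statistic is undefined (masked bins, truncated donut, or
    separation outside the evaluated range).
    """

    chrom: str
    bin_size: int
    n_bins: int
    max_d: int
    obs: np.ndarray
    lam: np.ndarray  # raw-scale donut expected
    oe_donut: np.ndarray
    q: np.ndarray
    fdr: float
    min_enrichment: float = 1.5

    def get(self, arr_name: str, i: int, j: int) -> float:
        d = j - i
        if d < 0:
            i, d = j, -d
        if not (0 <= i < self.n_bins and 0 <= d <= self.max_d and i + d < self.n_bins):
            return np.nan
        return float(getattr(self, arr_name)[i, d])

    def significant(self, fdr: float | None = None) -> pd.DataFrame:
        """Pixels below the FDR cut that are also locally enriched.

        Besides q < fdr a pixel must exceed ``min_enrichment`` observed over
        donut-expected (the HICCUPS fold-change convention); bare
        significance at permissive FDR floods the list with marginal pixels.
        """
        fdr = self.fdr if fdr is None else fdr
        ii, dd = np.nonzero(
            (np.nan_to_num(self.q, nan=1.0) < fdr)
            & (np.nan_to_num(self.oe_donut, nan=0.0) > self.min_enrichment)
        )
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "bin_i": ii,
                "bin_j": ii + dd,
                "resolution": self.bin_size,
                "obs": self.obs[ii, dd],
                "lam": self.lam[ii, dd],
                "oe_donut": self.oe_donut[ii, dd],
                "q": self.q[ii, dd],
            }
        )


def _band(dense: np.ndarray, max_d: int) -> np.ndarray:
    n = dense.shape[0]
    out = np.full((n, max_d + 1), np.nan, dtype=np.float64)
    for d in range(min(max_d + 1, n)):
        out[: n - d, d] = np.diagonal(dense, offset=d)
    return out


def lambda_chunked_bh(p: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """BH-adjust p-values within lambda chunks (powers of 2^(1/3))."""
    q = np.full_like(p, np.nan)
    good = np.isfinite(p) & np.isfinite(lam)
    if not good.any():
        return q
    chunk = np.zeros(p.shape, dtype=int)
    pos = good & (lam > 0)
    chunk[pos] = np.ceil(np.log(lam[pos]) / np.log(LAMBDA_CHUNK_BASE)).astype(int)
    for c in np.unique(chunk[good]):
        sel = good & (chunk == c)
        q[sel] = bh_adjust(p[sel])
    return q


def donut_stats(
    matrix: ContactMatrix,
    inner_diam: int,
    outer_diam: int,
    max_distance_bp: int = 2_000_000,
    fdr: float = 0.2,
    min_donut_fraction: float = 0.5,
    profile: np.ndarray | None = None,
) -> DonutResult:
    """Per-pixel donut expected, Poisson p and lambda-chunked BH q.

    Pixels are evaluated at separations between the outer donut radius + 1
    and ``max_distance_bp``. The donut expected is computed on balanced
    values and converted to the raw-count scale through the balancing
    weights, so the Poisson tail applies to integer observed counts.
    """
    n = matrix.n_bins
    bs = matrix.bin_size
    max_d = min(n - 1, max_distance_bp // bs)
    r_out = outer_diam // 2
    kern = donut_kernel(inner_diam, outer_diam)
    ksum = kern.sum()

    bal = matrix.balanced_dense()
    valid = np.isfinite(bal)
    bal0 = np.nan_to_num(bal, nan=0.0)
    if profile is None:
        profile = expected_profile(matrix)
    dist = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    prof = np.nan_to_num(profile, nan=0.0)
    ebal = prof[np.minimum(dist, n - 1)]
    ebal = np.where(valid, ebal, 0.0)

    donut_o = fftconvolve(bal0, kern, mode="same")
    donut_e = fftconvolve(ebal, kern, mode="same")
    donut_n = fftconvolve(valid.astype(float), kern, mode="same")

    with np.errstate(divide="ignore", invalid="ignore"):
        lam_bal = donut_o / donut_e * ebal
    w = matrix.weights
    ww = np.outer(w, w)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam_raw = lam_bal / ww
    ok = (
        valid
        & (donut_e > 0)
        & (donut_n >= min_donut_fraction * ksum - 1e-9)
        & (dist > r_out)
        & (dist <= max_d)
    )
    lam_raw[~ok] = np.nan

    obs_band = _band(matrix.dense().astype(float), max_d)
    lam_band = _band(lam_raw, max_d)
    with np.errstate(divide="ignore", invalid="ignore"):
        oe_band = obs_band / lam_band
    p_band = np.full_like(lam_band, np.nan)
    good = np.isfinite(lam_band) & np.isfinite(obs_band)
    p_band[good] = sps.poisson.sf(obs_band[good] - 1, lam_band[good])
    q_band = lambda_chunked_bh(p_band, lam_band)
    return DonutResult(matrix.chrom, bs, n, max_d, obs_band, lam_band, oe_band, q_band, fdr)


# ---------------------------------------------------------------------------
# artifact removal and pixel clustering
# ---------------------------------------------------------------------------

def filter_artifacts(pixels: pd.DataFrame, max_samples: int = 6) -> pd.DataFrame:
    """Drop pixels significant in more than ``max_samples`` of the samples.

    ``pixels`` must carry one row per (pixel, sample) with columns
    chrom/bin_i/bin_j/resolution/sample. Ubiquitous pixels are outlier
    artifacts, not stage-specific loops.
    """
    keycols = ["chrom", "resolution", "bin_i", "bin_j"]
    counts = pixels.groupby(keycols)["sample"].nunique()
    bad = counts[counts > max_samples].index
    if len(bad):
        log.info("artifact filter removed %d ubiquitous pixels", len(bad))
    idx = pixels.set_index(keycols).index
    return pixels[~idx.isin(bad)].reset_index(drop=True)


@dataclass
class LoopCluster:
    chrom: str
    resolution: int
    summit_i: int
    summit_j: int
    q_min: float
    members: pd.DataFrame
    samples: frozenset
    status: str = ""
    category: str = ""
    recovered: bool = False
    strength: dict = field(default_factory=dict)
    dynamics_cluster: int = 0
    persistence: str = "n/a"
    s_i_min: float = np.nan
    interrupted: bool = False
    supported: bool = False

    @property
    def anchor1(self) -> tuple[int, int]:
        return self.summit_i * self.resolution, (self.summit_i + 1) * self.resolution

    @property
    def anchor2(self) -> tuple[int, int]:
        return self.summit_j * self.resolution, (self.summit_j + 1) * self.resolution

    @property
    def x(self) -> float:  # bp centre of upstream anchor
        return (self.summit_i + 0.5) * self.resolution

    @property
    def y(self) -> float:
        return (self.summit_j + 0.5) * self.resolution

    @property
    def span(self) -> float:
        return self.y - self.x


def cluster_pixels(pixels: pd.DataFrame, radius_bp: float = 20_000) -> list[LoopCluster]:
    """Greedy two-pass clustering of significant pixels ordered by q_min.

    Pixels (deduplicated, with a precomputed cross-sample ``q_min``) are
    sorted by ascending q_min (ties broken by genomic coordinate). The best
    remaining pixel absorbs everything within ``radius_bp``; the cluster
    centroid and its far-edge distance s are then computed and a second pass
    absorbs pixels within radius + s of the centroid. Repeats until no pixel
    remains; the summit of each cluster is its lowest-q_min member.
    """
    clusters: list[LoopCluster] = []
    for chrom, sub in pixels.groupby("chrom", sort=True):
        sub = sub.sort_values(
            ["q_min", "bin_i", "bin_j"], kind="stable", ignore_index=True
        )
        x = (sub["bin_i"].to_numpy() + 0.5) * sub["resolution"].to_numpy()
        y = (sub["bin_j"].to_numpy() + 0.5) * sub["resolution"].to_numpy()
        alive = np.ones(len(sub), dtype=bool)
        order = np.arange(len(sub))
        while alive.any():
            top = order[alive][0]
            d = np.hypot(x - x[top], y - y[top])
            take = alive & (d <= radius_bp)
            cx, cy = x[take].mean(), y[take].mean()
            s = np.hypot(x[take] - cx, y[take] - cy).max()
            alive &= ~take
            d2 = np.hypot(x - cx, y - cy)
            take2 = alive & (d2 <= radius_bp + s)
            alive &= ~take2
            members = sub[take | take2]
            summit = members.iloc[members["q_min"].to_numpy().argmin()]
            samples = frozenset(
                s for ss in members["samples"] for s in ss
            ) if "samples" in members else frozenset()
            clusters.append(
                LoopCluster(
                    chrom=chrom,
                    resolution=int(summit["resolution"]),
                    summit_i=int(summit["bin_i"]),
                    summit_j=int(summit["bin_j"]),
                    q_min=float(summit["q_min"]),
                    members=members.reset_index(drop=True),
                    samples=samples,
                )
            )
    return clusters


def filter_singletons(clusters: list[LoopCluster], max_q: float = 0.02) -> list[LoopCluster]:
    """Keep singleton clusters only when strongly significant.

    Single unclustered pixels at a permissive FDR are dominated by
    multiple-testing leakage; the HICCUPS convention retains a loop without
    neighbouring pixels only when its q-value is far below the cut.
    """
    return [c for c in clusters if len(c.members) > 1 or c.q_min <= max_q]


def classify_status(
    clusters: list[LoopCluster], control_samples: set, auxin_samples: set
) -> None:
    """Lost = control-only pixels; gained = auxin-only; otherwise retained."""
    for cl in clusters:
        in_ctrl = bool(cl.samples & set(control_samples))
        in_aux = bool(cl.samples & set(auxin_samples))
        cl.status = "lost" if in_ctrl and not in_aux else (
            "gained" if in_aux and not in_ctrl else "retained"
        )


# ---------------------------------------------------------------------------
# false-negative recovery
# ---------------------------------------------------------------------------

def _pixel_passes(res: DonutResult, i: int, j: int, fdr, min_oe, min_obs) -> bool:
    q = res.get("q", i, j)
    oe = res.get("oe_donut", i, j)
    obs = res.get("obs", i, j)
    return (
        np.isfinite(q) and q < fdr and np.isfinite(oe) and oe > min_oe and obs > min_obs
    )


def recover_missed_loops(
    candidate_pixels: pd.DataFrame,
    merged_stats: dict[str, DonutResult],
    replicate_stats: dict[str, list[DonutResult]],
    strict_stages: tuple = ("ana_telo", "early_G1"),
    lenient_stages: tuple = ("mid_G1",),
    fdr: float = 0.2,
    min_oe: float = 1.5,
    min_obs: float = 10.0,
) -> pd.DataFrame:
    """Replicate-supported rescue of loop pixels dropped by the main caller.

    A pixel is valid at a strict stage when it passes all three filters
    (q < ``fdr``, observed/donut-expected > ``min_oe``, observed >
    ``min_obs``) in the replicate-merged sample and in every individual
    replicate; at a lenient stage the three filters must hold in all but at
    most one of {merged, replicates}. A pixel valid in at least one
    post-mitotic stage is returned.
    """
    rows = []
    for _, px in candidate_pixels.iterrows():
        i, j = int(px["bin_i"]), int(px["bin_j"])
        valid_any = False
        for stage in strict_stages:
            if stage not in merged_stats:
                continue
            items = [merged_stats[stage]] + list(replicate_stats.get(stage, []))
            if all(_pixel_passes(r, i, j, fdr, min_oe, min_obs) for r in items):
                valid_any = True
                break
        if not valid_any:
            for stage in lenient_stages:
                if stage not in merged_stats:
                    continue
                items = [merged_stats[stage]] + list(replicate_stats.get(stage, []))
                npass = sum(_pixel_passes(r, i, j, fdr, min_oe, min_obs) for r in items)
                if npass >= len(items) - 1 and npass >= 1:
                    valid_any = True
                    break
        if valid_any:
            rows.append(px)
    return pd.DataFrame(rows).reset_index(drop=True) if rows else candidate_pixels.iloc[:0]


def drop_prometa_outliers(
    pixels: pd.DataFrame,
    prometa_stats: DonutResult,
    top_fraction: float = 0.05,
    max_distance_bp: int = 2_000_000,
) -> pd.DataFrame:
    """Remove the top prometaphase O/E-donut tail and over-distance pixels."""
    oe_pm = np.array(
        [prometa_stats.get("oe_donut", int(i), int(j)) for i, j in
         zip(pixels["bin_i"], pixels["bin_j"])]
    )
    finite = oe_pm[np.isfinite(oe_pm)]
    cut = np.quantile(finite, 1 - top_fraction) if finite.size else np.inf
    sep = (pixels["bin_j"] - pixels["bin_i"]) * pixels["resolution"]
    keep = ~(np.nan_to_num(oe_pm, nan=-np.inf) > cut) & (sep <= max_distance_bp)
    return pixels[keep].reset_index(drop=True)


def drop_adjacent_to_loops(
    pixels: pd.DataFrame, clusters: list[LoopCluster], margin_bins: int = 1
) -> pd.DataFrame:
    """Remove pixels overlapping or adjacent (within one bin) to known loops."""
    member_px: dict[str, set] = {}
    for cl in clusters:
        st = member_px.setdefault(cl.chrom, set())
        for bi, bj in cl.members[["bin_i", "bin_j"]].itertuples(index=False):
            st.add((int(bi), int(bj)))
    keep = []
    for _, px in pixels.iterrows():
        near = False
        known = member_px.get(px["chrom"], set())
        for di in range(-margin_bins, margin_bins + 1):
            for dj in range(-margin_bins, margin_bins + 1):
                if (int(px["bin_i"]) + di, int(px["bin_j"]) + dj) in known:
                    near = True
                    break
            if near:
                break
        keep.append(not near)
    return pixels[np.array(keep, bool)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# resolution merge and categorisation
# ---------------------------------------------------------------------------

def merge_resolutions(
    clusters_10kb: list[LoopCluster], clusters_25kb: list[LoopCluster]
) -> list[LoopCluster]:
    """Union of both resolutions; drop 25-kb loops duplicating a 10-kb loop.

    Overlap = both anchors within one 25-kb bin of the 10-kb cluster anchors.
    """
    out = list(clusters_10kb)
    for c25 in clusters_25kb:
        dup = any(
            c10.chrom == c25.chrom
            and abs(c10.x - c25.x) <= 25_000
            and abs(c10.y - c25.y) <= 25_000
            for c10 in clusters_10kb
        )
        if not dup:
            out.append(c25)
    return out


def _anchor_hit(peaks: pd.DataFrame, chrom: str, center: float, window: float) -> bool:
    sub = peaks[peaks["chrom"] == chrom]
    lo, hi = center - window / 2, center + window / 2
    return bool(((sub["start"] < hi) & (sub["end"] > lo)).any())


def categorize_loops(
    clusters: list[LoopCluster],
    ctcf_cohesin: pd.DataFrame,
    cre: pd.DataFrame,
    anchor_window_bp: float = 30_000,
) -> None:
    """Assign structural / dual_function / cre / unclassified per cluster.

    A peak intersects an anchor when it overlaps (>= 1 bp) the 30-kb window
    centred on the anchor summit midpoint. Both anchors CTCF/cohesin-bound
    with CREs at neither or one anchor = structural; CTCF at both plus CREs
    at both = dual-function; CREs at both with CTCF at none or one = CRE.
    """
    for cl in clusters:
        ct1 = _anchor_hit(ctcf_cohesin, cl.chrom, cl.x, anchor_window_bp)
        ct2 = _anchor_hit(ctcf_cohesin, cl.chrom, cl.y, anchor_window_bp)
        cr1 = _anchor_hit(cre, cl.chrom, cl.x, anchor_window_bp)
        cr2 = _anchor_hit(cre, cl.chrom, cl.y, anchor_window_bp)
        nct, ncr = ct1 + ct2, cr1 + cr2
        if nct == 2 and ncr <= 1:
            cl.category = "structural"
        elif nct == 2 and ncr == 2:
            cl.category = "dual_function"
        elif ncr == 2 and nct <= 1:
            cl.category = "cre"
        else:
            cl.category = "unclassified"


# ---------------------------------------------------------------------------
# loop strength and dynamics
# ---------------------------------------------------------------------------

def loop_strength(
    cluster: LoopCluster, donut_by_sample: dict[str, DonutResult]
) -> dict[str, float]:
    """Mean observed/donut-expected over the 3x3 summit block, per sample.

    Masked pixels are dropped from the mean (flagged by the caller when
    fewer than 9 contribute, e.g. a summit one bin off the diagonal).
    """
    out = {}
    for sample, res in donut_by_sample.items():
        vals = [
            res.get("oe_donut", cluster.summit_i + di, cluster.summit_j + dj)
            for di in (-1, 0, 1)
            for dj in (-1, 0, 1)
        ]
        vals = [v for v in vals if np.isfinite(v)]
        out[sample] = float(np.mean(vals)) if vals else np.nan
        cluster.strength[sample] = out[sample]
    return out


def cluster_loop_dynamics(
    strengths: pd.DataFrame,
    control_cols: list[str],
    post_mitotic_control_cols: list[str],
    transient_hi_col: str,
    transient_lo_col: str,
    k: int = 4,
    seed: int = 0,
    restarts: int = 50,
) -> np.ndarray:
    """k-means dynamics clusters of CRE loop strengths in control samples.

    z-scores are taken across the control stages; clustering uses the three
    post-mitotic control columns. Labels are renumbered so cluster 1 is the
    transient class: maximal (z at ana/telo) - (z at mid-G1).
    """
    z = zscore_rows(strengths[control_cols].to_numpy(float))
    zdf = pd.DataFrame(z, columns=control_cols, index=strengths.index)
    lab = kmeans_labels(zdf[post_mitotic_control_cols].to_numpy(), k, seed, restarts)
    score = (zdf[transient_hi_col] - zdf[transient_lo_col]).to_numpy()
    from .stats import relabel_by_score

    return relabel_by_score(lab, score, descending=True)


def subcluster_persistence(
    strengths: pd.DataFrame,
    all_cols: list[str],
    post_mitotic_cols: list[str],
    auxin_late_col: str,
    seed: int = 0,
    restarts: int = 50,
) -> np.ndarray:
    """Split transient loops into persisting (P) vs non-persisting (NP).

    z-scores across both conditions; 2-means on the six post-mitotic columns;
    the subcluster with the higher auxin mid-G1 z persists under CTCF loss.
    """
    z = zscore_rows(strengths[all_cols].to_numpy(float))
    zdf = pd.DataFrame(z, columns=all_cols, index=strengths.index)
    lab = kmeans_labels(zdf[post_mitotic_cols].to_numpy(), 2, seed, restarts)
    mean_late = [zdf[auxin_late_col][lab == c].mean() for c in (0, 1)]
    p_cluster = int(np.argmax(mean_late))
    return np.where(lab == p_cluster, "P", "NP")


# ---------------------------------------------------------------------------
# structural / CRE interplay
# ---------------------------------------------------------------------------

def interplay_stats(
    cre_clusters: list[LoopCluster],
    structural_clusters: list[LoopCluster],
    loop_free_sites: pd.DataFrame | None = None,
    anchor_window_bp: float = 30_000,
) -> pd.DataFrame:
    """Interruption/support flags, s_i-min, per CRE loop.

    A structural loop *interrupts* a CRE loop when it covers exactly one of
    the CRE anchors (the anchor lies inside the structural span, extended by
    half the 30-kb anchor window) so that one structural anchor falls
    strictly between the CRE anchors; it *supports* the CRE loop when the
    CRE loop nests inside it. s_i-min is the distance from the influenced
    CRE anchor (the one nearer the interior structural anchor) to the
    nearest interior structural anchor. A parallel interruption flag is
    computed against loop-free CTCF/cohesin sites when given.
    """
    half = anchor_window_bp / 2
    rows = []
    for cl in cre_clusters:
        a1, a2 = cl.x, cl.y
        interior = []
        interrupted = supported = False
        for st in structural_clusters:
            if st.chrom != cl.chrom:
                continue
            s1, s2 = st.x, st.y
            covers1 = s1 - half < a1 < s2 + half
            covers2 = s1 - half < a2 < s2 + half
            if covers1 and covers2:
                supported = True
            elif covers1 or covers2:
                interrupted = True
            for m in (s1, s2):
                if a1 < m < a2:
                    interior.append(m)
        s_i_min = (
            min(min(abs(m - a1), abs(m - a2)) for m in interior)
            if interior
            else np.nan
        )
        site_interrupted = False
        if loop_free_sites is not None:
            sub = loop_free_sites[loop_free_sites["chrom"] == cl.chrom]
            mids = ((sub["start"] + sub["end"]) / 2).to_numpy()
            inside = mids[(mids > a1) & (mids < a2)]
            site_interrupted = bool(
                np.any(np.minimum(np.abs(inside - a1), np.abs(inside - a2)) <= half)
            )
        cl.s_i_min = s_i_min
        cl.interrupted = interrupted
        cl.supported = supported
        rows.append(
            (cl.chrom, cl.x, cl.y, interrupted, supported, s_i_min, site_interrupted)
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "x", "y", "interrupted", "supported", "s_i_min",
                 "site_interrupted"],
    )


def interplay_enrichment(
    flags: pd.Series, in_cluster: pd.Series
) -> tuple[float, float, bool]:
    """2x2 enrichment of a scenario flag in one loop cluster vs the rest."""
    from .stats import fisher_exact_2x2

    a = int((flags & in_cluster).sum())
    b = int((~flags & in_cluster).sum())
    c = int((flags & ~in_cluster).sum())
    d = int((~flags & ~in_cluster).sum())
    return fisher_exact_2x2(a, b, c, d)


# ---------------------------------------------------------------------------
# aggregate peak analysis
# ---------------------------------------------------------------------------

def apa(
    clusters: list[LoopCluster],
    oe: np.ndarray,
    chrom: str,
    bin_size: int,
    window_bins: int = 10,
    min_loop_bp: int = 100_000,
) -> np.ndarray | None:
    """Mean O/E pile-up around loop summits (numeric matrix, no rendering).

    Loops smaller than ``min_loop_bp`` and loops whose window leaves the
    matrix are excluded.
    """
    w = window_bins
    n = oe.shape[0]
    acc = np.zeros((2 * w + 1, 2 * w + 1))
    cnt = np.zeros_like(acc)
    used = 0
    for cl in clusters:
        if cl.chrom != chrom or cl.span < min_loop_bp:
            continue
        ci = int(round(cl.x / bin_size - 0.5))
        cj = int(round(cl.y / bin_size - 0.5))
        if ci - w < 0 or cj - w < 0 or ci + w >= n or cj + w >= n:
            continue
        block = oe[ci - w : ci + w + 1, cj - w : cj + w + 1]
        good = np.isfinite(block)
        acc[good] += block[good]
        cnt += good
        used += 1
    if used == 0:
        return None
    with np.errstate(invalid="ignore"):
        return acc / cnt
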
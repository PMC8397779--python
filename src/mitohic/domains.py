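"""Domain/boundary pipeline: cross-stage validation, boundary merging and
adjustment, cross-condition integration, aggregated domain analysis (ADA),
boundary dynamics clustering, chromatin-state-transition PCA and gene-domain
recovery.

Domains are carried as DataFrames with ``chrom``, ``start``, ``end`` (bp,
0-based half-open) plus provenance columns; boundary positions are bp
coordinates of bin starts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genome import STAGES
from .insulation import InsulationTrack
from .stats import fisher_exact_2x2, kmeans_labels, relabel_by_score, signed_rank, zscore_rows

log = logging.getLogger("mitohic.domains")


# ---------------------------------------------------------------------------
# cross-stage validation
# ---------------------------------------------------------------------------

def integrate_domains(
    stage_domains: dict[str, pd.DataFrame],
    reference_late: pd.DataFrame | None,
    bin_size: int,
    tol_bins: int = 8,
) -> pd.DataFrame:
    """Validate per-stage domains against later stages and average boundaries.

    A prometaphase domain must overlap (both boundaries within ``tol_bins``
    bins) at least three domains from later stages (including the late-G1
    reference); domains from later stages need at least one such match.
    Boundaries of retained domains are replaced by the mean over all
    overlapping later-stage matches; the stage of emergence is recorded.
    """
    tol = tol_bins * bin_size
    order = [s for s in STAGES if s in stage_domains]
    later_pool: dict[str, pd.DataFrame] = {}
    for i, stage in enumerate(order):
        parts = [stage_domains[s] for s in order[i + 1 :]]
        if reference_late is not None:
            parts.append(reference_late)
        later_pool[stage] = (
            pd.concat(parts, ignore_index=True)
            if parts
            else pd.DataFrame(columns=["chrom", "start", "end"])
        )
    rows = []
    for stage in order:
        need = 3 if stage == "prometa" else 1
        pool = later_pool[stage]
        if pool.empty and stage != "prometa":
            # nothing later to validate against (last stage, no reference):
            # domains pass through with their own coordinates
            for _, d in stage_domains[stage].iterrows():
                rows.append((d["chrom"], d["start"], d["end"], stage))
            continue
        for _, d in stage_domains[stage].iterrows():
            cand = pool[pool["chrom"] == d["chrom"]]
            hit = cand[
                (np.abs(cand["start"] - d["start"]) <= tol)
                & (np.abs(cand["end"] - d["end"]) <= tol)
            ]
            if len(hit) < need:
                continue
            start = float(hit["start"].mean())
            end = float(hit["end"].mean())
            rows.append((d["chrom"], start, end, stage))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "emergence"])
    if out.empty:
        return out
    out["start"] = out["start"].round().astype(int)
    out["end"] = out["end"].round().astype(int)
    return out.sort_values(["chrom", "start", "end"], ignore_index=True)


# ---------------------------------------------------------------------------
# boundary merging / adjustment
# ---------------------------------------------------------------------------

def merge_boundaries(positions, radius: float = 80_000) -> tuple[np.ndarray, dict]:
    """Iteratively merge boundaries closer than ``radius`` (bp).

    Starting from the first (5'-most) unprocessed boundary, all boundaries
    less than ``radius`` away are absorbed and the group is replaced by the
    mean of its coordinates; the sweep repeats on the remainder. Because two
    group means can themselves end up within ``radius``, the whole sweep is
    iterated until nothing changes, so the output is a fixpoint. Returns the
    merged positions and a mapping original -> merged coordinate.
    """
    pos = np.sort(np.asarray(list(positions), dtype=float))
    mapping = {p: p for p in pos}

    def sweep(values):
        out = {}
        remaining = sorted(values)
        while remaining:
            first = remaining[0]
            group = [p for p in remaining if abs(p - first) < radius]
            center = float(np.mean(group))
            for p in group:
                out[p] = center
            remaining = [p for p in remaining if abs(p - first) >= radius]
        return out

    current = sorted(set(mapping.values()))
    while True:
        step = sweep(current)
        mapping = {orig: step[m] for orig, m in mapping.items()}
        new = sorted(set(step.values()))
        if new == current:
            break
        current = new
    return np.array(current), mapping


def apply_boundary_merge(domains: pd.DataFrame, radius: float = 80_000) -> pd.DataFrame:
    """Merge the non-redundant boundary list per chromosome and reassign."""
    out = domains.copy()
    for chrom in out["chrom"].unique():
        sel = out["chrom"] == chrom
        bounds = np.unique(
            np.concatenate([out.loc[sel, "start"].to_numpy(), out.loc[sel, "end"].to_numpy()])
        )
        _, mapping = merge_boundaries(bounds, radius)
        out.loc[sel, "start"] = [int(round(mapping[b])) for b in out.loc[sel, "start"]]
        out.loc[sel, "end"] = [int(round(mapping[b])) for b in out.loc[sel, "end"]]
    return out


def adjust_boundaries(
    domains: pd.DataFrame,
    reference_tracks: dict[str, InsulationTrack],
    wiggle_bins: int = 6,
    min_domain_bp: int = 100_000,
    remerge_bp: int = 20_000,
) -> pd.DataFrame:
    """Snap each boundary to the insulation minimum of the reference track.

    Each boundary moves to the argmin of the mid-G1 control insulation within
    ``wiggle_bins`` bins; boundaries whose wiggle window is fully masked stay
    put (flagged). Domains below ``min_domain_bp`` are then dropped, and
    residual boundaries within ``remerge_bp`` are merged.
    """
    out = domains.copy()
    moved = {}
    for chrom in out["chrom"].unique():
        track = reference_tracks[chrom]
        bs = track.bin_size
        sel = out["chrom"] == chrom
        bounds = np.unique(
            np.concatenate([out.loc[sel, "start"].to_numpy(), out.loc[sel, "end"].to_numpy()])
        )
        for b in bounds:
            bin_ = int(b) // bs
            lo = max(0, bin_ - wiggle_bins)
            hi = min(len(track.values), bin_ + wiggle_bins + 1)
            window = track.values[lo:hi]
            if not np.any(np.isfinite(window)):
                moved[(chrom, b)] = int(b)  # unmoved, fully masked window
                continue
            best = lo + int(np.nanargmin(window))
            moved[(chrom, b)] = best * bs
    out["start"] = [moved[(c, s)] for c, s in zip(out["chrom"], out["start"])]
    out["end"] = [moved[(c, e)] for c, e in zip(out["chrom"], out["end"])]
    out = out[out["end"] - out["start"] >= min_domain_bp].reset_index(drop=True)
    return apply_boundary_merge(out, remerge_bp)


def integrate_conditions(
    control: pd.DataFrame, auxin: pd.DataFrame, radius: float = 80_000
) -> pd.DataFrame:
    """Union the post-adjustment control and auxin domain lists.

    An auxin domain with both boundaries within ``radius`` of the matching
    control domain adopts the control coordinates (``shared``); a
    single-boundary match snaps that boundary to the nearest control boundary
    (``auxin_boundary_matched``); otherwise the domain enters verbatim
    (``auxin_new``).
    """
    ctrl = control.copy()
    ctrl["provenance"] = "control"
    rows = [ctrl]
    new_rows = []
    for chrom in auxin["chrom"].unique():
        ctrl_c = control[control["chrom"] == chrom]
        ctrl_bounds = np.unique(
            np.concatenate([ctrl_c["start"].to_numpy(float), ctrl_c["end"].to_numpy(float)])
        ) if len(ctrl_c) else np.array([])
        for _, d in auxin[auxin["chrom"] == chrom].iterrows():
            both = ctrl_c[
                (np.abs(ctrl_c["start"] - d["start"]) < radius)
                & (np.abs(ctrl_c["end"] - d["end"]) < radius)
            ]
            if len(both):
                continue  # duplicate of a control domain; control coords kept
            up_hit = ctrl_bounds[np.abs(ctrl_bounds - d["start"]) < radius] if ctrl_bounds.size else np.array([])
            dn_hit = ctrl_bounds[np.abs(ctrl_bounds - d["end"]) < radius] if ctrl_bounds.size else np.array([])
            start, end = int(d["start"]), int(d["end"])
            if up_hit.size and not dn_hit.size:
                start = int(up_hit[np.argmin(np.abs(up_hit - d["start"]))])
                prov = "auxin_boundary_matched"
            elif dn_hit.size and not up_hit.size:
                end = int(dn_hit[np.argmin(np.abs(dn_hit - d["end"]))])
                prov = "auxin_boundary_matched"
            elif not up_hit.size and not dn_hit.size:
                prov = "auxin_new"
            else:
                # both boundaries near control boundaries but not of one domain
                start = int(up_hit[np.argmin(np.abs(up_hit - d["start"]))])
                end = int(dn_hit[np.argmin(np.abs(dn_hit - d["end"]))])
                prov = "auxin_boundary_matched"
            row = {k: d[k] for k in d.index}
            row.update(chrom=chrom, start=start, end=end, provenance=prov)
            new_rows.append(row)
    if new_rows:
        rows.append(pd.DataFrame(new_rows))
    return pd.concat(rows, ignore_index=True).sort_values(
        ["chrom", "start", "end"], ignore_index=True
    )


# ---------------------------------------------------------------------------
# aggregated domain analysis
# ---------------------------------------------------------------------------

def ada_stripes(i: int, j: int) -> tuple[list, list]:
    """Pixel index lists of the 8 inner and 8 outer ADA stripes.

    The corner pixel of a domain [start, end) at 10-kb bins is (i, j) with
    i = start/10kb, j = end/10kb. Inner stripes hug the corner just inside the
    domain, outer stripes sit just outside at the same genomic separations.
    Ranges are inclusive.
    """
    inner, outer = [], []
    for t in range(1, 5):
        inner.append([(i + t, c) for c in range(j - 9 + t, j - 4 + t)])          # horizontal
        inner.append([(r, j - 5 + t) for r in range(i + t, i + 5 + t)])          # vertical
        outer.append([(i - 9 + t, c) for c in range(j - 18 + t, j - 13 + t)])    # horizontal
        outer.append([(r, j + 4 + t) for r in range(i + 9 + t, i + 14 + t)])     # vertical
    return inner, outer


def ada_score(
    oe: np.ndarray,
    start_bp: int,
    end_bp: int,
    bin_size: int = 10_000,
    min_domain_bp: int = 150_000,
    max_oe: float = 30.0,
    min_outer_nonzero: int = 5,
    min_inner_nonzero: int = 10,
) -> tuple[float, bool, str]:
    """ADA = log2(sum O/E over inner stripes / sum over outer stripes).

    Returns (score, valid, reason). Invalid when the domain is below
    ``min_domain_bp``, any stripe leaves the matrix, any stripe pixel exceeds
    ``max_oe``, an outer stripe group has fewer than ``min_outer_nonzero``
    non-zero pixels, or an inner group fewer than ``min_inner_nonzero``.
    """
    if end_bp - start_bp < min_domain_bp:
        return np.nan, False, "too_small"
    i, j = start_bp // bin_size, end_bp // bin_size
    inner, outer = ada_stripes(i, j)
    n = oe.shape[0]
    all_px = [p for stripe in inner + outer for p in stripe]
    if any(r < 0 or c < 0 or r >= n or c >= n for r, c in all_px):
        return np.nan, False, "out_of_matrix"

    def collect(stripes, horizontal):
        vals = []
        for k, stripe in enumerate(stripes):
            if (k % 2 == 0) == horizontal:
                vals.extend(oe[r, c] for r, c in stripe)
        return np.nan_to_num(np.array(vals, float), nan=0.0)

    inner_h, inner_v = collect(inner, True), collect(inner, False)
    outer_h, outer_v = collect(outer, True), collect(outer, False)
    everything = np.concatenate([inner_h, inner_v, outer_h, outer_v])
    if np.any(everything > max_oe):
        return np.nan, False, "outlier_pixel"
    if min((outer_h > 0).sum(), (outer_v > 0).sum()) < min_outer_nonzero:
        return np.nan, False, "sparse_outer"
    if min((inner_h > 0).sum(), (inner_v > 0).sum()) < min_inner_nonzero:
        return np.nan, False, "sparse_inner"
    inner_sum = inner_h.sum() + inner_v.sum()
    outer_sum = outer_h.sum() + outer_v.sum()
    if outer_sum <= 0 or inner_sum <= 0:
        return np.nan, False, "zero_sum"
    return float(np.log2(inner_sum / outer_sum)), True, "ok"


def ada_dynamic_filter(
    ada: pd.DataFrame,
    post_mitotic_cols: list[str],
    prometa_cols: list[str],
    fold: float = 1.25,
) -> np.ndarray:
    """Dynamic domain validity: a real domain strengthens after mitotic exit.

    True where at least one post-mitotic sample's ADA is >= ``fold`` times the
    ADA of *both* prometaphase samples.
    """
    pm = ada[prometa_cols].to_numpy(float)
    post = ada[post_mitotic_cols].to_numpy(float)
    pm_ok = np.isfinite(pm).all(axis=1)
    post_ok = np.isfinite(post).any(axis=1)
    usable = pm_ok & post_ok
    thresh = fold * np.where(pm_ok, np.where(np.isfinite(pm), pm, -np.inf).max(axis=1), np.nan)
    best_post = np.where(np.isfinite(post), post, -np.inf).max(axis=1)
    return np.where(usable, best_post >= thresh, False)


# ---------------------------------------------------------------------------
# boundary dynamics clustering and transition PCA
# ---------------------------------------------------------------------------

def cluster_boundaries(
    dis: pd.DataFrame,
    post_mitotic_cols: list[str],
    order_col: str,
    k: int = 5,
    seed: int = 0,
    restarts: int = 50,
    max_missing: int = 2,
) -> pd.DataFrame:
    """k-means on boundary-strength z-scores over the post-mitotic samples.

    Rows are boundaries, columns the 8 (stage x condition) dIS values.
    Rows with more than ``max_missing`` missing values are excluded (label 0);
    remaining missing entries are imputed as 0 after z-scoring. Labels are
    renumbered 1..k by descending mean z in ``order_col`` so the labelling is
    reproducible.
    """
    x = dis.to_numpy(float)
    if np.isfinite(x).all(axis=1).sum() < k:
        raise ValueError("fewer complete boundaries than clusters")
    usable = (~np.isfinite(x)).sum(axis=1) <= max_missing
    z = np.zeros_like(x)
    z[usable] = zscore_rows(np.nan_to_num(x[usable], nan=0.0))
    z = np.nan_to_num(z, nan=0.0)
    cols = [dis.columns.get_loc(c) for c in post_mitotic_cols]
    labels = np.zeros(len(dis), dtype=int)
    lab = kmeans_labels(z[usable][:, cols], k, seed, restarts)
    labels[usable] = relabel_by_score(
        lab, z[usable][:, dis.columns.get_loc(order_col)], descending=True
    )
    out = pd.DataFrame(z, columns=[f"z_{c}" for c in dis.columns], index=dis.index)
    out["cluster"] = labels
    return out


def transition_pca(
    boundary_positions: pd.DataFrame,
    track_bins: dict[str, dict[str, np.ndarray]],
    bin_size: int = 10_000,
    flank_bp: int = 50_000,
    extreme_fraction: float = 0.2,
    marks: tuple[str, str] = ("H3K27me3", "H3K36me3"),
) -> pd.DataFrame:
    """PC1 chromatin-state-transition score per boundary.

    Each boundary contributes, per histone mark, the mean signal in ten 10-kb
    bins across +-``flank_bp``; columns are normalised to sum one, the two
    mark matrices are stitched side by side (20 columns) and PCA is applied.
    Boundaries in the top or bottom ``extreme_fraction`` of PC1 are flagged
    extreme (the chromatin-state transition points).
    """
    nb = flank_bp // bin_size
    rows, keep_idx = [], []
    for idx, (chrom, pos) in enumerate(
        boundary_positions[["chrom", "pos"]].itertuples(index=False)
    ):
        b = int(pos) // bin_size
        feats = []
        ok = True
        for mark in marks:
            track = track_bins[mark][chrom]
            lo, hi = b - nb, b + nb
            if lo < 0 or hi > len(track):
                ok = False
                break
            feats.append(track[lo:hi])
        if ok:
            rows.append(np.concatenate(feats))
            keep_idx.append(idx)
    mat = np.asarray(rows, float)
    if mat.shape[0] < 3:
        raise ValueError("too few boundaries with full windows for PCA")
    colsum = mat.sum(axis=0)
    colsum[colsum == 0] = 1.0
    mat = mat / colsum
    centered = mat - mat.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    pc1 = centered @ vt[0]
    # orient deterministically: positive PC1 = active (K36me3) upstream
    k36 = mat[:, nb * 2 :] if marks[1] == "H3K36me3" else mat[:, : nb * 2]
    contrast = k36[:, :nb].mean(axis=1) - k36[:, nb:].mean(axis=1)
    if np.corrcoef(pc1, contrast)[0, 1] < 0:
        pc1 = -pc1
    qlo, qhi = np.quantile(pc1, [extreme_fraction, 1 - extreme_fraction])
    out = boundary_positions.copy()
    out["pc1"] = np.nan
    out["extreme"] = False
    out.iloc[keep_idx, out.columns.get_loc("pc1")] = pc1
    out.iloc[keep_idx, out.columns.get_loc("extreme")] = (pc1 <= qlo) | (pc1 >= qhi)
    return out


def enrichment_fisher(a: int, b: int, c: int, d: int):
    """2x2 enrichment: sample odds ratio ad/bc and two-sided exact p-value."""
    return fisher_exact_2x2(a, b, c, d)


# ---------------------------------------------------------------------------
# gene-domain recovery
# ---------------------------------------------------------------------------

def recovery_rate(
    scores: pd.DataFrame, prometa_col: str, ref_col: str, clip: tuple = (0.0, 1.5)
) -> pd.DataFrame:
    """Per-row recovery (score_t - score_prometa) / (score_ref - score_prometa).

    Rows with a degenerate denominator are excluded. Values are clipped to
    ``clip`` for reporting.
    """
    denom = scores[ref_col] - scores[prometa_col]
    ok = denom.abs() > 1e-12
    out = scores.loc[ok].copy()
    for col in scores.columns:
        out[col] = ((scores.loc[ok, col] - scores.loc[ok, prometa_col]) / denom[ok]).clip(
            *clip
        )
    return out


SIZE_CLASSES = ((30_000, 50_000), (50_000, 100_000), (100_000, 150_000), (150_000, None))


def size_class(length: int) -> str:
    for lo, hi in SIZE_CLASSES:
        if length >= lo and (hi is None or length < hi):
            return f"{lo//1000}-{hi//1000}kb" if hi else f">{lo//1000}kb"
    return "<30kb"


def gene_domain_recovery(
    gene_ada: pd.DataFrame,
    gene_polii: pd.DataFrame,
    gene_lengths: pd.Series,
    prometa_col: str,
    ref_col: str,
) -> pd.DataFrame:
    """Compare gene-domain (ADA) vs PolII recovery per gene-size class.

    Both inputs are genes x stage tables on a shared index. Returns one row
    per (size class, stage) with the mean recoveries and the paired
    signed-rank p-value of the domain-vs-PolII comparison.
    """
    common = gene_ada.index.intersection(gene_polii.index)
    ada_rec = recovery_rate(gene_ada.loc[common], prometa_col, ref_col)
    pol_rec = recovery_rate(gene_polii.loc[common], prometa_col, ref_col)
    common = ada_rec.index.intersection(pol_rec.index)
    ada_rec, pol_rec = ada_rec.loc[common], pol_rec.loc[common]
    classes = gene_lengths.loc[common].map(size_class)
    rows = []
    for cls in classes.unique():
        sel = classes == cls
        for stage in gene_ada.columns:
            a = ada_rec.loc[sel, stage].to_numpy()
            p = pol_rec.loc[sel, stage].to_numpy()
            pval = signed_rank(a, p) if sel.sum() >= 3 else np.nan
            rows.append((cls, stage, int(sel.sum()), a.mean(), p.mean(), pval))
    return pd.DataFrame(
        rows,
        columns=["size_class", "stage", "n_genes", "domain_recovery",
                 "polii_recovery", "signed_rank_p"],
    )
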
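"""Activity-by-contact (ABC) enhancer-promoter scoring and differential
interaction testing.

The ABC score of a candidate element e for gene g is
``A_e * C_eg / sum_e' A_e' * C_e'g``: element activity (geometric mean of
H3K27ac and ATAC over the element) times Hi-C contact with the promoter,
normalised over all candidates within range of the gene, so scores per gene
sum to one. Pairs passing the score threshold in at least one sample are
assembled into a non-redundant list; contact strengths are compared between
conditions with a moderated t-test at FDR 0.1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .stats import moderated_t_test

log = logging.getLogger("mitohic.cre")


def element_activity(elements: pd.DataFrame, tracks: dict[str, pd.DataFrame]) -> pd.Series:
    """Geometric mean of H3K27ac and ATAC signal over each element."""
    means = {}
    for mark in ("h3k27ac", "atac"):
        track = tracks[mark]
        by_chrom = {c: g for c, g in track.groupby("chrom")}
        vals = []
        for chrom, start, end in elements[["chrom", "start", "end"]].itertuples(index=False):
            sub = by_chrom.get(chrom)
            total = 0.0
            if sub is not None:
                ov = np.minimum(sub["end"].to_numpy(), end) - np.maximum(
                    sub["start"].to_numpy(), start
                )
                pos = ov > 0
                total = float((sub["value"].to_numpy()[pos] * ov[pos]).sum())
            vals.append(total / (end - start))
        means[mark] = np.asarray(vals)
    return pd.Series(
        np.sqrt(means["h3k27ac"] * means["atac"]), index=elements.index, name="activity"
    )


def contact_strength(
    oe: np.ndarray, bin_i: int, bin_j: int, neighborhood: int = 1
) -> float:
    """O/E contact at a bin pair, averaged over a 3x3 neighbourhood, floored at 0."""
    n = oe.shape[0]
    vals = []
    for di in range(-neighborhood, neighborhood + 1):
        for dj in range(-neighborhood, neighborhood + 1):
            a, b = bin_i + di, bin_j + dj
            if 0 <= a < n and 0 <= b < n and np.isfinite(oe[a, b]):
                vals.append(max(oe[a, b], 0.0))
    return float(np.mean(vals)) if vals else np.nan


def abc_scores(
    elements: pd.DataFrame,
    genes: pd.DataFrame,
    activity: pd.Series,
    oe_by_chrom: dict[str, np.ndarray],
    bin_size: int,
    threshold: float = 0.01,
    max_distance: int = 5_000_000,
) -> pd.DataFrame:
    """ABC-score every candidate element against every in-range gene.

    ``elements`` carries candidate CREs (promoter elements included for P-P
    pairs, flagged by an ``is_promoter`` column). Scores per gene sum to one
    over its candidates; rows with score >= ``threshold`` are returned. Genes
    whose candidates all have zero activity x contact yield no pairs
    (flagged in the log).
    """
    rows = []
    for gname, gene in genes.set_index("name").iterrows():
        chrom = gene["chrom"]
        tss = int(gene["end"] if gene["strand"] == "-" else gene["start"])
        tss_bin = tss // bin_size
        oe = oe_by_chrom[chrom]
        cand = elements[
            (elements["chrom"] == chrom)
            & ((elements["start"] + elements["end"]) // 2 - tss).abs().le(max_distance)
        ]
        # the gene's own promoter element is not its own enhancer
        if "gene" in cand.columns:
            cand = cand[(cand.get("gene") != gname) | (~cand["is_promoter"])]
        if cand.empty:
            continue
        mids = ((cand["start"] + cand["end"]) // 2).to_numpy()
        contacts = np.array(
            [contact_strength(oe, m // bin_size, tss_bin) for m in mids]
        )
        a = activity.reindex(cand.index).to_numpy()
        prod = np.nan_to_num(a * contacts, nan=0.0)
        total = prod.sum()
        if total <= 0:
            log.warning("gene %s: zero total activity x contact, no pairs", gname)
            continue
        scores = prod / total
        for (eidx, el), score, c in zip(cand.iterrows(), scores, contacts):
            if score >= threshold:
                ptype = "PP" if bool(el.get("is_promoter", False)) else "EP"
                rows.append(
                    (ptype, el["chrom"], int(el["start"]), int(el["end"]), eidx,
                     gname, tss, float(score), float(c))
                )
    return pd.DataFrame(
        rows,
        columns=["pair_type", "chrom", "el_start", "el_end", "element", "gene",
                 "tss", "abc_score", "contact"],
    )


def assemble_pairs(
    per_sample: dict[str, pd.DataFrame],
    de_classes: pd.Series,
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Union per-sample ABC tables into one non-redundant pair list.

    A pair enters the list when its ABC score reaches ``threshold`` in at
    least one sample; its contact strengths and scores from *every* sample
    are carried as columns (a pair called in one sample still has measurable
    contact in the others). Each pair is stratified by the DE class of its
    gene.
    """
    frames = []
    for sample, df in per_sample.items():
        d = df.set_index(["element", "gene"])
        frames.append(
            d[["abc_score", "contact"]].rename(
                columns={"abc_score": f"abc_{sample}", "contact": f"contact_{sample}"}
            )
        )
    meta = (
        pd.concat(
            [
                df.set_index(["element", "gene"])[
                    ["pair_type", "chrom", "el_start", "el_end", "tss"]
                ]
                for df in per_sample.values()
            ]
        )
        .groupby(level=[0, 1])
        .first()
    )
    base = pd.concat([meta] + frames, axis=1)
    score_cols = [f"abc_{s}" for s in per_sample]
    base = base[(base[score_cols].fillna(0.0) >= threshold).any(axis=1)].reset_index()
    base["de_class"] = de_classes.reindex(base["gene"]).fillna("none").to_numpy()
    return base


def differential_interaction(
    pairs: pd.DataFrame,
    control_cols: list[str],
    auxin_cols: list[str],
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Moderated-t differential contact per pair, control vs auxin.

    Early- and mid-G1 samples are pooled as equal biological replicates by
    the caller (the column lists). Pairs missing any strength are skipped.
    Status: strengthened / reduced at adjusted p < ``fdr``, else unchanged.
    """
    x = pairs[control_cols].to_numpy(float)
    y = pairs[auxin_cols].to_numpy(float)
    complete = np.isfinite(x).all(axis=1) & np.isfinite(y).all(axis=1)
    out = pairs.copy()
    out["status"] = "unchanged"
    out["padj"] = np.nan
    if complete.sum() >= 2:
        res = moderated_t_test(x[complete], y[complete])
        idx = out.index[complete]
        out.loc[idx, "padj"] = res["padj"].to_numpy()
        sig = res["padj"].to_numpy() < fdr
        direction = np.where(res["diff"].to_numpy() > 0, "strengthened", "reduced")
        out.loc[idx, "status"] = np.where(sig, direction, "unchanged")
    out.loc[~complete, "status"] = "skipped"
    return out


def de_class_summary(pairs: pd.DataFrame) -> pd.DataFrame:
    """Fraction of genes per DE class with >=1 strengthened E-P pair."""
    ep = pairs[pairs["pair_type"] == "EP"]
    rows = []
    for cls, sub in ep.groupby("de_class"):
        genes = sub["gene"].unique()
        hit = sub[sub["status"] == "strengthened"]["gene"].unique()
        rows.append((cls, len(genes), len(hit), len(hit) / len(genes) if len(genes) else np.nan))
    return pd.DataFrame(rows, columns=["de_class", "n_genes", "n_strengthened", "fraction"])
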
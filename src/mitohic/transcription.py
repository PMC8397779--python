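"""PolII gene-body transcription: quantification, active-gene calling,
post-mitotic spiking PCA, differential expression and recovery rates.

Gene expression is read out as PolII occupancy over the gene body, defined
strand-aware as [TSS+500, TES) on plus-strand genes and (TES, TSS-500]
mirrored on minus-strand genes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .stats import kmeans_labels, nb_wald_test

log = logging.getLogger("mitohic.transcription")


def gene_body_interval(row: pd.Series, offset: int = 500) -> tuple[int, int]:
    """Strand-aware gene body: the TSS-proximal ``offset`` bp are excluded."""
    if row["strand"] == "-":
        start, end = int(row["start"]), int(row["end"]) - offset
    else:
        start, end = int(row["start"]) + offset, int(row["end"])
    return start, end


def quantify_gene_body(
    track: pd.DataFrame, genes: pd.DataFrame, offset: int = 500
) -> pd.DataFrame:
    """Sum and mean of a bedGraph signal over each gene body.

    Genes whose body collapses to nothing after the offset are excluded and
    logged. Overlap is computed exactly on the bedGraph intervals.
    """
    rows = []
    by_chrom = {c: g.sort_values("start") for c, g in track.groupby("chrom")}
    for name, gene in genes.set_index("name").iterrows():
        start, end = gene_body_interval(gene, offset)
        if end <= start:
            log.warning("gene %s: empty body after +%d offset, excluded", name, offset)
            continue
        sub = by_chrom.get(gene["chrom"])
        total = 0.0
        if sub is not None:
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            v = sub["value"].to_numpy()
            ov = np.minimum(e, end) - np.maximum(s, start)
            pos = ov > 0
            total = float((v[pos] * ov[pos]).sum())
        rows.append((name, total, total / (end - start)))
    return pd.DataFrame(rows, columns=["name", "sum", "mean"]).set_index("name")


def call_active_genes(
    genes: pd.DataFrame,
    polii_peaks: pd.DataFrame,
    promoter_activity: pd.DataFrame,
    body_signal: pd.DataFrame,
    post_mitotic_cols: list[str],
    prometa_cols: list[str],
    min_length: int = 1_000,
    promoter_flank: int = 250,
    low_quantile: float = 0.10,
    activation_fold: float = 1.5,
) -> pd.DataFrame:
    """Four-filter active-gene calling.

    1. the TSS overlaps at least one PolII peak;
    2. the gene is longer than ``min_length``;
    3. the promoter (TSS +- ``promoter_flank``) is not in the lowest decile of
       H3K27ac *or* ATAC signal (``promoter_activity`` carries per-gene
       ``h3k27ac`` and ``atac`` promoter means);
    4. body PolII in >= 1 post-mitotic sample is >= ``activation_fold`` times
       both prometaphase samples.
    Returns the gene table with per-filter flags and the final ``active`` flag.
    """
    out = genes.set_index("name").copy()
    tss = np.where(out["strand"] == "-", out["end"], out["start"]).astype(int)
    out["tss"] = tss

    peak_by_chrom = {c: g for c, g in polii_peaks.groupby("chrom")}
    f1 = []
    for chrom, t in zip(out["chrom"], tss):
        sub = peak_by_chrom.get(chrom)
        f1.append(
            bool(((sub["start"] <= t) & (sub["end"] > t)).any()) if sub is not None else False
        )
    out["f1_tss_peak"] = f1
    out["f2_length"] = (out["end"] - out["start"]) > min_length

    act = promoter_activity.reindex(out.index)
    k27_cut = act["h3k27ac"].quantile(low_quantile)
    atac_cut = act["atac"].quantile(low_quantile)
    out["f3_promoter_open"] = (act["h3k27ac"] > k27_cut) & (act["atac"] > atac_cut)

    body = body_signal.reindex(out.index)
    pm_max = body[prometa_cols].max(axis=1)
    out["f4_induced"] = (
        body[post_mitotic_cols].ge(activation_fold * pm_max, axis=0).any(axis=1)
    )
    out["active"] = (
        out["f1_tss_peak"] & out["f2_length"] & out["f3_promoter_open"] & out["f4_induced"]
    )
    for flt in ("f1_tss_peak", "f2_length", "f3_promoter_open", "f4_induced"):
        log.info("active-gene filter %s retains %d/%d", flt, int(out[flt].sum()), len(out))
    return out


def spiking_pca(
    signals: pd.DataFrame, last_three_cols: list[str], early_col: str
) -> pd.Series:
    """PC1 "spikiness" of post-mitotic reactivation per gene.

    Per-gene stage signals are normalised to sum one across the stages of
    ``signals``; PCA runs on the last three cell-cycle stages. The sign is
    fixed so that high PC1 = spiky (signal concentrated in early G1), via
    positive correlation with the early-G1 share. Genes with all-zero signal
    are excluded.
    """
    x = signals.to_numpy(float)
    totals = x.sum(axis=1)
    keep = totals > 0
    norm = x[keep] / totals[keep, None]
    ndf = pd.DataFrame(norm, columns=signals.columns, index=signals.index[keep])
    mat = ndf[last_three_cols].to_numpy()
    centered = mat - mat.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    pc1 = centered @ vt[0]
    if np.corrcoef(pc1, ndf[early_col].to_numpy())[0, 1] < 0:
        pc1 = -pc1
    return pd.Series(pc1, index=ndf.index, name="spiking_pc1")


def differential_expression(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    post_mitotic_stages: list[str],
    padj_cut: float = 0.05,
    fold_cut: float = 1.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-stage auxin-vs-control NB Wald tests and DE classification.

    ``counts`` is genes x sample columns; ``design`` maps column -> stage,
    condition, replicate. A gene is differentially expressed when adjusted
    p < ``padj_cut`` and |fold change| > ``fold_cut`` (strict) in at least one
    post-mitotic stage. Up/down classes come from 2-means on the per-stage
    log2 fold-change vectors, oriented so the cluster with positive mean
    log2FC is "up".
    """
    results = {}
    for stage in post_mitotic_stages:
        ctrl_cols = design.index[
            (design["stage"] == stage) & (design["condition"] == "control")
        ]
        aux_cols = design.index[
            (design["stage"] == stage) & (design["condition"] == "auxin")
        ]
        if len(ctrl_cols) < 2 or len(aux_cols) < 2:
            raise ValueError(f"{stage}: need >=2 replicates per condition")
        res = nb_wald_test(counts[ctrl_cols].to_numpy(), counts[aux_cols].to_numpy())
        res.index = counts.index
        results[stage] = res
    out = pd.DataFrame(index=counts.index)
    for stage, res in results.items():
        out[f"log2FC_{stage}"] = res["log2FC"]
        out[f"padj_{stage}"] = res["padj"]
    log_fold_cut = np.log2(fold_cut)
    sig = pd.DataFrame(
        {
            stage: (results[stage]["padj"] < padj_cut)
            & (results[stage]["log2FC"].abs() > log_fold_cut)
            for stage in post_mitotic_stages
        }
    ).fillna(False)
    out["de"] = sig.any(axis=1)
    out["de_class"] = "none"
    de_idx = out.index[out["de"]]
    if len(de_idx) >= 2:
        lfc = out.loc[de_idx, [f"log2FC_{s}" for s in post_mitotic_stages]].to_numpy()
        lfc = np.nan_to_num(lfc, nan=0.0)
        lab = kmeans_labels(lfc, 2, seed)
        means = [lfc[lab == c].mean() for c in (0, 1)]
        up_cluster = int(np.argmax(means))
        out.loc[de_idx, "de_class"] = np.where(lab == up_cluster, "up", "down")
    elif len(de_idx) == 1:
        mean_lfc = out.loc[de_idx, [f"log2FC_{s}" for s in post_mitotic_stages]].mean(axis=1)
        out.loc[de_idx, "de_class"] = np.where(mean_lfc > 0, "up", "down")
    return out


def polii_recovery(
    body_signal: pd.DataFrame,
    gene_lengths: pd.Series,
    prometa_col: str,
    ref_col: str,
) -> pd.DataFrame:
    """Per-size-class PolII recovery curves.

    recovery_t = (signal_t - signal_prometa) / (signal_ref - signal_prometa),
    clipped to [0, 1.5]; genes with a degenerate denominator are excluded.
    """
    from .domains import recovery_rate, size_class

    rec = recovery_rate(body_signal, prometa_col, ref_col)
    classes = gene_lengths.reindex(rec.index).map(size_class)
    rows = []
    for cls in classes.dropna().unique():
        sel = classes == cls
        for stage in body_signal.columns:
            rows.append((cls, stage, int(sel.sum()), rec.loc[sel, stage].mean()))
    return pd.DataFrame(rows, columns=["size_class", "stage", "n_genes", "recovery"])
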
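"""End-to-end orchestration: simulate -> balance -> compartments ->
insulation/domains -> loops -> transcription -> CRE pairs -> truth report.

``run_pipeline`` executes the whole analysis on a synthetic time course and
returns every intermediate table plus a planted-truth comparison summary;
``write_outputs`` dumps the result tables as TSV/BED/BEDPE.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import compartments as comp
from . import cre as cre_mod
from . import domains as dom
from . import insulation as ins
from . import loops as lp
from . import simulate as sim
from . import transcription as tx
from .genome import GenomeSpec, SampleKey, full_design, merged_design
from .io import PipelineConfig, bin_track
from .matrix import ContactMatrix, kr_balance, observed_over_expected

log = logging.getLogger("mitohic.pipeline")


def _balance(m: ContactMatrix, params: PipelineConfig) -> ContactMatrix:
    kr_balance(m, tol=params.kr_tol, max_iter=params.kr_max_iter,
               low_quantile=params.mask_low_quantile)
    return m


def _gene_density(genes: pd.DataFrame, genome: GenomeSpec, bin_size: int) -> dict:
    out = {}
    for chrom in genome.chroms:
        n = -(-genome.chromsizes[chrom] // bin_size)
        dens = np.zeros(n)
        for start in genes[genes["chrom"] == chrom]["start"]:
            dens[min(int(start) // bin_size, n - 1)] += 1
        out[chrom] = dens
    return out


def run_pipeline(
    genome: GenomeSpec | None = None,
    arch: sim.PlantedArchitecture | None = None,
    decay: sim.DecayModel | None = None,
    design: list[SampleKey] | None = None,
    params: PipelineConfig | None = None,
    seed: int = 0,
    outdir: str | None = None,
) -> dict:
    """Run the full synthetic-data analysis; returns a results dictionary."""
    params = params or PipelineConfig()
    genome = genome or sim.default_genome()
    arch = arch or sim.PlantedArchitecture.random(genome, seed=seed)
    decay = decay or sim.DecayModel()
    design = design or full_design()
    results: dict = {"genome": genome, "params": params}

    log.info("simulating %d replicate samples on %d chromosomes", len(design),
             len(genome.chroms))
    matrices, truth = sim.generate_timecourse(genome, arch, decay, design, seed=seed)
    merged = sim.merge_replicates(matrices)
    merged_keys = merged_design(design)
    tracks = sim.generate_tracks(genome, arch, design, seed=seed)
    annot = sim.generate_annotations(arch, seed=seed)
    results["truth"] = truth
    results["annotations"] = annot

    control_labels = {k.label() for k in merged_keys if k.condition == "control"}
    auxin_labels = {k.label() for k in merged_keys if k.condition != "control"}
    stage_of = {k.label(): k.stage for k in merged_keys}
    cond_of = {k.label(): k.condition for k in merged_keys}
    prometa_cols = [k.label() for k in merged_keys if k.stage == "prometa"]
    post_cols = [k.label() for k in merged_keys if k.stage != "prometa"]

    # ---------------- compartments (100 kb) --------------------------------
    gene_density = _gene_density(annot["genes"], genome, params.compartment_bin_size)
    profiles: dict[str, dict[str, comp.CompartmentProfile]] = {}
    oe100: dict[str, dict[str, np.ndarray]] = {}
    for key in merged_keys:
        profiles[key.label()] = {}
        oe100[key.label()] = {}
        for chrom in genome.analysis_chroms():
            m100 = _balance(merged[key][chrom].coarsen(params.compartment_bin_size), params)
            oe = observed_over_expected(m100)
            oe100[key.label()][chrom] = oe
            profiles[key.label()][chrom] = comp.call_compartments(
                oe, gene_density[chrom], chrom, params.compartment_bin_size
            )
    strength = {}
    for key in merged_keys:
        ref_key = SampleKey("mid_G1", key.condition, 0)
        ref = profiles.get(ref_key.label(), profiles[key.label()])
        try:
            gval, per_chrom = comp.compartment_strength(
                oe100[key.label()], ref, params.saddle_top_fraction, params.saddle_sections
            )
            strength[key.label()] = gval
        except ValueError:
            strength[key.label()] = np.nan
    results["compartment_strength"] = strength
    results["compartment_profiles"] = profiles

    rs = {}
    for key in merged_keys:
        # EV1 products come from the mid-G1 reference of the matching
        # condition: R(s) measures how far the final compartment structure
        # has spread, and a noisy own-sample EV1 would correlate with its
        # own O/E by construction
        ref_key = SampleKey("mid_G1", key.condition, 0)
        ref_prof = profiles.get(ref_key.label(), profiles[key.label()])
        curves = [
            comp.rs_curve(oe100[key.label()][c], ref_prof[c], params.rs_max_distance)
            for c in genome.analysis_chroms()
        ]
        rs[key.label()] = comp.average_rs_curves(curves)
    results["rs_curves"] = rs

    # tier interactions off the 50-kb mid-G1 control reference
    ref_mid = SampleKey("mid_G1", "control", 0)
    tier_tables = []
    for chrom in genome.analysis_chroms():
        m50 = _balance(merged[ref_mid][chrom].coarsen(params.tier_bin_size), params)
        oe50_ref = observed_over_expected(m50)
        prof50 = comp.call_compartments(
            oe50_ref,
            _gene_density(annot["genes"], genome, params.tier_bin_size)[chrom],
            chrom, params.tier_bin_size,
        )
        segs = comp.compartment_domains(prof50)
        for key in merged_keys:
            m50k = _balance(merged[key][chrom].coarsen(params.tier_bin_size), params)
            oe50 = observed_over_expected(m50k)
            tt = comp.tier_interactions(
                oe50, segs, params.tier_bin_size, genome.chromsizes[chrom],
                flank=params.tier_flank,
            )
            tt["sample"] = key.label()
            tt["chrom"] = chrom
            tier_tables.append(tt)
            sh = comp.shuffled_tier_control(
                oe50, segs, params.tier_bin_size, genome.chromsizes[chrom],
                n=params.tier_shuffle_n // len(genome.analysis_chroms()),
                seed=seed + 101, flank=params.tier_flank,
            )
            sh["sample"] = key.label()
            sh["chrom"] = chrom
            tier_tables.append(sh)
    results["tiers"] = pd.concat(tier_tables, ignore_index=True)

    # ---------------- per-chromosome 10-kb heavy lifting --------------------
    for key in merged_keys:
        for chrom in genome.chroms:
            _balance(merged[key][chrom], params)

    insulation_tracks: dict[str, dict[str, ins.InsulationTrack]] = {
        k.label(): {} for k in merged_keys
    }
    oe10: dict[str, dict[str, np.ndarray]] = {k.label(): {} for k in merged_keys}
    donut10: dict[str, dict[str, lp.DonutResult]] = {k.label(): {} for k in merged_keys}
    donut25: dict[str, dict[str, lp.DonutResult]] = {k.label(): {} for k in merged_keys}
    for key in merged_keys:
        for chrom in genome.chroms:
            m = merged[key][chrom]
            insulation_tracks[key.label()][chrom] = ins.insulation_score(
                m, params.insulation_window_bins, params.insulation_offset_bins,
                params.insulation_min_counts,
            )
            oe10[key.label()][chrom] = observed_over_expected(m).astype(np.float32)
            donut10[key.label()][chrom] = lp.donut_stats(
                m, params.donut_inner_diam_10kb, params.donut_outer_diam_10kb,
                params.loop_max_distance, params.donut_fdr_10kb,
            )
            m25 = _balance(m.coarsen(25_000), params)
            donut25[key.label()][chrom] = lp.donut_stats(
                m25, params.donut_inner_diam_25kb, params.donut_outer_diam_25kb,
                params.loop_max_distance, params.donut_fdr_25kb,
            )
            m._dense_cache = None  # free the raw dense copy
    results["insulation"] = insulation_tracks

    # ---------------- domains ----------------------------------------------
    # reference late-G1 control sample (wildtype-style), merged depth
    ref_late_domains = []
    for ci, chrom in enumerate(genome.chroms):
        surf = sim.mean_surface(arch, decay, chrom, "late_G1", "control")
        rng = np.random.default_rng([seed, 4, 0, 0, ci])
        mref = sim.sample_matrix(surf, 2 * decay.budget_per_replicate, rng, chrom,
                                 genome.bin_size)
        _balance(mref, params)
        tr = ins.insulation_score(mref)
        ref_late_domains.append(
            ins.candidate_domains(track=tr, prominence=params.domain_prominence,
                                  sub_prominence=params.subdomain_prominence,
                                  sub_cap_bp=params.subdomain_cap_bp)
        )
    ref_late = pd.concat(ref_late_domains, ignore_index=True)

    per_condition: dict[str, pd.DataFrame] = {}
    midg1_ctrl = insulation_tracks[SampleKey("mid_G1", "control", 0).label()]
    for condition in ("control", "auxin"):
        stage_domains = {}
        for key in merged_keys:
            if key.condition != condition:
                continue
            cand = [
                ins.candidate_domains(
                    track=insulation_tracks[key.label()][chrom],
                    prominence=params.domain_prominence,
                    sub_prominence=params.subdomain_prominence,
                    sub_cap_bp=params.subdomain_cap_bp,
                )
                for chrom in genome.chroms
            ]
            stage_domains[key.stage] = pd.concat(cand, ignore_index=True)
        validated = dom.integrate_domains(
            stage_domains, ref_late, genome.bin_size, params.domain_overlap_bins
        )
        merged_dom = dom.apply_boundary_merge(validated, params.boundary_merge_bp)
        adjusted = dom.adjust_boundaries(
            merged_dom, midg1_ctrl, params.boundary_adjust_bins,
            params.min_domain_bp, params.boundary_remerge_bp,
        )
        per_condition[condition] = adjusted.drop_duplicates(
            subset=["chrom", "start", "end"], ignore_index=True
        )
    final_domains = dom.integrate_conditions(
        per_condition["control"], per_condition["auxin"], params.boundary_merge_bp
    ).drop_duplicates(subset=["chrom", "start", "end"], ignore_index=True)

    # ADA per domain per sample + validity filters
    sample_labels = [k.label() for k in merged_keys]
    ada_rows = []
    for _, d in final_domains.iterrows():
        row = {"chrom": d["chrom"], "start": int(d["start"]), "end": int(d["end"])}
        valid_all = True
        for slab in sample_labels:
            score, ok, reason = dom.ada_score(
                oe10[slab][d["chrom"]], int(d["start"]), int(d["end"]),
                genome.bin_size, params.ada_min_domain_bp, params.ada_max_oe,
                params.ada_min_outer_nonzero, params.ada_min_inner_nonzero,
            )
            row[slab] = score
            valid_all &= ok
        row["stripe_valid"] = valid_all
        ada_rows.append(row)
    ada = pd.DataFrame(ada_rows)
    if len(ada):
        dyn = dom.ada_dynamic_filter(ada, post_cols, prometa_cols, params.ada_dynamic_fold)
        ada["dynamic_valid"] = dyn & ada["stripe_valid"]
    results["domains"] = final_domains
    results["ada"] = ada

    # boundaries: unique final positions + per-sample dIS
    brows = []
    for chrom in genome.chroms:
        sel = final_domains["chrom"] == chrom
        for pos in np.unique(
            np.concatenate([
                final_domains.loc[sel, "start"].to_numpy(),
                final_domains.loc[sel, "end"].to_numpy(),
            ])
        ) if sel.any() else []:
            row = {"chrom": chrom, "pos": int(pos)}
            for slab in sample_labels:
                row[slab] = ins.boundary_strength(
                    insulation_tracks[slab][chrom], int(pos) // genome.bin_size,
                    params.boundary_window_kb * 1000,
                )
            brows.append(row)
    boundaries = pd.DataFrame(brows)
    results["boundaries"] = boundaries

    if len(boundaries) >= params.boundary_kmeans_k:
        clustered = dom.cluster_boundaries(
            boundaries[sample_labels],
            post_mitotic_cols=post_cols,
            order_col=SampleKey("mid_G1", "control", 0).label(),
            k=params.boundary_kmeans_k, seed=seed, restarts=params.kmeans_restarts,
        )
        boundaries = pd.concat([boundaries, clustered], axis=1)
        results["boundaries"] = boundaries

    # transition PCA on histone tracks binned at 10 kb
    track_bins = {
        "H3K27me3": bin_track(tracks["h3k27me3"], genome, genome.bin_size),
        "H3K36me3": bin_track(tracks["h3k36me3"], genome, genome.bin_size),
    }
    if len(boundaries) >= 3:
        boundaries = dom.transition_pca(
            boundaries, track_bins, genome.bin_size, params.transition_flank_bp,
            params.transition_extreme_fraction,
        )
        results["boundaries"] = boundaries
        fisher_rows = []
        if "cluster" in boundaries:
            for c in sorted(boundaries["cluster"].unique()):
                if c == 0:
                    continue
                inc = boundaries["cluster"] == c
                ext = boundaries["extreme"].astype(bool)
                orr, pv, ok = dom.enrichment_fisher(
                    int((ext & inc).sum()), int((~ext & inc).sum()),
                    int((ext & ~inc).sum()), int((~ext & ~inc).sum()),
                )
                fisher_rows.append((c, orr, pv, ok))
            results["boundary_transition_enrichment"] = pd.DataFrame(
                fisher_rows, columns=["cluster", "odds_ratio", "pvalue", "defined"]
            )

    # ---------------- loops -------------------------------------------------
    def pixel_union(donut: dict, fdr_attr: str) -> pd.DataFrame:
        frames = []
        for slab in sample_labels:
            for chrom in genome.chroms:
                df = donut[slab][chrom].significant()
                df["sample"] = slab
                frames.append(df)
        return pd.concat(frames, ignore_index=True)

    clusters_all = []
    for res_name, donut in (("10kb", donut10), ("25kb", donut25)):
        pixels = pixel_union(donut, res_name)
        if pixels.empty:
            continue
        pixels = lp.filter_artifacts(pixels, params.artifact_max_samples)
        grouped = pixels.groupby(["chrom", "resolution", "bin_i", "bin_j"])
        agg = grouped.agg(samples=("sample", lambda s: frozenset(s))).reset_index()
        qmins = []
        for chrom_, res_, bi, bj in agg[["chrom", "resolution", "bin_i", "bin_j"]].itertuples(index=False):
            qs = [donut[s][chrom_].get("q", int(bi), int(bj)) for s in sample_labels]
            qs = [q for q in qs if np.isfinite(q)]
            qmins.append(min(qs) if qs else np.nan)
        agg["q_min"] = qmins
        agg = agg.dropna(subset=["q_min"])
        clusters_all.append(
            lp.filter_singletons(
                lp.cluster_pixels(agg, params.cluster_radius_bp), params.singleton_max_q
            )
        )
    clusters10 = clusters_all[0] if clusters_all else []
    clusters25 = clusters_all[1] if len(clusters_all) > 1 else []
    clusters = lp.merge_resolutions(clusters10, clusters25)
    lp.classify_status(clusters, control_labels, auxin_labels)

    # false-negative recovery from replicate-level donut stats (10 kb);
    # replicate O/E for early/mid G1 doubles as the per-replicate contact
    # measure of the differential E-P analysis
    rep_donut: dict[str, dict[str, dict]] = {}
    oe_rep: dict[tuple, dict[str, np.ndarray]] = {}
    for key in design:
        for chrom in genome.chroms:
            m = matrices[key][chrom]
            _balance(m, params)
            rep_donut.setdefault(chrom, {}).setdefault(
                (key.stage, key.condition), []
            ).append(
                lp.donut_stats(m, params.donut_inner_diam_10kb,
                               params.donut_outer_diam_10kb,
                               params.loop_max_distance, params.donut_fdr_10kb)
            )
            if key.stage in ("early_G1", "mid_G1") and key.condition in ("control", "auxin"):
                oe_rep.setdefault(
                    (key.stage, key.condition, key.replicate), {}
                )[chrom] = observed_over_expected(m).astype(np.float32)
            m._dense_cache = None
    recovered_all = []
    for chrom in genome.chroms:
        for condition in ("control", "auxin"):
            cond_labels = [k.label() for k in merged_keys if k.condition == condition]
            frames = [donut10[s][chrom].significant() for s in cond_labels]
            cand = pd.concat(frames, ignore_index=True).drop_duplicates(
                subset=["bin_i", "bin_j"], ignore_index=True
            )
            if cand.empty:
                continue
            merged_stats = {
                stage_of[s]: donut10[s][chrom] for s in cond_labels
            }
            rep_stats = {
                st: rep_donut[chrom].get((st, condition), [])
                for st in ("ana_telo", "early_G1", "mid_G1")
            }
            valid = lp.recover_missed_loops(
                cand, merged_stats, rep_stats,
                fdr=params.donut_fdr_10kb, min_oe=params.recovery_min_oe,
                min_obs=params.recovery_min_obs,
            )
            if valid.empty:
                continue
            pm_label = SampleKey("prometa", condition, 0).label()
            valid = lp.drop_prometa_outliers(
                valid, donut10[pm_label][chrom],
                params.recovery_prometa_top_fraction, params.loop_max_distance,
            )
            valid["sample"] = SampleKey("mid_G1", condition, 0).label()
            recovered_all.append(valid)
    if recovered_all:
        rec = pd.concat(recovered_all, ignore_index=True)
        rec = lp.drop_adjacent_to_loops(rec, clusters)
        if not rec.empty:
            grouped = rec.groupby(["chrom", "resolution", "bin_i", "bin_j"])
            agg = grouped.agg(samples=("sample", lambda s: frozenset(s))).reset_index()
            agg["q_min"] = [
                min(q for q in (donut10[s][c].get("q", int(bi), int(bj))
                                for s in sample_labels) if np.isfinite(q))
                for c, bi, bj in agg[["chrom", "bin_i", "bin_j"]].itertuples(index=False)
            ]
            new_clusters = lp.cluster_pixels(agg, params.cluster_radius_bp)
            for cl in new_clusters:
                cl.recovered = True
            lp.classify_status(new_clusters, control_labels, auxin_labels)
            clusters.extend(new_clusters)

    lp.categorize_loops(clusters, annot["ctcf_cohesin"], annot["cre_peaks"],
                        params.anchor_window_bp)
    for cl in clusters:
        donut = donut10 if cl.resolution == genome.bin_size else donut25
        lp.loop_strength(cl, {s: donut[s][cl.chrom] for s in sample_labels})
    results["loops"] = clusters

    # dynamics clustering of CRE loops detected in control
    cre_clusters = [
        cl for cl in clusters
        if cl.category in ("cre",) and (cl.samples & control_labels)
    ]
    control_cols = [k.label() for k in merged_keys if k.condition == "control"]
    pm_ctrl_cols = [c for c in control_cols if stage_of[c] != "prometa"]
    if len(cre_clusters) >= params.loop_kmeans_k:
        strengths = pd.DataFrame(
            [{s: cl.strength.get(s, np.nan) for s in sample_labels} for cl in cre_clusters]
        ).fillna(0.0)
        labels = lp.cluster_loop_dynamics(
            strengths, control_cols, pm_ctrl_cols,
            transient_hi_col=SampleKey("ana_telo", "control", 0).label(),
            transient_lo_col=SampleKey("mid_G1", "control", 0).label(),
            k=params.loop_kmeans_k, seed=seed, restarts=params.kmeans_restarts,
        )
        for cl, lab in zip(cre_clusters, labels):
            cl.dynamics_cluster = int(lab)
        transient = [cl for cl in cre_clusters if cl.dynamics_cluster == 1]
        if len(transient) >= 2:
            st = pd.DataFrame(
                [{s: cl.strength.get(s, np.nan) for s in sample_labels} for cl in transient]
            ).fillna(0.0)
            subs = lp.subcluster_persistence(
                st, sample_labels, post_cols,
                auxin_late_col=SampleKey("mid_G1", "auxin", 0).label(),
                seed=seed, restarts=params.kmeans_restarts,
            )
            for cl, sub in zip(transient, subs):
                cl.persistence = str(sub)

    structural = [cl for cl in clusters if cl.category in ("structural", "dual_function")]
    interplay = lp.interplay_stats(
        cre_clusters, structural, annot["ctcf_loop_free"], params.anchor_window_bp
    )
    results["interplay"] = interplay

    apa_out = {}
    for cat in ("structural", "cre"):
        cat_clusters = [cl for cl in clusters if cl.category == cat]
        mats = []
        for key in merged_keys:
            for chrom in genome.chroms:
                m = lp.apa(cat_clusters, oe10[key.label()][chrom], chrom,
                           genome.bin_size, params.apa_window_bins,
                           params.apa_min_loop_bp)
                if m is not None:
                    mats.append(m)
        if mats:
            apa_out[cat] = np.nanmean(np.stack(mats), axis=0)
    results["apa"] = apa_out

    # ---------------- transcription ----------------------------------------
    genes_bed = annot["genes"]
    body = {}
    for key in merged_keys:
        q = tx.quantify_gene_body(tracks["polii"][key], genes_bed, params.gene_body_offset)
        body[key.label()] = q["mean"]
    body_signal = pd.DataFrame(body)

    prom_act = {}
    for mark, track in (("h3k27ac", tracks["h3k27ac"]), ("atac", tracks["atac"])):
        tss_df = annot["tss"].copy()
        tss_df["start"] = (tss_df["start"] - params.promoter_flank).clip(lower=0)
        tss_df["end"] = tss_df["end"] + params.promoter_flank - 1
        tss_df["strand"] = "+"
        prom_act[mark] = tx.quantify_gene_body(track, tss_df, offset=0)["mean"]
    promoter_activity = pd.DataFrame(prom_act)

    active = tx.call_active_genes(
        genes_bed, annot["polii_peaks"], promoter_activity, body_signal,
        post_cols, prometa_cols, params.min_gene_length, params.promoter_flank,
        params.promoter_low_quantile, params.activation_fold,
    )
    results["genes"] = active

    active_idx = active.index[active["active"]]
    spiking = {}
    stage_order = [s for s in ("prometa", "ana_telo", "early_G1", "mid_G1")
                   if any(stage_of[c] == s for c in sample_labels)]
    for condition in ("control", "auxin"):
        cols = [SampleKey(s, condition, 0).label() for s in stage_order]
        last3 = cols[1:]
        spiking[condition] = tx.spiking_pca(
            body_signal.loc[active_idx, cols], last3,
            early_col=SampleKey("early_G1", condition, 0).label(),
        )
    results["spiking"] = spiking
    both = spiking["control"].index.intersection(spiking["auxin"].index)
    results["spiking_correlation"] = float(
        np.corrcoef(spiking["control"][both], spiking["auxin"][both])[0, 1]
    ) if len(both) > 2 else np.nan

    counts = tracks["counts"]
    design_df = pd.DataFrame(
        {
            "stage": [SampleKey.from_label(c).stage for c in counts.columns],
            "condition": [SampleKey.from_label(c).condition for c in counts.columns],
        },
        index=counts.columns,
    )
    de = tx.differential_expression(
        counts.loc[counts.index.intersection(active_idx)], design_df,
        [s for s in stage_order if s != "prometa"],
        params.de_padj, params.de_fold, seed=seed,
    )
    results["de"] = de

    gene_lengths = genes_bed.set_index("name").pipe(lambda d: d["end"] - d["start"])
    ctrl_cols = [SampleKey(s, "control", 0).label() for s in stage_order]
    results["polii_recovery"] = tx.polii_recovery(
        body_signal.loc[active_idx, ctrl_cols], gene_lengths,
        prometa_col=SampleKey("prometa", "control", 0).label(),
        ref_col=SampleKey("mid_G1", "control", 0).label(),
    )

    # gene-domain recovery: ADA on the gene-body square (documented stand-in)
    gd_rows = {}
    for gname, g in genes_bed.set_index("name").loc[active_idx].iterrows():
        row = {}
        for slab in ctrl_cols:
            score, ok, _ = dom.ada_score(
                oe10[slab][g["chrom"]], int(g["start"]), int(g["end"]),
                genome.bin_size, min_domain_bp=30_000,
            )
            row[slab] = score if ok else np.nan
        gd_rows[gname] = row
    gene_ada = pd.DataFrame(gd_rows).T.dropna()
    if len(gene_ada) >= 3:
        results["gene_domain_recovery"] = dom.gene_domain_recovery(
            gene_ada, body_signal.loc[gene_ada.index, ctrl_cols], gene_lengths,
            prometa_col=SampleKey("prometa", "control", 0).label(),
            ref_col=SampleKey("mid_G1", "control", 0).label(),
        )

    # ---------------- CRE / ABC ---------------------------------------------
    elements = annot["cre_peaks"].copy()
    elements["is_promoter"] = False
    prom_rows = annot["tss"].copy()
    prom_rows = prom_rows[prom_rows["name"].isin(active_idx)]
    prom_elements = pd.DataFrame(
        {
            "chrom": prom_rows["chrom"],
            "start": (prom_rows["start"] - params.promoter_flank).clip(lower=0),
            "end": prom_rows["end"] + params.promoter_flank,
            "name": "prom_" + prom_rows["name"],
            "is_promoter": True,
            "gene": prom_rows["name"].to_numpy(),
        }
    )
    elements = pd.concat([elements, prom_elements], ignore_index=True)
    activity = cre_mod.element_activity(
        elements, {"h3k27ac": tracks["h3k27ac"], "atac": tracks["atac"]}
    )
    active_genes_bed = genes_bed[genes_bed["name"].isin(active_idx)]
    abc_samples = [
        k.label() for k in merged_keys
        if k.stage in ("ana_telo", "early_G1", "mid_G1")
    ]
    per_sample = {}
    for slab in abc_samples:
        per_sample[slab] = cre_mod.abc_scores(
            elements, active_genes_bed, activity, oe10[slab], genome.bin_size,
            threshold=0.0, max_distance=params.abc_max_distance,
        )
    threshold_counts = {
        t: int(sum((df["abc_score"] >= t).sum() for df in per_sample.values()))
        for t in params.abc_thresholds
    }
    results["abc_threshold_counts"] = threshold_counts

    pairs = cre_mod.assemble_pairs(per_sample, de["de_class"],
                                   threshold=params.abc_threshold_main)
    # differential interaction on individual biological replicates, early- and
    # mid-G1 pooled as equal replicates per condition
    pool_ctrl, pool_aux = [], []
    for (stage, cond, rep), oe_by_chrom in sorted(oe_rep.items()):
        col = f"repcontact_{stage}_{cond}_rep{rep}"
        vals = [
            cre_mod.contact_strength(
                oe_by_chrom[r.chrom],
                int((r.el_start + r.el_end) // 2) // genome.bin_size,
                int(r.tss) // genome.bin_size,
            )
            for r in pairs.itertuples(index=False)
        ]
        pairs[col] = vals
        (pool_ctrl if cond == "control" else pool_aux).append(col)
    pairs = cre_mod.differential_interaction(pairs, pool_ctrl, pool_aux, params.ep_fdr)
    results["pairs"] = pairs
    results["ep_summary"] = cre_mod.de_class_summary(pairs)

    results["report"] = truth_report(results, arch, genome)
    if outdir:
        write_outputs(results, outdir)
    return results


# ---------------------------------------------------------------------------
# truth comparison
# ---------------------------------------------------------------------------

def truth_report(results: dict, arch: sim.PlantedArchitecture, genome: GenomeSpec) -> dict:
    """Planted-truth recall/accuracy summary of a pipeline run."""
    truth = results["truth"]
    bs = genome.bin_size
    report: dict = {}

    bt = truth["boundaries"]
    called = results["boundaries"]
    hits = 0
    for chrom, pos in bt[["chrom", "pos"]].itertuples(index=False):
        sub = called[called["chrom"] == chrom]["pos"].to_numpy() if len(called) else np.array([])
        if sub.size and np.min(np.abs(sub - pos)) <= bs:
            hits += 1
    report["boundary_recall"] = hits / len(bt) if len(bt) else np.nan
    report["n_boundaries_called"] = int(len(called))

    lt = truth["loops"]
    clusters = results["loops"]
    detectable = lt  # every planted class is enriched in >= 1 sample
    hit = 0
    matched_status = 0
    for _, row in detectable.iterrows():
        best = None
        for cl in clusters:
            if cl.chrom != row["chrom1"]:
                continue
            tol = max(cl.resolution, bs)
            if (abs(cl.x - (row["start1"] + bs / 2)) <= tol
                    and abs(cl.y - (row["start2"] + bs / 2)) <= tol):
                best = cl
                break
        if best is None:
            continue
        hit += 1
        expect = "lost" if row["class"] in ("structural", "dual_function") else (
            "gained" if row["class"] == "cre_gained" else "retained"
        )
        if row["class"] == "cre_transient" and not row["persists"]:
            expect = best.status  # transient loops may legitimately drop out under auxin
        if best.status == expect:
            matched_status += 1
    report["loop_recall"] = hit / len(detectable) if len(detectable) else np.nan
    report["loop_status_accuracy"] = matched_status / hit if hit else np.nan
    report["n_loop_clusters"] = len(clusters)

    de_truth = truth["genes"].set_index("name")["de_class"]
    de = results["de"]
    common = de.index.intersection(de_truth.index)
    planted = de_truth[common].isin(["up", "down"])
    calls = de.loc[common, "de"]
    tp = int((planted & calls).sum())
    fp = int((~planted & calls).sum())
    report["de_recall"] = tp / int(planted.sum()) if planted.sum() else np.nan
    report["de_fdr"] = fp / max(tp + fp, 1)

    pairs = results["pairs"]
    gained = truth["loops"][truth["loops"]["class"] == "cre_gained"]
    if len(pairs) and len(gained):
        # planted (enhancer, gene) pairs that made it into the assembled list
        hits, present = 0, 0
        for _, row in gained.iterrows():
            sub = pairs[
                (pairs["gene"] == row["gene"])
                & (pairs["chrom"] == row["chrom1"])
                & ((pairs["el_start"] - row["start1"]).abs() < 20_000)
            ]
            if len(sub):
                present += 1
                hits += int((sub["status"] == "strengthened").any())
        report["ep_pairs_present"] = present
        report["ep_planted_total"] = int(len(gained))
        report["ep_strengthened_recall"] = hits / present if present else np.nan
    return report


# ---------------------------------------------------------------------------
# output writing
# ---------------------------------------------------------------------------

def loops_to_bedpe(clusters: list) -> pd.DataFrame:
    rows = []
    for cl in clusters:
        rows.append(
            (cl.chrom, *map(int, cl.anchor1), cl.chrom, *map(int, cl.anchor2),
             cl.category or "na", cl.q_min, cl.status or "na",
             cl.dynamics_cluster, cl.persistence,
             cl.s_i_min if np.isfinite(cl.s_i_min) else -1,
             int(cl.interrupted), int(cl.supported), int(cl.recovered))
        )
    return pd.DataFrame(
        rows,
        columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2",
                 "category", "q_min", "status", "dynamics_cluster", "persistence",
                 "s_i_min", "interrupted", "supported", "recovered"],
    )


def write_outputs(results: dict, outdir: str) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    results["domains"].to_csv(out / "domains.tsv", sep="\t", index=False)
    results["ada"].to_csv(out / "ada.tsv", sep="\t", index=False)
    results["boundaries"].to_csv(out / "boundaries.tsv", sep="\t", index=False)
    loops_to_bedpe(results["loops"]).to_csv(out / "loops.bedpe", sep="\t", index=False)
    results["interplay"].to_csv(out / "interplay.tsv", sep="\t", index=False)
    results["tiers"].to_csv(out / "tiers.tsv", sep="\t", index=False)
    results["genes"].to_csv(out / "genes.tsv", sep="\t")
    results["de"].to_csv(out / "differential_expression.tsv", sep="\t")
    results["pairs"].to_csv(out / "ep_pairs.tsv", sep="\t", index=False)
    results["ep_summary"].to_csv(out / "ep_summary.tsv", sep="\t", index=False)
    for slab, curve in results["rs_curves"].items():
        curve.to_csv(out / f"rs_{slab}.tsv", sep="\t", index=False)
    pd.Series(results["compartment_strength"]).to_csv(
        out / "compartment_strength.tsv", sep="\t", header=["log2_strength"]
    )
    for cat, mat in results.get("apa", {}).items():
        np.savetxt(out / f"apa_{cat}.tsv", mat, delimiter="\t")
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    for name, df in results["truth"].items():
        df.to_csv(truth_dir / f"{name}.tsv", sep="\t", index=False)
    report = pd.Series(results["report"], dtype=object)
    report.to_csv(out / "truth_report.tsv", sep="\t", header=["value"])
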
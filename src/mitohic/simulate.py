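"""Synthetic mitosis-to-G1 Hi-C time course with planted ground truth.

The generator emits, for a desk-scale genome (default 2 chromosomes x 20 Mb
at 10 kb bins) and a 4-stage x 2-condition x 2-replicate design:

* per-sample contact matrices drawn as independent Poisson samples of a mean
  surface = distance decay x compartment checkerboard modulation (strength
  ramping from zero at prometaphase to its maximum at mid-G1) x domain block
  enrichment x Gaussian loop bumps whose amplitude depends on stage,
  condition and loop class;
* signal tracks (H3K27ac, ATAC, H3K36me3, H3K27me3, per-sample PolII) and a
  per-replicate gene-body count table with negative-binomial noise;
* peak/gene annotations aligned to the planted features;
* machine-readable truth tables for every planted feature.

Loop classes and their planted stage/condition response:

==============  =======================================================
structural      CTCF/cohesin anchored; ramps up through G1 in control,
                zero enrichment under auxin (CTCF degraded)
dual_function   as structural, but with CREs at both anchors
cre_stable      CRE-anchored, ramps up, unaffected by auxin
cre_transient   peaks at ana/telophase, fades in G1; a per-loop flag
                decides whether it persists into G1 under auxin
cre_gained      absent in control, appears under auxin (enhancer
                hijacking once the structural interruption is gone)
==============  =======================================================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeSpec, SampleKey
from .matrix import ContactMatrix

log = logging.getLogger("mitohic.simulate")

COMP_BIN = 100_000  # granularity of the planted compartment checkerboard

# stage ramps: fraction of the planted maximum reached at each stage
COMP_RAMP = {"prometa": 0.0, "ana_telo": 0.4, "early_G1": 0.75, "mid_G1": 1.0, "late_G1": 1.0}
DOMAIN_RAMP = COMP_RAMP
LOOP_RAMP = {
    "structural": {"prometa": 0.0, "ana_telo": 0.5, "early_G1": 0.8, "mid_G1": 1.0, "late_G1": 1.0},
    "dual_function": {"prometa": 0.0, "ana_telo": 0.5, "early_G1": 0.8, "mid_G1": 1.0, "late_G1": 1.0},
    "cre_stable": {"prometa": 0.0, "ana_telo": 0.5, "early_G1": 0.8, "mid_G1": 1.0, "late_G1": 1.0},
    "cre_transient": {"prometa": 0.0, "ana_telo": 1.0, "early_G1": 0.45, "mid_G1": 0.15, "late_G1": 0.1},
    "cre_gained": {"prometa": 0.0, "ana_telo": 0.5, "early_G1": 0.8, "mid_G1": 1.0, "late_G1": 1.0},
}
TRANSIENT_PERSIST_RAMP = {"prometa": 0.0, "ana_telo": 1.0, "early_G1": 0.9, "mid_G1": 0.85, "late_G1": 0.85}

# PolII gene-body stage profiles (relative occupancy)
EXPRESSION_PROFILE = {
    "spiky": {"prometa": 0.1, "ana_telo": 0.5, "early_G1": 1.5, "mid_G1": 0.8, "late_G1": 0.6},
    "gradual": {"prometa": 0.1, "ana_telo": 0.3, "early_G1": 0.6, "mid_G1": 1.0, "late_G1": 1.1},
    "silent": {"prometa": 0.05, "ana_telo": 0.05, "early_G1": 0.05, "mid_G1": 0.05, "late_G1": 0.05},
}
DE_FOLD = {"up": 2.0, "down": 0.5, "none": 1.0}


class GenerationError(ValueError):
    """Planted architecture incompatible with the genome."""


@dataclass
class DecayModel:
    """Distance decay of contact probability per stage.

    Prometaphase has a steeper long-range decay plus a short-range boost
    (condensed mitotic chromatin); the expected contact probability is
    strictly decreasing with distance at every stage.
    """

    exponents: dict = field(
        default_factory=lambda: {
            "prometa": 1.5, "ana_telo": 1.25, "early_G1": 1.1, "mid_G1": 1.0, "late_G1": 1.0,
        }
    )
    prometa_boost: float = 2.0
    prometa_boost_len_bins: float = 30.0
    # contacts per chromosome per replicate; 5e5/Mb gives the pixel depth of
    # published deep merged Hi-C maps, which 10-kb loop calling requires
    budget_per_replicate: float = 1.0e7


@dataclass
class PlantedLoop:
    chrom: str
    anchor1: int  # bp, bin start
    anchor2: int
    enrichment: float
    loop_class: str
    persists: bool = False  # transient loops only: persists into G1 under auxin
    gene: str = ""  # CRE loops wired to a gene promoter


@dataclass
class PlantedDomain:
    chrom: str
    start: int
    end: int
    intensity: float = 2.0
    static: bool = False  # artifact: constant across stages (no ramp)


@dataclass
class PlantedGene:
    chrom: str
    start: int
    end: int
    name: str
    strand: str
    profile_class: str  # spiky | gradual | silent
    de_class: str  # up | down | none
    base: float = 100.0

    @property
    def tss(self) -> int:
        return self.end if self.strand == "-" else self.start


@dataclass
class PlantedArchitecture:
    """Everything planted into the synthetic genome, with invariants."""

    genome: GenomeSpec
    compartments: dict  # chrom -> array of 'A'/'B' labels at COMP_BIN
    domains: list
    loops: list
    genes: list
    transition_fraction: float = 0.5  # boundaries coinciding with mark switches
    comp_strength: float = 0.6  # max of the exp(k v_i v_j) modulation
    bb_gain: float = 0.5  # auxin inter-block B-B gain at full ramp
    aa_loss: float = 0.2  # auxin inter-block A-A loss at full ramp

    def __post_init__(self) -> None:
        for lp in self.loops:
            length = self.genome.chromsizes[lp.chrom]
            if not (0 <= lp.anchor1 < lp.anchor2 < length):
                raise GenerationError(f"loop anchors outside {lp.chrom}: {lp}")
        for d in self.domains:
            if not (0 <= d.start < d.end <= self.genome.chromsizes[d.chrom]):
                raise GenerationError(f"domain outside {d.chrom}: {d}")
        for g in self.genes:
            if not (0 <= g.start < g.end <= self.genome.chromsizes[g.chrom]):
                raise GenerationError(f"gene outside {g.chrom}: {g}")

    # -- truth tables -------------------------------------------------------

    def truth_tables(self) -> dict[str, pd.DataFrame]:
        comp_rows = []
        for chrom, labels in self.compartments.items():
            for b, lab in enumerate(labels):
                comp_rows.append((chrom, b * COMP_BIN, (b + 1) * COMP_BIN, lab))
        loops = pd.DataFrame(
            [
                (l.chrom, l.anchor1, l.anchor1 + self.genome.bin_size, l.chrom,
                 l.anchor2, l.anchor2 + self.genome.bin_size, l.loop_class,
                 l.enrichment, l.persists, l.gene)
                for l in self.loops
            ],
            columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2",
                     "class", "enrichment", "persists", "gene"],
        )
        domains = pd.DataFrame(
            [(d.chrom, d.start, d.end, d.intensity, d.static) for d in self.domains],
            columns=["chrom", "start", "end", "intensity", "static"],
        )
        # boundaries = interior edges shared by two adjacent domains; the
        # outermost tiling ends border unstructured chromatin and are not
        # sharp insulation minima
        shared = set()
        for chrom in {d.chrom for d in self.domains}:
            starts = {d.start for d in self.domains if d.chrom == chrom}
            ends = {d.end for d in self.domains if d.chrom == chrom}
            shared |= {(chrom, p) for p in starts & ends}
        boundaries = pd.DataFrame(sorted(shared), columns=["chrom", "pos"])
        genes = pd.DataFrame(
            [
                (g.chrom, g.start, g.end, g.name, 0, g.strand, g.profile_class,
                 g.de_class, g.base)
                for g in self.genes
            ],
            columns=["chrom", "start", "end", "name", "score", "strand",
                     "profile_class", "de_class", "base"],
        )
        return {
            "compartments": pd.DataFrame(
                comp_rows, columns=["chrom", "start", "end", "label"]
            ),
            "domains": domains,
            "boundaries": boundaries,
            "loops": loops,
            "genes": genes,
        }

    # -- random factory -----------------------------------------------------

    @classmethod
    def random(
        cls,
        genome: GenomeSpec,
        seed: int = 0,
        n_structural: int = 12,
        n_dual: int = 4,
        n_cre_stable: int = 6,
        n_cre_transient: int = 8,
        n_cre_gained: int = 6,
        n_static_domains: int = 2,
        n_genes: int = 40,
        domain_intensity: float = 2.0,
        structural_enrichment: float = 4.0,
        cre_enrichment: float = 3.0,
        **kwargs,
    ) -> "PlantedArchitecture":
        rng = np.random.default_rng(seed)
        compartments = {}
        domains: list[PlantedDomain] = []
        loops: list[PlantedLoop] = []
        genes: list[PlantedGene] = []
        for chrom in genome.chroms:
            length = genome.chromsizes[chrom]
            ncomp = length // COMP_BIN
            labels = []
            lab = "A" if rng.random() < 0.5 else "B"
            while len(labels) < ncomp:
                run = int(rng.integers(5, 16))
                labels.extend([lab] * run)
                lab = "A" if lab == "B" else "B"
            compartments[chrom] = np.array(labels[:ncomp], dtype=object)

            # tiling domains with gaps; a few static artifacts
            # contiguous domain tiling: adjacent domains share boundaries, as
            # on real chromosomes, so each interior boundary is a sharp
            # insulation minimum between two enriched squares
            pos = 500_000
            chrom_domains = []
            while pos + 1_200_000 < length - 500_000:
                span = int(rng.integers(20, 101)) * 10_000  # 200 kb - 1 Mb
                chrom_domains.append(PlantedDomain(chrom, pos, pos + span, domain_intensity))
                pos += span
            static_idx = rng.choice(len(chrom_domains), size=min(n_static_domains, len(chrom_domains)), replace=False)
            for si in static_idx:
                chrom_domains[si].static = True
            domains.extend(chrom_domains)

            # genes: placed left-to-right with gaps, mostly in A compartment
            gene_specs = (
                [("up",)] * 4 + [("down",)] * 4 + [("none",)] * (n_genes - 12) + [("silent",)] * 4
            )
            rng.shuffle(gene_specs)
            gpos = 600_000
            gi = 0
            for spec_row in gene_specs:
                glen = int(np.exp(rng.uniform(np.log(30_000), np.log(200_000))))
                glen = max(30_000, (glen // 500) * 500)
                gap = int(rng.integers(60, 400)) * 500
                start = gpos + gap
                end = start + glen
                if end > length - 500_000:
                    break
                # nudge gene into an A-compartment bin where possible
                cbin = start // COMP_BIN
                if compartments[chrom][min(cbin, ncomp - 1)] == "B" and rng.random() < 0.75:
                    for shift in range(1, 8):
                        nb = min(cbin + shift, ncomp - 1)
                        if compartments[chrom][nb] == "A":
                            start = nb * COMP_BIN + 10_000
                            end = start + glen
                            break
                if end > length - 500_000:
                    break
                de = spec_row[0]
                if de == "silent":
                    profile, de_class = "silent", "none"
                else:
                    profile = "spiky" if rng.random() < 0.5 else "gradual"
                    de_class = de
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(
                    PlantedGene(chrom, start, end, f"{chrom}_g{gi}", strand, profile,
                                de_class, base=float(rng.uniform(60, 160)))
                )
                gi += 1
                gpos = end
            up_genes = [g for g in genes if g.chrom == chrom and g.de_class == "up"]

            # loops: anchors on the bin grid, kept >= 120 kb apart
            used: list[int] = []

            def place(span_lo: int, span_hi: int) -> tuple[int, int] | None:
                for _ in range(200):
                    span = int(rng.integers(span_lo // 10_000, span_hi // 10_000)) * 10_000
                    hi = (length - span - 400_000) // 10_000
                    if hi <= 40:
                        continue
                    a1 = int(rng.integers(40, hi)) * 10_000
                    a2 = a1 + span
                    if all(min(abs(a1 - u), abs(a2 - u)) >= 80_000 for u in used):
                        used.extend([a1, a2])
                        return a1, a2
                return None

            def add(n, cls_name, enr, span=(300_000, 1_500_000)):
                for _ in range(n):
                    anch = place(*span)
                    if anch is None:
                        log.warning("%s: could not place %s loop", chrom, cls_name)
                        continue
                    loops.append(PlantedLoop(chrom, anch[0], anch[1], enr, cls_name))

            add(n_structural, "structural", structural_enrichment, (250_000, 900_000))
            add(n_dual, "dual_function", structural_enrichment, (250_000, 900_000))
            add(n_cre_stable, "cre_stable", cre_enrichment, (200_000, 600_000))
            start_t = len(loops)
            add(n_cre_transient, "cre_transient", cre_enrichment, (200_000, 600_000))
            transient = [l for l in loops[start_t:] if l.loop_class == "cre_transient"]
            for idx, lp in enumerate(transient):
                lp.persists = idx < len(transient) // 2
            # gained loops wire an enhancer to an up-regulated promoter
            for k in range(n_cre_gained):
                gene = up_genes[k % len(up_genes)] if up_genes else None
                if gene is None:
                    break
                tss_bin_start = (gene.tss // 10_000) * 10_000
                for _ in range(200):
                    span = int(rng.integers(20, 60)) * 10_000
                    a1 = tss_bin_start - span
                    if a1 < 400_000:
                        continue
                    if all(abs(a1 - u) >= 60_000 for u in used):
                        used.extend([a1, tss_bin_start])
                        loops.append(
                            PlantedLoop(chrom, a1, tss_bin_start, cre_enrichment,
                                        "cre_gained", gene=gene.name)
                        )
                        break
        return cls(genome, compartments, domains, loops, genes, **kwargs)


# ---------------------------------------------------------------------------
# contact matrices
# ---------------------------------------------------------------------------

def _comp_vector(arch: PlantedArchitecture, chrom: str, n_bins: int, bin_size: int) -> np.ndarray:
    """Planted EV-like profile at matrix resolution.

    Block labels are expanded to fine bins and smoothed (sigma = 50 kb) so
    compartment transitions are gradual, as in real eigenvector profiles;
    hard 100-kb steps would plant artificial dot-like corners.
    """
    from scipy.ndimage import gaussian_filter1d

    labels = arch.compartments[chrom]
    idx = np.minimum((np.arange(n_bins) * bin_size) // COMP_BIN, len(labels) - 1)
    v = np.where(labels[idx] == "A", 1.0, -1.0)
    sigma_bins = max(50_000 / bin_size, 1e-9)
    return gaussian_filter1d(v, sigma_bins, mode="nearest")


def _block_ids(arch: PlantedArchitecture, chrom: str, n_bins: int, bin_size: int) -> np.ndarray:
    labels = arch.compartments[chrom]
    idx = np.minimum((np.arange(n_bins) * bin_size) // COMP_BIN, len(labels) - 1)
    lab = labels[idx]
    return np.concatenate([[0], np.cumsum(lab[1:] != lab[:-1])])


def mean_surface(
    arch: PlantedArchitecture,
    decay: DecayModel,
    chrom: str,
    stage: str,
    condition: str,
) -> np.ndarray:
    """Expected contact surface (upper triangle meaningful), normalised to sum 1."""
    genome = arch.genome
    bs = genome.bin_size
    n = genome.n_bins(chrom)
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
    surf = (d + 1.0) ** (-decay.exponents[stage])
    if stage == "prometa":
        surf *= 1.0 + decay.prometa_boost * np.exp(-d / decay.prometa_boost_len_bins)

    v = _comp_vector(arch, chrom, n, bs)
    k = arch.comp_strength * COMP_RAMP[stage]
    if k > 0:
        surf *= np.exp(k * np.outer(v, v))

    if condition in ("auxin", "auxin_triptolide"):
        ramp = DOMAIN_RAMP[stage]
        if ramp > 0:
            blocks = _block_ids(arch, chrom, n, bs)
            diff_block = blocks[:, None] != blocks[None, :]
            is_b = v < 0
            bb = diff_block & np.outer(is_b, is_b)
            aa = diff_block & np.outer(~is_b, ~is_b)
            surf[bb] *= 1.0 + arch.bb_gain * ramp
            surf[aa] *= 1.0 - arch.aa_loss * ramp

    for dom in arch.domains:
        if dom.chrom != chrom:
            continue
        ramp = 1.0 if dom.static else DOMAIN_RAMP[stage]
        f = 1.0 + (dom.intensity - 1.0) * ramp
        if f != 1.0:
            a, b = dom.start // bs, dom.end // bs
            surf[a:b, a:b] *= f

    sigma = 1.0  # isotropic Gaussian bump, one bin wide
    for lp in arch.loops:
        if lp.chrom != chrom:
            continue
        ramps = LOOP_RAMP[lp.loop_class]
        if condition in ("auxin", "auxin_triptolide"):
            if lp.loop_class in ("structural", "dual_function"):
                amp_ramp = 0.0
            elif lp.loop_class == "cre_transient" and lp.persists:
                amp_ramp = TRANSIENT_PERSIST_RAMP[stage]
            else:
                amp_ramp = ramps[stage]
        else:
            amp_ramp = 0.0 if lp.loop_class == "cre_gained" else ramps[stage]
        amp = (lp.enrichment - 1.0) * amp_ramp
        if amp <= 0:
            continue
        ai, aj = lp.anchor1 // bs, lp.anchor2 // bs
        w = 4
        i0, i1 = max(0, ai - w), min(n, ai + w + 1)
        j0, j1 = max(0, aj - w), min(n, aj + w + 1)
        di = (np.arange(i0, i1) - ai)[:, None]
        dj = (np.arange(j0, j1) - aj)[None, :]
        bump = amp * np.exp(-(di**2 + dj**2) / (2 * sigma**2))
        surf[i0:i1, j0:j1] *= 1.0 + bump
        surf[j0:j1, i0:i1] *= 1.0 + bump.T

    upper = np.triu(surf)
    return upper / upper.sum()


def sample_matrix(
    prob_upper: np.ndarray, budget: float, rng: np.random.Generator, chrom: str, bin_size: int
) -> ContactMatrix:
    counts = rng.poisson(prob_upper * budget)
    import scipy.sparse as sp

    return ContactMatrix(chrom, bin_size, sp.csr_matrix(counts.astype(float)))


def generate_timecourse(
    genome: GenomeSpec,
    arch: PlantedArchitecture,
    decay: DecayModel,
    design: list[SampleKey],
    seed: int = 0,
) -> tuple[dict, dict]:
    """Replicate-level contact matrices plus the planted truth tables.

    Returns ``(matrices, truth)`` with ``matrices[sample][chrom]`` a
    :class:`ContactMatrix`; identical seeds give bit-identical output.
    """
    if any(k.merged for k in design):
        raise ValueError("design must list replicate-level samples")
    surfaces: dict[tuple, np.ndarray] = {}
    matrices: dict[SampleKey, dict[str, ContactMatrix]] = {}
    from .genome import CONDITIONS, STAGES

    for key in design:
        matrices[key] = {}
        for ci, chrom in enumerate(genome.chroms):
            sk = (chrom, key.stage, key.condition)
            if sk not in surfaces:
                surfaces[sk] = mean_surface(arch, decay, chrom, key.stage, key.condition)
            rng = np.random.default_rng(
                [seed, STAGES.index(key.stage), CONDITIONS.index(key.condition),
                 key.replicate, ci]
            )
            matrices[key][chrom] = sample_matrix(
                surfaces[sk], decay.budget_per_replicate, rng, chrom, genome.bin_size
            )
    return matrices, arch.truth_tables()


def merge_replicates(matrices: dict) -> dict:
    """Sum replicate matrices into replicate-merged samples."""
    merged: dict[SampleKey, dict[str, ContactMatrix]] = {}
    for key, per_chrom in matrices.items():
        mkey = key.as_merged()
        if mkey not in merged:
            merged[mkey] = {
                c: ContactMatrix(m.chrom, m.bin_size, m.counts.copy())
                for c, m in per_chrom.items()
            }
        else:
            for c, m in per_chrom.items():
                merged[mkey][c] = ContactMatrix(
                    m.chrom, m.bin_size, merged[mkey][c].counts + m.counts
                )
    return merged


# ---------------------------------------------------------------------------
# signal tracks, counts and annotations
# ---------------------------------------------------------------------------

TRACK_BIN = 500  # bp resolution of the emitted bedGraph tracks


def _track_frame(genome: GenomeSpec, values: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for chrom, vals in values.items():
        length = genome.chromsizes[chrom]
        for b, v in enumerate(vals):
            if v != 0:
                rows.append((chrom, b * TRACK_BIN, min((b + 1) * TRACK_BIN, length), float(v)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def generate_tracks(
    genome: GenomeSpec,
    arch: PlantedArchitecture,
    design: list[SampleKey],
    seed: int = 0,
    nb_dispersion: float = 0.1,
    count_depth: float = 1.0,
) -> dict:
    """Histone/ATAC tracks, per-sample PolII tracks and gene-body counts.

    H3K36me3 is elevated over active gene bodies, H3K27me3 over B-compartment
    blocks; a configurable fraction of domain boundaries is additionally
    planted as chromatin-state transitions (K36 high on one flank, K27 on the
    other). PolII follows each gene's stage profile with the planted auxin
    fold changes; raw counts are negative-binomial per replicate.
    """
    rng = np.random.default_rng([seed, 7])
    nb = {c: -(-genome.chromsizes[c] // TRACK_BIN) for c in genome.chroms}

    k36 = {c: np.full(nb[c], 0.1) for c in genome.chroms}
    k27 = {c: np.full(nb[c], 0.1) for c in genome.chroms}
    k27ac = {c: np.full(nb[c], 0.05) for c in genome.chroms}
    atac = {c: np.full(nb[c], 0.05) for c in genome.chroms}

    for chrom in genome.chroms:
        labels = arch.compartments[chrom]
        starts = np.arange(nb[chrom]) * TRACK_BIN
        cidx = np.minimum(starts // COMP_BIN, len(labels) - 1)
        k27[chrom][labels[cidx] == "B"] = 2.0

    for g in arch.genes:
        b0, b1 = g.start // TRACK_BIN, -(-g.end // TRACK_BIN)
        if g.profile_class != "silent":
            k36[g.chrom][b0:b1] = 3.0 + rng.normal(0, 0.2, b1 - b0).clip(-1, 1)
            k27[g.chrom][b0:b1] = 0.1
        p0 = max(0, (g.tss - 500) // TRACK_BIN)
        p1 = min(nb[g.chrom], -(-(g.tss + 500) // TRACK_BIN))
        amp = 0.2 if g.profile_class == "silent" else float(rng.uniform(2.0, 6.0))
        k27ac[g.chrom][p0:p1] += amp
        atac[g.chrom][p0:p1] += amp * float(rng.uniform(0.7, 1.3))

    # activity bumps over the actual CRE peak intervals (same seed as the
    # annotation generator, so tracks and peaks stay aligned)
    cre_peaks = generate_annotations(arch, seed)["cre_peaks"]
    for chrom, start, end in cre_peaks[["chrom", "start", "end"]].itertuples(index=False):
        mid = (start + end) // 2
        b0 = max(0, (mid - 750) // TRACK_BIN)
        b1 = min(nb[chrom], -(-(mid + 750) // TRACK_BIN))
        amp = float(rng.uniform(2.0, 5.0))
        k27ac[chrom][b0:b1] += amp
        atac[chrom][b0:b1] += amp * float(rng.uniform(0.7, 1.3))

    # planted chromatin-state transitions at a fraction of boundaries
    bounds = list(
        arch.truth_tables()["boundaries"][["chrom", "pos"]].itertuples(index=False, name=None)
    )
    trans_rows = []
    for bi, (chrom, pos) in enumerate(bounds):
        if (bi % max(1, int(round(1 / max(arch.transition_fraction, 1e-9))))) != 0:
            continue
        fb = 50_000 // TRACK_BIN
        b = pos // TRACK_BIN
        lo, hi = max(0, b - fb), min(nb[chrom], b + fb)
        flip = bi % 2 == 0
        k36[chrom][lo:b] += 3.0 if flip else 0.0
        k27[chrom][lo:b] += 0.0 if flip else 2.5
        k36[chrom][b:hi] += 0.0 if flip else 3.0
        k27[chrom][b:hi] += 2.5 if flip else 0.0
        trans_rows.append((chrom, pos, "active_to_inactive" if flip else "inactive_to_active"))
    transitions = pd.DataFrame(trans_rows, columns=["chrom", "pos", "orientation"])

    # PolII: per-sample tracks + per-replicate gene-body counts
    genes = arch.genes
    polii_tracks: dict[SampleKey, pd.DataFrame] = {}
    merged_keys: dict[SampleKey, None] = {}
    for key in design:
        merged_keys.setdefault(key.as_merged())
    count_cols = {}
    body_signal_cols = {}
    sample_id = {k: i for i, k in enumerate(list(merged_keys) + design)}
    for key in list(merged_keys) + design:
        fold = {g.name: DE_FOLD[g.de_class] if (
            key.condition in ("auxin", "auxin_triptolide") and key.stage != "prometa"
        ) else 1.0 for g in genes}
        means = {
            g.name: g.base * EXPRESSION_PROFILE[g.profile_class][key.stage] * fold[g.name]
            for g in genes
        }
        if key.merged:
            vals = {c: np.full(nb[c], 0.02) for c in genome.chroms}
            sig = {}
            rng_k = np.random.default_rng([seed, 11, sample_id[key]])
            for g in genes:
                noise = float(rng_k.gamma(50.0, 1 / 50.0))
                level = means[g.name] * noise / 1000.0
                b0, b1 = g.start // TRACK_BIN, -(-g.end // TRACK_BIN)
                vals[g.chrom][b0:b1] += level
                t0 = max(0, (g.tss - 250) // TRACK_BIN)
                t1 = min(nb[g.chrom], -(-(g.tss + 250) // TRACK_BIN))
                vals[g.chrom][t0:t1] += 2 * level + 0.05
                sig[g.name] = means[g.name] * noise
            polii_tracks[key] = _track_frame(genome, vals)
            body_signal_cols[key.label()] = sig
        else:
            rng_k = np.random.default_rng([seed, 13, sample_id[key]])
            counts = {}
            for g in genes:
                mu = max(means[g.name] * count_depth, 0.01)
                lam = rng_k.gamma(1.0 / nb_dispersion, nb_dispersion * mu)
                counts[g.name] = int(rng_k.poisson(lam))
            count_cols[key.label()] = counts
    counts_df = pd.DataFrame(count_cols)
    body_signal = pd.DataFrame(body_signal_cols)

    return {
        "h3k36me3": _track_frame(genome, k36),
        "h3k27me3": _track_frame(genome, k27),
        "h3k27ac": _track_frame(genome, k27ac),
        "atac": _track_frame(genome, atac),
        "polii": polii_tracks,
        "counts": counts_df,
        "body_signal": body_signal,
        "transitions": transitions,
    }


def generate_annotations(arch: PlantedArchitecture, seed: int = 0) -> dict[str, pd.DataFrame]:
    """Peak/gene BED tables aligned to the planted loops and genes.

    Structural and dual-function loop anchors carry CTCF/cohesin co-occupied
    peaks within +-5 kb of the anchor midpoint; CRE-class loop anchors carry
    CRE peaks (at most one CTCF peak per CRE loop); extra loop-free
    CTCF/cohesin sites are scattered away from all anchors.
    """
    rng = np.random.default_rng([seed, 23])
    genome = arch.genome
    bs = genome.bin_size
    ctcf_rows, cre_rows = [], []

    def peak(chrom, anchor, width=400):
        mid = anchor + bs // 2 + int(rng.integers(-5_000, 5_001))
        return (chrom, max(0, mid - width // 2), mid + width // 2)

    for li, lp in enumerate(arch.loops):
        if lp.loop_class in ("structural", "dual_function"):
            ctcf_rows.append(peak(lp.chrom, lp.anchor1) + (f"ctcf_l{li}_a1",))
            ctcf_rows.append(peak(lp.chrom, lp.anchor2) + (f"ctcf_l{li}_a2",))
        if lp.loop_class in ("dual_function", "cre_stable", "cre_transient", "cre_gained"):
            cre_rows.append(peak(lp.chrom, lp.anchor1, 500) + (f"cre_l{li}_a1",))
            cre_rows.append(peak(lp.chrom, lp.anchor2, 500) + (f"cre_l{li}_a2",))
        if lp.loop_class in ("cre_stable", "cre_transient", "cre_gained") and li % 2 == 0:
            ctcf_rows.append(peak(lp.chrom, lp.anchor1) + (f"ctcf_l{li}_a1",))

    anchors = [(l.chrom, a) for l in arch.loops for a in (l.anchor1, l.anchor2)]
    free_rows = []
    for chrom in genome.chroms:
        ch_anchors = [a for c, a in anchors if c == chrom]
        placed = 0
        min_dist = 100_000
        attempts = 0
        while placed < 20 and attempts < 5000:
            attempts += 1
            if attempts % 1000 == 0:
                min_dist //= 2  # crowded chromosome: relax the exclusion zone
            pos = int(rng.integers(400_000, genome.chromsizes[chrom] - 400_000))
            if all(abs(pos - a) > min_dist for a in ch_anchors):
                free_rows.append((chrom, pos - 200, pos + 200, f"ctcf_free_{chrom}_{placed}"))
                placed += 1
    ctcf = pd.DataFrame(
        ctcf_rows + free_rows, columns=["chrom", "start", "end", "name"]
    ).sort_values(["chrom", "start"], ignore_index=True)
    loop_free = pd.DataFrame(free_rows, columns=["chrom", "start", "end", "name"])
    cre = pd.DataFrame(cre_rows, columns=["chrom", "start", "end", "name"]).sort_values(
        ["chrom", "start"], ignore_index=True
    )

    genes = pd.DataFrame(
        [(g.chrom, g.start, g.end, g.name, 0, g.strand) for g in arch.genes],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )
    tss = pd.DataFrame(
        [(g.chrom, g.tss, g.tss + 1, g.name, 0, g.strand) for g in arch.genes],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )
    polii_peaks = pd.DataFrame(
        [
            (g.chrom, max(0, g.tss - 300), g.tss + 300, f"polii_{g.name}")
            for g in arch.genes
            if g.profile_class != "silent"
        ],
        columns=["chrom", "start", "end", "name"],
    )
    return {
        "ctcf_cohesin": ctcf,
        "ctcf_loop_free": loop_free,
        "cre_peaks": cre,
        "genes": genes,
        "tss": tss,
        "polii_peaks": polii_peaks,
    }


def default_genome() -> GenomeSpec:
    """The desk-scale default: 2 chromosomes x 20 Mb at 10 kb bins."""
    return GenomeSpec({"chr1": 20_000_000, "chr2": 20_000_000}, 10_000)
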
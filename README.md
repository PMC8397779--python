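# mitohic

Chromatin architecture is rebuilt from scratch after every mitosis:
compartments, topological domains and loops are largely erased on condensed
mitotic chromosomes and re-emerge, on a time scale of hours, as cells pass
from anaphase/telophase through early and mid G1. `mitohic` is a toolkit for
quantifying that re-establishment from binned Hi-C contact matrices collected
along a mitosis-to-G1 time course, with and without acute (auxin-inducible)
CTCF depletion, together with the matched PolII ChIP-seq, histone-mark and
ATAC readouts. It is aimed at computational epigenomics groups who want a
tested, scriptable re-implementation of this analysis style rather than a
chain of one-off notebook steps.

## What it computes

* **A/B compartments** — per chromosome, EV1 of the Pearson correlation of
  the observed/expected (O/E) map, sign-oriented by gene density; saddle
  matrices and the genome-wide compartment strength
  `log2[(median top-20% AA + median top-20% BB) / (median top-20% AB + median top-20% BA)]`;
  the distance-resolved compartmentalisation curve
  `R(s) = Spearman(EV1_i * EV1_j, O/E_ij)` over pairs at separation `s`; and
  tiered local B–B / A–A interaction strengths with length-preserving
  shuffled controls.
* **Insulation and domains** — 12-bin sliding-window insulation scores on
  10-kb matrices, boundary strength `dIS = 2^max(IS) − 2^IS(boundary)` over
  ±120 kb, candidate domains from insulation minima (or imported calls),
  cross-stage validation (±8 bins; prometaphase domains need three later
  supporters), 80-kb boundary merging, minima adjustment, ±auxin
  integration, and the aggregated domain analysis (ADA) corner-stripe score
  with all its validity filters; boundary-dynamics k-means (k = 5) and a
  PCA chromatin-state-transition score from H3K27me3/H3K36me3.
* **Loops** — a donut-filtered Poisson caller (local expected from a square
  annulus, lambda-chunked Benjamini–Hochberg q-values) at 10 kb and 25 kb,
  ubiquitous-pixel artifact removal, two-pass growing-radius pixel
  clustering ordered by cross-sample q_min, replicate-supported
  false-negative recovery, lost/gained/retained classification under CTCF
  loss, CTCF/cohesin- and CRE-based categorisation (structural,
  dual-function, CRE loops), 3×3 summit strength, transient-loop dynamics
  clustering with persistence subclusters, structural/CRE interplay
  statistics (interruption, support, s_i-min) and numeric APA pile-ups.
* **Transcription** — PolII gene-body quantification (TSS+500 to TES,
  strand-aware), four-filter active-gene calling, post-mitotic spiking PCA,
  differential expression (NB Wald test, padj < 0.05 and fold change >
  1.25 in at least one post-mitotic stage) and size-classed recovery rates
  for gene-body PolII and gene domains.
* **Enhancer–promoter pairs** — minimal activity-by-contact (ABC) scores
  `A_e * C_eg / sum_e' A_e' * C_e'g`, thresholded pair assembly across
  samples, and moderated-t differential interaction at FDR 0.1 using
  per-replicate Hi-C contact strengths.
* **Synthetic time course** — a generator that plants all of the above
  (distance decay, compartment checkerboard ramping from zero at
  prometaphase, domain tiling, five loop classes with stage/condition
  programs, gene expression programs with spiking and DE, peak annotations)
  and emits machine-readable truth tables, so the whole pipeline is
  testable end to end without external downloads.

## Worked example

```python
from mitohic import simulate as sim
from mitohic.genome import GenomeSpec, full_design
from mitohic.pipeline import run_pipeline

genome = GenomeSpec({"chr1": 8_000_000}, 10_000)
arch = sim.PlantedArchitecture.random(genome, seed=1, n_structural=6, n_dual=2,
                                      n_cre_stable=3, n_cre_transient=4,
                                      n_cre_gained=2, n_genes=20)
decay = sim.DecayModel(budget_per_replicate=4.0e6)
results = run_pipeline(genome, arch, decay, full_design(), seed=1)

s = results["compartment_strength"]
print(f"compartment strength (log2): prometa {s['prometa_control_merged']:.2f} "
      f"-> mid-G1 {s['mid_G1_control_merged']:.2f}")
report = results["report"]
print(f"planted boundaries recovered: {report['boundary_recall']:.2f}")
print(f"planted loops recovered:      {report['loop_recall']:.2f}")
print(f"loop status accuracy:         {report['loop_status_accuracy']:.2f}")
```

prints

```
compartment strength (log2): prometa -0.04 -> mid-G1 1.54
planted boundaries recovered: 1.00
planted loops recovered:      1.00
loop status accuracy:         0.88
```

Compartment strength near zero at prometaphase and ~1.5 at mid-G1 is the
planted ramp being read back out by the saddle machinery; boundary and loop
recall compare the called features against the generator's truth tables, and
status accuracy checks that structural loops vanish under CTCF depletion
(lost) while condition-gained CRE loops are flagged gained.

The same pipeline is exposed as a CLI
(`mitohic simulate | balance | compartments | insulation | domains | loops |
expression | cre | report`, with `--config/--seed/--outdir/--log-level`);
`mitohic simulate` writes the full synthetic input bundle (COO matrices,
bedGraph tracks, BED annotations) plus a `truth/` directory, and
`mitohic report` runs everything and writes the result tables.

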
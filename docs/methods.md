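# Methods

This note documents the models, conventions and parameter choices behind
`mitohic`, in the order the pipeline applies them. Nothing here reports an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Contact matrices and balancing

All analyses run per chromosome on symmetric binned raw-count matrices
(upper triangle stored sparsely; coordinates 0-based half-open, bin =
`floor(position / bin_size)`). Matrix balancing is Knight–Ruiz: a Newton
iteration with conjugate-gradient inner solves that finds weights `w` such
that unmasked balanced row sums `sum_j w_i w_j c_ij` equal one, to an L2
residual below `kr_tol` (default 1e-6, `kr_max_iter` 1000). Bins with zero
marginal, or a marginal in the lowest `mask_low_quantile` (default 2%) of
the nonzero marginals, are masked beforehand — KR is unstable on
near-empty rows, and no external convention fixes this cut, so it is a
config value. On non-convergence the weights fall back to
1/sqrt(marginal) and the matrix is flagged. Balancing is scale-invariant:
multiplying counts by a constant leaves O/E unchanged.

The expected profile is the per-distance mean of balanced values over
unmasked pixels, per chromosome and per sample, with no smoothing; O/E is
balanced value over expected, so every unmasked diagonal of O/E averages
exactly one. Coarser grids (25/50/100 kb) are obtained by re-binning raw
counts by genomic start coordinate and re-balancing.

## Compartments

EV1 is the leading eigenvector of the Pearson correlation matrix of the
per-chromosome 100-kb O/E map (masked bins excluded; isolated undefined
pixels are neutralised to 1 before correlation). The global sign is chosen
so EV1 correlates non-negatively with gene density (default: gene count per
100-kb bin; density definition is configurable since covered-bp is an
equally defensible choice). A = EV1 > 0.

Saddle/compartment strength: bins are ordered by a reference EV1 — the
mid-G1 sample of the matching condition, so stage-to-stage comparisons use
one fixed ordering. Per chromosome the strength is
`(median AA + median BB) / (median AB + median BA)` over the pixels linking
the top and bottom `saddle_top_fraction` (default 20%) of ordered bins; the
genome value is log2 of the chromosome mean. Chromosomes with fewer usable
bins than saddle sections (50) are skipped.

R(s) is the Spearman correlation (average ranks on ties) between EV1
products and O/E over all unmasked pairs at separation `s`, from one bin up
to 125 Mb, averaged over chromosomes; separations with fewer than 10 pairs
are reported missing. The EV1 products are taken from the mid-G1 reference
profile of the matching condition: R(s) measures how far the *final*
compartment structure has spread, and using each sample's own EV1 would
correlate a noisy eigenvector with the very map it was derived from,
biasing the prometaphase curve upward.

Tier analysis segments the 50-kb mid-G1 control profile into maximal
same-label runs ("compartment domains"). A tier-k B–B pair spans k
consecutive A domains: its strength is the mean O/E between the 250-kb
flank upstream of the first A start and the 250-kb flank downstream of the
k-th A end. Pairs whose flank leaves the chromosome are skipped. The
shuffled control relocates 500 randomly chosen domains uniformly
(length-preserving) and evaluates the same flank rectangle.

## Insulation, boundaries, domains

Insulation of bin b sums balanced contacts in the window
`rows [b-12, b) x cols [b+1, b+13)` (12 x 12 bins at 10 kb, one bin off the
diagonal) and reports `log2((sum + 1) / (chromosome mean + 1))`. Windows
truncated by chromosome ends are masked, as are windows whose *raw* count
sum is below `insulation_min_counts` (default 12; the low-count rule could
equally be read per bin, so both the value and the window interpretation
are configurable). Boundary strength dIS unlogs the track: maximum over
±120 kb minus the value at the boundary, hence non-negative.

Candidate domains come from consecutive insulation local minima (peak
prominence `domain_prominence`, default 0.2, spans capped at 2 Mb) plus a
more sensitive second sweep (`subdomain_prominence` 0.1) contributing
sub-domains up to 500 kb; an import path accepts external domain calls
unchanged. Cross-stage validation keeps a prometaphase domain only if at
least three later-stage domains match it (both boundaries within ±8 bins),
and any later-stage domain with at least one later match; matched
boundaries are replaced by the mean over all supporters, and the stage of
emergence is recorded. Boundary merging absorbs, from the 5'-most boundary
outward, everything closer than 80 kb into the group mean; because two
group means can themselves land within 80 kb, the sweep is iterated until
the list is a fixpoint. Boundaries are then snapped to the mid-G1 control
insulation minimum within ±6 bins (unmovable when the window is fully
masked), domains under 100 kb are dropped, and a final 20-kb merge is
applied. Auxin-condition domains either adopt the control coordinates
(both boundaries within 80 kb of one control domain), snap a single
matching boundary, or enter verbatim as new.

ADA scores a domain with corner (i, j) at 10-kb bins as log2 of the summed
O/E in eight 5-pixel stripes just inside the corner over eight matching
stripes just outside, at identical genomic separations. Domains under
150 kb are excluded (outer stripes would cross into neighbours). A domain
is invalid if any stripe pixel exceeds O/E 30, an outer stripe group has
fewer than 5 non-zero pixels, or an inner group fewer than 10 — all
low-mappability guards. The dynamic filter keeps a domain only if at least
one of the six post-mitotic samples reaches 1.25x the ADA of both
prometaphase samples: real domains strengthen after mitotic exit, so
stage-constant "domains" are artifacts.

Boundary dynamics: per-boundary dIS over the 8 samples is row-z-scored and
k-means-clustered (k = 5, 50 restarts, fixed seed) on the six post-mitotic
columns; boundaries missing more than 2 of 8 values are excluded rather
than imputed. Cluster labels are renumbered by descending mean control
mid-G1 z so the labelling is reproducible (raw k-means labels are
arbitrary). The transition score is PC1 of the column-normalised
H3K27me3/H3K36me3 matrix over ±50 kb (ten 10-kb bins per mark, stitched to
20 columns); the sign is fixed so positive PC1 means active chromatin
upstream, and the top/bottom 20% are flagged as chromatin-state
transitions. Enrichment of transitions in a boundary cluster is a
two-sided Fisher exact test on the 2 x 2 table (sample odds ratio ad/bc; a
zero marginal yields an undefined ratio and p = 1 by convention).

## Loops

The caller implements the donut filter: the local expected value of pixel
(i, j) is the balanced sum over a square annulus (Chebyshev radius between
inner and outer donut radii, the row/column cross excluded), normalised by
the distance-expected sum over the same annulus and rescaled to the raw
count scale through the balancing weights. Significance is the Poisson
upper tail of the raw count, BH-adjusted within lambda chunks (expected
values binned in powers of 2^(1/3)) to stabilise the FDR across the
dynamic range. Parameters: 10 kb — inner/outer diameters 4/16 bins, FDR
0.2; 25 kb — 1/6 bins, FDR 0.01; separations above 2 Mb excluded. A
significant pixel must additionally exceed 1.5x its donut expected, and a
single-pixel cluster is kept only when q <= 0.02 — both standard
loop-calling conventions, without which BH leakage at the permissive FDR
floods the list with marginal singletons.

Pixels significant in more than 6 of the 8 samples are removed as
ubiquitous artifacts. Surviving pixels, ordered by ascending cross-sample
q_min (ties broken by genomic coordinate), are clustered greedily: the top
pixel absorbs everything within 20 kb, the cluster centroid and its
far-edge distance s are computed, and a second pass absorbs pixels within
20 kb + s of the centroid. The summit is the lowest-q_min member. Clusters
whose pixels come only from control samples are "lost", only from auxin
"gained", otherwise "retained".

False-negative recovery re-examines all raw significant pixels per
condition in every individual replicate: at ana/telophase and early G1 a
pixel must pass q < 0.2, O/E-donut > 1.5 and observed > 10 in the merged
sample *and every replicate*; at mid-G1 the three criteria must hold in
all but at most one of {merged, replicates} (with three replicates this is
the 3-of-4 rule; the default two-replicate design makes it 2-of-3).
Pixels in the top 5% of prometaphase O/E-donut, beyond 2 Mb, or within one
bin of an existing loop pixel are dropped; the remainder is clustered and
appended with a provenance flag. 25-kb clusters duplicating a 10-kb
cluster (both anchors within one 25-kb bin) are dropped.

Categories use peak overlap (>= 1 bp) with the 30-kb window centred on each
anchor summit: CTCF/cohesin at both anchors with CREs at <= 1 anchor =
structural; CTCF at both plus CREs at both = dual-function; CREs at both
with CTCF at <= 1 = CRE loop; anything else unclassified. Loop strength per
sample is the mean observed/donut-expected over the 3 x 3 summit block
(partial blocks use the unmasked subset). CRE-loop dynamics: z-scores
across the four control stages, 4-means on the three post-mitotic control
columns, cluster 1 relabelled as the transient class (maximal
ana/telophase-minus-mid-G1 z); transient loops are sub-clustered (2-means
on the six post-mitotic columns of both-condition z-scores) into
persisting (P, higher auxin mid-G1 z) versus non-persisting (NP).

Interplay: a structural loop *interrupts* a CRE loop when it covers exactly
one CRE anchor (anchor inside the structural span extended by half the
anchor window), so one structural anchor falls strictly between the CRE
anchors; it *supports* the CRE loop when both CRE anchors nest inside it.
s_i-min is the distance from the influenced CRE anchor — defined as the
anchor nearer the interior structural anchor — to the nearest interior
structural anchor. Per-cluster enrichment is Fisher-tested against all
other CRE loops, and the same computation runs against loop-free
CTCF/cohesin sites as a control. APA is the element-wise mean of O/E
windows (±10 bins) around summits, loops under 100 kb excluded; output is
numeric, not rendered.

## Transcription

Gene bodies are [TSS+500, TES) strand-aware; the 500-bp offset keeps
promoter-proximal PolII out of the body signal and is applied at the TSS
end only (applying it at both ends is a configurable alternative). Active
genes must (1) have a PolII peak at the TSS, (2) exceed 1 kb, (3) escape
the lowest decile of both H3K27ac and ATAC promoter signal (TSS ±250 bp),
and (4) reach 1.5x both prometaphase body signals in at least one
post-mitotic sample. Spiking PC1 is computed per condition on per-gene
stage profiles normalised to sum one, PCA on the last three stages, sign
fixed by positive correlation with the early-G1 share (high PC1 = spiky).

Differential expression is a per-stage two-group negative-binomial Wald
test: method-of-moments dispersion estimated within each condition
(pooling across conditions would absorb the treatment effect into the
dispersion), trimmed-mean pooled across genes, delta-method variance
`(1/mu + alpha)/n` on the log mean, BH adjustment. A gene is DE at
padj < 0.05 and |fold change| > 1.25 (strict) in >= 1 post-mitotic stage;
up/down labels come from 2-means on the per-stage log2FC vectors, the
cluster with positive mean log2FC being "up". Recovery rates are
`(x_t - x_prometa) / (x_ref - x_prometa)` with mid-G1 control as
reference, clipped to [0, 1.5] for reporting, aggregated in gene-size
classes (30–50, 50–100, 100–150, >150 kb) and compared between gene-domain
ADA and PolII by exact Wilcoxon signed-rank (normal approximation above 25
informative pairs). The gene-domain score is ADA applied to the gene-body
square with the size floor lowered to 30 kb — a documented stand-in, since
no standard definition exists for this quantity.

## Enhancer-promoter pairs

Element activity is the geometric mean of H3K27ac and ATAC over the
element; contact `C_eg` is the O/E at the element/TSS bin pair at 10 kb,
averaged over a 3 x 3 neighbourhood and floored at zero (consistent with
the loop-strength convention and robust to single-pixel noise). ABC scores
normalise activity x contact over all candidates within 5 Mb of the TSS,
so scores per gene sum to one; promoter elements of other active genes
enter the candidate set, giving promoter-promoter pairs. Pairs reaching
the working threshold (0.04; the 0.01–0.05 ladder is reported for
threshold-robustness checks) in at least one sample form the non-redundant
list, and contact strengths from *all* samples are attached. Differential
interaction pools early- and mid-G1 per-replicate contact values as equal
biological replicates per condition and applies a pooled-variance t-test
with empirical-Bayes shrinkage of the per-pair variance toward the global
mean variance (prior df 4); status at BH FDR 0.1.

## The synthetic time course

The generator defines the study conditions: 2 chromosomes x 20 Mb at 10-kb
bins; 4 stages (prometaphase, ana/telophase, early G1, mid G1) x 2
conditions (control, auxin) x 2 replicates; 1e7 contacts per chromosome
per replicate (5e5/Mb — the depth regime of published deep merged Hi-C
maps, which 10-kb loop calling genuinely requires; at several-fold lower
depth the Poisson tails of 3x dots beyond ~500 kb are unreachable).

Each matrix is an independent Poisson sample of a mean surface composed
of: a power-law decay per stage (exponent 1.5 at prometaphase with a
2x short-range boost decaying over 30 bins, relaxing to 1.0 by mid-G1);
a compartment modulation `exp(k * v_i * v_j)` with the planted profile
smoothed over 50 kb (hard 100-kb steps would plant corner dots no real
eigenvector produces) and k ramping 0 -> 0.6 from prometaphase to mid-G1;
contiguously tiled domain squares (200 kb – 1 Mb, 2x enrichment, ramping
with the same schedule; a couple of stage-constant "static artifact"
domains per chromosome exercise the dynamic ADA filter; boundaries are
shared edges, as on real chromosomes); isotropic Gaussian loop bumps
(sigma = 1 bin, matching the 3 x 3 strength neighbourhood) with class
programs — structural/dual-function 4x in control ramping through G1 and
absent under auxin; stable CRE 3x in both conditions; transient CRE 3x
peaking at ana/telophase and fading in G1, with half the loops persisting
into G1 under auxin; gained CRE absent in control and ramping in under
auxin, wired from an enhancer to the promoter of an up-regulated gene —
and, under auxin, inter-block B–B contacts gaining up to 1.5x and A–A
losing up to 0.8x with the stage ramp. Loop spans are 200–900 kb.

Tracks: H3K36me3 over active gene bodies, H3K27me3 over B blocks, half of
the boundaries planted as chromatin-state transitions with opposed marks
on the two flanks; H3K27ac/ATAC bumps over the actual CRE peak intervals
and promoters; per-sample PolII following each gene's stage profile
(spiky: early-G1 peak then decline; gradual: monotone rise; silent: flat)
with 2x/0.5x auxin fold changes for up/down genes and negative-binomial
gene-body counts (dispersion 0.1) per replicate. Annotations place
CTCF/cohesin peaks within ±5 kb of structural/dual anchors, CRE peaks at
CRE-class anchors (at most one CTCF peak per CRE loop), and 20 loop-free
CTCF sites per chromosome. All outputs are bit-identical under a fixed
seed.

What the generator does *not* emulate — and what passing tests therefore
do not certify on real data: mappability and GC bias, translocations,
restriction-fragment granularity, replicate batch effects, trans
contacts, nested domain hierarchies, distance-dependent loop anchors
(anchors are points, not extrusion trajectories), and realistic
peak-width/signal distributions. Recall numbers on the synthetic bundle
are upper bounds for real libraries.

## Numerical conventions

k-means uses 50 restarts and a fixed seed everywhere, with deterministic
relabelling rules as above. Spearman ties take average ranks. Fisher and
signed-rank tests are exact at small n. Matrices too short for a window or
with degenerate correlation structure raise rather than return silently.
Problem sizes in the test-suite benchmarks (20-Mb chromosomes, 300-gene
count tables, 200-pair differential tables, three-simulation averages for
the DE operating characteristic) were chosen as the smallest instances at
which the planted effects are statistically resolvable at the study-
condition effect sizes.

## Known limitations

Only the donut background is implemented (no horizontal/vertical/
lower-left filters), so pixels on strong stripe features can pass;
per-sample false clusters of the order of a few per 20 Mb remain at FDR
0.2. The NB Wald substitute is mildly anticonservative at two replicates
(empirical FDR up to ~1.5x nominal in the null-free tail); with five
replicates it meets its operating targets. Inter-chromosomal
normalisation, hierarchical TAD trees, stripe calling and sub-compartments
are out of scope.
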
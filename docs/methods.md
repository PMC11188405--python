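# Methods

This note records the models, algorithmic choices and their rationale, the
synthetic-data design, and the limits of what the test suite demonstrates.

## Genetic model and scan engine

**Population.** Doubled-haploid (DH) lines: each line is a single F1
gamete doubled to homozygosity, so every marker segregates in two classes
(coded 0 for the first parent, 1 for the second; heterozygote codes are
rejected as a contract violation). Chromosomes assort independently.

**Map function.** Haldane, `r = (1 − e^(−2d/100))/2`, because it makes
flanking-marker conditioning exact under crossover independence: the two
recombination events bracketing a test position are independent, giving
the closed form `P(Q=0 | g_L, g_R)` used by the scan. Kosambi is provided
for distance↔fraction conversion only. Results are mildly sensitive to
this choice; it is deliberately explicit rather than implied.

**Missing genotypes.** The conditional probability uses the nearest
non-missing marker on each side; a wholly missing side reduces to
single-flank conditioning and both sides missing gives 1/2. Cofactor
*covariate* columns (fixed across positions) are mean-imputed instead —
pairwise deletion would change the line set per position and make LODs
incomparable along the genome.

**Haley–Knott regression.** The trait is regressed on E[genotype | flanks]
rather than fitted by EM maximum likelihood. For DH populations (two
genotype classes, balanced frequencies) the approximation is excellent,
and it makes genome × transcriptome scanning feasible: with no cofactors
the LOD for every (position, trait) pair reduces to a single standardized
cross-product, so thousands of transcripts and permutations are scanned
with one matrix multiplication. `LOD = (n/2) log10(RSS₀/RSS₁)`; a
perfectly determined trait is capped at ratio 1e−12 (LOD = 6n) and flagged
`saturated` rather than overflowing.

**Evaluation grid.** 1-cM walking speed by default; the walk restarts at
each marker so markers are always evaluated exactly and no gap exceeds the
step.

**Cofactor selection.** Forward selection on single markers, capped at 5.
The entry criterion is an extended BIC: each step adds
`log n + 2 log m` (m = number of candidate markers) to the penalty.
Plain BIC ignores that every step takes the best of ~150 correlated
candidates and admits a spurious cofactor on nearly half of pure-noise
traits; the extended penalty restores the intended null behaviour (empty
sets on ≥ 90 % of noise traits) while still picking a marker carrying
R² = 0.5 essentially always. Ties break toward map order, making the
selection deterministic.

**CIM.** Cofactors enter both the null and full models but are excluded
within a 10-cM window of the test position (per chromosome), so they
absorb background QTL without swallowing the local signal. Distinct
window-exclusion subsets are cached (QR residualization per subset), which
keeps permutation scans with cofactors cheap.

**Permutation thresholds.** Trait values are shuffled across lines with
genotypes fixed; the threshold is the type-7 (linear-interpolation)
(1−α) quantile of genome-wide maximum LODs. Fewer than 20 permutations is
refused. Thresholds computed for a CIM scan reuse the same cofactor model,
so the null respects the fitted background. Seeds are recorded in the
returned object and echoed to JSON sidecars by the CLI.

**Peak calling.** Local maxima above threshold; on each chromosome, maxima
within 10 cM of a stronger kept peak merge into it (ties at equal LOD go
to the lower cM), and a weaker maximum whose own 1.5-LOD support interval
already contains a stronger kept peak is suppressed as a shoulder — without
this, the decaying flank of a strong QTL sheds spurious satellite peaks.
Support intervals are 1.5-LOD drops clipped to chromosome ends; the
reported physical interval interpolates marker bp linearly in cM. The
merged representative keeps the maximum-LOD position; no joint refit is
attempted.

## Expression preprocessing

Lowess MA normalization (statsmodels lowess, default span 0.3) removes
intensity-dependent dye bias per array, with dye-swap arrays sign-flipped.
Quantile normalization equalizes column distributions exactly; ties
receive the mean of their rank-run targets, which preserves idempotency on
tie-free data (with ties, a second pass can shift values within tie
groups — inherent to tie averaging, not an implementation artifact).
The probe filter keeps a probe iff its intensity exceeds the background
floor (20) in at least 30 % of samples — the only reading of the
filtering rule consistent with discarding "non-significant signal"
probes — then clamps survivors up to the floor and log2-transforms.
Differential expression uses the pooled-variance (Student) t, BH step-up
control at FDR 0.05, and a geometric fold change `2^|Δmean|` computed on
post-floor log2 means; both gates must pass for a call.

## Co-expression network

Unsigned adjacency `|cor|^β`. The soft power is the smallest β ∈ 1..20
whose scale-free fit reaches 0.8, where fit = −sign(slope)·R² from
regressing log10 p(k) on log10 k over 10 equal-width connectivity bins
(occupied bins only) — positive exactly when the degree distribution
decays, as a power law requires. If no power reaches the cut, the best
fit **among powers with mean connectivity ≥ 1** is used: below that the
network is effectively disconnected and the fit statistic is noise (an
unguarded argmax drifts to β = 20 and erases all module structure).

TOM follows the standard form `ω_ij = (ℓ_ij + a_ij)/(min(k_i,k_j)+1−a_ij)`
with unit diagonal. Modules come from average-linkage clustering of
1 − TOM with a deterministic static cut at 0.99 × the maximum merge
height; branches below 30 members are unassigned (label 0), survivors are
labelled 1..K by decreasing size. This replaces the dynamic-hybrid
tree-cut: its many unstated tuning constants are out of scope here, and
the static cut recovers planted modules at ARI ≥ 0.9 under the tested
conditions. The cut height and minimum size are configurable.

The module eigengene is the first right singular vector of the
standardized module matrix, scaled to unit variance (ddof = 1) and
oriented to correlate positively with the module's mean profile (first
member if the mean is degenerate). Merging is greedy: repeatedly merge the
pair of modules with the highest eigengene correlation ≥ 0.75, recompute,
stop when none qualifies; the survivor keeps the larger module's label.
Because eigengenes are recomputed, chains of pairwise-similar modules can
coalesce. Module–trait association is Pearson r with the two-sided
t-distribution p (n − 2 df) on pairwise-complete lines (≥ 5). The
|r| ≥ 0.75 hard-threshold edge list is an export product (SIF/TSV for
Cytoscape); its degree power-law fit is reported, never enforced.

## eQTL

All transcripts are scanned in IM mode by default: the vectorized engine
makes the genome × transcriptome scan a handful of matrix products, and
for single-eQTL architectures IM and CIM agree on peak location (CIM per
transcript is available by flag). The global permutation threshold pools
genome-wide maxima from 100 sampled transcripts × 10 permutations (1000
maxima) and takes the 95th percentile; its LOD value is data-dependent by
construction. Peaks merge within 10 cM; each record carries the nearest
marker to the peak. Classification: **cis** iff the gene position is
known, lies on the peak-marker chromosome, and |gene − marker| ≤ 4 Mb
(boundary inclusive); a different chromosome is trans at any distance;
unknown positions are "unplaced" and excluded from cis/trans tallies.
Gene position is the transcript interval midpoint. Trans hotspots are
counted in 10-cM bins and flagged by a BH-adjusted Poisson upper tail
against the mean count over occupied bins.

## Integration

Network QTL maps each eigengene with CIM and a module-specific permutation
threshold (per-module seeds derived deterministically from the stage
seed); peaks are named `qModule<k>_<chrom>_<i>`. Colocalization of two
peaks requires the same chromosome and (support-interval overlap OR peaks
within 10 cM) — the OR combination covers both sharp and shallow peaks.
The module–trait significance gate is BH across the full module × trait
grid at 0.05: a reproducible rule in place of reading a heatmap by eye.
The causal subnetwork is the union of qualifying modules' members with the
induced hard-threshold edges. Causal-gene tiers: `cis-colocal` (member of
a trait-associated module + cis-eQTL colocalizing with a trait pQTL) >
`trans-colocal` (same with a trans-eQTL) > `module-only`; within tier,
descending eQTL LOD. Fisher enrichment is one-sided (greater), reported
with both the raw p < 0.05 rule and BH-adjusted values; the default
universe is the filtered transcript set, not the whole array.

## Synthetic studies

The generator emulates the study design the pipeline assumes, with full
ground truth:

- **Genotypes** — per chromosome, a two-state Markov chain over the marker
  map with switch probability `haldane(Δd)`; first marker Bernoulli(1/2).
  Default genome: 3 chromosomes × 100 cM × 40 Mb, one marker per 2 cM
  (dense enough that the 4-Mb cis window spans several markers); default
  96 lines (the classic DH panel size; recovery experiments use 200).
- **Expression** — each planted module has a *hub gene* whose expression
  is cis-regulated by its hub marker at R² = `hub_r2` (default 0.5) and
  *is* the module latent; other members load on it at `loading`
  (default 0.8, within-module correlation ≈ loading²). Planted cis genes
  are `√R²·g + √(1−R²)·ε`. Cis-regulated genes (hubs included) are placed
  within ±0.5 Mb of their marker — the physical scale of real cis
  variation; the 4-Mb calling window exists to absorb marker sparsity and
  localization error, not gene–variant distance. Other transcripts are
  placed uniformly. On the default linear scale, intensities are
  `2^(b_t + x)` with per-transcript baselines `b_t ~ N(8, 3²)`, so a
  realistic fraction of probes sits near background and the filter has
  work; `expression_scale="log2"` emits log2 values directly for
  analysis-stage tests.
- **Traits** — `Σ √R²·driver + noise`, drivers being standardized marker
  codes or module latents; sibling traits share the systematic part
  (weight 0.9), emulating correlated fibre/lignin measures that map to the
  same loci; decoys are independent noise. R² overcommitment is a config
  error.

The end-to-end design point used in validation: n = 200 lines, a causal
module of 50 transcripts with hub R² = 0.25 (genetic control of module
activity), trait built on the module latent at R² = 0.64 (|r| ≈ 0.8, the
magnitude of a strong module–trait association), plus two decoy modules so
the transcriptome is modular rather than one block in noise. Under these
conditions the full chain (pQTL + mQTL + hub cis-eQTL mutual
colocalization and a top-tier hub call) succeeds in ≈ 92 % of simulations;
the residual failures are honest localization misses of the marker-level
R² ≈ 0.16 phenotype QTL.

**What the generator does not model:** segregation distortion (available
as no default), epistasis, genotype × environment, dye chemistry or array
image artifacts, expression heteroskedasticity beyond lognormal abundance,
and linkage-map error (the map is taken as given). Passing recovery tests
therefore demonstrates correctness of the machinery under the assumed
model, not robustness to all failure modes of real data.

## Problem sizes and numerics

Validation runs use deliberately compact designs — 150–200 lines,
300–1000 transcripts, 200–500 permutations, 10–50 replicates per
experiment — chosen so the full suite completes in about a minute while
every rate has a usable Monte-Carlo budget (e.g. 200 matched-null scans
for the false-positive band). Protocol-scale settings (3000 permutations)
remain the config defaults. Quantile interpolation is type 7 everywhere;
correlation-degenerate cases (zero-variance traits/transcripts/markers)
are either errors (traits), drops with warnings (transcripts), or skipped
positions (markers), as noted per function. LOD ties in peak calling break
toward the lower cM, then lexicographic chromosome order.
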
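# sysgen — systems genetics of doubled-haploid populations

`sysgen` is a Python library for dissecting complex quantitative traits by
combining linkage mapping with transcriptome-wide co-expression analysis in
doubled-haploid (DH) biparental populations, the design used in crop
genetics (e.g. oilseed-rape seed-quality studies). It implements the full
chain from genotype/expression/trait tables to prioritized causal genes:

1. **QTL mapping** — Haley–Knott composite interval mapping (CIM) over a
   1-cM evaluation grid, with forward-selected background cofactors
   (10-cM exclusion window), genome-wide permutation thresholds, 1.5-LOD
   support intervals and 10-cM peak merging.
2. **Expression preprocessing** — two-colour array lowess (MA) and quantile
   normalization, probe filtering against a background floor
   (keep iff intensity > 20 in ≥ 30 % of samples), flooring + log2,
   replicate averaging, and Student-*t*/Benjamini–Hochberg differential
   expression with a fold-change gate.
3. **Co-expression networks** — unsigned weighted adjacency |cor|^β with
   scale-free soft-power selection, topological overlap (TOM), average-
   linkage module detection, module eigengenes (first principal component),
   eigengene merging at similarity ≥ 0.75, module–trait correlation and a
   hard |r| ≥ 0.75 edge export for Cytoscape.
4. **eQTL analysis** — every transcript scanned as a trait against a pooled
   *global permutation threshold* (GPT), peaks merged within 10 cM and
   classified **cis** (gene within 4 Mb of the peak marker on the same
   chromosome) or **trans**, with Poisson-based trans-hotspot detection.
5. **Integration** — module eigengenes mapped as traits ("network QTL"),
   colocalization of pQTL/mQTL/eQTL (overlapping support intervals or peaks
   within 10 cM), Fisher-exact category enrichment, and evidence-tiered
   causal-gene calls: a gene in a trait-associated module whose cis-eQTL
   colocalizes with the trait QTL is the strongest candidate
   (`cis-colocal`), the reasoning that singles out genes like *CCR1* in
   lignin-pathway studies.

A first-class synthetic-data module simulates complete DH studies — Markov
recombination under the Haldane map function, cis-regulated hub genes whose
expression drives planted co-expression modules, and traits built from
module activity — with full ground truth, so every stage is validated by
recovery of planted structure.

## The statistics in brief

At grid position *x* with flanking markers L, R, a DH line's QTL genotype
probability is `P(Q=0 | g_L, g_R) = w_L w_R / (w_L w_R + w̄_L w̄_R)` with
`w = 1−r` or `r` by flank state and `r = (1 − e^(−2d/100))/2` (Haldane).
The trait is regressed on this conditional expectation (Haley–Knott);

```
LOD(x) = (n/2) · log10( RSS_null / RSS_full )
```

where both models carry the active cofactors (CIM excludes cofactors
within 10 cM of *x*). Significance is the 95th percentile of genome-wide
maximum LODs over trait permutations. TOM similarity is
`ω_ij = (ℓ_ij + a_ij) / (min(k_i,k_j) + 1 − a_ij)` with `ℓ = A²`, and the
module eigengene is the variance-maximizing unit combination of the
standardized member profiles.

## Worked example

```bash
python examples/01_qtl_mapping.py
```

```
simulated 200 DH lines x 153 markers; true QTL at A02 50 cM
cofactors: ['A02_m029']; genome-wide LOD threshold 2.24 (500 permutations, alpha 0.05)
QTL on A02 at 58 cM [55-60 cM, 22.0-24.0 Mb], LOD 7.0, R^2 0.15, additive +0.38 (high allele from P2)
```

One QTL with R² = 0.2 was planted at 50 cM on A02; the scan calls a single
peak 8 cM away (well inside typical localization error at this effect
size), explaining 15 % of trait variance, with the trait-raising allele
from parent P2. The other examples walk the remaining capabilities:
preprocessing (`02`), network + module–trait association (`03`), eQTL with
cis/trans classification (`04`) and end-to-end causal-gene prioritization
(`05`). A thin CLI (`sysgen simulate|preprocess|qtl|network|eqtl|integrate|report
--config run.yaml`) drives the same library functions from YAML configs and
writes per-stage manifests.

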
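# Methods

`clonehema` implements a desk-scale analysis of clonal hematopoiesis (CH)
from "reverse-called" blood somatic mutations: variants called with the
blood sample as the tumor input and the paired solid-tumor sample as the
germline reference. This note records the models, the parameter choices
that matter, and what the synthetic cohorts do and do not emulate.

## Reverse-calling filter cascade

Raw reverse calls are refined into the **full** catalog by an ordered
cascade; intersecting the full catalog with a second caller's output or a
mosaicism classifier's output yields the nested **mutect** and **mosaic**
catalogs.

| step | rule |
|---|---|
| basic | caller PASS, alternate reads >= 2, VAF < 0.5 (strict) |
| mappability | drop calls inside low-mappability intervals (DUST/UMAP-style BED) |
| dbs_merge | merge adjacent same-sample SNVs into double-base substitutions |
| pon_population | drop calls whose panel-of-normals frequency strictly exceeds the max frequency of the DNMT3A-R882H/JAK2-V617F hotspot keys, or whose population MAF strictly exceeds the resource cutoff (PoN TCGA 0.002, PoN HMF 0.008, gnomAD 0.0003) |
| common_snp | drop calls keyed (chrom, pos, ref, alt) in a common-SNP set |
| region_masks | drop calls in segmental duplications, simple repeats, masked regions |
| hypermutator | drop whole samples whose burden strictly exceeds the cohort's 97.5th percentile |

Numerical choices: all frequency comparisons are strict, ties kept; VAF is
recomputed as AD/DP whenever the FORMAT fields are present; internal
interval logic is 0-based half-open, VCF I/O 1-based; DBS merging is
left-greedy over runs of adjacent SNVs (a triplet becomes one DBS plus one
SNV), with the merged VAF the mean of the pair; the burden percentile uses
linear interpolation.

The percentile exclusion is defined on the cohort's burden distribution and
applied once. `run_cascade` records the computed threshold in its report
and accepts it back as an override, which makes the cascade a fixpoint on
its own output: re-running with a freshly recomputed percentile would
always shave the next-highest-burden sample, which is not the intended
semantics of a one-shot QC cut.

## SBS96 signatures

Catalogs count single-base substitutions in the 96 pyrimidine-centric
trinucleotide channels (COSMIC order); purine-reference variants are
reverse-complemented. The HSC reference construction averages per-donor
channel *frequencies* (each healthy donor normalized to its own total), so
high-burden donors do not dominate.

De novo extraction follows the bootstrapped-NMF convention:

* each bootstrap resamples every sample's catalog multinomially at its own
  total (seeds derived from the master seed and the bootstrap index);
* factorization is multiplicative-update NMF minimizing the generalized
  Kullback-Leibler divergence (a Frobenius variant is available via
  `objective="fro"`); the KL objective is non-increasing across updates,
  and convergence is declared at a relative objective change of 1e-6
  (at most 1000 iterations; non-convergence is counted and flagged);
* per-bootstrap solutions are clustered by greedy cosine matching to
  running centroids; consensus signatures are the centroids; per-cluster
  stability is the mean cosine-distance silhouette;
* k is chosen to maximize the mean silhouette **subject to decreasing
  reconstruction error**: among the k whose silhouette is within 0.02 of
  the best (i.e. equally reproducible across bootstraps), the lowest
  relative reconstruction error wins, smaller k on exact ties. A pure
  silhouette maximum is degenerate here — a merged low-rank solution can be
  exactly as reproducible as the true one.

Samples with 100 or fewer mutations are excluded from extraction (strict
"more than 100"). Exposures are refit per sample by non-negative least
squares on counts, with no sparsity penalty; near-duplicate signature pairs
(cosine > 0.999) are flagged as collinear but still fit.

The packaged HSC reference profile is a **synthetic stand-in** generated in
code: a flat clock-like background with elevated C>T at CpG and a raised
T>C component. The measured healthy-donor profile it emulates is not
redistributable; every quantitative claim in the tests is therefore about
recovery of this planted profile, not about the real signature's shape.

## CH classification

A donor is a CH case when they carry a nonsilent mutation (missense,
nonsense, frameshift, splice, in-frame indel — annotation is consumed, not
computed) in a compendium gene. The basis follows the cumulative-bar
ordering: known CH gene seen by germline calling > known CH gene seen only
by reverse calling > gene discovered in the primary/metastasis cohorts
(myeloid-driver tier included here) > targeted-cohort gene. Among
driver-mutated donors the median rate of hematopoiesis mutations per year
of age (HSC exposure / age) is computed; driverless donors strictly above
that median are rate-threshold cases. Donors exactly at the median are not
cases. With no driver-mutated donors the rate rule is skipped with a
warning. Gene-level summaries: pairwise Jaccard index and co-mutation
frequency (Jaccard undefined — NaN — for genes never mutated), and the
donor histogram over the number of mutated compendium genes.

The discovery-input filter keeps calls with VAF <= 0.4 (strictly above 0.4
removed), and a gene counts as expressed when the maximum of its fpkm
distribution across CD34+ cells is strictly above 15.

## Associations

CH status is regressed on age (years, untransformed), sex, and
cytotoxic/non-cytotoxic exposure flags by maximum-likelihood logistic
regression with Wald 95% CIs; perfect separation or a degenerate outcome
withholds the estimates with a flag. Gene-level models (mutated ~ treatment
+ covariates) are corrected by Benjamini-Hochberg within each treatment
family; genes mutated in fewer than 5 donors are skipped. The age-exposure
trend reports binned means +- sd (default 5-year bins) and the Pearson r/p
on unbinned data.

## TF-motif disruption scanning

Variants inside H3K27ac peaks overlapping an enhancer whose annotated
target gene is a compendium driver are expanded +-15 bp on the reference
and alternate haplotypes and scanned against the expressed-TF motifs. The
exact null distribution of the log2-odds score of a background k-mer is
computed by dynamic-programming convolution over motif positions at a score
granularity of 1e-3 log-odds units; a pseudocount of 0.001 is added to PWM
cells (FIMO-like defaults, order-0 background with configurable base
frequencies). Each haplotype's p-value is the minimum over all offsets and
both strands. With alpha = 1e-4: disruption iff p_ref < alpha <= p_alt,
creation iff p_alt < alpha <= p_ref, otherwise none (both-significant and
neither-significant are "none"). Windows shorter than the motif are
skipped, as are offsets containing non-ACGT bases.

## Synthetic cohorts

The real cohorts are access-controlled, so every stage is exercised on
simulated paired call sets. The generator's defaults are the study
conditions:

* 300 donors, ages uniform 30-80 years, CH prevalence 0.15;
* CH donors: one driver mutation at a named hotspot (DNMT3A/JAK2 labels on
  a seeded synthetic genome) plus Poisson(age x 1.0/yr) hitchhiking
  passengers drawn from the HSC-like profile, all at true VAF =
  clone_fraction / 2 with clone fractions uniform 0.05-0.40;
* read support Binomial(depth, VAF) with depth ~ Poisson(40); calls with
  zero alternate reads are not emitted (a caller would not report them);
* two artifact signatures at 10-60 mutations per donor each, VAF 0.05-0.25;
* 3% of donors are hypermutator-like, with artifact burdens inflated
  10-30x. These are the samples the 97.5th-percentile exclusion exists to
  remove; without them the cut would fall on the highest-burden genuine CH
  donors and destroy the age-exposure signal the cohort is supposed to
  carry;
* germline leakage: Poisson(5) variants per donor at true VAF 0.5, present
  in both the blood and the tumor call set (the reverse-calling premise);
* mutation placement respects trinucleotide context on the synthetic
  genome (uniform context availability; no real reference required), with
  a random strand so that catalog construction exercises pyrimidine
  collapsing.

Ground truth (CH status, driver gene, clone fraction, true passenger
count, hypermutator status) is stored beside — never inside — the emitted
VCFs.

For signature-extraction studies, `planted_mixture_catalogs` generates
catalogs directly: 150-500 mutations per sample, the HSC share uniform on
0.5-0.9 (mean 0.7) and the remainder split randomly between the two
artifact profiles. The per-sample variation is essential, not cosmetic:
with identical proportions in every sample the exposure matrix is rank
deficient and no factorization can separate the signatures; it is also what
real cohorts look like, where clone sizes and artifact burdens differ
between donors.

What the simulations do **not** emulate: read-level errors and alignment
artifacts, copy-number/mosaic-chromosomal-alteration CH, real
trinucleotide abundances of the human genome, cohort structure (cancer-type
composition, treatment-age confounding), indels, and realistic germline
variant density. Passing tests therefore demonstrate that the
implementation recovers what it is defined to recover under its own
generative assumptions — not that those assumptions capture everything in
protected patient data.

## Problem sizes

The test suite and the acceptance script choose sizes that keep each run in
minutes while leaving the statistics comfortably powered: signature
recovery uses 300 samples x 100 bootstraps x k in {2,3,4}; the
odds-ratio calibration uses 100 replicates at n = 2,000; the age-exposure
trend uses a 1,500-donor cohort (at the measured overall correlation of
r ~ 0.1, significance at 0.05 needs roughly 400 donors, so 1,500 gives
stable power while staying well under the real cohort's 3,785).

## Known limitations

* The compendium shipped by default is a placeholder (the simulator's two
  hotspot genes); the curated 64-gene list is a user-supplied TSV.
* Consequence annotation, the driver-discovery pipeline itself, external
  caller execution, and non-coding driver-element discovery are out of
  scope; the pipeline consumes their outputs.
* One tumor call set per donor is assumed (multi-tumor donors must be
  resolved upstream).
* The exact per-sample attribution method behind the published
  exposure-age figure is unstated; NNLS refitting is used here.
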
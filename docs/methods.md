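# Methods

## Normalization model

Targeted hybridization-counting panels report one count per probe per
sample with no amplification, so normalization is multiplicative and
per-sample. The pipeline models three nuisance components and removes
them in order:

1. **Background.** Orphan negative-control probes measure non-specific
   binding. The per-sample detection threshold is their mean plus two
   standard deviations (SD with the n − 1 denominator; with fewer than
   two negative probes the SD is undefined and the stage errors out).
   The threshold is subtracted from endogenous and housekeeping-candidate
   counts, and any corrected value below 1 is set to 1. The floor at 1
   (rather than at 0) makes the subsequent log2 transform well defined
   and non-negative everywhere, and maps "at or below background" to
   exactly 0 on the log scale. A probe is *detected* in a sample iff its
   raw count strictly exceeds the threshold — consistent with the floor,
   which sends counts at the threshold to the floor value.
2. **RNA content.** geNorm ranks the candidate reference genes: the
   stability of gene j is `M_j = mean_k sd_s(log2 x_js / x_ks)`, the
   least stable gene is removed and M recomputed until two remain
   (ties at the maximal M are resolved by removing the lexicographically
   first probe ID, for determinism). The pairwise variation
   `V(n, n+1) = sd_s(log2 NF_n / NF_{n+1})`, with `NF_n` the geometric
   mean of the n most stable candidates, decides how many genes to use:
   starting from two, a gene is added while `V ≥ 0.15`; the first
   `V < 0.15` stops the inclusion (an `--n-ref-genes` override fixes the
   count instead). geNorm runs on background-corrected linear-scale
   values, before scaling, because stability is defined on expression
   levels and background is an additive artifact.
3. **Scaling.** Each sample is multiplied by
   `geomean_s(NF) / NF_s`, floored at 1 and log2-transformed. Reference
   genes therefore average out flat across samples, and within-sample
   rank order of endogenous probes is preserved (the transform is a
   single positive scalar per sample plus a monotone log).

Samples in which more than 50 % of endogenous probes are undetected are
removed after normalization (the rule is idempotent: exactly one pass
changes the kept set). Positive controls (a fixed 4-fold geometric
ladder of spiked targets) are summarized per probe (mean, CV) in the
run report as an assay-performance readout but take no part in
normalization, which relies only on negative controls and reference
genes.

Two conventions the underlying macro-style workflows leave open were
fixed here: sample (n − 1) SD for the background threshold, and a
single global geNorm selection across all samples.

## Co-expression network

Pearson correlations `r_ij` are computed across all kept samples;
genes with zero variance (possible after flooring) are excluded from
the network with a warning. The *signed* soft adjacency
`a_ij = ((1 + r_ij)/2)^β` maps r = −1 to 0 and r = +1 to 1, so
anti-correlated genes are unconnected; β = 8 is the default soft
threshold, and a scale-free fit index (log-log regression of binned
connectivity frequency, R² with the slope's sign reported alongside) is
computed as a diagnostic. Topological overlap

```
TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)
```

smooths the adjacency by shared neighbours; `1 − TOM` is the clustering
dissimilarity. Genes are clustered by average linkage and the
dendrogram is cut at a *static* height of 0.5; resulting groups with at
least 10 genes become modules, labelled 1..k by decreasing size, and
all other genes get the unassigned label 0. A static cut at the stated
height — not the dynamic hybrid tree cut that the reference R package
applies internally — is the deliberate design choice here: it is the
procedure as usually described, it is reproducible from two parameters,
and at ~200 genes it needs no block-wise machinery.

The module eigengene is the first left singular vector of the
samples × genes matrix of z-scored member expression: unit Euclidean
norm across samples, sign-aligned to correlate non-negatively with the
module's mean standardized expression, with the first singular value's
variance share reported. Adding a constant to a member gene leaves the
eigengene unchanged (z-scoring), and a single-gene module's eigengene
is its own standardized profile.

## Enrichment

Module gene lists are tested against user-supplied gene sets with the
exact hypergeometric upper tail `P(X ≥ k)` for an overlap of k between
a module of n genes and a term covering K of the N background genes.
The background is the panel itself (all ~201 genes), never the genome:
a targeted panel is already heavily enriched for immune and cancer
processes, and a genome background would declare that bias
"enrichment" in every module. Terms are intersected with the background
before testing; significance is raw p < 0.01 with no multiplicity
correction by default (an optional BH column exists), matching the
convention for small targeted panels. Annotations come from a GMT file
assumed to be pre-propagated (no ontology-graph closure is performed).

## Paired and contingency statistics

*Eigengene differences.* Per module, a two-sided paired t-test on
progression − baseline eigengene values over the matched pairs; the
family of module tests is corrected with Holm–Šidák
(`adj_(i) = 1 − (1 − p_(i))^(m−i+1)` with a running maximum).
All-identical differences are a degenerate error, not a p-value.

*Single genes.* Within the largest module, per-gene paired t-tests with
Benjamini–Hochberg FDR at q = 0.05.

*Sample structure.* Samples are clustered on row-wise z-scored
expression (Euclidean distance, average linkage — the distance and
linkage are this package's choice, configurable). The two-group cut
cross-tabulated over pairs feeds the exact McNemar test of whether
baseline and progression members land in different clusters; a pair
"clusters as neighbours" iff its two samples form a two-leaf clade, and
neighbour calls by treatment arm feed the chi-square test.

*Binary detection.* The exact binomial McNemar
(`p = min(1, 2·P(X ≤ min(b, c)))`, `X ~ Bin(b + c, ½)`, p = 1 when
b + c = 0) is the primary paired test for detection-status flips — with
discordant counts b = 10, c = 3 it gives p = 0.0923, reproducing the
printed value for the paired IFN-γ analysis; a chi-square approximation
is available behind a flag. Unpaired detection-by-timepoint tables use
Pearson chi-square *without* Yates continuity correction (the
correction is available behind `--yates` but off by default; the
uncorrected form reproduces the printed 2×2 p-values such as 0.0331 for
the neighbour-by-arm table). Note the exact McNemar is conservative at
n ≈ 29: its realized type-I rate under random labels is ≈ 3 %, not 5 %,
a property of exactness and discreteness rather than a defect.

## Synthetic data generator

The generator emulates the study conditions the pipeline assumes: 201
endogenous probes, 6 normalization candidates (2 unstable decoys with
3× residual noise), 8 negative and 6 positive controls, and 29
baseline/progression pairs (58 samples, arms split ≈ 18:11). Per planted
module m and sample s a latent factor `f_ms ~ N(0,1)` is drawn; module
1's factor is shifted by −δ in progression samples (δ = 0.8 by default,
in factor-SD units; δ = 0 makes timepoints exchangeable). Endogenous
log2 expression is `μ_g + λ_g f_{m(g),s} + scale_s + ε`, with baselines
μ_g uniform on [4, 12] log2 counts (so detection calls vary across the
panel), loadings λ_g uniform on [0.5, 0.9] for module genes and 0
otherwise, a per-sample content shift `scale_s ~ N(0, 0.3)` that gives
normalization real work, and residual noise ε with SD 0.15. Counts are
Poisson around `2^expression` — the simplest count model consistent
with digital counting; negative-binomial overdispersion would be a
config extension. One module-1 gene is parked 0.6 log2 units above the
expected background threshold with the maximum loading: its
detectability then tracks the immune factor, reproducing
detection-status flips at progression (the IFN-γ analogue).

The free noise parameters (noise_sd = 0.15, neg_control_rate = 8,
candidate baselines on [9, 12]) were fixed once, by the a-priori
requirement that the planted modules be recoverable by the fixed
analysis parameters (β = 8, static cut 0.5, minimum size 10): with
β = 8 a within-module TOM above 0.5 needs within-module correlations
around 0.85+, which bounds the tolerable residual and counting noise.
δ itself is a free simulation parameter — the emulated study reports no
effect size usable for calibration.

What the generator does *not* model: FFPE degradation, batch/cartridge
effects, arm-specific biology, negative-binomial overdispersion, and
correlated module factors. Passing recovery and calibration tests on
this generator therefore demonstrates the pipeline's correctness and
its statistical calibration under clean count noise, not performance on
degraded clinical material.

Synthetic annotations plant one term per module (80 % of the term from
the module, 20 % background) plus uniformly drawn decoy terms.

## Numerical conventions

- All SDs and z-scores use the n − 1 denominator.
- Hierarchical clustering runs on condensed distance matrices through
  scipy; equal-height merges follow scipy's deterministic ordering.
- The dendrogram cut keeps groups merged at height ≤ the cutoff.
- TOM denominators of zero (isolated pairs) give TOM = 0.
- The hypergeometric tail is evaluated as `sf(k − 1)`; k = 0 returns
  exactly 1.
- Eigengene sign ties (exactly zero correlation with the mean profile)
  keep the SVD's sign.
- All simulation randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical configs give bit-identical
  datasets and pipeline reports (the run report carries a config hash
  and a results hash to make this checkable).

## Problem sizes

The validation suites use the study-scale geometry throughout (201
genes × 58 samples): 20 seeds for module-recovery medians, 200
replicates for power at δ = 0.8, 1000–2000 replicates for type-I
calibration, and exhaustive enumeration oracles at desk scale (TOM
≤ 8×8, McNemar b + c ≤ 12, hypergeometric N ≤ 250).

## Known limitations

- The static 0.5 cut can split or shed weakly loaded module genes that
  a dynamic tree cut would capture; recovered module sizes are
  typically within a few genes of the planted ones, not exact.
- geNorm's final two candidates cannot be ranked against each other by
  M alone; the implementation orders them by their final-round M and
  then lexicographically.
- The scale-free fit index is a diagnostic only: a ~200-gene modular
  panel is far from a scale-free regime, and the index is reported, not
  optimized.
- With a single planted-module family the per-gene FDR stage sees
  strongly correlated tests; BH remains valid under positive dependence
  but q-values are conservative.
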
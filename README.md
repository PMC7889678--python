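# panelnet

Co-expression network analysis for paired, targeted expression panels.

`panelnet` is built for the kind of study in which a custom
hybridization-counting panel (~200 cancer- and immune-related genes,
NanoString-style, with spiked positive controls, orphan-probe negative
controls and a handful of housekeeping candidates) is measured on
patient-matched tumor biopsies taken before treatment and again at
progression, and the question is whether treatment shifts coordinated
gene *programs* rather than single genes. It provides, as one tested
pipeline:

- **Normalization** — per-sample background threshold from negative
  controls (mean + 2 SD), subtraction with a floor at 1, geNorm
  selection of reference genes from the candidate set (stability `M`,
  pairwise variation `V(n, n+1)` with a 0.15 cutoff), geometric-mean
  scaling, log2 transform, detection calls, and removal of samples with
  > 50 % undetected probes.
- **Signed weighted co-expression modules** — Pearson correlations
  across samples, signed soft adjacency `a_ij = ((1 + r_ij)/2)^β` with
  β = 8, topological overlap `TOM_ij = (L_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)`,
  average-linkage clustering on `1 − TOM` with a static height cut at
  0.5 and minimum module size 10, and a module eigengene (first
  principal component of the standardized module expression) per
  module, plus a scale-free topology fit index.
- **Over-representation analysis** — exact hypergeometric upper-tail
  tests of module genes against user-supplied gene sets (GMT), with the
  panel itself as the background universe and raw p < 0.01 significance.
- **Paired and contingency statistics** — paired t-tests on eigengenes
  (Holm–Šidák corrected) and on single genes (Benjamini–Hochberg FDR),
  sample clustering with two-group cuts, neighbour-pair calls on the
  dendrogram, Pearson chi-square without continuity correction, and the
  exact binomial McNemar test for paired binary outcomes such as
  per-sample detection of a low-abundance cytokine transcript (IFN-γ).
- **A synthetic-data generator** — paired count-scale datasets with
  planted co-expression modules driven by latent factors, an
  immune-module shift `δ` at progression, unstable housekeeping decoys,
  and a near-threshold IFN-γ analogue, so every stage is testable
  without any external download.

## Worked example

Simulate a default study (29 patient pairs, 201 endogenous genes, four
planted modules of 47/30/25/20 genes, immune-module shift δ = 0.8) and
run the whole pipeline:

```sh
panelnet simulate --out-dir demo --seed 1
panelnet run --counts demo/counts.tsv --metadata demo/samples.tsv \
    --gmt demo/gene_sets.gmt --out-dir demo_out --ifng-gene G184
```

which prints

```
4 modules {1: 45, 2: 28, 3: 25, 4: 20}; report -> demo_out/report.json
```

Four modules are recovered (the largest, 45 genes, is the planted
47-gene immune module minus two low-abundance genes whose counts sit in
the background noise). The report's eigengene tests show the immune
module — and only it — significantly reduced at progression:

| module | mean ME difference | t (df = 28) | p | Holm–Šidák p |
|---|---|---|---|---|
| 1 | −0.115 | −3.48 | 0.0017 | **0.0067** |
| 2 | +0.014 | 0.43 | 0.674 | 0.894 |
| 3 | −0.006 | −0.17 | 0.863 | 0.894 |
| 4 | +0.023 | 0.65 | 0.519 | 0.889 |

and the IFN-γ analogue's detection flips across the 29 pairs (10
positive→negative, 4 negative→positive) give an exact McNemar
p = 0.180. Contingency helpers are also available directly:

```sh
panelnet assoc --test mcnemar --b 10 --c 3
# exact McNemar: b = 10, c = 3, p = 0.09229
```

Every stage is also usable on its own (`panelnet normalize`,
`panelnet network`, `panelnet enrich`, `panelnet diff`,
`panelnet assoc`, `panelnet report`), and the whole pipeline is a
library call (`panelnet.run_pipeline(PipelineConfig(...))`).

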
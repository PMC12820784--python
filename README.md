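# cellcircuit

Spatial cell-circuit analysis for single-cell spatial transcriptomics:
discovery of multicellular niches from cell-neighborhood composition,
niche-constrained ligand–receptor communication networks, driver-ligand
prioritization, dual-cytokine synergy statistics, and signature-based
severity scoring. The package is aimed at computational biologists studying
inflamed tissue — the motivating system is the inflammation-associated
fibroblast (IAF) circuit in inflammatory bowel disease, where activated
macrophages signal to IL-11-expressing fibroblasts inside shared tissue
niches — but every stage is generic over cell types, genes and conditions.

Because the full patient-scale atlases such analyses are run on are not
shippable, the package includes a first-class synthetic-tissue generator
with planted ground truth (niche regions, a sender→receiver circuit with
distance-decaying target-gene induction, condition-dependent abundance
shifts, and a cohort whose ordinal severity is driven by a planted gene
signature), so every stage is testable end to end.

## Methods at a glance

- **Niche discovery.** For each cell, count the cells of each type within a
  radius *r* = 30 µm in the same sample (the focal cell included), giving a
  cells × types frequency matrix. Cluster rows with k-means over a range of
  *k* and select the *k* maximizing the silhouette score.
- **Niche enrichment.** χ² test of independence on the niches × types
  contingency table, d.f. = (N−1)(C−1); per-cell p-values from standardized
  residuals (obs−exp)/√(exp(1−row/n)(1−col/n)), Bonferroni corrected over
  all N·C cells.
- **Differential abundance.** Dirichlet-multinomial regression
  y<sub>s</sub> ~ DM(n<sub>s</sub>, α<sub>s</sub>) with
  log α<sub>sc</sub> = a<sub>c</sub> + β<sub>c</sub>x<sub>s</sub>, the
  reference category pinned at β = 0, a 0.001 pseudocount, per-category
  likelihood-ratio tests and BH correction at FDR < 20 %.
- **Communication.** An interaction (S, ligand, R, receptor) is *relevant*
  when both genes are expressed in > 5 % of their cells, *significant* when
  additionally the ligand is DE-up in the sender or the receptor DE-up in
  the receiver; its score is the product of the two min–max-scaled
  (within gene, across types) mean logTP10K expressions. Interactions are
  kept only when sender and receiver are co-enriched in at least one niche;
  edge weight = Σ significant scores.
- **Ligand prioritization.** TFs selected by marker expression and by
  activity difference (> 0.75 at p < 0.01) each vote for their top-10
  ligands in a regulatory-potential matrix; ligands with ≥ 5 votes and a
  cognate receptor expressed in > 5 % of target cells survive.
- **Synergy.** For baseline X and single-stimulus increments ΔA, ΔB:
  E_add = X+ΔA+ΔB and E_syn = X(1+ΔA/X)(1+ΔB/X) = E_add + ΔA·ΔB/X.
- **Severity scoring.** Single-sample rank-weighted running-sum enrichment
  (exponent α = 0.25) per subject, then ordered probit
  P(y = j) = Φ(τ<sub>j</sub>−βz) − Φ(τ<sub>j−1</sub>−βz) with a one-sided
  Wald test of β > 0 and Bonferroni-corrected per-gene refinement.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
import cellcircuit as cc
from cellcircuit.pipeline import RunConfig, run_pipeline

manifest = run_pipeline(RunConfig(seed=1, outdir="out"))
```

This simulates a four-sample, ~20,000-cell atlas (four planted niche zones,
an activated-macrophage → inflamed-fibroblast circuit) and runs every stage.
Selected outputs from this exact run:

`out/silhouette.tsv` — the silhouette trace peaks at the planted niche
count:

```
k   silhouette
2   0.404728
3   0.537322
4   0.573204   <- selected
5   0.520361
```

`out/network.tsv` — the planted circuit edge carries the maximal score
(both partner genes peak in their own type, so the scaled-mean product is
1), with decoy marker-gene pairs far below:

```
sender             receiver           weight     n_significant_interactions
macrophage_act     fibroblast_inflam  1.000000   1
fibroblast         smc                0.008067   1
...
```

`out/abundance.tsv` — the planted 3-fold disease expansion of inflamed
fibroblasts is the strongest credible effect (β = 0.35, q = 1.2e-11), and
the smooth-muscle reference has β ≡ 0.

`out/probit.json` — the cohort's ssGSEA scores predict ordinal severity
(β > 0, one-sided p ≈ 7.5e-69 at the planted effect size).

`out/proximity.tsv` — target-gene expression in receiver cells falls
monotonically with distance to the nearest sender cell.

The same stages are exposed on the command line (`circuit run`,
`circuit simulate`, `circuit niches`, `circuit abundance`,
`circuit communicate`, `circuit prioritize`, `circuit score`).

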
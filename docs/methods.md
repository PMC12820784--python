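# Methods

This note documents the models implemented in `cellcircuit`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices that matter for reproducibility.

## Neighborhood composition and niche discovery

A niche is a recurrent multicellular microenvironment: the cell-type
composition of each cell's neighborhood, clustered across all cells and
samples. The neighborhood of cell *i* is every cell *j* in the same sample
with Euclidean distance d(i,j) ≤ r; the predicate is closed and the focal
cell is included in its own neighborhood, so an isolated cell has a row sum
of 1 (this also makes the count contribution exactly symmetric: *i* counts
*j* iff *j* counts *i*). Distances never cross sample boundaries because
coordinates have arbitrary per-sample origins. The default radius is
r = 30 µm, a one-to-two cell-diameter horizon in which direct juxtacrine
and short-range paracrine contact is plausible.

Neighbor search uses a k-d tree per sample; correctness is defined by (and
tested against) the brute-force all-pairs oracle.

Rows are clustered as **raw counts** by default. Row-normalized proportions
are available (`proportions=True`), but raw counts are the default because
local density is itself biologically structured (dense mucosa vs sparse
muscularis) and normalizing it away merges niches that differ mainly in
packing. k-means runs with 10 restarts at a fixed seed; the silhouette score
is computed on a seeded uniform subsample capped at 10,000 rows because the
full statistic is O(n²) and stabilizes well below that size. k is selected
as the silhouette argmax over the requested range (default 5–35), with ties
going to the smallest k. All-identical composition rows are rejected as
degenerate rather than silently producing one cluster.

## Niche–cell-type enrichment

The niches × types contingency table is tested for independence with the
χ² statistic (d.f. = (N−1)(C−1)). Per-(niche, type) inference uses
*adjusted standardized residuals*

    z = (obs − exp) / sqrt(exp · (1 − row/n) · (1 − col/n)),

which are approximately standard normal under independence; two-sided
normal p-values are Bonferroni-corrected over all N·C cells and a cell is
flagged *enriched* only when the corrected p < 0.05 **and** the residual is
positive (depletion is reported but not flagged). Empty niches or types are
dropped with a warning and the d.f. recomputed. Under simulated
independence the flagged fraction stays below the nominal level (property
test, 200 tables).

## Differential abundance

Compositional counts are modelled with a Dirichlet-multinomial regression:

    y_s ~ DM(n_s, alpha_s),  log alpha_sc = a_c + beta_c * x_s,

with x the binary condition and the declared reference category's
beta pinned to 0, which anchors all effects as changes *relative to the
reference* and makes them identifiable. A pseudocount of 0.001 is added to
every count. Each non-reference category is tested with a likelihood-ratio
test of beta_c = 0 (χ²₁), BH-corrected; q < 0.20 flags a credible change.
Reported log2 fold changes are of fitted relative abundances (proportions),
and are labelled as such.

This is a deliberate maximum-likelihood stand-in for the Bayesian
spike-and-slab Dirichlet-multinomial formulation usual for this task: the
operative decision rule (FDR-thresholded credible changes against a stable
reference) is preserved without MCMC. Optimization is L-BFGS-B with
analytic gradients (ftol 1e-12, gtol 1e-8). When the data carry no
extra-multinomial dispersion the concentration is unbounded along a flat
ridge; intercepts are therefore capped (a_c ≤ 15) and flat-ridge
termination with a small gradient is accepted — beta estimates are stable
along the ridge. Only a binary condition (plus optional batch) is
supported; multi-level covariate structures are out of scope.

## Communication networks

Marker detection is a one-vs-rest Wilcoxon rank-sum test per (gene, type)
on logTP10K-normalized values (library size 10,000, log1p), with log2 fold
changes of (mean+1) ratios and BH adjustment within type. A stringent
specificity filter (p < 0.05, lfc > 3, foreground fraction > 25 %,
background fraction < 10 %) is available for cell-state marker panels.

The interaction score for (sender S, ligand L, receiver R, receptor C) is

    score = m̂_L(S) · m̂_C(R),

where m̂ is the gene's mean normalized expression min–max scaled across
cell types. The score is bounded in [0,1], monotone in both partners, and
equals 1 exactly when both genes peak in their respective types; summed
over significant interactions it weights the directed S→R network edge.
*Relevant* requires both expressing fractions > τ = 0.05; *significant*
additionally requires DE support (ligand up in S or receptor up in R).
Significance via DE support rather than a permutation null reflects a
DE-driven analysis design; a permutation mode could be added but is not the
default. The spatial constraint retains an interaction only when sender and
receiver are both flagged enriched in at least one common niche; types
missing from the enrichment table are conservatively retained nowhere (with
a warning). Raising τ can only remove interactions, and removing the niche
constraint can never decrease an edge weight (both property-tested).

Only single-subunit ligand–receptor pairs are supported; heteromeric
complexes are out of scope.

Proximity profiles bin each target cell's distance to the nearest
same-sample source cell with left-closed bins, default edges
(0, 30, 60, 100, 200, ∞) µm, reporting per-bin n, mean normalized
expression and expressing fraction.

## Ligand prioritization funnel

Two TF-selection routes: (1) expression — target-type marker genes
(rank-sum p < 0.05; this threshold is a config knob since only the route's
outcome is conventionally reported) intersected with a TF universe;
(2) activity — TFs whose mean activity difference over the background
exceeds 0.75 with rank-sum p < 0.01. The union feeds the vote: each TF
votes for its top-10 ligands by regulatory-potential score (ties broken
lexicographically by ligand label so votes are reproducible); ligands with
≥ 5 votes survive, then must have ≥ 1 cognate receptor expressed in > 5 %
of target cells. The funnel is monotone: enlarging the TF set can only
grow vote counts; raising `min_votes` can only shrink the shortlist.
TF-activity inference itself (regulon scoring) and regulatory-potential
model construction are inputs, not implemented here. Family-based
shortlist expansion is a user-supplied table join, not hard-coded biology.

## Synergy statistic

For baseline X > 0 and single-stimulus increments ΔA, ΔB ≥ −X:

    E_add = X + ΔA + ΔB
    E_syn = X · (1 + ΔA/X) · (1 + ΔB/X) = E_add + ΔA·ΔB/X

The identity E_syn − E_add = ΔA·ΔB/X holds to machine precision
(property-tested over random inputs), and either increment being zero
collapses the two expectations. Classification of an observed dual response
uses a relative tolerance band around E_add (default 10 %): below the band
sub-additive, inside additive, above super-additive/synergistic. The
tolerance is a package choice — the expectations are usually reported
without a formal decision rule — and is exposed as a parameter.

## Signature derivation and severity scoring

Effector genes = {down on regulator knockout, adjusted p < 0.05} ∩ {up on
activation, adjusted p < 0.05}; the core signature further intersects
regulator-bound genes and cell-type-specific genes, so refined ⊆ core ⊆
effector by construction.

Single-sample enrichment is the rank-weighted running-sum statistic: genes
ranked descending (rank N at the top), in-set genes contribute ECDF steps
weighted by rank^α (α = 0.25), out-of-set genes uniform steps, and the
score is the summed ECDF difference over all ranks. The running-sum (not
max-deviation) form and α = 0.25 follow the canonical single-sample
variant; both are exposed as parameters. The score is rank-based, hence
invariant under strictly monotone transforms, and the set occupying the top
|S| ranks is the exhaustive maximum over same-size sets (verified
exhaustively in tests).

Ordered probit: P(y = j) = Φ(τ_j − βz) − Φ(τ_{j−1} − βz). The cutpoints are
optimized as (τ₁, log-gaps) so monotonicity is structural; the predictor is
standardized internally for conditioning and estimates are returned on the
original scale. BFGS with gradient tolerance 1e-8; the standard error of β
comes from a finite-difference second derivative at the optimum; the
reported p is the one-sided Wald test of β > 0. A diverging coefficient
(|β_std| > 50) raises a perfect-separation error. Per-gene signature
refinement fits one ordered probit per core gene and keeps genes passing
Bonferroni (over the core set) at 0.05 with β > 0; with thresholds
disabled it returns the core unchanged.

Bulk-deconvolution marker selection applies exactly three thresholds:
p < 1e-8, average log fold change ≥ 0.75, expressed in < 20 % of background
cells. The deconvolution solver itself is out of scope.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (config, seed); one root seed drives a
hierarchical `SeedSequence` tree (per sample, per stage), so adding samples
never perturbs earlier ones.

**Tissue.** Cells are a homogeneous spatial Poisson process within
axis-aligned rectangular niche regions (simplest unambiguous geometry for
planted-label recovery); types are drawn from per-niche composition
vectors, reweighted per condition by multiplicative abundance effects.
Counts are negative-binomial (gamma–Poisson, shared dispersion 10) rather
than Poisson, matching the overdispersion of real UMI data. Each type has
three high-mean marker genes over a low background. The planted circuit
scales the target gene's mean in receiver cells by
1 + (max_induction − 1)·exp(−d/decay_length), d the distance to the nearest
sender in the sample. The default density of 50 cells per 10⁴ µm² puts
≈ 14–15 cells in a 30-µm neighborhood, a realistic epithelial/mucosal
packing. The default demo atlas is four quadrant niches over a
1 mm × 1 mm section (~5,000 cells/sample); a separate gradient preset
confines senders to a 200-µm strip so receiver cells populate every
distance bin of the proximity profile with enough cells per bin for stable
bin means.

Not emulated: realistic tissue morphology, segmentation errors, doublets,
batch effects, cross-sample coordinate systems, or nucleus- vs whole-cell
transcript assignment differences. Passing tests therefore demonstrate
correctness of the inference machinery under the stated generative
assumptions, not robustness to those artefacts.

**Funnel resources.** The regulatory-potential matrix gives decoy ligands
i.i.d. uniform (exchangeable) scores; planted ligands are forced above all
decoys in supported TF columns and below them elsewhere, so their top-10
membership is exact by construction. The default universe used in tests is
120 ligands × 8 TFs — at NicheNet-like ligand-universe scale the
probability that any exchangeable decoy collects ≥ 5 of 8 top-10 votes is
≈ 2 %, which is what makes the ≥ 5-vote rule selective; with only a few
dozen ligands the same rule would pass decoys often. TF activities are
N(0,1) with a planted mean shift (default 1.0) in target-type cells.

**Cohort.** Each subject has a latent signature level s ~ N(0,1);
signature-gene expression is shifted by s over N(0,1) noise; severity is
the ordinal bin of u = β_true·s + N(0,1) by fixed thresholds placed at
equal-mass quantiles of u's theoretical marginal, so categories are
balanced in expectation. Defaults: 200 subjects, 400 genes, 50 signature
genes, β_true = 2, 4 categories.

## Problem sizes and determinism

The test suite and the acceptance script run everything at desk scale:
~5,000-cell single-sample tissues for niche recovery, ~20,000 cells for the
end-to-end pipeline, 100–200 simulations for calibration checks, n = 500
cohorts for probit calibration. These sizes were chosen so that every
stochastic property check has adequate power while a full run stays in the
minutes range on one CPU. All randomness flows from explicit seeds; the
pipeline writes a manifest of SHA-256 output digests and identical
config + inputs reproduce identical digests.

## Known limitations

- The niche constraint needs the enrichment flags of the *same* label set
  used in scoring; mapping between differently-resolved cell-type
  vocabularies (e.g. a fine single-cell atlas vs a coarser spatial panel)
  must be supplied by the user as a relabelling, not inferred.
- The Dirichlet-multinomial LRT is asymptotic; with very few samples per
  group p-values are approximate (the FDR calibration test covers
  n = 20/group).
- ssGSEA scores are comparable within a cohort; the optional min–max
  normalization flags itself in the output name.
- The ordered probit reports Wald (not profile-likelihood) inference.
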
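# Methods

This note documents the model, its parameters, the numerical choices,
what the synthetic-data generator does and does not emulate, and the
known limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Network assembly

The analysis universe is the set of genes passing the DE filters
(`padj < 0.05` strictly, `|log2FC| > 0.58` strictly; the printed
inequality directions are taken literally, and 2^0.58 ≈ 1.5-fold).
Duplicate gene rows collapse to the smallest adjusted p. The
per-condition subnetwork is built **over the DE genes only**: PPI and TF
edges are restricted to pairs inside the universe, and the GO layer is
computed for those genes. This matches the published subnetwork sizes
(tens of nodes per condition) rather than whole-interactome propagation.

Three layers are combined with relative weights 1.0 (PPI), 0.5 (GO) and
1.5 (TF):

- **PPI** — STRING-style `combined_score ≥ 400`, rescaled to (0, 1] by
  /1000 so all layers share one scale; undirected, self-loops dropped,
  duplicate pairs keep the maximum score.
- **TF** — TRRUST-style directed edges with unit weight, deduplicated.
- **GO** — undirected edges between annotated gene pairs whose
  functional similarity strictly exceeds 0.3. Term similarity is the
  Wang semantic-contribution method with the standard factors 0.8
  (`is_a`) and 0.6 (`part_of`); term sets are combined with the
  best-match average (BMA). Both constants and the combination rule are
  package choices — the upstream description names only the method
  family.

The combined raw adjacency is `W_raw(i,j) = Σ_layer layer_weight ×
edge_weight` (undirected edges symmetric, TF source→target only). `W`
row-normalizes `W_raw`; nodes without out-weight receive a unit
self-loop, so `W` is row-stochastic for every input. Node order is
lexicographic and fixed before any matrix is built.

## Diffusion

The printed update is `x(t+1) = γ x(t) + (1−γ) W D x(t)`. Two readings
are possible depending on the orientation of `W`; this package applies
the **transpose of the row-stochastic matrix**, so influence mass flows
along edges (source → target) and total mass is conserved exactly when
`D = I` (the transpose of a row-stochastic matrix is column-stochastic).
Each step is renormalized to the previous total, so `Σᵢ xᵢ(t) = 1` at
every step even with amplification; with `D = I` the renormalization is
a no-op up to 1e-12. Defaults: retention `γ = 0.7`, horizon `T = 5`.

The amplifier is diagonal, `D_ii = 1 + outdeg_TF(i)/max_outdeg_TF`
(identity when there is no TF layer), applied before the propagation
step. A consequence worth stating: under renormalized transpose
dynamics the multiplier boosts the influence received by a factor's
**targets**; the factor's own share weakly decreases (simulation over
random ensembles shows this systematically). Amplified hubs still
dominate the final ranking through their centrality and the extra mass
circulating in their neighborhood — the property suite checks exactly
these two facts rather than a self-gain that the operator does not
produce.

The initial vector is
`raw_i = |log2FC_i| × min(−log10(padj_i + 1e-300), 50) × (0.5 + 0.5 w_i)`,
normalized to sum 1. The three ingredients are prescribed; the product
form, the cap at 50 (bounds padj ≈ 0), and the 0.5 floor (keeps
tissue-silent genes from being zeroed) are package choices. The tissue
weight is `w_i = max(0, tanh((e_i − median)/(IQR + 1e-9)))` over the
expression table: zero at or below the tissue median, saturating for
strongly above-median genes; genes absent from the table get 0.

## Functional metrics

- **CGES** — fraction of a gene's annotations in the cancer-relevant
  term list. The packaged default list holds 75 GO identifiers
  keyword-matched to cancer-hallmark processes; it is an explicit
  stand-in (the size is what matters for the metric's range) and is
  replaceable via a one-column file.
- **GDS** — mean annotation depth; depth is the **longest** path to a
  root (conservative specificity; a shortest-path mode is available via
  `RunConfig.depth_mode`).
- **CMI** — `tanh(θ₁ · w · CGES) + θ₂ · GDS/GDS_max` with `θ₁ = 2`,
  `θ₂ = 0.1`, bounded in [0, 1+θ₂] and monotone in each ingredient.
  θ₁ and θ₂ are prescribed; the saturating-product-plus-depth-bonus form
  is a package choice (the source describes the index three mutually
  inconsistent ways; the ingredient list with θ₁, θ₂ is the only
  recoverable definition). `GDS_max` is taken over the analysis gene
  set.

## Scoring

`raw_i = x_i(T) · CMI_i · ω₁ + ω₂ c_i` with `ω₁ = 0.8`, `ω₂ = 0.4`;
`c_i` is degree/(n−1) on the combined undirected view (TF edges counted
once, direction ignored). Scores are `log1p`-transformed (handles
raw = 0; base e) and scaled so the condition's top gene reads 100. Two
modes ship: per-condition (default) and reference-condition scaling, in
which all conditions divide by the reference maximum and non-reference
scores may exceed 100 — the only mode consistent with a nominally 0–100
scale publishing a 200.00 top score. Ranking ties break by smaller padj,
then gene symbol, so rankings are deterministic.

## Trajectory analytics

- **Clustering** — genes whose total trajectory mass has robust z
  (median/MAD) > 3.5 are set aside as outliers; remaining trajectories
  are normalized by their own maximum and k-means-clustered (50
  restarts, fixed seed) for k ∈ {2…6}; the k with maximal mean
  silhouette is kept. Outliers are labeled OUTLIER and assigned post hoc
  to the nearest centroid for reporting. Identical trajectories are
  reported as degenerate (k = min, silhouette undefined). The 3.5
  robust-z outlier rule is a package choice; the 2-SD rule is reserved
  for hierarchy disruption where it is prescribed.
- **SVI** — `(cv/cv_max) × (0.5 + 0.5 c)` with cv the coefficient of
  variation over x(0…T); multiplicative form keeps flat trajectories at
  0 regardless of centrality; bounded in [0, 1]. CVs below 1e-9 snap to
  0 (round-off on flat trajectories).
- **FH** — Shannon entropy (natural log) of functional-category
  frequencies over the closed 1-hop neighborhood, normalized by
  log(#categories present in the universe), times degree/|V|. The 1-hop
  reading of "network module" is a package choice (no community
  detection is described); isolated genes score 0. Default categories
  derive from each gene's lexicographically smallest depth-1 ontology
  ancestor.
- **Two-condition statistics** — 1-D Wasserstein distances via the
  quantile-function integral; the permutation p-value shuffles pooled
  labels, `p = (1 + #{permuted ≥ observed})/(1 + B)`, default
  B = 9999 (the null construction is a package choice). Gene-level
  hierarchy disruption flags shared genes whose FH difference deviates
  from the mean difference by more than two sample standard deviations
  (ddof = 1; sd = 0 ⇒ no genes flagged). SVI is compared with Welch's
  unequal-variance t. The 2×2 laterality tables use chi-square without
  continuity correction (Fisher's exact is available). No multiple-
  testing correction is applied across analytics by default; a BH
  utility is exposed.

## Synthetic data

The generator emulates all five external inputs with controllable
structure; every bundle parses cleanly through the readers and is
byte-identical for a given seed.

- **DE tables** — exactly `round(frac_significant × n)` rows pass the
  default thresholds. Significant |log2FC| is lognormal truncated at
  0.58 (the significance boundary); significant padj is
  10^−U(1.31, 20); non-significant rows draw padj from U(0.05, 1).
- **PPI** — Chung–Lu random graphs with configurable mean degree;
  target degrees can follow |log2FC| (`degree_effect_coupling`) and the
  significant genes can be boosted (`sig_degree_boost`) so the
  DE subnetwork reaches a chosen density.
- **TF** — Poisson out-degrees; targets drawn mostly from the
  significant set. A planted hub receives strictly maximal combined
  degree and strictly maximal TF out-degree.
- **Ontology/annotations** — a rooted `is_a` tree (depth 4, branching 3)
  plus a few validated cross links; each gene annotates 2–5 deep terms
  from one mid-level module subtree, which makes pairwise gene
  similarity strongly right-skewed (most pairs share only the upper
  hierarchy) as real GO similarity is.
- **Expression** — lognormal; optionally rank-coupled to effect size.

The default two-condition pairing instantiates the architectural
contrast the comparison statistics are designed to expose, with
densities mirroring the published subnetworks (sparse ~2-edges-per-gene
hierarchical side vs dense hub side):

- *hierarchical* (left): degree, significance, tissue expression and
  functional-module membership all track effect size; one low-out-degree
  TF. Network influence then scales with the initial perturbation.
- *hub-amplified* (right): compressed fold changes (lognormal
  μ = −0.2, σ = 0.25), dense uniform connectivity, eight amplified TFs
  and a planted hub with |log2FC| ≈ 0.7. Influence decouples from
  expression magnitude.

What the generator does **not** emulate: probe-level microarray noise,
empirical-Bayes moderation of the DE statistics, realistic GO term
co-annotation frequencies, or literature-biased interactome coverage.
Passing tests therefore demonstrate that the pipeline recovers planted
structure and reproduces the directional contrasts under clean
conditions; they do not certify performance on real cohorts, where
confounding between the layers is stronger and annotation is far
sparser.

## Problem sizes and determinism

Default scenarios use 120 genes per condition (30 significant), chosen
so a full two-condition fit takes well under a second and seed-ensemble
properties (50–100 replicates) run in seconds. All randomness flows
through explicit integer seeds (numpy `default_rng`); k-means restarts,
permutation tests and generators are all seeded, and the CLI records
every seed and parameter in its JSON manifest.

## Known limitations

- Exact published score tables are not reproducible without the exact
  interactome/ontology/expression snapshots and the unstated formula
  choices documented above; the package targets the printed worked
  examples and the directional phenomena instead.
- The GO layer is O(n²) in annotated genes per condition; fine for
  DE-sized universes, not intended for whole-genome similarity layers.
- Gene identifiers are case-sensitive symbols; no alias mapping is
  performed.
- The reported network "density" statistic of the source has no
  consistent definition for the printed counts and is not reproduced.
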
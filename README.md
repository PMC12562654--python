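# dynafic

Multi-layer network diffusion for gene prioritization in two-condition
transcriptomic designs (e.g. left- versus right-sided colorectal tumors).

Differential-expression analysis ranks genes by how much they change; it
says nothing about how those changes propagate through the molecular
networks the genes live in. `dynafic` takes a filtered DE table for each
condition plus three molecular-interaction layers — STRING-style
protein–protein interactions, TRRUST-style directed transcription-factor
regulation, and a Gene Ontology functional-similarity layer built with
the Wang method — and converts them into time-resolved influence
trajectories and composite per-gene scores, then compares the two
conditions with distributional and clustering statistics.

## The model

The per-condition subnetwork `G = (V, E)` is built over the significant
DE genes with edge set `E = E_PPI ∪ E_TF ∪ E_GO` (layer weights 1.0 /
1.5 / 0.5). Influence diffuses in discrete time,

```
x(t+1) ∝ γ x(t) + (1 − γ) Wᵀ D x(t),        γ = 0.7,  t = 0 … T = 5
```

where `W` is the row-stochastic combined adjacency (the transpose moves
influence along edges), `D` is a diagonal operator amplifying
transcription factors in proportion to their regulatory out-degree (up
to 2×), and each step is renormalized so total influence mass stays 1.
The initial vector `x(0)` combines each gene's |log2FC|, its capped
−log10 adjusted p, and a tanh-scaled tissue-expression weight.

Each gene is then summarized by

```
DynaFIC(i) = x_i(T) · CMI(i) · ω₁ + ω₂ c_i,     ω₁ = 0.8, ω₂ = 0.4
```

with `c_i` the normalized degree centrality and `CMI` (context
modulation index) a composite of tissue weight, cancer-GO enrichment
(CGES) and ontology depth (GDS): `CMI = tanh(θ₁ · w · CGES) +
θ₂ · GDS/GDS_max` with `θ₁ = 2, θ₂ = 0.1`. Scores are log1p-transformed
and rescaled to 0–100 (a reference-condition mode lets the other
condition exceed 100). Trajectory-level analytics add the
stability-volatility index (SVI: normalized trajectory CV × affine
centrality), functional heterogeneity (FH: neighborhood category
entropy × neighborhood fraction), outlier-resistant k-means clustering
of trajectories with silhouette selection of k, and two-condition
statistics (1-D Wasserstein with a permutation null, Welch's t on SVI,
hypergeometric tissue-context enrichment, PPI-only ablation agreement).

## Worked example

Every input format can be emulated by the synthetic-data module, which
generates a paired scenario: a *hierarchical* condition whose
connectivity, significance and tissue expression all track effect size,
and a *hub-amplified* condition — a denser network with a planted
high-degree regulatory hub carrying only a modest fold change.

```python
from dynafic import two_condition_scenario
from dynafic.model import DynaFIC, compare

paths = two_condition_scenario("demo", seed=1)

def fit(side):
    p = paths[side]
    return DynaFIC.from_files(p["de"], p["ppi"], p["tf"], p["obo"],
                              p["annotations"], p["expression"],
                              p["cancer_terms"], name=side).fit()

left, right = fit("left"), fit("right")
print(left.summary(5))
```

```
DynaFIC results [left]
==========================================================
genes scored:        30
network:             30 nodes, 95 edges (ppi 45, tf 1, go 49)
diffusion:           gamma=0.7, T=5
score weights:       omega1=0.8, omega2=0.4
expression-influence r: 0.826
----------------------------------------------------------
rank gene            score   log2FC       padj
   1 L0017          100.00    -5.10   1.00e-20
   2 S0003           46.24    -2.75   4.41e-20
   3 S0006           43.43    -1.35   1.43e-15
   4 L0022           42.16    -1.31   6.31e-15
   5 L0013           40.86    -1.13   1.23e-13
```

The top-ranked gene carries the largest fold change and the strongest
significance — in the hierarchical condition expression magnitude
predicts network influence (r = 0.826 here). Comparing the two sides:

```python
report = compare(left, right, permutations=999, seed=1, reference="left")
print(report.to_dict())
```

```
score_wasserstein    47.36     (permutation p = 0.001)
svi_welch_t          -2.34     (p = 0.023)
pearson_r            {'left': 0.826, 'right': -0.181}
svi_mean             {'left': 0.269, 'right': 0.392}
```

The hub-amplified condition shows the architectural signature the
framework is designed to expose: expression magnitude no longer
predicts influence (r ≈ −0.18; the planted hub ranks first with a
modest fold change), and its genes are systematically more volatile
(higher mean SVI, negative Welch t for hierarchical-minus-hub).

A command-line interface wraps the same pipeline:

```
dynafic simulate --two-condition --seed 7 --out sim/
dynafic score --de sim/left/de_table.csv --ppi sim/left/ppi_edges.tsv \
  --tf sim/left/tf_edges.tsv --obo sim/left/ontology.obo \
  --annotations sim/left/annotations.tsv --expression sim/left/expression.tsv \
  --out runs/left
dynafic compare --left runs/left --right runs/right --reference left \
  --out report.json
```

Every run writes a JSON manifest (config, input hashes, seed, design
flags); identical manifests reproduce identical outputs.

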
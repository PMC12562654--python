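"""The DynaFIC model / results objects.

:class:`DynaFIC` bundles one condition's inputs (filtered DE table plus
the molecular-interaction layers) and ``fit()`` runs the pipeline —
subnetwork assembly over the DE genes, GO-layer construction, regulatory
amplification, influence diffusion, functional metrics and composite
scoring — returning a :class:`DynaFICResults` that carries the per-gene
score table, the influence trajectory and diagnostics, with ``summary()``
and trajectory clustering / SVI / FH accessors.  :func:`compare` takes
two fitted results and produces the two-condition
:class:`~dynafic.dynamics.ComparisonReport`.
"""

from __future__ import annotations

import logging
from typing import Dict, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd

from . import dynamics as dyn
from .diffusion import (
    InfluenceTrajectory,
    amplification_operator,
    initial_influence,
    propagate,
    tissue_weight,
)
from .io import (
    DegenerateInputError,
    DERecord,
    EdgeRecord,
    OntologyDAG,
    RunConfig,
    read_annotations,
    read_de_table,
    read_expression,
    read_ontology,
    read_ppi_edges,
    read_tf_edges,
)
from .metrics import compute_profiles, read_cancer_terms
from .network import (
    LAYER_GO,
    LAYER_PPI,
    LAYER_TF,
    MultiLayerNetwork,
    integrate_layers,
    ppi_only_view,
)
from .scoring import degree_centrality, dynafic_raw, scale_scores, score_table
from .semsim import build_go_layer

logger = logging.getLogger("dynafic")


class DynaFIC:
    """Multi-layer diffusion model for one condition.

    Parameters
    ----------
    de : sequence of DERecord
        The (already threshold-filtered) differential-expression records;
        they define the analysis gene universe.
    ppi_edges, tf_edges : sequences of EdgeRecord
        Full-interactome edge lists; both are restricted to the DE gene
        universe before integration (the per-condition subnetwork).
    ontology, annotations, expression : optional
        Ontology DAG, gene->term map and tissue expression table; any may
        be omitted, degrading gracefully (no GO layer, zero functional
        metrics, zero tissue weights).
    config : RunConfig
        All tunable parameters.
    """

    def __init__(
        self,
        de: Sequence[DERecord],
        ppi_edges: Sequence[EdgeRecord] = (),
        tf_edges: Sequence[EdgeRecord] = (),
        ontology: Optional[OntologyDAG] = None,
        annotations: Optional[Mapping[str, Set[str]]] = None,
        expression: Optional[Mapping[str, float]] = None,
        cancer_terms: Optional[Set[str]] = None,
        config: Optional[RunConfig] = None,
        name: str = "condition",
    ):
        if not de:
            raise DegenerateInputError("empty DE table after filtering")
        self.de = list(de)
        self.genes = [r.gene for r in self.de]
        universe = set(self.genes)
        self.ppi_edges = [e for e in ppi_edges
                          if e.source in universe and e.target in universe]
        self.tf_edges = [e for e in tf_edges
                         if e.source in universe and e.target in universe]
        self.ontology = ontology
        self.annotations = dict(annotations or {})
        self.expression = dict(expression or {})
        self.cancer_terms = cancer_terms
        self.config = config or RunConfig()
        self.name = name

    @classmethod
    def from_files(
        cls,
        de_path,
        ppi_path=None,
        tf_path=None,
        obo_path=None,
        annotations_path=None,
        expression_path=None,
        cancer_terms_path=None,
        config: Optional[RunConfig] = None,
        name: str = "condition",
    ) -> "DynaFIC":
        """Build a model straight from the external file formats."""
        cfg = config or RunConfig()
        de = read_de_table(de_path, cfg.de_padj_max, cfg.de_abs_lfc_min)
        ppi = read_ppi_edges(ppi_path, cfg.ppi_min_score) if ppi_path else []
        tf = read_tf_edges(tf_path) if tf_path else []
        dag = read_ontology(obo_path) if obo_path else None
        ann = read_annotations(annotations_path, dag) if (annotations_path and dag) else {}
        expr = read_expression(expression_path) if expression_path else {}
        ct = read_cancer_terms(cancer_terms_path) if cancer_terms_path else None
        return cls(de, ppi, tf, dag, ann, expr, ct, cfg, name)

    def build_network(self, ppi_only: bool = False) -> MultiLayerNetwork:
        """Integrate the per-condition subnetwork over the DE gene universe."""
        cfg = self.config
        go = []
        if not ppi_only and self.ontology is not None and self.annotations:
            go = build_go_layer(
                self.genes, self.annotations, self.ontology,
                threshold=cfg.go_sim_threshold, contrib=cfg.wang_contrib,
            )
        tf = [] if ppi_only else self.tf_edges
        return integrate_layers(
            self.ppi_edges, tf, go,
            layer_weights=cfg.layer_weights, extra_nodes=self.genes,
        )

    def fit(self, ppi_only: bool = False) -> "DynaFICResults":
        """Run the full pipeline and return a results object."""
        cfg = self.config
        network = self.build_network(ppi_only=ppi_only)
        if self.expression:
            w = tissue_weight(self.expression)
        else:
            w = {}
        x0 = initial_influence(self.de, w)
        D = amplification_operator(network)
        trajectory = propagate(x0, network, D, cfg.gamma, cfg.T, params=cfg)
        profiles = compute_profiles(
            self.genes, self.annotations, self.ontology, w,
            cancer_terms=self.cancer_terms,
            theta1=cfg.theta1, theta2=cfg.theta2, depth_mode=cfg.depth_mode,
        )
        scores = score_table(
            self.de, network, trajectory, profiles,
            omega1=cfg.omega1, omega2=cfg.omega2,
        )
        return DynaFICResults(self, network, trajectory, scores, profiles, w)


class DynaFICResults:
    """Fitted results: per-gene score table, trajectory and diagnostics."""

    def __init__(self, model: DynaFIC, network: MultiLayerNetwork,
                 trajectory: InfluenceTrajectory, scores: pd.DataFrame,
                 profiles, tissue_weights: Dict[str, float]):
        self.model = model
        self.network = network
        self.trajectory = trajectory
        self.scores = scores
        self.profiles = profiles
        self.tissue_weights = tissue_weights

    @property
    def name(self) -> str:
        return self.model.name

    @property
    def genes(self):
        return list(self.scores["gene"])

    def raw_scores(self) -> Dict[str, float]:
        return dict(zip(self.scores["gene"], self.scores["dynafic_raw"]))

    def scaled_scores(self) -> Dict[str, float]:
        return dict(zip(self.scores["gene"], self.scores["dynafic_scaled"]))

    def centrality(self) -> Dict[str, float]:
        return degree_centrality(self.network)

    def svi(self) -> Dict[str, float]:
        """Stability-volatility index over the DE genes."""
        return dyn.svi_table(self.trajectory, self.centrality(),
                             genes=self.model.genes)

    def fh(self, category_map: Optional[Mapping[str, str]] = None) -> Dict[str, float]:
        """Functional heterogeneity over the DE genes; categories default
        to each gene's top-level ontology ancestor."""
        cats = dict(category_map) if category_map else self.default_categories()
        return dyn.fh_table(self.network, cats, genes=self.model.genes)

    def default_categories(self) -> Dict[str, str]:
        """Gene -> functional category from the lexicographically smallest
        depth-1 ontology ancestor of its annotations ('Other' if none)."""
        dag = self.model.ontology
        out: Dict[str, str] = {}
        for g in self.model.genes:
            cat = "Other"
            if dag is not None:
                terms = self.model.annotations.get(g, ())
                level1 = sorted(
                    a for t in terms for a in dag.ancestors(t) if dag.depth(a) == 1
                )
                if level1:
                    cat = level1[0]
            out[g] = cat
        return out

    def cluster(self, k_range=(2, 3, 4, 5, 6), seed: Optional[int] = None,
                outlier_z: float = 3.5) -> dyn.ClusterReport:
        """Outlier-resistant temporal clustering of the DE-gene trajectories."""
        return dyn.cluster_trajectories(
            self.trajectory, k_range=k_range,
            seed=self.model.config.seed if seed is None else seed,
            outlier_z=outlier_z, genes=self.model.genes,
        )

    def expression_influence_r(self) -> float:
        return dyn.expression_influence_correlation(
            np.abs(self.scores["log2fc"].to_numpy()),
            self.scores["dynafic_scaled"].to_numpy(),
        )

    def summary(self, top: int = 10) -> str:
        """Human-readable fit summary with the top-ranked genes."""
        cfg = self.model.config
        df = self.scores
        lines = [
            "DynaFIC results" + (f" [{self.name}]" if self.name else ""),
            "=" * 58,
            f"genes scored:        {len(df)}",
            f"network:             {self.network.n_nodes()} nodes, "
            f"{sum(len(v) for v in self.network.layers.values())} edges "
            f"(ppi {len(self.network.layers[LAYER_PPI])}, "
            f"tf {len(self.network.layers[LAYER_TF])}, "
            f"go {len(self.network.layers[LAYER_GO])})",
            f"diffusion:           gamma={cfg.gamma}, T={cfg.T}",
            f"score weights:       omega1={cfg.omega1}, omega2={cfg.omega2}",
            f"expression-influence r: {self.expression_influence_r():.3f}"
            if len(df) >= 3 and df["log2fc"].abs().std() > 0 else
            "expression-influence r: n/a",
            "-" * 58,
            f"{'rank':>4} {'gene':<12} {'score':>8} {'log2FC':>8} {'padj':>10}",
        ]
        for _, row in df.head(top).iterrows():
            lines.append(
                f"{int(row['rank']):>4} {row['gene']:<12} "
                f"{row['dynafic_scaled']:>8.2f} {row['log2fc']:>8.2f} "
                f"{row['padj']:>10.2e}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<DynaFICResults [{self.name}]: {len(self.scores)} genes, "
                f"{self.network.n_nodes()}-node network>")


def rescale(results: Mapping[str, DynaFICResults],
            reference: Optional[str] = None) -> Dict[str, Dict[str, float]]:
    """Re-scale several conditions' raw scores jointly (reference mode maps
    the reference condition's top gene to 100; others may exceed 100)."""
    raw = {name: r.raw_scores() for name, r in results.items()}
    return scale_scores(raw, reference=reference)


def compare(
    left: DynaFICResults,
    right: DynaFICResults,
    permutations: Optional[int] = None,
    seed: Optional[int] = None,
    reference: Optional[str] = None,
    category_map: Optional[Mapping[str, str]] = None,
    special_genes: Optional[Set[str]] = None,
) -> dyn.ComparisonReport:
    """Two-condition comparison of fitted results.

    Computes the Wasserstein shift (with permutation p) between the two
    scaled-score distributions, the FH hierarchy disruption and its
    2-SD gene outliers, Welch's t on the SVI distributions, per-condition
    expression-influence correlations, PPI-only ablation agreements and,
    when ``special_genes`` (e.g. tissue-specific genes) are given, the
    hypergeometric enrichment of those genes among the top-quartile
    context-modulation (CMI) genes.
    """
    if permutations is None:
        permutations = left.model.config.permutations
    if seed is None:
        seed = left.model.config.seed
    flags = []
    if reference in ("left", "right"):
        scaled = rescale({"left": left, "right": right}, reference=reference)
        left_scores = {g: scaled["left"][g] for g in left.genes}
        right_scores = {g: scaled["right"][g] for g in right.genes}
    else:
        left_scores = left.scaled_scores()
        right_scores = right.scaled_scores()
    w_dist, w_p = dyn.wasserstein_permutation_p(
        list(left_scores.values()), list(right_scores.values()),
        B=permutations, seed=seed,
    )
    fh_l = left.fh(category_map)
    fh_r = right.fh(category_map)
    fh_dist, disrupted = dyn.hierarchy_disruption(fh_l, fh_r)
    if not set(fh_l) & set(fh_r):
        flags.append("disjoint gene universes: gene-level disruption skipped")
    svi_l, svi_r = left.svi(), right.svi()
    t, p = dyn.welch_t(list(svi_l.values()), list(svi_r.values()))
    pearson = {}
    for name, res in (("left", left), ("right", right)):
        try:
            pearson[name] = res.expression_influence_r()
        except DegenerateInputError:
            pearson[name] = float("nan")
            flags.append(f"{name}: degenerate expression-influence correlation")
    ablation = {}
    for name, res in (("left", left), ("right", right)):
        ppi_res = res.model.fit(ppi_only=True)
        ablation[name] = dyn.ablation_compare(res.raw_scores(), ppi_res.raw_scores())
    enrichment_p = None
    if special_genes:
        cmi_all = {**{g: p_.cmi for g, p_ in left.profiles.items()},
                   **{g: p_.cmi for g, p_ in right.profiles.items()}}
        universe = set(cmi_all)
        q75 = np.quantile(list(cmi_all.values()), 0.75)
        selected = {g for g, v in cmi_all.items() if v >= q75}
        enrichment_p = dyn.hypergeom_enrichment(
            selected, set(special_genes) & universe, universe
        )
    return dyn.ComparisonReport(
        wasserstein=w_dist, wasserstein_p=w_p,
        fh_wasserstein=fh_dist, disrupted_genes=disrupted,
        welch_t=t, welch_p=p, pearson_r=pearson,
        enrichment_p=enrichment_p, ablation_spearman=ablation,
        svi_mean={"left": float(np.mean(list(svi_l.values()))),
                  "right": float(np.mean(list(svi_r.values())))},
        flags=flags,
    )
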
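"""Synthetic input bundles emulating the five external data sources.

Each scenario writes a complete, parseable file bundle — STRING-style PPI
edges, TRRUST-style directed TF edges, an OBO ontology, gene->term
annotations, a GTEx-style tissue expression table and a
confounder-adjusted-style DE table — with controllable statistical
structure: the fraction of significant genes, lognormal effect sizes,
log-uniform adjusted p-values for significant genes, an optional planted
network hub, and an optional coupling between effect size and network
degree (a "hierarchical" architecture where connectivity scales with
effect size).

The two-condition scenario pairs a hierarchical condition (scores track
effect sizes) against a hub-amplified condition (denser network with a
planted high-degree, high-out-degree TF hub carrying only a modest fold
change), emulating the architectural contrast between compartmentalized
and hub-dominated disease networks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .io import DynaficError

CATEGORIES = ("Transcription", "Metabolism", "Transport", "Structural", "Signaling", "Other")


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic condition."""

    n_genes: int = 120
    frac_significant: float = 0.25
    # network
    ppi_model: str = "erdos_renyi"          # or "scale_free"
    ppi_mean_degree: float = 4.0
    degree_effect_coupling: float = 0.0     # 0 = uniform, 1 = degree ~ |log2FC|
    sig_degree_boost: float = 1.0           # extra connectivity of the disease module
    n_tfs: int = 4
    tf_out_mean: float = 4.0
    planted_hub: Optional[str] = None
    # DE laws
    lfc_mu: float = 0.0                     # lognormal on |log2FC| of significant genes
    lfc_sigma: float = 0.5
    lfc_sign: int = 0                       # -1 left-up, +1 right-up, 0 random
    padj_exp_range: Tuple[float, float] = (1.31, 20.0)
    effect_significance_coupling: float = 0.0  # >0 ties padj exponent to |log2FC| rank
    # ontology / annotation / expression
    ontology_depth: int = 4
    ontology_branching: int = 3
    annotations_per_gene: Tuple[int, int] = (2, 5)
    cancer_term_frac: float = 0.2
    expr_mu: float = 2.0                    # lognormal tissue expression
    expr_sigma: float = 1.0
    expression_effect_coupling: float = 0.0  # >0 ties expression rank to |log2FC|
    annotation_effect_coupling: float = 0.0  # >0 groups functional modules by effect tier
    seed: int = 0
    gene_names: Optional[List[str]] = None  # override auto G#### naming

    def n_significant(self) -> int:
        return int(round(self.frac_significant * self.n_genes))


def _gene_names(spec: ScenarioSpec) -> List[str]:
    if spec.gene_names is not None:
        if len(spec.gene_names) != spec.n_genes:
            raise DynaficError("gene_names length must equal n_genes")
        return list(spec.gene_names)
    return [f"G{i:04d}" for i in range(spec.n_genes)]


def _de_table(spec: ScenarioSpec, genes: Sequence[str], rng: np.random.Generator):
    """Rows (gene, log2fc, pvalue, padj); exactly n_significant pass the
    default thresholds (padj < 0.05, |log2FC| > 0.58)."""
    k = spec.n_significant()
    order = rng.permutation(spec.n_genes)
    sig_idx = set(order[:k].tolist())
    if spec.planted_hub is not None and genes.index(spec.planted_hub) not in sig_idx:
        sig_idx.discard(order[k - 1]) if k else None
        sig_idx.add(genes.index(spec.planted_hub))
    lo, hi = spec.padj_exp_range
    rows = []
    abs_lfc = {}
    for i, g in enumerate(genes):
        if i in sig_idx:
            lfc = float(rng.lognormal(spec.lfc_mu, spec.lfc_sigma))
            while lfc <= 0.58:  # truncate the law at the significance boundary
                lfc = float(rng.lognormal(spec.lfc_mu, spec.lfc_sigma))
            if g == spec.planted_hub:
                lfc = 0.58 + float(rng.uniform(0.1, 0.2))  # modest hub effect
            abs_lfc[g] = lfc
        else:
            lfc = float(rng.lognormal(spec.lfc_mu - 1.0, spec.lfc_sigma))
            padj = float(rng.uniform(0.05, 1.0))
            sign = _sign(spec, rng)
            rows.append((g, sign * lfc, min(1.0, padj * float(rng.uniform(0.1, 1.0))), padj))
            continue
        rows.append((g, None, None, None))  # filled below once lfc ranks are known
    # significant padj: exponent log-uniform, optionally rank-coupled to |lfc|
    sig_genes = [genes[i] for i in sorted(sig_idx)]
    ranks = {g: r for r, g in enumerate(sorted(sig_genes, key=lambda g: abs_lfc[g]))}
    n_sig = max(len(sig_genes) - 1, 1)
    out = []
    for g, lfc, p, padj in rows:
        if lfc is not None:
            out.append((g, lfc, p, padj))
            continue
        u = float(rng.uniform(0.0, 1.0))
        c = spec.effect_significance_coupling
        pos = c * (ranks[g] / n_sig) + (1.0 - c) * u
        expo = lo + (hi - lo) * pos
        padj = 10.0 ** (-expo)
        while not padj < 0.05:
            padj = 10.0 ** (-float(rng.uniform(lo, hi)))
        sign = _sign(spec, rng)
        out.append((g, sign * abs_lfc[g], padj * float(rng.uniform(0.1, 1.0)), padj))
    return out, sig_genes


def _sign(spec: ScenarioSpec, rng: np.random.Generator) -> int:
    if spec.lfc_sign:
        return spec.lfc_sign
    return -1 if rng.uniform() < 0.5 else 1


def _ppi_edges(spec: ScenarioSpec, genes: Sequence[str], abs_lfc: Dict[str, float],
               sig_genes: Sequence[str],
               rng: np.random.Generator) -> Dict[Tuple[str, str], int]:
    """Chung-Lu style random graph; target degrees optionally follow |log2FC|
    and the significant genes (the disease module) can be boosted so the
    per-condition subnetwork reaches a chosen density."""
    n = spec.n_genes
    if spec.ppi_model == "scale_free":
        base = np.array([1.0 / (i + 1) ** 0.5 for i in range(n)])
        base = base[rng.permutation(n)]
    elif spec.ppi_model == "erdos_renyi":
        base = np.ones(n)
    else:
        raise DynaficError(f"unknown ppi_model {spec.ppi_model!r}")
    c = spec.degree_effect_coupling
    if c > 0:
        eff = np.array([abs_lfc.get(g, 0.3) for g in genes])
        eff = eff / eff.mean()
        base = base * (eff ** c)
    if spec.sig_degree_boost != 1.0:
        sig = set(sig_genes)
        base = base * np.array(
            [spec.sig_degree_boost if g in sig else 1.0 for g in genes])
    target = base / base.mean() * spec.ppi_mean_degree
    two_m = target.sum()
    edges: Dict[Tuple[str, str], int] = {}
    for i in range(n):
        for j in range(i + 1, n):
            p = min(1.0, target[i] * target[j] / two_m)
            if rng.uniform() < p:
                score = int(rng.integers(400, 1001))
                edges[(genes[i], genes[j])] = score
    return edges


def _plant_hub(spec: ScenarioSpec, genes: Sequence[str], sig_genes: Sequence[str],
               edges: Dict[Tuple[str, str], int], rng: np.random.Generator) -> None:
    hub = spec.planted_hub
    deg = {g: 0 for g in genes}
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    max_other = max((d for g, d in deg.items() if g != hub), default=0)
    # connect the hub to every significant gene first, then pad with others
    targets = [g for g in sig_genes if g != hub]
    targets += [g for g in genes if g != hub and g not in sig_genes]
    need = max_other + 1
    if need > len(genes) - 1:
        raise DynaficError("infeasible planted hub: required degree exceeds n-1")
    linked = 0
    for g in targets:
        key = (hub, g) if hub < g else (g, hub)
        if key not in edges:
            edges[key] = int(rng.integers(700, 1001))
        linked += 1
        if linked >= max(need, len(sig_genes)):
            current = sum(1 for k in edges if hub in k)
            others = {n: 0 for n in genes}
            for a, b in edges:
                others[a] += 1
                others[b] += 1
            if current > max(d for g2, d in others.items() if g2 != hub):
                break


def _tf_edges(spec: ScenarioSpec, genes: Sequence[str], sig_genes: Sequence[str],
              rng: np.random.Generator) -> List[Tuple[str, str]]:
    pool = [g for g in sig_genes if g != spec.planted_hub] or list(genes)
    n_tfs = min(spec.n_tfs, len(pool))
    tfs = list(rng.choice(pool, size=n_tfs, replace=False))
    edges: List[Tuple[str, str]] = []
    outdeg: Dict[str, int] = {}
    for tf in tfs:
        d = 1 + int(rng.poisson(max(spec.tf_out_mean - 1.0, 0.0)))
        # regulatory targets drawn mostly from the significant set
        cand = [g for g in sig_genes if g != tf] + [g for g in genes if g not in sig_genes]
        take = [c for c in cand[: max(d * 2, 4)]]
        picked = list(rng.choice(take, size=min(d, len(take)), replace=False))
        for t in picked:
            edges.append((tf, t))
        outdeg[tf] = len(picked)
    if spec.planted_hub is not None:
        hub = spec.planted_hub
        top = max(outdeg.values(), default=0)
        cand = [g for g in sig_genes if g != hub]
        d = min(top + 1 if top else 2, len(cand))
        for t in list(rng.choice(cand, size=d, replace=False)):
            edges.append((hub, t))
    return sorted(set(edges))


def _expression(spec: ScenarioSpec, genes: Sequence[str], sig_genes: Sequence[str],
                abs_lfc: Dict[str, float], rng: np.random.Generator) -> Dict[str, float]:
    """Lognormal tissue expression; optionally rank-coupled to effect size
    for the significant genes (hierarchical architectures express their
    large-effect genes highly in the target tissue)."""
    from scipy.special import ndtri

    c = spec.expression_effect_coupling
    n_sig = max(len(sig_genes) - 1, 1)
    ranks = {g: r for r, g in enumerate(sorted(sig_genes, key=lambda g: abs_lfc[g]))}
    out = {}
    for g in genes:
        z = float(rng.standard_normal())
        if c > 0 and g in ranks:
            z_rank = float(ndtri((ranks[g] + 0.5) / (n_sig + 1)))
            z = c * z_rank + math.sqrt(1.0 - c * c) * z
        out[g] = float(np.exp(spec.expr_mu + spec.expr_sigma * z))
    return out


def _ontology(spec: ScenarioSpec, rng: np.random.Generator):
    """Rooted is_a tree of the given depth/branching plus a few cross links.

    Returns ``(terms, extra, depth_of, children)`` where ``terms`` is a
    list of (term, tree parent) pairs in creation order.
    """
    terms = [("T0000", None)]
    depth_of = {"T0000": 0}
    children: Dict[str, List[str]] = {"T0000": []}
    level = ["T0000"]
    counter = 1
    for depth in range(1, spec.ontology_depth + 1):
        nxt = []
        for parent in level:
            for _ in range(spec.ontology_branching):
                t = f"T{counter:04d}"
                counter += 1
                terms.append((t, parent))
                depth_of[t] = depth
                children.setdefault(parent, []).append(t)
                children[t] = []
                nxt.append(t)
        level = nxt
    extra: Dict[str, Set[str]] = {}
    all_terms = [t for t, _ in terms]
    tree_parent = {t: p for t, p in terms}
    n_cross = max(1, len(all_terms) // 20)
    for _ in range(n_cross):
        child = all_terms[int(rng.integers(1, len(all_terms)))]
        parent = all_terms[int(rng.integers(0, len(all_terms)))]
        if parent != child and _no_cycle(tree_parent, extra, child, parent):
            extra.setdefault(child, set()).add(parent)
    return terms, extra, depth_of, children


def _subtree(term: str, children: Dict[str, List[str]]) -> List[str]:
    out, stack = [], [term]
    while stack:
        t = stack.pop()
        out.append(t)
        stack.extend(children.get(t, ()))
    return out


def _write_obo(path: Path, terms, extra) -> None:
    child_of = {t: p for t, p in terms}
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        for t, parent in terms:
            fh.write(f"\n[Term]\nid: {t}\nname: synthetic term {t}\n")
            if parent is not None:
                fh.write(f"is_a: {parent} ! parent\n")
            for p in sorted(extra.get(t, ())):
                if p != parent and _no_cycle(child_of, extra, t, p):
                    fh.write(f"is_a: {p} ! cross link\n")


def _no_cycle(tree_parent, extra, child, parent) -> bool:
    # adding child -> parent must not close a loop: no upward path from
    # parent back to child through tree or existing cross edges
    stack, seen = [parent], set()
    while stack:
        node = stack.pop()
        if node == child:
            return False
        if node in seen:
            continue
        seen.add(node)
        if tree_parent.get(node) is not None:
            stack.append(tree_parent[node])
        stack.extend(extra.get(node, ()))
    return True


def generate_scenario(spec: ScenarioSpec, out_dir) -> Dict[str, Path]:
    """Write one condition's complete input bundle; deterministic given the seed.

    Returns a mapping of logical names (``de``, ``ppi``, ``tf``, ``obo``,
    ``annotations``, ``expression``, ``cancer_terms``, ``categories``) to
    the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec)
    if spec.planted_hub is not None and spec.planted_hub not in genes:
        genes[0] = spec.planted_hub  # hub takes the first auto-named slot

    de_rows, sig_genes = _de_table(spec, genes, rng)
    abs_lfc = {g: abs(l) for g, l, _p, _q in de_rows}
    ppi = _ppi_edges(spec, genes, abs_lfc, sig_genes, rng)
    if spec.planted_hub is not None:
        _plant_hub(spec, genes, sig_genes, ppi, rng)
    tf = _tf_edges(spec, genes, sig_genes, rng)
    terms, extra, depth_of, children = _ontology(spec, rng)
    all_terms = [t for t, _ in terms]
    # Module-structured annotation: each gene draws its terms from the deep
    # descendants of one random mid-level term, so functional similarity is
    # high within modules and strongly right-skewed overall (most gene
    # pairs share little beyond the upper hierarchy).
    module_depth = min(2, spec.ontology_depth)
    modules = [t for t in all_terms if depth_of[t] == module_depth]
    lo_a, hi_a = spec.annotations_per_gene
    sig_rank = {g: r for r, g in enumerate(sorted(sig_genes, key=lambda g: abs_lfc[g]))}
    n_sig = max(len(sig_genes), 1)
    annotations = {}
    for g in genes:
        ca = spec.annotation_effect_coupling
        if ca > 0 and g in sig_rank and rng.uniform() < ca:
            # effect-coherent modules: genes of similar effect size share function
            module = modules[int(sig_rank[g] / n_sig * len(modules))]
        else:
            module = modules[int(rng.integers(0, len(modules)))]
        pool = [t for t in _subtree(module, children)
                if depth_of[t] >= module_depth + 2]
        pool = pool or [module]
        annotations[g] = sorted(set(
            rng.choice(pool, size=int(rng.integers(lo_a, hi_a + 1)), replace=True)
        ))
    n_cancer = max(1, int(round(spec.cancer_term_frac * len(all_terms))))
    cancer_terms = sorted(rng.choice(all_terms[1:], size=min(n_cancer, len(all_terms) - 1),
                                     replace=False))
    expression = _expression(spec, genes, sig_genes, abs_lfc, rng)
    categories = {g: CATEGORIES[int(rng.integers(0, len(CATEGORIES)))] for g in genes}

    paths = {k: out / v for k, v in {
        "de": "de_table.csv", "ppi": "ppi_edges.tsv", "tf": "tf_edges.tsv",
        "obo": "ontology.obo", "annotations": "annotations.tsv",
        "expression": "expression.tsv", "cancer_terms": "cancer_terms.txt",
        "categories": "categories.tsv",
    }.items()}
    with open(paths["de"], "w") as fh:
        fh.write("gene,log2fc,pvalue,padj\n")
        for g, lfc, p, q in de_rows:
            fh.write(f"{g},{lfc:.6g},{p:.6g},{q:.6g}\n")
    with open(paths["ppi"], "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for (a, b), s in sorted(ppi.items()):
            fh.write(f"{a}\t{b}\t{s}\n")
    with open(paths["tf"], "w") as fh:
        fh.write("TF\ttarget\tmode\trefs\n")
        for a, b in tf:
            fh.write(f"{a}\t{b}\tUnknown\tsynthetic\n")
    _write_obo(paths["obo"], terms, extra)
    with open(paths["annotations"], "w") as fh:
        fh.write("gene\tterm\n")
        for g in genes:
            for t in annotations[g]:
                fh.write(f"{g}\t{t}\n")
    with open(paths["expression"], "w") as fh:
        fh.write("gene\tmedian_tpm\n")
        for g in genes:
            fh.write(f"{g}\t{expression[g]:.6g}\n")
    with open(paths["cancer_terms"], "w") as fh:
        fh.write("# synthetic cancer-relevant term list\n")
        for t in cancer_terms:
            fh.write(t + "\n")
    with open(paths["categories"], "w") as fh:
        fh.write("gene\tcategory\n")
        for g in genes:
            fh.write(f"{g}\t{categories[g]}\n")
    return paths


def two_condition_scenario(
    out_dir,
    spec_left: Optional[ScenarioSpec] = None,
    spec_right: Optional[ScenarioSpec] = None,
    shared_gene_frac: float = 0.3,
    seed: int = 0,
) -> Dict[str, Dict[str, Path]]:
    """Paired left/right bundles with the hierarchical-vs-hub contrast.

    Left: sparse network whose connectivity and significance both track
    effect size (hierarchical; wide fold-change range, left-upregulated).
    Right: denser network with a planted hub of modest fold change
    (hub-amplified, right-upregulated).  ``shared_gene_frac`` of the
    significant genes carry the same symbols in both conditions.
    """
    if not (0.0 <= shared_gene_frac <= 1.0):
        raise DynaficError("shared_gene_frac outside [0, 1]")
    left = spec_left or hierarchical_spec(seed)
    right = spec_right or hub_spec(seed + 1)
    # shared symbols among the significant genes of both conditions
    n_shared = int(round(shared_gene_frac * min(left.n_significant(), right.n_significant())))
    left = replace(left, gene_names=_shared_names(left, "L", n_shared))
    hub_name = right.planted_hub or "HUB0"
    right = replace(right, gene_names=_shared_names(right, "R", n_shared, reserve=hub_name),
                    planted_hub=hub_name)
    out = Path(out_dir)
    return {
        "left": generate_scenario(left, out / "left"),
        "right": generate_scenario(right, out / "right"),
    }


def hierarchical_spec(seed: int = 0) -> ScenarioSpec:
    """Default left-side condition: hierarchical architecture.

    Connectivity, statistical significance and tissue expression all track
    effect size, and regulatory machinery is minimal, so network influence
    scales with the initial perturbation (scores proportional to fold
    change)."""
    return ScenarioSpec(
        n_genes=120, frac_significant=0.25, ppi_mean_degree=1.5,
        sig_degree_boost=2.0,
        degree_effect_coupling=2.0, effect_significance_coupling=1.0,
        expression_effect_coupling=0.9, annotation_effect_coupling=0.9,
        lfc_mu=0.1, lfc_sigma=0.6, lfc_sign=-1,
        n_tfs=1, tf_out_mean=1.0, seed=seed,
    )


def hub_spec(seed: int = 1) -> ScenarioSpec:
    """Default right-side condition: dense hub-amplified architecture.

    A compressed fold-change range, uniform dense connectivity and strong
    regulatory amplification around a planted hub decouple network
    influence from expression magnitude."""
    return ScenarioSpec(
        n_genes=120, frac_significant=0.25, ppi_mean_degree=8.0,
        sig_degree_boost=3.5,
        degree_effect_coupling=0.0, effect_significance_coupling=0.0,
        lfc_mu=-0.2, lfc_sigma=0.25, lfc_sign=1,
        n_tfs=8, tf_out_mean=10.0,
        planted_hub="HUB0", seed=seed,
    )


def _shared_names(spec: ScenarioSpec, prefix: str, n_shared: int,
                  reserve: Optional[str] = None) -> List[str]:
    """Gene names with the first ``n_shared`` significant slots shared.

    Significant slots are determined by the same permutation the DE
    generator will draw, so shared symbols land on significant genes.
    """
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(spec.n_genes)
    k = spec.n_significant()
    names = [f"{prefix}{i:04d}" for i in range(spec.n_genes)]
    for j, idx in enumerate(order[:n_shared]):
        names[idx] = f"S{j:04d}"
    if reserve is not None:
        # the hub takes a condition-specific significant slot
        for idx in order[n_shared:k]:
            if not names[idx].startswith("S"):
                names[idx] = reserve
                break
        else:
            names[order[k - 1] if k else 0] = reserve
    return names
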
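"""Ontology semantic similarity: Wang term similarity and best-match-average
gene functional similarity, plus construction of the GO edge layer.

The Wang method scores a term pair by the semantic contributions of their
shared ancestors.  For a term ``a``, every ancestor ``t`` carries an
S-value: ``S_a(a) = 1`` and ``S_a(t)`` is the maximum over children ``c``
of ``t`` lying on a path to ``a`` of ``contrib(relation) * S_a(c)``.
Similarity is ``sum over shared ancestors of (S_a + S_b)`` divided by
``SV(a) + SV(b)`` where ``SV`` sums a term's own S-values.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Optional, Set

from .io import EdgeRecord, FormatError, OntologyDAG, LAYER_GO

DEFAULT_CONTRIB = {"is_a": 0.8, "part_of": 0.6}


def s_values(term: str, dag: OntologyDAG, contrib: Mapping[str, float]) -> Dict[str, float]:
    """Wang S-values of every ancestor of ``term`` (including itself)."""
    if term not in dag:
        raise FormatError(f"unknown ontology term {term!r}")
    sv: Dict[str, float] = {term: 1.0}
    # Process ancestors in order of decreasing S-value so each node's final
    # value is fixed before its parents are relaxed (Dijkstra-style on the
    # max-product semiring; all contribution factors are in (0,1)).
    frontier = {term}
    while frontier:
        node = max(frontier, key=lambda n: sv[n])
        frontier.discard(node)
        for parent, rel in dag.parents[node]:
            cand = contrib[rel] * sv[node]
            if cand > sv.get(parent, 0.0):
                sv[parent] = cand
                frontier.add(parent)
    return sv


def wang_term_similarity(
    a: str,
    b: str,
    dag: OntologyDAG,
    contrib: Optional[Mapping[str, float]] = None,
) -> float:
    """Wang semantic similarity between two ontology terms, in [0, 1]."""
    contrib = {**DEFAULT_CONTRIB, **(contrib or {})}
    sa = s_values(a, dag, contrib)
    sb = s_values(b, dag, contrib)
    shared = set(sa) & set(sb)
    if not shared:
        return 0.0
    num = sum(sa[t] + sb[t] for t in shared)
    return min(1.0, num / (sum(sa.values()) + sum(sb.values())))


class _TermSimCache:
    """Memoizes S-value tables and pairwise term similarities for one DAG."""

    def __init__(self, dag: OntologyDAG, contrib: Mapping[str, float]):
        self.dag = dag
        self.contrib = {**DEFAULT_CONTRIB, **contrib}
        self._sv: Dict[str, Dict[str, float]] = {}
        self._sim: Dict[frozenset, float] = {}

    def sv(self, term: str) -> Dict[str, float]:
        if term not in self._sv:
            self._sv[term] = s_values(term, self.dag, self.contrib)
        return self._sv[term]

    def sim(self, a: str, b: str) -> float:
        key = frozenset((a, b))
        if key not in self._sim:
            sa, sb = self.sv(a), self.sv(b)
            shared = set(sa) & set(sb)
            if not shared:
                self._sim[key] = 0.0
            else:
                self._sim[key] = min(1.0, sum(sa[t] + sb[t] for t in shared) / (
                    sum(sa.values()) + sum(sb.values())
                ))
        return self._sim[key]


def gene_functional_similarity(
    g1: str,
    g2: str,
    annotations: Mapping[str, Set[str]],
    dag: OntologyDAG,
    contrib: Optional[Mapping[str, float]] = None,
    _cache: Optional[_TermSimCache] = None,
) -> Optional[float]:
    """Best-match-average functional similarity between two genes.

    Averages, over both genes, the mean best-counterpart term similarity
    (mean of row maxima and column maxima of the pairwise term-similarity
    matrix).  Returns ``None`` for unannotated genes, which are excluded
    from the GO layer.
    """
    t1 = annotations.get(g1)
    t2 = annotations.get(g2)
    if not t1 or not t2:
        return None
    cache = _cache or _TermSimCache(dag, contrib or DEFAULT_CONTRIB)
    t1 = sorted(t1)
    t2 = sorted(t2)
    matrix = [[cache.sim(a, b) for b in t2] for a in t1]
    row_max = [max(row) for row in matrix]
    col_max = [max(matrix[i][j] for i in range(len(t1))) for j in range(len(t2))]
    return (sum(row_max) + sum(col_max)) / (len(t1) + len(t2))


def build_go_layer(
    genes,
    annotations: Mapping[str, Set[str]],
    dag: OntologyDAG,
    threshold: float = 0.3,
    contrib: Optional[Mapping[str, float]] = None,
) -> List[EdgeRecord]:
    """Undirected GO-similarity edges among ``genes``.

    Connects every annotated gene pair whose best-match-average similarity
    strictly exceeds ``threshold``; the edge weight is the similarity.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    cache = _TermSimCache(dag, contrib or DEFAULT_CONTRIB)
    annotated = sorted(g for g in set(genes) if annotations.get(g))
    edges: List[EdgeRecord] = []
    for i, g1 in enumerate(annotated):
        for g2 in annotated[i + 1:]:
            sim = gene_functional_similarity(g1, g2, annotations, dag, _cache=cache)
            if sim is not None and sim > threshold:
                edges.append(EdgeRecord(g1, g2, LAYER_GO, sim, directed=False))
    return edges
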
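"""Readers and writers for the external formats consumed by the pipeline.

All downstream modules operate on the in-memory types defined here:
:class:`DERecord`, :class:`EdgeRecord`, :class:`OntologyDAG`, annotation
maps, expression tables and :class:`RunConfig`.  Parsers validate rather
than coerce: malformed numerics raise :class:`ParseError` with the
offending line number, missing columns raise :class:`FormatError` naming
the column.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace
from functools import lru_cache
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import obonet
import yaml

logger = logging.getLogger("dynafic")

LAYER_PPI = "ppi"
LAYER_TF = "tf"
LAYER_GO = "go"


class DynaficError(Exception):
    """Base class for all package errors."""


class FormatError(DynaficError):
    """A file does not conform to the expected layout (e.g. missing column)."""


class ParseError(DynaficError):
    """A cell could not be parsed (non-numeric, out of range, ...)."""


class DegenerateInputError(DynaficError):
    """Numerically unusable input (all-zero signal, singleton network, ...)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DERecord:
    """One gene's differential-expression statistics.

    Attributes
    ----------
    gene : str
        Gene symbol (case-sensitive, nonempty).
    log2fc : float
        Signed log2 fold change.
    pvalue, padj : float
        Raw and BH-adjusted p-values, both in [0, 1].
    """

    gene: str
    log2fc: float
    pvalue: float
    padj: float

    def __post_init__(self) -> None:
        if not self.gene:
            raise ParseError("empty gene symbol in DE record")
        for name in ("pvalue", "padj"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParseError(f"{name}={v!r} outside [0, 1] for gene {self.gene}")


@dataclass(frozen=True)
class EdgeRecord:
    """A typed edge in one of the network layers.

    Undirected layers (``ppi``, ``go``) are stored canonically with
    ``source < target``; the ``tf`` layer is directed.
    """

    source: str
    target: str
    layer: str
    weight: float
    directed: bool

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ParseError(
                f"non-positive edge weight {self.weight!r} ({self.source}-{self.target})"
            )
        if not self.directed and self.source > self.target:
            raise ParseError(
                f"undirected edge not canonically ordered: {self.source} > {self.target}"
            )


class OntologyDAG:
    """A rooted ontology DAG with ``is_a`` / ``part_of`` parent relations.

    Parameters
    ----------
    parents : mapping
        term -> set of ``(parent_term, relation)`` pairs.  Terms appearing
        only as parents are added automatically.

    Raises
    ------
    FormatError
        If the relation graph contains a cycle (one cycle is listed).
    """

    def __init__(self, parents: Mapping[str, Set[Tuple[str, str]]]):
        self.parents: Dict[str, Set[Tuple[str, str]]] = {t: set(p) for t, p in parents.items()}
        for t, rels in list(self.parents.items()):
            for parent, rel in rels:
                if rel not in ("is_a", "part_of"):
                    raise FormatError(f"unsupported relation {rel!r} on term {t}")
                self.parents.setdefault(parent, set())
        self.terms: Set[str] = set(self.parents)
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for t, rels in self.parents.items():
            for parent, _rel in rels:
                g.add_edge(t, parent)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise FormatError(f"ontology contains a cycle: {cycle}")
        self._graph = g
        self.roots: Set[str] = {t for t in self.terms if not self.parents[t]}
        self._depth: Dict[str, int] = {}

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def ancestors(self, term: str) -> Set[str]:
        """All ancestors of ``term`` including the term itself."""
        if term not in self.terms:
            raise FormatError(f"unknown ontology term {term!r}")
        return {term} | nx.descendants(self._graph, term)

    def depth(self, term: str, mode: str = "longest") -> int:
        """Hierarchy depth of ``term``: path length to a root (root = 0).

        ``mode='longest'`` (default) uses the longest path to any root,
        ``mode='shortest'`` the shortest.
        """
        if term not in self.terms:
            raise FormatError(f"unknown ontology term {term!r}")
        if mode == "longest":
            if term not in self._depth:
                self._fill_longest_depths()
            return self._depth[term]
        if mode == "shortest":
            return self._shortest_depth(term)
        raise ValueError(f"unknown depth mode {mode!r}")

    def _fill_longest_depths(self) -> None:
        for t in nx.topological_sort(self._graph.reverse(copy=False)):
            ps = self.parents[t]
            self._depth[t] = 0 if not ps else 1 + max(self._depth[p] for p, _ in ps)

    @lru_cache(maxsize=None)
    def _shortest_depth(self, term: str) -> int:
        ps = self.parents[term]
        if not ps:
            return 0
        return 1 + min(self._shortest_depth(p) for p, _ in ps)

    def max_depth(self, mode: str = "longest") -> int:
        return max((self.depth(t, mode) for t in self.terms), default=0)


@dataclass
class RunConfig:
    """All tunable parameters of the pipeline with their defaults.

    gamma is the per-step influence retention of the diffusion; T the
    number of diffusion steps; omega1/omega2 weight the modulated
    influence and the centrality terms of the final score; theta1/theta2
    scale the context-modulation index; layer_weights weight the three
    edge layers when the combined adjacency is assembled.
    """

    gamma: float = 0.7
    T: int = 5
    omega1: float = 0.8
    omega2: float = 0.4
    theta1: float = 2.0
    theta2: float = 0.1
    layer_weights: Dict[str, float] = field(
        default_factory=lambda: {LAYER_PPI: 1.0, LAYER_GO: 0.5, LAYER_TF: 1.5}
    )
    ppi_min_score: int = 400
    go_sim_threshold: float = 0.3
    de_padj_max: float = 0.05
    de_abs_lfc_min: float = 0.58
    seed: int = 0
    permutations: int = 9999
    wang_contrib: Dict[str, float] = field(
        default_factory=lambda: {"is_a": 0.8, "part_of": 0.6}
    )
    depth_mode: str = "longest"
    scaling_reference: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError(f"gamma={self.gamma} outside (0, 1]")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.omega1 < 0 or self.omega2 < 0:
            raise ValueError("omega1/omega2 must be >= 0")
        if not (0.0 <= self.go_sim_threshold <= 1.0):
            raise ValueError("go_sim_threshold outside [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls()
        merged = {}
        for key, value in raw.items():
            base = getattr(cfg, key)
            if isinstance(base, dict) and isinstance(value, dict):
                merged[key] = {**base, **value}
            else:
                merged[key] = value
        return replace(cfg, **merged)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


# ---------------------------------------------------------------------------
# Parsing helpers
# ---------------------------------------------------------------------------

def _sniff_delimiter(header_line: str) -> str:
    return "\t" if header_line.count("\t") >= header_line.count(",") else ","


def _to_float(cell: str, line_no: int, path) -> float:
    try:
        v = float(cell)
    except (TypeError, ValueError):
        raise ParseError(f"{path}:{line_no}: non-numeric cell {cell!r}") from None
    if math.isnan(v):
        raise ParseError(f"{path}:{line_no}: NaN cell")
    return v


def _read_delimited(path) -> Tuple[List[str], List[Tuple[int, List[str]]]]:
    """Return (header, [(line_no, cells), ...]) with delimiter auto-detection."""
    lines = Path(path).read_text().splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        return [], []
    delim = _sniff_delimiter(lines[0])
    header = [c.strip() for c in lines[0].split(delim)]
    rows = []
    for i, ln in enumerate(lines[1:], start=2):
        rows.append((i, [c.strip() for c in ln.split(delim)]))
    return header, rows


DE_ALIASES = {
    "gene": ("gene", "symbol", "gene_symbol", "genes"),
    "log2fc": ("log2fc", "logfc", "log2foldchange", "lfc"),
    "pvalue": ("pvalue", "p", "p.value", "pval", "p_value"),
    "padj": ("padj", "adj.p.val", "fdr", "qvalue", "p_adj", "adjusted_pvalue"),
}


def _resolve_columns(header: Sequence[str], aliases: Mapping[str, Sequence[str]], path) -> Dict[str, int]:
    lower = [h.lower() for h in header]
    out = {}
    for canonical, names in aliases.items():
        idx = next((lower.index(n) for n in names if n in lower), None)
        if idx is None:
            raise FormatError(f"{path}: missing required column {canonical!r}")
        out[canonical] = idx
    return out


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_de_table(
    path,
    padj_max: float = 0.05,
    abs_lfc_min: float = 0.58,
    aliases: Optional[Mapping[str, Sequence[str]]] = None,
) -> List[DERecord]:
    """Read a differential-expression table and apply significance filters.

    Keeps records with ``padj < padj_max`` and ``|log2fc| > abs_lfc_min``
    (both strict).  Duplicate gene symbols collapse to the record with the
    smallest adjusted p-value; otherwise row order is preserved.
    """
    header, rows = _read_delimited(path)
    if not header:
        raise FormatError(f"{path}: empty DE table")
    cols = _resolve_columns(header, aliases or DE_ALIASES, path)
    records: List[DERecord] = []
    by_gene: Dict[str, int] = {}
    n_collapsed = 0
    for line_no, cells in rows:
        if len(cells) <= max(cols.values()):
            raise FormatError(f"{path}:{line_no}: too few columns")
        rec = DERecord(
            gene=cells[cols["gene"]],
            log2fc=_to_float(cells[cols["log2fc"]], line_no, path),
            pvalue=_to_float(cells[cols["pvalue"]], line_no, path),
            padj=_to_float(cells[cols["padj"]], line_no, path),
        )
        if not (rec.padj < padj_max and abs(rec.log2fc) > abs_lfc_min):
            continue
        if rec.gene in by_gene:
            n_collapsed += 1
            if rec.padj < records[by_gene[rec.gene]].padj:
                records[by_gene[rec.gene]] = rec
        else:
            by_gene[rec.gene] = len(records)
            records.append(rec)
    if n_collapsed:
        logger.info("collapsed %d duplicate DE rows (kept smallest padj)", n_collapsed)
    return records


def read_ppi_edges(path, min_score: int = 400) -> List[EdgeRecord]:
    """Read a STRING-style PPI edge list (``combined_score`` on a 0-1000 scale).

    Rows with ``combined_score >= min_score`` are kept; weights are the
    scores divided by 1000, self-loops dropped, duplicate pairs keep the
    maximum weight, edges stored canonically undirected.
    """
    header, rows = _read_delimited(path)
    if not header:
        return []
    cols = _resolve_columns(
        header,
        {"protein1": ("protein1", "source"), "protein2": ("protein2", "target"),
         "combined_score": ("combined_score", "score")},
        path,
    )
    best: Dict[Tuple[str, str], float] = {}
    for line_no, cells in rows:
        score = _to_float(cells[cols["combined_score"]], line_no, path)
        if not (0 <= score <= 1000):
            raise ParseError(f"{path}:{line_no}: combined_score {score} outside [0, 1000]")
        a, b = cells[cols["protein1"]], cells[cols["protein2"]]
        if a == b or score < min_score:
            continue
        key = (a, b) if a < b else (b, a)
        w = score / 1000.0
        if w > best.get(key, 0.0):
            best[key] = w
    return [
        EdgeRecord(s, t, LAYER_PPI, w, directed=False)
        for (s, t), w in sorted(best.items())
    ]


def read_tf_edges(path) -> List[EdgeRecord]:
    """Read a TRRUST-style directed TF->target edge list (weight fixed at 1)."""
    header, rows = _read_delimited(path)
    if not header:
        logger.warning("%s: empty TF edge file", path)
        return []
    cols = _resolve_columns(header, {"tf": ("tf", "source"), "target": ("target", "gene")}, path)
    seen: Set[Tuple[str, str]] = set()
    edges: List[EdgeRecord] = []
    for _line_no, cells in rows:
        tf, target = cells[cols["tf"]], cells[cols["target"]]
        if tf == target or (tf, target) in seen:
            continue
        seen.add((tf, target))
        edges.append(EdgeRecord(tf, target, LAYER_TF, 1.0, directed=True))
    if not edges:
        logger.warning("%s: no TF edges parsed", path)
    return edges


def read_ontology(path) -> OntologyDAG:
    """Read an OBO file (``is_a`` and ``relationship: part_of`` only)."""
    graph = obonet.read_obo(path, ignore_obsolete=True)
    parents: Dict[str, Set[Tuple[str, str]]] = {t: set() for t in graph.nodes}
    for child, parent, rel in graph.edges(keys=True):
        if rel in ("is_a", "part_of"):
            parents.setdefault(child, set()).add((parent, rel))
            parents.setdefault(parent, set())
    return OntologyDAG(parents)


def read_annotations(path, dag: OntologyDAG) -> Dict[str, Set[str]]:
    """Read a two-column gene<TAB>term annotation map validated against ``dag``.

    Terms absent from the DAG are dropped (count logged); genes left with
    no valid terms are omitted entirely.
    """
    header, rows = _read_delimited(path)
    if not header:
        return {}
    out: Dict[str, Set[str]] = {}
    n_dropped = 0
    for line_no, cells in rows:
        if len(cells) < 2:
            raise FormatError(f"{path}:{line_no}: expected two columns")
        gene, term = cells[0], cells[1]
        if term not in dag:
            n_dropped += 1
            continue
        out.setdefault(gene, set()).add(term)
    if n_dropped:
        logger.warning("%s: dropped %d annotations with unknown terms", path, n_dropped)
    return out


def read_expression(path) -> Dict[str, float]:
    """Read a two-column gene<TAB>median-expression table (values >= 0)."""
    header, rows = _read_delimited(path)
    if not header:
        return {}
    out: Dict[str, float] = {}
    for line_no, cells in rows:
        if len(cells) < 2:
            raise FormatError(f"{path}:{line_no}: expected two columns")
        v = _to_float(cells[1], line_no, path)
        if v < 0:
            raise ParseError(f"{path}:{line_no}: negative expression {v}")
        out[cells[0]] = v
    return out


# ---------------------------------------------------------------------------
# Edge list round trip (internal TSV dialect)
# ---------------------------------------------------------------------------

def write_edges(path, edges: Iterable[EdgeRecord]) -> None:
    """Write edges as a TSV with columns source/target/layer/weight/directed."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tlayer\tweight\tdirected\n")
        for e in edges:
            fh.write(f"{e.source}\t{e.target}\t{e.layer}\t{e.weight:.10g}\t{int(e.directed)}\n")


def read_edges(path) -> List[EdgeRecord]:
    """Read the internal edge-list TSV written by :func:`write_edges`."""
    header, rows = _read_delimited(path)
    if header != ["source", "target", "layer", "weight", "directed"]:
        raise FormatError(f"{path}: not an internal edge-list TSV")
    out = []
    for line_no, cells in rows:
        out.append(
            EdgeRecord(cells[0], cells[1], cells[2],
                       _to_float(cells[3], line_no, path), bool(int(cells[4])))
        )
    return out
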
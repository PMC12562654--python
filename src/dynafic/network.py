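"""Multi-layer network assembly and the normalized propagation matrix.

The integrated network combines three typed edge layers — PPI (undirected,
STRING-confidence weights), TF (directed regulatory edges) and GO
(undirected functional-similarity edges) — into a single weighted
adjacency.  Layer weights default to 1.0 (ppi), 0.5 (go) and 1.5 (tf).
Undirected edges contribute symmetrically; TF edges only source->target.
The propagation matrix W row-normalizes the combined adjacency, with a
unit self-loop on any node without outgoing weight, so W is always
row-stochastic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .io import (
    DegenerateInputError,
    EdgeRecord,
    LAYER_GO,
    LAYER_PPI,
    LAYER_TF,
)

DEFAULT_LAYER_WEIGHTS = {LAYER_PPI: 1.0, LAYER_GO: 0.5, LAYER_TF: 1.5}


@dataclass
class MultiLayerNetwork:
    """The integrated network: node order, layers, combined and normalized matrices.

    ``combined`` holds the raw directed weight matrix
    ``W_raw[i, j] = sum_layer layer_weight * edge_weight`` (undirected
    edges filled symmetrically).  ``W`` is the row-stochastic propagation
    matrix.  ``tf_outdeg`` maps each gene to its out-degree in the TF layer.
    """

    nodes: List[str]
    layers: Dict[str, List[EdgeRecord]]
    combined: np.ndarray
    W: np.ndarray
    tf_outdeg: Dict[str, int]
    layer_weights: Dict[str, float]

    @property
    def index(self) -> Dict[str, int]:
        return {g: i for i, g in enumerate(self.nodes)}

    def n_nodes(self) -> int:
        return len(self.nodes)

    def undirected_neighbors(self, gene: str) -> Set[str]:
        """Distinct neighbors of ``gene`` on the combined undirected view."""
        i = self.index[gene]
        mask = (self.combined[i, :] > 0) | (self.combined[:, i] > 0)
        mask[i] = False
        return {self.nodes[j] for j in np.nonzero(mask)[0]}


def integrate_layers(
    ppi: Sequence[EdgeRecord],
    tf: Sequence[EdgeRecord],
    go: Sequence[EdgeRecord],
    layer_weights: Optional[Mapping[str, float]] = None,
    extra_nodes: Iterable[str] = (),
) -> MultiLayerNetwork:
    """Combine the three edge layers into a :class:`MultiLayerNetwork`.

    The node set is the union of all edge endpoints plus ``extra_nodes``
    (genes that must remain scoreable even when isolated), ordered
    lexicographically.  Raises :class:`DegenerateInputError` on an empty
    union.
    """
    lw = dict(DEFAULT_LAYER_WEIGHTS)
    if layer_weights:
        lw.update(layer_weights)
    layers = {LAYER_PPI: list(ppi), LAYER_TF: list(tf), LAYER_GO: list(go)}
    node_set: Set[str] = set(extra_nodes)
    for edges in layers.values():
        for e in edges:
            node_set.add(e.source)
            node_set.add(e.target)
    if not node_set:
        raise DegenerateInputError("empty node union: no edges and no extra nodes")
    nodes = sorted(node_set)
    idx = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    combined = np.zeros((n, n))
    for layer, edges in layers.items():
        w_layer = lw[layer]
        for e in edges:
            i, j = idx[e.source], idx[e.target]
            combined[i, j] += w_layer * e.weight
            if not e.directed:
                combined[j, i] += w_layer * e.weight
    W = row_normalize(combined)
    tf_outdeg: Dict[str, int] = {}
    for e in layers[LAYER_TF]:
        tf_outdeg[e.source] = tf_outdeg.get(e.source, 0) + 1
    return MultiLayerNetwork(nodes, layers, combined, W, tf_outdeg, lw)


def row_normalize(combined: np.ndarray) -> np.ndarray:
    """Row-normalize a nonnegative matrix; zero rows get a unit self-loop."""
    W = combined.astype(float).copy()
    sums = W.sum(axis=1)
    zero = sums == 0
    W[zero, np.nonzero(zero)[0]] = 1.0
    sums[zero] = 1.0
    return W / sums[:, None]


def edge_metric_correlations(
    network: MultiLayerNetwork,
    annotations=None,
    dag=None,
) -> Tuple[np.ndarray, List[str], bool]:
    """Pearson correlations among per-pair PPI weight, GO similarity and
    TF regulatory strength.

    Gene pairs are the union of unordered pairs touched by any layer;
    a pair's value in a layer it does not appear in is 0 (TF strength is
    the maximum over the two directions).  Returns ``(R, metric_names,
    degenerate)`` where ``degenerate`` flags any zero-variance metric.
    Raises :class:`DegenerateInputError` with fewer than 3 pairs.
    """
    per_layer: Dict[str, Dict[Tuple[str, str], float]] = {
        LAYER_PPI: {}, LAYER_GO: {}, LAYER_TF: {}
    }
    for layer, edges in network.layers.items():
        for e in edges:
            key = tuple(sorted((e.source, e.target)))
            per_layer[layer][key] = max(per_layer[layer].get(key, 0.0), e.weight)
    pairs = sorted(set().union(*[set(d) for d in per_layer.values()]))
    if len(pairs) < 3:
        raise DegenerateInputError(f"need >= 3 gene pairs, got {len(pairs)}")
    names = [LAYER_PPI, LAYER_GO, LAYER_TF]
    X = np.array([[per_layer[m].get(p, 0.0) for p in pairs] for m in names])
    degenerate = bool(np.any(X.std(axis=1) == 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)
    np.fill_diagonal(R, 1.0)
    off = R[~np.eye(3, dtype=bool)]
    if np.any(np.abs(off[np.isfinite(off)]) >= 1.0 - 1e-12):
        degenerate = True
    return R, names, degenerate


def ppi_only_view(network: MultiLayerNetwork) -> MultiLayerNetwork:
    """Ablated copy keeping only the PPI layer (same node universe)."""
    return integrate_layers(
        network.layers[LAYER_PPI], [], [],
        layer_weights=network.layer_weights,
        extra_nodes=network.nodes,
    )
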
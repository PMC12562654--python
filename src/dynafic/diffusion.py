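"""Discrete-time influence diffusion with regulatory amplification.

The update per step is

    x(t+1)  ∝  gamma * x(t) + (1 - gamma) * W^T (D x(t))

where W is the row-stochastic combined adjacency (the transpose moves
influence mass along edges, source -> target), D is a diagonal operator
amplifying transcription factors in proportion to their TF-layer
out-degree, and each step is renormalized so the total influence mass is
conserved (with D = I the renormalization is a no-op up to round-off,
because W^T of a row-stochastic matrix is column-stochastic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence

import numpy as np

from .io import DegenerateInputError, DERecord, RunConfig
from .network import MultiLayerNetwork

logger = logging.getLogger("dynafic")

PADJ_FLOOR = 1e-300
NEGLOG10_CAP = 50.0


@dataclass
class AmplificationOperator:
    """Diagonal regulatory-amplification multipliers, 1 for non-TFs, up to 2
    for the transcription factor with the largest out-degree."""

    diag: Dict[str, float]

    def vector(self, nodes: Sequence[str]) -> np.ndarray:
        return np.array([self.diag.get(g, 1.0) for g in nodes])


@dataclass
class InfluenceTrajectory:
    """Gene-by-time matrix of diffused influence, X[:, t] = x(t)."""

    genes: List[str]
    X: np.ndarray  # shape (n_genes, T+1)
    params: RunConfig

    def row(self, gene: str) -> np.ndarray:
        return self.X[self.genes.index(gene), :]

    @property
    def T(self) -> int:
        return self.X.shape[1] - 1

    def final(self) -> Dict[str, float]:
        return dict(zip(self.genes, self.X[:, -1]))


def tissue_weight(expression: Mapping[str, float]) -> Dict[str, float]:
    """Tissue-specificity weights from median expression.

    w_i = max(0, tanh((e_i - median) / (IQR + 1e-9))) — zero at or below
    the tissue median, saturating toward 1 for strongly above-median
    genes.  Genes absent from the table get weight 0.
    """
    if len(expression) < 2:
        raise DegenerateInputError("need >= 2 genes with expression values")
    vals = np.array(list(expression.values()), dtype=float)
    med = float(np.median(vals))
    q75, q25 = np.percentile(vals, [75, 25])
    iqr = float(q75 - q25)
    if iqr == 0:
        logger.warning("all-equal expression values: all tissue weights are 0")
    return {
        g: float(max(0.0, np.tanh((e - med) / (iqr + 1e-9))))
        for g, e in expression.items()
    }


def initial_influence(
    de: Sequence[DERecord], w: Mapping[str, float]
) -> Dict[str, float]:
    """Initial influence vector x(0), normalized to sum 1.

    Each gene's raw influence is the product of its fold-change magnitude,
    its capped significance -log10(padj), and an affine-shifted tissue
    weight (0.5 + 0.5 w) so tissue-silent genes keep half weight.
    """
    if not de:
        raise DegenerateInputError("empty DE table")
    raw = {}
    for rec in de:
        sig = min(-np.log10(rec.padj + PADJ_FLOOR), NEGLOG10_CAP)
        raw[rec.gene] = abs(rec.log2fc) * sig * (0.5 + 0.5 * w.get(rec.gene, 0.0))
    total = sum(raw.values())
    if total <= 0:
        raise DegenerateInputError("no usable signal: all initial influences are 0")
    return {g: v / total for g, v in raw.items()}


def amplification_operator(network: MultiLayerNetwork) -> AmplificationOperator:
    """Build D: diag_i = 1 + outdeg_tf(i) / max_outdeg_tf (identity if no TF layer)."""
    outdeg = network.tf_outdeg
    if not outdeg:
        return AmplificationOperator({})
    max_out = max(outdeg.values())
    return AmplificationOperator({g: 1.0 + d / max_out for g, d in outdeg.items()})


def propagate(
    x0: Mapping[str, float],
    network: MultiLayerNetwork,
    D: AmplificationOperator,
    gamma: float,
    T: int,
    params: RunConfig | None = None,
) -> InfluenceTrajectory:
    """Iterate the diffusion update for T steps, recording all T+1 vectors."""
    if not (0.0 < gamma <= 1.0):
        raise ValueError(f"gamma={gamma} outside (0, 1]")
    if T < 1:
        raise ValueError("T must be >= 1")
    nodes = network.nodes
    unknown = set(x0) - set(nodes)
    if unknown:
        raise DegenerateInputError(
            f"initial-influence genes missing from network: {sorted(unknown)[:5]}"
        )
    x = np.array([x0.get(g, 0.0) for g in nodes], dtype=float)
    d = D.vector(nodes)
    WT = network.W.T
    X = np.empty((len(nodes), T + 1))
    X[:, 0] = x
    for t in range(T):
        y = gamma * x + (1.0 - gamma) * (WT @ (d * x))
        total = y.sum()
        if total <= 0:
            raise DegenerateInputError("influence mass vanished during diffusion")
        x = y * (x.sum() / total)
        X[:, t + 1] = x
    return InfluenceTrajectory(list(nodes), X, params or RunConfig(gamma=gamma, T=T))
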
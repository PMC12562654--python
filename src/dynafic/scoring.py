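"""Final composite gene scoring.

The raw score combines the final-step diffused influence, the
context-modulation index and normalized degree centrality:

    score_i = x_i(T) * CMI_i * omega1 + omega2 * c_i

Raw scores are then log1p-transformed and rescaled so the top gene of a
condition (or of a designated reference condition, in which case other
conditions may exceed 100) maps to 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import DegenerateInputError, DERecord
from .metrics import GeneFunctionalProfile
from .network import MultiLayerNetwork
from .diffusion import InfluenceTrajectory


@dataclass(frozen=True)
class GeneMetrics:
    gene: str
    x_T: float
    centrality: float
    cmi: float
    dynafic_raw: float
    dynafic_scaled: float
    rank: int


def degree_centrality(network: MultiLayerNetwork) -> Dict[str, float]:
    """Normalized degree centrality degree/(n-1) on the combined undirected
    view (TF edges counted once, direction ignored)."""
    n = network.n_nodes()
    if n < 2:
        raise DegenerateInputError("degree centrality undefined on a singleton network")
    return {g: len(network.undirected_neighbors(g)) / (n - 1) for g in network.nodes}


def dynafic_raw(
    x_T: float, cmi: float, centrality: float,
    omega1: float = 0.8, omega2: float = 0.4,
) -> float:
    if min(x_T, cmi, centrality) < 0:
        raise ValueError("inputs to the composite score must be nonnegative")
    return x_T * cmi * omega1 + omega2 * centrality


def scale_scores(
    raw: Mapping[str, Mapping[str, float]],
    reference: Optional[str] = None,
) -> Dict[str, Dict[str, float]]:
    """log1p-transform and rescale raw scores to a 0-100 reference range.

    ``raw`` maps condition -> {gene: raw score}.  With ``reference`` given,
    every condition is divided by the reference condition's maximum
    transformed score (non-reference conditions may exceed 100); otherwise
    each condition is scaled by its own maximum.
    """
    logs = {c: {g: float(np.log1p(v)) for g, v in scores.items()} for c, scores in raw.items()}
    if reference is not None:
        if reference not in logs:
            raise KeyError(f"reference condition {reference!r} not among {sorted(logs)}")
        ref_max = max(logs[reference].values(), default=0.0)
        maxima = {c: ref_max for c in logs}
    else:
        maxima = {c: max(s.values(), default=0.0) for c, s in logs.items()}
    out = {}
    for c, s in logs.items():
        if maxima[c] <= 0:
            raise DegenerateInputError(f"all-zero raw scores in condition {c!r}")
        out[c] = {g: 100.0 * v / maxima[c] for g, v in s.items()}
    return out


def score_table(
    de: Sequence[DERecord],
    network: MultiLayerNetwork,
    trajectory: InfluenceTrajectory,
    profiles: Mapping[str, GeneFunctionalProfile],
    omega1: float = 0.8,
    omega2: float = 0.4,
    scaled: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Assemble the per-gene metrics table, ranked by scaled score.

    One row per DE gene; ranking ties break by smaller padj, then gene
    symbol.  Raises :class:`DegenerateInputError` if a DE gene is missing
    from the trajectory/network universe.
    """
    genes = [r.gene for r in de]
    missing = [g for g in genes if g not in trajectory.genes or g not in network.index]
    if missing:
        raise DegenerateInputError(f"genes absent from the computed universe: {missing[:5]}")
    cent = degree_centrality(network)
    x_final = trajectory.final()
    rows = []
    for rec in de:
        p = profiles.get(rec.gene, GeneFunctionalProfile(0.0, 0.0, 0.0))
        raw = dynafic_raw(x_final[rec.gene], p.cmi, cent[rec.gene], omega1, omega2)
        rows.append({
            "gene": rec.gene, "log2fc": rec.log2fc, "padj": rec.padj,
            "x_T": x_final[rec.gene], "centrality": cent[rec.gene],
            "cges": p.cges, "gds": p.gds, "cmi": p.cmi, "dynafic_raw": raw,
        })
    df = pd.DataFrame(rows)
    if scaled is None:
        scaled = scale_scores({"_": dict(zip(df["gene"], df["dynafic_raw"]))})["_"]
    df["dynafic_scaled"] = df["gene"].map(scaled)
    df = df.sort_values(
        by=["dynafic_scaled", "padj", "gene"], ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
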
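"""GO-hierarchy functional metrics: CGES, GDS and the context-modulation
index (CMI).

CGES (cancer GO enrichment score) is the fraction of a gene's ontology
annotations falling in a configurable cancer-relevant term list; GDS (GO
depth score) is the mean hierarchy depth of its annotations (longest path
to a root by default, a specificity proxy); CMI combines the tissue
weight, CGES and GDS:

    CMI = tanh(theta1 * w * CGES) + theta2 * GDS / max_GDS

so it is bounded in [0, 1 + theta2] and monotone in each ingredient.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Set

import numpy as np

from .io import OntologyDAG


@dataclass(frozen=True)
class GeneFunctionalProfile:
    """Per-gene functional-metric bundle; unannotated genes carry zeros."""

    cges: float
    gds: float
    cmi: float


def default_cancer_terms() -> Set[str]:
    """The packaged cancer-hallmark GO term list (a documented stand-in list
    of hallmark-process identifiers; replace via the ``cancer_terms``
    argument or config file for a curated analysis)."""
    text = resources.files("dynafic").joinpath("data/cancer_go_terms.txt").read_text()
    return read_cancer_terms_text(text)


def read_cancer_terms_text(text: str) -> Set[str]:
    out = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.add(line.split()[0])
    return out


def read_cancer_terms(path) -> Set[str]:
    """Read a one-column text file of ontology term identifiers."""
    return read_cancer_terms_text(Path(path).read_text())


def cges(gene: str, annotations: Mapping[str, Set[str]], cancer_terms: Set[str]) -> float:
    """Fraction of the gene's annotations that are cancer-relevant (0 if unannotated)."""
    terms = annotations.get(gene)
    if not terms:
        return 0.0
    return len(terms & cancer_terms) / len(terms)


def gds(
    gene: str,
    annotations: Mapping[str, Set[str]],
    dag: OntologyDAG,
    depth_mode: str = "longest",
) -> float:
    """Mean ontology depth of the gene's annotations (0 if unannotated)."""
    terms = annotations.get(gene)
    if not terms:
        return 0.0
    return float(np.mean([dag.depth(t, depth_mode) for t in terms]))


def cmi(
    w: float,
    cges_value: float,
    gds_value: float,
    theta1: float = 2.0,
    theta2: float = 0.1,
    max_gds: float = 0.0,
) -> float:
    """Context-modulation index from tissue weight, CGES and GDS."""
    depth_term = theta2 * (gds_value / max_gds) if max_gds > 0 else 0.0
    return float(np.tanh(theta1 * w * cges_value) + depth_term)


def compute_profiles(
    genes: Sequence[str],
    annotations: Mapping[str, Set[str]],
    dag: Optional[OntologyDAG],
    tissue_w: Mapping[str, float],
    cancer_terms: Optional[Set[str]] = None,
    theta1: float = 2.0,
    theta2: float = 0.1,
    depth_mode: str = "longest",
) -> Dict[str, GeneFunctionalProfile]:
    """CGES/GDS/CMI for every gene in ``genes``.

    ``max_GDS`` for the CMI depth term is taken over this gene set.  With
    no ontology (``dag`` is None) all profiles are zero.
    """
    if dag is None:
        return {g: GeneFunctionalProfile(0.0, 0.0, 0.0) for g in genes}
    ct = cancer_terms if cancer_terms is not None else default_cancer_terms()
    cges_v = {g: cges(g, annotations, ct) for g in genes}
    gds_v = {g: gds(g, annotations, dag, depth_mode) for g in genes}
    max_gds = max(gds_v.values(), default=0.0)
    return {
        g: GeneFunctionalProfile(
            cges_v[g],
            gds_v[g],
            cmi(tissue_w.get(g, 0.0), cges_v[g], gds_v[g], theta1, theta2, max_gds),
        )
        for g in genes
    }
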
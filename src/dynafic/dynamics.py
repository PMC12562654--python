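"""Trajectory-level and two-condition analytics.

Covers temporal clustering of influence trajectories (outlier-resistant
k-means with silhouette selection of k), the stability-volatility index
(SVI), functional heterogeneity (FH) of network neighborhoods, functional
hierarchy disruption via 1-D Wasserstein distance with a permutation
null, Welch's t comparison of SVI, expression-influence correlation,
hypergeometric tissue-context enrichment, PPI-only ablation agreement,
and the cohort set-arithmetic / contingency worked-example utilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .io import DegenerateInputError
from .diffusion import InfluenceTrajectory
from .network import MultiLayerNetwork

OUTLIER_LABEL = "OUTLIER"


# ---------------------------------------------------------------------------
# Per-gene indices
# ---------------------------------------------------------------------------

def svi(trajectory_row: np.ndarray, centrality: float, max_cv: float) -> float:
    """Stability-volatility index of one gene.

    Coefficient of variation of the influence trajectory, normalized by
    the cohort maximum CV, times an affine centrality factor
    (0.5 + 0.5 c); bounded in [0, 1].  Flat or all-zero trajectories
    score 0 regardless of centrality.
    """
    x = np.asarray(trajectory_row, dtype=float)
    if x.size < 2:
        raise DegenerateInputError("trajectory needs at least 2 time points")
    cv = _cv(x)
    if max_cv <= 0:
        return 0.0
    return (cv / max_cv) * (0.5 + 0.5 * centrality)


def _cv(x: np.ndarray) -> float:
    """Coefficient of variation; round-off noise on flat trajectories snaps to 0."""
    cv = float(np.std(x) / (np.mean(x) + 1e-12))
    return 0.0 if cv < 1e-9 else cv


def svi_table(
    trajectory: InfluenceTrajectory, centrality: Mapping[str, float],
    genes: Optional[Sequence[str]] = None,
) -> Dict[str, float]:
    """SVI for every gene (or the given subset), with the max-CV
    normalization taken over that same gene set."""
    genes = list(genes) if genes is not None else list(trajectory.genes)
    idx = {g: i for i, g in enumerate(trajectory.genes)}
    cvs = {g: _cv(trajectory.X[idx[g]]) for g in genes}
    max_cv = max(cvs.values(), default=0.0)
    return {
        g: svi(trajectory.X[idx[g]], centrality.get(g, 0.0), max_cv) for g in genes
    }


def functional_heterogeneity(
    gene: str,
    network: MultiLayerNetwork,
    category_map: Mapping[str, str],
) -> float:
    """Functional heterogeneity of a gene's 1-hop network neighborhood.

    Shannon entropy (natural log) of functional-category frequencies over
    the closed neighborhood, normalized by log of the number of
    categories present in the whole node universe, scaled by the gene's
    neighborhood fraction degree/|V|.  Isolated genes score 0.
    """
    neighbors = network.undirected_neighbors(gene)
    if not neighbors:
        return 0.0
    universe_cats = {category_map.get(g, "Other") for g in network.nodes}
    if len(universe_cats) < 2:
        return 0.0
    cats = [category_map.get(g, "Other") for g in neighbors | {gene}]
    _, counts = np.unique(cats, return_counts=True)
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    h_norm = h / np.log(len(universe_cats))
    return h_norm * len(neighbors) / network.n_nodes()


def fh_table(network: MultiLayerNetwork, category_map: Mapping[str, str],
             genes: Optional[Sequence[str]] = None) -> Dict[str, float]:
    genes = list(genes) if genes is not None else list(network.nodes)
    return {g: functional_heterogeneity(g, network, category_map) for g in genes}


# ---------------------------------------------------------------------------
# Distributional statistics
# ---------------------------------------------------------------------------

def wasserstein_1d(a: Sequence[float], b: Sequence[float]) -> float:
    """Order-1 Wasserstein distance between two 1-D samples (quantile-
    function integral; mean |sorted(a) - sorted(b)| for equal sizes)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise DegenerateInputError("empty sample")
    return float(stats.wasserstein_distance(a, b))


def wasserstein_permutation_p(
    a: Sequence[float], b: Sequence[float], B: int = 9999, seed: int = 0
) -> Tuple[float, float]:
    """Observed distance plus a label-permutation p-value
    ``(1 + #{permuted >= observed}) / (1 + B)``."""
    if B < 99:
        raise ValueError("need at least 99 permutations")
    a, b = np.asarray(a, float), np.asarray(b, float)
    obs = wasserstein_1d(a, b)
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(B):
        perm = rng.permutation(pooled)
        if wasserstein_1d(perm[: a.size], perm[a.size:]) >= obs:
            count += 1
    return obs, (1 + count) / (1 + B)


def welch_t(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Welch's unequal-variance t statistic and two-sided p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError("Welch's t needs n >= 2 per sample")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise DegenerateInputError("zero variance in both samples")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def hierarchy_disruption(
    fh_left: Mapping[str, float], fh_right: Mapping[str, float]
) -> Tuple[float, List[str]]:
    """Distribution shift and per-gene disruption of FH scores.

    Returns the 1-D Wasserstein distance between the two FH score
    distributions, plus the shared genes whose FH difference
    (right - left) deviates from the mean difference by more than two
    sample standard deviations.
    """
    dist = wasserstein_1d(list(fh_left.values()), list(fh_right.values()))
    shared = sorted(set(fh_left) & set(fh_right))
    disrupted: List[str] = []
    if len(shared) >= 3:
        d = np.array([fh_right[g] - fh_left[g] for g in shared])
        sd = float(np.std(d, ddof=1))
        if sd > 0:
            m = float(np.mean(d))
            disrupted = [g for g, di in zip(shared, d) if abs(di - m) > 2 * sd]
    return dist, disrupted


def expression_influence_correlation(
    abs_log2fc: Sequence[float], scores: Sequence[float]
) -> float:
    """Pearson r between |log2FC| and the scaled score within one condition."""
    x, y = np.asarray(abs_log2fc, float), np.asarray(scores, float)
    if x.size < 3:
        raise DegenerateInputError("correlation needs >= 3 genes")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("zero variance in correlation input")
    return float(stats.pearsonr(np.abs(x), y)[0])


def hypergeom_enrichment(
    selected: Set[str], special: Set[str], universe: Set[str]
) -> float:
    """Upper-tail hypergeometric p of |selected ∩ special| given the sizes."""
    if not universe:
        raise DegenerateInputError("empty universe")
    if not selected <= universe or not special <= universe:
        raise DegenerateInputError("selected/special sets must be subsets of the universe")
    k = len(selected & special)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(special), len(selected)))


def ablation_compare(
    scores_full: Mapping[str, float], scores_ppi_only: Mapping[str, float]
) -> float:
    """Spearman rank agreement of scores between full and PPI-only runs."""
    shared = sorted(set(scores_full) & set(scores_ppi_only))
    if len(shared) < 3:
        raise DegenerateInputError("need >= 3 shared genes for ablation comparison")
    a = [scores_full[g] for g in shared]
    b = [scores_ppi_only[g] for g in shared]
    if a == b:
        return 1.0
    return float(stats.spearmanr(a, b)[0])


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (utility; no correction is applied by default)."""
    return stats.false_discovery_control(np.asarray(pvalues, float), method="bh")


# ---------------------------------------------------------------------------
# Worked-example cohort utilities
# ---------------------------------------------------------------------------

def set_comparison_stats(set_simple: Set[str], set_adjusted: Set[str]) -> Dict[str, float]:
    """Set arithmetic between two DE gene lists (e.g. simple vs
    confounder-adjusted models): lost/gained/shared counts, the lost
    percentage of the simple set, and the Jaccard overlap percentage."""
    if not set_simple or not set_adjusted:
        raise DegenerateInputError("both gene sets must be nonempty")
    lost = set_simple - set_adjusted
    gained = set_adjusted - set_simple
    shared = set_simple & set_adjusted
    union = set_simple | set_adjusted
    return {
        "lost_n": len(lost),
        "lost_pct": 100.0 * len(lost) / len(set_simple),
        "gained_n": len(gained),
        "shared_n": len(shared),
        "jaccard_pct": 100.0 * len(shared) / len(union),
    }


def contingency_props(a_pos: int, a_n: int, b_pos: int, b_n: int) -> Dict[str, float]:
    """Two-group positive percentages (one decimal) and the 2x2 chi-square
    p-value (no continuity correction)."""
    if a_n <= 0 or b_n <= 0:
        raise DegenerateInputError("zero group totals")
    if a_pos > a_n or b_pos > b_n:
        raise ValueError("positives exceed totals")
    table = np.array([[a_pos, a_n - a_pos], [b_pos, b_n - b_pos]])
    if a_pos / a_n == b_pos / b_n:
        chi2_p = 1.0
    else:
        chi2_p = float(stats.chi2_contingency(table, correction=False)[1])
    return {
        "pct_a": round(100.0 * a_pos / a_n, 1),
        "pct_b": round(100.0 * b_pos / b_n, 1),
        "chi2_p": chi2_p,
    }


def fisher_exact_p(a_pos: int, a_n: int, b_pos: int, b_n: int) -> float:
    table = [[a_pos, a_n - a_pos], [b_pos, b_n - b_pos]]
    return float(stats.fisher_exact(table)[1])


# ---------------------------------------------------------------------------
# Trajectory clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterReport:
    """Outlier-resistant k-means clustering of influence trajectories."""

    labels: Dict[str, object]          # gene -> cluster id (int) or OUTLIER
    k: int
    silhouette: Optional[float]
    centroids: np.ndarray              # k x (T+1), on max-normalized trajectories
    outlier_assignment: Dict[str, int] = field(default_factory=dict)
    degenerate: bool = False


def cluster_trajectories(
    trajectory: InfluenceTrajectory,
    k_range: Sequence[int] = (2, 3, 4, 5, 6),
    seed: int = 0,
    outlier_z: float = 3.5,
    genes: Optional[Sequence[str]] = None,
) -> ClusterReport:
    """Cluster per-gene influence trajectories into temporal archetypes.

    Genes whose total trajectory mass has a robust z-score (median/MAD)
    above ``outlier_z`` are set aside as outliers.  Remaining trajectories
    are normalized by their own maximum and clustered with k-means (50
    restarts, fixed seed) for each k in ``k_range``; the k with maximal
    mean silhouette is kept.  Outliers are labeled ``OUTLIER`` and also
    assigned post hoc to the nearest centroid for reporting.  Degenerate
    inputs (identical trajectories) report k = min(k_range) with an
    undefined silhouette and the ``degenerate`` flag set.
    """
    genes = list(genes) if genes is not None else list(trajectory.genes)
    idx = {g: i for i, g in enumerate(trajectory.genes)}
    X = np.stack([trajectory.X[idx[g]] for g in genes])
    mass = X.sum(axis=1)
    med = np.median(mass)
    mad = np.median(np.abs(mass - med))
    if mad > 0:
        rz = np.abs(mass - med) / (1.4826 * mad)
    else:
        rz = np.zeros_like(mass)
    out_mask = rz > outlier_z
    keep = [g for g, o in zip(genes, out_mask) if not o]
    outliers = [g for g, o in zip(genes, out_mask) if o]
    k_range = sorted(k_range)
    if len(keep) < max(k_range) + 1:
        raise DegenerateInputError(
            f"too few non-outlier genes ({len(keep)}) for k up to {max(k_range)}"
        )
    Xk = np.stack([trajectory.X[idx[g]] for g in keep])
    maxima = Xk.max(axis=1, keepdims=True)
    maxima[maxima == 0] = 1.0
    Xn = Xk / maxima
    if np.allclose(Xn, Xn[0], atol=1e-12):
        k = k_range[0]
        km = KMeans(n_clusters=1, n_init=1, random_state=seed).fit(Xn)
        labels: Dict[str, object] = {g: 0 for g in keep}
        labels.update({g: OUTLIER_LABEL for g in outliers})
        return ClusterReport(labels, k, None, km.cluster_centers_,
                             {g: 0 for g in outliers}, degenerate=True)
    best = None
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=50, random_state=seed).fit(Xn)
        if len(set(km.labels_)) < 2:
            continue
        sil = float(silhouette_score(Xn, km.labels_))
        if best is None or sil > best[0]:
            best = (sil, k, km)
    if best is None:
        raise DegenerateInputError("k-means produced no valid partition")
    sil, k, km = best
    labels = {g: int(l) for g, l in zip(keep, km.labels_)}
    labels.update({g: OUTLIER_LABEL for g in outliers})
    out_assign = {}
    for g in outliers:
        x = trajectory.X[idx[g]]
        m = x.max() if x.max() > 0 else 1.0
        out_assign[g] = int(np.argmin(np.linalg.norm(km.cluster_centers_ - x / m, axis=1)))
    return ClusterReport(labels, k, sil, km.cluster_centers_, out_assign)


# ---------------------------------------------------------------------------
# Two-condition comparison report
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """Two-condition comparison statistics (left vs right)."""

    wasserstein: float
    wasserstein_p: float
    fh_wasserstein: float
    disrupted_genes: List[str]
    welch_t: float
    welch_p: float
    pearson_r: Dict[str, float]
    enrichment_p: Optional[float]
    ablation_spearman: Dict[str, float]
    svi_mean: Dict[str, float]
    flags: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "score_wasserstein": self.wasserstein,
            "score_wasserstein_p": self.wasserstein_p,
            "fh_wasserstein": self.fh_wasserstein,
            "disrupted_genes": self.disrupted_genes,
            "svi_welch_t": self.welch_t,
            "svi_welch_p": self.welch_p,
            "pearson_r": self.pearson_r,
            "enrichment_p": self.enrichment_p,
            "ablation_spearman": self.ablation_spearman,
            "svi_mean": self.svi_mean,
            "flags": self.flags,
        }
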
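import numpy as np
import pytest

from conftest import ppi
from dynafic.diffusion import InfluenceTrajectory
from dynafic.io import DegenerateInputError, RunConfig
from dynafic.network import integrate_layers
from dynafic.dynamics import (
    OUTLIER_LABEL,
    ablation_compare,
    benjamini_hochberg,
    cluster_trajectories,
    contingency_props,
    expression_influence_correlation,
    functional_heterogeneity,
    hierarchy_disruption,
    hypergeom_enrichment,
    set_comparison_stats,
    svi,
    svi_table,
    wasserstein_1d,
    wasserstein_permutation_p,
    welch_t,
)
from oracles import wasserstein_lp, welch_t_formula


def make_trajectory(rows: dict) -> InfluenceTrajectory:
    genes = sorted(rows)
    X = np.array([rows[g] for g in genes], dtype=float)
    return InfluenceTrajectory(genes, X, RunConfig(T=max(1, X.shape[1] - 1)))


class TestSvi:
    def test_constant_trajectory_is_zero(self):
        assert svi(np.full(6, 0.2), centrality=1.0, max_cv=2.0) == 0.0

    def test_max_cv_and_full_centrality_reach_one(self):
        x = np.array([1.0, 0.5, 0.25])
        cv = np.std(x) / (np.mean(x) + 1e-12)
        assert svi(x, 1.0, cv) == pytest.approx(1.0)

    def test_direct_evaluation_with_zero_centrality(self):
        x = np.array([1.0, 0.5, 0.25])
        cv = np.std(x) / (np.mean(x) + 1e-12)
        assert svi(x, 0.0, max_cv=2 * cv) == pytest.approx(0.25)

    def test_table_bounded_in_unit_interval(self):
        rng = np.random.default_rng(0)
        traj = make_trajectory({f"g{i}": rng.uniform(0, 1, 6) for i in range(20)})
        cent = {f"g{i}": float(rng.uniform()) for i in range(20)}
        vals = svi_table(traj, cent)
        assert all(0.0 <= v <= 1.0 for v in vals.values())


class TestFunctionalHeterogeneity:
    def _net(self):
        # 10-node universe; gene "g" has 4 neighbors
        edges = [ppi("g", n, 0.9) for n in ("n1", "n2", "n3", "n4")]
        extra = [f"z{i}" for i in range(5)]
        return integrate_layers(edges, [], [], extra_nodes=extra)

    def test_isolated_gene_is_zero(self):
        net = integrate_layers([ppi("a", "b", 0.5)], [], [], extra_nodes=["iso"])
        assert functional_heterogeneity("iso", net, {}) == 0.0

    def test_homogeneous_neighborhood_is_zero(self):
        net = self._net()
        cats = {g: "A" for g in net.nodes}
        assert functional_heterogeneity("g", net, cats) == 0.0

    def test_hand_computed_value(self):
        net = self._net()
        cats = {"n1": "A", "n2": "A", "n3": "B", "n4": "B", "g": "C",
                "z0": "A", "z1": "B", "z2": "C", "z3": "A", "z4": "B"}
        p = np.array([2, 2, 1]) / 5.0  # closed neighborhood {A,A,B,B,C}
        h_norm = -(p * np.log(p)).sum() / np.log(3)  # 3 categories in universe
        expected = h_norm * 4 / 10                   # degree 4 of 10 nodes
        assert functional_heterogeneity("g", net, cats) == pytest.approx(expected)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(1)
        edges = [ppi(f"a{i}", f"a{int(rng.integers(8)) + 8}", 0.9) for i in range(8)]
        net = integrate_layers(edges, [], [])
        cats = {g: f"C{int(rng.integers(3))}" for g in net.nodes}
        for g in net.nodes:
            assert 0.0 <= functional_heterogeneity(g, net, cats) <= 1.0


class TestWasserstein:
    def test_identical_samples(self):
        a = [0.2, 0.5, 0.9]
        assert wasserstein_1d(a, a) == 0.0

    def test_sorted_difference_oracle(self):
        assert wasserstein_1d([0, 1], [1, 2]) == pytest.approx(1.0)

    def test_translation_property(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=40)
        assert wasserstein_1d(a, a + 2.5) == pytest.approx(2.5)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_lp_transport_on_small_samples(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 10, size=int(rng.integers(1, 6))).astype(float)
        b = rng.integers(0, 10, size=int(rng.integers(1, 6))).astype(float)
        assert wasserstein_1d(a, b) == pytest.approx(wasserstein_lp(a, b), abs=1e-8)

    def test_permutation_p_floor_and_identity(self):
        a = [0.1, 0.2, 0.3, 0.4]
        d, p = wasserstein_permutation_p(a, a, B=99, seed=0)
        assert d == 0.0
        assert p == 1.0

    def test_permutation_p_detects_strong_shift(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 40)
        b = rng.normal(5, 1, 40)
        _, p = wasserstein_permutation_p(a, b, B=199, seed=1)
        assert p == pytest.approx(1 / 200)

    def test_null_calibration(self):
        """Under the null the permutation p-value is approximately uniform:
        p > 0.05 in the vast majority of seeded replicates."""
        rng = np.random.default_rng(10)
        hits = 0
        reps = 60
        for i in range(reps):
            a = rng.normal(size=50)
            b = rng.normal(size=50)
            _, p = wasserstein_permutation_p(a, b, B=299, seed=1000 + i)
            hits += p > 0.05
        assert hits >= int(0.9 * reps)

    def test_permutation_label_invariance(self):
        a = [1.0, 2.0, 3.0]
        b = [2.0, 2.5, 4.0]
        d1, p1 = wasserstein_permutation_p(a, b, B=199, seed=5)
        d2, p2 = wasserstein_permutation_p(b, a, B=199, seed=5)
        assert d1 == pytest.approx(d2)
        assert p1 == pytest.approx(p2)


class TestWelch:
    def test_identical_samples(self):
        t, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        t, p = welch_t(a, b)
        t_exp, p_exp = welch_t_formula(a, b)
        assert t == pytest.approx(t_exp)
        assert p == pytest.approx(p_exp)

    def test_scale_invariance_of_t(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=10), rng.normal(1, 2, size=12)
        t1, _ = welch_t(a, b)
        t2, _ = welch_t(3 * a, 3 * b)
        assert t1 == pytest.approx(t2)

    def test_degenerate_variances(self):
        with pytest.raises(DegenerateInputError):
            welch_t([1.0, 1.0], [2.0, 2.0])
        with pytest.raises(DegenerateInputError):
            welch_t([1.0], [2.0, 3.0])


class TestHierarchyDisruption:
    def test_identical_distributions(self):
        fh = {"a": 0.1, "b": 0.2, "c": 0.3}
        dist, disrupted = hierarchy_disruption(fh, dict(fh))
        assert dist == 0.0
        assert disrupted == []

    def test_two_sd_boundary_not_flagged(self):
        # d = (0,0,0,0,10): mean 2, sample sd sqrt(20); |10-2| = 8 < 2 sd
        left = {f"g{i}": 0.0 for i in range(5)}
        right = dict(left)
        right["g4"] = 10.0
        _, disrupted = hierarchy_disruption(left, right)
        assert disrupted == []

    def test_clear_outlier_flagged(self):
        left = {f"g{i}": 0.0 for i in range(10)}
        right = {f"g{i}": 0.01 * i for i in range(10)}
        right["g9"] = 50.0
        _, disrupted = hierarchy_disruption(left, right)
        assert disrupted == ["g9"]

    def test_translation_moves_wasserstein_only(self):
        left = {f"g{i}": 0.1 * i for i in range(6)}
        right = {g: v + 0.7 for g, v in left.items()}
        dist, disrupted = hierarchy_disruption(left, right)
        assert dist == pytest.approx(0.7)
        assert disrupted == []  # constant shift: sd of differences is 0


class TestClusterTrajectories:
    def _planted(self, rng, n_per=10, noise=0.02):
        fast = np.array([1.0, 0.45, 0.2, 0.1, 0.05, 0.02])
        slow = np.array([1.0, 0.95, 0.9, 0.85, 0.8, 0.75])
        rows = {}
        for i in range(n_per):
            rows[f"f{i}"] = fast * (1 + noise * rng.standard_normal(6))
            rows[f"s{i}"] = slow * (1 + noise * rng.standard_normal(6))
        return make_trajectory(rows)

    def test_planted_two_clusters_recovered(self):
        rng = np.random.default_rng(0)
        rep = cluster_trajectories(self._planted(rng), seed=0)
        assert rep.k == 2
        assert rep.silhouette > 0.8
        groups = {}
        for g, lab in rep.labels.items():
            groups.setdefault(g[0], set()).add(lab)
        assert len(groups["f"]) == 1 and len(groups["s"]) == 1
        assert groups["f"] != groups["s"]

    def test_recovery_robust_to_twenty_percent_noise(self):
        """k = 2 recovered in at least 95% of seeded noisy replicates."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            rep = cluster_trajectories(self._planted(rng, noise=0.2), seed=seed)
            hits += rep.k == 2
        assert hits >= 95

    def test_massive_gene_flagged_outlier(self):
        rng = np.random.default_rng(1)
        traj = self._planted(rng)
        X = traj.X.copy()
        genes = list(traj.genes)
        X[genes.index("f0")] *= 100.0
        big = InfluenceTrajectory(genes, X, traj.params)
        rep = cluster_trajectories(big, seed=0)
        assert rep.labels["f0"] == OUTLIER_LABEL
        assert rep.outlier_assignment["f0"] in range(rep.k)

    def test_identical_trajectories_degenerate(self):
        rows = {f"g{i}": np.array([1.0, 0.5, 0.25, 0.2, 0.1, 0.05])
                for i in range(10)}
        rep = cluster_trajectories(make_trajectory(rows), seed=0)
        assert rep.degenerate
        assert rep.k == 2
        assert rep.silhouette is None

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        traj = self._planted(rng, noise=0.2)
        r1 = cluster_trajectories(traj, seed=3)
        r2 = cluster_trajectories(traj, seed=3)
        assert r1.labels == r2.labels and r1.k == r2.k

    def test_too_few_genes_rejected(self):
        rows = {f"g{i}": np.array([1.0, 0.5]) for i in range(4)}
        with pytest.raises(DegenerateInputError):
            cluster_trajectories(make_trajectory(rows), k_range=(2, 6), seed=0)


class TestCorrelationAndEnrichment:
    def test_proportional_scores(self):
        lfc = [0.5, 1.0, 2.0, 3.0]
        assert expression_influence_correlation(lfc, [5, 10, 20, 30]) == pytest.approx(1.0)

    def test_antiproportional_scores(self):
        lfc = np.array([0.5, 1.0, 2.0])
        scores = 10.0 - 2.0 * lfc
        assert expression_influence_correlation(lfc, scores) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            expression_influence_correlation([1, 1, 1], [1, 2, 3])

    def test_hypergeom_full_overlap_closed_form(self):
        universe = {f"g{i}" for i in range(20)}
        special = {f"g{i}" for i in range(5)}
        from math import comb
        p = hypergeom_enrichment(special, special, universe)
        assert p == pytest.approx(1 / comb(20, 5))

    def test_hypergeom_trivial_and_null_cases(self):
        u = {f"g{i}" for i in range(10)}
        assert hypergeom_enrichment(u, u, u) == pytest.approx(1.0)
        p = hypergeom_enrichment({"g0", "g1"}, {"g8", "g9"}, u)
        assert p > 0.5  # zero overlap with a small special set: p near 1

    def test_ablation_identity_and_reversal(self):
        full = {"a": 3.0, "b": 2.0, "c": 1.0}
        assert ablation_compare(full, dict(full)) == 1.0
        assert ablation_compare(full, {"a": 1.0, "b": 2.0, "c": 3.0}) == pytest.approx(-1.0)

    def test_ablation_needs_shared_genes(self):
        with pytest.raises(DegenerateInputError):
            ablation_compare({"a": 1.0}, {"b": 2.0})

    def test_bh_is_monotone_and_bounded(self):
        p = [0.001, 0.01, 0.02, 0.5, 0.9]
        q = benjamini_hochberg(p)
        assert np.all(q >= p)
        assert np.all(q <= 1.0)


class TestWorkedExampleUtilities:
    def test_set_comparison_identical_and_disjoint(self):
        s = {f"g{i}" for i in range(10)}
        stats = set_comparison_stats(s, set(s))
        assert stats["lost_n"] == 0 and stats["jaccard_pct"] == pytest.approx(100.0)
        stats = set_comparison_stats(s, {f"h{i}" for i in range(5)})
        assert stats["jaccard_pct"] == 0.0

    def test_contingency_equal_proportions(self):
        out = contingency_props(10, 100, 10, 100)
        assert out["pct_a"] == out["pct_b"] == 10.0
        assert out["chi2_p"] == pytest.approx(1.0)

    def test_contingency_validation(self):
        with pytest.raises(DegenerateInputError):
            contingency_props(1, 0, 1, 10)
        with pytest.raises(ValueError):
            contingency_props(11, 10, 1, 10)
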
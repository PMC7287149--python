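import math

import numpy as np
import pytest
from scipy import stats

import csenet as cn


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def binomial_tail(K, M, omega, alternative):
    """Direct summation of binomial probabilities."""
    pmf = [math.comb(M, k) * omega**k * (1 - omega) ** (M - k) for k in range(M + 1)]
    if alternative == "greater":
        return sum(pmf[K:])
    return sum(pmf[: K + 1])


def fisher_two_sided(a, b, c, d):
    """Hypergeometric enumeration: sum of tables as or less probable."""
    row1, col1, total = a + b, a + c, a + b + c + d
    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    probs = {x: stats.hypergeom.pmf(x, total, col1, row1) for x in range(lo, hi + 1)}
    observed = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= observed * (1 + 1e-9)))


def make_network(genes, edges):
    m = np.zeros((len(genes), len(genes)), dtype=int)
    idx = {g: i for i, g in enumerate(genes)}
    for x, y in edges:
        m[idx[x], idx[y]] = m[idx[y], idx[x]] = 1
    return cn.AdjacencyMatrix(genes, m)


def random_network(n, omega, rng):
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    n_edges = int(omega * len(pairs))
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    m = np.zeros((n, n), dtype=int)
    for c in chosen:
        i, j = pairs[c]
        m[i, j] = m[j, i] = 1
    return cn.AdjacencyMatrix([f"g{i:03d}" for i in range(n)], m)


# ---------------------------------------------------------------------------
# edge counting
# ---------------------------------------------------------------------------

class TestEdgeCounts:
    def test_within_triangle_and_independent_set(self):
        genes = [f"g{i}" for i in range(6)]
        A = make_network(genes, [("g0", "g1"), ("g1", "g2"), ("g0", "g2")])
        assert cn.count_edges_within(A, {"g0", "g1", "g2"}) == (3, 3)
        assert cn.count_edges_within(A, {"g3", "g4", "g5"}) == (0, 3)

    def test_within_partial_set(self):
        genes = [f"g{i}" for i in range(5)]
        A = make_network(genes, [("g0", "g1"), ("g2", "g3")])
        assert cn.count_edges_within(A, set(genes)) == (2, 10)

    def test_within_drops_absent_genes_with_warning(self):
        A = make_network(["g0", "g1"], [("g0", "g1")])
        with pytest.warns(UserWarning, match="dropped"):
            K, M = cn.count_edges_within(A, {"g0", "g1", "missing"})
        assert (K, M) == (1, 1)

    def test_between_complete_bipartite(self):
        genes = [f"g{i}" for i in range(5)]
        edges = [(a, b) for a in ("g0", "g1") for b in ("g2", "g3", "g4")]
        A = make_network(genes, edges)
        assert cn.count_edges_between(A, {"g0", "g1"}, {"g2", "g3", "g4"}) == (6, 6)

    def test_between_single_cross_edge(self):
        genes = [f"g{i}" for i in range(9)]
        A = make_network(genes, [("g0", "g5")])
        K, M = cn.count_edges_between(A, {"g0", "g1", "g2", "g3"},
                                      {"g4", "g5", "g6", "g7", "g8"})
        assert (K, M) == (1, 20)

    def test_between_overlapping_sets_rejected(self):
        A = make_network(["g0", "g1", "g2"], [("g0", "g1")])
        with pytest.raises(ValueError, match="overlap"):
            cn.count_edges_between(A, {"g0", "g1"}, {"g1", "g2"})


# ---------------------------------------------------------------------------
# pronounced sub-network test
# ---------------------------------------------------------------------------

class TestPronounced:
    def test_flag_follows_expected_count(self):
        res = cn.pronounced_test(1, 10, 0.005)
        assert res.pronounced  # 1 > 0.05
        assert not cn.pronounced_test(0, 10, 0.005).pronounced

    def test_hand_example_tail_sum(self):
        res = cn.pronounced_test(2, 10, 0.005)
        assert res.p_value == pytest.approx(binomial_tail(2, 10, 0.005, "greater"),
                                            rel=1e-10)
        assert res.p_value == pytest.approx(1.10e-3, rel=0.01)

    def test_zero_observed_greater_is_one(self):
        assert cn.pronounced_test(0, 12, 0.1).p_value == 1.0

    @pytest.mark.parametrize("omega", [0.005, 0.1, 0.5])
    @pytest.mark.parametrize("alternative", ["greater", "less"])
    def test_equals_brute_force_on_all_small_instances(self, omega, alternative):
        for M in range(1, 31):
            for K in range(M + 1):
                expected = binomial_tail(K, M, omega, alternative)
                got = cn.pronounced_test(K, M, omega, alternative=alternative).p_value
                assert got == pytest.approx(expected, abs=1e-12)

    def test_mean_internal_edges_matches_expectation(self):
        """Mean K over random networks at sparsity omega is omega*M."""
        rng = np.random.default_rng(2024)
        subset = {f"g{i:03d}" for i in range(10)}  # M = 45
        ks = []
        for _ in range(2000):
            A = random_network(50, 0.05, rng)
            ks.append(cn.count_edges_within(A, subset)[0])
        assert np.mean(ks) == pytest.approx(0.05 * 45, abs=0.12)


# ---------------------------------------------------------------------------
# Fisher comparisons
# ---------------------------------------------------------------------------

class TestFisherComparisons:
    def test_identical_counts_p_one(self):
        assert cn.compare_networks_fisher(4, 4, 20) == 1.0
        assert cn.compare_node_counts_fisher(7, 15, 7) == 1.0

    def test_hand_enumerated_tables(self):
        assert cn.compare_networks_fisher(0, 5, 5) == pytest.approx(2 / 252, rel=1e-9)
        assert cn.compare_node_counts_fisher(10, 10, 0) == pytest.approx(
            2 / math.comb(20, 10), rel=1e-9)

    def test_symmetry_in_network_order(self):
        assert cn.compare_networks_fisher(3, 9, 12) == pytest.approx(
            cn.compare_networks_fisher(9, 3, 12), rel=1e-12)
        assert cn.compare_node_counts_fisher(3, 12, 9) == pytest.approx(
            cn.compare_node_counts_fisher(9, 12, 3), rel=1e-12)

    def test_equals_hypergeometric_enumeration_on_small_tables(self):
        for M in (5, 11, 17, 23, 30):
            for K_A in range(0, M + 1, 3):
                for K_B in range(0, M + 1, 4):
                    expected = fisher_two_sided(K_A, M - K_A, K_B, M - K_B)
                    got = cn.compare_networks_fisher(K_A, K_B, M)
                    assert got == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# two-proportion z and guilt-by-association
# ---------------------------------------------------------------------------

class TestTwoProportionZ:
    def test_equal_proportions_z_zero(self):
        res = cn.two_proportion_z(5, 10, 10, 20)
        assert res.z == 0.0 and res.p_value == 1.0

    def test_hand_example(self):
        res = cn.two_proportion_z(30, 60, 10, 40)
        assert res.pooled == pytest.approx(0.4)
        assert res.z == pytest.approx(2.5)
        assert res.p_value == pytest.approx(2 * stats.norm.sf(2.5), rel=1e-12)

    def test_antisymmetric_under_group_swap(self):
        res = cn.two_proportion_z(8, 20, 3, 30)
        swapped = cn.two_proportion_z(3, 30, 8, 20)
        assert res.z == pytest.approx(-swapped.z)

    def test_degenerate_pooled_proportion(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = cn.two_proportion_z(0, 10, 0, 20)
        assert res.p_value == 1.0


class TestGeneCategoryTest:
    def test_zero_edges_greater_is_one(self):
        A = make_network(["g0", "g1", "g2"], [("g1", "g2")])
        res = cn.gene_category_test("g0", {"g1", "g2"}, A, omega=0.005)
        assert res.p_value == 1.0

    def test_hand_tail_sum(self):
        genes = [f"g{i}" for i in range(60)]
        category = set(genes[1:51])  # m = 50
        A = make_network(genes, [("g0", "g1"), ("g0", "g2"), ("g0", "g3")])
        res = cn.gene_category_test("g0", category, A, omega=0.005)
        assert res.observed == 3
        assert res.p_value == pytest.approx(binomial_tail(3, 50, 0.005, "greater"),
                                            rel=1e-10)
        assert res.p_value == pytest.approx(2.1e-3, rel=0.05)

    def test_single_member_category_single_trial(self):
        A = make_network(["g0", "g1"], [("g0", "g1")])
        res = cn.gene_category_test("g0", {"g1"}, A, omega=0.07)
        assert res.p_value == pytest.approx(0.07)

    def test_focal_gene_excluded_from_its_category(self):
        A = make_network(["g0", "g1", "g2"], [("g0", "g1")])
        res = cn.gene_category_test("g0", {"g0", "g1", "g2"}, A, omega=0.1)
        assert res.n_possible == 2  # g0 itself removed

    def test_degree_conditioned_variant_uses_hypergeometric(self):
        genes = [f"g{i}" for i in range(12)]
        A = make_network(genes, [("g0", g) for g in genes[1:6]])
        res = cn.gene_category_test("g0", set(genes[1:5]), A, omega=0.005,
                                    condition_on_degree=True)
        expected = stats.hypergeom.sf(res.observed - 1, 11, 4, 5)
        assert res.p_value == pytest.approx(float(expected), rel=1e-10)


class TestGuiltByAssociation:
    def _profiled_network(self):
        genes = ["hub"] + [f"g{i}" for i in range(20)]
        edges = [("hub", f"g{i}") for i in range(10)]
        A = make_network(genes, edges)
        annotations = {f"g{i}": "catA" if i < 8 else "catB" for i in range(20)}
        annotations["hub"] = "catB"
        return A, annotations

    def test_concentrated_neighbours_give_positive_z(self):
        A, annotations = self._profiled_network()
        profile = cn.guilt_by_association_profile("hub", A, annotations)
        top = profile.iloc[0]
        assert top["category"] == "catA"
        assert top["z"] > 0

    def test_delegates_to_two_proportion_z(self):
        A, annotations = self._profiled_network()
        profile = cn.guilt_by_association_profile("hub", A, annotations)
        row = profile[profile["category"] == "catA"].iloc[0]
        direct = cn.two_proportion_z(int(row["neighbours_in_category"]),
                                     int(row["degree"]),
                                     int(row["background_count"]),
                                     20)
        assert row["z"] == pytest.approx(direct.z, rel=1e-12)

    def test_background_matching_proportions_z_zero(self):
        genes = ["hub", "a1", "a2", "b1", "b2"]
        A = make_network(genes, [("hub", "a1"), ("hub", "b1")])
        annotations = {"a1": "catA", "a2": "catA", "b1": "catB", "b2": "catB"}
        profile = cn.guilt_by_association_profile("hub", A, annotations)
        assert (profile["z"] == 0.0).all()

    def test_isolated_gene_rejected(self):
        A = make_network(["g0", "g1", "g2"], [("g1", "g2")])
        with pytest.raises(ValueError, match="no edges"):
            cn.guilt_by_association_profile("g0", A, {"g1": "c", "g2": "c"})


# ---------------------------------------------------------------------------
# catalog evaluation
# ---------------------------------------------------------------------------

class TestEvaluateCatalog:
    def test_single_set_single_row(self):
        A = make_network(["g0", "g1", "g2"], [("g0", "g1")])
        table = cn.evaluate_catalog(A, {"only": {"g0", "g1"}}, omega=0.1)
        assert len(table) == 1
        assert table.iloc[0]["K"] == 1

    def test_within_and_between_families_adjusted_separately(self):
        genes = [f"g{i}" for i in range(9)]
        A = make_network(genes, [("g0", "g1"), ("g3", "g4"), ("g0", "g3")])
        catalog = {"s1": set(genes[:3]), "s2": set(genes[3:6]), "s3": set(genes[6:])}
        table = cn.evaluate_catalog(A, catalog, omega=0.05)
        assert set(table["kind"]) == {"within", "between"}
        assert len(table[table["kind"] == "within"]) == 3
        assert len(table[table["kind"] == "between"]) == 3
        assert table["q"].notna().all()

    def test_shared_genes_removed_from_between_pairs(self):
        genes = [f"g{i}" for i in range(6)]
        A = make_network(genes, [("g0", "g3")])
        catalog = {"left": {"g0", "g1", "g2"}, "right": {"g2", "g3", "g4"}}
        table = cn.evaluate_catalog(A, catalog, omega=0.05)
        row = table[table["kind"] == "between"].iloc[0]
        assert row["M"] == 4  # 2 x 2 after dropping shared g2

    def test_type_one_error_calibrated_on_random_sets(self):
        """Fraction of random sets significant at 0.05 stays near 0.05."""
        rng = np.random.default_rng(99)
        A = random_network(120, 0.05, rng)
        hits = 0
        draws = 200
        for _ in range(draws):
            picked = rng.choice(120, size=15, replace=False)
            genes = {A.gene_ids[i] for i in picked}
            K, M = cn.count_edges_within(A, genes)
            if cn.pronounced_test(K, M, 0.05).p_value <= 0.05:
                hits += 1
        assert hits / draws <= 0.09  # ~0.05 expected; binomial noise + discreteness

    def test_true_modules_detected_on_cse_network(self, default_dataset,
                                                  default_networks):
        X, _, truth = default_dataset
        net_cse, _ = default_networks
        catalog, _ = cn.generate_annotations(truth, X.gene_ids, seed=1)
        table = cn.evaluate_catalog(net_cse, catalog, omega=0.005, between=False)
        modules = table[table["set"].str.startswith("module")]
        decoys = table[table["set"].str.startswith("decoy")]
        assert modules["pronounced"].all()
        assert (modules["p"] < 1e-4).sum() >= 9
        assert (decoys["p"] > 0.01).all()
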
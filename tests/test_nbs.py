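import numpy as np
import pytest
from scipy import stats

from vnsnet import nbs
from vnsnet.montage import CHANNELS, edge_index, edge_pairs


class TestEdgewiseGlm:
    def test_identical_groups_give_null_stats(self, rng):
        x = rng.standard_normal((10, 171))
        features = np.vstack([x, x])
        labels = ["responder"] * 10 + ["nonresponder"] * 10
        out = nbs.edgewise_glm_stats(features, labels)
        np.testing.assert_allclose(out.t, 0.0, atol=1e-12)
        np.testing.assert_allclose(out.p, 1.0, atol=1e-12)

    def test_hand_computed_pooled_t(self):
        """Groups {1,2,3} vs {4,5,6}: means 2 and 5, pooled variance 1,
        se = sqrt(2/3), so t = -3/sqrt(2/3) = -3.674, p(df=4) = 0.0214."""
        features = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        labels = np.array([1, 1, 1, 0, 0, 0])
        out = nbs.edgewise_glm_stats(features, labels)
        se = np.sqrt(2.0 / 3.0)
        # group1 = label 1 ({1,2,3}); t = (2 - 5)/se
        assert out.t[0] == pytest.approx(-3.0 / se, rel=1e-12)
        assert out.p[0] == pytest.approx(2 * stats.t.sf(3.0 / se, df=4), rel=1e-12)
        assert out.p[0] == pytest.approx(0.0214, abs=5e-4)

    def test_t_squared_equals_anova_f(self, rng):
        features = rng.standard_normal((30, 8))
        labels = rng.integers(0, 2, size=30)
        while min(labels.sum(), 30 - labels.sum()) < 2:
            labels = rng.integers(0, 2, size=30)
        out = nbs.edgewise_glm_stats(features, labels)
        for k in range(8):
            f = stats.f_oneway(features[labels == 1, k], features[labels == 0, k])
            assert out.t[k] ** 2 == pytest.approx(f.statistic, abs=1e-10)
            assert out.p[k] == pytest.approx(f.pvalue, abs=1e-10)

    def test_zero_variance_edge_degenerates_to_null(self):
        features = np.ones((8, 2))
        features[:, 1] = np.arange(8.0)
        labels = [1, 1, 1, 1, 0, 0, 0, 0]
        out = nbs.edgewise_glm_stats(features, labels)
        assert out.t[0] == 0.0 and out.p[0] == 1.0
        assert out.p[1] < 1.0

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            nbs.edgewise_glm_stats(np.zeros((3, 2)), [1, 1, 0])


class TestSuprathresholdGraph:
    @pytest.fixture
    def stats_(self, rng):
        p = rng.uniform(0, 1, 171)
        return nbs.EdgeStatistics(t=rng.standard_normal(171), p=p, n_group1=10, n_group0=10)

    def test_threshold_one_keeps_everything(self, stats_):
        g = nbs.suprathreshold_graph(stats_, 1.0)
        assert len(g.edges) == 171
        assert g.degrees.sum() == 2 * 171
        assert (g.degrees <= 18).all()

    def test_vanishing_threshold_empties_graph(self, stats_):
        g = nbs.suprathreshold_graph(stats_, 1e-12)
        assert g.edges == []

    def test_threshold_nesting(self, stats_):
        sets = [
            set(nbs.suprathreshold_graph(stats_, thr).edges)
            for thr in (0.001, 0.005, 0.01, 0.05)
        ]
        for smaller, larger in zip(sets, sets[1:]):
            assert smaller <= larger


def _union_find_components(edges):
    parent = {}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in edges:
        parent.setdefault(i, i)
        parent.setdefault(j, j)
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    groups = {}
    for i, j in edges:
        groups.setdefault(find(i), []).append((i, j))
    return sorted((sorted(v) for v in groups.values()), key=lambda c: (-len(c), c))


class TestConnectedComponents:
    def _graph(self, edges):
        return nbs.SupraThresholdGraph(threshold=0.05, edges=edges, n_nodes=19)

    def test_single_edge_single_component(self):
        c3, c4 = CHANNELS.index("C3"), CHANNELS.index("C4")
        comps = nbs.connected_components(self._graph([(c3, c4)]))
        assert comps == [[(c3, c4)]]

    def test_path_plus_isolated_pair(self):
        comps = nbs.connected_components(self._graph([(0, 1), (1, 2), (5, 6)]))
        assert [len(c) for c in comps] == [2, 1]
        assert comps[0] == [(0, 1), (1, 2)]

    def test_matches_union_find_oracle_on_random_graphs(self, rng):
        pairs = edge_pairs(19)
        for _ in range(100):
            k = int(rng.integers(0, 40))
            edges = [pairs[i] for i in rng.choice(171, size=k, replace=False)]
            bfs = nbs.connected_components(self._graph(edges))
            assert bfs == _union_find_components(edges)


class TestNbsFweTest:
    def test_identical_groups_select_nothing(self, rng):
        x = rng.standard_normal((12, 171))
        features = np.vstack([x, x])
        labels = np.array([1] * 12 + [0] * 12)
        res = nbs.nbs_fwe_test(features, labels, n_perm=99, seed=0)
        assert res.components == []
        assert res.selected_edges == []
        assert res.max_component_size == 0

    def test_planted_network_recovered(self, planted_features):
        features, labels, spec = planted_features
        res = nbs.nbs_fwe_test(features, labels, threshold=0.05, n_perm=500, seed=1)
        planted = set(spec.differential_edges)
        recovered = planted & set(res.selected_edges)
        assert len(recovered) >= 0.8 * len(planted)
        assert min(res.fwe_p) < 0.05

    def test_pvalue_lower_bound_convention(self, planted_features):
        features, labels, _ = planted_features
        res = nbs.nbs_fwe_test(features, labels, n_perm=200, seed=2)
        for p in res.fwe_p:
            assert p >= 1.0 / 201.0

    def test_deterministic_under_seed(self, planted_features):
        features, labels, _ = planted_features
        a = nbs.nbs_fwe_test(features, labels, n_perm=100, seed=7)
        b = nbs.nbs_fwe_test(features, labels, n_perm=100, seed=7)
        assert a.fwe_p == b.fwe_p
        np.testing.assert_array_equal(a.perm_max_sizes, b.perm_max_sizes)

    def test_patient_unit_swaps_whole_patients(self, rng):
        # 8 patients x 5 epochs; patient-level permutation must keep all
        # epochs of a patient on the same side
        n_pat, n_ep = 8, 5
        pids = np.repeat(np.arange(n_pat), n_ep)
        y = np.repeat([1, 1, 1, 1, 0, 0, 0, 0], n_ep).astype(float)
        rows = nbs._permuted_label_rows(y, pids, "patient", 50, np.random.default_rng(0))
        for r in rows:
            for pid in range(n_pat):
                vals = r[pids == pid]
                assert (vals == vals[0]).all()
            assert r.sum() == y.sum()

    def test_patient_unit_needs_two_patients_per_group(self, rng):
        features = rng.standard_normal((20, 5))
        pids = np.repeat([0, 1, 2], [10, 5, 5])
        labels = np.repeat([1, 0, 0], [10, 5, 5])
        with pytest.raises(ValueError):
            nbs.nbs_fwe_test(
                features, labels, unit="patient", patient_ids=pids, n_perm=10, seed=0
            )

    def test_null_distribution_matches_exhaustive_enumeration(self, rng):
        """With 5 vs 5 observations there are C(10,5) = 252 distinct label
        assignments; the sampled max-component-size null must match the
        exhaustive enumeration's distribution closely."""
        from itertools import combinations

        n, n_nodes = 10, 8
        n_edges = n_nodes * (n_nodes - 1) // 2
        features = rng.standard_normal((n, n_edges))
        labels = np.array([1] * 5 + [0] * 5)
        pairs = edge_pairs(n_nodes)

        def max_comp(y):
            s = nbs.edgewise_glm_stats(features, y)
            g = nbs.suprathreshold_graph(s, 0.05, n_nodes)
            comps = nbs._bfs_components(g.edges)
            return len(comps[0]) if comps else 0

        exhaustive = []
        for pos in combinations(range(n), 5):
            y = np.zeros(n)
            y[list(pos)] = 1
            exhaustive.append(max_comp(y))
        exhaustive = np.array(exhaustive)

        res = nbs.nbs_fwe_test(features, labels, n_perm=4000, seed=3)
        if res.components:
            obs = res.max_component_size
            exact_p = (1 + np.sum(exhaustive >= obs)) / (len(exhaustive) + 1)
            assert res.fwe_p[0] == pytest.approx(exact_p, abs=0.05)
        # CDFs agree on every support point
        for size in np.unique(exhaustive):
            exact_cdf = np.mean(exhaustive <= size)
            sampled_cdf = np.mean(res.perm_max_sizes <= size)
            assert sampled_cdf == pytest.approx(exact_cdf, abs=0.05)


class TestRankHubs:
    def _result(self, edges):
        return nbs.NBSResult(
            components=[edges],
            fwe_p=[0.001],
            max_component_size=len(edges),
            selected_edges=sorted(edges),
            threshold=0.05,
            n_permutations=100,
            unit="epoch",
        )

    def test_star_graph_degree_formatting(self):
        c4 = CHANNELS.index("C4")
        spokes = [i for i in range(19) if i != c4][:11]
        ranking = nbs.rank_hubs(self._result([(min(c4, s), max(c4, s)) for s in spokes]))
        assert ranking[0]["node"] == "C4"
        assert ranking[0]["degree"] == 11
        assert ranking[0]["ratio"] == "11/19"

    def test_empty_network_empty_ranking(self):
        assert nbs.rank_hubs(self._result([])) == []

    def test_triangle_ties_break_in_canonical_order(self):
        c3, c4, pz = (CHANNELS.index(c) for c in ("C3", "C4", "Pz"))
        edges = [(c3, c4), (min(c4, pz), max(c4, pz)), (min(c3, pz), max(c3, pz))]
        ranking = nbs.rank_hubs(self._result(edges))
        assert [r["degree"] for r in ranking] == [2, 2, 2]
        assert [r["node"] for r in ranking] == ["C3", "C4", "Pz"]
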
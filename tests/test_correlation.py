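import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from peakmine import (
    PeakTable,
    RangeFilter,
    build_network,
    correlate_pair,
    correlated_neighbors,
    correlation_scatter,
    topology_stats,
)
from peakmine.correlation import benjamini_hochberg


# -- independent oracles ----------------------------------------------------

def brute_force_tau_b(x, y):
    """Tau-b by explicit enumeration of all pairs with tie corrections."""
    n = len(x)
    concordant = discordant = 0
    for i in range(n):
        for j in range(i + 1, n):
            s = (x[i] - x[j]) * (y[i] - y[j])
            if s > 0:
                concordant += 1
            elif s < 0:
                discordant += 1
    n0 = n * (n - 1) // 2

    def tie_term(v):
        counts = {}
        for item in v:
            counts[item] = counts.get(item, 0) + 1
        return sum(t * (t - 1) // 2 for t in counts.values())

    denom = math.sqrt((n0 - tie_term(x)) * (n0 - tie_term(y)))
    return (concordant - discordant) / denom


def random_tied_pairs(n_pairs, seed, nmax=8):
    rng = np.random.default_rng(seed)
    for _ in range(n_pairs):
        n = int(rng.integers(4, nmax + 1))
        # heavy ties: draw from a small integer alphabet
        x = rng.integers(0, 4, size=n).astype(float)
        y = rng.integers(0, 4, size=n).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            x[0] += 1.0
            y[0] += 1.0
        yield x, y


class TestCorrelatePair:
    def test_pearson_perfect_line(self):
        res = correlate_pair([1, 2, 3, 4], [2, 4, 6, 8], "pearson")
        assert res.r == pytest.approx(1.0, abs=1e-15)
        assert res.p_two_tailed == 0.0

    def test_kendall_hand_example(self):
        # 6 concordant, 4 discordant of the 10 pairs, no ties
        res = correlate_pair([1, 2, 3, 4, 5], [3, 4, 1, 2, 5], "kendall_tau_b")
        assert res.r == pytest.approx(0.2, abs=1e-15)

    def test_one_tailed_is_half_two_tailed(self):
        rng = np.random.default_rng(0)
        for method in ("pearson", "spearman", "kendall_tau_b"):
            for _ in range(20):
                x, y = rng.random(7), rng.random(7)
                res = correlate_pair(x, y, method)
                assert res.p_one_tailed == res.p_two_tailed / 2

    def test_tau_b_matches_brute_force(self):
        for x, y in random_tied_pairs(200, seed=42):
            res = correlate_pair(x, y, "kendall_tau_b")
            assert res.r == pytest.approx(brute_force_tau_b(x, y), abs=1e-12)

    def test_spearman_matches_pearson_on_midranks(self):
        for x, y in random_tied_pairs(200, seed=43):
            res = correlate_pair(x, y, "spearman")
            rx, ry = stats.rankdata(x), stats.rankdata(y)
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert res.r == pytest.approx(oracle, abs=1e-12)

    def test_pearson_matches_covariance_formula(self):
        rng = np.random.default_rng(44)
        for _ in range(200):
            x, y = rng.random(8), rng.random(8)
            res = correlate_pair(x, y, "pearson")
            oracle = np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
            assert res.r == pytest.approx(oracle, abs=1e-12)

    @pytest.mark.parametrize("method", ["pearson", "spearman", "kendall_tau_b"])
    def test_matches_scipy(self, method):
        """Independent library cross-check, values and p-values."""
        rng = np.random.default_rng(7)
        for _ in range(30):
            x = rng.integers(0, 5, size=10).astype(float)
            y = rng.integers(0, 5, size=10).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            res = correlate_pair(x, y, method)
            if method == "pearson":
                ref = stats.pearsonr(x, y)
            elif method == "spearman":
                ref = stats.spearmanr(x, y)
            else:
                ref = stats.kendalltau(x, y, variant="b", method="asymptotic")
            assert res.r == pytest.approx(ref.statistic, abs=1e-12)
            assert res.p_two_tailed == pytest.approx(ref.pvalue, abs=1e-9)

    @pytest.mark.parametrize("method", ["pearson", "spearman", "kendall_tau_b"])
    def test_symmetry_and_bounds(self, method):
        rng = np.random.default_rng(3)
        for _ in range(25):
            x = rng.integers(0, 3, size=6).astype(float)
            y = rng.integers(0, 3, size=6).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            a = correlate_pair(x, y, method)
            b = correlate_pair(y, x, method)
            assert a.r == pytest.approx(b.r, abs=1e-15)
            assert -1.0 <= a.r <= 1.0
            assert 0.0 <= a.p_two_tailed <= 1.0

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(st.integers(0, 5), min_size=4, max_size=10),
        st.integers(1, 3),
        st.integers(0, 4),
    )
    def test_rank_methods_invariant_under_monotone_maps(self, xs, scale, shift):
        rng = np.random.default_rng(abs(hash(tuple(xs))) % 2**31)
        x = np.array(xs, dtype=float)
        y = rng.random(len(x))
        if np.ptp(x) == 0:
            return
        monotone = np.exp(scale * x) + shift  # strictly increasing map
        for method in ("spearman", "kendall_tau_b"):
            assert correlate_pair(x, y, method).r == pytest.approx(
                correlate_pair(monotone, y, method).r, abs=1e-12
            )
        # Pearson: invariant under positive affine maps only
        assert correlate_pair(x, y, "pearson").r == pytest.approx(
            correlate_pair(scale * x + shift, y, "pearson").r, abs=1e-12
        )

    def test_constant_vector_flagged_undefined(self):
        res = correlate_pair([1, 1, 1, 1], [1, 2, 3, 4], "pearson")
        assert res.undefined
        assert math.isnan(res.r)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            correlate_pair([1, 2], [3, 4], "pearson")


def known_structure_table():
    """m1~m2 (r ~ 1), m3 and m4 near-orthogonal noise, m5 constant."""
    t = np.linspace(0, 1, 12)
    rng = np.random.default_rng(0)
    m1 = 10 + 5 * t
    m2 = 3 + 4 * t + 0.01 * rng.standard_normal(12)
    m3 = rng.random(12)
    m4 = rng.random(12)
    m5 = np.full(12, 7.0)
    return PeakTable(
        ["m1", "m2", "m3", "m4", "m5"],
        [f"s{i}" for i in range(12)],
        np.array([m1, m2, m3, m4, m5]),
    )


class TestBuildNetwork:
    def test_visible_edge_set(self):
        net = build_network(known_structure_table(), "pearson", RangeFilter.min_abs(0.8))
        visible = {frozenset((e.a, e.b)) for e in net.visible_edges()}
        assert frozenset(("m1", "m2")) in visible
        assert not any(frozenset(("m3", "m4")) == v for v in visible)

    def test_full_store_has_all_pairs(self):
        net = build_network(known_structure_table(), "spearman")
        assert len(net.results) == 5 * 4 // 2

    def test_constant_molecule_pairs_undefined_never_visible(self):
        net = build_network(known_structure_table(), "pearson", RangeFilter())
        for other in ("m1", "m2", "m3", "m4"):
            assert net.result("m5", other).undefined
            assert not net.is_visible("m5", other)

    def test_vectorized_matches_pairwise(self):
        table = known_structure_table()
        for method in ("pearson", "spearman"):
            net = build_network(table, method)
            for (a, b), res in net.results.items():
                if res.undefined:
                    continue
                direct = correlate_pair(table.profile(a), table.profile(b), method)
                assert res.r == pytest.approx(direct.r, abs=1e-10)
                assert res.p_two_tailed == pytest.approx(direct.p_two_tailed, abs=1e-10)

    def test_too_few_samples(self):
        t = PeakTable(["a", "b"], ["s1", "s2"], np.array([[1.0, 2.0], [3.0, 4.0]]))
        with pytest.raises(ValueError):
            build_network(t)


class TestNeighborsAndScatter:
    def test_neighbors_sorted_by_abs_r(self):
        rng = np.random.default_rng(1)
        t = np.linspace(0, 1, 10)
        table = PeakTable(
            ["hub", "pos", "neg"],
            [f"s{i}" for i in range(10)],
            np.array([
                1 + t,
                1 + 0.9 * t + 0.05 * rng.standard_normal(10),
                2 - t,
            ]),
        )
        net = build_network(table, "pearson", RangeFilter.min_abs(0.5))
        rows = [(mol, r) for mol, _, r in correlated_neighbors(net, "hub")]
        assert [m for m, _ in rows] == ["neg", "pos"]
        assert rows[0][1] == pytest.approx(-1.0, abs=1e-12)

    def test_isolated_node_has_no_neighbors(self):
        net = build_network(known_structure_table(), "pearson", RangeFilter.min_abs(0.99))
        assert correlated_neighbors(net, "m3") == []

    def test_unknown_molecule(self):
        net = build_network(known_structure_table(), "pearson")
        with pytest.raises(KeyError):
            correlated_neighbors(net, "nope")

    def test_scatter_points_and_result(self, toy_table):
        points, res = correlation_scatter(toy_table, "901.7314", "903.7465")
        assert points == [(1, 2), (2, 4), (3, 6), (4, 8)]
        assert res.r == pytest.approx(1.0, abs=1e-12)


class TestTopologyStats:
    def test_path_graph_degrees_and_connectivity(self):
        # hand graph a-b-c via explicit range filter on constructed data
        t = np.linspace(0, 1, 8)
        rng = np.random.default_rng(2)
        noise = rng.standard_normal(8)
        table = PeakTable(
            ["a", "b", "c"],
            [f"s{i}" for i in range(8)],
            np.array([
                1 + t,
                1 + 0.97 * t + 0.03 * noise,
                1 + 0.9 * t + 0.3 * np.abs(noise),
            ]),
        )
        net = build_network(table, "pearson")
        rs = sorted(abs(res.r) for res in net.results.values())
        cut = (rs[0] + rs[1]) / 2  # keep exactly the two strongest pairs
        stats_ = topology_stats(net.with_filter(RangeFilter.min_abs(cut)))
        assert stats_.degree_histogram == {1: 2, 2: 1}
        assert stats_.average_neighbors == pytest.approx(4 / 3)
        assert stats_.neighborhood_connectivity == {1: pytest.approx(2.0), 2: pytest.approx(1.0)}
        # correlation histogram covers ALL stored pairs regardless of visibility
        assert sum(stats_.correlation_histogram.values()) == 3

    def test_complete_graph_k4(self):
        t = np.linspace(0, 1, 10)
        table = PeakTable(
            ["a", "b", "c", "d"],
            [f"s{i}" for i in range(10)],
            np.array([1 + t, 2 + 2 * t, 3 + t, 5 + 4 * t]),
        )
        stats_ = topology_stats(build_network(table, "pearson", RangeFilter.min_abs(0.99)))
        assert stats_.degree_histogram == {3: 4}
        assert stats_.neighborhood_connectivity == {3: pytest.approx(3.0)}
        assert stats_.average_neighbors == pytest.approx(3.0)


def test_benjamini_hochberg_monotone_and_bounded():
    rng = np.random.default_rng(9)
    p = rng.random(50)
    adj = benjamini_hochberg(p)
    assert np.all(adj >= p - 1e-15)
    assert np.all((0 <= adj) & (adj <= 1))
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)
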
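"""Graph metrics against hand-computed and brute-force oracles."""

import numpy as np
import pytest

from idionet.metrics import (
    betweenness,
    closeness,
    density_metrics,
    strength,
    to_distances,
)

from conftest import make_network, oracle_metrics, random_weighted_network

# Path graph A-B (w=0.5), B-C (w=0.25): d(A,B)=2, d(B,C)=4, d(A,C)=6.
PATH = make_network("ABC", {("A", "B"): 0.5, ("B", "C"): 0.25})


class TestDistances:
    def test_path_graph_hand_oracle(self):
        d = to_distances(PATH).to_frame()
        assert d.loc["A", "B"] == pytest.approx(2.0)
        assert d.loc["B", "C"] == pytest.approx(4.0)
        assert d.loc["A", "C"] == pytest.approx(6.0)

    def test_complete_graph_direct_edge_always_shortest(self):
        net = make_network(
            "ABC", {("A", "B"): 0.4, ("A", "C"): 0.4, ("B", "C"): 0.4}
        )
        d = to_distances(net).d
        off = d[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 2.5)

    def test_isolated_node_row_is_infinite(self):
        net = make_network("ABC", {("A", "B"): 0.5})
        d = to_distances(net).to_frame()
        assert np.isinf(d.loc["C", "A"]) and np.isinf(d.loc["C", "B"])
        assert d.loc["C", "C"] == 0.0

    def test_negative_weight_uses_magnitude(self):
        net = make_network("AB", {("A", "B"): -0.5})
        assert to_distances(net).d[0, 1] == pytest.approx(2.0)


class TestStrength:
    def test_direct_sum(self):
        net = make_network("ABC", {("A", "B"): 0.3, ("A", "C"): 0.2})
        s = strength(net)
        assert s["A"] == pytest.approx(0.5)
        assert s["B"] == pytest.approx(0.3)
        assert s["C"] == pytest.approx(0.2)

    def test_absolute_value_convention(self):
        net = make_network("AB", {("A", "B"): -0.3})
        assert strength(net)["A"] == pytest.approx(0.3)

    def test_empty_network(self):
        net = make_network("AB", {})
        assert (strength(net) == 0).all()


class TestCloseness:
    def test_path_graph_hand_oracle(self):
        c = closeness(PATH)
        assert c["A"] == pytest.approx(1 / 8)
        assert c["B"] == pytest.approx(1 / 6)
        assert c["C"] == pytest.approx(1 / 10)

    def test_disconnected_node_gets_zero_with_warning(self):
        net = make_network("ABC", {("A", "B"): 0.5})
        with pytest.warns(UserWarning, match="disconnected"):
            c = closeness(net)
        assert (c == 0).sum() == 3  # C unreachable poisons every node

    def test_two_node_network(self):
        net = make_network("AB", {("A", "B"): 0.5})
        assert closeness(net).tolist() == pytest.approx([0.5, 0.5])


class TestBetweenness:
    def test_path_graph_midpoint(self):
        b = betweenness(PATH)
        assert b.tolist() == pytest.approx([0.0, 1.0, 0.0])

    def test_equal_triangle_all_zero(self):
        net = make_network(
            "ABC", {("A", "B"): 0.5, ("B", "C"): 0.5, ("A", "C"): 0.5}
        )
        assert betweenness(net).tolist() == pytest.approx([0.0, 0.0, 0.0])

    def test_geodesic_tie_splits_fractionally(self):
        # d(A,C) direct = 4 equals the A-B-C detour (2+2): two geodesics,
        # so B carries half the A-C dependency.
        net = make_network(
            "ABC", {("A", "C"): 0.25, ("A", "B"): 0.5, ("B", "C"): 0.5}
        )
        assert betweenness(net)["B"] == pytest.approx(0.5)

    def test_matches_enumeration_oracle_on_random_graphs(self, rng):
        for _ in range(30):
            net = random_weighted_network(rng)
            oracle = oracle_metrics(net.w)
            np.testing.assert_allclose(
                betweenness(net).to_numpy(), oracle["betweenness"], atol=1e-9
            )

    def test_matches_networkx_brandes(self, rng):
        nx = pytest.importorskip("networkx")
        for _ in range(20):
            net = random_weighted_network(rng)
            g = nx.Graph()
            g.add_nodes_from(range(net.n_items))
            for i in range(net.n_items):
                for j in range(i + 1, net.n_items):
                    if net.w[i, j] != 0:
                        g.add_edge(i, j, length=1 / abs(net.w[i, j]))
            ref = nx.betweenness_centrality(g, weight="length", normalized=False)
            np.testing.assert_allclose(
                betweenness(net).to_numpy(),
                [ref[i] for i in range(net.n_items)],
                atol=1e-9,
            )


class TestDensityMetrics:
    def test_path_graph_hand_oracle(self):
        dm = density_metrics(PATH)
        assert dm.aspl == pytest.approx(4.0)
        assert dm.global_efficiency == pytest.approx((1 / 2 + 1 / 4 + 1 / 6) / 3)
        assert dm.fraction_reachable == 1.0

    def test_complete_graph_closed_form(self):
        w = 0.4
        net = make_network(
            "ABCD",
            {(a, b): w for a, b in [("A", "B"), ("A", "C"), ("A", "D"),
                                     ("B", "C"), ("B", "D"), ("C", "D")]},
        )
        dm = density_metrics(net)
        assert dm.aspl == pytest.approx(1 / w)
        assert dm.global_efficiency == pytest.approx(w)

    def test_two_isolated_nodes(self):
        net = make_network("AB", {})
        dm = density_metrics(net)
        assert dm.global_efficiency == 0.0
        assert np.isnan(dm.aspl)
        assert dm.fraction_reachable == 0.0

    def test_partially_disconnected_excludes_pairs_with_warning(self):
        net = make_network("ABC", {("A", "B"): 0.5})
        with pytest.warns(UserWarning, match="unreachable"):
            dm = density_metrics(net)
        assert dm.aspl == pytest.approx(2.0)
        assert dm.fraction_reachable == pytest.approx(1 / 3)


class TestInvariants:
    def test_all_metrics_match_oracle_on_random_graphs(self, rng):
        for _ in range(30):
            net = random_weighted_network(rng)
            oracle = oracle_metrics(net.w)
            np.testing.assert_allclose(to_distances(net).d, oracle["dist"], atol=1e-9)
            np.testing.assert_allclose(
                strength(net).to_numpy(), oracle["strength"], atol=1e-9
            )
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                np.testing.assert_allclose(
                    closeness(net).to_numpy(), oracle["closeness"], atol=1e-9
                )
                dm = density_metrics(net)
            if np.isnan(oracle["aspl"]):
                assert np.isnan(dm.aspl)
            else:
                assert dm.aspl == pytest.approx(oracle["aspl"], abs=1e-9)
            assert dm.global_efficiency == pytest.approx(
                oracle["global_efficiency"], abs=1e-9
            )

    def test_strengthening_an_edge_shrinks_distances_and_raises_efficiency(
        self, rng
    ):
        import warnings

        for _ in range(10):
            net = random_weighted_network(rng, n_nodes=5, density=0.5)
            i, j = 0, 1
            w2 = net.w.copy()
            w2[i, j] = w2[j, i] = min(0.95, abs(w2[i, j]) + 0.3)
            net2 = make_network([f"n{k}" for k in range(5)],
                                {})
            net2.w = w2
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                d1, d2 = to_distances(net).d, to_distances(net2).d
                e1 = density_metrics(net).global_efficiency
                e2 = density_metrics(net2).global_efficiency
            assert (d2 <= d1 + 1e-12).all()
            assert e2 >= e1 - 1e-12

    def test_permutation_equivariance(self, rng):
        net = random_weighted_network(rng, n_nodes=6)
        perm = list(rng.permutation(6))
        net_p = net.permuted(perm)
        np.testing.assert_allclose(
            strength(net_p).to_numpy(), strength(net).to_numpy()[perm], atol=1e-12
        )
        np.testing.assert_allclose(
            betweenness(net_p).to_numpy(),
            betweenness(net).to_numpy()[perm],
            atol=1e-9,
        )

    def test_closeness_positive_iff_fully_reachable(self, rng):
        import warnings

        for _ in range(10):
            net = random_weighted_network(rng, density=0.4)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                c = closeness(net)
            d = to_distances(net).d
            for i in range(net.n_items):
                reachable = np.isfinite(np.delete(d[i], i)).all()
                assert (c.iloc[i] > 0) == (reachable and net.n_items > 1)
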
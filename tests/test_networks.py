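import numpy as np
import pandas as pd
import pytest

import microstab as ms


def net_from_edges(nodes, edges):
    return ms.InteractionNetwork(
        nodes=list(nodes),
        edges=pd.DataFrame(edges, columns=["source", "target", "weight"]),
    )


class TestSubjectNetwork:
    def test_zero_abundance_node_excluded(self, two_taxon_model):
        m = ms.CLVModel(
            ["a", "b", "d"], 2,
            [0.1, 0.2, 0],
            [[-1.0, 0.5, 0], [0.3, -1.0, 0], [0, 0, 0]],
            np.zeros((3, 0)),
        )
        net = ms.subject_network(m, [0.5, 0.0, 0.5])
        assert net.nodes == ["a", "d"]
        assert not ((net.edges["source"] == "b") | (net.edges["target"] == "b")).any()

    def test_zero_matrix_gives_edgeless_network(self):
        m = ms.CLVModel(["a", "b", "d"], 2, np.zeros(3), np.zeros((3, 3)), np.zeros((3, 0)))
        net = ms.subject_network(m, [0.3, 0.3, 0.4])
        assert net.n_edges == 0
        assert ms.network_stats(net).C == 0.0

    def test_full_support_edge_count_matches_nonzero_pattern(self, small_cohort):
        model = small_cohort[0]
        pi0 = np.full(model.n_taxa, 1 / model.n_taxa)
        net = ms.subject_network(model, pi0)
        expected = int((model.A != 0).sum())  # denominator row already zero
        assert net.n_edges == expected

    def test_denominator_has_no_incoming_edges(self, small_cohort):
        model = small_cohort[0]
        pi0 = np.full(model.n_taxa, 1 / model.n_taxa)
        net = ms.subject_network(model, pi0)
        dname = model.taxon_names[model.denominator]
        assert not (net.edges["target"] == dname).any()


class TestNetworkStats:
    def test_connectance_definition(self):
        net = net_from_edges(
            "abc",
            [["a", "b", 1.0], ["b", "a", 1.0], ["a", "c", 1.0], ["c", "b", 1.0]],
        )
        assert ms.network_stats(net).C == pytest.approx(4 / 3)

    def test_degree_heterogeneity_population_variance(self):
        # degrees (2, 1, 1) -> population variance 2/9
        net = net_from_edges("abc", [["a", "b", 1.0]])
        stats = ms.network_stats(net)
        assert stats.H == pytest.approx(2 / 9)

    def test_reciprocal_strengths_hand_example(self):
        # A_12 = -1 (edge b->a), A_21 = -2 (edge a->b), N = 3
        net = net_from_edges("abc", [["b", "a", -1.0], ["a", "b", -2.0]])
        stats = ms.network_stats(net)
        assert stats.S_c == pytest.approx(0.5)
        assert stats.S_m == pytest.approx(0.0)
        assert stats.S == pytest.approx(1.5)

    def test_relabelling_invariance(self):
        e1 = [["a", "b", -1.0], ["b", "a", -2.0], ["c", "a", 0.5]]
        e2 = [["x", "y", -1.0], ["y", "x", -2.0], ["z", "x", 0.5]]
        s1 = ms.network_stats(net_from_edges("abc", e1))
        s2 = ms.network_stats(net_from_edges("xyz", e2))
        for key in ("C", "H", "S", "S_c", "S_m"):
            assert getattr(s1, key) == pytest.approx(getattr(s2, key))


class TestDecompositionB:
    def test_reference_values(self):
        assert ms.decomposition_b(100, 10) == pytest.approx(2.0)
        assert ms.decomposition_b(7, 7) == pytest.approx(1.0)

    def test_monotone_in_edges(self):
        assert ms.decomposition_b(20, 10) > ms.decomposition_b(10, 10)

    def test_edgeless_flagged_missing(self):
        assert np.isnan(ms.decomposition_b(0, 5))


class TestExchangeIndices:
    def test_hand_worked_pair(self):
        ex = pd.DataFrame(
            [
                ["X", "a", "import"], ["X", "b", "import"], ["X", "c", "export"],
                ["Y", "b", "import"], ["Y", "c", "import"], ["Y", "a", "export"],
            ],
            columns=["genus", "metabolite", "direction"],
        )
        idx = ms.exchange_indices(ex, prevalence_cap=1.0)
        row = idx.iloc[0]
        assert row["crossfeeding"] == pytest.approx(2 / 3)
        assert row["competition"] == pytest.approx(1 / 3)

    def test_pure_competition(self):
        ex = pd.DataFrame(
            [["X", "a", "import"], ["Y", "a", "import"]],
            columns=["genus", "metabolite", "direction"],
        )
        idx = ms.exchange_indices(ex, prevalence_cap=1.0)
        assert idx.iloc[0]["competition"] == pytest.approx(1.0)
        assert idx.iloc[0]["crossfeeding"] == pytest.approx(0.0)

    def test_ubiquitous_metabolite_filtered(self):
        ex = pd.DataFrame(
            [
                ["X", "ubiq", "import"], ["Y", "ubiq", "import"], ["Z", "ubiq", "import"],
                ["X", "rare", "import"], ["Y", "rare", "import"],
            ],
            columns=["genus", "metabolite", "direction"],
        )
        idx = ms.exchange_indices(ex, prevalence_cap=0.7)
        xy = idx[(idx.genus_x == "X") & (idx.genus_y == "Y")].iloc[0]
        # ubiq participates in every pair -> dropped; only 'rare' remains
        assert xy["competition"] == pytest.approx(1.0)
        xz = idx[(idx.genus_x == "X") & (idx.genus_y == "Z")].iloc[0]
        assert xz["competition"] == 0.0


class TestExchangeNetwork:
    def test_zero_indices_give_edgeless(self):
        idx = pd.DataFrame(
            [["X", "Y", 0.0, 0.0]],
            columns=["genus_x", "genus_y", "crossfeeding", "competition"],
        )
        net, stats = ms.exchange_network(idx, ["X", "Y"])
        assert net.n_edges == 0
        assert stats.C == 0.0

    def test_single_pair_strengths(self):
        idx = pd.DataFrame(
            [["X", "Y", 0.4, 0.0]],
            columns=["genus_x", "genus_y", "crossfeeding", "competition"],
        )
        net, stats = ms.exchange_network(idx, ["X", "Y"])
        assert net.n_edges == 2  # one undirected pair as two directed edges
        assert stats.S_m == pytest.approx(0.4)
        assert stats.S_c == pytest.approx(0.0)
        assert stats.S == pytest.approx(0.2)  # mean of (0.4, 0) then non-zero average

    def test_uncovered_baseline_taxon_dropped(self):
        idx = pd.DataFrame(
            [["X", "Y", 0.4, 0.1]],
            columns=["genus_x", "genus_y", "crossfeeding", "competition"],
        )
        with pytest.warns(UserWarning, match="without exchange coverage"):
            net, _ = ms.exchange_network(idx, ["X", "Y", "Zmissing"])
        assert "Zmissing" not in net.nodes


class TestSyntheticExchangeConsistency:
    def test_reciprocal_negative_pair_scores_competition(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = -0.5
        m = ms.CLVModel(["w", "x", "y", "d"], 3, np.zeros(4), A, np.zeros((4, 0)))
        ex = ms.generate_exchange_table(m, noise_rate=0.0, seed=0)
        idx = ms.exchange_indices(ex, prevalence_cap=1.0)
        pair = idx[(idx.genus_x == "w") & (idx.genus_y == "x")].iloc[0]
        assert pair["competition"] > 0
        assert pair["crossfeeding"] == 0.0

    def test_reciprocal_positive_pair_scores_crossfeeding(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 0.5
        m = ms.CLVModel(["w", "x", "y", "d"], 3, np.zeros(4), A, np.zeros((4, 0)))
        ex = ms.generate_exchange_table(m, noise_rate=0.0, seed=0)
        idx = ms.exchange_indices(ex, prevalence_cap=1.0)
        pair = idx[(idx.genus_x == "w") & (idx.genus_y == "x")].iloc[0]
        assert pair["crossfeeding"] > 0

    def test_deterministic(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = -0.5
        m = ms.CLVModel(["w", "x", "y", "d"], 3, np.zeros(4), A, np.zeros((4, 0)))
        a = ms.generate_exchange_table(m, noise_rate=0.5, seed=5)
        b = ms.generate_exchange_table(m, noise_rate=0.5, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestStabilityNetworkAssociations:
    def test_self_association_is_perfect(self):
        rng = np.random.default_rng(0)
        n = 40
        values = rng.normal(size=n)
        panel = pd.DataFrame(
            {
                "stp_bc": values,
                "delta_t": rng.integers(1, 10, n),
                "shannon_baseline": rng.normal(2, 0.1, n),
                "intervention": ["none"] * n,
            },
            index=[f"s{i}" for i in range(n)],
        )
        net = pd.DataFrame({"C": values}, index=panel.index)
        out = ms.stability_network_associations(panel, net, metric_cols=["stp_bc"])
        row = out[(out.stat == "C") & (out.metric == "stp_bc")].iloc[0]
        assert row["r"] == pytest.approx(1.0)

    def test_constant_statistic_flagged(self):
        rng = np.random.default_rng(1)
        n = 30
        panel = pd.DataFrame(
            {
                "stp_bc": rng.normal(size=n),
                "delta_t": rng.integers(1, 10, n),
                "shannon_baseline": rng.normal(2, 0.1, n),
                "intervention": ["none"] * n,
            },
            index=[f"s{i}" for i in range(n)],
        )
        net = pd.DataFrame({"C": np.ones(n)}, index=panel.index)
        out = ms.stability_network_associations(panel, net, metric_cols=["stp_bc"])
        assert out.iloc[0]["flag"] == "constant"

    def test_underpowered_flagged(self):
        panel = pd.DataFrame(
            {
                "stp_bc": [0.1, 0.2, 0.3],
                "delta_t": [1, 2, 3],
                "shannon_baseline": [2.0, 2.1, 2.2],
                "intervention": ["none"] * 3,
            },
            index=["a", "b", "c"],
        )
        net = pd.DataFrame({"C": [1.0, 2.0, 3.0]}, index=panel.index)
        out = ms.stability_network_associations(panel, net, metric_cols=["stp_bc"])
        assert out.iloc[0]["flag"] == "underpowered"
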
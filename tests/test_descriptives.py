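"""Descriptive network statistics against hand counts and enumeration."""

import numpy as np
import pytest

from alaamnet.data import TieRecord
from alaamnet.descriptives import (
    acceptance_prevalence,
    centrality_by_group,
    centrality_profile,
    composition_summary,
    degree_stats,
    density,
    ego_alter_crosstab,
    isolates,
    jaccard_overlap,
    network_summary,
    perception_summary,
    reciprocity,
    transitivity,
)
from conftest import make_network, make_person
from oracles import brute_centralities, random_arcs


class TestDensity:
    def test_two_arcs_among_three_nodes(self):
        assert density(make_network([(0, 1), (1, 2)], 3, True)) == pytest.approx(2 / 6)

    def test_complete_directed_triad(self):
        arcs = [(i, j) for i in range(3) for j in range(3) if i != j]
        assert density(make_network(arcs, 3, True)) == 1.0

    def test_undirected_denominator(self):
        assert density(make_network([(0, 1)], 3, False)) == pytest.approx(1 / 3)

    def test_single_node_undefined(self):
        with pytest.raises(ValueError):
            density(make_network([], 1, True))


class TestReciprocity:
    def test_hand_enumeration(self):
        net = make_network([(0, 1), (1, 0), (0, 2)], 3, True)
        assert reciprocity(net) == pytest.approx(2 / 3)

    def test_no_mutual_pairs(self):
        assert reciprocity(make_network([(0, 1), (1, 2)], 3, True)) == 0.0

    def test_symmetrized_network_is_one(self, rng):
        arcs = random_arcs(rng, 6, 0.4, True)
        sym = list({a for (i, j) in arcs for a in [(i, j), (j, i)]})
        assert reciprocity(make_network(sym, 6, True)) == 1.0

    def test_empty_tie_set_undefined(self):
        with pytest.raises(ValueError):
            reciprocity(make_network([], 3, True))


class TestTransitivity:
    def test_triangle(self):
        assert transitivity(make_network([(0, 1), (1, 2), (0, 2)], 3, False)) == 1.0

    def test_path_has_no_closure(self):
        assert transitivity(make_network([(0, 1), (1, 2)], 3, False)) == 0.0

    def test_enumerated_four_node_graph(self):
        # edges {01,02,12,23}: 5 connected triples, 3 closed
        net = make_network([(0, 1), (0, 2), (1, 2), (2, 3)], 4, False)
        assert transitivity(net) == pytest.approx(3 / 5)

    def test_any_tree_is_zero(self, rng):
        arcs = [(i, int(rng.integers(i))) for i in range(1, 8)]
        assert transitivity(make_network(arcs, 8, False)) == 0.0

    def test_no_triples_undefined(self):
        with pytest.raises(ValueError):
            transitivity(make_network([(0, 1)], 4, False))


class TestIsolatesAndDegrees:
    def test_star_plus_two_lone_nodes(self):
        net = make_network([(0, 1), (0, 2), (0, 3)], 6, False)
        assert isolates(net) == 2

    def test_empty_graph_all_isolates(self):
        assert isolates(make_network([], 5, True)) == 5

    def test_out_degree_mean(self):
        stats = degree_stats(make_network([(0, 1), (0, 2)], 3, True))
        assert stats["mean_out_degree"] == pytest.approx(2 / 3)
        assert stats["range_in_degree"] == (0, 1)

    def test_undirected_clique_degrees(self):
        net = make_network([(0, 1), (0, 2), (1, 2)], 3, False)
        stats = degree_stats(net)
        assert stats["mean_out_degree"] == 2.0
        assert stats["mean_in_degree"] == 2.0


class TestCentrality:
    def test_directed_path_center(self):
        prof = centrality_profile(make_network([(0, 1), (1, 2)], 3, True))
        assert prof.loc["1", "betweenness"] == pytest.approx(1.0)
        assert prof.loc["0", "harmonic"] == pytest.approx(1.5)  # 1/1 + 1/2
        assert prof.loc["2", "harmonic"] == 0.0

    def test_isolate_has_zero_centrality(self):
        prof = centrality_profile(make_network([(0, 1)], 3, True))
        assert prof.loc["2", ["in_degree", "out_degree", "betweenness",
                              "harmonic"]].eq(0).all()

    @pytest.mark.parametrize("directed", [True, False])
    def test_matches_path_enumeration_oracle(self, rng, directed):
        for _ in range(25):
            n = int(rng.integers(3, 7))
            arcs = random_arcs(rng, n, 0.35, directed)
            net = make_network(arcs, n, directed)
            prof = centrality_profile(net)
            betw, harm = brute_centralities(arcs, n, directed)
            np.testing.assert_allclose(prof["betweenness"].to_numpy(), betw,
                                       atol=1e-9)
            np.testing.assert_allclose(prof["harmonic"].to_numpy(), harm,
                                       atol=1e-9)

    def test_group_summary_shapes(self, small_records):
        net = make_network([(0, 1)], 6, True)
        net = make_network([(0, 1)], 6, True)
        prof = centrality_profile(
            make_net_on_records(small_records, [("000101", "000102")]),
            small_records)
        by_role = centrality_by_group(prof, "community_role")
        assert "in_degree_median" in by_role.columns


def make_net_on_records(records, arcs, directed=True):
    from alaamnet.data import LayerNetwork

    return LayerNetwork([r.person_id for r in records], arcs, directed=directed)


class TestJaccard:
    def test_identical_edge_sets(self):
        a = make_network([(0, 1), (1, 2)], 3, True)
        b = make_network([(0, 1), (1, 2)], 3, True)
        assert jaccard_overlap(a, b) == 1.0

    def test_disjoint_edge_sets(self):
        a = make_network([(0, 1)], 3, True)
        b = make_network([(1, 2)], 3, True)
        assert jaccard_overlap(a, b) == 0.0

    def test_symmetric_and_unordered_against_undirected(self, rng):
        a = make_network([(0, 1), (2, 1)], 3, True)
        b = make_network([(1, 0)], 3, False)
        # compared as unordered pairs: {01,12} vs {01} -> 1/2
        assert jaccard_overlap(a, b) == pytest.approx(0.5)
        assert jaccard_overlap(a, b) == jaccard_overlap(b, a)

    def test_both_empty_undefined(self):
        with pytest.raises(ValueError):
            jaccard_overlap(make_network([], 3, True), make_network([], 3, True))


class TestCompositionAndCrosstabs:
    def test_kin_share_of_four_ties(self, small_records):
        ties = [TieRecord("000101", "000102", "chatting", kin=k,
                          ego_gender="woman", alter_gender="man")
                for k in (1, 1, 1, 0)]
        out = composition_summary(ties, small_records)
        assert out.loc[("all", "all"), "pct_kin"] == pytest.approx(75.0)

    def test_all_same_gender_is_hundred_pct(self, small_records):
        ties = [TieRecord("000101", "000103", "chatting", kin=0,
                          ego_gender="woman", alter_gender="woman")]
        out = composition_summary(ties, small_records)
        assert out.loc[("all", "all"), "pct_same_gender"] == pytest.approx(100.0)

    def test_crosstab_hand_counted(self, small_records):
        net = make_net_on_records(small_records, [
            ("000101", "000103"),  # 1-1
            ("000101", "000102"),  # 1-0
            ("000102", "000201"),  # 0-0
            ("000201", "000301"),  # 0-1
            ("000202", "000201"),  # 0-0
            ("000301", "000101"),  # 1-1
        ])
        outcome = {r.person_id: r.ipvaw_accept for r in small_records}
        tab = ego_alter_crosstab(net, outcome)
        assert tab.loc[1, 1] == 2 and tab.loc[1, 0] == 1
        assert tab.loc[0, 0] == 2 and tab.loc[0, 1] == 1
        assert tab.to_numpy().sum() == net.n_ties

    def test_crosstab_all_accepting_single_cell(self, small_records):
        accepting = [r for r in small_records if r.ipvaw_accept == 1]
        net = make_net_on_records(accepting, [("000101", "000103")])
        tab = ego_alter_crosstab(net, {r.person_id: 1 for r in accepting})
        assert tab.loc[1, 1] == 1 and tab.to_numpy().sum() == 1


class TestPerceptions:
    def test_all_zero_perceptions(self):
        records = [make_person(str(i), perceived_pct_men=0,
                               perceived_pct_women=0) for i in range(5)]
        out = perception_summary(records)
        assert out.loc["all", "pct_men_gt0"] == 0.0
        assert out.loc["all", "pct_women_gt50"] == 0.0

    def test_hand_counted_shares(self):
        men_vals = [0, 0, 10, 20, 30, 60, 90, 0, 10, 50]
        records = [make_person(str(i), perceived_pct_men=v,
                               perceived_pct_women=0)
                   for i, v in enumerate(men_vals)]
        out = perception_summary(records)
        assert out.loc["all", "pct_men_gt0"] == pytest.approx(70.0)
        assert out.loc["all", "pct_men_gt10"] == pytest.approx(50.0)
        assert out.loc["all", "pct_men_gt50"] == pytest.approx(20.0)

    def test_prevalence_by_gender(self, small_records):
        prev = acceptance_prevalence(small_records)
        assert prev["overall"] == pytest.approx(100 * 3 / 6)
        assert prev["woman"] == pytest.approx(100 * 2 / 3)


def test_network_summary_bounds(rng):
    for directed in (True, False):
        arcs = random_arcs(rng, 10, 0.25, directed)
        net = make_network(arcs, 10, directed)
        s = network_summary(net)
        assert 0 <= s.density <= 1
        if not np.isnan(s.reciprocity):
            assert 0 <= s.reciprocity <= 1
        if not np.isnan(s.transitivity):
            assert 0 <= s.transitivity <= 1
        assert s.n_isolates <= net.n
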
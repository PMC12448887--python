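"""Data model, file I/O, household construction, and alter matching."""

import textwrap

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alaamnet.data import (
    AlterNameRecord,
    CensusNameEntry,
    LayerNetwork,
    build_household_network,
    build_layer,
    levenshtein_similarity,
    match_alters,
    read_edge_list,
    read_node_table,
    write_edge_list,
    write_node_table,
)
from conftest import make_network, make_person
from oracles import naive_levenshtein

NODE_HEADER = ("person_id,household_id,village,gender,age,education,"
               "wealth_rank,community_role,ipvaw_accept,is_reporter,"
               "perceived_pct_men,perceived_pct_women\n")


def write_nodes(tmp_path, rows):
    path = tmp_path / "nodes.csv"
    path.write_text(NODE_HEADER + "".join(r + "\n" for r in rows))
    return path


GOOD_ROWS = [
    "000101,0001,1,woman,30,none,5,none,1,1,20,0",
    "000102,0001,1,man,45,some primary,3,kebele leader,0,0,0,0",
    "000201,0002,2,man,19,some secondary or beyond,8,none,0,1,50,10",
]


class TestReadNodeTable:
    def test_well_formed_rows_all_parse(self, tmp_path):
        records, report = read_node_table(write_nodes(tmp_path, GOOD_ROWS))
        assert len(records) == 3
        assert report.errors == []
        assert records[0].person_id == "000101"
        assert records[0].ipvaw_accept == 1
        assert records[1].community_role == "kebele leader"
        assert records[2].perceived_pct_women == 10

    @pytest.mark.parametrize("bad_row, n_expected", [
        ("000301,0003,1,woman,30,none,5,none,2,1,0,0", 3),      # outcome not 0/1
        ("000301,0003,1,woman,30,none,11,none,0,1,0,0", 3),     # wealth out of range
        ("000301,0003,1,woman,30,none,5,none,0,1,15,0", 3),     # pct not multiple of 10
        ("000301,0003,1,elder,30,none,5,none,0,1,0,0", 3),      # unknown gender level
        ("000101,0003,1,woman,30,none,5,none,0,1,0,0", 3),      # duplicate id
    ])
    def test_invalid_row_rejected_with_report(self, tmp_path, bad_row, n_expected):
        records, report = read_node_table(
            write_nodes(tmp_path, GOOD_ROWS + [bad_row]))
        assert len(records) == n_expected
        assert len(report.errors) == 1

    def test_missing_required_column_is_hard_error(self, tmp_path):
        path = tmp_path / "nodes.csv"
        path.write_text("person_id,gender\n000101,woman\n")
        with pytest.raises(ValueError, match="missing required columns"):
            read_node_table(path)

    def test_leading_zeros_preserved(self, tmp_path):
        records, _ = read_node_table(write_nodes(tmp_path, GOOD_ROWS))
        assert records[0].household_id == "0001"


class TestReadEdgeList:
    def test_two_arc_file(self, tmp_path):
        path = tmp_path / "edges.csv"
        path.write_text("ego_id,alter_id,kin\n000101,000102,1\n000102,000201,0\n")
        ties, report = read_edge_list(path, "chatting")
        assert len(ties) == 2
        assert ties[0].kin == 1 and ties[1].kin == 0
        assert report.errors == []

    def test_self_loop_rejected(self, tmp_path):
        path = tmp_path / "edges.csv"
        path.write_text("ego_id,alter_id\n000101,000101\n000101,000102\n")
        ties, report = read_edge_list(path, "chatting")
        assert len(ties) == 1
        assert len(report.errors) == 1 and "self-loop" in report.errors[0]

    def test_unmatched_alter_flagged_and_excluded_from_network(self, tmp_path):
        records = [make_person("a"), make_person("b")]
        path = tmp_path / "edges.csv"
        path.write_text("ego_id,alter_id\na,b\na,zzz\n")
        ties, _ = read_edge_list(path, "chatting", records)
        assert [t.matched for t in ties] == [1, 0]
        net = build_layer(ties, records, "chatting")
        assert net.n_ties == 1

    def test_roundtrip_through_writers(self, tmp_path, small_records):
        write_node_table(small_records, tmp_path / "n.csv")
        back, report = read_node_table(tmp_path / "n.csv")
        assert report.errors == []
        assert [r.person_id for r in back] == [r.person_id for r in small_records]
        path = tmp_path / "e.csv"
        ties, _ = read_edge_list_fixture(path)
        write_edge_list(ties, path)
        again, rep2 = read_edge_list(path, "chatting")
        assert len(again) == len(ties) and rep2.errors == []


def read_edge_list_fixture(path):
    path.write_text("ego_id,alter_id,kin\n000101,000102,1\n000102,000201,0\n")
    return read_edge_list(path, "chatting")


class TestHouseholdNetwork:
    def test_household_of_three_is_a_clique(self):
        records = [make_person(p, household_id="h1") for p in "abc"]
        net = build_household_network(records)
        assert net.n_ties == 3 and not net.directed

    def test_multi_household_head_bridges_but_members_do_not(self):
        records = [make_person("h", household_id="A"),
                   make_person("a1", household_id="A"),
                   make_person("b1", household_id="B"),
                   make_person("b2", household_id="B")]
        net = build_household_network(records, head_map={"h": ["B"]})
        pairs = {tuple(sorted((net.nodes[i], net.nodes[j]))) for i, j in net.arcs}
        assert tuple(sorted(("h", "a1"))) in pairs
        assert tuple(sorted(("h", "b1"))) in pairs
        assert tuple(sorted(("h", "b2"))) in pairs
        assert tuple(sorted(("a1", "b1"))) not in pairs
        assert tuple(sorted(("a1", "b2"))) not in pairs
        # B's own clique is intact
        assert tuple(sorted(("b1", "b2"))) in pairs

    def test_singleton_households_become_isolates(self):
        records = [make_person("a", household_id="h1"),
                   make_person("b", household_id="h2")]
        net = build_household_network(records)
        assert net.n_ties == 0 and net.n == 2

    def test_mutual_arc_encoding_has_reciprocity_one(self):
        from alaamnet.descriptives import reciprocity

        records = [make_person(p, household_id="h1") for p in "abc"]
        assert reciprocity(build_household_network(records)) == 1.0


class TestTranspose:
    def test_arcs_reversed(self):
        net = make_network([(0, 1), (1, 2)], 3, directed=True)
        t = net.transpose()
        assert sorted(t.arcs) == [(1, 0), (2, 1)]

    def test_involution(self):
        net = make_network([(0, 1), (1, 2), (2, 0)], 3, directed=True)
        assert net.transpose().transpose() == net

    def test_undirected_returned_unchanged(self):
        net = make_network([(0, 1)], 2, directed=False)
        assert net.transpose() == net

    def test_degree_sequences_swap(self, rng):
        from oracles import random_arcs

        arcs = random_arcs(rng, 8, 0.3, directed=True)
        net = make_network(arcs, 8, directed=True)
        t = net.transpose()
        assert np.array_equal(net.in_degrees(), t.out_degrees())
        assert np.array_equal(net.out_degrees(), t.in_degrees())
        assert net.n_ties == t.n_ties


CENSUS = [
    CensusNameEntry("01", "Abebe", "Kebede", "Tulu", "man"),
    CensusNameEntry("02", "Abeba", "Kebede", "Tulu", "woman"),
    CensusNameEntry("03", "Chaltu", "Gemechu", "Dinsa", "woman"),
]


class TestMatchAlters:
    def test_exact_match_has_similarity_one(self):
        alter = AlterNameRecord("Chaltu", "Gemechu", "Dinsa", gender="woman")
        report = match_alters([alter], CENSUS)
        assert report.results[0].person_id == "03"
        assert report.results[0].similarity == pytest.approx(1.0)

    def test_dissimilar_alter_unmatched(self):
        alter = AlterNameRecord("Xxxxxxxx", "Yyyyyyyy", "Zzzzzzzz")
        report = match_alters([alter], CENSUS)
        assert report.results[0].person_id is None
        assert report.match_rate == 0.0

    def test_one_char_typo_matches_with_oracle_similarity(self):
        alter = AlterNameRecord("Chalte", "Gemechu", "Dinsa", gender="woman")
        report = match_alters([alter], CENSUS)
        assert report.results[0].person_id == "03"
        expected = np.mean([
            1 - naive_levenshtein("chalte", "chaltu") / 6,
            1 - naive_levenshtein("gemechu", "gemechu") / 7,
            1 - naive_levenshtein("dinsa", "dinsa") / 5,
        ])
        assert report.results[0].similarity == pytest.approx(expected)

    def test_gender_hard_constraint(self):
        alter = AlterNameRecord("Abebe", "Kebede", "Tulu", gender="woman")
        report = match_alters([alter], CENSUS)
        assert report.results[0].person_id == "02"  # same-name man excluded

    def test_census_against_itself_is_identity(self):
        alters = [AlterNameRecord(c.given_name, c.father_name,
                                  c.grandfather_name, gender=c.gender)
                  for c in CENSUS]
        report = match_alters(alters, CENSUS)
        assert [r.person_id for r in report.results] == ["01", "02", "03"]

    def test_tie_broken_by_smallest_person_id(self):
        census = [CensusNameEntry("09", "Tola"), CensusNameEntry("02", "Tola")]
        report = match_alters([AlterNameRecord("Tola")], census)
        assert report.results[0].person_id == "02"

    def test_empty_census_all_unmatched(self):
        report = match_alters([AlterNameRecord("Tola")], [])
        assert report.results[0].person_id is None


@settings(max_examples=200, deadline=None)
@given(st.text(alphabet="abcde", max_size=12), st.text(alphabet="abcde", max_size=12))
def test_levenshtein_similarity_matches_dp_oracle(a, b):
    sim = levenshtein_similarity(a, b)
    if not a and not b:
        assert sim == 1.0
    else:
        assert sim == pytest.approx(
            1 - naive_levenshtein(a, b) / max(len(a), len(b)))


def test_layer_network_rejects_self_loops_and_duplicate_nodes():
    with pytest.raises(ValueError, match="self-loop"):
        make_network([(0, 0)], 2, directed=True)
    with pytest.raises(ValueError, match="duplicate"):
        LayerNetwork(["a", "a"], [], directed=True)
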
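import itertools
import math

import networkx as nx
import numpy as np
import pytest

from evoccur.netstruct import (
    GeneNetwork,
    KnowledgeGraph,
    build_networks,
    compute_metrics,
    cross_level_sharing,
    meta_network,
    rank_networks,
    score_from_p,
    score_genesets,
    score_network,
    structuring_percentages,
)
from evoccur.occurrence import GeneSelection


def kg_from_edges(edges, background=None):
    g = nx.Graph()
    g.add_edges_from(edges)
    return KnowledgeGraph(g, background_size=background)


def hypergeom_tail_oracle(k, bg, n_focus, draws):
    """Brute-force hypergeometric upper tail P(X >= k)."""
    total = math.comb(bg, draws)
    s = 0
    for i in range(k, min(n_focus, draws) + 1):
        s += math.comb(n_focus, i) * math.comb(bg - n_focus, draws - i)
    return s / total


class TestBuildNetworks:
    def test_two_disjoint_cliques(self):
        edges = list(itertools.combinations([f"A{i}" for i in range(10)], 2))
        edges += list(itertools.combinations([f"B{i}" for i in range(10)], 2))
        kg = kg_from_edges(edges)
        focus = {f"A{i}" for i in range(5)} | {f"B{i}" for i in range(5)}
        nets = build_networks(focus, kg, max_size=35)
        assert len(nets) == 2
        assert not (nets[0].members & nets[1].members)
        covered = set().union(*(n.focus for n in nets))
        assert covered == focus

    def test_large_module_splits_with_overlap_and_coverage(self):
        rng = np.random.default_rng(5)
        genes = [f"M{i:02d}" for i in range(40)]
        edges = [
            (a, b) for a, b in itertools.combinations(genes, 2)
            if rng.random() < 0.4
        ]
        kg = kg_from_edges(edges)
        focus = set(genes)
        nets = build_networks(focus, kg, max_size=35)
        assert len(nets) >= 2
        covered = set().union(*(n.focus for n in nets))
        assert covered == focus  # every focus gene appears somewhere
        assert any(
            a.members & b.members for a, b in itertools.combinations(nets, 2)
        )

    def test_isolated_focus_gene_two_node_network(self):
        kg = kg_from_edges([("ACAD9", "PARTNER")])
        (net,) = build_networks({"ACAD9"}, kg, max_size=35)
        assert net.members == {"ACAD9", "PARTNER"}
        assert net.focus == {"ACAD9"}

    def test_focus_without_edges_unreachable(self):
        g = nx.Graph()
        g.add_node("LONELY")
        g.add_edge("A", "B")
        kg = KnowledgeGraph(g)
        nets = build_networks({"LONELY", "A"}, kg, max_size=10)
        assert all("LONELY" not in n.members for n in nets)

    def test_max_size_respected(self):
        edges = list(itertools.combinations([f"G{i}" for i in range(50)], 2))
        kg = kg_from_edges(edges)
        nets = build_networks({f"G{i}" for i in range(50)}, kg, max_size=35)
        assert all(len(n.members) <= 35 for n in nets)

    def test_empty_focus_errors(self):
        with pytest.raises(ValueError):
            build_networks(set(), kg_from_edges([("A", "B")]), 35)

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        genes = [f"N{i:02d}" for i in range(60)]
        edges = [
            (a, b) for a, b in itertools.combinations(genes, 2)
            if rng.random() < 0.15
        ]
        kg = kg_from_edges(edges)
        focus = set(genes[::2])
        a = build_networks(focus, kg, 35)
        b = build_networks(focus, kg, 35)
        assert [(n.members, n.focus) for n in a] == [(n.members, n.focus) for n in b]


class TestScoreNetwork:
    def test_score_of_p_001_is_2(self):
        assert score_from_p(0.01) == pytest.approx(2.0)

    def test_score_of_p_1_is_0(self):
        assert score_from_p(1.0) == 0.0

    def test_matches_bruteforce_hypergeometric(self):
        kg = kg_from_edges([("A", "B")], background=1000)
        net = GeneNetwork(1, frozenset(f"g{i}" for i in range(35)),
                          frozenset(f"g{i}" for i in range(10)))
        score = score_network(net, kg, n_focus_total=100)
        p = hypergeom_tail_oracle(10, 1000, 100, 35)
        assert score == pytest.approx(-math.log10(p), abs=1e-9)

    def test_focus_exceeding_members_errors(self):
        net = GeneNetwork(1, frozenset({"a", "b"}), frozenset({"a", "b"}))
        kg = kg_from_edges([("A", "B")], background=100)
        with pytest.raises(ValueError):
            score_network(net, kg, n_focus_total=1)

    @pytest.mark.parametrize("members,focus", [(2, 1), (10, 4), (35, 20), (35, 35)])
    def test_oracle_agreement_grid(self, members, focus):
        kg = kg_from_edges([("A", "B")], background=2500)
        net = GeneNetwork(1, frozenset(f"g{i}" for i in range(members)),
                          frozenset(f"g{i}" for i in range(focus)))
        score = score_network(net, kg, n_focus_total=200)
        p = hypergeom_tail_oracle(focus, 2500, 200, members)
        assert 10 ** (-score) == pytest.approx(p, abs=1e-9)


class TestStructuringMetrics:
    def test_printed_common_pct(self):
        common_pct, _, _ = structuring_percentages(202, 63, 193)
        assert common_pct == 31.19

    def test_printed_specific_pct(self):
        _, specific, specific_pct = structuring_percentages(202, 63, 193)
        assert specific == 130
        assert specific_pct == 64.36

    def test_single_network_no_common(self):
        net = GeneNetwork(1, frozenset({"a", "b", "c"}), frozenset({"a", "b"}),
                          score=5.0, rank=1)
        m = compute_metrics([net], genes_output=10)
        assert m.common == 0
        assert m.common_pct == 0.0
        assert m.specific == m.main_size == 3
        assert m.eligible == 2

    def test_overlapping_networks(self):
        n1 = GeneNetwork(1, frozenset({"a", "b", "x"}), frozenset({"a", "b"}),
                         score=5.0, rank=1)
        n2 = GeneNetwork(2, frozenset({"b", "c", "y"}), frozenset({"b", "c"}),
                         score=3.0, rank=2)
        m = compute_metrics([n1, n2], genes_output=10)
        assert m.eligible == 3  # a, b, c
        assert m.common == 1    # b
        assert m.main_size == 3
        assert m.specific == 2  # main minus common-in-main
        assert m.best_score == 5.0


class TestMetaNetwork:
    def test_shared_genes_weight(self):
        a = GeneNetwork(1, frozenset({"x", "y", "a"}), frozenset({"a"}), 3.0, 1)
        b = GeneNetwork(2, frozenset({"x", "y", "b"}), frozenset({"b"}), 2.0, 2)
        c = GeneNetwork(3, frozenset({"z", "c"}), frozenset({"c"}), 1.0, 3)
        meta = meta_network([a, b, c], major_min_focus=1)
        assert meta.graph.edges[1, 2]["weight"] == 2
        assert {frozenset(comp) for comp in meta.components} == {
            frozenset({1, 2}), frozenset({3})
        }

    def test_chain_forms_single_component(self):
        nets = []
        for i in range(13):
            members = frozenset({f"s{i}", f"s{i+1}", f"u{i}"})
            nets.append(GeneNetwork(i + 1, members, frozenset({f"u{i}"}), 5.0, i + 1))
        meta = meta_network(nets, major_min_focus=1)
        assert len(meta.components) == 1
        assert meta.components[0] == set(range(1, 14))

    def test_no_sharing_all_singletons(self):
        nets = [
            GeneNetwork(i + 1, frozenset({f"a{i}", f"b{i}"}), frozenset({f"a{i}"}), 2.0, i + 1)
            for i in range(4)
        ]
        meta = meta_network(nets, major_min_focus=3)
        assert len(meta.components) == 4
        assert meta.major_ids == []


class TestCrossLevelSharing:
    def test_printed_56_5(self):
        strict = GeneNetwork(
            1,
            frozenset(f"f{i}" for i in range(23)) | frozenset({"l1", "l2"}),
            frozenset(f"f{i}" for i in range(23)),
            10.0, 1,
        )
        loose = GeneNetwork(
            1, frozenset(f"f{i}" for i in range(13)) | frozenset({"m1"}),
            frozenset(f"f{i}" for i in range(13)), 9.0, 1,
        )
        sm = cross_level_sharing([strict], [loose])
        assert sm.values[0, 0] == 56.5

    def test_subset_is_100(self):
        strict = GeneNetwork(1, frozenset({"a", "b"}), frozenset({"a", "b"}), 5.0, 1)
        loose = GeneNetwork(1, frozenset({"a", "b", "c"}), frozenset({"a"}), 4.0, 1)
        assert cross_level_sharing([strict], [loose]).values[0, 0] == 100.0

    def test_disjoint_is_0(self):
        strict = GeneNetwork(1, frozenset({"a"}), frozenset({"a"}), 5.0, 1)
        loose = GeneNetwork(1, frozenset({"z"}), frozenset(), 4.0, 1)
        assert cross_level_sharing([strict], [loose]).values[0, 0] == 0.0

    def test_empty_lists_error(self):
        with pytest.raises(ValueError):
            cross_level_sharing([], [])


def selection_of(genes):
    return GeneSelection(
        level=">=4/6", k_min=4, n_donors=6, ev_threshold=1.28,
        gene_ids=frozenset(genes), summary_ev={g: 2.0 for g in genes},
    )


class TestScoreGenesets:
    def test_perfect_overlap_matches_hypergeometric(self):
        genes = [f"g{i}" for i in range(10)]
        sets = {"S": frozenset(genes)}
        (row,) = score_genesets(selection_of(genes), sets, background_size=1000)
        p = hypergeom_tail_oracle(10, 1000, 10, 10)
        assert row["p"] == pytest.approx(p, rel=1e-9)
        assert row["score"] == pytest.approx(-math.log10(p), abs=1e-9)

    def test_disjoint_scores_zero(self):
        sets = {"S": frozenset({"x", "y"})}
        (row,) = score_genesets(selection_of(["a", "b"]), sets, background_size=100)
        assert row["p"] == pytest.approx(1.0)
        assert row["score"] == 0.0

    def test_set_equal_background_scores_zero(self):
        genes = [f"g{i}" for i in range(50)]
        sets = {"ALL": frozenset(genes)}
        (row,) = score_genesets(selection_of(genes[:5]), sets, background_size=50)
        assert row["p"] == pytest.approx(1.0)
        assert row["score"] == pytest.approx(0.0, abs=1e-12)


class TestRanking:
    def test_rank_by_score_then_focus(self):
        kg = kg_from_edges([("A", "B")], background=1000)
        big = GeneNetwork(1, frozenset(f"g{i}" for i in range(20)),
                          frozenset(f"g{i}" for i in range(10)))
        small = GeneNetwork(2, frozenset({"h1", "h2"}), frozenset({"h1"}))
        ordered = rank_networks([small, big], kg, n_focus_total=11)
        assert len(ordered[0].focus) >= len(ordered[1].focus)
        assert ordered[0].rank == 1
        assert ordered[0].score >= ordered[1].score
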
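import itertools
from fractions import Fraction

import networkx as nx
import pytest

from cipn_netgrow.core_analysis import (
    AnalysisConfig,
    AnalysisError,
    GeneNetwork,
    build_seed_networks,
    core_analysis,
    expand_network,
    grow_seed_network,
    map_focus_genes,
    merge_networks,
    rank_focus_genes,
    specific_connectivity,
)
from cipn_netgrow.knowledge_base import neighborhood
from cipn_netgrow.literature import FocusGeneSet
from cipn_netgrow.synthetic_kb import PlantedModule, SyntheticKBConfig, generate_kb

from conftest import kb_from_edges, kb_from_graph


def focus_set(genes):
    return FocusGeneSet(agent="synthetic", genes=tuple(genes))


class TestRanking:
    def test_k4_with_isolated_focus_gene(self, k4_kb):
        """All K4 members tie at triangular connectivity 3 and order
        lexicographically; the isolated focus gene is excluded."""
        k4_kb.ensure_molecule("E")
        ranking = rank_focus_genes(k4_kb, focus_set("EDCBA"))
        assert ranking.ranked == ["A", "B", "C", "D", "E"]
        assert ranking.excluded == ["E"]
        assert ranking.connectivity["A"] == 3

    def test_single_focus_gene(self, triangle_kb):
        ranking = rank_focus_genes(triangle_kb, ["A"])
        assert ranking.ranked == ["A"] and ranking.excluded == []

    def test_all_tie_star_is_lexicographic(self, star_kb):
        ranking = rank_focus_genes(star_kb, ["l2", "c", "l1"])
        assert ranking.ranked == ["c", "l1", "l2"]

    def test_unmapped_symbols_reported_not_dropped(self, triangle_kb):
        ranking = rank_focus_genes(triangle_kb, ["A", "NOPE"])
        assert ranking.unmapped == ["NOPE"]

    def test_symbol_mapping_falls_back_to_display_symbol(self):
        from cipn_netgrow.knowledge_base import KnowledgeBase, Molecule

        kb = KnowledgeBase(molecules=[Molecule("id1", symbol="GSTP1")])
        mapped, unmapped = map_focus_genes(kb, ["GSTP1"])
        assert mapped == ["id1"] and unmapped == []

    def test_no_mappable_focus_raises(self, triangle_kb):
        with pytest.raises(AnalysisError):
            rank_focus_genes(triangle_kb, ["X", "Y"])


class TestSeedNetworks:
    def test_star_center_seed_with_two_focus_leaves(self, star_kb):
        net = grow_seed_network(star_kb, "c", ["l1", "l3"])
        assert set(net.genes) == {"c", "l1", "l3"}
        assert net.provenance["c"][0] == "seed"
        assert net.provenance["l1"][0] == "neighborhood"

    def test_seed_without_focus_neighbors_is_singleton(self, star_kb):
        net = grow_seed_network(star_kb, "l1", ["l2"])
        assert net.genes == ["l1"]

    def test_one_hop_rule_excludes_two_hop_focus(self):
        """On a 4-cycle of focus genes the seed gains only its two direct
        neighbors; the diagonally opposite focus gene stays out."""
        kb = kb_from_edges(
            [("F1", "F2"), ("F2", "F3"), ("F3", "F4"), ("F4", "F1"),
             ("F1", "x1"), ("x1", "x2"), ("x2", "F3"), ("x1", "x3")]
        )
        net = grow_seed_network(kb, "F1", ["F2", "F3", "F4"])
        assert set(net.genes) == {"F1", "F2", "F4"}

    def test_disjoint_components_give_two_networks(self):
        kb = kb_from_edges([("A", "B"), ("C", "D")])
        nets, _ = build_seed_networks(kb, ["A", "B", "C", "D"])
        assert len(nets) == 2
        assert [sorted(n.genes) for n in nets] == [["A", "B"], ["C", "D"]]

    def test_mutually_adjacent_focus_gives_one_network(self, k4_kb):
        nets, _ = build_seed_networks(k4_kb, ["A", "B", "C", "D"])
        assert len(nets) == 1

    def test_planted_modules_recovered_as_seed_networks(self):
        """Two fully dense planted modules produce exactly two seed networks
        whose focus sets equal the planted assignments."""
        cfg = SyntheticKBConfig(
            n_background=300,
            planted_modules=(
                PlantedModule(10, 6, intra_density=1.0, attach_edges=2),
                PlantedModule(10, 5, intra_density=1.0, attach_edges=2),
            ),
            seed=11,
        )
        kb, truth = generate_kb(cfg)
        nets, _ = build_seed_networks(kb, sorted(truth.all_focus()))
        assert len(nets) == 2
        assert {frozenset(n.focus_genes) for n in nets} == {
            frozenset(truth.focus["module1"]),
            frozenset(truth.focus["module2"]),
        }

    def test_coverage_and_disjointness(self):
        g = nx.gnp_random_graph(40, 0.1, seed=3)
        kb = kb_from_graph(g)
        focus = [str(i) for i in range(0, 40, 3)]
        nets, ranking = build_seed_networks(kb, focus)
        covered = [g for n in nets for g in n.focus_genes]
        assert len(covered) == len(set(covered))  # disjoint
        assert set(covered) | set(ranking.excluded) == set(focus)


class TestSpecificConnectivity:
    def test_identical_sets_score_one(self, star_kb):
        assert specific_connectivity(star_kb, "c", neighborhood(star_kb, "c")) == 1.0

    def test_disjoint_sets_score_zero(self):
        kb = kb_from_edges([("A", "B"), ("C", "D")])
        assert specific_connectivity(kb, "A", {"C", "D"}) == 0.0

    def test_set_arithmetic_example(self):
        """neighborhood(g) = {g,a,b,c}, network = {b,c,d} -> 2/5."""
        kb = kb_from_edges([("g", "a"), ("g", "b"), ("g", "c")], extra_nodes=["d"])
        assert specific_connectivity(kb, "g", {"b", "c", "d"}) == pytest.approx(0.4)

    def test_empty_network_rejected(self, triangle_kb):
        with pytest.raises(ValueError):
            specific_connectivity(triangle_kb, "A", set())


class TestMerging:
    def test_single_bridge_merges_two_networks(self):
        kb = kb_from_edges(
            [("A", "B"), ("C", "D"), ("x", "A"), ("x", "C")]
        )
        nets, _ = build_seed_networks(kb, ["A", "B", "C", "D"])
        merged = merge_networks(kb, nets, focus_ids={"A", "B", "C", "D"})
        assert len(merged) == 1
        assert "x" in merged[0].genes
        assert merged[0].provenance["x"][0] == "bridge"

    def test_no_bridge_is_noop(self):
        kb = kb_from_edges([("A", "B"), ("C", "D")])
        nets, _ = build_seed_networks(kb, ["A", "B", "C", "D"])
        merged = merge_networks(kb, nets, focus_ids={"A", "B", "C", "D"})
        assert len(merged) == 2

    def test_focus_gene_cannot_bridge(self):
        kb = kb_from_edges([("A", "B"), ("C", "D"), ("f", "A"), ("f", "C")])
        focus = {"A", "B", "C", "D", "f"}
        nets, _ = build_seed_networks(kb, sorted(focus))
        # f joins A's seed network via the one-hop rule; C-D stays separate
        merged = merge_networks(kb, nets, focus_ids=focus)
        assert len(merged) == 2

    def test_three_modules_sharing_one_hub_fully_merge(self):
        edges = []
        for prefix in ("A", "B", "C"):
            trio = [f"{prefix}{i}" for i in range(3)]
            edges += list(itertools.combinations(trio, 2))
            edges.append(("hub", trio[0]))
        kb = kb_from_edges(edges)
        focus = {f"{p}{i}" for p in "ABC" for i in range(3)}
        nets, _ = build_seed_networks(kb, sorted(focus))
        assert len(nets) == 3
        merged = merge_networks(kb, nets, focus_ids=focus)
        assert len(merged) == 1
        assert "hub" in merged[0].genes
        assert merged[0].focus_genes == focus

    def test_size_cap_blocks_merge(self):
        kb = kb_from_edges([("A", "B"), ("C", "D"), ("x", "A"), ("x", "C")])
        nets, _ = build_seed_networks(kb, ["A", "B", "C", "D"])
        config = AnalysisConfig(max_network_size=4)
        merged = merge_networks(kb, nets, config, focus_ids={"A", "B", "C", "D"})
        assert len(merged) == 2  # 2+2+1 bridge = 5 > 4


def brute_force_expansion_order(kb, start_genes, cap):
    """Independent oracle: recompute every candidate's specific connectivity
    from scratch at every step, choose the maximum (lexicographic ties)."""
    members = list(start_genes)
    order = []
    while len(members) < cap:
        best = None
        for c in sorted(kb.molecules):
            if c in members:
                continue
            hood = neighborhood(kb, c)
            inter = len(hood & set(members))
            union = len(hood | set(members))
            sc = Fraction(inter, union)
            if sc > 0 and (best is None or sc > best[1]):
                best = (c, sc)
        if best is None:
            break
        members.append(best[0])
        order.append(best[0])
    return order


class TestExpansion:
    def test_network_at_cap_is_unchanged(self, k4_kb):
        net = GeneNetwork(genes=["A", "B"], focus_genes={"A", "B"})
        out = expand_network(k4_kb, net, AnalysisConfig(max_network_size=2))
        assert out.genes == ["A", "B"]

    def test_only_positive_scoring_candidate_added_first(self):
        # y's neighborhood is inside net ∪ {y}; z is disconnected from net
        kb = kb_from_edges([("A", "B"), ("y", "A"), ("y", "B"), ("z", "w")])
        net = GeneNetwork(genes=["A", "B"], focus_genes={"A", "B"})
        out = expand_network(kb, net, AnalysisConfig(max_network_size=3))
        assert out.genes == ["A", "B", "y"]
        assert out.provenance["y"][0] == "expansion"

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_admission_order_matches_stepwise_oracle(self, seed):
        """Greedy admission sequence equals exhaustive per-step recomputation
        on random instances of up to 50 nodes."""
        g = nx.gnp_random_graph(50, 0.08, seed=seed)
        kb = kb_from_graph(g)
        start = ["0", "1", "2"]
        cap = 20
        expected = brute_force_expansion_order(kb, start, cap)
        net = GeneNetwork(genes=list(start), focus_genes=set(start))
        out = expand_network(kb, net, AnalysisConfig(max_network_size=cap))
        assert out.genes[3:] == expected

    def test_admission_is_prefix_monotone_in_cap(self):
        """Raising max_network_size never changes genes admitted earlier."""
        g = nx.gnp_random_graph(60, 0.07, seed=9)
        kb = kb_from_graph(g)
        start = ["0", "1"]
        runs = {}
        for cap in (5, 10, 20):
            net = GeneNetwork(genes=list(start), focus_genes=set(start))
            runs[cap] = expand_network(
                kb, net, AnalysisConfig(max_network_size=cap)
            ).genes
        assert runs[10][: len(runs[5])] == runs[5]
        assert runs[20][: len(runs[10])] == runs[10]


class TestCoreAnalysis:
    def test_isolated_focus_gene_reported_not_networked(self):
        kb = kb_from_edges([("a", "b")], extra_nodes=["lone"])
        result = core_analysis(kb, ["lone"])
        assert result.networks == []
        assert result.excluded == ["lone"]

    def test_planted_module_recovery(self):
        """The top-scoring network recovers at least 90 % of the planted
        module's focus genes and is significant."""
        cfg = SyntheticKBConfig(
            n_background=3000,
            m_attach=2,
            planted_modules=(PlantedModule(30, 20, 0.4, 5),),
            seed=42,
        )
        kb, truth = generate_kb(cfg)
        result = core_analysis(kb, sorted(truth.all_focus()))
        top = result.networks[0]
        planted = truth.focus["module1"]
        recall = len(top.network.focus_genes & planted) / len(planted)
        assert recall >= 0.9
        assert top.score > 5 and top.significant

    def test_deterministic_including_provenance(self):
        cfg = SyntheticKBConfig(
            n_background=500,
            planted_modules=(PlantedModule(15, 8, 0.5, 3),),
            seed=4,
        )
        kb, truth = generate_kb(cfg)
        focus = sorted(truth.all_focus())
        r1 = core_analysis(kb, focus)
        r2 = core_analysis(kb, focus)
        assert [s.network.genes for s in r1.networks] == [
            s.network.genes for s in r2.networks
        ]
        assert [s.network.provenance for s in r1.networks] == [
            s.network.provenance for s in r2.networks
        ]
        assert [s.p_value for s in r1.networks] == [s.p_value for s in r2.networks]

    def test_size_and_count_caps_respected(self):
        cfg = SyntheticKBConfig(n_background=400, m_attach=2, scatter_focus=30, seed=8)
        kb, truth = generate_kb(cfg)
        config = AnalysisConfig(max_network_size=20, max_networks=3)
        result = core_analysis(kb, sorted(truth.all_focus()), config)
        assert len(result.networks) <= 3
        assert all(len(s.network.genes) <= 20 for s in result.networks)

    def test_focus_coverage_accounting(self):
        """Every mappable focus gene is either in exactly one network's focus
        set or excluded."""
        cfg = SyntheticKBConfig(n_background=400, m_attach=2, scatter_focus=25, seed=13)
        kb, truth = generate_kb(cfg)
        focus = sorted(truth.all_focus())
        result = core_analysis(kb, focus)
        owned = [g for s in result.networks for g in s.network.focus_genes]
        assert len(owned) == len(set(owned))
        assert set(owned) | set(result.excluded) == set(focus)
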
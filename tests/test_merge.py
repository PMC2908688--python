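"""Similarity measures, MRG construction, IGMM merging and refinement."""

import math
from itertools import combinations

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transmod import (
    ConfigurationError,
    ModuleSet,
    build_mrg,
    igmm,
    merge_clique,
    refine,
    sim_combined,
    sim_gene,
    sim_min_combined,
    sim_min_gene,
    sim_min_tissue,
    sim_tissue,
)
from conftest import make_module


def brute_force_overlap(a, b):
    """Independent oracle: count shared items by exhaustive comparison."""
    return sum(1 for x in a for y in b if x == y)


class TestSimilarityForms:
    def test_worked_example_gene_level(self, worked_example):
        h, m, orth, _ = worked_example
        assert round(sim_gene(h, m, orth), 3) == 0.401

    def test_identity_is_one_disjoint_is_zero(self):
        a = make_module("a", ["g1", "g2", "g3"], ["liver", "lung"])
        b = make_module("b", ["g4", "g5"], ["heart"])
        assert sim_gene(a, a) == 1.0
        assert sim_tissue(a, a) == 1.0
        assert sim_combined(a, a) == 1.0
        assert sim_gene(a, b) == 0.0
        assert sim_tissue(a, b) == 0.0
        assert sim_combined(a, b) == 0.0

    def test_tissue_level_hand_value(self):
        a = make_module("a", ["g1"], ["liver", "kidney"])
        b = make_module("b", ["g1"], ["liver"])
        assert sim_tissue(a, b) == pytest.approx(1 / math.sqrt(2))

    def test_combined_level_on_worked_example(self, worked_example):
        h, m, orth, _ = worked_example
        # identical single-tissue sets: (3 + 1) / sqrt((7+1)(8+1))
        assert sim_combined(h, m, orth) == pytest.approx(4 / math.sqrt(72))

    def test_min_cardinality_hand_values(self, worked_example):
        h, m, orth, _ = worked_example
        assert sim_min_gene(h, m, orth) == pytest.approx(3 / 7)
        sub = make_module("sub", ["g1", "g2"], ["liver"])
        sup = make_module("sup", ["g1", "g2", "g3", "g4"], ["liver", "lung"])
        assert sim_min_gene(sub, sup) == 1.0
        assert sim_min_tissue(sub, sup) == 1.0
        assert sim_min_combined(sub, sup) == 1.0

    def test_empty_sets_raise(self):
        a = make_module("a", ["g1"], [])
        b = make_module("b", ["g2"], ["liver"])
        with pytest.raises(ConfigurationError):
            sim_tissue(a, b)
        with pytest.raises(ConfigurationError):
            sim_combined(a, b)

    @settings(max_examples=200, derandomize=True)
    @given(
        ga=st.sets(st.integers(0, 15), min_size=1, max_size=10),
        gb=st.sets(st.integers(0, 15), min_size=1, max_size=10),
        ta=st.sets(st.integers(0, 5), min_size=1, max_size=4),
        tb=st.sets(st.integers(0, 5), min_size=1, max_size=4),
    )
    def test_axioms_against_brute_force_oracle(self, ga, gb, ta, tb):
        a = make_module("a", [f"g{i}" for i in ga], [f"t{i}" for i in ta])
        b = make_module("b", [f"g{i}" for i in gb], [f"t{i}" for i in tb])
        og = brute_force_overlap(sorted(a.genes), sorted(b.genes))
        ot = brute_force_overlap(sorted(a.tissues), sorted(b.tissues))
        for f, expected in [
            (sim_gene, og / math.sqrt(len(ga) * len(gb))),
            (sim_tissue, ot / math.sqrt(len(ta) * len(tb))),
            (sim_combined, (og + ot) / math.sqrt((len(ga) + len(ta)) * (len(gb) + len(tb)))),
            (sim_min_gene, og / min(len(ga), len(gb))),
            (sim_min_tissue, ot / min(len(ta), len(tb))),
            (sim_min_combined, (og + ot) / min(len(ga) + len(ta), len(gb) + len(tb))),
        ]:
            v, w = f(a, b), f(b, a)
            assert v == pytest.approx(expected)
            assert v == pytest.approx(w)          # symmetry
            assert 0.0 <= v <= 1.0                # range
        if ga <= gb:
            assert sim_min_gene(a, b) == 1.0      # nesting


class TestMergeClique:
    def test_two_modules_keep_exactly_the_intersection(self):
        a = make_module("a", ["g1", "g2", "g3"], ["liver", "lung"])
        b = make_module("b", ["g2", "g3", "g4"], ["liver"])
        merged = merge_clique([a, b], membership=0.8)
        # ceil(0.8 * 2) = 2 of 2 -> intersection
        assert merged.genes == {"g2", "g3"}
        assert merged.tissues == {"liver"}

    def test_item_in_four_of_five_is_kept(self):
        mods = [make_module(f"m{i}", ["core", f"u{i}"], ["liver"]) for i in range(5)]
        mods[0] = make_module("m0", ["core", "maybe"], ["liver"])
        for i in (1, 2, 3):
            mods[i].gene_scores["maybe"] = 1.0
        merged = merge_clique(mods, membership=0.8)
        # "maybe" sits in 4 of 5 parents: 4 >= ceil(4.0) -> kept
        assert "maybe" in merged.genes
        assert "core" in merged.genes
        assert all(f"u{i}" not in merged.genes for i in range(1, 5))

    def test_identical_modules_merge_to_themselves(self):
        mods = [make_module(f"m{i}", ["g1", "g2"], ["liver", "lung"])
                for i in range(4)]
        merged = merge_clique(mods)
        assert merged.genes == {"g1", "g2"}
        assert merged.tissues == {"liver", "lung"}

    def test_tissue_scores_are_signed_means_of_parents(self):
        a = make_module("a", ["g1", "g2"], tissue_scores={"liver": 2.0, "cd4": -1.0})
        b = make_module("b", ["g1", "g2"], tissue_scores={"liver": 4.0, "cd4": -3.0})
        merged = merge_clique([a, b])
        assert merged.tissue_scores["liver"] == pytest.approx(3.0)
        assert merged.tissue_scores["cd4"] == pytest.approx(-2.0)

    def test_empty_result_dissolves(self):
        a = make_module("a", ["g1"], ["liver"])
        b = make_module("b", ["g2"], ["lung"])
        assert merge_clique([a, b]) is None


class TestMrgAndIgmm:
    def test_low_similarity_gives_edgeless_graph(self, three_disjoint_modules):
        g = build_mrg(three_disjoint_modules, threshold=0.7)
        assert g.number_of_edges() == 0
        out = igmm(three_disjoint_modules)
        assert [m.content_key() for m in out] == \
               [m.content_key() for m in three_disjoint_modules]

    def test_identical_modules_give_single_edge_and_collapse(self):
        ms = ModuleSet([make_module("a", ["g1", "g2", "g3"], ["liver"]),
                        make_module("b", ["g1", "g2", "g3"], ["liver"])],
                       species="human")
        assert build_mrg(ms).number_of_edges() == 1
        out = igmm(ms)
        assert len(out) == 1
        assert out.modules[0].genes == {"g1", "g2", "g3"}

    def test_three_mutually_similar_modules_form_a_triangle(self):
        base = [f"g{i}" for i in range(10)]
        ms = ModuleSet([make_module("a", base, ["liver"]),
                        make_module("b", base[:9] + ["x"], ["liver"]),
                        make_module("c", base[:9] + ["y"], ["liver"])],
                       species="human")
        g = build_mrg(ms, threshold=0.7)
        cliques = sorted(sorted(c) for c in nx.find_cliques(g))
        assert cliques == [["a", "b", "c"]]

    def test_chain_resolves_deterministically(self):
        # A-B and B-C similar, A-C not: two maximal cliques sharing B.
        a = [f"g{i}" for i in range(10)]
        b = a[2:10] + ["x", "y"]           # |A&B| = 8 -> sim 0.8
        c = b[2:10] + ["u", "v"]           # |B&C| = 8, |A&C| = 6 -> sim 0.6
        ms = ModuleSet([make_module("A", a, ["liver"]),
                        make_module("B", b, ["liver"]),
                        make_module("C", c, ["liver"])], species="human")
        out1 = igmm(ms, threshold=0.7)
        out2 = igmm(ms, threshold=0.7)
        assert [m.content_key() for m in out1] == [m.content_key() for m in out2]
        # ties broken lexicographically: clique {A,B} merges first
        merged_ids = [m.module_id for m in out1]
        assert any("mrg" in mid for mid in merged_ids)

    def test_igmm_is_idempotent(self):
        rng = np.random.default_rng(8)
        pool = [f"g{i}" for i in range(30)]
        mods = []
        for i in range(6):
            genes = rng.choice(pool, size=12, replace=False)
            mods.append(make_module(f"m{i}", genes, ["liver"]))
        ms = ModuleSet(mods, species="human")
        once = igmm(ms)
        twice = igmm(once)
        assert [m.content_key() for m in once] == [m.content_key() for m in twice]

    def test_merging_never_invents_content(self):
        rng = np.random.default_rng(9)
        pool = [f"g{i}" for i in range(20)]
        mods = [make_module(f"m{i}", rng.choice(pool, size=10, replace=False),
                            ["liver", "lung"]) for i in range(5)]
        ms = ModuleSet(mods, species="human")
        out = igmm(ms, threshold=0.5)
        all_genes = set().union(*(m.genes for m in mods))
        for m in out:
            assert m.genes <= all_genes
            parents = m.provenance.get("merged_from")
            if parents:
                k = len(parents)
                need = math.ceil(0.8 * k)
                parent_mods = [p for p in mods if p.module_id in parents]
                if len(parent_mods) == k:  # first-round merge, parents are inputs
                    for g in m.genes:
                        assert sum(g in p.genes for p in parent_mods) >= need

    def test_maximal_cliques_match_brute_force_on_small_graphs(self):
        rng = np.random.default_rng(10)
        for trial in range(20):
            n = int(rng.integers(2, 9))
            g = nx.Graph()
            g.add_nodes_from(range(n))
            for i, j in combinations(range(n), 2):
                if rng.random() < 0.5:
                    g.add_edge(i, j)
            # brute force: every subset that is a clique and not extendable
            brute = []
            for size in range(1, n + 1):
                for sub in combinations(range(n), size):
                    if all(g.has_edge(i, j) for i, j in combinations(sub, 2)):
                        if not any(all(g.has_edge(i, k) for i in sub)
                                   for k in set(g) - set(sub)):
                            brute.append(set(sub))
            found = [set(c) for c in nx.find_cliques(g)]
            assert sorted(map(sorted, brute)) == sorted(map(sorted, found))


class TestRefine:
    def test_raw_module_surviving_unmerged_is_kept(self):
        raw = ModuleSet([make_module("a", ["g1", "g2"], ["liver"])], "human")
        merged = ModuleSet([make_module("a", ["g1", "g2"], ["liver"])],
                           "human", stage="merged")
        out = refine(merged, raw)
        assert len(out) == 1 and out.stage == "refined"

    def test_merged_module_containing_a_raw_module_is_kept(self):
        raw = ModuleSet([make_module("r", ["g1", "g2"], ["liver"])], "human")
        merged = ModuleSet(
            [make_module("m", ["g1", "g2", "g3"], ["liver", "lung"])],
            "human", stage="merged")
        assert len(refine(merged, raw)) == 1

    def test_merged_module_without_full_overlap_is_dropped(self):
        raw = ModuleSet([make_module("r", ["g1", "g2", "g3"], ["liver"])], "human")
        merged = ModuleSet([make_module("m", ["g2", "g3", "g4"], ["liver"])],
                           "human", stage="merged")
        assert len(refine(merged, raw)) == 0

    def test_tissue_mismatch_also_drops(self):
        raw = ModuleSet([make_module("r", ["g1", "g2"], ["liver", "lung"])], "human")
        merged = ModuleSet([make_module("m", ["g1", "g2"], ["heart"])],
                           "human", stage="merged")
        assert len(refine(merged, raw)) == 0
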
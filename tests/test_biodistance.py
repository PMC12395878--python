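"""Pathway filtering, chain extraction, pair generation, similarity decay."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from biosynkey import fixtures
from biosynkey.biodistance import (
    DistancePair,
    PathwayGraph,
    ReactionChain,
    decay_curve,
    filter_pathways,
    generate_pairs,
    longest_chain,
    shuffle_control,
)
from biosynkey.structio import record_from_smiles, skeleton_key

ALKANES = ["C" * n for n in range(1, 12)]  # distinct trivial structures


def linear_graph(n_nodes, pathway_id="p", smiles=None):
    smiles = smiles or ALKANES
    nodes = {
        f"c{i}": record_from_smiles(smiles[i % len(smiles)], f"c{i}")
        for i in range(n_nodes)
    }
    edges = tuple((f"c{i}", f"c{i+1}") for i in range(n_nodes - 1))
    return PathwayGraph(pathway_id=pathway_id, nodes=nodes, edges=edges)


class TestFilterPathways:
    def test_short_pathway_excluded(self):
        refs = [record_from_smiles("C", "ref")]
        assert filter_pathways([linear_graph(6)], refs) == []  # 5 reactions

    def test_long_pathway_without_natural_product_excluded(self):
        refs = [record_from_smiles("c1ccccc1", "ref")]  # not among alkanes
        assert filter_pathways([linear_graph(8)], refs) == []

    def test_six_reaction_pathway_with_reference_kept(self):
        graph = linear_graph(7)
        refs = [record_from_smiles("CCC", "ref")]  # matches node c2
        assert filter_pathways([graph], refs) == [graph]

    def test_reference_matching_ignores_stereochemistry(self):
        graph = linear_graph(7, smiles=["OC[C@H](O)CO"] + ALKANES)
        refs = [record_from_smiles("OC[C@@H](O)CO", "ref")]
        assert filter_pathways([graph], refs) == [graph]


class TestLongestChain:
    def test_linear_path_returned_whole(self):
        chain = longest_chain(linear_graph(7))
        assert chain.length == 6
        assert [c.id for c in chain.compounds] == [f"c{i}" for i in range(7)]

    def test_y_branch_takes_stem_plus_long_arm(self):
        # stem of 2 edges, then arms of 3 and 5 edges
        nodes = {
            f"n{i}": record_from_smiles(ALKANES[i % len(ALKANES)], f"n{i}")
            for i in range(11)
        }
        stem = [("n0", "n1"), ("n1", "n2")]
        short_arm = [("n2", "a0"), ("a0", "a1"), ("a1", "a2")]
        long_arm = [("n2", "b0"), ("b0", "b1"), ("b1", "b2"), ("b2", "b3"), ("b3", "b4")]
        for i in range(3):
            nodes[f"a{i}"] = record_from_smiles(ALKANES[i], f"a{i}")
        for i in range(5):
            nodes[f"b{i}"] = record_from_smiles(ALKANES[i + 3], f"b{i}")
        graph = PathwayGraph(
            pathway_id="y", nodes=nodes, edges=tuple(stem + short_arm + long_arm)
        )
        chain = longest_chain(graph)
        assert chain.length == 7
        assert [c.id for c in chain.compounds] == [
            "n0", "n1", "n2", "b0", "b1", "b2", "b3", "b4",
        ]

    def test_equal_length_paths_tie_break_lexicographically(self):
        nodes = {
            k: record_from_smiles(ALKANES[i], k)
            for i, k in enumerate(["a0", "a1", "b0", "b1"])
        }
        graph = PathwayGraph(
            pathway_id="tie", nodes=nodes, edges=(("b0", "b1"), ("a0", "a1"))
        )
        chain = longest_chain(graph)
        assert [c.id for c in chain.compounds] == ["a0", "a1"]

    def test_cycle_does_not_loop_forever(self):
        nodes = {k: record_from_smiles(ALKANES[i], k) for i, k in enumerate("abc")}
        graph = PathwayGraph(
            pathway_id="cyc", nodes=nodes, edges=(("a", "b"), ("b", "c"), ("c", "a"))
        )
        assert longest_chain(graph).length == 2

    def test_edgeless_graph_rejected(self):
        graph = PathwayGraph(
            pathway_id="e", nodes={"a": record_from_smiles("C", "a")}, edges=()
        )
        with pytest.raises(ValueError):
            longest_chain(graph)


class TestGeneratePairs:
    @pytest.mark.parametrize("length", range(1, 11))
    def test_per_distance_counts_match_enumeration(self, length):
        compounds = tuple(
            record_from_smiles(ALKANES[i % len(ALKANES)], f"c{i}")
            for i in range(length + 1)
        )
        chain = ReactionChain(pathway_id="p", compounds=compounds)
        pairs = generate_pairs(chain)
        # exhaustive expectation: every (x, x+n) with n <= min(6, L)
        expected = {
            n: length - n + 1 for n in range(1, min(6, length) + 1)
        }
        observed: dict[int, int] = {}
        for pair in pairs:
            observed[pair.n_reactions] = observed.get(pair.n_reactions, 0) + 1
        assert observed == expected

    def test_chain_of_two_compounds_gives_single_pair(self):
        chain = ReactionChain(
            pathway_id="p",
            compounds=(record_from_smiles("C", "a"), record_from_smiles("CC", "b")),
        )
        pairs = generate_pairs(chain)
        assert len(pairs) == 1
        assert pairs[0].n_reactions == 1

    def test_distances_never_exceed_n_max(self):
        compounds = tuple(
            record_from_smiles(ALKANES[i % len(ALKANES)], f"c{i}") for i in range(10)
        )
        pairs = generate_pairs(ReactionChain(pathway_id="p", compounds=compounds))
        assert max(p.n_reactions for p in pairs) == 6


class TestShuffleControl:
    @staticmethod
    def _pairs(n=12):
        return [
            DistancePair(
                compound_a=record_from_smiles(ALKANES[i % 11], f"a{i}"),
                compound_b=record_from_smiles(ALKANES[(i + 1) % 11], f"b{i}"),
                n_reactions=1,
            )
            for i in range(n)
        ]

    def test_deterministic_for_fixed_seed(self):
        pairs = self._pairs()
        one = shuffle_control(pairs, seed=5)
        two = shuffle_control(pairs, seed=5)
        assert [p.compound_b.id for p in one] == [p.compound_b.id for p in two]

    def test_partner_multiset_preserved(self):
        pairs = self._pairs()
        control = shuffle_control(pairs, seed=5)
        assert sorted(p.compound_b.id for p in control) == sorted(
            p.compound_b.id for p in pairs
        )
        assert all(p.is_control for p in control)

    def test_no_control_pair_is_a_self_pair(self):
        pairs = self._pairs()
        control = shuffle_control(pairs, seed=5)
        for pair in control:
            assert skeleton_key(pair.compound_a) != skeleton_key(pair.compound_b)

    def test_all_identical_molecules_is_impossible(self):
        pairs = [
            DistancePair(
                compound_a=record_from_smiles("CCO", f"a{i}"),
                compound_b=record_from_smiles("CCO", f"b{i}"),
                n_reactions=1,
            )
            for i in range(4)
        ]
        with pytest.raises(ValueError):
            shuffle_control(pairs, seed=0)


class TestDecayCurve:
    def test_identical_molecule_pairs_score_one_at_every_distance(self, registry):
        pairs = [
            DistancePair(
                compound_a=record_from_smiles("CC(C)CCO", f"a{n}"),
                compound_b=record_from_smiles("CC(C)CCO", f"b{n}"),
                n_reactions=n,
            )
            for n in range(1, 7)
        ]
        curve = decay_curve(pairs, [], registry, methods=("biosynfoni",))
        assert all(v == [1.0] for v in curve.per_n["biosynfoni"].values())

    def test_unrelated_control_molecules_score_near_zero(self, registry):
        control = [
            DistancePair(
                compound_a=record_from_smiles("CCCCCC", "a"),
                compound_b=record_from_smiles("OP(=O)(O)O", "b"),
                n_reactions=1,
                is_control=True,
            )
        ]
        pairs = [
            DistancePair(
                compound_a=record_from_smiles("CCO", "x"),
                compound_b=record_from_smiles("CCO", "y"),
                n_reactions=1,
            )
        ]
        curve = decay_curve(pairs, control, registry, methods=("biosynfoni",))
        assert curve.control["biosynfoni"][0] == 0.0

    def test_synthetic_chains_show_monotone_similarity_decay(self, registry):
        chains = fixtures.make_chain_set(50, n_steps=6, seed=11)
        pairs = []
        for sc in chains:
            pairs.extend(generate_pairs(sc.chain))
        control = shuffle_control(pairs, seed=11)
        curve = decay_curve(pairs, control, registry, methods=("biosynfoni",))
        medians = curve.medians().loc["biosynfoni"]
        assert (medians.diff().dropna() <= 0).all()
        rho = spearmanr(medians.index, medians.values).statistic
        assert rho <= -0.8
        assert curve.control_medians()["biosynfoni"] < medians[1]

    def test_long_format_export_has_all_rows(self, registry):
        chains = fixtures.make_chain_set(3, n_steps=4, seed=2)
        pairs = []
        for sc in chains:
            pairs.extend(generate_pairs(sc.chain))
        control = shuffle_control(pairs, seed=2)
        curve = decay_curve(pairs, control, registry, methods=("biosynfoni", "maccs"))
        frame = curve.to_frame()
        assert set(frame["method"]) == {"biosynfoni", "maccs"}
        assert len(frame) == 2 * (len(pairs) + len(control))
        assert frame.loc[~frame["is_control"], "n"].between(1, 6).all()
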
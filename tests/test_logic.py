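"""Read-once enumeration, function scoring, staged ensemble learning,
AND-gate pair analysis."""

import itertools

import numpy as np
import pandas as pd
import pytest

from _oracles import eval_tree, readonce_tables_2var, readonce_tables_3var
from scboolnet.logic import (
    BooleanFunction,
    LearningConfig,
    and_pair_enrichment,
    and_pair_ranking,
    enumerate_readonce,
    learn_all,
    learn_node,
    make_function,
    score_function,
)
from scboolnet.network import Node, SignedNetwork
from scboolnet.preprocess import BinaryMatrix


def make_binary(rows: dict) -> BinaryMatrix:
    df = pd.DataFrame(rows).T
    df.columns = [f"c{i}" for i in range(df.shape[1])]
    cents = pd.DataFrame({"low": 0.0, "high": 1.0}, index=df.index)
    return BinaryMatrix(df.astype(int), cents)


class TestEnumerateReadonce:
    def test_single_parent_gives_identity_and_negation(self):
        fs = enumerate_readonce(["A"], "T")
        assert len(fs) == 2
        assert {f.truth_table for f in fs} == {0b10, 0b01}

    def test_two_parent_tables_match_exhaustive_scan(self):
        fs = enumerate_readonce(["A", "B"], "T")
        assert {f.truth_table for f in fs} == readonce_tables_2var()

    def test_three_parent_tables_match_exhaustive_scan(self):
        fs = enumerate_readonce(["A", "B", "C"], "T")
        assert {f.truth_table for f in fs} == readonce_tables_3var()

    def test_deduplicated_and_deterministic_order(self):
        a = [f.truth_table for f in enumerate_readonce(["A", "B", "C"], "T")]
        b = [f.truth_table for f in enumerate_readonce(["A", "B", "C"], "T")]
        assert a == b and len(a) == len(set(a))

    def test_formula_reproduces_truth_table(self):
        # whole-ensemble sweep: evaluate each tree on all patterns
        for fs in (enumerate_readonce(["A", "B"], "T"),
                   enumerate_readonce(["A", "B", "C"], "T")):
            for f in fs:
                p = len(f.parents)
                for pat in range(2**p):
                    env = {f.parents[j]: (pat >> j) & 1 for j in range(p)}
                    got = eval_tree(f.tree, env, f.parents)
                    assert got == (f.truth_table >> pat) & 1

    def test_parent_cap_enforced(self):
        with pytest.raises(ValueError, match="max_parents"):
            enumerate_readonce(list("ABCDEFG"), "T", max_parents=6)

    def test_target_cannot_be_its_own_parent(self):
        with pytest.raises(ValueError):
            make_function("A", ("A",), ("lit", 0, False))


class TestScoreFunction:
    def test_identity_on_matching_row_scores_one(self):
        bm = make_binary({"A": [0, 1, 1, 0], "T": [0, 1, 1, 0]})
        f = make_function("T", ("A",), ("lit", 0, False))
        assert score_function(f, bm) == 1.0

    def test_function_and_negation_agreements_sum_to_one(self, rng):
        bm = make_binary(
            {g: rng.integers(0, 2, 50) for g in ["A", "B", "T"]}
        )
        for f in enumerate_readonce(["A", "B"], "T"):
            neg_table = f.truth_table ^ 0b1111
            g = next(
                h for h in enumerate_readonce(["A", "B"], "T")
                if h.truth_table == neg_table
            )
            assert score_function(f, bm) + score_function(g, bm) == pytest.approx(1.0)

    def test_matches_per_cell_loop_oracle(self, rng):
        genes = ["A", "B", "C", "T"]
        bm = make_binary({g: rng.integers(0, 2, 50) for g in genes})
        for f in enumerate_readonce(["A", "B", "C"], "T")[:40]:
            agree = 0
            for c in bm.values.columns:
                env = {p: int(bm.values.loc[p, c]) for p in f.parents}
                if eval_tree(f.tree, env, f.parents) == int(bm.values.loc["T", c]):
                    agree += 1
            assert score_function(f, bm) == pytest.approx(agree / 50)


def snapshots_from_function(f: BooleanFunction, extra: dict | None = None) -> BinaryMatrix:
    """All input patterns of f's parents plus the implied target row."""
    p = len(f.parents)
    rows = {g: [] for g in list(f.parents) + [f.target]}
    for pat in range(2**p):
        for j, g in enumerate(f.parents):
            rows[g].append((pat >> j) & 1)
        rows[f.target].append((f.truth_table >> pat) & 1)
    for g, bits in (extra or {}).items():
        rows[g] = bits
    return make_binary(rows)


class TestLearnNode:
    def test_noiseless_recovery_of_generating_function(self):
        # truth: T = (A AND NOT B) OR C over all 8 input patterns
        tree = ("OR", ("AND", ("lit", 0, False), ("lit", 1, True)), ("lit", 2, False))
        f = make_function("T", ("A", "B", "C"), tree)
        bm = snapshots_from_function(f)
        net = SignedNetwork(
            [Node(g) for g in "ABCT"],
            {("A", "T"): 1, ("B", "T"): -1, ("C", "T"): 1},
        )
        ens = learn_node("T", net, bm, LearningConfig(theta=0.95))
        assert ens.stage == "prior" and ens.agreement == 1.0
        assert {g.truth_table for g in ens.functions} == {f.truth_table}

    def test_constant_rows_resolved_by_identity(self):
        bm = make_binary({"A": [1, 1, 1, 1], "T": [1, 1, 1, 1]})
        net = SignedNetwork([Node("A"), Node("T")], {("A", "T"): 1})
        ens = learn_node("T", net, bm, LearningConfig())
        assert ens.agreement == 1.0 and ens.novel_links == set()

    def test_stage2_single_reassignment_finds_matching_pool_gene(self, rng):
        target = rng.integers(0, 2, 40)
        bm = make_binary(
            {"A": rng.integers(0, 2, 40), "P": target, "T": target}
        )
        net = SignedNetwork(
            [Node(g) for g in ["A", "P", "T"]], {("A", "T"): 1}
        )
        cfg = LearningConfig(theta=0.9, refinement_pool=("A", "P"))
        ens = learn_node("T", net, bm, cfg)
        assert ens.stage == "reassign_single"
        assert ens.functions[0].parents == ("P",)
        assert ens.novel_links == {"P"}

    def test_unresolved_flag_instead_of_silent_empty(self, rng):
        # target independent of everything: nothing can reach theta
        bm = make_binary(
            {"A": [0, 1] * 20, "T": list(rng.integers(0, 2, 40))}
        )
        net = SignedNetwork([Node("A"), Node("T")], {("A", "T"): 1})
        ens = learn_node("T", net, bm, LearningConfig(theta=0.99))
        assert ens.stage == "unresolved" and ens.functions

    def test_theta_monotonicity(self, small8, small8_binary):
        pool = tuple(small8.network.gene_ids)
        sizes = []
        for theta in (0.7, 0.85, 0.95):
            ens = learn_node(
                "Tcf3", small8.network, small8_binary,
                LearningConfig(theta=theta, refinement_pool=pool),
            )
            sizes.append((theta, ens.stage, ens.degeneracy, ens.agreement))
        # raising theta never enlarges the ensemble produced at the same stage
        for (t1, s1, d1, a1), (t2, s2, d2, a2) in zip(sizes, sizes[1:]):
            if s1 == s2:
                assert d2 <= d1

    def test_pruning_soundness(self, small8, small8_learned):
        # every kept function fits at least as well as the full-prior-set best
        for g, ens in small8_learned.ensembles.items():
            if ens.stage != "prior":
                continue
            for f in ens.functions:
                assert f.agreement == pytest.approx(ens.agreement)


class TestConsensus:
    def test_sign_coherence_of_consensus_edges(self, small8_learned):
        for tgt, ens in small8_learned.ensembles.items():
            cons = ens.consensus_edges()
            n = ens.degeneracy
            for parent, sign in cons.items():
                same = sum(
                    1 for f in ens.functions
                    if f.literal_signs().get(parent) == sign
                )
                assert same / n > ens.consensus_fraction

    def test_mixed_parity_blocks_link(self):
        f1 = make_function("T", ("A",), ("lit", 0, False))
        f2 = make_function("T", ("A",), ("lit", 0, True))
        from scboolnet.logic import FunctionEnsemble

        ens = FunctionEnsemble("T", [f1, f2], 1.0, "prior", ("A",))
        assert ens.consensus_edges() == {}

    def test_noiseless_constant_data_leaves_zero_novel_links(self):
        genes = ["A", "B", "T"]
        bm = make_binary({g: [1] * 8 for g in genes})
        net = SignedNetwork([Node(g) for g in genes], {("A", "T"): 1, ("A", "B"): 1})
        res = learn_all(net, bm, LearningConfig())
        assert res.unresolved == []
        assert all(not e.novel_links for e in res.ensembles.values())


class TestLearnAll:
    def test_recovers_most_true_edges_under_study_conditions(
        self, small8, small8_learned
    ):
        true_edges = {(a, b, s) for (a, b), s in small8.network.edges.items()}
        cons = {(a, b, s) for (a, b), s in small8_learned.consensus.edges.items()}
        assert len(cons & true_edges) / len(true_edges) >= 0.9

    def test_condition_specific_learning_localizes_differences(self):
        from scboolnet import binarize, gen_cells, make_ground_truth, normalize_ct
        from scboolnet.logic import learn_all

        gt_a = make_ground_truth("small8")
        # variant truth: the Tcf3 gate flips from AND to OR (same parents),
        # and the Fgf5 inverter reads Tcf3 instead of Gata6
        gt_b = make_ground_truth("small8")
        gt_b.functions["Tcf3"] = make_function(
            "Tcf3", ("Pou5f1", "Sox2"), ("OR", ("lit", 0, False), ("lit", 1, False))
        )
        gt_b.functions["Fgf5"] = make_function("Fgf5", ("Tcf3",), ("lit", 0, True))
        gt_b.network = SignedNetwork(
            gt_b.network.nodes,
            {**{k: v for k, v in gt_b.network.edges.items() if k != ("Gata6", "Fgf5")},
             ("Tcf3", "Fgf5"): -1},
        )
        results = {}
        for label, gt in (("a", gt_a), ("b", gt_b)):
            em, _ = gen_cells(gt, seed=11)
            bm = binarize(normalize_ct(em))
            results[label] = learn_all(gt.network, bm, LearningConfig())
        cons_a = results["a"].consensus.edges
        cons_b = results["b"].consensus.edges
        differing_targets = {b for (a, b) in set(cons_a) ^ set(cons_b)}
        # differences concentrate on the rewired node's neighborhood
        assert differing_targets <= {"Fgf5", "Tcf3"}
        assert ("Tcf3", "Fgf5") in cons_b and ("Gata6", "Fgf5") not in cons_b


class TestAndPairs:
    def test_single_and_function_yields_one_pair(self):
        from scboolnet.logic import FunctionEnsemble

        f = make_function("T", ("A", "B"), ("AND", ("lit", 0, False), ("lit", 1, False)))
        ens = {"T": FunctionEnsemble("T", [f], 1.0, "prior", ("A", "B"))}
        assert and_pair_ranking(ens) == [(frozenset({"A", "B"}), 1)]

    def test_frequencies_match_manual_tally(self):
        from scboolnet.logic import FunctionEnsemble

        # f1 = (A AND B); f2 = (A AND B) OR C ; f3 = C OR (A AND NOT B)
        f1 = make_function("T", ("A", "B"), ("AND", ("lit", 0, False), ("lit", 1, False)))
        f2 = make_function(
            "T", ("A", "B", "C"),
            ("OR", ("AND", ("lit", 0, False), ("lit", 1, False)), ("lit", 2, False)),
        )
        f3 = make_function(
            "U", ("C", "A", "B"),
            ("OR", ("lit", 0, False), ("AND", ("lit", 1, False), ("lit", 2, True))),
        )
        ens = {
            "T": FunctionEnsemble("T", [f1, f2], 1.0, "prior", ()),
            "U": FunctionEnsemble("U", [f3], 1.0, "prior", ()),
        }
        assert dict(and_pair_ranking(ens)) == {frozenset({"A", "B"}): 3}

    def test_nested_and_bridges_cross_subtree_leaves(self):
        from scboolnet.logic import FunctionEnsemble

        # A AND (B OR C): AND node bridges A with both B and C
        f = make_function(
            "T", ("A", "B", "C"),
            ("AND", ("lit", 0, False), ("OR", ("lit", 1, False), ("lit", 2, False))),
        )
        ens = {"T": FunctionEnsemble("T", [f], 1.0, "prior", ())}
        assert dict(and_pair_ranking(ens)) == {
            frozenset({"A", "B"}): 1,
            frozenset({"A", "C"}): 1,
        }

    def test_enrichment_direction_on_constructed_reference(self):
        from scboolnet.logic import FunctionEnsemble

        funcs = {}
        pairs = [("A", "B"), ("C", "D"), ("E", "F")]
        for i, (x, y) in enumerate(pairs):
            f = make_function(
                f"T{i}", (x, y), ("AND", ("lit", 0, False), ("lit", 1, False))
            )
            funcs[f"T{i}"] = FunctionEnsemble(f"T{i}", [f], 1.0, "prior", ())
        universe = list("ABCDEFGH")
        n_hit, p_ref = and_pair_enrichment(
            funcs, [frozenset(p) for p in pairs], universe
        )
        assert n_hit == 3
        _, p_off = and_pair_enrichment(
            funcs, [frozenset({"G", "H"})], universe
        )
        assert p_ref < p_off
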
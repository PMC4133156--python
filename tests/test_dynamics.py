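"""Synchronous update, attractor detection, basin weighting, screens."""

import numpy as np
import pandas as pd
import pytest

from _oracles import naive_attractors, naive_step
from scboolnet.dynamics import (
    ConstantRule,
    NetworkModel,
    PerturbationSpec,
    delta_sim,
    exact_attractors,
    knockdown_screen,
    run_to_attractor,
    sample_models,
    simulate_condition,
    step,
)
from scboolnet.logic import FunctionEnsemble, make_function
from scboolnet.preprocess import BinaryMatrix


def random_model(rng, n=6):
    genes = [f"g{i}" for i in range(n)]
    rules = {}
    for i, g in enumerate(genes):
        others = [h for h in genes if h != g]
        k = int(rng.integers(1, 3))
        parents = tuple(rng.choice(others, size=k, replace=False))
        if k == 1:
            tree = ("lit", 0, bool(rng.integers(2)))
        else:
            tree = (
                str(rng.choice(["AND", "OR"])),
                ("lit", 0, bool(rng.integers(2))),
                ("lit", 1, bool(rng.integers(2))),
            )
        rules[g] = make_function(g, parents, tree)
    return NetworkModel(genes, rules)


def rules_for_oracle(model):
    out = {}
    for g in model.roster:
        r = model.rules[g]
        if isinstance(r, ConstantRule):
            out[g] = ("const", r.value)
        else:
            out[g] = ("func", r.parents, r.tree)
    return out


class TestStep:
    def test_constant_rules_ignore_state(self):
        genes = ["A", "B"]
        model = NetworkModel(genes, {"A": ConstantRule("A", 1), "B": ConstantRule("B", 0)})
        assert step(model, [0, 1]).tolist() == [1, 0]
        assert step(model, [1, 0]).tolist() == [1, 0]

    def test_mutual_activation_fixed_point(self):
        model = NetworkModel(
            ["A", "B"],
            {"A": make_function("A", ("B",), ("lit", 0, False)),
             "B": make_function("B", ("A",), ("lit", 0, False))},
        )
        assert step(model, [1, 1]).tolist() == [1, 1]

    def test_random_models_match_naive_per_gene_oracle(self, rng):
        for _ in range(25):
            model = random_model(rng)
            state = {g: int(rng.integers(2)) for g in model.roster}
            got = step(model, [state[g] for g in model.roster])
            want = naive_step(model.roster, rules_for_oracle(model), state)
            assert got.tolist() == [want[g] for g in model.roster]

    def test_clamped_gene_forced_off(self):
        model = NetworkModel(["A", "B"], {"A": ConstantRule("A", 1),
                                          "B": ConstantRule("B", 1)})
        pert = PerturbationSpec(frozenset(["A"]), "A")
        assert step(model, [1, 1], pert).tolist() == [0, 1]


class TestRunToAttractor:
    def test_negative_two_loop_gives_length_four_cycle(self):
        # A activates B, B inhibits A
        model = NetworkModel(
            ["A", "B"],
            {"A": make_function("A", ("B",), ("lit", 0, True)),
             "B": make_function("B", ("A",), ("lit", 0, False))},
        )
        att, steps = run_to_attractor(model, [1, 0])
        assert att is not None and att.cycle_length == 4
        # hand-enumerated transition graph: every state lies on the cycle
        assert steps == 0
        np.testing.assert_allclose(att.mean_state, [0.5, 0.5])

    def test_fixed_point_detected_with_step_count(self):
        model = NetworkModel(
            ["A", "B"],
            {"A": ConstantRule("A", 1),
             "B": make_function("B", ("A",), ("lit", 0, False))},
        )
        att, steps = run_to_attractor(model, [0, 0])
        assert att.cycle_length == 1
        assert att.states[0].tolist() == [1, 1]
        assert steps <= 2

    def test_non_convergence_is_flagged_not_raised(self):
        model = NetworkModel(
            ["A", "B"],
            {"A": make_function("A", ("B",), ("lit", 0, True)),
             "B": make_function("B", ("A",), ("lit", 0, False))},
        )
        att, steps = run_to_attractor(model, [1, 0], max_steps=2)
        assert att is None and steps == 2

    def test_attractors_match_exhaustive_transition_graph(self, rng):
        for _ in range(20):
            model = random_model(rng, n=int(rng.integers(3, 8)))
            oracle = naive_attractors(model.roster, rules_for_oracle(model))
            got = exact_attractors(model)
            assert got == oracle

    def test_trajectory_is_deterministic(self, rng):
        model = random_model(rng)
        init = [int(rng.integers(2))] * model.n
        a1 = run_to_attractor(model, init)
        a2 = run_to_attractor(model, init)
        assert a1[1] == a2[1]
        assert [s.tolist() for s in a1[0].states] == [s.tolist() for s in a2[0].states]


class TestSimulateCondition:
    def test_single_global_fixed_point_reported_exactly(self):
        model = NetworkModel(
            ["A", "B"],
            {"A": ConstantRule("A", 1),
             "B": make_function("B", ("A",), ("lit", 0, False))},
        )
        res = simulate_condition([model], PerturbationSpec(), n_init=20, seed=0)
        assert res.g.tolist() == [1.0, 1.0]
        assert res.dominant_frequency == 1.0

    def test_sampled_basins_within_three_binomial_se_of_exact(self, rng):
        for _ in range(5):
            model = random_model(rng, n=6)
            exact = exact_attractors(model)
            res = simulate_condition([model], PerturbationSpec(), n_init=100, seed=7)
            sampled = {
                tuple(model.pack(s.astype(int)) for s in a.states): a.basin_weight
                for a in res.attractors_per_model[0]
            }
            for key, w in sampled.items():
                p = exact.get(key, 0.0)
                se = np.sqrt(max(p * (1 - p), 1e-9) / 100)
                assert abs(w - p) <= max(3 * se, 1e-9)

    def test_basin_weights_sum_to_one(self, rng):
        model = random_model(rng)
        res = simulate_condition([model], PerturbationSpec(), n_init=50, seed=3)
        total = sum(a.basin_weight for a in res.attractors_per_model[0])
        assert total == pytest.approx(1.0)

    def test_clamped_gene_reports_zero_activity(self, rng):
        model = random_model(rng)
        g0 = model.roster[0]
        res = simulate_condition(
            [model], PerturbationSpec(frozenset([g0]), g0), n_init=50, seed=3
        )
        assert res.g[g0] == 0.0

    def test_seed_is_mandatory(self, rng):
        model = random_model(rng)
        with pytest.raises(ValueError, match="seed"):
            simulate_condition([model], PerturbationSpec(), n_init=10)


class TestDeltaSim:
    def _sim_result(self, g):
        from scboolnet.dynamics import SimulationResult

        return SimulationResult(g, "baseline", pd.Series(dtype=float), {})

    def test_baseline_vs_itself_is_zero(self):
        g = pd.DataFrame({"baseline": [0.2, 0.8], "kd": [0.2, 0.8]}, index=["A", "B"])
        ds = delta_sim(self._sim_result(g))
        assert (ds == 0).all().all()

    def test_clamped_gene_that_was_on_goes_down(self):
        g = pd.DataFrame({"baseline": [1.0], "kd": [0.0]}, index=["A"])
        assert delta_sim(self._sim_result(g)).loc["A", "kd"] == -1

    def test_matches_elementwise_formula_on_grid(self):
        vals = np.linspace(0, 1, 6)
        for eps in (0.05, 0.1, 0.3):
            for gb in vals:
                g = pd.DataFrame({"baseline": [gb] * 6, "kd": vals})
                ds = delta_sim(self._sim_result(g), eps=eps)
                for i, gv in enumerate(vals):
                    d = gv - gb
                    want = 0 if abs(d) <= eps else (1 if d > 0 else -1)
                    assert ds.iloc[i]["kd"] == want


class TestKnockdownScreen:
    def test_single_knockdowns_combinatorics(self, rng):
        model = random_model(rng, n=4)
        sim = knockdown_screen([model], model.roster[:3], max_combo=1,
                               n_init=10, seed=1)
        assert list(sim.g.columns)[0] == "baseline"
        assert len(sim.g.columns) == 4

    def test_seven_condition_panel(self, rng):
        model = random_model(rng, n=5)
        sim = knockdown_screen([model], model.roster[:3], max_combo=3,
                               n_init=10, seed=1)
        # 3 singles + 3 doubles + 1 triple + baseline
        assert len(sim.g.columns) == 8

    def test_fifteen_factor_double_screen_has_120_conditions(self, rng):
        from math import comb

        assert 15 + comb(15, 2) == 120  # the panel arithmetic itself
        model = random_model(rng, n=16)
        sim = knockdown_screen([model], model.roster[:15], max_combo=2,
                               n_init=2, max_steps=10, seed=1)
        assert len(sim.g.columns) == 121

    def test_sole_activator_knockdown_silences_target(self):
        # X is the only activator of Y; Z keeps itself alive via W
        model = NetworkModel(
            ["X", "Y"],
            {"X": ConstantRule("X", 1),
             "Y": make_function("Y", ("X",), ("lit", 0, False))},
        )
        sim = knockdown_screen([model], ["X"], max_combo=1, n_init=10, seed=2)
        ds = delta_sim(sim)
        assert ds.loc["Y", "X"] == -1

    def test_unknown_gene_rejected(self, rng):
        model = random_model(rng, n=4)
        with pytest.raises(ValueError):
            knockdown_screen([model], ["nope"], max_combo=1, n_init=5, seed=0)


class TestSampleModels:
    def test_empty_ensemble_falls_back_to_majority_constant(self):
        bm = BinaryMatrix(
            pd.DataFrame({"c0": [1, 0], "c1": [1, 0], "c2": [1, 1]},
                         index=["A", "B"]).astype(int),
            pd.DataFrame({"low": 0.0, "high": 1.0}, index=["A", "B"]),
        )
        ens = {"A": FunctionEnsemble("A", [], 0.0, "unresolved", ())}
        models = sample_models(ens, ["A", "B"], bm, n_models=2, seed=0)
        for m in models:
            assert isinstance(m.rules["A"], ConstantRule) and m.rules["A"].value == 1
            assert isinstance(m.rules["B"], ConstantRule) and m.rules["B"].value == 0

    def test_sampling_is_seed_deterministic(self, small8_learned, small8_binary, small8):
        roster = small8.network.gene_ids
        m1 = sample_models(small8_learned.ensembles, roster, small8_binary, 5, seed=9)
        m2 = sample_models(small8_learned.ensembles, roster, small8_binary, 5, seed=9)
        for a, b in zip(m1, m2):
            assert a.rules == b.rules
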
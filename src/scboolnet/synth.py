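"""Synthetic-data generation from a known Boolean ground truth.

Every input the pipeline consumes — perturbation/binding evidence tables,
single-cell Ct matrices, knockdown fold-change panels — can be generated
from a ground-truth network with known update rules, so each stage (and
the end-to-end run) is testable against the truth without any external
dataset.

The cell generator emulates a 96-well microfluidic qPCR chip: each cell is
an independent trajectory of the true network relaxed to its attractor,
one attractor state is sampled as the cell's snapshot (matching the
learner's steady-state assumption), bits are flipped with a small noise
probability, and ON/OFF bits are emitted as Ct values drawn from two
Gaussians (ON genes amplify early, ~Ct 20; OFF genes late, ~Ct 33, capped
at the 35-cycle detection limit), yielding the familiar bimodal -dCt
histograms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dynamics import (
    ConstantRule,
    NetworkModel,
    PerturbationSpec,
    Rule,
    _find_attractor_int,
    simulate_condition,
)
from .logic import Tree, make_function
from .network import EvidenceRecord, EvidenceTable, Node, SignedNetwork
from .preprocess import BinaryMatrix, ExpressionMatrix


@dataclass
class GroundTruth:
    """A true network + update rules and the generator's noise geometry.

    Ct geometry defaults produce clearly bimodal -dCt distributions while
    leaving the binarizer a realistic job: ON ~ N(20, 1.5), OFF ~ N(33,
    1.5) capped at 35; the housekeeping gene sits at a fixed Ct of 15.
    """

    network: SignedNetwork
    functions: dict[str, Rule]
    n_cells: int = 96
    flip_noise: float = 0.05
    ct_high_mean: float = 20.0
    ct_low_mean: float = 33.0
    ct_sd: float = 1.5
    ct_cap: float = 35.0
    ct_housekeeping: float = 15.0
    housekeeping: str = "Gapdh"
    kd_noise_sd: float = 0.25
    fc_scale: float = 4.0

    def __post_init__(self) -> None:
        if not self.ct_low_mean > self.ct_high_mean:
            raise ValueError("ct_low_mean must exceed ct_high_mean (higher Ct = lower expression)")
        if not 0 <= self.flip_noise < 0.5:
            raise ValueError("flip_noise must lie in [0, 0.5)")

    def model(self) -> NetworkModel:
        return NetworkModel(self.network.gene_ids, self.functions, provenance="truth")


def _lit(j: int, neg: bool = False) -> Tree:
    return ("lit", j, neg)


def _chain(op: str, leaves: list[Tree]) -> Tree:
    tree = leaves[0]
    for leaf in leaves[1:]:
        tree = (op, tree, leaf)
    return tree


def rules_from_topology(
    net: SignedNetwork,
    max_parents: int = 6,
    default_on: Sequence[str] = (),
) -> dict[str, Rule]:
    """Canonical read-once rules implied by a signed topology.

    Each gene turns ON when at least one activator is ON and no repressor
    is ON: f = (a1 OR a2 OR ...) AND NOT r1 AND NOT r2 ...  Self-edges are
    dropped; parents beyond ``max_parents`` are truncated in roster order.
    Input-free genes become constants: 1 if listed in ``default_on``
    (upstream signals held active), else 0.
    """
    rules: dict[str, Rule] = {}
    for g in net.gene_ids:
        parents = net.parents_of(g, drop_self=True)[:max_parents]
        if not parents:
            rules[g] = ConstantRule(g, int(g in default_on))
            continue
        names = tuple(p for p, _ in parents)
        acts = [_lit(j) for j, (_, s) in enumerate(parents) if s > 0]
        reps = [_lit(j, neg=True) for j, (_, s) in enumerate(parents) if s < 0]
        if acts and reps:
            tree = ("AND", _chain("OR", acts), _chain("AND", reps))
        elif acts:
            tree = _chain("OR", acts)
        else:
            tree = _chain("AND", reps)
        rules[g] = make_function(g, names, tree)
    return rules


def make_ground_truth(preset: str = "small8", **overrides) -> GroundTruth:
    """Construct a named ground-truth system.

    ``small8``: 8 genes, 10 signed edges — two independent bistable
    mutual-activation pairs plus AND/OR readouts and two inverters, so the
    attractor ensemble covers diverse parent input patterns.

    ``mesc30``: the vendored 30-node seed network with canonical
    activator-OR / repressor-AND-NOT rules (auto-regulation dropped for
    dynamics) and upstream signals held ON.
    """
    if preset == "small8":
        # Two bistable mutual-activation pairs (independent heritable
        # "cell states"), two-input readouts drawing their parents from
        # *different* pairs (so snapshot data cover all four input
        # patterns and the gate is identifiable), and two inverters.
        genes = ["Pou5f1", "Nanog", "Sox2", "Esrrb", "Tcf3", "Cdx2", "Gata6", "Fgf5"]
        P, N, S, E, T, C, G, F = genes
        edges = {
            (P, N): 1, (N, P): 1,          # bistable pair 1
            (S, E): 1, (E, S): 1,          # bistable pair 2
            (P, T): 1, (S, T): 1,          # T = P AND S
            (T, C): -1,                    # C = NOT T
            (N, G): 1, (E, G): 1,          # G = N OR E
            (G, F): -1,                    # F = NOT G
        }
        net = SignedNetwork([Node(g) for g in genes], edges)
        functions: dict[str, Rule] = {
            P: make_function(P, (N,), _lit(0)),
            N: make_function(N, (P,), _lit(0)),
            S: make_function(S, (E,), _lit(0)),
            E: make_function(E, (S,), _lit(0)),
            T: make_function(T, (P, S), ("AND", _lit(0), _lit(1))),
            C: make_function(C, (T,), _lit(0, True)),
            G: make_function(G, (N, E), ("OR", _lit(0), _lit(1))),
            F: make_function(F, (G,), _lit(0, True)),
        }
        return GroundTruth(net, functions, **overrides)
    if preset == "mesc30":
        from .io import load_seed_network

        net = load_seed_network()
        funcs = rules_from_topology(net, default_on=("Stat3",))
        return GroundTruth(net, funcs, **overrides)
    raise ValueError(f"unknown preset {preset!r}")


# ----------------------------------------------------------------------
# generators
# ----------------------------------------------------------------------

def gen_evidence(
    gt: GroundTruth,
    n_lof: int = 2,
    n_gof: int = 1,
    error_rate: float = 0.0,
    chip_fp_rate: float = 0.0,
    seed: int = 0,
) -> EvidenceTable:
    """Evidence reports for every true edge, with optional sign errors.

    Each edge receives one ChIP row plus ``n_lof`` LOF and ``n_gof`` GOF
    sign reports matching the true sign except with probability
    ``error_rate``.  Non-edges acquire spurious ChIP rows at
    ``chip_fp_rate`` (they stay absent from the vote without functional
    evidence).
    """
    if not (0 <= error_rate < 1 and 0 <= chip_fp_rate < 1):
        raise ValueError("rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    records: list[EvidenceRecord] = []
    genes = gt.network.gene_ids
    for (a, b), s in sorted(gt.network.edges.items()):
        records.append(EvidenceRecord(a, b, "ChIP", None, f"chip::{a}->{b}"))
        for k in range(n_lof):
            rep = -s if rng.random() < error_rate else s
            records.append(EvidenceRecord(a, b, "LOF", rep, f"lof{k}::{a}->{b}"))
        for k in range(n_gof):
            rep = -s if rng.random() < error_rate else s
            records.append(EvidenceRecord(a, b, "GOF", rep, f"gof{k}::{a}->{b}"))
    if chip_fp_rate > 0:
        for a in genes:
            for b in genes:
                if (a, b) not in gt.network.edges and rng.random() < chip_fp_rate:
                    records.append(EvidenceRecord(a, b, "ChIP", None, f"chipfp::{a}->{b}"))
    return EvidenceTable(records, roster=genes)


def gen_cells(
    gt: GroundTruth,
    conditions: Sequence[str] = ("serum_LIF",),
    seed: int = 0,
    max_steps: int = 100,
    max_retries: int = 40,
    fixed_points_only: bool = True,
) -> tuple[ExpressionMatrix, BinaryMatrix]:
    """Single-cell Ct matrix plus the latent true binary matrix.

    Per cell: evolve the true network from a uniform random initial state
    to its attractor, sample one attractor state, flip each bit with
    probability ``flip_noise``, then emit Ct ~ N(ct_high_mean, ct_sd) for
    ON bits and N(ct_low_mean, ct_sd) capped at the detection limit for
    OFF bits.  Each condition label gets ``gt.n_cells`` cells from the
    same truth.

    With ``fixed_points_only`` (the default) trajectories landing on limit
    cycles are resampled: real cells occupy stable expression states, and
    synchronous-update limit cycles are artifacts of the update scheme
    that would violate the learner's steady-state snapshot assumption.
    Non-converged or persistently cyclic draws fall back, after
    ``max_retries``, to a state sampled from whatever recurrent set was
    found.
    """
    rng = np.random.default_rng(seed)
    model = gt.model()
    n = model.n
    cols: dict[str, np.ndarray] = {}
    latent: dict[str, np.ndarray] = {}
    cond_labels = {}
    for cond in conditions:
        for ci in range(gt.n_cells):
            cell = f"{cond}_c{ci:03d}"
            states: tuple[int, ...] | None = None
            for _ in range(max_retries):
                init = int(rng.integers(0, 2**n))
                run = _find_attractor_int(model, init, 0, max_steps)
                if run.attractor_key is not None and (
                    not fixed_points_only or len(run.attractor_key) == 1
                ):
                    states = run.attractor_key
                    break
            if states is None:  # bounded-retry fallback, flagged by docs
                states = run.attractor_key or (run.final_state,)
            state = model.unpack(states[int(rng.integers(len(states)))])
            flips = rng.random(n) < gt.flip_noise
            bits = np.where(flips, 1 - state, state)
            latent[cell] = bits
            ct = np.where(
                bits == 1,
                rng.normal(gt.ct_high_mean, gt.ct_sd, n),
                np.minimum(rng.normal(gt.ct_low_mean, gt.ct_sd, n), gt.ct_cap),
            )
            cols[cell] = ct
            cond_labels[cell] = cond
    genes = list(model.roster)
    expr = pd.DataFrame(cols, index=genes)
    expr.loc[gt.housekeeping] = gt.ct_housekeeping
    em = ExpressionMatrix(
        expr, pd.Series(cond_labels), housekeeping=gt.housekeeping, cap=gt.ct_cap
    )
    bm_vals = pd.DataFrame(latent, index=genes).astype(int)
    centroids = pd.DataFrame(
        {"low": -(gt.ct_low_mean - gt.ct_housekeeping),
         "high": -(gt.ct_high_mean - gt.ct_housekeeping)},
        index=genes,
    )
    return em, BinaryMatrix(bm_vals, centroids)


def gen_kd_fc(
    gt: GroundTruth,
    kd_sets: Sequence[Sequence[str]],
    n_init: int = 200,
    max_steps: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Experimental-style log2 fold-change table from simulated knockdowns.

    The true network is simulated under each clamp set; the fold-change is
    dE = -fc_scale * (g_kd - g_baseline) + N(0, kd_noise_sd), honoring the
    Ct-space orientation (positive = down-regulation).
    """
    rng = np.random.default_rng(seed)
    model = gt.model()
    base = simulate_condition(
        [model], PerturbationSpec(frozenset(), "baseline"),
        n_init=n_init, max_steps=max_steps, rng=rng,
    )
    cols = {}
    for kd in kd_sets:
        pert = PerturbationSpec.knockdown(list(kd))
        res = simulate_condition(
            [model], pert, n_init=n_init, max_steps=max_steps, rng=rng
        )
        dg = res.g - base.g
        noise = rng.normal(0.0, gt.kd_noise_sd, len(dg))
        cols[pert.label] = -gt.fc_scale * dg + noise
    return pd.DataFrame(cols)
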
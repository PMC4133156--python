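"""Synchronous Boolean dynamics: attractor detection, basin weighting,
and in-silico knockdown screens.

All genes update simultaneously from the previous global state.  A
knockdown clamps its gene to OFF at every step including the initial
state.  An attractor is any recurrent state set reached by the
deterministic trajectory — a fixed point (length 1) or a limit cycle;
limit cycles contribute their per-gene cycle mean to the reported
activity.  Each attractor is weighted by its basin size, estimated as the
fraction of random initial conditions flowing into it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .logic import BooleanFunction, FunctionEnsemble
from .preprocess import BinaryMatrix


@dataclass(frozen=True)
class ConstantRule:
    """Update rule of an input-free node: a frozen 0/1 value."""

    target: str
    value: int

    parents: tuple[str, ...] = ()


Rule = BooleanFunction | ConstantRule


class NetworkModel:
    """One concrete Boolean network: a roster and one update rule per gene."""

    def __init__(self, roster: Sequence[str], rules: Mapping[str, Rule],
                 provenance: str = ""):
        self.roster = tuple(roster)
        self.index = {g: i for i, g in enumerate(self.roster)}
        for g in self.roster:
            if g not in rules:
                raise ValueError(f"no update rule for {g}")
            for p in rules[g].parents:
                if p not in self.index:
                    raise ValueError(f"rule for {g} references unknown gene {p}")
        self.rules = {g: rules[g] for g in self.roster}
        self.provenance = provenance
        # per-gene (parent positions, truth table int) for fast stepping
        self._compiled = []
        for g in self.roster:
            r = self.rules[g]
            if isinstance(r, ConstantRule):
                self._compiled.append(((), int(r.value)))
            else:
                self._compiled.append(
                    (tuple(self.index[p] for p in r.parents), r.truth_table)
                )

    @property
    def n(self) -> int:
        return len(self.roster)

    # integer-packed states: bit i of the state int = gene self.roster[i]
    def pack(self, bits: Sequence[int]) -> int:
        s = 0
        for i, b in enumerate(bits):
            if b:
                s |= 1 << i
        return s

    def unpack(self, state: int) -> np.ndarray:
        return np.array([(state >> i) & 1 for i in range(self.n)], dtype=np.int8)

    def step_int(self, state: int, clamp_mask: int = 0) -> int:
        nxt = 0
        for i, (ppos, table) in enumerate(self._compiled):
            if not ppos:
                bit = table & 1
            else:
                idx = 0
                for j, p in enumerate(ppos):
                    idx |= ((state >> p) & 1) << j
                bit = (table >> idx) & 1
            if bit:
                nxt |= 1 << i
        return nxt & ~clamp_mask


@dataclass(frozen=True)
class PerturbationSpec:
    """Set of genes clamped OFF plus a condition label."""

    clamped_off: frozenset = frozenset()
    label: str = "baseline"

    @staticmethod
    def knockdown(genes: Sequence[str]) -> "PerturbationSpec":
        return PerturbationSpec(frozenset(genes), "+".join(sorted(genes)) or "baseline")


def _clamp_mask(model: NetworkModel, pert: PerturbationSpec) -> int:
    mask = 0
    for g in pert.clamped_off:
        if g not in model.index:
            raise ValueError(f"clamped gene {g!r} not in roster")
        mask |= 1 << model.index[g]
    return mask


def step(
    model: NetworkModel, state: Sequence[int], pert: PerturbationSpec | None = None
) -> np.ndarray:
    """One synchronous update of a 0/1 state vector; clamped genes forced 0."""
    state = list(state)
    if len(state) != model.n:
        raise ValueError("state length does not match roster")
    mask = _clamp_mask(model, pert) if pert else 0
    return model.unpack(model.step_int(model.pack(state), mask))


@dataclass
class Attractor:
    """A recurrent state set with its estimated basin weight."""

    states: list[np.ndarray]  # ordered cycle; length 1 = fixed point
    basin_weight: float = 0.0

    @property
    def cycle_length(self) -> int:
        return len(self.states)

    @property
    def mean_state(self) -> np.ndarray:
        return np.mean(self.states, axis=0)


@dataclass
class AttractorRun:
    attractor_key: tuple[int, ...] | None  # canonical packed cycle; None = not converged
    steps: int  # steps to enter the recurrent set
    final_state: int


def _find_attractor_int(
    model: NetworkModel, init: int, clamp_mask: int, max_steps: int,
    cache: dict[int, int] | None = None,
) -> AttractorRun:
    state = init & ~clamp_mask
    seen: dict[int, int] = {state: 0}
    traj = [state]
    for t in range(1, max_steps + 1):
        if cache is not None:
            nxt = cache.get(state)
            if nxt is None:
                nxt = model.step_int(state, clamp_mask)
                cache[state] = nxt
        else:
            nxt = model.step_int(state, clamp_mask)
        state = nxt
        if state in seen:
            t0 = seen[state]
            cycle = traj[t0:]
            k = cycle.index(min(cycle))
            canon = tuple(cycle[k:] + cycle[:k])
            return AttractorRun(canon, t0, state)
        seen[state] = t
        traj.append(state)
    return AttractorRun(None, max_steps, state)


def run_to_attractor(
    model: NetworkModel,
    init: Sequence[int],
    pert: PerturbationSpec | None = None,
    max_steps: int = 30,
) -> tuple[Attractor | None, int]:
    """Evolve one initial condition until a state revisit (or max_steps).

    Returns (attractor, steps-to-reach); a non-converged trajectory yields
    (None, max_steps) — a flagged outcome, not an exception.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    mask = _clamp_mask(model, pert) if pert else 0
    run = _find_attractor_int(model, model.pack(init), mask, max_steps)
    if run.attractor_key is None:
        return None, run.steps
    states = [model.unpack(s) for s in run.attractor_key]
    return Attractor(states), run.steps


@dataclass
class ConditionResult:
    """Basin-weighted outcome of one perturbation condition."""

    label: str
    g: pd.Series  # per gene, mean over models of basin-weighted activity
    dominant_frequency: float  # mean over models of max attractor weight
    steps: list[int]  # steps-to-attractor across all runs
    attractors_per_model: list[list[Attractor]] = field(default_factory=list)
    n_nonconverged: int = 0


def simulate_condition(
    models: Sequence[NetworkModel],
    pert: PerturbationSpec,
    n_init: int = 100,
    max_steps: int = 30,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ConditionResult:
    """Monte-Carlo basin weighting of one condition over sampled models.

    For each model, ``n_init`` uniform random initial states (clamped genes
    fixed at 0) are evolved; each attractor's weight is the fraction of
    starts reaching it; per-gene activity is the weight-averaged mean state
    (limit cycles contribute their cycle mean); the reported activity is
    averaged over models.
    """
    if not models:
        raise ValueError("need at least one model")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    if rng is None:
        if seed is None:
            raise ValueError("a seed (or rng) is mandatory for reproducibility")
        rng = np.random.default_rng(seed)
    roster = models[0].roster
    g_models = []
    dom = []
    steps_all: list[int] = []
    attractors_all = []
    n_noncon = 0
    for model in models:
        if model.roster != roster:
            raise ValueError("models must share a roster")
        mask = _clamp_mask(model, pert)
        cache: dict[int, int] = {}
        weights: dict[tuple[int, ...], int] = {}
        for _ in range(n_init):
            init = int(rng.integers(0, 2 ** model.n)) & ~mask
            run = _find_attractor_int(model, init, mask, max_steps, cache)
            if run.attractor_key is None:
                n_noncon += 1
                key = (run.final_state,)  # best available: record final state
            else:
                key = run.attractor_key
            weights[key] = weights.get(key, 0) + 1
            steps_all.append(run.steps)
        attrs = []
        gvec = np.zeros(model.n)
        for key, cnt in sorted(weights.items()):
            a = Attractor([model.unpack(s) for s in key], cnt / n_init)
            attrs.append(a)
            gvec += a.basin_weight * a.mean_state
        g_models.append(gvec)
        dom.append(max(w for w in (a.basin_weight for a in attrs)))
        attractors_all.append(attrs)
    g = pd.Series(np.mean(g_models, axis=0), index=list(roster))
    return ConditionResult(
        pert.label, g, float(np.mean(dom)), steps_all, attractors_all, n_noncon
    )


@dataclass
class SimulationResult:
    """Genes x conditions table of basin-weighted mean activities."""

    g: pd.DataFrame  # rows genes, columns condition labels
    baseline: str
    dominant_frequency: pd.Series
    conditions: dict[str, ConditionResult]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.g.index)


def delta_sim(result: SimulationResult, baseline: str | None = None,
              eps: float = 0.1) -> pd.DataFrame:
    """Three-level expression change vs baseline: sign(g - g_baseline) with
    |difference| <= eps mapped to 0 (-1 down, 0 no change, +1 up)."""
    base = baseline if baseline is not None else result.baseline
    if base not in result.g.columns:
        raise ValueError(f"baseline condition {base!r} not present")
    diff = result.g.sub(result.g[base], axis=0)
    ds = np.sign(diff.where(diff.abs() > eps, 0.0)).astype(int)
    return ds


def sample_models(
    ensembles: Mapping[str, FunctionEnsemble],
    roster: Sequence[str],
    binary: BinaryMatrix,
    n_models: int = 10,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[NetworkModel]:
    """Sample concrete networks from the learned ensembles.

    Per gene, one member function is drawn uniformly (independently across
    genes).  A gene whose ensemble is empty gets a constant rule frozen at
    its majority binarized value — the state space must stay closed.
    """
    if rng is None:
        if seed is None:
            raise ValueError("a seed (or rng) is mandatory for reproducibility")
        rng = np.random.default_rng(seed)
    models = []
    for m in range(n_models):
        rules: dict[str, Rule] = {}
        for g in roster:
            ens = ensembles.get(g)
            if ens is not None and ens.functions:
                rules[g] = ens.functions[int(rng.integers(len(ens.functions)))]
            else:
                maj = int(round(binary.values.loc[g].mean()))
                rules[g] = ConstantRule(g, maj)
        models.append(NetworkModel(roster, rules, provenance=f"sample_{m}"))
    return models


def knockdown_screen(
    models: Sequence[NetworkModel],
    subset: Sequence[str],
    max_combo: int = 1,
    n_init: int = 100,
    max_steps: int = 30,
    seed: int = 0,
    extra_conditions: Sequence[PerturbationSpec] = (),
) -> SimulationResult:
    """Simulate the unperturbed baseline plus every single (and pair, and
    triple, per ``max_combo``) knockdown of genes from ``subset``.

    The same sampled models are held fixed across all conditions of one
    screen so conditions are compared like-for-like.
    """
    roster = models[0].roster
    for g in subset:
        if g not in roster:
            raise ValueError(f"screen gene {g!r} not in roster")
    if max_combo not in (1, 2, 3):
        raise ValueError("max_combo must be 1, 2 or 3")
    perts = [PerturbationSpec(frozenset(), "baseline")]
    for k in range(1, max_combo + 1):
        for combo in itertools.combinations(subset, k):
            perts.append(PerturbationSpec.knockdown(combo))
    perts.extend(extra_conditions)
    cols = {}
    dom = {}
    conds = {}
    for i, pert in enumerate(perts):
        res = simulate_condition(
            models, pert, n_init=n_init, max_steps=max_steps, seed=seed + i
        )
        cols[pert.label] = res.g
        dom[pert.label] = res.dominant_frequency
        conds[pert.label] = res
    g = pd.DataFrame(cols)
    return SimulationResult(g, "baseline", pd.Series(dom), conds)


# ----------------------------------------------------------------------
# exhaustive oracle-style analysis for small models (also used by tests)
# ----------------------------------------------------------------------

def exact_attractors(
    model: NetworkModel, pert: PerturbationSpec | None = None
) -> dict[tuple[int, ...], float]:
    """Exact attractors and basin fractions from the full 2**n transition
    graph (free genes only).  Tractable for small n."""
    mask = _clamp_mask(model, pert) if pert else 0
    free = [i for i in range(model.n) if not (mask >> i) & 1]
    basins: dict[tuple[int, ...], int] = {}
    cache: dict[int, int] = {}
    for combo in range(1 << len(free)):
        init = 0
        for j, i in enumerate(free):
            if (combo >> j) & 1:
                init |= 1 << i
        run = _find_attractor_int(model, init, mask, 2 ** model.n + 1, cache)
        basins[run.attractor_key] = basins.get(run.attractor_key, 0) + 1
    total = 1 << len(free)
    return {k: v / total for k, v in basins.items()}
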
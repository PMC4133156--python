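"""Learning read-once AND/OR/NOT Boolean transition functions from
binarized single-cell snapshots, constrained by a prior signed topology.

Each candidate update rule for a target gene is a *read-once* formula: an
expression tree whose internal nodes are binary AND/OR, whose leaves are
the parent genes each appearing exactly once, optionally negated.  (Any
read-once formula with NOT at arbitrary positions can be rewritten with
negations pushed to the leaves, so leaf-level negation loses no
generality.)  XOR and threshold gates are excluded by construction.

A function's fit is the fraction of cells in which its output on the
cell's parent states equals the cell's target state — single cells are
treated as steady-state snapshots, so the same cell provides both the
input and the output of the rule.

Learning proceeds in stages: first all read-once functions over the prior
parent set and every subset reachable by recursively removing parents
one-by-one are scored (auto-regulatory edges are dropped first); if no
function reaches the agreement threshold, single replacement parents and
then parent pairs are drawn from a refinement pool of core regulators.
The returned ensemble holds every function at the maximal attained
agreement, with equal-agreement members ordered so those whose literal
signs match more prior edge signs come first.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np

from .network import SignedNetwork
from .preprocess import BinaryMatrix

# expression trees: ("lit", parent_index, negated) | (op, left, right)
Tree = tuple


@dataclass(frozen=True)
class BooleanFunction:
    """A read-once formula over an ordered parent tuple plus its truth table.

    ``truth_table`` is an integer whose bit ``i`` is the output for the
    input pattern in which parent ``j`` contributes bit ``j`` of ``i``.
    """

    target: str
    parents: tuple[str, ...]
    tree: Tree
    truth_table: int
    agreement: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.parents) < 1:
            raise ValueError("a learned function needs at least one parent")
        if len(set(self.parents)) != len(self.parents):
            raise ValueError("repeated parent")
        if self.target in self.parents:
            raise ValueError("auto-regulation is excluded from dynamic rules")

    @property
    def formula(self) -> str:
        return _format_tree(self.tree, self.parents)

    def literal_signs(self) -> dict[str, int]:
        """+1 for an unnegated leaf, -1 for a negated one (read-once, so
        each parent has a single, well-defined polarity)."""
        out: dict[str, int] = {}
        _collect_signs(self.tree, self.parents, out)
        return out

    def evaluate(self, parent_bits: np.ndarray) -> np.ndarray:
        """Evaluate on an (n_obs, n_parents) 0/1 array via table lookup."""
        idx = np.zeros(parent_bits.shape[0], dtype=np.int64)
        for j in range(len(self.parents)):
            idx |= parent_bits[:, j].astype(np.int64) << j
        table = np.array(
            [(self.truth_table >> i) & 1 for i in range(1 << len(self.parents))],
            dtype=np.int8,
        )
        return table[idx]


def _format_tree(tree: Tree, parents: tuple[str, ...]) -> str:
    if tree[0] == "lit":
        _, j, neg = tree
        return f"NOT({parents[j]})" if neg else parents[j]
    op, l, r = tree
    return f"{op}({_format_tree(l, parents)},{_format_tree(r, parents)})"


def _collect_signs(tree: Tree, parents: tuple[str, ...], out: dict[str, int]) -> None:
    if tree[0] == "lit":
        _, j, neg = tree
        out[parents[j]] = -1 if neg else 1
    else:
        _collect_signs(tree[1], parents, out)
        _collect_signs(tree[2], parents, out)


def _tree_table(tree: Tree, n: int) -> int:
    """Truth table (int over 2**n patterns) of an expression tree."""
    if tree[0] == "lit":
        _, j, neg = tree
        var = 0
        for i in range(1 << n):
            if (i >> j) & 1:
                var |= 1 << i
        return ((1 << (1 << n)) - 1) ^ var if neg else var
    op, l, r = tree
    tl, tr = _tree_table(l, n), _tree_table(r, n)
    return (tl & tr) if op == "AND" else (tl | tr)


def make_function(target: str, parents: Sequence[str], tree: Tree) -> BooleanFunction:
    """Build a BooleanFunction from an explicit expression tree."""
    return BooleanFunction(
        target, tuple(parents), tree, _tree_table(tree, len(parents))
    )


# ----------------------------------------------------------------------
# read-once enumeration
# ----------------------------------------------------------------------

MAX_PARENTS_HARD = 6


@lru_cache(maxsize=None)
def _readonce_tables(n: int, subset: frozenset) -> dict[int, Tree]:
    """Distinct truth tables (over the full 2**n pattern space) of read-once
    formulas whose leaf set is exactly ``subset`` of variables 0..n-1.

    Built bottom-up: a formula over S is ``left op right`` for an unordered
    split S = A | B; deduplication by truth table at every level keeps the
    dictionaries small.  Deterministic: splits and sub-tables are visited
    in sorted order and the first tree found for a table is kept.
    """
    full = (1 << (1 << n)) - 1
    members = sorted(subset)
    if len(members) == 1:
        j = members[0]
        var = 0
        for i in range(1 << n):
            if (i >> j) & 1:
                var |= 1 << i
        return {var: ("lit", j, False), full ^ var: ("lit", j, True)}
    out: dict[int, Tree] = {}
    anchor = members[0]
    rest = members[1:]
    for k in range(0, len(rest)):
        for combo in itertools.combinations(rest, k):
            a = frozenset((anchor,) + combo)
            b = subset - a
            if not b:
                continue
            ta = _readonce_tables(n, a)
            tb = _readonce_tables(n, b)
            for va in sorted(ta):
                for vb in sorted(tb):
                    t_and = va & vb
                    if t_and not in out:
                        out[t_and] = ("AND", ta[va], tb[vb])
                    t_or = va | vb
                    if t_or not in out:
                        out[t_or] = ("OR", ta[va], tb[vb])
    return out


def enumerate_readonce(
    parents: Sequence[str], target: str = "", max_parents: int = MAX_PARENTS_HARD
) -> list[BooleanFunction]:
    """All read-once AND/OR/NOT functions over exactly these parents,
    deduplicated by truth table, in deterministic (ascending-table) order."""
    p = len(parents)
    if p < 1:
        raise ValueError("need at least one parent")
    if p > max_parents:
        raise ValueError(
            f"{p} parents exceeds max_parents={max_parents}; read-once "
            "enumeration is exponential — raise the cap explicitly if intended"
        )
    tables = _readonce_tables(p, frozenset(range(p)))
    return [
        BooleanFunction(target, tuple(parents), tables[t], t)
        for t in sorted(tables)
    ]


# ----------------------------------------------------------------------
# scoring
# ----------------------------------------------------------------------

def _pattern_counts(
    binary: BinaryMatrix, parents: Sequence[str], target: str
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per input pattern: number of cells with target 0 and with target 1."""
    vals = binary.values
    n_cells = vals.shape[1]
    if n_cells == 0:
        raise ValueError("empty binary matrix")
    idx = np.zeros(n_cells, dtype=np.int64)
    for j, g in enumerate(parents):
        idx |= vals.loc[g].to_numpy(dtype=np.int64) << j
    tgt = vals.loc[target].to_numpy(dtype=np.int64)
    size = 1 << len(parents)
    cnt1 = np.bincount(idx[tgt == 1], minlength=size).astype(np.int64)
    cnt0 = np.bincount(idx[tgt == 0], minlength=size).astype(np.int64)
    return cnt0, cnt1, n_cells


def score_function(f: BooleanFunction, binary: BinaryMatrix) -> float:
    """Fraction of cells whose snapshot satisfies f(parent bits) == target bit."""
    cnt0, cnt1, n = _pattern_counts(binary, f.parents, f.target)
    agree = 0
    for pat in range(1 << len(f.parents)):
        agree += cnt1[pat] if (f.truth_table >> pat) & 1 else cnt0[pat]
    return agree / n


def _score_tables(
    tables: np.ndarray, cnt0: np.ndarray, cnt1: np.ndarray, n: int
) -> np.ndarray:
    """Vectorized agreement for many truth tables (uint64) at once.

    Accumulates per input pattern instead of materializing the full
    (n_tables x 2**p) bit matrix, keeping memory flat for big ensembles.
    """
    size = len(cnt0)
    agree = np.full(len(tables), cnt0.sum(), dtype=np.int64)
    one = np.uint64(1)
    for pat in range(size):
        diff = int(cnt1[pat] - cnt0[pat])
        if diff:
            agree += ((tables >> np.uint64(pat)) & one).astype(np.int64) * diff
    return agree / n


# ----------------------------------------------------------------------
# staged learning
# ----------------------------------------------------------------------

@dataclass
class LearningConfig:
    """Knobs of the function-learning stage.

    theta: agreement threshold as a fraction of cells (0.5 < theta <= 1).
    max_parents: cap on parent-set size for read-once enumeration.
    refinement_pool: candidate regulators for the reassignment stage
        (classically the core pluripotency factors).
    consensus_fraction: a parent->target link enters the consensus network
        only if present with one polarity in more than this fraction of
        equally-well-fitted functions.
    """

    theta: float = 0.85
    max_parents: int = MAX_PARENTS_HARD
    refinement_pool: tuple[str, ...] = ()
    consensus_fraction: float = 0.9
    seed: int = 0
    prefer_prior_signs: bool = True

    def __post_init__(self) -> None:
        if not 0.5 < self.theta <= 1.0:
            raise ValueError("theta must lie in (0.5, 1]")


@dataclass
class FunctionEnsemble:
    """Equally-well-fitted functions for one target plus bookkeeping."""

    target: str
    functions: list[BooleanFunction]
    agreement: float
    stage: str  # prior | reassign_single | reassign_pair | unresolved | no_prior
    prior_parents: tuple[str, ...] = ()
    consensus_fraction: float = 0.9

    @property
    def degeneracy(self) -> int:
        return len(self.functions)

    @property
    def pruned_links(self) -> set[str]:
        used = set().union(*(set(f.parents) for f in self.functions)) if self.functions else set()
        return set(self.prior_parents) - used

    @property
    def novel_links(self) -> set[str]:
        used = set().union(*(set(f.parents) for f in self.functions)) if self.functions else set()
        return used - set(self.prior_parents)

    def consensus_edges(self) -> dict[str, int]:
        """Parents present with a single polarity in > consensus_fraction of
        members, mapped to their sign.  Mixed polarity blocks the link."""
        if not self.functions:
            return {}
        n = len(self.functions)
        pos: dict[str, int] = {}
        neg: dict[str, int] = {}
        for f in self.functions:
            for g, s in f.literal_signs().items():
                (pos if s > 0 else neg)[g] = (pos if s > 0 else neg).get(g, 0) + 1
        out: dict[str, int] = {}
        for g in set(pos) | set(neg):
            if pos.get(g, 0) / n > self.consensus_fraction:
                out[g] = 1
            elif neg.get(g, 0) / n > self.consensus_fraction:
                out[g] = -1
        return out


def _prior_sign_matches(f: BooleanFunction, prior_signs: Mapping[str, int]) -> int:
    return sum(
        1 for g, s in f.literal_signs().items() if prior_signs.get(g) == s
    )


def _best_functions(
    parent_sets: Sequence[tuple[str, ...]],
    target: str,
    binary: BinaryMatrix,
    cfg: LearningConfig,
    prior_signs: Mapping[str, int],
) -> tuple[list[BooleanFunction], float]:
    """Score all read-once functions over each parent set; return every
    function at the maximal agreement (across all sets), ordered with
    prior-sign-consistent members first."""
    best: list[BooleanFunction] = []
    best_a = -1.0
    for ps in parent_sets:
        tables_dict = _readonce_tables(len(ps), frozenset(range(len(ps))))
        tables = np.array(sorted(tables_dict), dtype=np.uint64)
        cnt0, cnt1, n = _pattern_counts(binary, ps, target)
        agr = _score_tables(tables, cnt0, cnt1, n)
        top = agr.max()
        if top < best_a - 1e-12:
            continue
        if top > best_a + 1e-12:
            best, best_a = [], float(top)
        for t, a in zip(tables[agr >= best_a - 1e-12], agr[agr >= best_a - 1e-12]):
            t = int(t)
            best.append(
                BooleanFunction(target, ps, tables_dict[t], t, agreement=float(a))
            )
    if cfg.prefer_prior_signs:
        best.sort(
            key=lambda f: (
                -_prior_sign_matches(f, prior_signs),
                len(f.parents),
                f.parents,
                f.truth_table,
            )
        )
    else:
        best.sort(key=lambda f: (len(f.parents), f.parents, f.truth_table))
    return best, best_a


def learn_node(
    target: str,
    prior: SignedNetwork,
    binary: BinaryMatrix,
    cfg: LearningConfig,
) -> FunctionEnsemble:
    """Staged search for the best-fitting read-once update rules of one gene.

    Stage 1 scores all read-once functions over the prior parent set and
    every subset obtained by recursive one-by-one parent removal.  Stage 2
    (only when nothing reaches theta) reassigns parents from the refinement
    pool: singles first, then pairs.  If no stage reaches theta the
    best-agreement ensemble is returned flagged "unresolved" — never
    silently empty.
    """
    prior_parents = tuple(
        g for g, _ in prior.parents_of(target, drop_self=True)
    )
    prior_signs = {g: s for g, s in prior.parents_of(target, drop_self=True)}

    def subsets(parents: tuple[str, ...]) -> list[tuple[str, ...]]:
        out = []
        for k in range(min(len(parents), cfg.max_parents), 0, -1):
            out.extend(itertools.combinations(parents, k))
        return out

    if not prior_parents:
        if not cfg.refinement_pool:
            return FunctionEnsemble(target, [], 0.0, "no_prior", (), cfg.consensus_fraction)
        stage1_sets: list[tuple[str, ...]] = []
    else:
        stage1_sets = subsets(prior_parents)

    if stage1_sets:
        funcs, agr = _best_functions(stage1_sets, target, binary, cfg, prior_signs)
        if agr >= cfg.theta:
            return FunctionEnsemble(
                target, funcs, agr, "prior", prior_parents, cfg.consensus_fraction
            )
    else:
        funcs, agr = [], -1.0

    pool = tuple(g for g in cfg.refinement_pool if g != target)
    for stage, sets in (
        ("reassign_single", [(g,) for g in pool]),
        ("reassign_pair", list(itertools.combinations(pool, 2))),
    ):
        if not sets:
            continue
        funcs2, agr2 = _best_functions(sets, target, binary, cfg, prior_signs)
        if agr2 >= cfg.theta:
            return FunctionEnsemble(
                target, funcs2, agr2, stage, prior_parents, cfg.consensus_fraction
            )
        if agr2 > agr:
            funcs, agr = funcs2, agr2
    return FunctionEnsemble(
        target, funcs, max(agr, 0.0), "unresolved", prior_parents, cfg.consensus_fraction
    )


@dataclass
class LearnResult:
    ensembles: dict[str, FunctionEnsemble]
    consensus: SignedNetwork

    @property
    def unresolved(self) -> list[str]:
        return [t for t, e in self.ensembles.items() if e.stage == "unresolved"]


def learn_all(
    prior: SignedNetwork, binary: BinaryMatrix, cfg: LearningConfig
) -> LearnResult:
    """Learn ensembles for every network gene and build the consensus network.

    Consensus edges are the parent->target links present with a single
    polarity in more than ``cfg.consensus_fraction`` of each ensemble's
    equally-well-fitted functions; literal polarity gives the edge sign.
    """
    missing = [g for g in prior.gene_ids if g not in set(binary.gene_ids)]
    if missing:
        raise ValueError(f"genes missing from binary matrix: {missing}")
    ensembles = {g: learn_node(g, prior, binary, cfg) for g in prior.gene_ids}
    edges: dict[tuple[str, str], int] = {}
    for tgt, ens in ensembles.items():
        for parent, sign in ens.consensus_edges().items():
            edges[(parent, tgt)] = sign
    consensus = SignedNetwork(list(prior.nodes), edges)
    return LearnResult(ensembles, consensus)


# ----------------------------------------------------------------------
# AND-gate pair analysis
# ----------------------------------------------------------------------

def _and_pairs(tree: Tree, parents: tuple[str, ...]) -> set[frozenset]:
    """Unordered regulator pairs bridged by some AND node: all cross pairs
    of leaves between the two subtrees of each AND."""
    pairs: set[frozenset] = set()

    def leaves(t: Tree) -> list[str]:
        if t[0] == "lit":
            return [parents[t[1]]]
        return leaves(t[1]) + leaves(t[2])

    def walk(t: Tree) -> None:
        if t[0] == "lit":
            return
        op, l, r = t
        if op == "AND":
            for a in leaves(l):
                for b in leaves(r):
                    pairs.add(frozenset((a, b)))
        walk(l)
        walk(r)

    walk(tree)
    return pairs


def and_pair_ranking(
    ensembles: Mapping[str, FunctionEnsemble]
) -> list[tuple[frozenset, int]]:
    """Regulator pairs ranked by how many member functions join them with an
    AND gate.  Descending frequency; ties broken lexicographically."""
    if not ensembles:
        raise ValueError("empty ensemble map")
    counts: dict[frozenset, int] = {}
    for ens in ensembles.values():
        for f in ens.functions:
            for pair in _and_pairs(f.tree, f.parents):
                counts[pair] = counts.get(pair, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], tuple(sorted(kv[0]))))


def and_pair_enrichment(
    ensembles: Mapping[str, FunctionEnsemble],
    reference_pairs: Sequence[frozenset],
    universe: Sequence[str],
) -> tuple[int, float]:
    """One-tailed Fisher exact test: are reference (e.g. known
    protein-protein-interaction) pairs over-represented among AND-supported
    pairs, against all unordered pairs of the given regulator universe?

    Returns (number of reference pairs AND-supported, p-value).
    """
    from scipy.stats import fisher_exact

    supported = {p for p, c in and_pair_ranking(ensembles) if c > 0}
    all_pairs = {frozenset(p) for p in itertools.combinations(sorted(set(universe)), 2)}
    ref = {frozenset(p) for p in reference_pairs} & all_pairs
    a = len(ref & supported)
    b = len(ref - supported)
    c = len((all_pairs - ref) & supported)
    d = len(all_pairs - ref - supported)
    _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
    return a, float(p)
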
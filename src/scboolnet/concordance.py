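"""Concordance between in-silico knockdown predictions and experimental
fold-changes, benchmarking against a random predictor, and robustness of
the whole pipeline to data / topology randomization.

Sign conventions.  The simulated change dS takes -1/0/+1 for
down-regulation / no change / up-regulation.  Experimental values dE are
log2 fold-changes in Ct space relative to empty-vector controls: positive
dE means down-regulation, negative means up-regulation.  Perfect agreement
therefore has dS and tanh(dE/c) of opposite sign, and the disagreement
magnitude is d = |dS + tanh(dE/c)|, in [0, 2].

The discordance score is a logistic squashing of d:

    D = sigma(k * (d - d0)),   sigma(x) = 1 / (1 + exp(-x))

with defaults k = 4, d0 = 1, c = 2.  D is strictly inside (0, 1): even a
perfectly concordant entry never reaches 0 and a maximally discordant one
never reaches 1 — so a "percent concordance" display 100*(1-D) never
attains 100.  The objective O is the mean of D over all gene x condition
entries.  Any strictly increasing logistic of a disagreement magnitude
honoring the sign conventions above would serve; this parameterization
keeps D <= 0.05 at d = 0 and D >= 0.95 at d = 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import ttest_1samp

from .network import SignedNetwork
from .preprocess import BinaryMatrix


@dataclass(frozen=True)
class DiscordanceParams:
    k: float = 4.0  # logistic steepness
    d0: float = 1.0  # disagreement magnitude at the D = 0.5 midpoint
    c: float = 2.0  # log2-fold-change saturation scale of tanh

    def __post_init__(self) -> None:
        if not (self.k > 0 and self.c > 0):
            raise ValueError("k and c must be positive")


def discordance(
    delta_s, delta_e, params: DiscordanceParams = DiscordanceParams()
):
    """Elementwise discordance D in (0, 1); accepts scalars or arrays."""
    ds = np.asarray(delta_s, dtype=float)
    de = np.asarray(delta_e, dtype=float)
    if not np.all(np.isfinite(de)):
        raise ValueError("non-finite experimental fold-changes")
    if not np.all(np.isin(ds, (-1.0, 0.0, 1.0))):
        raise ValueError("simulated changes must be in {-1, 0, +1}")
    d = np.abs(ds + np.tanh(de / params.c))
    out = expit(params.k * (d - params.d0))
    return float(out) if out.ndim == 0 else out


class ExperimentFC:
    """Gene x condition log2 fold-changes, Ct-space orientation
    (positive = down-regulation).  Conventionally-signed log2FC input
    (positive = up-regulation) must be declared via ``orientation="expression"``
    and is flipped on ingest — silent sign inversion is the classic bug here."""

    def __init__(self, values: pd.DataFrame, orientation: str = "ct"):
        if orientation not in ("ct", "expression"):
            raise ValueError("orientation must be 'ct' or 'expression'")
        vals = values.astype(float)
        if not np.isfinite(vals.to_numpy()).all():
            raise ValueError("fold-change table contains non-finite values")
        self.values = -vals if orientation == "expression" else vals

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class DiscordanceMatrix:
    D: pd.DataFrame  # gene x condition, in (0, 1)

    @property
    def objective(self) -> float:
        """O: mean discordance over all entries."""
        return float(self.D.to_numpy().mean())

    @property
    def concordance_display(self) -> pd.DataFrame:
        """100 * (1 - D); never attains 100 by construction."""
        return 100.0 * (1.0 - self.D)


def compare(
    delta_s: pd.DataFrame,
    exp: ExperimentFC,
    params: DiscordanceParams = DiscordanceParams(),
    conditions: Sequence[str] | None = None,
) -> DiscordanceMatrix:
    """Elementwise discordance between a simulated change matrix and the
    experimental table, over their aligned gene/condition rosters."""
    if conditions is None:
        conditions = [c for c in exp.values.columns]
    genes = list(exp.values.index)
    missing_g = [g for g in genes if g not in delta_s.index]
    missing_c = [c for c in conditions if c not in delta_s.columns]
    if missing_g or missing_c:
        raise ValueError(
            f"roster mismatch: genes {missing_g} / conditions {missing_c} absent from simulation"
        )
    ds = delta_s.loc[genes, conditions]
    de = exp.values.loc[genes, conditions]
    D = pd.DataFrame(
        discordance(ds.to_numpy(), de.to_numpy(), params),
        index=genes, columns=list(conditions),
    )
    return DiscordanceMatrix(D)


# ----------------------------------------------------------------------
# random-predictor benchmark
# ----------------------------------------------------------------------

def random_predictor_expectation(
    exp: ExperimentFC, params: DiscordanceParams = DiscordanceParams()
) -> float:
    """Closed-form expected objective of the uniform three-point random
    predictor: each entry's dS is -1, 0 or +1 with probability 1/3."""
    de = exp.values.to_numpy(dtype=float)
    acc = np.zeros_like(de)
    for s in (-1.0, 0.0, 1.0):
        acc += discordance(np.full_like(de, s), de, params)
    return float((acc / 3.0).mean())


@dataclass
class RandomPredictorResult:
    objectives: np.ndarray  # O of each random matrix
    o_model: float
    statistic: float
    pvalue: float  # one-sample t-test of random Os vs the model O

    @property
    def mean(self) -> float:
        return float(self.objectives.mean())

    @property
    def sd(self) -> float:
        return float(self.objectives.std(ddof=1))


def random_predictor_test(
    exp: ExperimentFC,
    o_model: float,
    n_rand: int = 500,
    params: DiscordanceParams = DiscordanceParams(),
    seed: int = 0,
) -> RandomPredictorResult:
    """Monte-Carlo distribution of the random predictor's objective against
    the fixed experimental table, and a one-sample t-test of the null that
    the random mean equals the model's objective."""
    if n_rand < 2:
        raise ValueError("n_rand must be >= 2")
    rng = np.random.default_rng(seed)
    de = exp.values.to_numpy(dtype=float)
    objectives = np.empty(n_rand)
    for i in range(n_rand):
        ds = rng.integers(-1, 2, size=de.shape).astype(float)
        objectives[i] = discordance(ds, de, params).mean()
    stat, p = ttest_1samp(objectives, popmean=o_model)
    return RandomPredictorResult(objectives, o_model, float(stat), float(p))


# ----------------------------------------------------------------------
# robustness to data / topology randomization
# ----------------------------------------------------------------------

def flip_bits(binary: BinaryMatrix, percent: float, rng: np.random.Generator) -> BinaryMatrix:
    """Randomize ceil(percent% of entries) uniformly chosen matrix bits.

    Each selected entry is re-drawn uniformly from {0, 1} (a coin flip,
    i.e. flipped with probability 1/2).  Deterministically inverting the
    selected bits would NOT destroy information at percent = 100 — the
    complement of a binary matrix is learnable back to an equivalent
    model — so full selection must mean full randomization for the
    p = 100 anchor (no residual predictive power) to hold.
    """
    vals = binary.values.to_numpy().copy()
    n_flip = int(np.ceil(percent / 100.0 * vals.size))
    if n_flip:
        flat = rng.choice(vals.size, size=n_flip, replace=False)
        vals.flat[flat] = rng.integers(0, 2, size=n_flip)
    return BinaryMatrix(
        pd.DataFrame(vals, index=binary.values.index, columns=binary.values.columns),
        binary.centroids,
        list(binary.degenerate_genes),
    )


def rewire_edges(net: SignedNetwork, percent: float, rng: np.random.Generator) -> SignedNetwork:
    """Reassign ceil(percent% of edges) to uniformly chosen new ordered
    endpoint pairs, keeping the edge count and signs, never duplicating an
    existing edge."""
    genes = net.gene_ids
    edges = dict(net.edges)
    keys = sorted(edges)
    n_rewire = int(np.ceil(percent / 100.0 * len(keys)))
    if n_rewire:
        chosen = rng.choice(len(keys), size=n_rewire, replace=False)
        for ki in chosen:
            old = keys[ki]
            sign = edges.pop(old)
            for _ in range(10_000):
                a = genes[int(rng.integers(len(genes)))]
                b = genes[int(rng.integers(len(genes)))]
                if (a, b) not in edges:
                    edges[(a, b)] = sign
                    break
            else:  # pragma: no cover - astronomically unlikely on real sizes
                edges[old] = sign
    return SignedNetwork(list(net.nodes), edges)


@dataclass
class RobustnessCurve:
    """Relative accuracy of the whole pipeline as randomization grows.

    relative accuracy(p) = (O_random - O(p)) / (O_random - O(0)), anchored
    at exactly 1 for p = 0 and at 0 in expectation for full randomization.
    """

    mode: str  # flip_data | rewire_links
    table: pd.DataFrame  # columns: p, mean, sd, plus one column per repeat
    o_random: float
    o_baseline: float


def robustness(
    binary: BinaryMatrix,
    prior: SignedNetwork,
    exp: ExperimentFC,
    pipeline: Callable[[BinaryMatrix, SignedNetwork, int], float],
    mode: str = "flip_data",
    p_grid: Sequence[float] = (0, 10, 20, 30, 40, 50),
    repeats: int = 10,
    params: DiscordanceParams = DiscordanceParams(),
    seed: int = 0,
) -> RobustnessCurve:
    """Re-run learn -> simulate -> compare on progressively randomized
    inputs and track the relative accuracy.

    ``pipeline(binary, prior, seed) -> O`` encapsulates one full
    learn/screen/compare pass; this function only owns the randomization
    and the accuracy normalization.  p = 0 repeats are identity runs and
    the baseline O(0) is computed once from the unperturbed inputs.
    """
    if mode not in ("flip_data", "rewire_links"):
        raise ValueError("mode must be flip_data or rewire_links")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if any(p < 0 or p > 100 for p in p_grid):
        raise ValueError("p_grid entries must lie in [0, 100]")
    o_random = random_predictor_expectation(exp, params)
    o_base = pipeline(binary, prior, seed)
    denom = o_random - o_base
    if denom <= 0:
        raise ValueError(
            "baseline pipeline is no better than the random predictor; "
            "relative accuracy is undefined"
        )
    rows = []
    for p in p_grid:
        accs = []
        for r in range(repeats):
            if p == 0:
                accs.append(1.0)  # identity repeat by definition
                continue
            rng = np.random.default_rng((seed, int(p), r))
            if mode == "flip_data":
                b2, n2 = flip_bits(binary, p, rng), prior
            else:
                b2, n2 = binary, rewire_edges(prior, p, rng)
            o_p = pipeline(b2, n2, seed + r)
            accs.append((o_random - o_p) / denom)
        rows.append([p, float(np.mean(accs)), float(np.std(accs, ddof=1)) if repeats > 1 else 0.0, *accs])
    cols = ["p", "mean", "sd"] + [f"rep{r}" for r in range(repeats)]
    return RobustnessCurve(mode, pd.DataFrame(rows, columns=cols), o_random, o_base)
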
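"""Lineage-commitment propensity predictions for knockdown conditions.

Two complementary scoring routes over a configurable lineage-marker
signature:

* simulation route — uses the basin-weighted network state after each
  in-silico knockdown: a marker's change signal is its own activity change
  when the marker is part of the dynamical model, otherwise the
  sign-weighted mean change of its curated upstream regulators;
* direct-target route — no dynamics at all: each knocked-down TF
  contributes the negation of its curated edge sign to every marker it
  binds and regulates, and effects add across the knocked-down set.

Positive scores mean predicted commitment toward the lineage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .dynamics import PerturbationSpec, SimulationResult
from .network import SignedNetwork

logger = logging.getLogger(__name__)


class LineageSignature:
    """Marker -> lineage assignments, optionally with curated upstream links.

    Backed by a table with columns (marker, lineage, upstream_regulator,
    sign); multiple rows per marker are allowed — one per upstream link — and
    a marker may serve several lineages only by being listed once per
    lineage.  Markers without upstream rows must be in-network to be scored
    by the simulation route.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"marker", "lineage", "upstream_regulator", "sign"}
        if not required <= set(table.columns):
            raise ValueError(f"signature table needs columns {sorted(required)}")
        if table.empty:
            raise ValueError("empty signature")
        self.table = table.copy()

    @property
    def lineages(self) -> list[str]:
        return sorted(self.table["lineage"].unique())

    def markers_of(self, lineage: str) -> list[str]:
        return sorted(self.table.loc[self.table["lineage"] == lineage, "marker"].unique())

    def upstream_links(self, marker: str) -> list[tuple[str, int]]:
        rows = self.table[
            (self.table["marker"] == marker)
            & self.table["upstream_regulator"].notna()
            & (self.table["upstream_regulator"] != "")
        ]
        return [(r.upstream_regulator, int(r.sign)) for r in rows.itertuples()]


@dataclass
class LineageScoreMatrix:
    scores: pd.DataFrame  # condition x lineage
    method: str  # simulation | direct_target


def lineage_score_sim(
    sim: SimulationResult,
    sig: LineageSignature,
    baseline: str | None = None,
) -> LineageScoreMatrix:
    """Lineage propensities from the simulated network state.

    Per condition and lineage: mean over the lineage's markers of the
    marker's change signal delta-g = g_condition - g_baseline.  Markers
    outside the simulated roster anchor through their curated upstream
    links as the sign-weighted mean of the regulators' delta-g; markers
    with no anchor at all are skipped with a warning.
    """
    base = baseline if baseline is not None else sim.baseline
    dg = sim.g.sub(sim.g[base], axis=0)
    roster = set(sim.gene_ids)
    rows = {}
    for cond in sim.g.columns:
        scores = {}
        for lin in sig.lineages:
            signals = []
            for m in sig.markers_of(lin):
                if m in roster:
                    signals.append(dg.loc[m, cond])
                else:
                    links = [(u, s) for u, s in sig.upstream_links(m) if u in roster]
                    if not links:
                        logger.warning("marker %s has no in-network anchor; skipped", m)
                        continue
                    signals.append(
                        float(np.mean([s * dg.loc[u, cond] for u, s in links]))
                    )
            scores[lin] = float(np.mean(signals)) if signals else float("nan")
        rows[cond] = scores
    return LineageScoreMatrix(pd.DataFrame(rows).T[sig.lineages], "simulation")


def lineage_score_direct(
    net: SignedNetwork,
    kds: Sequence[PerturbationSpec],
    sig: LineageSignature,
) -> LineageScoreMatrix:
    """Dynamics-free baseline: additive direct-target effects.

    Each knocked-down TF contributes -sign(TF -> marker) for every curated
    bound-and-responsive link to a marker (the assembled network holds
    exactly those links); marker effects sum over the knocked-down set and
    average within each lineage.
    """
    rows = {}
    for pert in kds:
        effects: dict[str, float] = {}
        for tf in pert.clamped_off:
            for (a, b), s in net.edges.items():
                if a == tf:
                    effects[b] = effects.get(b, 0.0) - s
        scores = {}
        for lin in sig.lineages:
            vals = [effects.get(m, 0.0) for m in sig.markers_of(lin)]
            scores[lin] = float(np.mean(vals)) if vals else float("nan")
        rows[pert.label] = scores
    return LineageScoreMatrix(pd.DataFrame(rows).T[sig.lineages], "direct_target")


def method_contrast(
    sim_scores: LineageScoreMatrix, direct_scores: LineageScoreMatrix
) -> pd.DataFrame:
    """Per condition: top lineage under each route, whether they agree, and
    the Spearman rank correlation across lineages (NaN when a route's
    scores are constant and ranks are undefined)."""
    a, b = sim_scores.scores, direct_scores.scores
    if list(a.index) != list(b.index) or list(a.columns) != list(b.columns):
        raise ValueError("score grids are not aligned")
    rows = []
    for cond in a.index:
        va, vb = a.loc[cond].to_numpy(), b.loc[cond].to_numpy()
        if np.all(va == va[0]) or np.all(vb == vb[0]):
            rho = float("nan")
        else:
            rho = float(spearmanr(va, vb).statistic)
        top_a = a.loc[cond].idxmax() if not np.all(np.isnan(va)) else None
        top_b = b.loc[cond].idxmax() if not np.all(np.isnan(vb)) else None
        rows.append((cond, top_a, top_b, top_a == top_b, rho))
    return pd.DataFrame(
        rows, columns=["condition", "top_sim", "top_direct", "top_agree", "spearman_rho"]
    ).set_index("condition")
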
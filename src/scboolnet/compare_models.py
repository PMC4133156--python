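"""Consensus and unique regulatory interactions across learned models.

Interactions are compared as signed ordered pairs: an edge whose sign
flipped between two models counts as two different interactions (sign
changes during learning are meaningful rewiring, not noise).  Sign-blind
matching is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .network import SignedNetwork

Interaction = tuple[str, str, int]


@dataclass
class ConsensusCount:
    counts: dict[Interaction, int]  # interaction -> number of models containing it
    histogram: dict[int, int]  # k -> number of interactions present in exactly k models
    n_models: int

    @property
    def unique(self) -> int:
        """Interactions present in exactly one model."""
        return self.histogram.get(1, 0)

    @property
    def consensus(self) -> int:
        """Interactions shared by all models."""
        return self.histogram.get(self.n_models, 0)


def consensus_count(
    models: Sequence[tuple[str, SignedNetwork]], sign_sensitive: bool = True
) -> ConsensusCount:
    """Tally each interaction's occurrence across a set of learned models.

    Models must share a node roster.  With ``sign_sensitive=False`` the
    sign is collapsed to 0 before matching.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models to compare")
    roster = set(models[0][1].gene_ids)
    counts: dict[Interaction, int] = {}
    for _, net in models:
        if set(net.gene_ids) != roster:
            raise ValueError("models do not share a node roster")
        for (a, b), s in net.edges.items():
            key = (a, b, s if sign_sensitive else 0)
            counts[key] = counts.get(key, 0) + 1
    histogram: dict[int, int] = {}
    for k in counts.values():
        histogram[k] = histogram.get(k, 0) + 1
    return ConsensusCount(counts, histogram, len(models))
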
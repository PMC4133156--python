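"""Signed directed regulatory-network assembly and feedback-loop analysis.

A regulatory edge TF -> gene is accepted only when physical binding evidence
(ChIP) coincides with functional evidence (loss- or gain-of-function
perturbation followed by expression profiling).  The edge sign is decided by
a weighted majority vote over the perturbation studies, with loss-of-function
reports weighted more heavily than gain-of-function reports, and the result
binarized with the sign function.  Conflicts that the vote cannot resolve
(weighted sum exactly zero) are dropped and surfaced in the provenance log so
they can be settled by explicit, citable overrides.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

NODE_CLASSES = ("pluripotency", "lineage")
LINEAGE_TAGS = ("trophectoderm", "endoderm", "mesoderm", "ectoderm", "none")
SOURCE_KINDS = ("LOF", "GOF", "ChIP")


@dataclass(frozen=True)
class EvidenceRecord:
    """One study-level report about a regulator/target pair."""

    regulator: str
    target: str
    source_kind: str  # LOF | GOF | ChIP
    sign: int | None  # +1 / -1 for LOF and GOF, None for ChIP
    study_id: str = ""

    def __post_init__(self) -> None:
        if self.source_kind not in SOURCE_KINDS:
            raise ValueError(f"unknown source_kind {self.source_kind!r}")
        if self.source_kind == "ChIP":
            if self.sign is not None:
                raise ValueError("ChIP records carry no sign")
        elif self.sign not in (-1, 1):
            raise ValueError(
                f"{self.source_kind} record needs sign in {{-1,+1}}, got {self.sign!r}"
            )


class EvidenceTable:
    """Collection of evidence records with duplicate rejection.

    Duplicates are keyed on (regulator, target, study_id, source_kind): the
    same study cannot report the same kind of evidence for a pair twice.
    """

    def __init__(self, records: Iterable[EvidenceRecord], roster: Sequence[str] | None = None):
        self.records: list[EvidenceRecord] = list(records)
        seen: set[tuple[str, str, str, str]] = set()
        for r in self.records:
            key = (r.regulator, r.target, r.study_id, r.source_kind)
            if key in seen:
                raise ValueError(f"duplicate evidence record {key}")
            seen.add(key)
            if roster is not None:
                for g in (r.regulator, r.target):
                    if g not in roster:
                        raise ValueError(f"gene {g!r} not in declared roster")
        self.roster = list(roster) if roster is not None else None

    def __len__(self) -> int:
        return len(self.records)

    def by_pair(self) -> dict[tuple[str, str], dict[str, list[int] | bool]]:
        """Group records as {(regulator, target): {lof: [...], gof: [...], chip: bool}}."""
        pairs: dict[tuple[str, str], dict] = {}
        for r in self.records:
            d = pairs.setdefault(
                (r.regulator, r.target), {"lof": [], "gof": [], "chip": False}
            )
            if r.source_kind == "LOF":
                d["lof"].append(r.sign)
            elif r.source_kind == "GOF":
                d["gof"].append(r.sign)
            else:
                d["chip"] = True
        return pairs


@dataclass(frozen=True)
class Node:
    gene: str
    node_class: str = "pluripotency"
    lineage_tag: str = "none"

    def __post_init__(self) -> None:
        if self.node_class not in NODE_CLASSES:
            raise ValueError(f"bad node_class {self.node_class!r}")
        if self.lineage_tag not in LINEAGE_TAGS:
            raise ValueError(f"bad lineage_tag {self.lineage_tag!r}")


class SignedNetwork:
    """Directed graph with +/-1 edge signs and typed nodes.

    At most one edge per ordered (regulator, target) pair.  Self-edges
    (auto-regulation) are allowed and reported by :attr:`auto_edges`.
    """

    def __init__(self, nodes: Iterable[Node | str], edges: Mapping[tuple[str, str], int]):
        self.nodes: list[Node] = [
            n if isinstance(n, Node) else Node(n) for n in nodes
        ]
        ids = [n.gene for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate node ids")
        self._ids = set(ids)
        self.edges: dict[tuple[str, str], int] = {}
        for (a, b), s in edges.items():
            if s not in (-1, 1):
                raise ValueError(f"edge sign must be +/-1, got {s!r}")
            if a not in self._ids or b not in self._ids:
                raise ValueError(f"edge ({a},{b}) references unknown node")
            self.edges[(a, b)] = int(s)

    # -- basic queries ------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return [n.gene for n in self.nodes]

    @property
    def auto_edges(self) -> list[tuple[str, int]]:
        return [(a, s) for (a, b), s in self.edges.items() if a == b]

    def node_class_sizes(self) -> dict[str, int]:
        sizes = {c: 0 for c in NODE_CLASSES}
        for n in self.nodes:
            sizes[n.node_class] += 1
        return sizes

    def parents_of(self, gene: str, *, drop_self: bool = False) -> list[tuple[str, int]]:
        out = [
            (a, s) for (a, b), s in self.edges.items()
            if b == gene and not (drop_self and a == b)
        ]
        order = {g: i for i, g in enumerate(self.gene_ids)}
        return sorted(out, key=lambda e: order[e[0]])

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for n in self.nodes:
            g.add_node(n.gene, node_class=n.node_class, lineage_tag=n.lineage_tag)
        for (a, b), s in self.edges.items():
            g.add_edge(a, b, sign=s)
        return g

    # -- serialization ------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "nodes": [
                    {"id": n.gene, "node_class": n.node_class, "lineage_tag": n.lineage_tag}
                    for n in self.nodes
                ],
                "edges": [
                    {"source": a, "target": b, "sign": s}
                    for (a, b), s in sorted(self.edges.items())
                ],
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SignedNetwork":
        obj = json.loads(text)
        nodes = [Node(d["id"], d["node_class"], d["lineage_tag"]) for d in obj["nodes"]]
        edges = {(d["source"], d["target"]): d["sign"] for d in obj["edges"]}
        return cls(nodes, edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges


# ----------------------------------------------------------------------
# edge voting and assembly
# ----------------------------------------------------------------------

def vote_edge_sign(
    lof_signs: Sequence[int],
    gof_signs: Sequence[int],
    chip: int,
    w_lof: float = 2.0,
    w_gof: float = 1.0,
) -> int | None:
    """Weighted majority vote over perturbation evidence, gated by binding.

    Returns ``+1`` or ``-1``, or ``None`` when the edge is absent: no binding
    evidence (``chip == 0``), no functional evidence at all, or an exact tie
    of the weighted sum (ties are dropped, never defaulted to a sign; callers
    log them for manual curation).
    """
    if chip not in (0, 1):
        raise ValueError(f"chip must be 0 or 1, got {chip!r}")
    if not w_lof > w_gof > 0:
        raise ValueError("weights must satisfy w_lof > w_gof > 0")
    for s in list(lof_signs) + list(gof_signs):
        if s not in (-1, 1):
            raise ValueError(f"evidence sign must be +/-1, got {s!r}")
    if chip == 0 or (not lof_signs and not gof_signs):
        return None
    total = w_lof * sum(lof_signs) + w_gof * sum(gof_signs)
    if total == 0:
        return None
    return 1 if total > 0 else -1


@dataclass(frozen=True)
class Override:
    """Curated correction of a voted edge: set a sign, add, or remove."""

    regulator: str
    target: str
    action: int | str  # +1 / -1 / "remove"
    allow_add: bool = False
    citation: str = ""

    def __post_init__(self) -> None:
        if self.action not in (-1, 1, "remove"):
            raise ValueError(f"override action must be +/-1 or 'remove', got {self.action!r}")


@dataclass
class AssemblyResult:
    network: SignedNetwork
    log: list[str] = field(default_factory=list)


def assemble_network(
    evidence: EvidenceTable,
    roster: Sequence[Node | str],
    overrides: Sequence[Override] = (),
    w_lof: float = 2.0,
    w_gof: float = 1.0,
) -> AssemblyResult:
    """Run the edge vote over every evidenced pair, then apply curated overrides.

    Overrides are applied last and logged.  An override touching a pair with
    no evidence requires ``allow_add=True``; silently inventing edges is an
    error.  Zero-sum vote ties are dropped and logged.
    """
    nodes = [n if isinstance(n, Node) else Node(n) for n in roster]
    ids = {n.gene for n in nodes}
    log: list[str] = []
    edges: dict[tuple[str, str], int] = {}
    evidenced: set[tuple[str, str]] = set()
    for (a, b), d in sorted(evidence.by_pair().items()):
        if a not in ids or b not in ids:
            raise ValueError(f"evidence pair ({a},{b}) outside roster")
        evidenced.add((a, b))
        decision = vote_edge_sign(d["lof"], d["gof"], int(d["chip"]), w_lof, w_gof)
        if decision is None:
            if d["chip"] and (d["lof"] or d["gof"]):
                # evidence present but vote tied at zero
                total = w_lof * sum(d["lof"]) + w_gof * sum(d["gof"])
                if total == 0:
                    log.append(f"tie dropped: {a}->{b} (weighted sum 0)")
        else:
            edges[(a, b)] = decision
    for ov in overrides:
        pair = (ov.regulator, ov.target)
        if ov.regulator not in ids or ov.target not in ids:
            raise ValueError(f"override {pair} outside roster")
        if pair not in evidenced and not ov.allow_add:
            raise ValueError(
                f"override on unevidenced pair {pair} without allow_add flag"
            )
        if ov.action == "remove":
            if pair in edges:
                del edges[pair]
                log.append(f"override remove: {pair[0]}->{pair[1]} [{ov.citation}]")
            else:
                log.append(f"override remove (no-op): {pair[0]}->{pair[1]} [{ov.citation}]")
        else:
            edges[pair] = int(ov.action)
            log.append(
                f"override set {ov.action:+d}: {pair[0]}->{pair[1]} [{ov.citation}]"
            )
    return AssemblyResult(SignedNetwork(nodes, edges), log)


# ----------------------------------------------------------------------
# feedback loops
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class Loop:
    cycle: tuple[str, ...]  # canonical rotation, lexicographically smallest start
    sign: int  # product of member edge signs
    is_auto: bool

    @property
    def length(self) -> int:
        return len(self.cycle)


@dataclass
class LoopCatalog:
    loops: list[Loop]

    @property
    def counts(self) -> tuple[int, int, int, int]:
        """(n_auto_pos, n_auto_neg, n_pos, n_neg); the last two are length >= 2."""
        n_ap = sum(1 for l in self.loops if l.is_auto and l.sign > 0)
        n_an = sum(1 for l in self.loops if l.is_auto and l.sign < 0)
        n_p = sum(1 for l in self.loops if not l.is_auto and l.sign > 0)
        n_n = sum(1 for l in self.loops if not l.is_auto and l.sign < 0)
        return (n_ap, n_an, n_p, n_n)


def _canonical(cycle: Sequence[str]) -> tuple[str, ...]:
    i = min(range(len(cycle)), key=lambda k: cycle[k])
    return tuple(cycle[i:]) + tuple(cycle[:i])


def enumerate_loops(net: SignedNetwork, max_length: int | None = None) -> LoopCatalog:
    """Every simple directed cycle of the network with its sign.

    Auto-regulatory loops are length-1 cycles and counted separately from
    loops of length >= 2.  Cycles are reported in a canonical rotation
    (lexicographically smallest starting node) so the catalog is
    duplicate-free.
    """
    g = net.to_networkx()
    loops: list[Loop] = []
    for cyc in nx.simple_cycles(g, length_bound=max_length):
        sign = 1
        for i in range(len(cyc)):
            sign *= net.edges[(cyc[i], cyc[(i + 1) % len(cyc)])]
        loops.append(Loop(_canonical(cyc), sign, len(cyc) == 1))
    loops.sort(key=lambda l: (l.length, l.cycle))
    return LoopCatalog(loops)


def rank_loops(
    models: Sequence[SignedNetwork], max_length: int | None = None
) -> list[tuple[Loop, int]]:
    """Occurrence count of each canonical loop across an ensemble of networks.

    Sorted by descending occurrence; ties broken by (length, lexicographic
    cycle).  Models must share a node roster.
    """
    if not models:
        raise ValueError("empty model list")
    roster = set(models[0].gene_ids)
    counts: dict[Loop, int] = {}
    for m in models:
        if set(m.gene_ids) != roster:
            raise ValueError("models do not share a node roster")
        for loop in enumerate_loops(m, max_length).loops:
            counts[loop] = counts.get(loop, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0].length, kv[0].cycle))
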
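"""Readers and writers for the pipeline's delimited-text interchange
formats, and loaders for the vendored seed-network fixtures.

Formats:

* evidence TSV — columns regulator, target, source_kind, sign, study_id
  (sign empty for ChIP rows);
* network — JSON ({nodes: [...], edges: [...]}) or a 3-column signed
  edge-list TSV (source, target, sign);
* expression CSV — genes as rows, cells as columns, first column gene
  ids; companion cell-metadata TSV (cell_id, condition);
* binary CSV — same shape, {0, 1};
* ensemble JSON — per target, the equally-well-fitted functions with
  prefix-notation formulas;
* signature TSV — marker, lineage, upstream_regulator, sign.

The vendored seed fixtures are a synthetic stand-in for the published
30-node mESC pluripotency network (whose machine-readable edge list was
never deposited): realistic gene names and motif structure, constructed
wiring, matching the published node/edge/feedback-loop census.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .logic import FunctionEnsemble, make_function
from .network import (
    EvidenceRecord,
    EvidenceTable,
    Node,
    Override,
    SignedNetwork,
)


# ----------------------------------------------------------------------
# evidence / overrides
# ----------------------------------------------------------------------

def read_evidence_tsv(path: str | Path, roster: Sequence[str] | None = None) -> EvidenceTable:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    records = []
    for row in df.itertuples(index=False):
        sign = int(row.sign) if row.sign not in ("", None) else None
        records.append(
            EvidenceRecord(row.regulator, row.target, row.source_kind, sign, row.study_id)
        )
    return EvidenceTable(records, roster)


def write_evidence_tsv(table: EvidenceTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("regulator\ttarget\tsource_kind\tsign\tstudy_id\n")
        for r in table.records:
            s = "" if r.sign is None else f"{r.sign:+d}"
            fh.write(f"{r.regulator}\t{r.target}\t{r.source_kind}\t{s}\t{r.study_id}\n")


def read_overrides_tsv(path: str | Path) -> list[Override]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    out = []
    for row in df.itertuples(index=False):
        action = row.action if row.action == "remove" else int(row.action)
        allow_add = getattr(row, "allow_add", "") in ("1", "true", "True")
        out.append(
            Override(row.regulator, row.target, action, allow_add,
                     getattr(row, "citation", ""))
        )
    return out


# ----------------------------------------------------------------------
# networks
# ----------------------------------------------------------------------

def read_network_json(path: str | Path) -> SignedNetwork:
    return SignedNetwork.from_json(Path(path).read_text())


def write_network_json(net: SignedNetwork, path: str | Path) -> None:
    Path(path).write_text(net.to_json())


def read_network_tsv(
    path: str | Path, nodes: Sequence[Node] | None = None
) -> SignedNetwork:
    """3-column signed edge list; node roster inferred from edges unless given."""
    df = pd.read_csv(path, sep="\t", comment="#")
    edges = {(r.source, r.target): int(r.sign) for r in df.itertuples(index=False)}
    if nodes is None:
        ids = sorted({g for e in edges for g in e})
        nodes = [Node(g) for g in ids]
    return SignedNetwork(nodes, edges)


def write_network_tsv(net: SignedNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tsign\n")
        for (a, b), s in sorted(net.edges.items()):
            fh.write(f"{a}\t{b}\t{s:+d}\n")


# ----------------------------------------------------------------------
# expression / binary matrices
# ----------------------------------------------------------------------

def read_expression_csv(
    expr_path: str | Path,
    meta_path: str | Path | None = None,
    housekeeping: str = "Gapdh",
):
    from .preprocess import ExpressionMatrix

    values = pd.read_csv(expr_path, index_col=0)
    conditions = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col="cell_id")
        conditions = meta["condition"]
    return ExpressionMatrix(values, conditions, housekeeping)


def write_expression_csv(em, expr_path: str | Path, meta_path: str | Path | None = None) -> None:
    em.values.to_csv(expr_path)
    if meta_path is not None:
        pd.DataFrame({"cell_id": em.values.columns, "condition": em.conditions.values}).to_csv(
            meta_path, sep="\t", index=False
        )


def write_binary_csv(bm, path: str | Path) -> None:
    bm.values.to_csv(path)


def read_binary_csv(path: str | Path):
    from .preprocess import BinaryMatrix

    values = pd.read_csv(path, index_col=0).astype(int)
    centroids = pd.DataFrame(
        {"low": 0.0, "high": 1.0}, index=values.index
    )  # audit centroids unavailable on re-read
    return BinaryMatrix(values, centroids)


# ----------------------------------------------------------------------
# ensembles
# ----------------------------------------------------------------------

def write_ensembles_json(ensembles: dict[str, FunctionEnsemble], path: str | Path) -> None:
    obj = {}
    for tgt, ens in ensembles.items():
        obj[tgt] = {
            "stage": ens.stage,
            "agreement": ens.agreement,
            "degeneracy": ens.degeneracy,
            "prior_parents": list(ens.prior_parents),
            "pruned_links": sorted(ens.pruned_links),
            "novel_links": sorted(ens.novel_links),
            "functions": [
                {
                    "formula": f.formula,
                    "parents": list(f.parents),
                    "tree": f.tree,
                    "truth_table": f.truth_table,
                    "agreement": f.agreement,
                }
                for f in ens.functions
            ],
        }
    Path(path).write_text(json.dumps(obj, indent=1))


def _tree_from_json(node) -> tuple:
    if node[0] == "lit":
        return ("lit", int(node[1]), bool(node[2]))
    return (node[0], _tree_from_json(node[1]), _tree_from_json(node[2]))


def read_ensembles_json(path: str | Path) -> dict[str, FunctionEnsemble]:
    obj = json.loads(Path(path).read_text())
    out = {}
    for tgt, d in obj.items():
        funcs = []
        for fd in d["functions"]:
            f = make_function(tgt, tuple(fd["parents"]), _tree_from_json(fd["tree"]))
            funcs.append(
                type(f)(tgt, f.parents, f.tree, f.truth_table, fd.get("agreement", float("nan")))
            )
        out[tgt] = FunctionEnsemble(
            tgt, funcs, d["agreement"], d["stage"], tuple(d["prior_parents"])
        )
    return out


# ----------------------------------------------------------------------
# vendored seed fixtures
# ----------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("scboolnet.data").joinpath(name)


def load_seed_nodes() -> list[Node]:
    with resources.as_file(_data_path("seed_nodes.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return [Node(r.gene, r.node_class, r.lineage_tag) for r in df.itertuples(index=False)]


def load_seed_network() -> SignedNetwork:
    """The vendored 30-node / 106-edge signed seed network (synthetic
    stand-in wiring; published loop census: 10 positive auto-loops, 26
    positive and 13 negative longer loops)."""
    nodes = load_seed_nodes()
    with resources.as_file(_data_path("seed_network_edges.tsv")) as p:
        return read_network_tsv(p, nodes)


def load_seed_evidence() -> EvidenceTable:
    nodes = [n.gene for n in load_seed_nodes()]
    with resources.as_file(_data_path("seed_evidence.tsv")) as p:
        return read_evidence_tsv(p, nodes)


def load_seed_overrides() -> list[Override]:
    with resources.as_file(_data_path("seed_overrides.tsv")) as p:
        return read_overrides_tsv(p)


def load_seed_signatures():
    from .lineage import LineageSignature

    with resources.as_file(_data_path("seed_signatures.tsv")) as p:
        df = pd.read_csv(p, sep="\t").fillna("")
    return LineageSignature(df)


def seed_pluripotency_genes() -> list[str]:
    return [n.gene for n in load_seed_nodes() if n.node_class == "pluripotency"]
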
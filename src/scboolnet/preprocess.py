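"""Single-cell qPCR preprocessing: capping, housekeeping normalization,
K-means binarization, and heterogeneity / co-expression statistics.

Raw data are Ct values (PCR cycle thresholds; lower Ct = higher expression).
Values above the detection limit of 35 cycles are recorded as 35 on ingest.
Normalization subtracts the housekeeping gene's Ct per cell and negates, so
normalized values (-dCt) are log2-expression-like.  Because most genes are
bimodal across single cells, each gene is quantized to ON/OFF with two-means
clustering; the cluster with the higher centroid maps to 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

CT_CAP = 35.0


class ExpressionMatrix:
    """Genes x cells Ct matrix with per-cell condition labels.

    Ct values greater than the detection cap (35 cycles) are considered
    non-detectable and recorded as 35 on construction.  Non-detectable
    cells are kept, not dropped; after binarization they populate the low
    cluster.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        conditions: pd.Series | None = None,
        housekeeping: str = "Gapdh",
        cap: float = CT_CAP,
    ):
        if values.isna().any().any():
            raise ValueError("missing Ct values are not allowed")
        if housekeeping not in values.index:
            raise ValueError(f"housekeeping gene {housekeeping!r} missing from matrix")
        self.values = values.clip(upper=cap).astype(float)
        self.housekeeping = housekeeping
        self.cap = cap
        if conditions is None:
            conditions = pd.Series("all", index=values.columns)
        self.conditions = conditions.reindex(values.columns)
        if self.conditions.isna().any():
            raise ValueError("every cell needs a condition label")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_condition(self, condition: str) -> "ExpressionMatrix":
        cells = self.conditions[self.conditions == condition].index
        return ExpressionMatrix(
            self.values[cells], self.conditions[cells], self.housekeeping, self.cap
        )


class NormalizedMatrix:
    """Genes x cells -dCt matrix (target Ct minus housekeeping Ct, negated)."""

    def __init__(self, values: pd.DataFrame, conditions: pd.Series, housekeeping: str):
        self.values = values
        self.conditions = conditions
        self.housekeeping = housekeeping

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class BinaryMatrix:
    """Genes x cells 0/1 matrix plus per-gene cluster centroids for audit."""

    values: pd.DataFrame
    centroids: pd.DataFrame  # columns: low, high (on the -dCt scale)
    degenerate_genes: list[str] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


def normalize_ct(m: ExpressionMatrix) -> NormalizedMatrix:
    """-dCt normalization: value(g, c) = -(Ct(g, c) - Ct(housekeeping, c))."""
    hk = m.values.loc[m.housekeeping]
    nm = -(m.values.sub(hk, axis=1))
    return NormalizedMatrix(nm, m.conditions, m.housekeeping)


def _kmeans2_1d(x: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Deterministic 1-D two-means: centroids seeded at the 10th/90th
    percentiles, Lloyd iterations to convergence.  Returns (low, high,
    labels) with labels oriented so 1 = high cluster."""
    lo, hi = np.percentile(x, [10, 90])
    if lo == hi:  # degenerate: caller handles orientation
        return lo, hi, np.zeros(len(x), dtype=int)
    for _ in range(100):
        mid = (lo + hi) / 2.0
        lab = (x > mid).astype(int)
        # guard: percentile init can leave a side empty on skewed data
        if lab.all() or not lab.any():
            break
        nlo, nhi = x[lab == 0].mean(), x[lab == 1].mean()
        if nlo == lo and nhi == hi:
            break
        lo, hi = nlo, nhi
    if lo > hi:  # orientation rule: 1 is always the larger centroid
        lo, hi = hi, lo
        lab = 1 - lab
    return float(lo), float(hi), lab


def binarize(nm: NormalizedMatrix, scope: str = "per_gene") -> BinaryMatrix:
    """Quantize -dCt values to ON/OFF with two-means clustering.

    scope="per_gene" clusters each gene on its own scale (each gene's
    bimodality has its own dynamic range); scope="pooled" fits a single
    two-means split over all genes' values and applies its midpoint
    threshold everywhere.  All-constant genes become all-0 or all-1
    (relative to the matrix-wide mean) with a logged warning.
    """
    if scope not in ("per_gene", "pooled"):
        raise ValueError(f"scope must be per_gene or pooled, got {scope!r}")
    vals = nm.values
    grand_mean = float(vals.values.mean())
    labels = {}
    cents = {}
    degenerate = []
    if scope == "pooled":
        lo, hi, _ = _kmeans2_1d(vals.values.ravel())
        thr = (lo + hi) / 2.0
    for g in vals.index:
        x = vals.loc[g].to_numpy(dtype=float)
        if np.unique(x).size < 2:
            bit = int(x[0] >= grand_mean)
            labels[g] = np.full(len(x), bit)
            cents[g] = (x[0], x[0])
            degenerate.append(g)
            logger.warning("gene %s is constant; binarized all-%d", g, bit)
            continue
        if scope == "pooled":
            labels[g] = (x > thr).astype(int)
            cents[g] = (lo, hi)
        else:
            lo_g, hi_g, lab = _kmeans2_1d(x)
            labels[g] = lab
            cents[g] = (lo_g, hi_g)
    bm = pd.DataFrame(labels, index=vals.columns).T.loc[vals.index].astype(int)
    bm.columns = vals.columns
    centroids = pd.DataFrame(cents, index=["low", "high"]).T.loc[vals.index]
    return BinaryMatrix(bm, centroids, degenerate)


@dataclass
class DispersionReport:
    """Per-gene index of dispersion in two conditions plus a paired test.

    The index is variance/mean of linear-scale expression 2**(-dCt) per
    gene.  The paired one-tailed t-test across genes tests H1: condition b
    is less dispersed than condition a.
    """

    dispersion: pd.DataFrame  # columns: condition_a, condition_b
    statistic: float
    pvalue: float


def dispersion_index(nm: NormalizedMatrix) -> pd.Series:
    """Variance/mean of linearized expression (2**-dCt) per gene."""
    lin = np.exp2(nm.values)
    mean = lin.mean(axis=1)
    var = lin.var(axis=1, ddof=1)
    out = var / mean
    out[mean == 0] = 0.0
    return out


def dispersion_compare(nm_a: NormalizedMatrix, nm_b: NormalizedMatrix) -> DispersionReport:
    """Compare expression heterogeneity between two conditions, paired by gene."""
    shared = [g for g in nm_a.gene_ids if g in set(nm_b.gene_ids)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared genes for a paired comparison")
    da = dispersion_index(nm_a).loc[shared]
    db = dispersion_index(nm_b).loc[shared]
    diffs = da - db
    if np.allclose(diffs, 0):
        # all paired differences zero: no evidence either way
        stat, p = 0.0, 0.5
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, p = stats.ttest_rel(da, db, alternative="greater")
    table = pd.DataFrame({"condition_a": da, "condition_b": db})
    return DispersionReport(table, float(stat), float(p))


@dataclass
class GeneAssociation:
    distances: pd.DataFrame  # 1 - Pearson correlation, gene x gene
    flagged_genes: list[str]  # zero-variance genes (distance set to max 2)
    gene_order: list[str]  # average-linkage / Euclidean dendrogram leaf order
    cell_order: list[str]


def gene_association(nm: NormalizedMatrix) -> GeneAssociation:
    """Gene-gene distance (1 - Pearson r) and display orderings.

    Zero-variance genes have undefined correlation; their distances are
    recorded as the maximum (2) and the genes flagged.  Display orderings
    come from separate average-linkage, Euclidean-distance hierarchical
    clusterings of genes and of cells.
    """
    vals = nm.values
    if vals.shape[1] < 2:
        raise ValueError("need at least 2 cells")
    sd = vals.std(axis=1, ddof=0)
    flagged = list(vals.index[sd == 0])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(vals.to_numpy(dtype=float))
    dist = 1.0 - corr
    bad = np.isin(vals.index, flagged)
    dist[bad, :] = 2.0
    dist[:, bad] = 2.0
    np.fill_diagonal(dist, 0.0)
    distances = pd.DataFrame(dist, index=vals.index, columns=vals.index)

    def _leaf_order(mat: np.ndarray) -> list[int]:
        if mat.shape[0] < 2:
            return list(range(mat.shape[0]))
        link = hierarchy.average(pdist(mat, metric="euclidean"))
        return list(hierarchy.leaves_list(link))

    gene_order = [vals.index[i] for i in _leaf_order(vals.to_numpy())]
    cell_order = [vals.columns[i] for i in _leaf_order(vals.to_numpy().T)]
    return GeneAssociation(distances, flagged, gene_order, cell_order)
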
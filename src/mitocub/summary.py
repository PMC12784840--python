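"""Cross-species descriptive statistics, RSCU matrices, and clustering.

Distribution shape uses the population-moment definitions
``g1 = m3 / m2^(3/2)`` and excess kurtosis ``g2 = m4 / m2^2 - 3``; the
standard deviation is the sample (n-1) form, matching the "mean ± sd"
reporting convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist

from .genetic_code import TABLE5, CodonTable5

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SummaryStats:
    label: str
    n: int
    mean: float
    sd: float | None
    cv: float | None
    minimum: float
    maximum: float
    median: float
    skewness: float | None
    kurtosis: float | None        # excess


@dataclass(frozen=True)
class CodonMatrix:
    """Rows = units (species or genes), columns = analyzed codons, cells =
    RSCU (NaN marks an absent family)."""

    row_labels: tuple
    col_labels: tuple
    values: np.ndarray


@dataclass(frozen=True)
class ClusterTree:
    """Complete-linkage merge sequence over the rows of a CodonMatrix."""

    leaf_labels: tuple
    linkage: np.ndarray            # scipy linkage matrix, (n-1, 4)
    leaf_order: tuple              # dendrogram left-to-right leaf labels

    def newick(self) -> str:
        if len(self.leaf_labels) == 1:
            return f"{self.leaf_labels[0]};"
        tree = sch.to_tree(self.linkage)

        def walk(node):
            if node.is_leaf():
                return self.leaf_labels[node.id]
            left, right = walk(node.get_left()), walk(node.get_right())
            dl = node.dist - node.get_left().dist
            dr = node.dist - node.get_right().dist
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return walk(tree) + ";"


def summarize(values, label: str = "") -> SummaryStats:
    """Moment-based descriptive statistics of one variable."""
    x = np.asarray([float(v) for v in values], dtype=float)
    if x.size < 1:
        raise ValueError("no values to summarize")
    mean = float(x.mean())
    if x.size < 2:
        return SummaryStats(label, 1, mean, None, None, mean, mean, mean, None, None)

    sd = float(x.std(ddof=1))
    m2 = float(((x - mean) ** 2).mean())
    m3 = float(((x - mean) ** 3).mean())
    m4 = float(((x - mean) ** 4).mean())
    skew = m3 / m2 ** 1.5 if m2 > 0 else None
    kurt = m4 / m2 ** 2 - 3.0 if m2 > 0 else None
    return SummaryStats(
        label=label, n=int(x.size), mean=mean, sd=sd,
        cv=sd / mean if mean != 0 else None,
        minimum=float(x.min()), maximum=float(x.max()),
        median=float(np.median(x)),
        skewness=skew, kurtosis=kurt,
    )


def build_rscu_matrix(profiles, code: CodonTable5 = TABLE5) -> CodonMatrix:
    """Align RSCU profiles into one matrix with a fixed codon column order
    (grouped by amino acid, lexicographic within each family)."""
    if not profiles:
        raise ValueError("no profiles")
    labels = [p.label for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate row labels in RSCU matrix")

    cols = sorted(code.analyzed_codons, key=lambda c: (code.forward[c], c))
    mat = np.full((len(profiles), len(cols)), np.nan)
    for i, p in enumerate(profiles):
        for j, c in enumerate(cols):
            v = p.rscu.get(c)
            if v is not None:
                mat[i, j] = v
    return CodonMatrix(row_labels=tuple(labels), col_labels=tuple(cols), values=mat)


def hierarchical_cluster(matrix: CodonMatrix, transpose: bool = False) -> ClusterTree:
    """Agglomerative complete-linkage clustering under Euclidean distance.

    Missing cells are imputed as 0 for the distance computation only (with a
    logged warning); set ``transpose`` to cluster codons instead of units.
    Row order is sorted by label first so ties break deterministically.
    """
    vals = matrix.values.T if transpose else matrix.values
    labels = matrix.col_labels if transpose else matrix.row_labels

    order = sorted(range(len(labels)), key=lambda i: labels[i])
    labels = tuple(labels[i] for i in order)
    vals = vals[order]

    if np.isnan(vals).any():
        log.warning("RSCU matrix has %d missing cells; imputing 0 for clustering",
                    int(np.isnan(vals).sum()))
        vals = np.nan_to_num(vals, nan=0.0)

    if len(labels) == 1:
        return ClusterTree(leaf_labels=labels, linkage=np.empty((0, 4)),
                           leaf_order=labels)

    link = sch.linkage(pdist(vals, metric="euclidean"), method="complete")
    leaves = sch.leaves_list(link)
    return ClusterTree(
        leaf_labels=labels,
        linkage=link,
        leaf_order=tuple(labels[i] for i in leaves),
    )


def write_summary_table(stats, path) -> None:
    def fmt(v):
        return "" if v is None else f"{v:.6g}"

    with open(path, "w") as fh:
        fh.write("variable\tn\tmean\tsd\tcv\tmin\tmax\tmedian\tskewness\tkurtosis\n")
        for s in stats:
            fh.write(f"{s.label}\t{s.n}\t{fmt(s.mean)}\t{fmt(s.sd)}\t{fmt(s.cv)}\t"
                     f"{fmt(s.minimum)}\t{fmt(s.maximum)}\t{fmt(s.median)}\t"
                     f"{fmt(s.skewness)}\t{fmt(s.kurtosis)}\n")


def write_rscu_matrix_csv(matrix: CodonMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("unit," + ",".join(matrix.col_labels) + "\n")
        for label, row in zip(matrix.row_labels, matrix.values):
            cells = ",".join("" if math.isnan(v) else f"{v:.6f}" for v in row)
            fh.write(f"{label},{cells}\n")
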
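"""Tissue-expression clustering and relative-expression matrices.

Genes are clustered on their per-tissue median TPM profiles by agglomerative
hierarchical clustering (euclidean metric, complete linkage by default) and
the tree is cut at a fixed cophenetic distance — 7.6 by default, the cut used
for the published 28-group partition of the candidate risk genes. Group ids
are relabelled by first-occurrence order of the input genes so labels are
reproducible; the numbers themselves are arbitrary.

Relative expression rescales each gene row to [0, 1] by (x - min)/(max - min)
for heatmap display; constant rows map to all-zero and are flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

LINKAGES = ("complete", "average", "single")
TRANSFORMS = ("none", "log10p1")


@dataclass
class ClusterParams:
    linkage: str = "complete"
    metric: str = "euclidean"
    cut_height: float = 7.6
    transform: str = "none"

    def __post_init__(self) -> None:
        if self.linkage not in LINKAGES:
            raise ValueError(f"linkage must be one of {LINKAGES}")
        if self.metric != "euclidean":
            raise ValueError("only the euclidean metric is supported")
        if not self.cut_height > 0:
            raise ValueError("cut_height must be positive")
        if self.transform not in TRANSFORMS:
            raise ValueError(f"transform must be one of {TRANSFORMS}")


@dataclass
class ExpressionMatrix:
    """Gene x tissue median-TPM table. Missing values become 0 with a logged count."""

    values: pd.DataFrame  # index = genes, columns = tissues

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("gene and tissue labels must be unique")
        n_missing = int(self.values.isna().sum().sum())
        if n_missing:
            logger.info("expression matrix: %d missing values set to 0", n_missing)
            self.values = self.values.fillna(0.0)
        if (self.values.to_numpy() < 0).any():
            raise ValueError("median TPM values must be >= 0")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, genes) -> "ExpressionMatrix":
        keep = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[keep].copy())

    def write_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def read_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)


def hierarchical_cluster(
    matrix: ExpressionMatrix, params: Optional[ClusterParams] = None
) -> dict[str, int]:
    """Cut an agglomerative tree at ``cut_height``; gene -> group id (1-based).

    Group ids are assigned in order of first gene appearance in the matrix,
    so the partition is deterministic and invariant (up to relabelling) under
    row permutation.
    """
    params = params or ClusterParams()
    x = matrix.values.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite expression values")
    if params.transform == "log10p1":
        x = np.log10(x + 1.0)
    genes = matrix.genes
    if len(genes) == 0:
        raise ValueError("need at least one gene")
    if len(genes) == 1:
        return {genes[0]: 1}
    z = linkage(pdist(x, metric=params.metric), method=params.linkage)
    raw = fcluster(z, t=params.cut_height, criterion="distance")
    relabel: dict[int, int] = {}
    out: dict[str, int] = {}
    for gene, grp in zip(genes, raw):
        if grp not in relabel:
            relabel[grp] = len(relabel) + 1
        out[gene] = relabel[grp]
    return out


def linkage_matrix(matrix: ExpressionMatrix, params: Optional[ClusterParams] = None) -> np.ndarray:
    """The raw scipy linkage matrix, for dendrogram dumps and height checks."""
    params = params or ClusterParams()
    x = matrix.values.to_numpy(dtype=float)
    if params.transform == "log10p1":
        x = np.log10(x + 1.0)
    return linkage(pdist(x, metric=params.metric), method=params.linkage)


def relative_expression(matrix: ExpressionMatrix) -> tuple[pd.DataFrame, list[str]]:
    """Row-wise (x - min)/(max - min) rescale to [0, 1].

    Returns the rescaled frame and the list of constant (flagged) genes, which
    map to all-zero rows.
    """
    vals = matrix.values
    row_min = vals.min(axis=1)
    row_max = vals.max(axis=1)
    span = row_max - row_min
    constant = list(vals.index[span == 0])
    safe_span = span.replace(0, 1.0)
    rel = vals.sub(row_min, axis=0).div(safe_span, axis=0)
    rel.loc[constant] = 0.0
    return rel, constant
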
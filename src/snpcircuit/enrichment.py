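"""Gene-set over-representation, BH FDR control, and a specificity
permutation test of cell-type enrichment.

Over-representation uses the exact hypergeometric upper tail: for a query of
n genes from a universe of N, of which K belong to a term and k to both,
p = P(X >= k) with X ~ Hypergeometric(N, K, n). Term catalogs are supplied as
GMT files; no ontology structure is assumed.

The cell-type enrichment test follows the SNPsea idea in simplified form:
each GWAS locus contributes a set of candidate genes; per cell type, a
gene's *specificity percentile* ranks its share of expression (expression
divided by the gene's total) against all genes; a locus scores the minimum
percentile over its genes; the study statistic per cell type is the sum of
-log(locus score). Significance comes from gene-count-matched random loci,
with the add-one permutation estimator so p is never zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, rankdata
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix


@dataclass
class GeneSetCollection:
    """Term id -> (term name, member genes), restricted to an explicit universe."""

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    @classmethod
    def from_dict(
        cls, sets: Mapping[str, Iterable[str]], universe: Iterable[str],
        names: Optional[Mapping[str, str]] = None,
    ) -> "GeneSetCollection":
        uni = frozenset(universe)
        if not uni:
            raise ValueError("empty universe")
        cleaned = {}
        for term, members in sets.items():
            restricted = frozenset(members) & uni
            if restricted:  # empty sets are not retained
                cleaned[term] = ((names or {}).get(term, term), restricted)
        return cls(sets=cleaned, universe=uni)

    @classmethod
    def read_gmt(cls, path, universe: Optional[Iterable[str]] = None) -> "GeneSetCollection":
        """GMT: term <tab> description <tab> gene1 <tab> gene2 ... per line.

        Without an explicit universe, the union of all member genes is used.
        """
        raw: dict[str, list[str]] = {}
        names: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or not parts[0]:
                    continue
                raw[parts[0]] = [g for g in parts[2:] if g]
                names[parts[0]] = parts[1]
        uni = universe if universe is not None else {g for m in raw.values() for g in m}
        return cls.from_dict(raw, uni, names)

    def write_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for term in sorted(self.sets):
                name, members = self.sets[term]
                fh.write("\t".join([term, name, *sorted(members)]) + "\n")


@dataclass(frozen=True)
class OraResult:
    term: str
    name: str
    k: int  # overlap
    K: int  # set size
    n: int  # query size
    N: int  # universe size
    p: float
    fdr: float = float("nan")


def hypergeometric_ora(
    query: Iterable[str], collection: GeneSetCollection, fdr_max: Optional[float] = None
) -> list[OraResult]:
    """Upper-tail hypergeometric test of a query set against every term.

    Query genes outside the universe are dropped (with their count reflected
    in ``n``); results come back BH-adjusted and sorted by p. ``fdr_max``
    optionally filters the returned list.
    """
    q = set(query) & collection.universe
    N = len(collection.universe)
    n = len(q)
    results = []
    for term in sorted(collection.sets):
        name, members = collection.sets[term]
        K = len(members)
        k = len(q & members)
        # P(X >= k) = sf(k - 1)
        p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        results.append(OraResult(term=term, name=name, k=k, K=K, n=n, N=N, p=min(p, 1.0)))
    if results:
        fdrs = bh_fdr([r.p for r in results])
        results = [
            OraResult(r.term, r.name, r.k, r.K, r.n, r.N, r.p, fdr) for r, fdr in zip(results, fdrs)
        ]
    results.sort(key=lambda r: (r.p, r.term))
    if fdr_max is not None:
        results = [r for r in results if r.fdr <= fdr_max]
    return results


def ora_table(results: Sequence[OraResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"term": r.term, "name": r.name, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
             "p": r.p, "fdr": r.fdr}
            for r in results
        ]
    )


def bh_fdr(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(pvals), dtype=float)
    if len(p) == 0:
        return []
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


@dataclass(frozen=True)
class SnpseaResult:
    cell_type: str
    observed_score: float
    null_mean: float
    null_sd: float
    empirical_p: float
    n_perm: int


def specificity_scores(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene, per-cell-type specificity percentile ranks in (0, 1].

    A gene's expression is divided by its row sum (its share of expression in
    each cell type); within each cell type, genes are ranked descending on
    that share, ties averaged, and the rank is divided by the number of genes.
    Small percentile = highly specific. All-zero genes get the worst
    percentile (1.0) everywhere and are flagged via the ``all_zero`` attr.
    """
    vals = matrix.values
    if len(vals) < 2:
        raise ValueError("need at least 2 genes to rank specificity")
    row_sums = vals.sum(axis=1)
    zero_rows = row_sums == 0
    shares = vals.div(row_sums.replace(0, 1.0), axis=0)
    n_genes = len(vals)
    pct = shares.apply(lambda col: rankdata(-col.to_numpy(), method="average") / n_genes, axis=0)
    pct = pd.DataFrame(pct, index=vals.index, columns=vals.columns)
    pct.loc[zero_rows] = 1.0
    pct.attrs["all_zero"] = list(vals.index[zero_rows])
    return pct


def _locus_statistic(loci_percentiles: list[np.ndarray]) -> np.ndarray:
    """Sum over loci of -log(min percentile within the locus); vector per cell type."""
    return np.sum([-np.log(p.min(axis=0)) for p in loci_percentiles], axis=0)


def snpsea_lite(
    loci: Sequence[Iterable[str]],
    specificity: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> list[SnpseaResult]:
    """Permutation test of cell-type-specific expression of GWAS locus genes.

    ``loci`` is one gene set per SNP locus. Genes absent from the specificity
    matrix are dropped; a locus left empty is an error. The null resamples
    loci matched on gene count from the matrix's genes.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    genes_index = {g: i for i, g in enumerate(specificity.index)}
    mat = specificity.to_numpy(dtype=float)
    locus_rows: list[np.ndarray] = []
    for i, locus in enumerate(loci):
        idx = [genes_index[g] for g in locus if g in genes_index]
        if not idx:
            raise ValueError(f"locus {i} has no genes present in the specificity matrix")
        locus_rows.append(np.asarray(idx))
    observed = _locus_statistic([mat[idx] for idx in locus_rows])
    rng = np.random.default_rng(seed)
    n_genes = mat.shape[0]
    exceed = np.zeros(mat.shape[1], dtype=int)
    null_sum = np.zeros(mat.shape[1])
    null_sq = np.zeros(mat.shape[1])
    sizes = [len(idx) for idx in locus_rows]
    for _ in range(n_perm):
        null_loci = [mat[rng.choice(n_genes, size=s, replace=False)] for s in sizes]
        stat = _locus_statistic(null_loci)
        exceed += stat >= observed
        null_sum += stat
        null_sq += stat**2
    pvals = (1 + exceed) / (n_perm + 1)
    means = null_sum / n_perm
    sds = np.sqrt(np.maximum(null_sq / n_perm - means**2, 0.0))
    return [
        SnpseaResult(
            cell_type=str(ct),
            observed_score=float(observed[j]),
            null_mean=float(means[j]),
            null_sd=float(sds[j]),
            empirical_p=float(pvals[j]),
            n_perm=n_perm,
        )
        for j, ct in enumerate(specificity.columns)
    ]
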
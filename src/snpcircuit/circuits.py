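"""eQTL filtering, nearest-gene assignment, and SNP→gene regulatory circuits.

An eQTL association links a variant to a gene's expression in one tissue with
a nominal p-value and a signed slope (effect per alternate allele). After the
genome-wide filter (p < 5e-8 by default), associations are collapsed into a
bipartite SNP→gene graph: one edge per (variant, gene) pair, annotated with
the number of distinct tissues and a direction — ``up`` if every tissue slope
is positive, ``down`` if every one is negative, ``mixed`` otherwise (the
unanimity rule; mixed edges are additionally expanded per tissue).

Nearest genes use the full gene span, not the TSS; the discordance statistic
reports what fraction of eQTL target genes are *not* the nearest gene of any
of their eQTL SNPs, the classic argument against nearest-gene target
assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet, closest

REQUIRED_EQTL_COLUMNS = ["rsid", "gene_id", "gene_symbol", "tissue", "pval_nominal", "slope"]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    symbol: str
    chrom: str
    start: int  # 0-based
    end: int  # exclusive
    strand: str = "."

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.gene_id, None, self.strand)


def read_eqtl_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_eqtl_frame(df)


def validate_eqtl_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_EQTL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"eQTL table missing columns: {missing}")
    return df


def filter_associations(rows: pd.DataFrame, p_max: float = 5e-8) -> pd.DataFrame:
    """Retain associations with nominal p strictly below ``p_max``.

    Retained rows must carry finite nonzero slopes; offending rows are dropped.
    """
    if not (0 < p_max < 1):
        raise ValueError("p_max must be in (0, 1)")
    validate_eqtl_frame(rows)
    kept = rows[rows["pval_nominal"] < p_max].copy()
    slopes = pd.to_numeric(kept["slope"], errors="coerce")
    kept = kept[np.isfinite(slopes) & (slopes != 0)]
    return kept.reset_index(drop=True)


def association_counts(retained: pd.DataFrame) -> tuple[int, int]:
    """(distinct SNPs, distinct genes) among retained associations."""
    return retained["rsid"].nunique(), retained["gene_id"].nunique()


def genes_interval_set(genes: Sequence[GeneModel]) -> IntervalSet:
    return IntervalSet([g.interval() for g in genes])


def nearest_gene(
    snp: tuple[str, int], genes: Sequence[GeneModel]
) -> tuple[Optional[GeneModel], Optional[int], list[GeneModel]]:
    """Closest gene span to a SNP (1-based position); containment wins with distance 0.

    Ties at minimal distance are all reported; the lowest-coordinate gene is
    primary. Returns ``(None, None, [])`` when the chromosome has no gene.
    """
    by_id = {g.gene_id: g for g in genes}
    primary, dist, ties = closest(snp, genes_interval_set(genes))
    if primary is None:
        return None, None, []
    return by_id[primary.name], dist, [by_id[iv.name] for iv in ties]


def nearest_gene_discordance(
    retained: pd.DataFrame, genes: Sequence[GeneModel],
    snp_positions: Optional[dict[str, tuple[str, int]]] = None,
) -> tuple[int, int, Optional[float]]:
    """Fraction of eQTL target genes that are nobody's nearest gene.

    For every retained SNP, compute its nearest gene(s); a target gene is
    *concordant* if it is the nearest gene of at least one of its eQTL SNPs.
    Returns (n_discordant, n_target_genes, fraction); fraction is None on
    empty input (undefined, not zero). ``snp_positions`` maps rsid ->
    (chrom, 1-based pos); required unless the table carries chrom/pos columns.
    """
    if len(retained) == 0:
        return 0, 0, None
    if snp_positions is None:
        if not {"chrom", "pos"} <= set(retained.columns):
            raise ValueError("need snp_positions or chrom/pos columns")
        snp_positions = {
            r.rsid: (r.chrom, int(r.pos)) for r in retained.drop_duplicates("rsid").itertuples()
        }
    nearest_by_snp: dict[str, set[str]] = {}
    for rsid, point in snp_positions.items():
        _, _, ties = nearest_gene(point, genes)
        nearest_by_snp[rsid] = {g.gene_id for g in ties}
    targets = retained.groupby("gene_id")["rsid"].agg(set)
    n_total = len(targets)
    n_discordant = sum(
        1
        for gene_id, rsids in targets.items()
        if not any(gene_id in nearest_by_snp.get(r, set()) for r in rsids)
    )
    return n_discordant, n_total, n_discordant / n_total


def tissue_summary(retained: pd.DataFrame, snp_subset: Optional[set[str]] = None) -> pd.DataFrame:
    """Per-tissue distinct-SNP and distinct-gene counts.

    Columns: tissue, n_eqtl_snps, n_genes (full retained set) and, when a
    subset is given, n_subset_snps, n_subset_genes for the restricted set.
    Tissues with no subset rows keep zeros.
    """
    full = (
        retained.groupby("tissue")
        .agg(n_eqtl_snps=("rsid", "nunique"), n_genes=("gene_id", "nunique"))
        .reset_index()
    )
    if snp_subset is not None:
        sub = retained[retained["rsid"].isin(snp_subset)]
        subsum = (
            sub.groupby("tissue")
            .agg(n_subset_snps=("rsid", "nunique"), n_subset_genes=("gene_id", "nunique"))
            .reset_index()
        )
        full = full.merge(subsum, on="tissue", how="left")
        full[["n_subset_snps", "n_subset_genes"]] = (
            full[["n_subset_snps", "n_subset_genes"]].fillna(0).astype(int)
        )
    return full.sort_values("tissue").reset_index(drop=True)


@dataclass
class CircuitGraph:
    """Bipartite SNP→gene graph with per-edge direction, tissues, and slopes."""

    edges: pd.DataFrame  # rsid, gene_id, gene_symbol, direction, n_tissues, tissues, slopes

    @property
    def snp_nodes(self) -> list[str]:
        return sorted(self.edges["rsid"].unique())

    @property
    def gene_nodes(self) -> list[str]:
        return sorted(self.edges["gene_id"].unique())

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, rsid: str) -> int:
        return int((self.edges["rsid"] == rsid).sum())

    def genes_of(self, rsid: str) -> set[str]:
        return set(self.edges.loc[self.edges["rsid"] == rsid, "gene_id"])

    def snps_of(self, gene_id: str) -> set[str]:
        return set(self.edges.loc[self.edges["gene_id"] == gene_id, "rsid"])

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.snp_nodes, bipartite="snp")
        g.add_nodes_from(self.gene_nodes, bipartite="gene")
        for row in self.edges.itertuples():
            g.add_edge(
                row.rsid,
                row.gene_id,
                direction=row.direction,
                n_tissues=row.n_tissues,
                tissues=row.tissues,
                slopes=row.slopes,
            )
        return g

    def per_gene_summary(self, clusters: Optional[dict[str, int]] = None) -> pd.DataFrame:
        """Per-gene rows in the Gene / Cluster / Direction / Tissue N style.

        Direction per gene aggregates its edges with the same unanimity rule;
        Tissue N counts distinct tissues across the gene's edges.
        """
        rows = []
        for gene_id, grp in self.edges.groupby("gene_id", sort=True):
            all_slopes = [s for slopes in grp["slopes"] for s in slopes]
            tissues = sorted({t for ts in grp["tissues"] for t in ts})
            rows.append(
                {
                    "gene_id": gene_id,
                    "gene_symbol": grp["gene_symbol"].iloc[0],
                    "cluster": clusters.get(gene_id, -1) if clusters else -1,
                    "direction": _direction(all_slopes),
                    "n_tissues": len(tissues),
                    "snps": ",".join(sorted(grp["rsid"])),
                }
            )
        return pd.DataFrame(rows)

    def per_tissue_expansion(self) -> pd.DataFrame:
        """One row per (rsid, gene, tissue, slope) — resolves mixed edges per tissue."""
        rows = []
        for row in self.edges.itertuples():
            for t, s in zip(row.tissues, row.slopes):
                rows.append((row.rsid, row.gene_id, t, s, "up" if s > 0 else "down"))
        return pd.DataFrame(rows, columns=["rsid", "gene_id", "tissue", "slope", "direction"])


def _direction(slopes: Sequence[float]) -> str:
    if all(s > 0 for s in slopes):
        return "up"
    if all(s < 0 for s in slopes):
        return "down"
    return "mixed"


def build_circuit(retained: pd.DataFrame, snp_subset: Optional[set[str]] = None) -> CircuitGraph:
    """Collapse retained associations into the bipartite circuit graph.

    One edge per distinct (rsid, gene) pair restricted to ``snp_subset`` (all
    SNPs when None); direction is the unanimity rule over the edge's slopes.
    """
    rows = retained if snp_subset is None else retained[retained["rsid"].isin(snp_subset)]
    edges = []
    for (rsid, gene_id), grp in rows.groupby(["rsid", "gene_id"], sort=True):
        tissues = list(grp["tissue"])
        slopes = [float(s) for s in grp["slope"]]
        edges.append(
            {
                "rsid": rsid,
                "gene_id": gene_id,
                "gene_symbol": grp["gene_symbol"].iloc[0],
                "direction": _direction(slopes),
                "n_tissues": len(set(tissues)),
                "tissues": tissues,
                "slopes": slopes,
            }
        )
    return CircuitGraph(
        edges=pd.DataFrame(
            edges,
            columns=["rsid", "gene_id", "gene_symbol", "direction", "n_tissues", "tissues", "slopes"],
        )
    )


def read_gene_models_bed(path) -> list[GeneModel]:
    """Gene models from BED6 (name = ``gene_id|symbol`` or plain gene_id)."""
    from .intervals import read_bed

    genes = []
    for iv in read_bed(path):
        if "|" in iv.name:
            gene_id, symbol = iv.name.split("|", 1)
        else:
            gene_id = symbol = iv.name
        genes.append(GeneModel(gene_id, symbol, iv.chrom, iv.start, iv.end, iv.strand))
    return genes
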
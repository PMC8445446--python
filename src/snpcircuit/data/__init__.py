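"""Bundled reference tables for the type 1 diabetes (T1D) case study.

Two kinds of tables are shipped:

* Curated study tables (``high_probability_snps.tsv``, ``immune_genes.tsv``):
  the 26 high-probability causal enhancer SNPs with their eQTL gene counts,
  lncRNA counts and TF motifs, and the 57 immune-response genes among the 159
  eQTL target genes with functional categories and expression-cluster groups.

* Synthetic circuit reconstructions (``*_circuit_edges_synthetic.tsv``): edge
  lists for the HLA (6p21.33) and 16p11.2 regulatory circuits. Headline
  structure (per-SNP degrees, shared-gene patterns, published direction and
  tissue counts) is faithful; edges whose details are not public are filled
  with plausible synthetic values, hence the ``_synthetic`` suffix.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_high_probability_snps() -> pd.DataFrame:
    """The 26 high-probability causal enhancer SNPs.

    Columns: rsid, db_source (GWAS catalog vs LD expansion), chrom, pos,
    n_eqtl_genes (0 = not an eQTL), n_lncrnas, tf_motifs ("-" = none).
    """
    return _read("high_probability_snps.tsv")


def load_immune_genes() -> pd.DataFrame:
    """The 57 immune-response genes among the eQTL target genes.

    Columns: ensembl_id, symbol, name, note, category (antigen_presentation,
    immune_signaling, adaptive_immunity, innate_immunity, other_immune),
    high_prob_snps (comma-joined rsids or "-"), hclust_group.
    """
    return _read("immune_genes.tsv")


def load_hla_circuit() -> pd.DataFrame:
    """Synthetic reconstruction of the HLA (6p21.33) regulatory circuit.

    Edges from the two lncRNA-resident eQTLs rs886424 (11 genes) and
    rs3129716 (14 genes) to their 25 distinct target genes, with expression
    cluster, association direction, and affected-tissue counts.
    """
    return _read("hla_circuit_edges_synthetic.tsv")


def load_chr16_circuit() -> pd.DataFrame:
    """Synthetic reconstruction of the 16p11.2 regulatory circuit.

    Edges from four eQTLs to 19 distinct genes: 16 genes shared by all four
    SNPs, SGF29 and RABEP2 linked to three, and SBK1 linked only to
    rs4788084.
    """
    return _read("chr16_circuit_edges_synthetic.tsv")


__all__ = [
    "load_high_probability_snps",
    "load_immune_genes",
    "load_hla_circuit",
    "load_chr16_circuit",
]
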
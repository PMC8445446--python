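"""Regulatory circuits: the bundled HLA and 16p11.2 reference tables, and a
circuit built from raw eQTL associations.

The reference tables reproduce the published circuit structure of the type 1
diabetes study: two lncRNA-resident eQTLs in the HLA locus targeting 25 genes
(degrees 11 and 14), and four eQTLs in 16p11.2 targeting 19 genes with a
shared 16-gene core.
"""

import pandas as pd

from snpcircuit.circuits import build_circuit, filter_associations
from snpcircuit.data import load_chr16_circuit, load_hla_circuit

hla = load_hla_circuit()
print("HLA circuit:", hla["gene_symbol"].nunique(), "genes;",
      {r: int(n) for r, n in hla.groupby("rsid").size().items()})

c16 = load_chr16_circuit()
by_gene = c16.groupby("gene_symbol")["rsid"].agg(set)
print("16p11.2 circuit:", c16["gene_symbol"].nunique(), "genes;",
      sum(len(s) == 4 for s in by_gene), "genes shared by all four eQTLs")
print("SBK1 is targeted only by:", sorted(by_gene["SBK1"]))

# Building a circuit from scratch: one edge per (SNP, gene), direction by the
# unanimity rule over the per-tissue slopes.
eqtl = pd.DataFrame(
    [
        ("rs1", "g1", "G1", "whole_blood", 1e-12, 0.8),
        ("rs1", "g1", "G1", "pancreas", 1e-9, 0.5),
        ("rs1", "g2", "G2", "whole_blood", 1e-10, -0.4),
        ("rs1", "g2", "G2", "spleen", 1e-9, 0.2),   # opposing sign -> mixed
        ("rs2", "g1", "G1", "whole_blood", 0.01, 0.9),  # not significant
    ],
    columns=["rsid", "gene_id", "gene_symbol", "tissue", "pval_nominal", "slope"],
)
retained = filter_associations(eqtl, p_max=5e-8)
circuit = build_circuit(retained)
print()
print(circuit.edges[["rsid", "gene_id", "direction", "n_tissues"]].to_string(index=False))
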
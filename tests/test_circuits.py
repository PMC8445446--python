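"""eQTL filtering, circuit graphs, direction rule, and nearest-gene logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from snpcircuit.circuits import (
    GeneModel,
    association_counts,
    build_circuit,
    filter_associations,
    nearest_gene,
    nearest_gene_discordance,
    tissue_summary,
    validate_eqtl_frame,
)


def _eqtl(rows):
    return pd.DataFrame(
        rows, columns=["rsid", "gene_id", "gene_symbol", "tissue", "pval_nominal", "slope"]
    )


def test_filter_is_strictly_below_threshold():
    df = _eqtl(
        [
            ("a", "g1", "G1", "t1", 4.9e-8, 0.5),
            ("b", "g1", "G1", "t1", 5e-8, 0.5),  # equality fails the strict filter
            ("c", "g1", "G1", "t1", 1e-3, 0.5),
        ]
    )
    kept = filter_associations(df)
    assert list(kept["rsid"]) == ["a"]


def test_filter_drops_bad_slopes_and_validates_p_max():
    df = _eqtl(
        [
            ("a", "g1", "G1", "t1", 1e-10, 0.0),  # zero slope
            ("b", "g1", "G1", "t1", 1e-10, np.nan),  # missing slope
            ("c", "g1", "G1", "t1", 1e-10, np.inf),  # non-finite
            ("d", "g1", "G1", "t1", 1e-10, -0.3),
        ]
    )
    assert list(filter_associations(df)["rsid"]) == ["d"]
    with pytest.raises(ValueError):
        filter_associations(df, p_max=0)
    with pytest.raises(ValueError):
        filter_associations(df, p_max=1.0)
    with pytest.raises(ValueError, match="missing columns"):
        validate_eqtl_frame(df.drop(columns=["slope"]))


@given(st.lists(st.sampled_from([-1.0, 1.0]), min_size=1, max_size=6))
def test_direction_unanimity_rule(signs):
    rows = [
        ("rs1", "g1", "G1", f"t{i}", 1e-10, 0.5 * s) for i, s in enumerate(signs)
    ]
    circuit = build_circuit(_eqtl(rows))
    direction = circuit.edges.iloc[0]["direction"]
    if all(s > 0 for s in signs):
        assert direction == "up"
    elif all(s < 0 for s in signs):
        assert direction == "down"
    else:
        assert direction == "mixed"


def test_circuit_one_edge_per_pair_with_distinct_tissue_count():
    rows = _eqtl(
        [
            ("rs1", "g1", "G1", "t1", 1e-10, 0.5),
            ("rs1", "g1", "G1", "t2", 1e-10, 0.4),
            ("rs1", "g1", "G1", "t2", 1e-10, 0.3),  # repeated tissue
            ("rs1", "g2", "G2", "t1", 1e-10, -0.2),
            ("rs2", "g1", "G1", "t1", 1e-10, 0.1),
        ]
    )
    circuit = build_circuit(rows)
    assert circuit.n_edges == 3
    edge = circuit.edges.set_index(["rsid", "gene_id"]).loc[("rs1", "g1")]
    assert edge["n_tissues"] == 2  # distinct tissues, not rows
    assert circuit.degree("rs1") == 2
    assert circuit.genes_of("rs1") == {"g1", "g2"}
    assert circuit.snps_of("g1") == {"rs1", "rs2"}
    g = circuit.to_networkx()
    assert g.number_of_edges() == 3
    assert g["rs1"]["g2"]["direction"] == "down"


def test_circuit_snp_subset_restriction():
    rows = _eqtl(
        [
            ("rs1", "g1", "G1", "t1", 1e-10, 0.5),
            ("rs2", "g2", "G2", "t1", 1e-10, 0.5),
        ]
    )
    sub = build_circuit(rows, snp_subset={"rs1"})
    assert sub.snp_nodes == ["rs1"] and sub.gene_nodes == ["g1"]
    assert association_counts(rows) == (2, 2)


def test_per_gene_summary_aggregates_with_unanimity():
    rows = _eqtl(
        [
            ("rs1", "g1", "G1", "t1", 1e-10, 0.5),
            ("rs2", "g1", "G1", "t2", 1e-10, -0.5),  # opposing SNP -> mixed gene
            ("rs1", "g2", "G2", "t1", 1e-10, 0.5),
        ]
    )
    summary = build_circuit(rows).per_gene_summary({"g1": 3})
    g1 = summary.set_index("gene_id").loc["g1"]
    assert g1["direction"] == "mixed"
    assert g1["n_tissues"] == 2
    assert g1["cluster"] == 3
    assert g1["snps"] == "rs1,rs2"
    assert summary.set_index("gene_id").loc["g2", "cluster"] == -1


def test_tissue_summary_distinct_count_oracle():
    rows = _eqtl(
        [
            ("rs1", "g1", "G1", "blood", 1e-10, 0.5),
            ("rs1", "g2", "G2", "blood", 1e-10, 0.5),
            ("rs2", "g1", "G1", "blood", 1e-10, 0.5),
            ("rs2", "g1", "G1", "pancreas", 1e-10, 0.5),
        ]
    )
    summary = tissue_summary(rows, snp_subset={"rs1"}).set_index("tissue")
    assert summary.loc["blood", "n_eqtl_snps"] == 2
    assert summary.loc["blood", "n_genes"] == 2
    assert summary.loc["blood", "n_subset_snps"] == 1
    assert summary.loc["blood", "n_subset_genes"] == 2
    assert summary.loc["pancreas", "n_subset_snps"] == 0  # zero, not NaN
    assert len(summary) == rows["tissue"].nunique()


GENES = [
    GeneModel("g_left", "L", "chr1", 100, 200),
    GeneModel("g_right", "R", "chr1", 300, 400),
    GeneModel("g_other", "O", "chr2", 0, 50),
]


def test_nearest_gene_containment_ties_and_missing_chrom():
    inside, d, _ = nearest_gene(("chr1", 150), GENES)  # 1-based 150 -> inside g_left
    assert inside.gene_id == "g_left" and d == 0
    # Asymmetric convention: right of g_left (p0 >= end) is p0 - end + 1,
    # left of g_right is start - p0, so the equidistant point needs offset spans.
    tie_genes = [
        GeneModel("g_left", "L", "chr1", 100, 200),
        GeneModel("g_right", "R", "chr1", 301, 400),
    ]
    primary, d, ties = nearest_gene(("chr1", 251), tie_genes)  # p0 = 250
    assert d == 51
    assert {g.gene_id for g in ties} == {"g_left", "g_right"}
    assert primary.gene_id == "g_left"
    assert nearest_gene(("chrX", 10), GENES) == (None, None, [])


def test_discordance_hand_case_and_empty():
    # rs_a sits inside g_left but targets g_right -> g_right is discordant;
    # rs_b targets its own nearest gene g_right -> g_right becomes concordant.
    retained = _eqtl(
        [
            ("rs_a", "g_right", "R", "t1", 1e-10, 0.5),
            ("rs_a", "g_left", "L", "t1", 1e-10, 0.5),
        ]
    )
    positions = {"rs_a": ("chr1", 150)}
    n_disc, n_total, frac = nearest_gene_discordance(retained, GENES, positions)
    assert (n_disc, n_total) == (1, 2) and frac == pytest.approx(0.5)
    retained2 = pd.concat(
        [retained, _eqtl([("rs_b", "g_right", "R", "t1", 1e-10, 0.5)])]
    )
    positions["rs_b"] = ("chr1", 350)
    n_disc, n_total, frac = nearest_gene_discordance(retained2, GENES, positions)
    assert (n_disc, n_total, frac) == (0, 2, 0.0)
    assert nearest_gene_discordance(retained.iloc[:0], GENES, {}) == (0, 0, None)


def test_per_tissue_expansion_resolves_mixed_edges():
    rows = _eqtl(
        [
            ("rs1", "g1", "G1", "t1", 1e-10, 0.5),
            ("rs1", "g1", "G1", "t2", 1e-10, -0.5),
        ]
    )
    circuit = build_circuit(rows)
    assert circuit.edges.iloc[0]["direction"] == "mixed"
    expanded = circuit.per_tissue_expansion()
    assert sorted(zip(expanded["tissue"], expanded["direction"])) == [
        ("t1", "up"), ("t2", "down")
    ]
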
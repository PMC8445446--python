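"""Funnel filters: rank ordinal logic, state selection, and end-to-end annotation."""

import numpy as np
import pandas as pd
import pytest

from snpcircuit.funnel import (
    DEFAULT_ENHANCER_STATES,
    RANK_ORDER,
    RegulomeRank,
    annotate_lncrna,
    annotate_snps,
    annotated_table,
    prioritize,
    rank_passes,
    read_rank_table,
    select_enhancer_states,
    venn_report,
)
from snpcircuit.intervals import GenomicInterval, IntervalSet
from snpcircuit.ld import TieredVariants


def _tiered(rows):
    variants = pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "tier"])
    pairs = pd.DataFrame(columns=["lead_rsid", "proxy_rsid", "r2", "dprime"])
    return TieredVariants(variants=variants, pairs=pairs)


THRESH = RegulomeRank.parse("2b")


def test_rank_ordinal_frozen_examples():
    assert rank_passes(RegulomeRank.parse("1f"), THRESH)
    assert rank_passes(RegulomeRank.parse("2b"), THRESH)  # threshold passes itself
    assert not rank_passes(RegulomeRank.parse("2c"), THRESH)
    assert not rank_passes(RegulomeRank.parse("3a"), THRESH)
    assert not rank_passes(RegulomeRank.parse("7"), THRESH)


def test_rank_order_total_and_parse_errors():
    ordinals = [RegulomeRank.parse(r).ordinal for r in RANK_ORDER]
    assert ordinals == sorted(ordinals) and len(set(ordinals)) == len(ordinals)
    assert RegulomeRank.parse(" 2B ").raw == "2b"  # whitespace/case tolerant
    with pytest.raises(ValueError, match="unknown"):
        RegulomeRank.parse("8")
    with pytest.raises(ValueError, match="unknown"):
        RegulomeRank.parse("")


def test_select_enhancer_states_filters_and_merges(caplog):
    seg = IntervalSet(
        [
            GenomicInterval("chr1", 0, 100, "13_EnhA1"),
            GenomicInterval("chr1", 100, 200, "14_EnhA2"),  # book-ended: merges
            GenomicInterval("chr1", 300, 400, "1_TssA"),  # not an enhancer state
            GenomicInterval("chr1", 500, 600, "18_EnhAc"),
        ]
    )
    enh = select_enhancer_states(seg)
    assert [(i.start, i.end) for i in enh] == [(0, 200), (500, 600)]
    with caplog.at_level("WARNING"):
        select_enhancer_states(seg, {"13_EnhA1", "99_Nope"})
    assert "99_Nope" in caplog.text


def _mini_scenario():
    """Five SNPs exercising every funnel pattern; positions are 1-based."""
    snps = _tiered(
        [
            ("rs_pass", "chr1", 150, 1),  # enhancer + TFBS + rank 2a -> high
            ("rs_no_tfbs", "chr1", 350, 2),  # enhancer only
            ("rs_bad_rank", "chr1", 550, 2),  # enhancer + TFBS, rank 3a
            ("rs_no_rank", "chr1", 750, 2),  # enhancer + TFBS, no rank record
            ("rs_nothing", "chr2", 150, 2),  # nothing at all
        ]
    )
    enhancers = IntervalSet(
        [
            GenomicInterval("chr1", 100, 200, "enh1"),
            GenomicInterval("chr1", 300, 400, "enh2"),
            GenomicInterval("chr1", 500, 600, "enh3"),
            GenomicInterval("chr1", 700, 800, "enh4"),
        ]
    )
    tfbs = IntervalSet(
        [
            GenomicInterval("chr1", 140, 160, "EBF1"),
            GenomicInterval("chr1", 540, 560, "MAX"),
            GenomicInterval("chr1", 740, 760, "USF1"),
        ]
    )
    ranks = {
        "rs_pass": RegulomeRank.parse("2a"),
        "rs_bad_rank": RegulomeRank.parse("3a"),
        "rs_nothing": RegulomeRank.parse("1a"),  # rank alone is not enough
    }
    return snps, enhancers, tfbs, ranks


def test_annotate_snps_mini_scenario_counts():
    snps, enhancers, tfbs, ranks = _mini_scenario()
    annotated, report = annotate_snps(snps, enhancers, tfbs, ranks)
    assert report.n_candidates == 5
    assert report.n_enhancer_snps == 4
    assert report.n_tfbs_enhancer_snps == 3  # rs_pass, rs_bad_rank, rs_no_rank
    assert report.n_rank_pass == 2  # rs_pass, rs_nothing
    assert report.n_high_probability == 1
    assert prioritize(annotated) == {"rs_pass"}
    by = {s.rsid: s for s in annotated}
    assert by["rs_no_rank"].rank is None and not by["rs_no_rank"].is_high_probability
    report.check_monotone()


def test_annotate_snps_threshold_widens_the_set():
    snps, enhancers, tfbs, ranks = _mini_scenario()
    _, report = annotate_snps(snps, enhancers, tfbs, ranks, threshold="3a")
    assert report.n_high_probability == 2  # rs_bad_rank (3a) now passes


def test_loose_tfbs_reading_admits_enhancer_mates():
    """require_tfbs_in_enhancer=False passes any SNP in a TFBS-overlapping enhancer."""
    snps = _tiered([("rs_a", "chr1", 110, 1), ("rs_b", "chr1", 190, 2)])
    enhancers = IntervalSet([GenomicInterval("chr1", 100, 200, "enh")])
    tfbs = IntervalSet([GenomicInterval("chr1", 105, 115, "TF")])  # covers rs_a only
    ranks = {r: RegulomeRank.parse("2a") for r in ("rs_a", "rs_b")}
    _, strict = annotate_snps(snps, enhancers, tfbs, ranks)
    assert strict.n_tfbs_enhancer_snps == 1
    _, loose = annotate_snps(snps, enhancers, tfbs, ranks, require_tfbs_in_enhancer=False)
    assert loose.n_tfbs_enhancer_snps == 2


def test_enhancer_region_counts_after_merge():
    # Two SNPs in one merged region, one in another: 3 SNPs, 2 regions.
    snps = _tiered(
        [("a", "chr1", 110, 1), ("b", "chr1", 190, 2), ("c", "chr1", 510, 2)]
    )
    enhancers = IntervalSet(
        [GenomicInterval("chr1", 100, 200, "e"), GenomicInterval("chr1", 500, 600, "f")]
    )
    _, report = annotate_snps(snps, enhancers, IntervalSet([]), {})
    assert report.n_enhancer_snps == 3
    assert report.n_enhancer_regions == 2


def test_annotate_lncrna_emits_pairs_per_transcript():
    snps = _tiered([("a", "chr1", 150, 1), ("b", "chr1", 999, 2)])
    lnc = IntervalSet(
        [
            GenomicInterval("chr1", 100, 200, "lnc1"),
            GenomicInterval("chr1", 120, 180, "lnc2"),  # overlapping transcript
        ]
    )
    pairs = annotate_lncrna(snps, lnc)
    assert sorted(map(tuple, pairs.itertuples(index=False))) == [
        ("a", "lnc1"),
        ("a", "lnc2"),
    ]


def test_venn_report_trivials_and_subsets():
    assert venn_report(set(), set(), set()) == {
        "high": 0, "high_eqtl": 0, "high_lncrna": 0, "high_eqtl_lncrna": 0
    }
    v = venn_report({"a", "b", "c"}, {"b", "c", "x"}, {"c", "y"})
    assert v == {"high": 3, "high_eqtl": 2, "high_lncrna": 1, "high_eqtl_lncrna": 1}
    assert v["high_eqtl_lncrna"] <= min(v["high_eqtl"], v["high_lncrna"]) <= v["high"]


def test_annotated_table_schema():
    snps, enhancers, tfbs, ranks = _mini_scenario()
    annotated, _ = annotate_snps(snps, enhancers, tfbs, ranks)
    table = annotated_table(annotated)
    assert list(table.columns) == [
        "rsid", "tier", "in_enhancer", "in_tfbs", "rank", "n_lncrnas", "high_probability"
    ]
    assert len(table) == 5
    assert table.set_index("rsid").loc["rs_pass", "high_probability"]


def test_read_rank_table_errors(tmp_path):
    path = tmp_path / "ranks.tsv"
    path.write_text("rsid\tscore\nrs1\t2b\n")
    with pytest.raises(ValueError, match="category"):
        read_rank_table(path)
    path.write_text("rsid\tcategory\nrs1\t2b\nrs2\t1a\n")
    ranks = read_rank_table(path)
    assert ranks["rs1"].raw == "2b" and ranks["rs2"].raw == "1a"
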
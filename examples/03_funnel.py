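"""The enhancer/TFBS/regulatory-rank prioritization funnel on a hand-built case.

Five candidate SNPs exercise every pattern: only the SNP that lies inside an
active-enhancer state AND a TFBS cluster AND carries a regulatory rank of 2b
or stronger survives as "high probability". A rank record alone is never
enough, and a missing rank record fails the filter (absence is not evidence).
"""

import pandas as pd

from snpcircuit import GenomicInterval, IntervalSet
from snpcircuit.funnel import RegulomeRank, annotate_snps, annotated_table, prioritize
from snpcircuit.ld import TieredVariants

snps = TieredVariants(
    variants=pd.DataFrame(
        [
            ("rs_pass", "chr1", 150, 1),      # enhancer + TFBS + rank 2a
            ("rs_no_tfbs", "chr1", 350, 2),   # enhancer only
            ("rs_bad_rank", "chr1", 550, 2),  # enhancer + TFBS, rank 3a
            ("rs_no_rank", "chr1", 750, 2),   # enhancer + TFBS, no rank record
            ("rs_rank_only", "chr2", 150, 2), # strong rank, no enhancer
        ],
        columns=["rsid", "chrom", "pos", "tier"],
    ),
    pairs=pd.DataFrame(columns=["lead_rsid", "proxy_rsid", "r2", "dprime"]),
)
enhancers = IntervalSet(
    [GenomicInterval("chr1", s, s + 100, "13_EnhA1") for s in (100, 300, 500, 700)]
)
tfbs = IntervalSet(
    [GenomicInterval("chr1", s, s + 20, tf)
     for s, tf in ((140, "EBF1"), (540, "MAX"), (740, "USF1"))]
)
ranks = {
    "rs_pass": RegulomeRank.parse("2a"),
    "rs_bad_rank": RegulomeRank.parse("3a"),
    "rs_rank_only": RegulomeRank.parse("1a"),
}

annotated, report = annotate_snps(snps, enhancers, tfbs, ranks, threshold="2b")
print(annotated_table(annotated).to_string(index=False))
print()
print(f"funnel: {report.n_candidates} candidates -> {report.n_enhancer_snps} in "
      f"enhancers -> {report.n_tfbs_enhancer_snps} in TFBS-containing enhancers "
      f"-> {report.n_high_probability} high probability")
print(f"high-probability set: {sorted(prioritize(annotated))}")
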
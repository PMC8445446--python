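"""LD statistics by hand, then lead-SNP proxy expansion on a panel.

Shows the D / D' / r-squared arithmetic on a tiny 2x2 haplotype table, the
closed-form r-squared of one-sided proxy noise, and the tiered candidate set
produced by expanding leads at r-squared > 0.6 and D' = 1.
"""

import numpy as np

from snpcircuit.ld import (
    HaplotypePanel,
    Site,
    expand_leads,
    haplotype_counts,
    ld_stats,
)

# A 2x2 haplotype table: counts (n11, n10, n01, n00) = (2, 1, 0, 2).
res = ld_stats((2, 1, 0, 2))
print(f"worked example: D = {res.D:.2f}, D' = {res.Dprime:.0f}, r2 = {res.r2:.4f}")

# One-sided proxy noise keeps D' = 1 exactly: flip some of the lead's
# 0-allele haplotypes to 1. With lead frequency 1/2 and flip fraction p = 0.1
# on 120 haplotypes, r2 = q(1-p)/(q+(1-q)p) = 9/11.
lead = np.array([1] * 60 + [0] * 60, dtype=np.int8)
proxy = lead.copy()
proxy[60:66] = 1
panel = HaplotypePanel(
    [Site("rs_lead", "chr1", 10_000), Site("rs_proxy", "chr1", 12_000)],
    np.vstack([lead, proxy]),
)
res = ld_stats(haplotype_counts(panel, 0, 1))
print(f"one-sided proxy: D' = {res.Dprime:.6f}, r2 = {res.r2:.4f} (9/11 = {9/11:.4f})")

# Proxy expansion: the proxy joins Tier 2; the lead stays Tier 1.
tiered = expand_leads(panel, ["rs_lead"], r2_min=0.6, dprime_min=1.0)
print(tiered.variants.to_string(index=False))
print(tiered.pairs.to_string(index=False))
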
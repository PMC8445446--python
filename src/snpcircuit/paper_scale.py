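"""Headline-scale synthetic study: a planted bundle matching the published funnel.

This preset emits raw input files (haplotypes, lead table, chromatin-state and
TFBS BED tracks, rank table, lncRNA and gene BEDs, eQTL table, expression
matrix, gene sets) whose *recomputed* analysis reproduces the published
study's headline cardinalities:

* 129 genome-wide-significant leads; 1,688 LD proxies (r² > 0.6, D' = 1);
  1,939 lead-proxy pairs; 1,817 candidate SNPs;
* 484 candidate SNPs inside 188 merged enhancer regions; 140 of them inside
  85 TFBS-containing enhancers; 94 SNPs with regulatory rank >= "2b";
* 26 high-probability causal enhancer SNPs; 15 of them eQTLs for 64 distinct
  genes (with two hub SNPs of degree 11 and 14 and a four-SNP locus of
  degrees 17/18/18/18); 745 eQTL SNPs for 159 genes overall;
* 78 SNPs inside 42 lncRNA transcripts (199 SNP-transcript pairs), 4 of the
  high-probability SNPs among them, 2 in the triple overlap.

Everything is planted structurally — LD blocks use one-sided exact-count
flips (D' = 1 exactly, r² = 9/11 ≈ 0.818), annotation intervals are carved
around known site positions — so the pipeline's counts are deterministic
functions of the seed-controlled layout, not of sampling luck.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd

from .circuits import GeneModel
from .enrichment import GeneSetCollection
from .expression import ExpressionMatrix
from .funnel import RegulomeRank
from .intervals import GenomicInterval, IntervalSet
from .ld import HaplotypePanel, Site
from .synthetic import (
    ENHANCER_STATES,
    FAILING_RANKS,
    NON_ENHANCER_STATES,
    PASSING_RANKS,
    TF_NAMES,
    AnnotationBundle,
    PlantedTruth,
)

N_CHROMOSOMES = 22
CHROM_LENGTH = 30_000_000
N_HAPLOTYPES = 120
SITE_SPACING = 1_000
BLOCK_SPACING = 3_000_000
FLIPS_PER_PROXY = 6  # of 60 zero-allele haplotypes -> r^2 = 0.9/1.1 = 0.818

EQTL_TISSUES = ["whole_blood", "pancreas", "skeletal_muscle"] + [
    f"tissue_{t:02d}" for t in range(4, 49)
]  # 48 tissues
EXPRESSION_TISSUES = EQTL_TISSUES + [f"tissue_{t:02d}" for t in range(49, 54)]  # 53


def _blocks() -> list[tuple[int, int]]:
    """(n_leads, n_proxies) per LD block.

    129 leads, 1,688 proxies; double-lead blocks make each of their proxies a
    proxy of two leads, so pairs = 1,437 + 2 x 251 = 1,939.
    """
    return [(1, 13)] * 89 + [(1, 14)] * 20 + [(2, 25)] * 9 + [(2, 26)]


def paper_scale_bundle(seed: int = 0) -> tuple[HaplotypePanel, PlantedTruth, AnnotationBundle]:
    rng = np.random.default_rng(seed)
    blocks = _blocks()
    truth = PlantedTruth()

    # --- haplotype panel -------------------------------------------------
    sites: list[Site] = []
    rows: list[np.ndarray] = []
    block_sites: list[list[int]] = []  # global site indices per block, positional order
    half = N_HAPLOTYPES // 2
    for b, (n_leads, n_proxies) in enumerate(blocks):
        chrom = f"chr{b % N_CHROMOSOMES + 1}"
        base = 200_000 + (b // N_CHROMOSOMES) * BLOCK_SPACING + int(rng.integers(0, 200_000))
        lead = np.zeros(N_HAPLOTYPES, dtype=np.int8)
        lead[rng.choice(N_HAPLOTYPES, size=half, replace=False)] = 1
        idxs: list[int] = []
        offset = 0
        for l in range(n_leads):
            rsid = f"rs{100000 + b * 100 + l}"
            sites.append(Site(rsid, chrom, base + offset * SITE_SPACING))
            rows.append(lead.copy())
            idxs.append(len(sites) - 1)
            offset += 1
        for p in range(n_proxies):
            rsid = f"rs{100000 + b * 100 + 10 + p}"
            proxy = lead.copy()
            zeros = np.flatnonzero(lead == 0)
            proxy[rng.choice(zeros, size=FLIPS_PER_PROXY, replace=False)] = 1
            sites.append(Site(rsid, chrom, base + offset * SITE_SPACING))
            rows.append(proxy)
            idxs.append(len(sites) - 1)
            truth.proxy_of[rsid] = f"rs{100000 + b * 100}"
            offset += 1
        block_sites.append(idxs)
    panel = HaplotypePanel(sites, np.vstack(rows))
    rsid_of = [s.rsid for s in sites]

    # --- run allocation over consecutive sites ---------------------------
    # kind -> list of runs (each run = list of global site indices)
    demands: list[tuple[str, int]] = (
        [("tfbs_enh", 2)] * 55 + [("tfbs_enh", 1)] * 30
        + [("plain_enh", 4)] * 35 + [("plain_enh", 3)] * 68
    )
    # lncRNA groups: (kind, total sites, sites at depth 3)
    lnc_groups: list[tuple[int, int]] = []  # (n_c3, n_c2) for 3-transcript groups
    c3_sizes = [5, 5] + [4] * 9  # 46 depth-3 sites over 11 groups
    c2_extra = [2] * 7 + [1] * 4  # 18 depth-2 sites over the same groups
    for a, b2 in zip(c3_sizes, c2_extra):
        lnc_groups.append((a, b2))
        demands.append(("lnc3", a + b2))
    for _ in range(2):  # 2-transcript groups, 5 depth-2 sites each
        demands.append(("lnc2", 5))

    runs: dict[str, list[list[int]]] = {"tfbs_enh": [], "plain_enh": [], "lnc3": [], "lnc2": []}
    cursor_block, cursor_pos = 0, 0
    for kind, size in demands:
        while cursor_pos + size > len(block_sites[cursor_block]):
            cursor_block += 1
            cursor_pos = 0
        run = block_sites[cursor_block][cursor_pos : cursor_pos + size]
        cursor_pos += size
        runs[kind].append(run)
    allocated = {i for rlist in runs.values() for run in rlist for i in run}
    free_sites = [i for i in range(len(sites)) if i not in allocated]

    # --- enhancer + TFBS tracks ------------------------------------------
    segmentation: list[GenomicInterval] = []
    tfbs: list[GenomicInterval] = []

    def span(run: list[int], pad: int) -> tuple[str, int, int]:
        first, last = sites[run[0]], sites[run[-1]]
        return first.chrom, first.pos - 1 - pad, last.pos - 1 + pad + 1

    for j, run in enumerate(runs["tfbs_enh"] + runs["plain_enh"]):
        chrom, start, end = span(run, 300)
        segmentation.append(
            GenomicInterval(chrom, start, end, ENHANCER_STATES[j % len(ENHANCER_STATES)])
        )
    for j, run in enumerate(runs["tfbs_enh"]):
        chrom, start, end = span(run, 150)
        tfbs.append(GenomicInterval(chrom, start, end, TF_NAMES[j % len(TF_NAMES)]))
    # TFBS clusters outside enhancers (do not change funnel counts).
    tfbs_only_sites = free_sites[:20]
    for j, i in enumerate(tfbs_only_sites):
        s = sites[i]
        tfbs.append(GenomicInterval(s.chrom, s.pos - 1 - 150, s.pos + 150, TF_NAMES[(j + 3) % len(TF_NAMES)]))
    # SNP-free enhancers and non-enhancer filler states, far from all sites.
    for j in range(10):
        chrom = f"chr{j + 1}"
        start = CHROM_LENGTH - 1_000_000 - j * 10_000
        segmentation.append(GenomicInterval(chrom, start, start + 800, ENHANCER_STATES[j % 6]))
    for j in range(N_CHROMOSOMES):
        segmentation.append(GenomicInterval(f"chr{j + 1}", 1_000, 5_000,
                                            NON_ENHANCER_STATES[j % len(NON_ENHANCER_STATES)]))

    # --- high-probability set and regulatory ranks ------------------------
    tfbs_sites = [i for run in runs["tfbs_enh"] for i in run]  # 140
    plain_enh_sites = [i for run in runs["plain_enh"] for i in run]  # 344
    high = [run[0] for run in runs["tfbs_enh"][:26]]  # 26, one per region
    truth.causal_rsids = {rsid_of[i] for i in high}

    ranks: dict[str, RegulomeRank] = {}
    for j, i in enumerate(high):
        ranks[rsid_of[i]] = RegulomeRank.parse(PASSING_RANKS[j % len(PASSING_RANKS)])
    rank_pass_enh_only = plain_enh_sites[:40]
    rank_pass_plain = free_sites[20:48]  # disjoint from tfbs_only_sites
    for j, i in enumerate(rank_pass_enh_only + rank_pass_plain):
        ranks[rsid_of[i]] = RegulomeRank.parse(PASSING_RANKS[j % len(PASSING_RANKS)])
    remaining_tfbs = [i for i in tfbs_sites if i not in set(high)]
    for j, i in enumerate(remaining_tfbs):
        if j % 2 == 0:  # half get a failing record, half none at all
            ranks[rsid_of[i]] = RegulomeRank.parse(FAILING_RANKS[j % len(FAILING_RANKS)])

    # --- gene models -------------------------------------------------------
    genes: list[GeneModel] = []
    for b in range(len(blocks)):
        last = sites[block_sites[b][-1]]
        genes.append(GeneModel(f"GENE{len(genes):04d}", f"G{len(genes)}", last.chrom,
                               last.pos + 3_000, last.pos + 5_000, "+"))
    for b in range(40):
        last = sites[block_sites[b][-1]]
        genes.append(GeneModel(f"GENE{len(genes):04d}", f"G{len(genes)}", last.chrom,
                               last.pos + 8_000, last.pos + 10_000, "-"))
    assert len(genes) == 159
    gene_ids = [g.gene_id for g in genes]

    # --- eQTL table --------------------------------------------------------
    # Gene sets of the 15 high-probability eQTLs; union is exactly genes 0..63.
    high_rs = [rsid_of[i] for i in high]
    edge_plan: dict[str, list[int]] = {}
    edge_plan[high_rs[0]] = list(range(0, 11))  # hub, degree 11
    edge_plan[high_rs[1]] = list(range(11, 25))  # hub, degree 14
    shared_locus = list(range(28, 44))  # 16 genes shared by a 4-SNP locus
    edge_plan[high_rs[2]] = [27] + shared_locus  # + a private gene, degree 17
    for k in (3, 4, 5):
        edge_plan[high_rs[k]] = [25, 26] + shared_locus  # degree 18
    tail_sizes = [3, 3, 2, 2, 2, 2, 2, 2, 2]  # 20 genes over 9 SNPs
    g = 44
    for k, sz in enumerate(tail_sizes):
        edge_plan[high_rs[6 + k]] = list(range(g, g + sz))
        g += sz
    assert g == 64

    non_high = [i for i in range(len(sites)) if i not in set(high)]
    other_eqtl = [int(i) for i in rng.choice(len(non_high), size=730, replace=False)]
    other_eqtl_sites = [non_high[i] for i in other_eqtl]
    for j, i in enumerate(other_eqtl_sites):
        plan = [64 + j] if j < 95 else []
        extra = rng.integers(0, 3)
        plan += [int(x) for x in rng.choice(159, size=int(extra), replace=False)]
        if not plan:
            plan = [int(rng.integers(0, 159))]
        edge_plan[rsid_of[i]] = sorted(set(plan))

    def signal_p() -> float:
        return 10.0 ** rng.uniform(-18, math.log10(5e-8))

    eqtl_rows: list[dict] = []
    for rsid, gene_idx in edge_plan.items():
        links: set[tuple[str, str, int]] = set()
        for gidx in gene_idx:
            gene = genes[gidx]
            n_tis = int(rng.integers(1, 4))
            for ti in rng.choice(len(EQTL_TISSUES), size=n_tis, replace=False):
                slope = float(rng.uniform(0.1, 1.2)) * (1 if rng.random() < 0.5 else -1)
                eqtl_rows.append({
                    "rsid": rsid, "gene_id": gene.gene_id, "gene_symbol": gene.symbol,
                    "tissue": EQTL_TISSUES[int(ti)], "pval_nominal": signal_p(),
                    "slope": slope,
                })
                links.add((gene.gene_id, EQTL_TISSUES[int(ti)], 1 if slope > 0 else -1))
        truth.true_targets[rsid] = links
    # Noise above the threshold, including on the 11 non-eQTL high-probability SNPs.
    noise_targets = [rsid_of[i] for i in high[15:]] + [
        rsid_of[int(i)] for i in rng.choice(len(sites), size=400, replace=False)
    ]
    for rsid in noise_targets:
        gene = genes[int(rng.integers(0, 159))]
        eqtl_rows.append({
            "rsid": rsid, "gene_id": gene.gene_id, "gene_symbol": gene.symbol,
            "tissue": EQTL_TISSUES[int(rng.integers(0, len(EQTL_TISSUES)))],
            "pval_nominal": 10.0 ** rng.uniform(math.log10(5e-8), 0),
            "slope": float(rng.uniform(0.05, 0.5)) * (1 if rng.random() < 0.5 else -1),
        })
    eqtl = pd.DataFrame(eqtl_rows).sort_values(["rsid", "gene_id", "tissue"]).reset_index(drop=True)

    # --- lncRNA transcripts -----------------------------------------------
    lncrnas: list[GenomicInterval] = []
    lnc_id = 0

    def transcript(chrom: str, start: int, end: int) -> None:
        nonlocal lnc_id
        lncrnas.append(GenomicInterval(chrom, start, end, f"NONHSAT{lnc_id:05d}.1"))
        lnc_id += 1

    # 4 high-probability SNPs in 5 transcripts (5 pairs); the first two are
    # also eQTLs, completing the published triple overlap of 2.
    for i, n_tx in zip((high[0], high[1], high[15], high[16]), (1, 2, 1, 1)):
        s = sites[i]
        for t in range(n_tx):
            transcript(s.chrom, s.pos - 1 - 100 - 20 * t, s.pos + 100 + 20 * t)
    # 11 groups of 3 nested transcripts and 2 groups of 2 (74 SNPs, 194 pairs).
    for (n_c3, n_c2), run in zip(lnc_groups, runs["lnc3"]):
        chrom = sites[run[0]].chrom
        inner = run[:n_c3]
        transcript(chrom, sites[inner[0]].pos - 1 - 50, sites[inner[-1]].pos + 50)
        transcript(chrom, sites[run[0]].pos - 1 - 150, sites[run[-1]].pos + 150)
        transcript(chrom, sites[run[0]].pos - 1 - 250, sites[run[-1]].pos + 250)
    for run in runs["lnc2"]:
        chrom = sites[run[0]].chrom
        transcript(chrom, sites[run[0]].pos - 1 - 50, sites[run[-1]].pos + 50)
        transcript(chrom, sites[run[0]].pos - 1 - 150, sites[run[-1]].pos + 150)
    assert lnc_id == 42

    # --- lead table, expression, gene sets ---------------------------------
    lead_rsids = [s.rsid for s in sites if s.rsid not in truth.proxy_of]
    leads = pd.DataFrame({
        "rsid": lead_rsids,
        "chrom": [sites[panel.index_of(r)].chrom for r in lead_rsids],
        "pos": [sites[panel.index_of(r)].pos for r in lead_rsids],
        "pvalue": 10.0 ** rng.uniform(-30, math.log10(5e-8), size=len(lead_rsids)),
    })
    vals = rng.uniform(0.0, 2.0, size=(159, len(EXPRESSION_TISSUES)))
    for gi in range(159):
        vals[gi, gi % len(EXPRESSION_TISSUES)] = rng.uniform(20.0, 120.0)
    expression = ExpressionMatrix(pd.DataFrame(vals, index=gene_ids, columns=EXPRESSION_TISSUES))

    background = [f"BG{i:04d}" for i in range(341)]
    universe = set(gene_ids) | set(background)
    sets: dict[str, list[str]] = {
        "PLANTED:high_prob_targets": gene_ids[:64] + background[:6],
    }
    uni_list = sorted(universe)
    for j in range(8):
        pick = rng.choice(len(uni_list), size=25, replace=False)
        sets[f"RANDOM:{j}"] = [uni_list[int(x)] for x in pick]
    gene_sets = GeneSetCollection.from_dict(sets, universe)

    bundle = AnnotationBundle(
        leads=leads,
        segmentation=IntervalSet(segmentation).sort(),
        tfbs=IntervalSet(tfbs).sort(),
        ranks=ranks,
        lncrnas=IntervalSet(lncrnas).sort(),
        genes=genes,
        eqtl=eqtl,
        expression=expression,
        gene_sets=gene_sets,
    )
    return panel, truth, bundle
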
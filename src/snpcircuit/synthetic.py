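"""Seeded synthetic inputs with known planted truth.

Every downstream stage — LD expansion, the enhancer/TFBS/rank funnel, eQTL
circuits, expression clustering, enrichment — is testable without any external
database because the generator emits all input files itself and records what
it planted:

* LD blocks: each lead SNP gets proxies copied from the lead's haplotype
  column with controlled noise. The default ``one_sided`` flip mode flips an
  exact number of haplotypes carrying the lead's 0 allele, which keeps D' = 1
  exactly (only three haplotype classes exist) while r² = q(1-p)/(q+(1-q)p)
  is tuned by ``flip_prob`` (q = lead allele frequency). A ``symmetric`` mode
  XORs Bernoulli(flip_prob) noise onto every haplotype instead, giving
  correlation ≈ 1-2·flip_prob at q = 0.5 but destroying exact D' = 1.
* Annotation tracks: six active-enhancer chromatin states among non-enhancer
  states, TFBS clusters nested in some enhancers, ordinal regulatory ranks,
  lncRNA transcripts, gene models, a multi-tissue eQTL table with signed
  slopes (signal p-values log-uniform below the significance threshold, noise
  log-uniform above it), and a tissue-clustered expression matrix.
* Planted truth: every causal SNP lies inside an enhancer state AND a TFBS
  cluster AND carries a rank passing "2b" AND has at least one significant
  eQTL row; every non-causal SNP fails at least one of those conditions.
  Causal SNPs sit at the midpoint of their enhancer so recovery does not
  hinge on boundary conventions (tested separately in the intervals module).

:func:`paper_scale_bundle` is a preset whose planted cardinalities equal the
published study's headline funnel (129 leads, 1,939 lead-proxy pairs, 1,817
candidates, 484 enhancer SNPs in 188 regions, 140 SNPs in 85 TFBS-containing
enhancers, 94 rank-passing SNPs, 26 high-probability SNPs of which 15 are
eQTLs for 64 genes, 745 eQTL SNPs for 159 genes, 78 lncRNA SNPs in 42
transcripts with 199 pairs); the pipeline recomputes every one of those
numbers from the emitted raw files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .circuits import GeneModel
from .enrichment import GeneSetCollection
from .expression import ExpressionMatrix
from .funnel import DEFAULT_ENHANCER_STATES, RANK_ORDER, RegulomeRank
from .intervals import GenomicInterval, IntervalSet, read_bed, write_bed
from .ld import HaplotypePanel, Site

ENHANCER_STATES = sorted(DEFAULT_ENHANCER_STATES)
NON_ENHANCER_STATES = ["1_TssA", "5_Tx", "9_TxReg", "24_ReprPC", "25_Quies"]
PASSING_RANKS = RANK_ORDER[: RANK_ORDER.index("2b") + 1]
FAILING_RANKS = RANK_ORDER[RANK_ORDER.index("2b") + 1 :]
TF_NAMES = ["EBF1", "MAX", "USF1", "CTCF", "POLR2A", "SPI1", "RELA", "STAT1"]


class ConfigError(ValueError):
    """Invalid synthetic configuration; the message names the offending field."""


class ConsistencyError(ValueError):
    """Planted truth and haplotype panel disagree."""


@dataclass
class SyntheticConfig:
    n_leads: int = 8
    proxies_per_lead: int = 4
    flip_prob: float = 0.1
    n_haplotypes: int = 120
    n_chromosomes: int = 4
    chrom_length: int = 30_000_000
    n_enhancers: int = 16
    enhancer_len: int = 1000
    tfbs_len: int = 200
    frac_causal: float = 0.25
    n_genes: int = 24
    n_tissues: int = 8
    n_lncrnas: int = 6
    eqtl_p_signal: float = 5e-8
    eqtl_p_noise: float = 5e-8
    seed: int = 0
    flip_mode: str = "one_sided"  # or "symmetric"

    def validate(self) -> None:
        for fname in ("n_leads", "proxies_per_lead", "n_haplotypes", "n_chromosomes",
                      "n_enhancers", "n_genes", "n_tissues", "n_lncrnas"):
            if getattr(self, fname) < 0:
                raise ConfigError(f"{fname} must be >= 0")
        if not (0 <= self.flip_prob < 0.5):
            raise ConfigError("flip_prob must lie in [0, 0.5)")
        if not (0 <= self.frac_causal <= 1):
            raise ConfigError("frac_causal must lie in [0, 1]")
        if not (self.chrom_length > self.enhancer_len > self.tfbs_len > 0):
            raise ConfigError("need chrom_length > enhancer_len > tfbs_len > 0")
        if not (0 < self.eqtl_p_signal < 1):
            raise ConfigError("eqtl_p_signal must lie in (0, 1)")
        if not (0 < self.eqtl_p_noise < 1):
            raise ConfigError("eqtl_p_noise must lie in (0, 1)")
        if self.n_haplotypes < 2:
            raise ConfigError("n_haplotypes must be >= 2")
        if self.n_chromosomes < 1:
            raise ConfigError("n_chromosomes must be >= 1")
        if self.flip_mode not in ("one_sided", "symmetric"):
            raise ConfigError("flip_mode must be 'one_sided' or 'symmetric'")


@dataclass
class PlantedTruth:
    causal_rsids: set[str] = field(default_factory=set)
    proxy_of: dict[str, str] = field(default_factory=dict)
    # rsid -> set of (gene_id, tissue, slope sign +1/-1)
    true_targets: dict[str, set[tuple[str, str, int]]] = field(default_factory=dict)

    def true_edges(self) -> set[tuple[str, str]]:
        return {(r, g) for r, links in self.true_targets.items() for g, _, _ in links}


@dataclass
class AnnotationBundle:
    """Everything the pipeline consumes, as in-memory objects plus writers."""

    leads: pd.DataFrame  # rsid, chrom, pos, pvalue
    segmentation: IntervalSet
    tfbs: IntervalSet
    ranks: dict[str, RegulomeRank]
    lncrnas: IntervalSet
    genes: list[GeneModel]
    eqtl: pd.DataFrame
    expression: ExpressionMatrix
    gene_sets: GeneSetCollection

    def write_dir(self, panel: HaplotypePanel, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {k: outdir / v for k, v in {
            "leads": "leads.tsv", "haplotypes": "haplotypes.tsv",
            "segmentation": "segmentation.bed", "tfbs": "tfbs.bed",
            "ranks": "ranks.tsv", "lncrnas": "lncrnas.bed", "genes": "genes.bed",
            "eqtl": "eqtl.tsv", "expression": "expression.tsv",
            "gene_sets": "gene_sets.gmt",
        }.items()}
        self.leads.to_csv(paths["leads"], sep="\t", index=False)
        panel.write_tsv(paths["haplotypes"])
        write_bed(self.segmentation, paths["segmentation"])
        write_bed(self.tfbs, paths["tfbs"])
        pd.DataFrame(
            sorted((r, v.raw) for r, v in self.ranks.items()),
            columns=["rsid", "category"],
        ).to_csv(paths["ranks"], sep="\t", index=False)
        write_bed(self.lncrnas, paths["lncrnas"])
        write_bed(
            IntervalSet([GenomicInterval(g.chrom, g.start, g.end, f"{g.gene_id}|{g.symbol}",
                                         None, g.strand) for g in self.genes]),
            paths["genes"],
        )
        self.eqtl.to_csv(paths["eqtl"], sep="\t", index=False)
        self.expression.write_tsv(paths["expression"])
        self.gene_sets.write_gmt(paths["gene_sets"])
        return paths


def _block_layout(cfg: SyntheticConfig, n_blocks: int, rng: np.random.Generator,
                  spacing: int = 3_000_000) -> list[tuple[str, int]]:
    """(chrom, jittered base position) per block, round-robin over chromosomes."""
    per_chrom = math.ceil(n_blocks / cfg.n_chromosomes)
    if 500_000 + per_chrom * spacing > cfg.chrom_length:
        raise ConfigError("chrom_length too small for the requested number of lead blocks")
    out = []
    for b in range(n_blocks):
        chrom = f"chr{b % cfg.n_chromosomes + 1}"
        base = 200_000 + (b // cfg.n_chromosomes) * spacing + int(rng.integers(0, 100_000))
        out.append((chrom, base))
    return out


def _proxy_from_lead(lead: np.ndarray, flip_prob: float, mode: str,
                     rng: np.random.Generator) -> np.ndarray:
    if mode == "symmetric":
        noise = rng.random(lead.shape[0]) < flip_prob
        return (lead ^ noise.astype(np.int8)).astype(np.int8)
    # one_sided: flip an exact count of 0-allele haplotypes to 1 (D' stays 1).
    proxy = lead.copy()
    zeros = np.flatnonzero(lead == 0)
    k = int(round(flip_prob * len(zeros)))
    if k:
        proxy[rng.choice(zeros, size=k, replace=False)] = 1
    return proxy


def generate_haplotypes(config: SyntheticConfig) -> tuple[HaplotypePanel, PlantedTruth]:
    """Lead/proxy haplotype panel with independent LD blocks.

    Each lead block holds one lead at allele frequency 1/2 and
    ``proxies_per_lead`` proxies derived from it; distinct blocks are
    generated independently; positions are strictly increasing per chromosome.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    layout = _block_layout(config, config.n_leads, rng)
    step = max(4 * config.enhancer_len, 2000)
    sites: list[Site] = []
    rows: list[np.ndarray] = []
    truth = PlantedTruth()
    half = config.n_haplotypes // 2
    for b, (chrom, base) in enumerate(layout):
        lead = np.zeros(config.n_haplotypes, dtype=np.int8)
        lead[rng.choice(config.n_haplotypes, size=half, replace=False)] = 1
        lead_rsid = f"rs{(b + 1) * 1000}"
        sites.append(Site(lead_rsid, chrom, base))
        rows.append(lead)
        for i in range(config.proxies_per_lead):
            rsid = f"rs{(b + 1) * 1000 + i + 1}"
            pos = base + (i + 1) * step + int(rng.integers(0, step // 4))
            sites.append(Site(rsid, chrom, pos))
            rows.append(_proxy_from_lead(lead, config.flip_prob, config.flip_mode, rng))
            truth.proxy_of[rsid] = lead_rsid
    panel = HaplotypePanel(sites, np.vstack(rows) if rows else np.zeros((0, config.n_haplotypes)))
    n_causal = int(round(config.frac_causal * panel.n_sites))
    causal_idx = rng.choice(panel.n_sites, size=n_causal, replace=False) if n_causal else []
    truth.causal_rsids = {panel.sites[i].rsid for i in causal_idx}
    return panel, truth


# Failure patterns for non-causal SNPs: each fails >=1 funnel condition.
_FAIL_PATTERNS = ("none", "enhancer_only", "enh_tfbs_bad_rank", "rank_only", "tfbs_only")


def generate_annotations(
    config: SyntheticConfig, panel: HaplotypePanel, truth: PlantedTruth
) -> AnnotationBundle:
    """Annotation tracks, eQTL table, and expression matrix around a panel."""
    config.validate()
    if not truth.causal_rsids <= {s.rsid for s in panel.sites}:
        raise ConsistencyError("causal rsids not all present in panel")
    rng = np.random.default_rng(config.seed + 1)
    by_rsid = {s.rsid: s for s in panel.sites}
    lead_rsids = [s.rsid for s in panel.sites if s.rsid not in truth.proxy_of]

    leads = pd.DataFrame(
        {
            "rsid": lead_rsids,
            "chrom": [by_rsid[r].chrom for r in lead_rsids],
            "pos": [by_rsid[r].pos for r in lead_rsids],
            "pvalue": 10.0 ** rng.uniform(-15, math.log10(5e-8), size=len(lead_rsids)),
        }
    )

    segmentation: list[GenomicInterval] = []
    tfbs: list[GenomicInterval] = []
    ranks: dict[str, RegulomeRank] = {}
    state_cycle = 0

    def add_enhancer(site: Site) -> None:
        nonlocal state_cycle
        p0 = site.pos - 1
        segmentation.append(
            GenomicInterval(site.chrom, p0 - config.enhancer_len // 2,
                            p0 + config.enhancer_len - config.enhancer_len // 2,
                            ENHANCER_STATES[state_cycle % len(ENHANCER_STATES)])
        )
        state_cycle += 1

    def add_tfbs(site: Site) -> None:
        p0 = site.pos - 1
        tfbs.append(
            GenomicInterval(site.chrom, p0 - config.tfbs_len // 2,
                            p0 + config.tfbs_len - config.tfbs_len // 2,
                            TF_NAMES[len(tfbs) % len(TF_NAMES)])
        )

    eqtl_eligible: list[str] = []  # SNPs allowed to carry signal eQTLs
    for site in panel.sites:
        if site.rsid in truth.causal_rsids:
            add_enhancer(site)
            add_tfbs(site)
            ranks[site.rsid] = RegulomeRank.parse(str(rng.choice(PASSING_RANKS)))
            eqtl_eligible.append(site.rsid)
        else:
            pattern = _FAIL_PATTERNS[int(rng.integers(0, len(_FAIL_PATTERNS)))]
            if pattern == "enhancer_only":
                add_enhancer(site)
                eqtl_eligible.append(site.rsid)
            elif pattern == "enh_tfbs_bad_rank":
                add_enhancer(site)
                add_tfbs(site)
                if rng.random() < 0.5:  # failing record vs no record at all
                    ranks[site.rsid] = RegulomeRank.parse(str(rng.choice(FAILING_RANKS)))
            elif pattern == "rank_only":
                ranks[site.rsid] = RegulomeRank.parse(str(rng.choice(PASSING_RANKS)))
            elif pattern == "tfbs_only":
                add_tfbs(site)

    # SNP-free enhancers plus non-enhancer filler states, placed between blocks.
    n_extra = max(0, config.n_enhancers - len(segmentation))
    for j in range(n_extra):
        chrom = f"chr{j % config.n_chromosomes + 1}"
        start = config.chrom_length - 2_000_000 - j * 5_000
        segmentation.append(GenomicInterval(chrom, start, start + config.enhancer_len,
                                            ENHANCER_STATES[j % len(ENHANCER_STATES)]))
    for j in range(config.n_chromosomes):
        chrom = f"chr{j + 1}"
        segmentation.append(GenomicInterval(chrom, 1000, 5000, NON_ENHANCER_STATES[j % len(NON_ENHANCER_STATES)]))

    # Gene models: per block of the panel, after the last site.
    genes: list[GeneModel] = []
    block_last: dict[str, int] = {}
    for s in panel.sites:
        block_last[s.chrom] = max(block_last.get(s.chrom, 0), s.pos)
    gi = 0
    chroms = sorted(block_last)
    while gi < config.n_genes and chroms:
        chrom = chroms[gi % len(chroms)]
        offset = 50_000 + (gi // len(chroms)) * 30_000
        start = block_last[chrom] + offset
        genes.append(GeneModel(f"GENE{gi:04d}", f"G{gi}", chrom, start, start + 10_000,
                               "+" if gi % 2 == 0 else "-"))
        gi += 1

    # lncRNA transcripts around randomly chosen sites (role-independent).
    lncrnas: list[GenomicInterval] = []
    if config.n_lncrnas and panel.n_sites:
        chosen = rng.choice(panel.n_sites, size=min(config.n_lncrnas, panel.n_sites),
                            replace=False)
        for j, si in enumerate(sorted(int(i) for i in chosen)):
            s = panel.sites[si]
            pad = 150 + 50 * (j % 3)
            lncrnas.append(GenomicInterval(s.chrom, s.pos - 1 - pad, s.pos - 1 + pad,
                                           f"NONHSAT{j:05d}.1"))

    tissues = [f"tissue_{t:02d}" for t in range(config.n_tissues)]
    eqtl_rows: list[dict] = []

    def signal_p() -> float:
        lo = math.log10(config.eqtl_p_signal)
        return 10.0 ** rng.uniform(lo - 10, lo)

    def noise_p() -> float:
        return 10.0 ** rng.uniform(math.log10(config.eqtl_p_noise), 0)

    gene_ids = [g.gene_id for g in genes]
    for rsid in eqtl_eligible:
        if not gene_ids or not tissues:
            break
        n_targets = int(rng.integers(1, min(3, len(gene_ids)) + 1))
        targets = rng.choice(len(gene_ids), size=n_targets, replace=False)
        links: set[tuple[str, str, int]] = set()
        for t_idx in targets:
            g = genes[int(t_idx)]
            n_tis = int(rng.integers(1, min(3, len(tissues)) + 1))
            for ti in rng.choice(len(tissues), size=n_tis, replace=False):
                slope = float(rng.uniform(0.1, 1.0)) * (1 if rng.random() < 0.5 else -1)
                eqtl_rows.append(
                    {"rsid": rsid, "gene_id": g.gene_id, "gene_symbol": g.symbol,
                     "tissue": tissues[int(ti)], "pval_nominal": signal_p(), "slope": slope}
                )
                links.add((g.gene_id, tissues[int(ti)], 1 if slope > 0 else -1))
        truth.true_targets[rsid] = links
    # Noise associations above the threshold, on random SNPs (both kinds).
    if gene_ids and tissues:
        for si in rng.choice(panel.n_sites, size=min(panel.n_sites, panel.n_sites // 2 + 1),
                             replace=False):
            s = panel.sites[int(si)]
            g = genes[int(rng.integers(0, len(genes)))]
            slope = float(rng.uniform(0.05, 0.5)) * (1 if rng.random() < 0.5 else -1)
            eqtl_rows.append(
                {"rsid": s.rsid, "gene_id": g.gene_id, "gene_symbol": g.symbol,
                 "tissue": tissues[int(rng.integers(0, len(tissues)))],
                 "pval_nominal": noise_p(), "slope": slope}
            )
    eqtl = pd.DataFrame(
        eqtl_rows,
        columns=["rsid", "gene_id", "gene_symbol", "tissue", "pval_nominal", "slope"],
    ).sort_values(["rsid", "gene_id", "tissue"]).reset_index(drop=True)

    expression = _tissue_clustered_expression(gene_ids, tissues, rng)
    gene_sets = _synthetic_gene_sets(truth, gene_ids, rng)

    return AnnotationBundle(
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


def _tissue_clustered_expression(
    gene_ids: list[str], tissues: list[str], rng: np.random.Generator
) -> ExpressionMatrix:
    """Each gene is high in one 'home' tissue and near-zero elsewhere."""
    if not gene_ids or not tissues:
        return ExpressionMatrix(pd.DataFrame(np.zeros((max(len(gene_ids), 1), 1)),
                                             index=gene_ids or ["GENE0000"],
                                             columns=tissues or ["tissue_00"]))
    vals = rng.uniform(0.0, 2.0, size=(len(gene_ids), len(tissues)))
    for i in range(len(gene_ids)):
        home = int(rng.integers(0, len(tissues)))
        vals[i, home] = rng.uniform(20.0, 100.0)
    return ExpressionMatrix(pd.DataFrame(vals, index=gene_ids, columns=tissues))


def _synthetic_gene_sets(
    truth: PlantedTruth, gene_ids: list[str], rng: np.random.Generator, n_random: int = 5
) -> GeneSetCollection:
    """One term enriched for planted target genes, plus random terms."""
    background = [f"BG{i:04d}" for i in range(max(50, 2 * len(gene_ids)))]
    universe = set(gene_ids) | set(background)
    target_genes = sorted({g for links in truth.true_targets.values() for g, _, _ in links})
    sets: dict[str, list[str]] = {}
    if target_genes:
        sets["PLANTED:target_circuit"] = target_genes + background[:5]
    uni_list = sorted(universe)
    for j in range(n_random):
        size = int(rng.integers(10, 30))
        members = rng.choice(len(uni_list), size=min(size, len(uni_list)), replace=False)
        sets[f"RANDOM:{j}"] = [uni_list[int(m)] for m in members]
    return GeneSetCollection.from_dict(sets, universe)


def generate_bundle(config: SyntheticConfig) -> tuple[HaplotypePanel, PlantedTruth, AnnotationBundle]:
    """Convenience: haplotypes + annotations in one call."""
    panel, truth = generate_haplotypes(config)
    bundle = generate_annotations(config, panel, truth)
    return panel, truth, bundle
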
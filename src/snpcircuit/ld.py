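"""Pairwise haplotype linkage disequilibrium and lead-SNP proxy expansion.

Works on a phased haplotype panel (rows = biallelic sites coded 0/1, columns =
haplotypes). LD statistics follow the standard definitions:

    D   = p11 - pA * pB
    D'  = |D| / Dmax,  Dmax = min(pA(1-pB), (1-pA)pB)  if D > 0
                       Dmax = min(pA*pB, (1-pA)(1-pB)) if D < 0
    r^2 = D^2 / (pA(1-pA) pB(1-pB))

where pA, pB are allele-1 frequencies at the two sites and p11 the frequency
of the 1/1 haplotype. Lead SNPs are expanded into Tier-2 proxies with the
common post-GWAS criteria r^2 > r2_min (strict) and D' >= dprime_min, within a
physical window around each lead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Numerical tolerance under which D' counts as exactly 1.
DPRIME_ONE_TOL = 1e-9


class MonomorphicSiteError(ValueError):
    """LD is undefined when a margin is monomorphic; callers must skip, not coerce."""


@dataclass(frozen=True)
class Site:
    rsid: str
    chrom: str
    pos: int  # 1-based bp


@dataclass
class HaplotypePanel:
    """Phased 0/1 alleles: one row per site, one column per haplotype."""

    sites: list[Site]
    alleles: np.ndarray  # shape (n_sites, n_haplotypes), dtype int8

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2 or self.alleles.shape[0] != len(self.sites):
            raise ValueError("alleles must be (n_sites, n_haplotypes)")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("alleles must be 0/1 with no missing values")
        last: dict[str, int] = {}
        for s in self.sites:
            if s.chrom in last and s.pos <= last[s.chrom]:
                raise ValueError(f"positions not strictly increasing on {s.chrom} at {s.rsid}")
            last[s.chrom] = s.pos
        self._index = {s.rsid: i for i, s in enumerate(self.sites)}
        if len(self._index) != len(self.sites):
            raise ValueError("duplicate rsids in panel")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[1]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def index_of(self, rsid: str) -> int:
        return self._index[rsid]

    def is_monomorphic(self, i: int) -> bool:
        col = self.alleles[i]
        return bool(col.min() == col.max())

    def to_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {"rsid": [s.rsid for s in self.sites],
             "chrom": [s.chrom for s in self.sites],
             "pos": [s.pos for s in self.sites]}
        )
        hap = pd.DataFrame(self.alleles, columns=[f"hap{j}" for j in range(self.n_haplotypes)])
        return pd.concat([meta, hap], axis=1)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "HaplotypePanel":
        df = pd.read_csv(path, sep="\t")
        hap_cols = [c for c in df.columns if c.startswith("hap")]
        sites = [Site(r.rsid, r.chrom, int(r.pos)) for r in df.itertuples()]
        return cls(sites, df[hap_cols].to_numpy(dtype=np.int8))


@dataclass(frozen=True)
class LDResult:
    D: float
    Dprime: float
    r2: float
    n_haplotypes: int


@dataclass
class TieredVariants:
    """Candidate set: Tier 1 = GWAS leads, Tier 2 = LD proxies, with pair provenance."""

    variants: pd.DataFrame  # columns: rsid, chrom, pos, tier
    pairs: pd.DataFrame  # columns: lead_rsid, proxy_rsid, r2, dprime

    @property
    def n_candidates(self) -> int:
        return len(self.variants)

    def tier(self, which: int) -> pd.DataFrame:
        return self.variants[self.variants["tier"] == which]

    def write_pairs_tsv(self, path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)


def haplotype_counts(panel: HaplotypePanel, site_a: int, site_b: int) -> tuple[int, int, int, int]:
    """2x2 haplotype counts (n11, n10, n01, n00) for allele 1/0 at two sites."""
    if not (0 <= site_a < panel.n_sites and 0 <= site_b < panel.n_sites):
        raise IndexError(f"site index out of range: {site_a}, {site_b}")
    a = panel.alleles[site_a]
    b = panel.alleles[site_b]
    n11 = int(np.sum((a == 1) & (b == 1)))
    n10 = int(np.sum((a == 1) & (b == 0)))
    n01 = int(np.sum((a == 0) & (b == 1)))
    n00 = int(np.sum((a == 0) & (b == 0)))
    return n11, n10, n01, n00


def ld_stats(counts: tuple[int, int, int, int]) -> LDResult:
    """D, D', r^2 from a 2x2 haplotype count table.

    Raises :class:`MonomorphicSiteError` when either margin is fixed: LD is
    undefined there and silently coercing to 0 (or to D'=1) would distort
    proxy expansion.
    """
    n11, n10, n01, n00 = counts
    n = n11 + n10 + n01 + n00
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    pA = (n11 + n10) / n
    pB = (n11 + n01) / n
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise MonomorphicSiteError("monomorphic margin: LD undefined")
    p11 = n11 / n
    D = p11 - pA * pB
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    elif D < 0:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    else:
        dmax = 1.0  # D = 0 -> D' = 0 regardless
    dprime = abs(D) / dmax if dmax > 0 else 0.0
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    # Clamp float dust so invariants 0<=r2<=1, 0<=D'<=1 hold exactly.
    return LDResult(D=D, Dprime=min(dprime, 1.0), r2=min(r2, 1.0), n_haplotypes=n)


def ld_between(panel: HaplotypePanel, site_a: int, site_b: int) -> LDResult:
    return ld_stats(haplotype_counts(panel, site_a, site_b))


def expand_leads(
    panel: HaplotypePanel,
    leads: Sequence[str],
    r2_min: float = 0.6,
    dprime_min: float = 1.0,
    window: int = 1_000_000,
) -> TieredVariants:
    """Expand lead SNPs into the tiered candidate set.

    A panel site within ``window`` bp of a lead joins Tier 2 when r^2 > r2_min
    (strict) and D' >= dprime_min (compared with a 1e-9 tolerance so an exact
    D'=1 criterion survives floating point). A site that is both a lead and a
    proxy stays Tier 1; such lead-lead links are not recorded in the pairs
    table. Monomorphic sites are skipped with a warning. Output is
    deduplicated and independent of lead input order.
    """
    if not (0 < r2_min <= 1):
        raise ValueError("r2_min must be in (0, 1]")
    if window <= 0:
        raise ValueError("window must be positive")
    lead_set = set()
    for rsid in leads:
        try:
            panel.index_of(rsid)
        except KeyError:
            logger.warning("lead %s absent from panel; excluded", rsid)
            continue
        lead_set.add(rsid)
    pair_rows = []
    tier2: set[str] = set()
    for lead in sorted(lead_set):
        li = panel.index_of(lead)
        lsite = panel.sites[li]
        if panel.is_monomorphic(li):
            logger.warning("lead %s is monomorphic; skipped", lead)
            continue
        for j, site in enumerate(panel.sites):
            if j == li or site.chrom != lsite.chrom or abs(site.pos - lsite.pos) > window:
                continue
            if panel.is_monomorphic(j):
                continue
            res = ld_stats(haplotype_counts(panel, li, j))
            if res.r2 > r2_min and res.Dprime >= dprime_min - DPRIME_ONE_TOL:
                if site.rsid not in lead_set:
                    tier2.add(site.rsid)
                    pair_rows.append((lead, site.rsid, res.r2, res.Dprime))
    rows = []
    for s in panel.sites:
        if s.rsid in lead_set:
            rows.append((s.rsid, s.chrom, s.pos, 1))
        elif s.rsid in tier2:
            rows.append((s.rsid, s.chrom, s.pos, 2))
    variants = pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "tier"])
    pairs = pd.DataFrame(pair_rows, columns=["lead_rsid", "proxy_rsid", "r2", "dprime"])
    pairs = pairs.sort_values(["lead_rsid", "proxy_rsid"]).reset_index(drop=True)
    return TieredVariants(variants=variants, pairs=pairs)
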
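"""Enhancer-SNP prioritization funnel.

Candidate SNPs are passed through three positional/evidence filters:

1. chromatin-state filter — keep SNPs inside merged enhancer-state segments
   (active-enhancer ChromHMM tags by default);
2. TFBS filter — of those, keep SNPs that also fall inside a ChIP-seq TFBS
   cluster ("TFBS-containing enhancer" read as a positional conjunction);
3. regulatory-evidence filter — keep SNPs whose RegulomeDB-style ordinal rank
   is at least as strong as a threshold (default "2b": functional motif
   evidence).

Survivors are the "high-probability" causal enhancer SNPs. Independently,
SNPs inside lncRNA transcripts are annotated, and a Venn report summarizes
overlaps between the high-probability set, eQTL SNPs, and lncRNA SNPs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .intervals import IntervalSet, annotate_containment, merge
from .ld import TieredVariants

logger = logging.getLogger(__name__)

#: Active-enhancer chromatin-state tags used by default (18-state ChromHMM model).
DEFAULT_ENHANCER_STATES = frozenset(
    {"13_EnhA1", "14_EnhA2", "15_EnhAF", "16_EnhW1", "17_EnhW2", "18_EnhAc"}
)

#: RegulomeDB-style ordinal categories from strongest to weakest evidence.
RANK_ORDER = ["1a", "1b", "1c", "1d", "1e", "1f", "2a", "2b", "2c", "3a", "3b", "4", "5", "6", "7"]
_RANK_ORDINAL = {raw: i for i, raw in enumerate(RANK_ORDER)}


class RankParseError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class RegulomeRank:
    """Ordinal regulatory-evidence category; lower ordinal = stronger evidence."""

    ordinal: int
    raw: str

    @classmethod
    def parse(cls, token: str) -> "RegulomeRank":
        raw = str(token).strip().lower()
        if raw not in _RANK_ORDINAL:
            raise RankParseError(f"unknown regulatory rank category: {token!r}")
        return cls(ordinal=_RANK_ORDINAL[raw], raw=raw)


def rank_passes(rank: RegulomeRank, threshold: RegulomeRank) -> bool:
    """True iff ``rank`` carries evidence at least as strong as ``threshold``."""
    return rank.ordinal <= threshold.ordinal


@dataclass
class AnnotatedSnp:
    rsid: str
    tier: int
    in_enhancer: bool = False
    enhancer_ids: list[str] = field(default_factory=list)
    in_tfbs: bool = False
    tf_names: list[str] = field(default_factory=list)
    rank: Optional[RegulomeRank] = None
    lncrna_ids: list[str] = field(default_factory=list)
    is_high_probability: bool = False


@dataclass
class FunnelReport:
    n_candidates: int = 0
    n_enhancer_snps: int = 0
    n_enhancer_regions: int = 0
    n_tfbs_enhancer_snps: int = 0
    n_tfbs_enhancers: int = 0
    n_rank_pass: int = 0
    n_high_probability: int = 0
    venn: dict = field(default_factory=dict)

    def check_monotone(self) -> None:
        """Funnel attrition must be monotone; violated only by a logic bug."""
        assert self.n_high_probability <= min(self.n_tfbs_enhancer_snps, self.n_rank_pass), self
        assert self.n_tfbs_enhancer_snps <= self.n_enhancer_snps <= self.n_candidates, self

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def select_enhancer_states(
    segmentation: IntervalSet, states: Iterable[str] = DEFAULT_ENHANCER_STATES
) -> IntervalSet:
    """Keep segments whose state name is in ``states``, then merge.

    Merging avoids duplicated counts from overlapping or abutting enhancer
    segments (a SNP then occupies at most one enhancer region).
    """
    states = set(states)
    present = {iv.name for iv in segmentation}
    for unknown in sorted(states - present):
        logger.warning("requested state %s not present in segmentation", unknown)
    selected = IntervalSet([iv for iv in segmentation if iv.name in states])
    if len(selected) == 0:
        return selected
    return merge(selected)


@dataclass
class TrackOccupancy:
    label: str
    snp_flags: dict[str, bool]
    snp_regions: dict[str, list[str]]
    n_occupied_snps: int
    n_occupied_regions: int
    occupied_regions: list[str]


def annotate_track_occupancy(
    snps: TieredVariants, track: IntervalSet, label: str
) -> TrackOccupancy:
    """Flag SNPs contained (distance 0) in the track; count occupied regions.

    Regions are identified by ``chrom:start-end`` so per-region SNP tallies
    stay well defined even when names repeat (e.g. a TF bound at many sites).
    """
    points = [(r.chrom, int(r.pos)) for r in snps.variants.itertuples()]
    rsids = list(snps.variants["rsid"])
    per_chrom = track.by_chrom()
    flags: dict[str, bool] = {}
    region_map: dict[str, list[str]] = {}
    occupied: set[str] = set()
    for rsid, (chrom, pos) in zip(rsids, points):
        p0 = pos - 1
        names = []
        for iv in per_chrom.get(chrom, []):
            if iv.start > p0:
                break
            if iv.start <= p0 < iv.end:
                key = f"{iv.chrom}:{iv.start}-{iv.end}"
                names.append(key)
                occupied.add(key)
        flags[rsid] = bool(names)
        region_map[rsid] = names
    return TrackOccupancy(
        label=label,
        snp_flags=flags,
        snp_regions=region_map,
        n_occupied_snps=sum(flags.values()),
        n_occupied_regions=len(occupied),
        occupied_regions=sorted(occupied),
    )


def read_rank_table(path) -> dict[str, RegulomeRank]:
    """Read a two-column TSV (rsid, category) of regulatory ranks."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"rsid", "category"} - set(df.columns)
    if missing:
        raise ValueError(f"rank table missing columns: {sorted(missing)}")
    return {r.rsid: RegulomeRank.parse(r.category) for r in df.itertuples()}


def annotate_snps(
    snps: TieredVariants,
    enhancers: IntervalSet,
    tfbs: IntervalSet,
    ranks: Mapping[str, RegulomeRank],
    lncrnas: Optional[IntervalSet] = None,
    threshold: RegulomeRank | str = "2b",
    require_tfbs_in_enhancer: bool = True,
) -> tuple[list[AnnotatedSnp], FunnelReport]:
    """Run the whole funnel and return per-SNP annotations plus stage counts.

    ``require_tfbs_in_enhancer=True`` (default) reads "located within
    TFBS-containing enhancers" as the SNP lying in an enhancer AND in a TFBS
    cluster. The looser reading — SNP in an enhancer that overlaps a TFBS
    anywhere — is available with ``False``.
    """
    if isinstance(threshold, str):
        threshold = RegulomeRank.parse(threshold)
    enh_occ = annotate_track_occupancy(snps, enhancers, "enhancer")
    tfbs_occ = annotate_track_occupancy(snps, tfbs, "tfbs")

    if not require_tfbs_in_enhancer:
        # An enhancer region counts as TFBS-containing if any TFBS cluster
        # overlaps it; every SNP in such an enhancer passes stage 2.
        tfbs_merged = merge(tfbs)
        tf_by_chrom = tfbs_merged.by_chrom()

        def enhancer_has_tfbs(region_key: str) -> bool:
            chrom, span = region_key.split(":")
            start, end = (int(x) for x in span.split("-"))
            for iv in tf_by_chrom.get(chrom, []):
                if iv.start >= end:
                    break
                if iv.end > start:
                    return True
            return False

        tfbs_enh_regions = {k for k in enh_occ.occupied_regions if enhancer_has_tfbs(k)}

    annotated: list[AnnotatedSnp] = []
    lnc_map: dict[str, list[str]] = {}
    if lncrnas is not None and len(lncrnas):
        pairs = annotate_lncrna(snps, lncrnas)
        for _, row in pairs.iterrows():
            lnc_map.setdefault(row["rsid"], []).append(row["lncrna_id"])

    n_tfbs_enh = 0
    tfbs_enh_region_hits: set[str] = set()
    for row in snps.variants.itertuples():
        snp = AnnotatedSnp(rsid=row.rsid, tier=int(row.tier))
        snp.in_enhancer = enh_occ.snp_flags[row.rsid]
        snp.enhancer_ids = enh_occ.snp_regions[row.rsid]
        snp.in_tfbs = tfbs_occ.snp_flags[row.rsid]
        snp.tf_names = tfbs_occ.snp_regions[row.rsid]
        snp.rank = ranks.get(row.rsid)
        snp.lncrna_ids = lnc_map.get(row.rsid, [])
        if require_tfbs_in_enhancer:
            in_tfbs_enh = snp.in_enhancer and snp.in_tfbs
        else:
            in_tfbs_enh = snp.in_enhancer and any(
                rk in tfbs_enh_regions for rk in snp.enhancer_ids
            )
        if in_tfbs_enh:
            n_tfbs_enh += 1
            tfbs_enh_region_hits.update(snp.enhancer_ids)
        # Absence of a rank record fails the filter: absence is not evidence.
        snp.is_high_probability = bool(
            in_tfbs_enh and snp.rank is not None and rank_passes(snp.rank, threshold)
        )
        annotated.append(snp)

    report = FunnelReport(
        n_candidates=snps.n_candidates,
        n_enhancer_snps=enh_occ.n_occupied_snps,
        n_enhancer_regions=enh_occ.n_occupied_regions,
        n_tfbs_enhancer_snps=n_tfbs_enh,
        n_tfbs_enhancers=len(tfbs_enh_region_hits),
        n_rank_pass=sum(
            1 for s in annotated if s.rank is not None and rank_passes(s.rank, threshold)
        ),
        n_high_probability=sum(1 for s in annotated if s.is_high_probability),
    )
    report.check_monotone()
    return annotated, report


def prioritize(annotated: Sequence[AnnotatedSnp], threshold: RegulomeRank | str = "2b") -> set[str]:
    """High-probability set from already-annotated SNPs (order-free, deterministic)."""
    if isinstance(threshold, str):
        threshold = RegulomeRank.parse(threshold)
    return {
        s.rsid
        for s in annotated
        if s.in_enhancer and s.in_tfbs and s.rank is not None and rank_passes(s.rank, threshold)
    }


def annotate_lncrna(snps: TieredVariants, lncrnas: IntervalSet) -> pd.DataFrame:
    """One row per (SNP, containing lncRNA transcript); SNPs may pair repeatedly."""
    points = [(r.chrom, int(r.pos)) for r in snps.variants.itertuples()]
    contained = annotate_containment(points, lncrnas)
    rows = []
    for rsid, point in zip(snps.variants["rsid"], points):
        for name in contained[point]:
            rows.append((rsid, name))
    return pd.DataFrame(rows, columns=["rsid", "lncrna_id"])


def venn_report(high: set[str], eqtl_snps: set[str], lncrna_snps: set[str]) -> dict[str, int]:
    """Overlap cardinalities between the prioritized set, eQTL SNPs, and lncRNA SNPs."""
    return {
        "high": len(high),
        "high_eqtl": len(high & eqtl_snps),
        "high_lncrna": len(high & lncrna_snps),
        "high_eqtl_lncrna": len(high & eqtl_snps & lncrna_snps),
    }


def annotated_table(annotated: Sequence[AnnotatedSnp]) -> pd.DataFrame:
    """Flat per-SNP table mirroring a published-style summary of the funnel."""
    rows = []
    for s in annotated:
        rows.append(
            {
                "rsid": s.rsid,
                "tier": s.tier,
                "in_enhancer": s.in_enhancer,
                "in_tfbs": s.in_tfbs,
                "rank": s.rank.raw if s.rank else "",
                "n_lncrnas": len(s.lncrna_ids),
                "high_probability": s.is_high_probability,
            }
        )
    return pd.DataFrame(rows)
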
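"""LD statistics: frozen worked examples, exhaustive oracles, and panel I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snpcircuit.ld import (
    DPRIME_ONE_TOL,
    HaplotypePanel,
    MonomorphicSiteError,
    Site,
    expand_leads,
    haplotype_counts,
    ld_stats,
)


def _oracle(n11, n10, n01, n00):
    """Independent reference: r^2 via numpy correlation, D' from first principles."""
    a = np.array([1] * (n11 + n10) + [0] * (n01 + n00), dtype=float)
    b = np.array([1] * n11 + [0] * n10 + [1] * n01 + [0] * n00, dtype=float)
    r = np.corrcoef(a, b)[0, 1]
    n = n11 + n10 + n01 + n00
    pA, pB, p11 = (n11 + n10) / n, (n11 + n01) / n, n11 / n
    D = p11 - pA * pB
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    elif D < 0:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    else:
        return D, 0.0, r * r
    return D, abs(D) / dmax, r * r


def test_frozen_worked_example():
    # Counts (n11, n10, n01, n00) = (2, 1, 0, 2), n = 5.
    res = ld_stats((2, 1, 0, 2))
    assert res.D == pytest.approx(2 / 5 - (3 / 5) * (2 / 5))  # 0.16
    assert res.Dprime == pytest.approx(1.0)
    assert res.r2 == pytest.approx(4 / 9)
    assert res.n_haplotypes == 5


def test_monomorphic_margin_is_an_error_not_zero():
    with pytest.raises(MonomorphicSiteError):
        ld_stats((3, 0, 2, 0))  # site B fixed at 1
    with pytest.raises(MonomorphicSiteError):
        ld_stats((0, 0, 2, 3))  # site A fixed at 0
    with pytest.raises(ValueError):
        ld_stats((1, 0, 0, 0))  # fewer than 2 haplotypes


def test_exhaustive_oracle_all_tables_up_to_n12():
    """Exhaustive agreement with an independent oracle for every 2x2 table, N <= 12."""
    checked = 0
    for n in range(2, 13):
        for n11 in range(n + 1):
            for n10 in range(n - n11 + 1):
                for n01 in range(n - n11 - n10 + 1):
                    n00 = n - n11 - n10 - n01
                    counts = (n11, n10, n01, n00)
                    pA = (n11 + n10) / n
                    pB = (n11 + n01) / n
                    if pA in (0, 1) or pB in (0, 1):
                        with pytest.raises(MonomorphicSiteError):
                            ld_stats(counts)
                        continue
                    res = ld_stats(counts)
                    D, dprime, r2 = _oracle(*counts)
                    assert res.D == pytest.approx(D, abs=1e-12)
                    assert res.Dprime == pytest.approx(min(dprime, 1.0), abs=1e-9)
                    assert res.r2 == pytest.approx(min(r2, 1.0), abs=1e-9)
                    # Invariants and class-count equivalences.
                    assert 0 <= res.r2 <= 1 and 0 <= res.Dprime <= 1
                    n_classes = sum(1 for c in counts if c > 0)
                    if res.Dprime >= 1 - DPRIME_ONE_TOL:
                        assert n_classes <= 3
                    if n_classes <= 3:
                        assert res.Dprime == pytest.approx(1.0) or res.D == 0
                    if res.r2 == pytest.approx(1.0):
                        assert (n10 == 0 and n01 == 0) or (n11 == 0 and n00 == 0)
                    checked += 1
    assert checked > 1000


@given(
    st.tuples(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
    .filter(lambda c: sum(c) >= 2)
    .filter(lambda c: 0 < c[0] + c[1] < sum(c) and 0 < c[0] + c[2] < sum(c))
)
def test_symmetry_under_site_swap_and_allele_flip(counts):
    n11, n10, n01, n00 = counts
    res = ld_stats(counts)
    swapped = ld_stats((n11, n01, n10, n00))  # swap the two sites
    flipped = ld_stats((n00, n01, n10, n11))  # relabel both alleles
    for other in (swapped, flipped):
        assert res.r2 == pytest.approx(other.r2, abs=1e-12)
        assert res.Dprime == pytest.approx(other.Dprime, abs=1e-12)


def _panel(rows, chrom="chr1", start=100, step=1000):
    sites = [Site(f"rs{i}", chrom, start + i * step) for i in range(len(rows))]
    return HaplotypePanel(sites, np.array(rows, dtype=np.int8))


def test_one_sided_flip_r2_closed_form():
    """Flipping 6 of 60 zero-haplotypes of a freq-1/2 lead: D'=1, r2 = q(1-p)/(q+(1-q)p)."""
    n = 120
    lead = np.array([1] * 60 + [0] * 60, dtype=np.int8)
    proxy = lead.copy()
    proxy[60:66] = 1  # 6 of the 60 zeros, p = 0.1
    panel = _panel([lead, proxy])
    res = ld_stats(haplotype_counts(panel, 0, 1))
    q, p = 0.5, 0.1
    assert res.Dprime == pytest.approx(1.0)
    assert res.r2 == pytest.approx(q * (1 - p) / (q + (1 - q) * p))  # 0.81818...
    assert res.r2 == pytest.approx(9 / 11)


def test_symmetric_flip_correlation_near_one_minus_2p():
    """XOR-noise proxies: correlation ~ 1 - 2*flip_prob at allele frequency 1/2."""
    rng = np.random.default_rng(7)
    n = 10_000
    p = 0.1
    lead = (rng.random(n) < 0.5).astype(np.int8)
    noise = (rng.random(n) < p).astype(np.int8)
    proxy = lead ^ noise
    panel = _panel([lead, proxy])
    res = ld_stats(haplotype_counts(panel, 0, 1))
    r = math.copysign(math.sqrt(res.r2), res.D)
    assert r == pytest.approx(1 - 2 * p, abs=0.03)
    # and D' < 1: all four haplotype classes are populated
    assert res.Dprime < 1 - DPRIME_ONE_TOL


def test_expand_leads_strictness_window_and_lead_lead_exclusion():
    lead = np.array([1] * 6 + [0] * 6, dtype=np.int8)
    perfect = lead.copy()  # r2 = 1
    sites = [
        Site("lead_a", "chr1", 1000),
        Site("proxy", "chr1", 2000),
        Site("lead_b", "chr1", 3000),  # also in perfect LD, but itself a lead
        Site("far", "chr1", 5_000_000),  # outside the window
        Site("other_chrom", "chr2", 1000),
    ]
    panel = HaplotypePanel(sites, np.array([lead, perfect, perfect, perfect, perfect]))
    tiered = expand_leads(panel, ["lead_a", "lead_b"], window=1_000_000)
    tiers = dict(zip(tiered.variants["rsid"], tiered.variants["tier"]))
    assert tiers == {"lead_a": 1, "proxy": 2, "lead_b": 1}
    # lead-lead links are not recorded as pairs
    assert set(zip(tiered.pairs["lead_rsid"], tiered.pairs["proxy_rsid"])) == {
        ("lead_a", "proxy"),
        ("lead_b", "proxy"),
    }


def test_expand_leads_r2_threshold_is_strict():
    # Build a proxy with r2 exactly 0.6... not trivial; instead check a pair
    # whose r2 is below/at the threshold never enters.
    lead = np.array([1] * 5 + [0] * 5, dtype=np.int8)
    weak = np.array([1, 1, 1, 0, 0, 1, 1, 0, 0, 0], dtype=np.int8)  # partial LD
    panel = _panel([lead, weak])
    res = ld_stats(haplotype_counts(panel, 0, 1))
    tiered = expand_leads(panel, ["rs0"], r2_min=res.r2)  # threshold == actual r2
    assert "rs1" not in set(tiered.variants["rsid"])  # strict > excludes equality


def test_expand_leads_skips_monomorphic_and_warns_absent(caplog):
    lead = np.array([1] * 4 + [0] * 4, dtype=np.int8)
    mono = np.ones(8, dtype=np.int8)
    panel = _panel([lead, mono])
    with caplog.at_level("WARNING"):
        tiered = expand_leads(panel, ["rs0", "rs_missing"])
    assert "rs_missing" in caplog.text
    assert set(tiered.variants["rsid"]) == {"rs0"}  # monomorphic site skipped silently


def test_expand_leads_order_invariance():
    rng = np.random.default_rng(3)
    rows = (rng.random((6, 40)) < 0.5).astype(np.int8)
    panel = _panel(list(rows))
    a = expand_leads(panel, ["rs0", "rs2", "rs4"])
    b = expand_leads(panel, ["rs4", "rs0", "rs2"])
    assert a.variants.equals(b.variants)
    assert a.pairs.equals(b.pairs)


def test_panel_validation_errors():
    good = np.zeros((2, 4), dtype=np.int8)
    with pytest.raises(ValueError, match="increasing"):
        HaplotypePanel([Site("a", "chr1", 10), Site("b", "chr1", 10)], good)
    with pytest.raises(ValueError, match="duplicate"):
        HaplotypePanel([Site("a", "chr1", 10), Site("a", "chr1", 20)], good)
    with pytest.raises(ValueError, match="0/1"):
        HaplotypePanel([Site("a", "chr1", 10)], np.array([[0, 2, 1, 0]]))


def test_panel_tsv_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    rows = (rng.random((3, 10)) < 0.5).astype(np.int8)
    panel = _panel(list(rows))
    path = tmp_path / "panel.tsv"
    panel.write_tsv(path)
    back = HaplotypePanel.read_tsv(path)
    assert back.sites == panel.sites
    assert np.array_equal(back.alleles, panel.alleles)
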
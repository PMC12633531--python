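"""Strand normalization, motif counting and APOBEC enrichment tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from kataegis_storm.apobec import (
    EnrichmentResult,
    MotifCounts,
    adjust_attribution,
    apobec_enrichment_test,
    attribute_cohort,
    classify_a3,
    count_motifs,
    merge_windows,
    normalize_strand,
    revcomp,
)
from kataegis_storm.datamodel import DetectionParams, GenomeRef, SnvRecord
from kataegis_storm.detect import KataegisEvent


def hypergeom_tail_ge(a, b, c, d):
    """Oracle: P(X >= a) for the 2x2 table [[a,b],[c,d]] with fixed margins,
    by direct summation of the hypergeometric pmf."""
    row1, col1, n = a + b, a + c, a + b + c + d
    total = 0.0
    for k in range(a, min(row1, col1) + 1):
        if row1 - k > n - col1:
            continue
        total += (math.comb(col1, k) * math.comb(n - col1, row1 - k)
                  / math.comb(n, row1))
    return total


# ---------------------------------------------------------------------------
# strand normalization
# ---------------------------------------------------------------------------

def test_purine_reference_is_reverse_complemented():
    # plus strand around the site reads T G A; pyrimidine view is T C A
    g = GenomeRef.from_sequences({"chr1": "AATGACC"})
    snv = SnvRecord("s", "chr1", 4, "G", "A")
    ref, alt, window = normalize_strand(snv, g, flank=1)
    assert (ref, alt) == ("C", "T")
    assert window == "TCA"


def test_pyrimidine_reference_window_unchanged():
    g = GenomeRef.from_sequences({"chr1": "AATCACC"})
    snv = SnvRecord("s", "chr1", 4, "C", "T")
    ref, alt, window = normalize_strand(snv, g, flank=1)
    assert (ref, alt, window) == ("C", "T", "TCA")


@settings(deadline=None, derandomize=True, max_examples=100)
@given(st.text(alphabet="ACGT", min_size=1, max_size=50))
def test_reverse_complement_is_an_involution(seq):
    assert revcomp(revcomp(seq)) == seq


def test_window_truncated_at_chromosome_end():
    g = GenomeRef.from_sequences({"chr1": "ACGTA"})
    snv = SnvRecord("s", "chr1", 2, "C", "T")
    _, _, window = normalize_strand(snv, g, flank=20)
    assert window == "ACGTA"


# ---------------------------------------------------------------------------
# motif counting
# ---------------------------------------------------------------------------

def test_single_site_hand_count():
    g = GenomeRef.from_sequences({"chr1": "AATCATA"})
    snv = SnvRecord("s", "chr1", 4, "C", "T")  # context T-C-A
    counts = count_motifs([snv], g, flank=3)
    assert counts.mut_c == 1 and counts.mut_tcw == 1
    # preceding base (A) is a purine -> RTCW
    assert counts.mut_rtcw == 1 and counts.mut_ytcw == 0
    assert counts.ctx_tcw >= 1 and counts.ctx_c >= counts.ctx_tcw


def test_g_run_has_no_tcw_context():
    g = GenomeRef.from_sequences({"chr1": "GGGGGGGGG"})
    snv = SnvRecord("s", "chr1", 5, "G", "A")
    counts = count_motifs([snv], g, flank=4)
    assert counts.mut_c == 1  # G normalizes to C
    assert counts.mut_tcw == 0 and counts.ctx_tcw == 0
    assert counts.ctx_c == 9


def brute_force_context_counts(seq):
    """Independent oracle: per-position scan of both strands."""
    c = tcw = ytcw = rtcw = 0
    rc = revcomp(seq)
    for s in (seq, rc):
        for i, base in enumerate(s):
            if base != "C":
                continue
            c += 1
            if i >= 1 and i + 1 < len(s) and s[i - 1] == "T" and s[i + 1] in "AT":
                tcw += 1
                if i >= 2:
                    if s[i - 2] in "CT":
                        ytcw += 1
                    elif s[i - 2] in "AG":
                        rtcw += 1
    return c, tcw, ytcw, rtcw


def test_context_counts_match_brute_force_scan(rng):
    bases = np.array(list("ACGT"))
    seq = "".join(bases[rng.integers(0, 4, size=4000)])
    g = GenomeRef.from_sequences({"chr1": seq})
    snvs = []
    for pos in sorted(rng.choice(np.arange(30, 3970), size=50, replace=False)):
        ref = seq[pos - 1]
        alt = "ACGT".replace(ref, "")[int(rng.integers(0, 3))]
        snvs.append(SnvRecord("s", "chr1", int(pos), ref, alt))
    counts = count_motifs(snvs, g, flank=20)
    merged = merge_windows(snvs, g, 20)
    c = tcw = ytcw = rtcw = 0
    for chrom, lo, hi in merged:
        r = brute_force_context_counts(seq[lo - 1 : hi])
        c, tcw, ytcw, rtcw = c + r[0], tcw + r[1], ytcw + r[2], rtcw + r[3]
    assert (counts.ctx_c, counts.ctx_tcw) == (c, tcw)
    assert (counts.ctx_ytcw, counts.ctx_rtcw) == (ytcw, rtcw)


def test_mutated_ytcw_rtcw_partition_tcw(small_cohort):
    sample = small_cohort.samples[0]
    counts = count_motifs(sample.snvs, small_cohort.genome, flank=20)
    assert counts.mut_ytcw + counts.mut_rtcw == counts.mut_tcw
    assert counts.mut_tcw <= counts.mut_c
    assert counts.ctx_tcw <= counts.ctx_c


def test_overlapping_windows_are_merged():
    g = GenomeRef.from_sequences({"chr1": "A" * 100})
    snvs = [SnvRecord("s", "chr1", p, "A", "G") for p in (50, 55)]
    merged = merge_windows(snvs, g, 20)
    assert merged == [("chr1", 30, 75)]


# ---------------------------------------------------------------------------
# enrichment tests
# ---------------------------------------------------------------------------

def test_fisher_p_matches_hypergeometric_tail():
    ev = MotifCounts(mut_c=10, mut_tcw=9, ctx_c=100, ctx_tcw=10)
    bg = MotifCounts(mut_c=100, mut_tcw=10, ctx_c=1000, ctx_tcw=100)
    r = apobec_enrichment_test(ev, bg)
    assert r.table == ((9, 1), (10, 90))
    assert r.p == pytest.approx(hypergeom_tail_ge(9, 1, 10, 90), rel=1e-9)


def test_null_table_is_not_enriched():
    ev = MotifCounts(mut_c=20, mut_tcw=2, ctx_c=200, ctx_tcw=20)
    bg = MotifCounts(mut_c=200, mut_tcw=20, ctx_c=2000, ctx_tcw=200)
    r = apobec_enrichment_test(ev, bg)
    assert r.odds_ratio == pytest.approx(1.0)
    assert r.p > 0.5


def test_zero_cytosine_event_is_flagged():
    ev = MotifCounts(mut_c=0)
    bg = MotifCounts(mut_c=50, mut_tcw=5, ctx_c=100, ctx_tcw=10)
    r = apobec_enrichment_test(ev, bg)
    assert r.p == 1.0 and r.note == "no cytosine mutations"


def test_accessibility_factor_rescales_background():
    # event context is twice as TCW-accessible as the background's
    ev = MotifCounts(mut_c=10, mut_tcw=5, ctx_c=100, ctx_tcw=20)
    bg = MotifCounts(mut_c=100, mut_tcw=10, ctx_c=1000, ctx_tcw=100)
    r = apobec_enrichment_test(ev, bg)
    assert r.table[1][0] == 20  # 10 * (0.20 / 0.10)


def test_a3_classification_extremes():
    all_y = MotifCounts(mut_tcw=8, mut_ytcw=8, mut_rtcw=0,
                        ctx_ytcw=50, ctx_rtcw=50)
    p_a3a, p_a3b = classify_a3(all_y)
    assert p_a3a < 0.05 < p_a3b
    all_r = MotifCounts(mut_tcw=8, mut_ytcw=0, mut_rtcw=8,
                        ctx_ytcw=50, ctx_rtcw=50)
    p_a3a, p_a3b = classify_a3(all_r)
    assert p_a3b < 0.05 < p_a3a


def test_balanced_preference_is_ambiguous():
    even = MotifCounts(mut_tcw=12, mut_ytcw=6, mut_rtcw=6,
                       ctx_ytcw=50, ctx_rtcw=50)
    p_a3a, p_a3b = classify_a3(even)
    assert p_a3a > 0.5 and p_a3b > 0.5
    results = [EnrichmentResult(((6, 6), (50, 50)), 2.0, 0.001,
                                p_a3a=p_a3a, p_a3b=p_a3b)]
    events = [KataegisEvent("s", "chr1", 1, 2, 4, (0, 1, 2, 3), 1.0)]
    adjust_attribution(results, events, alpha=0.05)
    assert events[0].apobec_enriched and events[0].a3_class == "ambiguous"


def test_bh_fdr_is_monotone_and_order_invariant(rng):
    ps = rng.uniform(size=30)
    results = [EnrichmentResult(((1, 1), (1, 1)), 1.5, float(p),
                                p_a3a=1.0, p_a3b=1.0) for p in ps]
    events = [KataegisEvent("s", "chr1", i, i + 1, 4, (), 1.0)
              for i in range(30)]
    adjust_attribution(results, events)
    order = np.argsort([r.p for r in results])
    fdrs = np.array([r.fdr for r in results])[order]
    assert np.all(np.diff(fdrs) >= -1e-12)
    assert all(r.fdr >= r.p - 1e-12 for r in results)
    # permuting the events leaves each event's fdr unchanged
    perm = rng.permutation(30)
    results2 = [EnrichmentResult(((1, 1), (1, 1)), 1.5, float(ps[i]),
                                 p_a3a=1.0, p_a3b=1.0) for i in perm]
    events2 = [KataegisEvent("s", "chr1", int(i), int(i) + 1, 4, (), 1.0)
               for i in perm]
    adjust_attribution(results2, events2)
    fdr_by_p = {r.p: r.fdr for r in results}
    for r in results2:
        assert r.fdr == pytest.approx(fdr_by_p[r.p])


def test_cohort_attribution_annotates_events(small_cohort):
    params = DetectionParams()
    from kataegis_storm.detect import detect_cohort

    snvs = {s.sample_id: s.snvs for s in small_cohort.samples}
    events = detect_cohort(snvs, params, small_cohort.genome)
    attribute_cohort(events, snvs, small_cohort.genome, params)
    for evs in events.values():
        for e in evs:
            assert e.apobec_enriched is not None
            assert e.a3_class in {"A3A", "A3B", "ambiguous", "none"}
            if e.apobec_enriched:
                assert e.a3_class != "none"
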
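"""APOBEC attribution: accessibility-adjusted TCW enrichment of events and
A3A/A3B sub-attribution by the YTCW/RTCW tetranucleotide preference.

All substitution and motif counting is pyrimidine-normalized: a mutation or
motif occurrence on the minus strand is reverse-complemented so the mutated
base is always read as C.  Motifs (W = A/T, Y = C/T, R = A/G):

  TCW   T-C-W with the central C mutated
  YTCW  preceded by a pyrimidine  -> APOBEC3A preference
  RTCW  preceded by a purine      -> APOBEC3B preference

Each event is compared with the sample's non-clustered SNVs on the count of
mutated cytosines in C and TCW, with the background TCW count rescaled by the
ratio of motif accessibility (TCW-per-C in the +/-flank context windows of
event vs background sites) before the one-sided Fisher exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import DetectionParams, GenomeRef, SnvRecord
from .detect import KataegisEvent

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifCounts:
    """Mutation and context-accessibility counts for one SNV set."""

    mut_c: int = 0
    mut_tcw: int = 0
    mut_ytcw: int = 0
    mut_rtcw: int = 0
    ctx_c: int = 0
    ctx_tcw: int = 0
    ctx_ytcw: int = 0
    ctx_rtcw: int = 0
    n_dropped_n: int = 0  # contexts containing N, dropped from motif counts


@dataclass
class EnrichmentResult:
    table: Tuple[Tuple[int, int], Tuple[int, int]]
    odds_ratio: float
    p: float
    fdr: Optional[float] = None
    apobec_enriched: bool = False
    a3_class: str = "none"
    p_a3a: Optional[float] = None
    p_a3b: Optional[float] = None
    note: str = ""


# ---------------------------------------------------------------------------
# Strand normalization and motif counting
# ---------------------------------------------------------------------------

def normalize_strand(snv: SnvRecord, genome: GenomeRef,
                     flank: int = 20) -> Tuple[str, str, str]:
    """Pyrimidine-centric substitution and context window.

    If the reference base is a purine (G/A) the substitution and its window
    are reverse-complemented so ref is C or T.  The window is the +/-flank
    slice around the site, truncated at chromosome ends.
    """
    lo = max(1, snv.pos - flank)
    hi = min(genome.length(snv.chrom), snv.pos + flank)
    window = genome.sequence(snv.chrom, lo, hi)
    centre = snv.pos - lo  # index of the site within window
    ref, alt = snv.ref, snv.alt
    if ref in "GA":
        window = revcomp(window)
        centre = len(window) - 1 - centre
        ref, alt = revcomp(ref), revcomp(alt)
    # re-centre so callers can index the mutated base
    return ref, alt, window[: centre] + ref + window[centre + 1:]


def _pyr_context(snv: SnvRecord, genome: GenomeRef) -> Optional[str]:
    """Pyrimidine-normalized tetranucleotide (Y/R)-T-C-W frame around a C
    mutation: 2 bases 5' and 1 base 3' of the C, i.e. window[pos-2..pos+1]
    on the pyrimidine strand.  None near chromosome ends."""
    if snv.ref == "C":
        if snv.pos - 2 < 1 or snv.pos + 1 > genome.length(snv.chrom):
            return None
        return genome.sequence(snv.chrom, snv.pos - 2, snv.pos + 1)
    if snv.ref == "G":
        if snv.pos - 1 < 1 or snv.pos + 2 > genome.length(snv.chrom):
            return None
        return revcomp(genome.sequence(snv.chrom, snv.pos - 1, snv.pos + 2))
    return None


def merge_windows(snvs: Sequence[SnvRecord], genome: GenomeRef,
                  flank: int) -> List[Tuple[str, int, int]]:
    """Union of +/-flank windows around the SNVs (1-based inclusive)."""
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for s in snvs:
        lo = max(1, s.pos - flank)
        hi = min(genome.length(s.chrom), s.pos + flank)
        by_chrom.setdefault(s.chrom, []).append((lo, hi))
    merged = []
    for chrom in sorted(by_chrom, key=genome.order):
        ivals = sorted(by_chrom[chrom])
        cur_lo, cur_hi = ivals[0]
        for lo, hi in ivals[1:]:
            if lo <= cur_hi + 1:
                cur_hi = max(cur_hi, hi)
            else:
                merged.append((chrom, cur_lo, cur_hi))
                cur_lo, cur_hi = lo, hi
        merged.append((chrom, cur_lo, cur_hi))
    return merged


def _count_context_motifs(seq: str, counts: MotifCounts) -> None:
    """Count C / TCW / YTCW / RTCW occurrences in ``seq``, both strands,
    pyrimidine-normalized (minus-strand motifs read as their plus-strand
    reverse complements)."""
    counts.ctx_c += seq.count("C") + seq.count("G")
    n = len(seq)
    for i in range(n):
        b = seq[i]
        if b == "C":
            # plus strand: T C W  reading left to right
            if i >= 1 and i + 1 < n and seq[i - 1] == "T" and seq[i + 1] in "AT":
                counts.ctx_tcw += 1
                if i >= 2:
                    prev = seq[i - 2]
                    if prev in "CT":
                        counts.ctx_ytcw += 1
                    elif prev in "AG":
                        counts.ctx_rtcw += 1
        elif b == "G":
            # minus strand: plus-strand pattern W G A (revcomp of T C W)
            if i >= 1 and i + 1 < n and seq[i + 1] == "A" and seq[i - 1] in "AT":
                counts.ctx_tcw += 1
                if i + 2 < n:
                    nxt = seq[i + 2]  # revcomp position of the Y/R base
                    if nxt in "AG":
                        counts.ctx_ytcw += 1
                    elif nxt in "CT":
                        counts.ctx_rtcw += 1


def count_motifs(snvs: Sequence[SnvRecord], genome: GenomeRef,
                 flank: int = 20) -> MotifCounts:
    """Mutation and accessibility counts for an SNV set.

    mut_* counts pyrimidine-normalized cytosine mutations and their TCW /
    YTCW / RTCW contexts; ctx_* counts motif occurrences within the union of
    +/-flank windows (overlapping windows merged first so dense clusters do
    not double-count).  Contexts containing N are dropped and tallied.
    """
    if not snvs:
        raise ValueError("count_motifs requires a non-empty SNV set")
    counts = MotifCounts()
    for s in snvs:
        if s.ref not in "CG":
            continue
        counts.mut_c += 1
        ctx = _pyr_context(s, genome)
        if ctx is None or "N" in ctx:
            counts.n_dropped_n += 1
            continue
        # ctx = (Y/R) T C W frame: ctx[1:3] == "TC" means TCW when ctx[3] in AT
        if ctx[1] == "T" and ctx[3] in "AT":
            counts.mut_tcw += 1
            if ctx[0] in "CT":
                counts.mut_ytcw += 1
            else:
                counts.mut_rtcw += 1
    for chrom, lo, hi in merge_windows(snvs, genome, flank):
        _count_context_motifs(genome.sequence(chrom, lo, hi), counts)
    return counts


# ---------------------------------------------------------------------------
# Enrichment tests
# ---------------------------------------------------------------------------

def apobec_enrichment_test(event_counts: MotifCounts,
                           background_counts: MotifCounts) -> EnrichmentResult:
    """One-sided Fisher exact test for TCW enrichment of an event versus the
    sample's non-clustered SNVs, with the background TCW count rescaled by the
    accessibility factor

        a = (ctx_tcw_ev / ctx_c_ev) / (ctx_tcw_bg / ctx_c_bg).

    The 2x2 table is [[mut_tcw_ev, mut_c_ev - mut_tcw_ev],
    [round(mut_tcw_bg * a), mut_c_bg - round(mut_tcw_bg * a)]].  FDR and the
    enriched flag are filled in by :func:`attribute_events` across the event
    family.
    """
    ev, bg = event_counts, background_counts
    if ev.mut_c == 0:
        return EnrichmentResult(((0, 0), (bg.mut_tcw, bg.mut_c - bg.mut_tcw)),
                                odds_ratio=float("nan"), p=1.0,
                                note="no cytosine mutations")
    if bg.mut_c < 1:
        raise ValueError("background must contain at least one cytosine mutation")
    if ev.ctx_c > 0 and bg.ctx_c > 0 and bg.ctx_tcw > 0:
        a = (ev.ctx_tcw / ev.ctx_c) / (bg.ctx_tcw / bg.ctx_c)
    else:
        a = 1.0
    b_tcw = int(round(bg.mut_tcw * a))
    b_tcw = min(max(b_tcw, 0), bg.mut_c)
    table = ((ev.mut_tcw, ev.mut_c - ev.mut_tcw), (b_tcw, bg.mut_c - b_tcw))
    odds, p = stats.fisher_exact(table, alternative="greater")
    return EnrichmentResult(table, odds_ratio=float(odds), p=float(p))


def classify_a3(event_counts: MotifCounts) -> Tuple[float, float]:
    """Raw one-sided Fisher p-values for A3A (YTCW) and A3B (RTCW) preference.

    Tables compare mutated YTCW:RTCW against their context accessibility
    YTCW:RTCW; the class decision (after BH across events) is made by
    :func:`attribute_events`.
    """
    ev = event_counts
    if ev.mut_tcw == 0:
        return 1.0, 1.0
    t_a3a = ((ev.mut_ytcw, ev.mut_rtcw), (ev.ctx_ytcw, ev.ctx_rtcw))
    t_a3b = ((ev.mut_rtcw, ev.mut_ytcw), (ev.ctx_rtcw, ev.ctx_ytcw))
    _, p_a3a = stats.fisher_exact(t_a3a, alternative="greater")
    _, p_a3b = stats.fisher_exact(t_a3b, alternative="greater")
    return float(p_a3a), float(p_a3b)


def attribute_events(events: Sequence[KataegisEvent],
                     snvs: Sequence[SnvRecord],
                     genome: GenomeRef,
                     params: DetectionParams) -> List[EnrichmentResult]:
    """Enrichment-test every event of one sample against its non-clustered
    SNVs.  Raw p-values only; call :func:`adjust_attribution` on the pooled
    cohort results to fill FDRs, flags and A3 classes."""
    member = set()
    for e in events:
        member.update(e.member_indices)
    background = [s for i, s in enumerate(snvs) if i not in member]
    results = []
    if not background:
        log.warning("sample %s: no non-clustered SNVs; events untestable",
                    snvs[0].sample_id if snvs else "?")
        for e in events:
            results.append(EnrichmentResult(((0, 0), (0, 0)), float("nan"), 1.0,
                                            note="no background SNVs"))
        return results
    bg_counts = count_motifs(background, genome, params.flank)
    for e in events:
        ev_counts = count_motifs([snvs[i] for i in e.member_indices],
                                 genome, params.flank)
        if bg_counts.mut_c < 1:
            r = EnrichmentResult(((ev_counts.mut_tcw, ev_counts.mut_c - ev_counts.mut_tcw),
                                  (0, 0)), float("nan"), 1.0,
                                 note="no background cytosine mutations")
        else:
            r = apobec_enrichment_test(ev_counts, bg_counts)
        r.p_a3a, r.p_a3b = classify_a3(ev_counts)
        results.append(r)
    return results


def adjust_attribution(results: Sequence[EnrichmentResult],
                       events: Sequence[KataegisEvent],
                       alpha: float = 0.05) -> None:
    """BH-adjust the pooled enrichment p-values, set the enriched flag
    (requires odds ratio > 1), then BH-adjust the A3A/A3B families over the
    enriched events and set the a3_class of each event in place:
    exactly one significant preference -> that class; both or neither ->
    ambiguous; non-enriched -> none."""
    if not results:
        return
    ps = [r.p for r in results]
    _, fdrs, _, _ = multipletests(ps, alpha=alpha, method="fdr_bh")
    for r, f in zip(results, fdrs):
        r.fdr = float(f)
        # odds_ratio > 1 admits inf (a zero margin on the enriched side);
        # NaN (untestable event) compares False
        r.apobec_enriched = bool(f < alpha and r.odds_ratio > 1)
    enriched_idx = [i for i, r in enumerate(results) if r.apobec_enriched]
    if enriched_idx:
        fa = multipletests([results[i].p_a3a for i in enriched_idx],
                           alpha=alpha, method="fdr_bh")[1]
        fb = multipletests([results[i].p_a3b for i in enriched_idx],
                           alpha=alpha, method="fdr_bh")[1]
        for i, qa, qb in zip(enriched_idx, fa, fb):
            sig_a, sig_b = qa < alpha, qb < alpha
            if sig_a and not sig_b:
                results[i].a3_class = "A3A"
            elif sig_b and not sig_a:
                results[i].a3_class = "A3B"
            else:
                results[i].a3_class = "ambiguous"
    for e, r in zip(events, results):
        e.apobec_enriched = r.apobec_enriched
        e.a3_class = r.a3_class


def attribute_cohort(events_by_sample: Dict[str, Sequence[KataegisEvent]],
                     snvs_by_sample: Dict[str, Sequence[SnvRecord]],
                     genome: GenomeRef,
                     params: DetectionParams) -> Dict[str, List[EnrichmentResult]]:
    """Per-sample tests pooled into one BH family across all events of the run."""
    per_sample: Dict[str, List[EnrichmentResult]] = {}
    flat_results: List[EnrichmentResult] = []
    flat_events: List[KataegisEvent] = []
    for sid in sorted(events_by_sample):
        res = attribute_events(events_by_sample[sid], snvs_by_sample[sid],
                               genome, params)
        per_sample[sid] = res
        flat_results.extend(res)
        flat_events.extend(events_by_sample[sid])
    adjust_attribution(flat_results, flat_events, params.alpha)
    return per_sample
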
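"""Evolutionary timing: assign SNVs to clonal/subclonal epochs and refine
kataegis events into per-epoch "evolutionary kataegis".

Epoch rules (multiplicity-based timing):
  * CCF below the clonal threshold  -> subclonal
  * clonal + locus gained (major_cn >= 2) + multiplicity >= 2 -> clonal_early
  * clonal + gained + multiplicity 1 -> clonal_late
  * clonal + copy-neutral locus -> clonal_unspecified (CN carries no timing)
Missing CCF or multiplicity -> unknown (excluded from proportions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CLONAL_EPOCHS, CnSegment, DetectionParams, SnvRecord
from .detect import KataegisEvent

log = logging.getLogger(__name__)

EPOCH_ORDER = ("clonal_early", "clonal_late", "clonal_unspecified", "subclonal")


@dataclass
class EvoKataegisEvent:
    """An epoch-homogeneous subset of a parent event that re-passes the
    detection criteria."""

    parent_index: int
    sample_id: str
    chrom: str
    epoch: str
    member_positions: Tuple[int, ...]
    n_snv: int


def assign_epoch(ccf: Optional[float], multiplicity: Optional[int],
                 major_cn: int, minor_cn: int,
                 clonal_ccf_threshold: float = 0.9) -> str:
    if ccf is None or multiplicity is None:
        return "unknown"
    if ccf < clonal_ccf_threshold:
        return "subclonal"
    gained = major_cn >= 2
    if gained and multiplicity >= 2:
        return "clonal_early"
    if gained and multiplicity == 1:
        return "clonal_late"
    return "clonal_unspecified"


def estimate_multiplicity(vaf: float, purity: float, cn_total: int) -> int:
    """Multiplicity from VAF when no annotation is given:
    round(vaf * (purity * CN_total + 2 * (1 - purity)) / purity), floor 1."""
    if not (0 < purity <= 1):
        raise ValueError("purity must be in (0, 1]")
    return max(1, round(vaf * (purity * cn_total + 2 * (1 - purity)) / purity))


def annotate_epochs(snvs: Sequence[SnvRecord], segments: Sequence[CnSegment],
                    clonal_ccf_threshold: float = 0.9) -> int:
    """Set ``epoch`` in place on each SNV from its overlapping CN segment.

    Returns the number of SNVs left 'unknown' (missing annotations or no
    overlapping segment).
    """
    by_chrom: Dict[str, List[CnSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for segs in by_chrom.values():
        segs.sort(key=lambda s: s.start)
    n_unknown = 0
    for s in snvs:
        seg = _overlapping(by_chrom.get(s.chrom, ()), s.pos)
        if seg is None:
            s.epoch = "unknown"
            n_unknown += 1
            continue
        s.epoch = assign_epoch(s.ccf, s.multiplicity, seg.major_cn, seg.minor_cn,
                               clonal_ccf_threshold)
        if s.epoch == "unknown":
            n_unknown += 1
    if n_unknown:
        log.info("annotate_epochs: %d SNVs without usable timing annotations", n_unknown)
    return n_unknown


def _overlapping(segs: Sequence[CnSegment], pos: int) -> Optional[CnSegment]:
    lo, hi = 0, len(segs) - 1
    while lo <= hi:
        mid = (lo + hi) // 2
        s = segs[mid]
        if pos < s.start:
            hi = mid - 1
        elif pos > s.end:
            lo = mid + 1
        else:
            return s
    return None


def refine_events(event: KataegisEvent, snvs: Sequence[SnvRecord],
                  params: DetectionParams,
                  parent_index: int = 0) -> List[EvoKataegisEvent]:
    """Split one event into per-epoch subsets and re-test each subset.

    A subset passes when it has at least ``kmin`` members and all successive
    within-subset distances are below ``d_max`` (raw distances; PCF is not
    re-run on event-sized subsets).  Members with epoch 'unknown' never form
    evolutionary events.  The union of returned members never exceeds the
    parent's members and subsets are disjoint by construction.
    """
    members = [snvs[i] for i in event.member_indices]
    groups: Dict[str, List[int]] = {}
    for m in members:
        epoch = m.epoch or "unknown"
        groups.setdefault(epoch, []).append(m.pos)
    out: List[EvoKataegisEvent] = []
    for epoch in EPOCH_ORDER:
        pos = sorted(groups.get(epoch, ()))
        if len(pos) < params.kmin:
            continue
        if any(b - a >= params.d_max for a, b in zip(pos, pos[1:])):
            continue
        out.append(EvoKataegisEvent(
            parent_index=parent_index, sample_id=event.sample_id,
            chrom=event.chrom, epoch=epoch,
            member_positions=tuple(pos), n_snv=len(pos),
        ))
    return out


def refine_cohort(events_by_sample: Dict[str, Sequence[KataegisEvent]],
                  snvs_by_sample: Dict[str, Sequence[SnvRecord]],
                  params: DetectionParams) -> Dict[str, List[EvoKataegisEvent]]:
    out: Dict[str, List[EvoKataegisEvent]] = {}
    for sid in sorted(events_by_sample):
        evo: List[EvoKataegisEvent] = []
        for i, ev in enumerate(events_by_sample[sid]):
            evo.extend(refine_events(ev, snvs_by_sample[sid], params, parent_index=i))
        out[sid] = evo
    return out


def event_epoch_label(event: KataegisEvent, snvs: Sequence[SnvRecord]) -> str:
    """Majority epoch among members (ties to the earlier epoch in the clonal ->
    subclonal order); 'unknown' when no member is timed."""
    counts: Dict[str, int] = {}
    for i in event.member_indices:
        e = snvs[i].epoch or "unknown"
        if e != "unknown":
            counts[e] = counts.get(e, 0) + 1
    if not counts:
        return "unknown"
    return max(EPOCH_ORDER, key=lambda e: (counts.get(e, 0), -EPOCH_ORDER.index(e)))


def epoch_proportions(events_by_sample: Dict[str, Sequence[KataegisEvent]],
                      snvs_by_sample: Dict[str, Sequence[SnvRecord]]):
    """Per-sample clonal fractions of kataegic vs genome-wide SNVs.

    Returns (DataFrame, result dict) where the dict holds the group medians
    and the paired two-sided Wilcoxon signed-rank p-value over samples with at
    least one kataegis event.  SNVs with epoch 'unknown' are excluded from
    both denominators.
    """
    rows = []
    for sid in sorted(snvs_by_sample):
        snvs = snvs_by_sample[sid]
        events = events_by_sample.get(sid, ())
        member = set()
        for e in events:
            member.update(e.member_indices)
        kat = [snvs[i].epoch for i in member]
        allv = [s.epoch for s in snvs]
        kat_frac = _clonal_fraction(kat)
        all_frac = _clonal_fraction(allv)
        rows.append({
            "sample_id": sid, "n_events": len(events),
            "kataegis_clonal_frac": kat_frac, "genome_clonal_frac": all_frac,
        })
    df = pd.DataFrame(rows)
    paired = df[(df.n_events > 0) & df.kataegis_clonal_frac.notna()
                & df.genome_clonal_frac.notna()]
    res = {
        "median_kataegis_clonal_frac": float(paired.kataegis_clonal_frac.median())
        if len(paired) else float("nan"),
        "median_genome_clonal_frac": float(paired.genome_clonal_frac.median())
        if len(paired) else float("nan"),
        "n_paired": int(len(paired)),
    }
    diffs = (paired.kataegis_clonal_frac - paired.genome_clonal_frac).to_numpy()
    if len(diffs) == 0 or np.allclose(diffs, 0):
        res["p_wilcoxon"] = 1.0  # degenerate all-tied case
    else:
        res["p_wilcoxon"] = float(stats.wilcoxon(
            paired.kataegis_clonal_frac, paired.genome_clonal_frac,
            zero_method="wilcox", alternative="two-sided").pvalue)
    return df, res


def _clonal_fraction(epochs) -> float:
    timed = [e for e in epochs if e is not None and e != "unknown"]
    if not timed:
        return float("nan")
    return sum(e in CLONAL_EPOCHS for e in timed) / len(timed)
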
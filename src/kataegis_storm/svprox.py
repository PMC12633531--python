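"""Kataegis / structural-variant proximity: distances to breakpoints, the
pseudo-event simulation null, log-spaced-bin rank tests, and SV-associated vs
SV-independent classification.

For each event the null is 1,000 pseudo events with the same interval length,
centred on non-clustered SNVs drawn with replacement from the same sample.
Per patient group, simulation replicate j pools the j-th pseudo interval of
every event; per distance bin the empirical rank p-values are

    p_enrich = (1 + #{j : sim_j >= obs}) / (n_sim + 1)
    p_sparse = (1 + #{j : sim_j <= obs}) / (n_sim + 1)

BH-adjusted across bins x groups per direction.  Events in enriched bins are
SV-associated, in sparse bins SV-independent, else unclassified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import BEYOND, DetectionParams, GenomeRef, SnvRecord, SvBreakpoint
from .detect import KataegisEvent

log = logging.getLogger(__name__)


@dataclass
class ProximityNull:
    """Observed vs simulated distance-bin counts for one patient group."""

    group_id: str
    bin_edges: Tuple[float, ...]
    observed_counts: np.ndarray  # (n_bins,)
    sim_counts: np.ndarray  # (n_sim, n_bins)
    p_enrich: np.ndarray
    p_sparse: np.ndarray
    fdr_enrich: Optional[np.ndarray] = None
    fdr_sparse: Optional[np.ndarray] = None
    bin_class: Optional[List[str]] = None


def breakpoint_index(breakpoints: Sequence[SvBreakpoint]) -> Dict[str, np.ndarray]:
    """Sorted breakend positions per chromosome (TRA mates count at each locus)."""
    by_chrom: Dict[str, List[int]] = {}
    for b in breakpoints:
        by_chrom.setdefault(b.chrom, []).append(b.pos)
    return {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in by_chrom.items()}


def interval_bp_distance(starts: np.ndarray, ends: np.ndarray,
                         sorted_bps: np.ndarray) -> np.ndarray:
    """Distance from each interval [start, end] to the nearest breakpoint:
    0 when a breakpoint lies inside, else the gap to the nearer edge;
    inf when the array is empty."""
    starts = np.atleast_1d(np.asarray(starts, dtype=np.int64))
    ends = np.atleast_1d(np.asarray(ends, dtype=np.int64))
    if sorted_bps.size == 0:
        return np.full(starts.shape, BEYOND)
    idx = np.searchsorted(sorted_bps, starts)
    left = np.where(idx > 0, starts - sorted_bps.take(np.maximum(idx - 1, 0)), np.inf)
    right_idx = np.minimum(idx, sorted_bps.size - 1)
    right_bp = sorted_bps.take(right_idx)
    inside = (idx < sorted_bps.size) & (right_bp <= ends)
    right = np.where(idx < sorted_bps.size, np.maximum(right_bp - ends, 0), np.inf)
    d = np.minimum(left, right)
    d[inside] = 0.0
    return d


def event_sv_distance(event: KataegisEvent,
                      bp_index: Dict[str, np.ndarray]) -> float:
    """0 if a breakpoint falls within the event, else the minimum gap to the
    nearer event edge over same-chromosome breakpoints; BEYOND (inf) when the
    chromosome carries no breakpoint."""
    bps = bp_index.get(event.chrom, np.empty(0, dtype=np.int64))
    return float(interval_bp_distance(
        np.array([event.start]), np.array([event.end]), bps)[0])


def simulate_pseudo_events(event: KataegisEvent,
                           non_clustered: Sequence[SnvRecord],
                           n_sim: int,
                           genome: GenomeRef,
                           rng: np.random.Generator):
    """n_sim pseudo intervals with the event's span, centred on non-clustered
    SNVs drawn with replacement, clipped to the drawn SNV's chromosome.

    Returns (chroms, starts, ends) arrays of length n_sim, or None when the
    sample has no non-clustered SNVs (event excluded from simulation).
    """
    if not non_clustered:
        log.warning("sample %s: no non-clustered SNVs, event %s:%d excluded "
                    "from simulation", event.sample_id, event.chrom, event.start)
        return None
    span = event.span
    picks = rng.integers(0, len(non_clustered), size=n_sim)
    chroms = np.array([non_clustered[i].chrom for i in picks])
    centres = np.array([non_clustered[i].pos for i in picks], dtype=np.int64)
    starts = centres - span // 2
    ends = starts + span
    lengths = np.array([genome.length(c) for c in chroms], dtype=np.int64)
    shift_lo = np.maximum(1 - starts, 0)
    starts += shift_lo
    ends += shift_lo
    shift_hi = np.maximum(ends - lengths, 0)
    starts -= shift_hi
    ends -= shift_hi
    starts = np.maximum(starts, 1)  # span longer than chromosome: clip
    return chroms, starts, ends


def bin_distances(distances: Sequence[float],
                  edges: Sequence[float]) -> np.ndarray:
    """Histogram with half-open bins [edge_i, edge_{i+1}); BEYOND and any
    distance past the last finite edge fall in the final bin."""
    edges = np.asarray(edges, dtype=float)
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("negative distance")
    idx = np.searchsorted(edges, d, side="right") - 1
    idx = np.clip(idx, 0, len(edges) - 2)
    return np.bincount(idx, minlength=len(edges) - 1)


def proximity_test(observed_distances: Sequence[float],
                   pseudo_distances: np.ndarray,
                   edges: Sequence[float],
                   group_id: str = "all") -> ProximityNull:
    """Rank-based enrichment/sparsity p-values per distance bin.

    ``pseudo_distances`` has shape (n_events, n_sim): row i holds the pseudo
    distances of event i; replicate j pools column j over events.
    """
    n_bins = len(edges) - 1
    obs = bin_distances(observed_distances, edges)
    pseudo = np.asarray(pseudo_distances, dtype=float)
    n_sim = pseudo.shape[1]
    edges_arr = np.asarray(edges, dtype=float)
    idx = np.searchsorted(edges_arr, pseudo, side="right") - 1
    idx = np.clip(idx, 0, n_bins - 1)
    sim = np.zeros((n_sim, n_bins), dtype=np.int64)
    for b in range(n_bins):
        sim[:, b] = (idx == b).sum(axis=0)
    p_enrich = (1 + (sim >= obs[None, :]).sum(axis=0)) / (n_sim + 1)
    p_sparse = (1 + (sim <= obs[None, :]).sum(axis=0)) / (n_sim + 1)
    return ProximityNull(group_id, tuple(edges), obs, sim,
                         p_enrich.astype(float), p_sparse.astype(float))


def adjust_proximity(nulls: Sequence[ProximityNull], alpha: float = 0.05) -> None:
    """BH across bins x groups per direction; classify each bin.  When a bin
    is significant in both directions, enrichment wins and a warning is
    logged."""
    if not nulls:
        return
    pe = np.concatenate([n.p_enrich for n in nulls])
    psp = np.concatenate([n.p_sparse for n in nulls])
    fe = multipletests(pe, alpha=alpha, method="fdr_bh")[1]
    fs = multipletests(psp, alpha=alpha, method="fdr_bh")[1]
    off = 0
    for n in nulls:
        k = len(n.p_enrich)
        n.fdr_enrich = fe[off : off + k]
        n.fdr_sparse = fs[off : off + k]
        n.bin_class = []
        for qe, qs in zip(n.fdr_enrich, n.fdr_sparse):
            if qe < alpha and qs < alpha:
                log.warning("group %s: bin significant in both directions; "
                            "classified enriched", n.group_id)
                n.bin_class.append("enriched")
            elif qe < alpha:
                n.bin_class.append("enriched")
            elif qs < alpha:
                n.bin_class.append("sparse")
            else:
                n.bin_class.append("neither")
        off += k


def classify_events_by_bin(events: Sequence[KataegisEvent],
                           distances: Sequence[float],
                           null: ProximityNull) -> None:
    """Set sv_class in place: enriched bin -> SV_associated, sparse bin ->
    SV_independent, else unclassified."""
    if null.bin_class is None:
        raise ValueError("run adjust_proximity before classifying events")
    edges = np.asarray(null.bin_edges, dtype=float)
    for e, d in zip(events, distances):
        b = int(np.clip(np.searchsorted(edges, d, side="right") - 1,
                        0, len(edges) - 2))
        cls = null.bin_class[b]
        e.sv_distance = d
        e.sv_class = {"enriched": "SV_associated",
                      "sparse": "SV_independent"}.get(cls, "unclassified")


def run_proximity_analysis(events_by_sample: Dict[str, Sequence[KataegisEvent]],
                           snvs_by_sample: Dict[str, Sequence[SnvRecord]],
                           breakpoints_by_sample: Dict[str, Sequence[SvBreakpoint]],
                           genome: GenomeRef,
                           params: DetectionParams,
                           rng: np.random.Generator,
                           group_of: Optional[Dict[str, str]] = None,
                           ) -> Dict[str, ProximityNull]:
    """Full SV-proximity stage over a cohort.

    ``group_of`` maps sample -> patient group (ancestry x risk); a single
    'all' group is used when omitted.  Events and their sv_distance/sv_class
    fields are annotated in place.  Events of samples with no non-clustered
    SNVs are excluded from the null (logged).
    """
    edges = params.distance_bin_edges
    per_group_obs: Dict[str, List[float]] = {}
    per_group_pseudo: Dict[str, List[np.ndarray]] = {}
    per_group_events: Dict[str, List[KataegisEvent]] = {}
    for sid in sorted(events_by_sample):
        events = events_by_sample[sid]
        if not events:
            continue
        group = (group_of or {}).get(sid, "all")
        snvs = snvs_by_sample[sid]
        member = set()
        for e in events:
            member.update(e.member_indices)
        non_clustered = [s for i, s in enumerate(snvs) if i not in member]
        bp_idx = breakpoint_index(breakpoints_by_sample.get(sid, ()))
        for e in events:
            pseudo = simulate_pseudo_events(e, non_clustered, params.n_sim,
                                            genome, rng)
            if pseudo is None:
                e.sv_distance = event_sv_distance(e, bp_idx)
                e.sv_class = "unclassified"
                continue
            chroms, starts, ends = pseudo
            pd_dist = np.full(params.n_sim, BEYOND)
            for c in np.unique(chroms):
                mask = chroms == c
                bps = bp_idx.get(str(c), np.empty(0, dtype=np.int64))
                pd_dist[mask] = interval_bp_distance(starts[mask], ends[mask], bps)
            per_group_obs.setdefault(group, []).append(event_sv_distance(e, bp_idx))
            per_group_pseudo.setdefault(group, []).append(pd_dist)
            per_group_events.setdefault(group, []).append(e)
    nulls: Dict[str, ProximityNull] = {}
    for group in sorted(per_group_obs):
        nulls[group] = proximity_test(
            per_group_obs[group], np.vstack(per_group_pseudo[group]),
            edges, group_id=group)
    adjust_proximity(list(nulls.values()), params.alpha)
    for group, null in nulls.items():
        classify_events_by_bin(per_group_events[group],
                               per_group_obs[group], null)
    return nulls


def sv_type_proximity(events_by_sample: Dict[str, Sequence[KataegisEvent]],
                      breakpoints_by_sample: Dict[str, Sequence[SvBreakpoint]],
                      window: float = 10_000.0,
                      alpha: float = 0.05):
    """Per-SV-type two-sided Fisher test: (within `window` of any event vs
    not) x (this type vs others), pooled over samples, BH across types.
    Chromothripsis-flagged breakends are tested as their own pseudo-type.

    Returns a list of dicts with type, table, odds ratio, p, fdr, direction.
    """
    counts: Dict[str, List[int]] = {}  # type -> [near, far]
    for sid, breakpoints in breakpoints_by_sample.items():
        events = [e for e in events_by_sample.get(sid, ())]
        ev_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for e in events:
            ev_by_chrom.setdefault(e.chrom, []).append((e.start, e.end))
        for b in breakpoints:
            near = any(s - window <= b.pos <= t + window
                       for s, t in ev_by_chrom.get(b.chrom, ()))
            labels = [b.sv_class]
            if b.chromothripsis_flag:
                labels.append("chromothripsis")
            for lab in labels:
                c = counts.setdefault(lab, [0, 0])
                c[0 if near else 1] += 1
    total_near = sum(c[0] for k, c in counts.items() if k != "chromothripsis")
    total_far = sum(c[1] for k, c in counts.items() if k != "chromothripsis")
    results = []
    for lab in sorted(counts):
        near, far = counts[lab]
        # chromothripsis overlaps the base classes; its complement is the rest
        table = ((near, far), (max(total_near - near, 0), max(total_far - far, 0)))
        if near + far == 0:
            continue
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        exp_near = (near + far) * total_near / max(total_near + total_far, 1)
        results.append({"sv_type": lab, "table": table,
                        "odds_ratio": float(odds), "p": float(p),
                        "direction": "enriched" if near > exp_near else "depleted"})
    if results:
        fdrs = multipletests([r["p"] for r in results], alpha=alpha,
                             method="fdr_bh")[1]
        for r, q in zip(results, fdrs):
            r["fdr"] = float(q)
    return results
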
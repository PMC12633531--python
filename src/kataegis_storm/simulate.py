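"""Synthetic tumour-cohort generator with full truth labels.

Emulates the statistical structure of a WGS somatic call set at desk scale:
a random reference genome; background SNVs at ~1/Mb; planted kataegis events
(>= 4 member SNVs over ~kb spans) with strand-coordinated APOBEC TCW bias
realised at actual TCW occurrences of the reference; SV breakend pairs with a
configurable kataegis-coupling fraction and distance; a two-state CCF
clonal/subclonal architecture with whole-chromosome copy-number segments; and
a clinical table.  Everything is deterministic under the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .datamodel import (
    ClinicalRecord,
    CnSegment,
    GenomeRef,
    SnvRecord,
    SvBreakpoint,
)

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions of the synthetic cohort (defaults are the conditions
    every test and the acceptance run use)."""

    n_samples: int = 20
    chrom_lengths: Tuple[int, ...] = (50_000_000, 50_000_000, 50_000_000)
    background_rate: float = 1.0  # SNVs per Mb
    kataegis_prevalence: float = 0.4
    # events per positive sample: 1 + Geometric(p), capped (median 2, max 13)
    events_geom_p: float = 0.3
    max_events: int = 13
    # SNVs per event: min + Geometric(p), capped (median 6)
    min_snvs_per_event: int = 4
    snvs_geom_p: float = 0.25
    max_snvs_per_event: int = 25
    # member gaps: uniform in [gap_min, gap_max] bp, so every planted event
    # satisfies the sub-kb consecutive-distance property that defines
    # kataegis; median span ~ 2.5 kb at the median 6 members
    gap_min: int = 100
    gap_max: int = 900
    apobec_omega: float = 0.9  # fraction of members planted at TCW sites
    strand_coordination: float = 0.9
    n_svs: int = 60  # breakend pairs per sample
    coupling_rho: float = 0.55  # fraction of events anchored near a breakpoint
    coupling_d: int = 10_000
    # coupled anchor offset |N(log 2 kb, 0.45)| lognormal, so spanning / <1 kb /
    # <10 kb event fractions echo observed tumour cohorts (~13/40/50%)
    coupled_offset_log_median: float = math.log(2000.0)
    coupled_offset_log_sd: float = 0.45
    clonal_fraction: float = 0.68  # genome-wide SNVs
    event_clonal_fraction: float = 0.65  # planted events
    subclonal_ccf: float = 0.4
    ccf_noise_sd: float = 0.05
    purity: float = 0.7
    gained_fraction: float = 1 / 3  # chromosomes carrying a 2+1 gain
    early_fraction: float = 0.5  # clonal SNVs on gained chromosomes at mult 2
    ancestry_mix: Tuple[Tuple[str, float], ...] = (("AFR", 0.5), ("EUR", 0.5))
    hr_fraction: float = 0.6
    sv_class_weights: Tuple[Tuple[str, float], ...] = (
        ("DEL", 0.3), ("DUP", 0.2), ("INV", 0.2), ("TRA", 0.3))
    chromothripsis_fraction: float = 0.1
    min_event_separation: int = 10_000  # >= 10 x d_max between truth events
    seed: int = 0

    @property
    def chrom_names(self) -> Tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(len(self.chrom_lengths)))


@dataclass
class TruthEvent:
    sample_id: str
    chrom: str
    start: int
    end: int
    positions: Tuple[int, ...]
    epoch: str
    apobec_flag: bool
    coupled_flag: bool


@dataclass
class SampleData:
    sample_id: str
    snvs: List[SnvRecord]
    breakpoints: List[SvBreakpoint]
    cn_segments: List[CnSegment]
    clinical: ClinicalRecord
    purity: float
    truth_events: List[TruthEvent]
    snv_clonality: Dict[int, str] = field(default_factory=dict)  # idx -> clonal/subclonal


@dataclass
class Cohort:
    config: SimConfig
    genome: GenomeRef
    samples: List[SampleData]

    @property
    def truth_events(self) -> List[TruthEvent]:
        return [t for s in self.samples for t in s.truth_events]


# ---------------------------------------------------------------------------
# Reference
# ---------------------------------------------------------------------------

def generate_reference(config: SimConfig, rng: np.random.Generator) -> GenomeRef:
    """I.i.d. uniform ACGT sequence per chromosome, deterministic under seed."""
    sequences = {}
    for name, length in zip(config.chrom_names, config.chrom_lengths):
        if length <= 0:
            raise ValueError("chromosome lengths must be positive")
        idx = rng.integers(0, 4, size=length, dtype=np.uint8)
        sequences[name] = _BASE_ARR[idx].tobytes().decode("ascii")
    return GenomeRef.from_sequences(sequences)


# ---------------------------------------------------------------------------
# Helpers shared with module-level tests
# ---------------------------------------------------------------------------

def sample_truncated_geometric(rng, p: float, minimum: int, maximum: int) -> int:
    return int(min(minimum + rng.geometric(p) - 1, maximum))


def sample_event_geometry(config: SimConfig, rng) -> Tuple[int, np.ndarray]:
    """(n_members, member gaps) of one planted event."""
    n = sample_truncated_geometric(rng, config.snvs_geom_p,
                                   config.min_snvs_per_event,
                                   config.max_snvs_per_event)
    gaps = rng.integers(config.gap_min, config.gap_max + 1, size=n - 1)
    return n, gaps


def sample_uniform_positions(rng, chrom_lengths: Sequence[int], n: int
                             ) -> List[Tuple[int, int]]:
    """n positions uniform over the concatenated genome -> (chrom_idx, pos)."""
    lengths = np.asarray(chrom_lengths, dtype=np.int64)
    cum = np.cumsum(lengths)
    flat = rng.integers(0, cum[-1], size=n)
    chrom_idx = np.searchsorted(cum, flat, side="right")
    offset = flat - np.concatenate(([0], cum[:-1]))[chrom_idx]
    return [(int(c), int(o) + 1) for c, o in zip(chrom_idx, offset)]


def _tcw_sites(seq: str, lo_pos: int) -> List[Tuple[int, str]]:
    """(1-based genomic position, strand) of every TCW central C in ``seq``
    (plus strand) or G (TCW on the minus strand).  ``lo_pos`` is the genomic
    position of seq[0]."""
    sites = []
    for i in range(1, len(seq) - 1):
        if seq[i] == "C" and seq[i - 1] == "T" and seq[i + 1] in "AT":
            sites.append((lo_pos + i, "+"))
        elif seq[i] == "G" and seq[i + 1] == "A" and seq[i - 1] in "AT":
            sites.append((lo_pos + i, "-"))
    return sites


# ---------------------------------------------------------------------------
# Per-sample generation
# ---------------------------------------------------------------------------

def generate_sample(config: SimConfig, genome: GenomeRef, sample_id: str,
                    rng: np.random.Generator) -> SampleData:
    chrom_names = list(genome.chrom_names)
    chrom_lengths = [genome.length(c) for c in chrom_names]
    max_span = (config.max_snvs_per_event - 1) * config.gap_max
    if max_span >= min(chrom_lengths):
        raise ValueError("event span exceeds chromosome length; infeasible config")

    gained = rng.random(len(chrom_names)) < config.gained_fraction
    cn_segments = [
        CnSegment(sample_id, c, 1, L, 2 if g else 1, 1)
        for c, L, g in zip(chrom_names, chrom_lengths, gained)
    ]
    gained_by_chrom = dict(zip(chrom_names, gained))

    breakpoints = _generate_svs(config, genome, sample_id, rng)

    # background SNVs
    n_bg = rng.poisson(config.background_rate * sum(chrom_lengths) / 1e6)
    taken: Dict[str, set] = {c: set() for c in chrom_names}
    snvs: List[SnvRecord] = []
    for ci, pos in sample_uniform_positions(rng, chrom_lengths, n_bg):
        chrom = chrom_names[ci]
        if pos in taken[chrom]:
            continue
        taken[chrom].add(pos)
        ref = genome.sequence(chrom, pos, pos)
        if ref == "N":
            continue
        alt = _random_alt(ref, rng)
        snvs.append(_timed_snv(sample_id, chrom, pos, ref, alt,
                               clonal=rng.random() < config.clonal_fraction,
                               gained=gained_by_chrom[chrom],
                               config=config, rng=rng))

    # planted kataegis events
    truth_events: List[TruthEvent] = []
    if rng.random() < config.kataegis_prevalence:
        n_events = sample_truncated_geometric(
            rng, config.events_geom_p, 1, config.max_events)
        placed: List[Tuple[str, int, int]] = []
        for _ in range(n_events):
            ev = _plant_event(config, genome, sample_id, rng, breakpoints,
                              placed, gained_by_chrom, taken)
            if ev is None:
                continue
            truth, members = ev
            truth_events.append(truth)
            placed.append((truth.chrom, truth.start, truth.end))
            snvs.extend(members)

    snvs.sort(key=lambda s: (genome.order(s.chrom), s.pos))
    clinical = _generate_clinical(config, sample_id, rng,
                                  positive=len(truth_events) > 0)
    return SampleData(sample_id, snvs, breakpoints, cn_segments, clinical,
                      config.purity, truth_events)


def _random_alt(ref: str, rng) -> str:
    return "ACGT".replace(ref, "")[rng.integers(0, 3)]


def _timed_snv(sample_id, chrom, pos, ref, alt, clonal, gained, config, rng,
               epoch_override: Optional[str] = None) -> SnvRecord:
    if epoch_override is not None:
        epoch = epoch_override
        clonal = epoch != "subclonal"
    elif clonal:
        if gained:
            epoch = "clonal_early" if rng.random() < config.early_fraction \
                else "clonal_late"
        else:
            epoch = "clonal_unspecified"
    else:
        epoch = "subclonal"
    truth_ccf = 1.0 if clonal else config.subclonal_ccf
    ccf = float(np.clip(truth_ccf + rng.normal(0, config.ccf_noise_sd),
                        1e-6, 1.0))
    mult = 2 if epoch == "clonal_early" else 1
    return SnvRecord(sample_id, chrom, pos, ref, alt, ccf=ccf,
                     multiplicity=mult, epoch=None)


def _generate_svs(config, genome, sample_id, rng) -> List[SvBreakpoint]:
    chrom_names = list(genome.chrom_names)
    chrom_lengths = [genome.length(c) for c in chrom_names]
    classes = [c for c, _ in config.sv_class_weights]
    weights = np.array([w for _, w in config.sv_class_weights], dtype=float)
    weights /= weights.sum()
    breakends: List[SvBreakpoint] = []
    for _ in range(config.n_svs):
        sv_class = classes[rng.choice(len(classes), p=weights)]
        ct = bool(rng.random() < config.chromothripsis_fraction)
        if sv_class == "TRA" and len(chrom_names) > 1:
            ci, cj = rng.choice(len(chrom_names), size=2, replace=False)
            p1 = int(rng.integers(1, chrom_lengths[ci] + 1))
            p2 = int(rng.integers(1, chrom_lengths[cj] + 1))
            c1, c2 = chrom_names[ci], chrom_names[cj]
        else:
            if sv_class == "TRA":
                sv_class = "INV"  # single-chromosome genome cannot host a TRA
            ci = int(rng.choice(len(chrom_names),
                                p=np.asarray(chrom_lengths) / sum(chrom_lengths)))
            c1 = c2 = chrom_names[ci]
            size = int(np.clip(rng.lognormal(math.log(1e5), 1.0), 50,
                               chrom_lengths[ci] - 2))
            p1 = int(rng.integers(1, chrom_lengths[ci] - size))
            p2 = p1 + size
        breakends.append(SvBreakpoint(sample_id, c1, p1, sv_class, ct, mate=(c2, p2)))
        breakends.append(SvBreakpoint(sample_id, c2, p2, sv_class, ct, mate=(c1, p1)))
    return breakends


def _plant_event(config, genome, sample_id, rng, breakpoints, placed,
                 gained_by_chrom, taken):
    chrom_names = list(genome.chrom_names)
    chrom_lengths = [genome.length(c) for c in chrom_names]
    n_members, gaps = sample_event_geometry(config, rng)
    span = int(gaps.sum())
    coupled = bool(rng.random() < config.coupling_rho) and len(breakpoints) > 0

    for _attempt in range(50):
        if coupled:
            bp = breakpoints[rng.integers(0, len(breakpoints))]
            offset = rng.lognormal(config.coupled_offset_log_median,
                                   config.coupled_offset_log_sd)
            offset = min(offset, config.coupling_d) * (1 if rng.random() < 0.5 else -1)
            chrom = bp.chrom
            anchor = int(bp.pos + offset)
        else:
            (ci, anchor), = sample_uniform_positions(rng, chrom_lengths, 1)
            chrom = chrom_names[ci]
        start = anchor - span // 2
        end = start + span
        if start < 1 or end > genome.length(chrom):
            continue
        sep = config.min_event_separation
        if any(c == chrom and start - sep <= e and s <= end + sep
               for c, s, e in placed):
            continue
        members = _plant_members(config, genome, chrom, start, gaps,
                                 rng, taken[chrom])
        if members is None:
            continue
        epoch = _event_epoch(config, gained_by_chrom[chrom], rng)
        snvs = [_timed_snv(sample_id, chrom, pos, ref, alt, clonal=None,
                           gained=gained_by_chrom[chrom], config=config,
                           rng=rng, epoch_override=epoch)
                for pos, ref, alt in members]
        positions = tuple(sorted(p for p, _, _ in members))
        return TruthEvent(sample_id, chrom, positions[0], positions[-1],
                          positions, epoch, config.apobec_omega > 0,
                          coupled), snvs
    return None


def _event_epoch(config, gained: bool, rng) -> str:
    if rng.random() >= config.event_clonal_fraction:
        return "subclonal"
    if gained:
        return "clonal_early" if rng.random() < config.early_fraction \
            else "clonal_late"
    return "clonal_unspecified"


def _plant_members(config, genome, chrom, start, gaps,
                   rng, taken) -> Optional[List[Tuple[int, str, str]]]:
    """Member (pos, ref, alt) triples at ``start + cumsum(gaps)``; with
    probability apobec_omega a member snaps to the nearest TCW occurrence of
    the chosen strand within +/- half the minimum gap (so every consecutive
    distance stays below d_max), and mutates C>T or C>G on the pyrimidine
    strand.  Non-targeted members take a uniform substitution in place."""
    ideal = start + np.concatenate(([0], np.cumsum(gaps)))
    margin = max(config.gap_min // 2 - 1, 5)
    lo = max(1, int(ideal[0]) - margin - 2)
    hi = min(genome.length(chrom), int(ideal[-1]) + margin + 2)
    window = genome.sequence(chrom, lo, hi)
    sites = _tcw_sites(window, lo)
    plus_pos = np.array([p for p, st in sites if st == "+"], dtype=np.int64)
    minus_pos = np.array([p for p, st in sites if st == "-"], dtype=np.int64)
    event_strand = "+" if rng.random() < 0.5 else "-"
    members: Dict[int, Tuple[str, str]] = {}
    for p in ideal:
        p = int(p)
        pos = None
        if rng.random() < config.apobec_omega:
            strand = event_strand if rng.random() < config.strand_coordination \
                else ("+" if rng.random() < 0.5 else "-")
            # prefer the chosen strand's sites; fall back to the opposite
            # strand before abandoning the TCW target
            near = []
            for pool in ((plus_pos, minus_pos) if strand == "+"
                         else (minus_pos, plus_pos)):
                cand = pool[np.abs(pool - p) <= margin] if pool.size else []
                near = [q for q in cand if q not in members and q not in taken]
                if near:
                    break
            if near:
                pos = int(near[rng.integers(0, len(near))])
                ref = window[pos - lo]
                if ref == "C":  # pyrimidine strand on plus
                    alt = "T" if rng.random() < 0.5 else "G"
                else:  # G: the C sits on the minus strand
                    alt = "A" if rng.random() < 0.5 else "C"
                members[pos] = (ref, alt)
                continue
        # non-targeted member (or no reachable TCW site): stay at the ideal
        # position, uniform substitution
        for cand in (p, p + 1, p - 1, p + 2, p - 2):
            if 1 <= cand <= genome.length(chrom) and cand not in members \
                    and cand not in taken:
                pos = cand
                break
        if pos is None:
            return None
        ref = window[pos - lo]
        if ref == "N":
            return None
        members[pos] = (ref, _random_alt(ref, rng))
    if len(members) < len(ideal):
        return None
    for p in members:
        taken.add(p)
    return [(p, members[p][0], members[p][1]) for p in sorted(members)]


def _generate_clinical(config, sample_id, rng, positive: bool) -> ClinicalRecord:
    ancestries = [a for a, _ in config.ancestry_mix]
    w = np.array([p for _, p in config.ancestry_mix], dtype=float)
    ancestry = ancestries[rng.choice(len(ancestries), p=w / w.sum())]
    hr = rng.random() < config.hr_fraction
    isup = int(rng.integers(3, 6)) if hr else int(rng.integers(1, 3))
    psa = float(np.round(rng.lognormal(math.log(60 if ancestry == "AFR" else 10), 0.8), 2))
    age = float(int(rng.normal(68 if ancestry == "AFR" else 63, 6)))
    followup = float(int(rng.uniform(365, 3000)))
    # adverse outcomes mildly coupled to kataegis positivity
    p_met = 0.25 if positive else 0.12
    met = bool(rng.random() < p_met)
    bcr = bool(met or rng.random() < 0.2)
    return ClinicalRecord(sample_id, ancestry, isup, psa=psa, age=age,
                          followup_days=followup, bcr_flag=bcr,
                          metastasis_flag=met)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def generate_cohort(config: SimConfig) -> Cohort:
    """Deterministic cohort: one SeedSequence tree rooted at config.seed."""
    root = np.random.SeedSequence(config.seed)
    ref_ss, *sample_ss = root.spawn(config.n_samples + 1)
    genome = generate_reference(config, np.random.default_rng(ref_ss))
    samples = [
        generate_sample(config, genome, f"S{i:03d}", np.random.default_rng(ss))
        for i, ss in enumerate(sample_ss)
    ]
    return Cohort(config, genome, samples)


def emit_cohort(cohort: Cohort, out_dir) -> Dict[str, object]:
    """Write the cohort as VCF + BEDPE per sample, cohort-level TSVs, FASTA
    and a truth JSON.  Files round-trip losslessly through the readers."""
    from . import io as kio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kio.write_fasta(cohort.genome, out / "reference.fa")
    purity = {}
    cn: List[CnSegment] = []
    clinical = []
    manifest_samples = []
    for s in cohort.samples:
        kio.write_snvs(s.snvs, out / f"{s.sample_id}.vcf", fmt="vcf",
                       genome=cohort.genome)
        kio.write_sv_bedpe(kio.breakends_as_pairs(s.breakpoints),
                           out / f"{s.sample_id}.bedpe")
        purity[s.sample_id] = s.purity
        cn.extend(s.cn_segments)
        clinical.append(s.clinical)
        manifest_samples.append(s.sample_id)
    kio.write_cn_segments(cn, out / "cn_segments.tsv")
    kio.write_purity(purity, out / "purity.tsv")
    kio.write_clinical(clinical, out / "clinical.tsv")
    truth = {
        "config": {k: v for k, v in asdict(cohort.config).items()},
        "samples": manifest_samples,
        "events": [asdict(t) for t in cohort.truth_events],
        "burden": {s.sample_id: len(s.truth_events) for s in cohort.samples},
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, default=list)
    return truth
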
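"""Readers and writers for the external formats the pipeline touches.

VCF 4.2 for SNVs (read via cyvcf2, written as sites-level text with timing
annotations in INFO), BEDPE for SV breakends, TSV with named headers for
copy-number segments / purity / clinical tables / event tables, FASTA for
the reference, and BED (0-based half-open) for event export.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .datamodel import (
    BASES,
    GenomeRef,
    SnvRecord,
    SvBreakpoint,
    CnSegment,
    ClinicalRecord,
    sort_snvs,
)
from .detect import KataegisEvent

log = logging.getLogger(__name__)

SNV_TSV_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "ccf", "multiplicity", "epoch"]

EVENT_COLUMNS = [
    "sample_id", "chrom", "start", "end", "n_snv", "span", "max_adjusted_imd",
    "member_indices", "epoch", "apobec_enriched", "a3_class", "sv_distance", "sv_class",
]


def _check_chrom(chrom: str, genome: Optional[GenomeRef], where: str):
    if genome is not None and chrom not in genome:
        raise ValueError(f"{where}: chromosome {chrom!r} not in reference")


# ---------------------------------------------------------------------------
# SNVs
# ---------------------------------------------------------------------------

def read_snvs(path, fmt: str = "vcf", genome: Optional[GenomeRef] = None,
              sample_id: Optional[str] = None) -> List[SnvRecord]:
    """Read somatic SNVs from a VCF 4.2 or a TSV with named headers.

    Multi-allelic VCF rows are split into one record per alternate allele;
    rows that are not single-nucleotide substitutions are skipped and counted.
    Records are returned sorted by (sample, chromosome order, position).
    """
    path = Path(path)
    if fmt == "vcf":
        records, skipped = _read_snvs_vcf(path, sample_id)
    elif fmt == "tsv":
        records, skipped = _read_snvs_tsv(path, sample_id)
    else:
        raise ValueError(f"unknown SNV format {fmt!r}")
    if skipped:
        log.info("read_snvs(%s): skipped %d non-SNV rows", path.name, skipped)
    for r in records:
        _check_chrom(r.chrom, genome, f"read_snvs({path.name})")
        if genome is not None and r.pos > genome.length(r.chrom):
            raise ValueError(
                f"read_snvs({path.name}): position {r.chrom}:{r.pos} beyond chromosome end"
            )
    return sort_snvs(records, genome)


def _read_snvs_vcf(path: Path, sample_id: Optional[str]):
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    sid = sample_id or (vcf.samples[0] if vcf.samples else path.stem)
    records: List[SnvRecord] = []
    skipped = 0
    for var in vcf:
        ref = var.REF.upper()
        for alt in var.ALT:
            alt = alt.upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
                skipped += 1
                continue
            info = dict(var.INFO)
            ccf = info.get("CCF")
            mult = info.get("MULT")
            epoch = info.get("EPOCH")
            records.append(SnvRecord(
                sample_id=sid, chrom=var.CHROM, pos=var.POS, ref=ref, alt=alt,
                # htslib stores INFO floats at single precision; restore the
                # writer's 6-significant-digit representation
                ccf=float(f"{float(ccf):.6g}") if ccf is not None else None,
                multiplicity=int(mult) if mult is not None else None,
                epoch=str(epoch) if epoch is not None else None,
            ))
    return records, skipped


def _read_snvs_tsv(path: Path, sample_id: Optional[str]):
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"chrom", "pos", "ref", "alt"} - set(df.columns)
    if missing:
        raise ValueError(f"SNV TSV {path} missing columns: {sorted(missing)}")
    records: List[SnvRecord] = []
    skipped = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        ref, alt = str(d["ref"]).upper(), str(d["alt"]).upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
            skipped += 1
            continue
        try:
            records.append(SnvRecord(
                sample_id=str(d.get("sample_id") or sample_id or path.stem),
                chrom=str(d["chrom"]), pos=int(d["pos"]), ref=ref, alt=alt,
                ccf=None if pd.isna(d.get("ccf")) else float(d["ccf"]),
                multiplicity=None if pd.isna(d.get("multiplicity")) else int(d["multiplicity"]),
                epoch=None if pd.isna(d.get("epoch")) else str(d["epoch"]),
            ))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}:{i}: malformed SNV row: {exc}") from exc
    return records, skipped


def write_snvs(snvs: Sequence[SnvRecord], path, fmt: str = "vcf",
               genome: Optional[GenomeRef] = None) -> None:
    """Write SNVs as a sites-level VCF 4.2 (timing annotations in INFO) or TSV."""
    path = Path(path)
    if fmt == "tsv":
        rows = [{
            "sample_id": s.sample_id, "chrom": s.chrom, "pos": s.pos,
            "ref": s.ref, "alt": s.alt, "ccf": s.ccf,
            "multiplicity": s.multiplicity, "epoch": s.epoch,
        } for s in snvs]
        pd.DataFrame(rows, columns=SNV_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
        return
    if fmt != "vcf":
        raise ValueError(f"unknown SNV format {fmt!r}")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CCF,Number=1,Type=Float,Description="Cancer cell fraction">\n')
        fh.write('##INFO=<ID=MULT,Number=1,Type=Integer,Description="Mutation multiplicity">\n')
        fh.write('##INFO=<ID=EPOCH,Number=1,Type=String,Description="Evolutionary epoch">\n')
        if genome is not None:
            for c in genome.chrom_names:
                fh.write(f"##contig=<ID={c},length={genome.length(c)}>\n")
        else:
            for c in dict.fromkeys(s.chrom for s in snvs):
                fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in snvs:
            info = []
            if s.ccf is not None:
                info.append(f"CCF={s.ccf:.6g}")
            if s.multiplicity is not None:
                info.append(f"MULT={s.multiplicity}")
            if s.epoch is not None:
                info.append(f"EPOCH={s.epoch}")
            fh.write(f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t"
                     f"{';'.join(info) or '.'}\n")


# ---------------------------------------------------------------------------
# SV BEDPE
# ---------------------------------------------------------------------------

BEDPE_COLUMNS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
                 "name", "score", "strand1", "strand2"]


def read_sv_bedpe(path, sample_id: Optional[str] = None,
                  genome: Optional[GenomeRef] = None) -> List[SvBreakpoint]:
    """Read SV breakends from BEDPE.

    Each row yields two mated breakends.  BEDPE starts are 0-based; breakend
    position is ``start + 1`` (1-based).  Optional 11th/12th columns carry the
    SV class and a chromothripsis flag.
    """
    path = Path(path)
    sid = sample_id or path.stem
    breakends: List[SvBreakpoint] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise ValueError(f"{path}:{lineno}: BEDPE row has {len(f)} < 10 columns")
            try:
                c1, s1, c2, s2 = f[0], int(f[1]), f[3], int(f[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BEDPE row: {exc}") from exc
            sv_class = f[10] if len(f) > 10 and f[10] else "OTHER"
            ct = len(f) > 11 and f[11] in ("1", "True", "true")
            if sv_class == "TRA" and c1 == c2:
                raise ValueError(
                    f"{path}:{lineno}: TRA row with identical chromosomes {c1}"
                )
            p1, p2 = s1 + 1, s2 + 1
            _check_chrom(c1, genome, f"read_sv_bedpe({path.name}):{lineno}")
            _check_chrom(c2, genome, f"read_sv_bedpe({path.name}):{lineno}")
            breakends.append(SvBreakpoint(sid, c1, p1, sv_class, ct, mate=(c2, p2)))
            breakends.append(SvBreakpoint(sid, c2, p2, sv_class, ct, mate=(c1, p1)))
    return breakends


def write_sv_bedpe(pairs: Iterable[Tuple[SvBreakpoint, SvBreakpoint]], path) -> None:
    """Write mated breakend pairs as BEDPE (one row per pair)."""
    with open(path, "w") as fh:
        for i, (a, b) in enumerate(pairs):
            fh.write("\t".join(map(str, [
                a.chrom, a.pos - 1, a.pos, b.chrom, b.pos - 1, b.pos,
                f"sv{i}", ".", "+", "-", a.sv_class,
                1 if a.chromothripsis_flag else 0,
            ])) + "\n")


def breakends_as_pairs(breakends: Sequence[SvBreakpoint]):
    """Group a flat mated breakend list back into pairs (for re-writing)."""
    pairs, seen = [], set()
    index = {}
    for i, b in enumerate(breakends):
        index.setdefault((b.chrom, b.pos), []).append(i)
    for i, b in enumerate(breakends):
        if i in seen or b.mate is None:
            continue
        for j in index.get(b.mate, []):
            m = breakends[j]
            if j != i and j not in seen and m.mate == (b.chrom, b.pos) \
                    and m.sv_class == b.sv_class:
                pairs.append((b, m))
                seen.add(i)
                seen.add(j)
                break
    return pairs


# ---------------------------------------------------------------------------
# Copy number, purity, clinical
# ---------------------------------------------------------------------------

def read_cn_segments(path) -> List[CnSegment]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [CnSegment(str(r.sample_id), str(r.chrom), int(r.start), int(r.end),
                      int(r.major_cn), int(r.minor_cn))
            for r in df.itertuples(index=False)]


def write_cn_segments(segments: Sequence[CnSegment], path) -> None:
    pd.DataFrame([{
        "sample_id": s.sample_id, "chrom": s.chrom, "start": s.start,
        "end": s.end, "major_cn": s.major_cn, "minor_cn": s.minor_cn,
    } for s in segments]).to_csv(path, sep="\t", index=False)


def read_purity(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return {str(r.sample_id): float(r.purity) for r in df.itertuples(index=False)}


def write_purity(purity: dict, path) -> None:
    pd.DataFrame({"sample_id": list(purity), "purity": list(purity.values())}
                 ).to_csv(path, sep="\t", index=False)


def _opt(v, cast):
    return None if v is None or (isinstance(v, float) and math.isnan(v)) else cast(v)


def read_clinical(path) -> List[ClinicalRecord]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples(index=False):
        d = r._asdict()
        out.append(ClinicalRecord(
            sample_id=str(d["sample_id"]), ancestry=str(d["ancestry"]),
            isup_gg=int(d["isup_gg"]),
            psa=_opt(d.get("psa"), float), age=_opt(d.get("age"), float),
            followup_days=_opt(d.get("followup_days"), float),
            bcr_flag=_opt(d.get("bcr_flag"), lambda v: bool(int(v))),
            metastasis_flag=_opt(d.get("metastasis_flag"), lambda v: bool(int(v))),
        ))
    return out


def write_clinical(records: Sequence[ClinicalRecord], path) -> None:
    pd.DataFrame([{
        "sample_id": c.sample_id, "ancestry": c.ancestry, "risk": c.risk,
        "isup_gg": c.isup_gg, "psa": c.psa, "age": c.age,
        "followup_days": c.followup_days,
        "bcr_flag": None if c.bcr_flag is None else int(c.bcr_flag),
        "metastasis_flag": None if c.metastasis_flag is None else int(c.metastasis_flag),
    } for c in records]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Kataegis event tables
# ---------------------------------------------------------------------------

def write_events(events: Sequence[KataegisEvent], path, bed_path=None) -> None:
    """Write one row per event; optional BED companion (0-based half-open)."""
    rows = []
    for e in events:
        rows.append({
            "sample_id": e.sample_id, "chrom": e.chrom, "start": e.start,
            "end": e.end, "n_snv": e.n_snv, "span": e.span,
            "max_adjusted_imd": e.max_adjusted_imd,
            "member_indices": ";".join(map(str, e.member_indices)),
            "epoch": e.epoch,
            "apobec_enriched": None if e.apobec_enriched is None else int(e.apobec_enriched),
            "a3_class": e.a3_class,
            "sv_distance": e.sv_distance,
            "sv_class": e.sv_class,
        })
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for e in events:
                fh.write(f"{e.chrom}\t{e.start - 1}\t{e.end}\t{e.sample_id}\t{e.n_snv}\n")


def read_events(path) -> List[KataegisEvent]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    events = []
    for r in df.itertuples(index=False):
        d = r._asdict()
        members = tuple(int(x) for x in str(d["member_indices"]).split(";")) \
            if not pd.isna(d["member_indices"]) and str(d["member_indices"]) else ()
        events.append(KataegisEvent(
            sample_id=str(d["sample_id"]), chrom=str(d["chrom"]),
            start=int(d["start"]), end=int(d["end"]), n_snv=int(d["n_snv"]),
            member_indices=members,
            max_adjusted_imd=float(d["max_adjusted_imd"]),
            epoch=_opt(d.get("epoch"), str),
            apobec_enriched=_opt(d.get("apobec_enriched"), lambda v: bool(int(v))),
            a3_class=_opt(d.get("a3_class"), str),
            sv_distance=_opt(d.get("sv_distance"), float),
            sv_class=_opt(d.get("sv_class"), str),
        ))
    return events


def write_fasta(genome: GenomeRef, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for c in genome.chrom_names:
            fh.write(f">{c}\n")
            seq = genome.sequence(c, 1, genome.length(c))
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
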
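"""Core domain types shared by every pipeline stage.

Coordinate convention: 1-based inclusive everywhere in memory (the VCF
convention).  Conversion to/from 0-based half-open happens only at the
BED/BEDPE boundary in :mod:`kataegis_storm.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

BASES = frozenset("ACGT")

EPOCHS = ("clonal_early", "clonal_late", "clonal_unspecified", "subclonal", "unknown")
CLONAL_EPOCHS = ("clonal_early", "clonal_late", "clonal_unspecified")

SV_CLASSES = ("DEL", "DUP", "INV", "TRA", "OTHER")

ANCESTRIES = ("AFR", "EUR", "ASI")

#: Sentinel distance for "no breakpoint on this chromosome".
BEYOND = math.inf


class GenomeRef:
    """Reference genome: ordered chromosomes, lengths and a sequence accessor.

    Sequences may be held in memory (synthetic genomes) or served lazily from
    an indexed FASTA.  A lengths-only instance supports every coordinate
    operation but raises if sequence is requested.
    """

    def __init__(
        self,
        chrom_names: Sequence[str],
        chrom_lengths: Sequence[int],
        sequences: Optional[Mapping[str, str]] = None,
        _fasta=None,
    ):
        if len(chrom_names) != len(chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if any(l <= 0 for l in chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        self.chrom_names = list(chrom_names)
        self.chrom_lengths = {c: int(l) for c, l in zip(chrom_names, chrom_lengths)}
        self._order = {c: i for i, c in enumerate(self.chrom_names)}
        self._sequences = dict(sequences) if sequences is not None else None
        self._fasta = _fasta

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_sequences(cls, sequences: Mapping[str, str]) -> "GenomeRef":
        names = list(sequences)
        return cls(names, [len(sequences[c]) for c in names], sequences=sequences)

    @classmethod
    def from_fasta(cls, path) -> "GenomeRef":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path))
        names = list(fa.keys())
        lengths = [len(fa[c]) for c in names]
        return cls(names, lengths, _fasta=fa)

    # -- queries ----------------------------------------------------------
    def __contains__(self, chrom: str) -> bool:
        return chrom in self._order

    def order(self, chrom: str) -> int:
        """Rank of ``chrom`` in order of appearance (deterministic sort key)."""
        return self._order[chrom]

    def length(self, chrom: str) -> int:
        return self.chrom_lengths[chrom]

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    @property
    def has_sequence(self) -> bool:
        return self._sequences is not None or self._fasta is not None

    def sequence(self, chrom: str, start: int, end: int) -> str:
        """Uppercase sequence of the 1-based inclusive interval [start, end]."""
        if chrom not in self._order:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not (1 <= start <= end <= self.chrom_lengths[chrom]):
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome "
                f"(length {self.chrom_lengths[chrom]})"
            )
        if self._sequences is not None:
            seq = self._sequences[chrom][start - 1 : end]
        elif self._fasta is not None:
            seq = str(self._fasta[chrom][start - 1 : end])
        else:
            raise RuntimeError("GenomeRef holds lengths only, no sequence")
        seq = seq.upper()
        if len(seq) != end - start + 1:
            raise RuntimeError("sequence accessor returned wrong length")
        return seq

    def sort_key(self, chrom: str, pos: int) -> Tuple[int, int]:
        return (self._order[chrom], pos)


@dataclass
class SnvRecord:
    """One somatic single-nucleotide variant, optionally timing-annotated."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    ccf: Optional[float] = None
    multiplicity: Optional[int] = None
    epoch: Optional[str] = None

    def __post_init__(self):
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"ref/alt must be single bases in ACGT, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ccf is not None and not (0.0 <= self.ccf <= 1.0):
            raise ValueError(f"ccf outside [0,1]: {self.ccf}")
        if self.epoch is not None and self.epoch not in EPOCHS:
            raise ValueError(f"unknown epoch label {self.epoch!r}")


@dataclass
class SvBreakpoint:
    """One structural-variant breakend with its SV-class label."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    sv_class: str = "OTHER"
    chromothripsis_flag: bool = False
    mate: Optional[Tuple[str, int]] = None

    def __post_init__(self):
        if self.sv_class not in SV_CLASSES:
            raise ValueError(f"unknown sv_class {self.sv_class!r}")
        if self.sv_class == "TRA":
            if self.mate is not None and self.mate[0] == self.chrom:
                raise ValueError(
                    f"TRA breakend at {self.chrom}:{self.pos} has intra-chromosomal mate"
                )


@dataclass
class CnSegment:
    """Allele-specific copy-number segment (1-based inclusive)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    major_cn: int
    minor_cn: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"segment start > end: {self.start} > {self.end}")
        if self.major_cn < self.minor_cn:
            raise ValueError("major_cn must be >= minor_cn")
        if self.minor_cn < 0:
            raise ValueError("copy numbers must be non-negative")

    @property
    def total_cn(self) -> int:
        return self.major_cn + self.minor_cn

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class ClinicalRecord:
    """Per-patient clinical metadata.

    ``risk`` is derived from the ISUP grade group: LR for GG1-2, HR for GG3-5.
    """

    sample_id: str
    ancestry: str
    isup_gg: int
    risk: Optional[str] = None
    psa: Optional[float] = None  # ng/mL
    age: Optional[float] = None  # years
    followup_days: Optional[float] = None
    bcr_flag: Optional[bool] = None
    metastasis_flag: Optional[bool] = None

    def __post_init__(self):
        if self.ancestry not in ANCESTRIES:
            raise ValueError(f"unknown ancestry {self.ancestry!r}")
        if not (1 <= self.isup_gg <= 5):
            raise ValueError(f"isup_gg must be 1-5, got {self.isup_gg}")
        derived = "LR" if self.isup_gg <= 2 else "HR"
        if self.risk is None:
            self.risk = derived
        elif self.risk != derived:
            raise ValueError(
                f"risk {self.risk!r} inconsistent with ISUP GG{self.isup_gg}"
            )

    @property
    def group(self) -> str:
        return f"{self.ancestry}_{self.risk}"


@dataclass
class DetectionParams:
    """Tunable parameters of the whole pipeline, with the defaults used throughout.

    kmin / d_max implement the calling rule: a minimum of four SNVs with
    PCF-adjusted inter-mutational distances below one kilobase, identical for
    all samples.
    """

    kmin: int = 4
    d_max: float = 1000.0  # bp
    pcf_gamma: float = 25.0
    flank: int = 20  # bp per side of a mutation's context window
    n_sim: int = 1000
    distance_bin_edges: Tuple[float, ...] = (
        0.0, 1e3, 1e4, 1e5, 1e6, 1e7, 1e8, math.inf,
    )
    #: segment-mean used as the adjusted distance: the back-transformed mean
    #: of log10 IMDs (the level PCF fits) is robust to a single bridging
    #: distance inside a segment; 'arithmetic' averages the raw IMDs instead
    adjusted_mode: str = "geometric"
    burden_split: int = 1  # "elevated burden" means kataegis count > this
    outlier_z: float = 3.0
    alpha: float = 0.05
    clonal_ccf_threshold: float = 0.9
    rng_seed: int = 0

    def __post_init__(self):
        if self.kmin < 2:
            raise ValueError("kmin must be >= 2")
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        edges = self.distance_bin_edges
        if any(a >= b for a, b in zip(edges, edges[1:])):
            raise ValueError("distance_bin_edges must be strictly increasing")
        if edges[0] != 0:
            raise ValueError("first distance bin edge must be 0")


def sort_snvs(snvs, genome: Optional[GenomeRef] = None):
    """Sort SNVs by (sample, chromosome order, position).

    Chromosome order follows the GenomeRef when given, else order of first
    appearance in the input (deterministic either way).
    """
    if genome is not None:
        key_of = genome.order
    else:
        seen = {}
        for s in snvs:
            seen.setdefault(s.chrom, len(seen))
        key_of = seen.__getitem__
    return sorted(snvs, key=lambda s: (s.sample_id, key_of(s.chrom), s.pos))
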
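"""Domain types: reads, references, repeat units, alignments, clusters.

Coordinates are 0-based half-open everywhere inside the package; conversion
to/from 1-based happens only at the SAM boundary (handled by pysam) and GTF
parsing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from .seq import check_alphabet, normalize, rotate


@dataclass
class SequenceRecord:
    """One read (or merged read pair): identifier, bases, optional quality.

    The sequence is normalized on construction (uppercase, U -> T) and must
    be non-empty over {A, C, G, T, N}. Quality, when present, is a Sanger
    (Phred+33) string of equal length.
    """

    id: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self) -> None:
        self.seq = normalize(self.seq)
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        check_alphabet(self.seq, f"record {self.id!r}")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


class Reference:
    """An ordered name -> sequence map standing for a genome or transcriptome."""

    def __init__(self, sequences: Iterable[tuple[str, str]] | dict[str, str]):
        items = sequences.items() if isinstance(sequences, dict) else sequences
        self._seqs: dict[str, str] = {}
        for name, seq in items:
            if name in self._seqs:
                raise ValueError(f"duplicate reference name {name!r}")
            seq = normalize(seq)
            if not seq:
                raise ValueError(f"reference {name!r}: empty sequence")
            check_alphabet(seq, f"reference {name!r}")
            self._seqs[name] = seq
        if not self._seqs:
            raise ValueError("reference contains no sequences")

    @property
    def names(self) -> list[str]:
        return list(self._seqs)

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __len__(self) -> int:
        return len(self._seqs)

    def items(self) -> Iterator[tuple[str, str]]:
        return iter(self._seqs.items())

    def length(self, name: str) -> int:
        return len(self._seqs[name])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def fetch(self, name: str, start: int, end: int) -> str:
        seq = self._seqs[name]
        if start < 0 or end > len(seq) or end <= start:
            raise ValueError(
                f"interval [{start}, {end}) outside reference {name!r} "
                f"of length {len(seq)}"
            )
        return seq[start:end]


@dataclass
class RepeatUnit:
    """The reconstructed repeating unit of one read.

    ``period`` is the tandem period in nt; ``copies`` = read length / period;
    ``mismatches`` counts errors in the shifted self-comparison that called
    the period (0 for non-tandem pass-through reads).
    """

    source_id: str
    unit: str
    period: int
    copies: float
    mismatches: int
    is_tandem: bool

    def __post_init__(self) -> None:
        if len(self.unit) != self.period:
            raise ValueError("unit length must equal period")


@dataclass
class RotationFamily:
    """All one-base cyclic shifts of a repeat unit, with provenance."""

    unit: RepeatUnit
    rotations: list[str]

    @property
    def family_id(self) -> str:
        return self.unit.source_id

    @property
    def period(self) -> int:
        return self.unit.period

    @classmethod
    def from_unit(cls, unit: RepeatUnit) -> "RotationFamily":
        return cls(unit=unit, rotations=[rotate(unit.unit, k) for k in range(unit.period)])


@dataclass
class AlignmentHit:
    """One candidate placement of one rotation."""

    family_id: str
    rotation_index: int
    ref_name: str
    start: int
    end: int
    strand: str
    mismatches: int
    unique: bool = False


@dataclass
class ReconstructedRead:
    """The representative original-RNA sequence chosen for one family."""

    family_id: str
    rotation_index: int
    sequence: str
    ref_name: str
    start: int
    end: int
    strand: str
    mismatches: int


@dataclass
class Rejection:
    """A family (or read) dropped from analysis, with a reason code."""

    family_id: str
    reason: str  # ambiguous | no_hit | no_unique | not_converged


@dataclass
class TruthRecord:
    """Pre-recorded origin of a simulated fragment."""

    fragment_id: str
    ref_name: str
    start: int
    end: int
    strand: str
    phase: Optional[int] = None


@dataclass
class Cluster:
    """A genomic interval aggregating reconstructed reads on one strand."""

    ref_name: str
    start: int
    end: int
    strand: str
    read_count: int
    t2c_reads: int = 0
    bins: list[int] = field(default_factory=list)
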
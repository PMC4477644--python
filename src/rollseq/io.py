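"""File-format boundaries: FASTQ, FASTA, SAM and BED6.

Internal coordinates are 0-based half-open; pysam converts SAM's 1-based
POS on read, and the SAM writer converts back. No science lives here.
"""

from __future__ import annotations

import re
import warnings
from typing import Iterable, Iterator, Sequence

import pysam
from Bio import SeqIO

from .records import AlignmentHit, Reference, SequenceRecord
from .seq import revcomp

__all__ = [
    "FastqParseError",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "parse_sam",
    "write_sam",
    "write_bed",
    "read_bed",
]


class FastqParseError(ValueError):
    pass


# Rotation provenance is encoded in SAM/FASTA query names as "<family>|rot<k>".
_QNAME_RE = re.compile(r"^(?P<family>.+)\|rot(?P<rot>\d+)$")


def format_rotation_name(family_id: str, rotation_index: int) -> str:
    return f"{family_id}|rot{rotation_index}"


def parse_rotation_name(qname: str) -> tuple[str, int] | None:
    m = _QNAME_RE.match(qname)
    if m is None:
        return None
    return m.group("family"), int(m.group("rot"))


def read_fastq(path) -> Iterator[SequenceRecord]:
    """Stream 4-line FASTQ records, normalizing U->T and case-folding.

    The parser is deliberately strict: a malformed record raises
    :class:`FastqParseError` naming the offending line number.
    """
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FastqParseError(f"line {lineno}: expected '@' header, got {header[:30]!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise FastqParseError(f"line {lineno}: truncated record {header[1:]!r}")
            lineno += 3
            if not plus.startswith("+"):
                raise FastqParseError(f"line {lineno - 1}: expected '+' separator")
            if len(qual) != len(seq):
                raise FastqParseError(
                    f"line {lineno}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            yield SequenceRecord(id=header[1:], seq=seq, qual=qual)


def write_fastq(records: Iterable[SequenceRecord], path) -> int:
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            qual = rec.qual if rec.qual is not None else "I" * len(rec.seq)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")
            n += 1
    return n


def read_fasta(path) -> Reference:
    """Load a FASTA file into a :class:`Reference` (multi-line records
    concatenated, duplicate headers rejected)."""
    pairs = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA header {rec.id!r}")
        seen.add(rec.id)
        pairs.append((rec.id, str(rec.seq)))
    if not pairs:
        raise ValueError(f"no FASTA records in {path}")
    return Reference(pairs)


def write_fasta(sequences: Reference | Iterable[tuple[str, str]], path, width: int = 70) -> int:
    items = sequences.items() if isinstance(sequences, Reference) else sequences
    n = 0
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
            n += 1
    return n


def parse_sam(path) -> Iterator[AlignmentHit]:
    """Stream mapped SAM records whose query names encode "<family>|rot<k>".

    Unmapped records are skipped; query names that do not follow the
    encoding are skipped with a warning. The ``unique`` flag is provisional
    (True); :func:`rollseq.mapping.import_external_alignments` re-derives it
    from the multiplicity of records per query.
    """
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            parsed = parse_rotation_name(aln.query_name)
            if parsed is None:
                warnings.warn(
                    f"SAM query name {aln.query_name!r} does not match "
                    "'<family>|rot<k>'; record skipped"
                )
                continue
            family_id, rot = parsed
            try:
                nm = int(aln.get_tag("NM"))
            except KeyError:
                nm = 0
            yield AlignmentHit(
                family_id=family_id,
                rotation_index=rot,
                ref_name=aln.reference_name,
                start=aln.reference_start,
                end=aln.reference_end,
                strand="-" if aln.is_reverse else "+",
                mismatches=nm,
                unique=True,
            )


def write_sam(hits: Iterable[AlignmentHit], reference: Reference, path,
              sequences: dict[tuple[str, int], str] | None = None) -> int:
    """Write hits as a plain-text SAM file (ungapped, CIGAR `<L>M`).

    ``sequences`` optionally maps (family_id, rotation_index) to the query
    sequence; minus-strand records store the reverse complement, per SAM
    convention. Without it SEQ is '*'.
    """
    n = 0
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name in reference.names:
            fh.write(f"@SQ\tSN:{name}\tLN:{reference.length(name)}\n")
        for h in hits:
            qname = format_rotation_name(h.family_id, h.rotation_index)
            flag = 16 if h.strand == "-" else 0
            length = h.end - h.start
            seq = "*"
            if sequences is not None:
                s = sequences.get((h.family_id, h.rotation_index))
                if s is not None:
                    seq = revcomp(s) if h.strand == "-" else s
            fh.write(
                f"{qname}\t{flag}\t{h.ref_name}\t{h.start + 1}\t255\t{length}M\t"
                f"*\t0\t0\t{seq}\t*\tNM:i:{h.mismatches}\n"
            )
            n += 1
    return n


BedRecord = tuple[str, int, int, str, float, str]


def write_bed(intervals: Iterable[Sequence], path) -> int:
    """Write 6-column BED, sorted by (chrom, start).

    Each interval is (chrom, start, end, name, score, strand) with 0-based
    half-open coordinates.
    """
    rows = []
    for iv in intervals:
        chrom, start, end, name, score, strand = iv
        start, end = int(start), int(end)
        if start < 0 or end <= start:
            raise ValueError(f"invalid BED interval [{start}, {end}) on {chrom}")
        rows.append((str(chrom), start, end, str(name), score, str(strand)))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")
    return len(rows)


def read_bed(path) -> list[BedRecord]:
    out: list[BedRecord] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name, score, strand = line.rstrip("\n").split("\t")
            out.append((chrom, int(start), int(end), name, float(score), strand))
    return out
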
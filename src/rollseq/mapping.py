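"""Expanded alignment: align every rotation, keep unique hits, require
convergence to one locus, and pick the representative original sequence.

The built-in aligner is a seeded, ungapped, both-strand mapper: every k-mer
of the query (and of its reverse complement) seeds a candidate diagonal,
which is verified by direct mismatch counting. It guarantees discovery of
any placement with <= m mismatches when the query is long enough that some
k-mer window must be error-free (length >= (m+1) * k); shorter queries are
found whenever an exact seed survives — the practical regime for the
synthetic references used here. Spliced or genome-scale alignment is
delegated to an external aligner through the SAM import path.

A rotation is *uniquely aligned* when exactly one location attains its
minimal mismatch count. A family is accepted only when all its unique hits
converge to one reference, strand and start window (the convergence check),
after which the hit with the fewest mismatches — ties broken by leftmost
start, then lowest rotation index — names the representative sequence.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from typing import Iterable, Optional, Union

import numpy as np

from .io import parse_sam
from .records import (
    AlignmentHit,
    ReconstructedRead,
    Reference,
    Rejection,
    RotationFamily,
)
from .seq import encode, kmer_codes, mismatches_encoded, revcomp

__all__ = [
    "KmerIndex",
    "index_reference",
    "align_ungapped",
    "check_convergence",
    "select_representative",
    "resolve_family",
    "resolve_families",
    "import_external_alignments",
    "resolve_from_sam",
]


class KmerIndex:
    """Exact k-mer -> position index over the forward reference.

    Minus-strand queries are handled at query time by seeding with the
    reverse complement; reported coordinates are always forward-reference.
    """

    def __init__(self, reference: Reference, k: int = 12):
        if k < 1:
            raise ValueError("k must be >= 1")
        if reference.total_length == 0:
            raise ValueError("empty reference")
        self.k = k
        self.reference = reference
        self.names = reference.names
        self.lengths = np.array([reference.length(n) for n in self.names], dtype=np.int64)
        self.offsets = np.concatenate(([0], np.cumsum(self.lengths)))[:-1]

        self._enc = np.concatenate([encode(reference[n]) for n in self.names])
        code_chunks, pos_chunks = [], []
        for off, name in zip(self.offsets, self.names):
            codes, valid = kmer_codes(encode(reference[name]), k)
            idx = np.nonzero(valid)[0]
            code_chunks.append(codes[idx])
            pos_chunks.append(idx + off)
        codes = np.concatenate(code_chunks)
        pos = np.concatenate(pos_chunks)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._pos = pos[order]

    def candidate_starts(self, qenc: np.ndarray) -> np.ndarray:
        """Global start positions seeded by any exact k-mer of the query."""
        qcodes, valid = kmer_codes(qenc, self.k)
        idx = np.nonzero(valid)[0]
        if idx.size == 0:
            return np.empty(0, dtype=np.int64)
        qc = qcodes[idx]
        lo = np.searchsorted(self._codes, qc, side="left")
        hi = np.searchsorted(self._codes, qc, side="right")
        chunks = [self._pos[l:h] - off for off, l, h in zip(idx, lo, hi) if h > l]
        if not chunks:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(chunks))

    def locate(self, gstart: int, length: int) -> Optional[tuple[str, int]]:
        """Map a global start to (ref_name, local_start), or None when the
        window would cross a sequence boundary."""
        i = int(np.searchsorted(self.offsets, gstart, side="right")) - 1
        if gstart < 0 or gstart + length > self.offsets[i] + self.lengths[i]:
            return None
        return self.names[i], int(gstart - self.offsets[i])


def index_reference(reference: Reference, k: int = 12) -> KmerIndex:
    return KmerIndex(reference, k=k)


def align_ungapped(
    query: str,
    index: KmerIndex,
    max_mismatch: int = 2,
    family_id: str = "",
    rotation_index: int = 0,
) -> list[AlignmentHit]:
    """All ungapped placements of ``query`` with <= max_mismatch mismatches,
    on both strands, found by seed-and-verify.

    The ``unique`` flag is set on the single best hit iff exactly one
    location attains the minimal mismatch count.
    """
    L = len(query)
    if L < index.k:
        raise ValueError(f"query length {L} < k={index.k}")
    hits: list[AlignmentHit] = []
    for strand, q in (("+", query), ("-", revcomp(query))):
        qenc = encode(q)
        for gstart in index.candidate_starts(qenc):
            loc = index.locate(int(gstart), L)
            if loc is None:
                continue
            seg = index._enc[gstart : gstart + L]
            mism = mismatches_encoded(seg, qenc)
            if mism <= max_mismatch:
                name, start = loc
                hits.append(
                    AlignmentHit(
                        family_id=family_id,
                        rotation_index=rotation_index,
                        ref_name=name,
                        start=start,
                        end=start + L,
                        strand=strand,
                        mismatches=mism,
                        unique=False,
                    )
                )
    _flag_unique(hits)
    return hits


def _flag_unique(hits: list[AlignmentHit]) -> None:
    """Set unique=True on the minimal-mismatch hit iff it is unrivalled."""
    if not hits:
        return
    mmin = min(h.mismatches for h in hits)
    best = [h for h in hits if h.mismatches == mmin]
    for h in hits:
        h.unique = False
    if len(best) == 1:
        best[0].unique = True


def check_convergence(hits: Iterable[AlignmentHit], max_span: int) -> bool:
    """True iff all (unique) hits share reference and strand and their starts
    span at most ``max_span`` bases. Empty hit sets do not converge."""
    hits = list(hits)
    if not hits:
        return False
    if len({(h.ref_name, h.strand) for h in hits}) != 1:
        return False
    starts = [h.start for h in hits]
    return max(starts) - min(starts) <= max_span


def select_representative(
    family: RotationFamily, hits: list[AlignmentHit]
) -> ReconstructedRead:
    """Pick the best converged unique hit: fewest mismatches, then leftmost
    start, then lowest rotation index; its rotation is the representative
    original-RNA sequence."""
    best = min(hits, key=lambda h: (h.mismatches, h.start, h.rotation_index))
    return ReconstructedRead(
        family_id=family.family_id,
        rotation_index=best.rotation_index,
        sequence=family.rotations[best.rotation_index],
        ref_name=best.ref_name,
        start=best.start,
        end=best.end,
        strand=best.strand,
        mismatches=best.mismatches,
    )


def _resolve_hits(
    family: RotationFamily, hits: list[AlignmentHit], max_span: Optional[int]
) -> Union[ReconstructedRead, Rejection]:
    if not hits:
        return Rejection(family.family_id, "no_hit")
    unique_hits = [h for h in hits if h.unique]
    if not unique_hits:
        return Rejection(family.family_id, "no_unique")
    span = family.period if max_span is None else max_span
    if not check_convergence(unique_hits, span):
        return Rejection(family.family_id, "not_converged")
    return select_representative(family, unique_hits)


def resolve_family(
    family: RotationFamily,
    index: KmerIndex,
    max_mismatch: int = 2,
    max_span: Optional[int] = None,
) -> Union[ReconstructedRead, Rejection]:
    """Full expanded-alignment resolution of one rotation family:
    align all rotations -> keep unique -> convergence -> representative."""
    hits: list[AlignmentHit] = []
    for k, rot in enumerate(family.rotations):
        hits.extend(
            align_ungapped(
                rot, index, max_mismatch, family_id=family.family_id, rotation_index=k
            )
        )
    return _resolve_hits(family, hits, max_span)


def resolve_families(
    families: Iterable[RotationFamily],
    index: KmerIndex,
    max_mismatch: int = 2,
    max_span: Optional[int] = None,
) -> tuple[list[ReconstructedRead], list[Rejection]]:
    accepted, rejected = [], []
    for fam in families:
        res = resolve_family(fam, index, max_mismatch=max_mismatch, max_span=max_span)
        (accepted if isinstance(res, ReconstructedRead) else rejected).append(res)
    return accepted, rejected


def import_external_alignments(
    sam_path, families: dict[str, RotationFamily]
) -> dict[str, list[AlignmentHit]]:
    """Group SAM hits by family and re-derive per-rotation uniqueness.

    A rotation (one SAM query) is unique iff exactly one of its records
    attains its minimal NM — the same rule the built-in aligner applies, so
    exporting and re-importing the built-in hits is the identity. Hits for
    unknown families are skipped with a warning.
    """
    by_query: dict[tuple[str, int], list[AlignmentHit]] = defaultdict(list)
    for hit in parse_sam(sam_path):
        if hit.family_id not in families:
            warnings.warn(f"SAM family {hit.family_id!r} not in provided families; skipped")
            continue
        by_query[(hit.family_id, hit.rotation_index)].append(hit)

    grouped: dict[str, list[AlignmentHit]] = defaultdict(list)
    for (family_id, _rot), hits in by_query.items():
        _flag_unique(hits)
        grouped[family_id].extend(hits)
    return dict(grouped)


def resolve_from_sam(
    sam_path,
    families: dict[str, RotationFamily],
    max_span: Optional[int] = None,
) -> tuple[list[ReconstructedRead], list[Rejection]]:
    """Resolve all families from an external aligner's SAM output.

    Families with no mapped records are rejected with reason ``no_hit``.
    """
    grouped = import_external_alignments(sam_path, families)
    accepted, rejected = [], []
    for family_id, fam in families.items():
        res = _resolve_hits(fam, grouped.get(family_id, []), max_span)
        (accepted if isinstance(res, ReconstructedRead) else rejected).append(res)
    return accepted, rejected
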
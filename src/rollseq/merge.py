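"""Overlap-merging of paired-end reads into full-length cDNA sequences.

Rolling-circle libraries are sequenced 2 x 100 nt; the insert is usually
shorter than the two mates combined, so mate 1's 3' end overlaps the
reverse complement of mate 2. The merger scans candidate overlap lengths
from the longest feasible down to ``min_overlap`` and accepts the first
(i.e. longest) whose mismatch fraction is within tolerance — disagreeing
bases are resolved toward the higher base quality, ties toward mate 1.

Pairs that fail to merge are retained: downstream analysis uses mate 1
alone in that case.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

from .records import SequenceRecord
from .seq import revcomp


@dataclass
class MergePolicy:
    """Merging parameters.

    min_overlap
        Smallest acceptable overlap, in bases (default 10 nt).
    max_mismatch_rate
        Largest tolerated fraction of mismatching bases within the overlap.
    quality_arbitration
        When True and both mates carry qualities, a disagreeing overlap base
        is taken from the mate with the higher quality; otherwise mate 1 wins.
    """

    min_overlap: int = 10
    max_mismatch_rate: float = 0.25
    quality_arbitration: bool = True

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not 0 <= self.max_mismatch_rate < 1:
            raise ValueError("max_mismatch_rate must be in [0, 1)")


def merge_pair(
    r1: SequenceRecord, r2: SequenceRecord, policy: MergePolicy | None = None
) -> Optional[SequenceRecord]:
    """Merge a read pair; returns the merged record or None when no overlap
    of at least ``policy.min_overlap`` bases passes the mismatch threshold.

    ``r2`` is the standard reverse-complement-oriented mate. The merged
    length is always ``len(r1) + len(r2) - overlap``.
    """
    policy = policy or MergePolicy()
    s1, s2 = r1.seq, revcomp(r2.seq)
    q1 = r1.qual
    q2 = r2.qual[::-1] if r2.qual is not None else None
    n1, n2 = len(s1), len(s2)

    chosen = None
    for ov in range(min(n1, n2), policy.min_overlap - 1, -1):
        a = s1[n1 - ov :]
        b = s2[:ov]
        mism = [i for i in range(ov) if a[i] != b[i]]
        if len(mism) <= policy.max_mismatch_rate * ov:
            chosen = (ov, mism)
            break
    if chosen is None:
        return None

    ov, mism = chosen
    overlap = list(s1[n1 - ov :])
    oq1 = q1[n1 - ov :] if q1 is not None else None
    oq2 = q2[:ov] if q2 is not None else None
    for i in mism:
        if (
            policy.quality_arbitration
            and oq1 is not None
            and oq2 is not None
            and oq2[i] > oq1[i]
        ):
            overlap[i] = s2[i]
    merged_seq = s1[: n1 - ov] + "".join(overlap) + s2[ov:]

    merged_qual = None
    if q1 is not None and q2 is not None:
        overlap_q = "".join(max(oq1[i], oq2[i]) for i in range(ov))
        merged_qual = q1[: n1 - ov] + overlap_q + q2[ov:]
    return SequenceRecord(id=r1.id, seq=merged_seq, qual=merged_qual)


def merge_pairs(
    pairs: Iterable[tuple[SequenceRecord, SequenceRecord]],
    policy: MergePolicy | None = None,
) -> Iterator[tuple[Optional[SequenceRecord], SequenceRecord, SequenceRecord]]:
    """Yield (merged-or-None, r1, r2) for each pair."""
    policy = policy or MergePolicy()
    for r1, r2 in pairs:
        yield merge_pair(r1, r2, policy), r1, r2
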
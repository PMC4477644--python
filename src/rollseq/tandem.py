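"""Repeating-unit extraction and rotation expansion.

A rolling-circle read is (approximately) a tandem repetition of the original
small-RNA sequence, entered at an arbitrary rotation phase. The period is
called by the shifted self-comparison: ``p`` is a period of ``s`` when
``s[0:n-p]`` and ``s[p:n]`` agree up to ``floor(max_error_frac * p)``
mismatches, and the read spans at least ``min_copies`` periods. The smallest
qualifying ``p`` wins, which suppresses harmonics (2p, 3p, ...).

The single-copy consensus is the per-column majority over all copies, with
ties broken toward the earliest copy. Rotation expansion then produces all
``p`` one-base cyclic shifts of the consensus, so that the shift matching
the genome's linear order can be identified by alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .records import RepeatUnit, RotationFamily, SequenceRecord
from .seq import hamming


@dataclass
class ExtractionParams:
    """Tandem-calling parameters.

    Defaults target the 20-100 nt small-RNA regime: periods between 16 and
    100 nt, an error budget of 10% of the period, and a requirement that the
    read spans at least 1.5 copies before a tandem call is made.
    """

    min_period: int = 16
    max_period: int = 100
    max_error_frac: float = 0.10
    min_copies: float = 1.5

    def __post_init__(self) -> None:
        if self.min_period < 1:
            raise ValueError("min_period must be >= 1")
        if self.max_period < self.min_period:
            raise ValueError("max_period must be >= min_period")
        if not 0 <= self.max_error_frac < 1:
            raise ValueError("max_error_frac must be in [0, 1)")
        if self.min_copies < 1:
            raise ValueError("min_copies must be >= 1")


def find_period(
    seq: str,
    min_period: int = 16,
    max_period: int = 100,
    max_error_frac: float = 0.10,
    min_copies: float = 1.5,
) -> Optional[int]:
    """Smallest tandem period of ``seq`` within the allowed range, or None.

    The candidate range is [min_period, min(max_period, floor(n/min_copies))]
    and a candidate ``p`` qualifies when the shifted self-comparison has at
    most ``floor(max_error_frac * p)`` mismatches.
    """
    if not seq:
        raise ValueError("find_period: empty sequence")
    n = len(seq)
    hi = min(max_period, int(n / min_copies))
    for p in range(min_period, hi + 1):
        cap = int(max_error_frac * p)
        if hamming(seq[: n - p], seq[p:], cap=cap) <= cap:
            return p
    return None


def build_consensus(seq: str, period: int) -> str:
    """Majority-vote consensus of the tandem copies of ``seq``.

    For unit position j the vote is over seq[j], seq[j+p], seq[j+2p], ...
    (a partial final copy contributes where present). Ties go to the base of
    the earliest copy among the tied candidates.
    """
    if not 1 <= period <= len(seq):
        raise ValueError("period out of range")
    out = []
    for j in range(period):
        column = seq[j::period]
        counts: dict[str, int] = {}
        for base in column:
            counts[base] = counts.get(base, 0) + 1
        best = max(counts.values())
        # earliest copy whose base attains the max count
        out.append(next(b for b in column if counts[b] == best))
    return "".join(out)


def extract_repeat_unit(
    rec: SequenceRecord, params: ExtractionParams | None = None
) -> Optional[RepeatUnit]:
    """Call the repeating unit of one read.

    Tandem reads yield a consensus unit with ``is_tandem=True``. A read in
    which no period is found passes through whole (``is_tandem=False``) when
    it is short enough to be a plausible single copy (length <= max_period);
    longer period-less reads are ambiguous and rejected (None).
    """
    params = params or ExtractionParams()
    seq = rec.seq
    p = find_period(
        seq,
        min_period=params.min_period,
        max_period=params.max_period,
        max_error_frac=params.max_error_frac,
        min_copies=params.min_copies,
    )
    if p is None:
        if len(seq) > params.max_period:
            return None
        return RepeatUnit(
            source_id=rec.id,
            unit=seq,
            period=len(seq),
            copies=1.0,
            mismatches=0,
            is_tandem=False,
        )
    consensus = build_consensus(seq, p)
    return RepeatUnit(
        source_id=rec.id,
        unit=consensus,
        period=p,
        copies=len(seq) / p,
        mismatches=hamming(seq[: len(seq) - p], seq[p:]),
        is_tandem=True,
    )


def expand_rotations(unit: RepeatUnit) -> RotationFamily:
    """All ``period`` one-base cyclic shifts of the unit (rotation k moves k
    bases from the 5' end to the 3' end)."""
    return RotationFamily.from_unit(unit)
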
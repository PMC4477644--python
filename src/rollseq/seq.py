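"""Low-level sequence utilities shared across the package.

All internal sequences are uppercase DNA over {A, C, G, T, N}; RNA input
(``U``) is normalized to ``T`` at ingest. ``N`` is treated as mismatching
everything, including another ``N``.
"""

from __future__ import annotations

import numpy as np

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# ASCII -> 2-bit code; anything that is not A/C/G/T (including N) maps to 4.
_CODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE_LUT[ord(_b)] = _i


def normalize(seq: str) -> str:
    """Uppercase and convert U to T. Idempotent."""
    return seq.upper().replace("U", "T")


def check_alphabet(seq: str, context: str = "sequence") -> None:
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"{context} contains invalid characters: {sorted(bad)}")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def rotate(seq: str, k: int) -> str:
    """Cyclic left rotation: rotate('ACGT', 1) == 'CGTA'."""
    k %= len(seq)
    return seq[k:] + seq[:k]


def hamming(a: str, b: str, cap: int | None = None) -> int:
    """Mismatch count between equal-length strings.

    A position counts as a mismatch when the characters differ or either is
    ``N``. With ``cap`` set, returns early with ``cap + 1`` as soon as the
    count exceeds it (callers only need the <= cap decision).
    """
    if len(a) != len(b):
        raise ValueError("hamming requires equal-length strings")
    m = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            m += 1
            if cap is not None and m > cap:
                return m
    return m


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array (A=0 C=1 G=2 T=3, N/other=4)."""
    return _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling base-4 codes for every k-mer of an encoded sequence.

    Returns ``(codes, valid)`` where ``valid[i]`` is False when the window
    contains an ambiguous base (such k-mers can never match exactly and are
    excluded from seeding).
    """
    n = enc.size
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    codes = np.zeros(m, dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + enc[j : j + m]
    cs = np.concatenate(([0], np.cumsum(enc == 4, dtype=np.int64)))
    valid = (cs[k:] - cs[:-k]) == 0
    return codes, valid


def mismatches_encoded(a: np.ndarray, b: np.ndarray) -> int:
    """Mismatch count between two encoded arrays; code 4 (N) mismatches all."""
    return int(np.count_nonzero((a != b) | (a == 4) | (b == 4)))
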
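"""Post-resolution analytics for rolling-circle CLIP libraries.

Covers terminal-base composition (ligase bias diagnostics), the per-read
mutation spectrum (the 4-SU chemistry leaves a diagnostic excess of T->C
transitions at protein-binding sites), a deterministic single-linkage
cluster builder with 10-bp binning, background-cluster subtraction against
a control library, the binned ln(count+1) replicate correlation, genomic
annotation of clusters against a GTF, and the positions-11-30 core
criterion used for the randomized 40-mer template.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import Cluster, ReconstructedRead, Reference
from .seq import hamming, revcomp

__all__ = [
    "terminal_base_profile",
    "MutationSpectrum",
    "mutation_spectrum",
    "build_clusters",
    "subtract_background",
    "replicate_r2",
    "core_mapped_fraction",
]

_BASES = ("A", "C", "G", "T")


def _seq_of(item) -> str:
    for attr in ("unit", "sequence", "seq"):
        s = getattr(item, attr, None)
        if s is not None:
            return s
    return str(item)


def terminal_base_profile(items: Iterable) -> pd.DataFrame:
    """Base fractions at the 5' and 3' termini.

    Accepts repeat units, reads, or plain strings. Returns a 4x2 table
    (rows A/C/G/T, columns ``5p``/``3p``); each column sums to 1.
    """
    seqs = [_seq_of(x) for x in items]
    if not seqs:
        raise ValueError("terminal_base_profile: empty input")
    counts = {b: [0, 0] for b in _BASES}
    for s in seqs:
        if s[0] in counts:
            counts[s[0]][0] += 1
        if s[-1] in counts:
            counts[s[-1]][1] += 1
    df = pd.DataFrame(counts, index=["5p", "3p"]).T.astype(float)
    return df / df.sum(axis=0)


@dataclass
class MutationSpectrum:
    """Counts of the 12 reference->read substitutions over aligned reads."""

    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    aligned_base_total: int = 0
    reads_with_t2c: int = 0
    unique_read_total: int = 0

    def count(self, ref_base: str, read_base: str) -> int:
        return self.counts.get((ref_base, read_base), 0)

    @property
    def t2c_read_fraction(self) -> float:
        if self.unique_read_total == 0:
            return 0.0
        return self.reads_with_t2c / self.unique_read_total

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"ref": r, "read": q, "count": self.counts.get((r, q), 0)}
            for r in _BASES
            for q in _BASES
            if r != q
        ]
        return pd.DataFrame(rows)


def mutation_spectrum(
    reads: Sequence[ReconstructedRead], reference: Reference
) -> MutationSpectrum:
    """Substitution spectrum of resolved reads against their mapped loci.

    Strand-aware: a minus-strand read is compared against the reverse
    complement of its reference window, so substitutions are reported in
    the read (RNA) sense — a 4-SU conversion on either strand appears as
    T->C, never as A->G. Positions involving N are skipped.
    """
    spec = MutationSpectrum()
    spec.unique_read_total = len(reads)
    for read in reads:
        ref_seg = reference.fetch(read.ref_name, read.start, read.end)
        if read.strand == "-":
            ref_seg = revcomp(ref_seg)
        has_t2c = False
        for rb, qb in zip(ref_seg, read.sequence):
            if rb == "N" or qb == "N":
                continue
            spec.aligned_base_total += 1
            if rb != qb:
                spec.counts[(rb, qb)] = spec.counts.get((rb, qb), 0) + 1
                if rb == "T" and qb == "C":
                    has_t2c = True
        if has_t2c:
            spec.reads_with_t2c += 1
    return spec


def _five_prime_end(read: ReconstructedRead) -> int:
    return read.start if read.strand == "+" else read.end - 1


def build_clusters(
    reads: Sequence[ReconstructedRead],
    max_gap: int = 0,
    bin_size: int = 10,
    t2c: Optional[Sequence[bool]] = None,
) -> list[Cluster]:
    """Single-linkage clustering of same-strand reads.

    Two reads join one cluster when ``next.start - current.end < max_gap``;
    the default 0 therefore requires strict interval overlap. Each read is
    counted in the ``bin_size``-bp bin (anchored at the cluster start)
    containing its 5' end. ``t2c`` optionally flags, per read, whether it
    carries at least one T->C conversion.
    """
    flags = list(t2c) if t2c is not None else [False] * len(reads)
    if len(flags) != len(reads):
        raise ValueError("t2c flags must align with reads")
    order = sorted(range(len(reads)), key=lambda i: (reads[i].ref_name, reads[i].strand, reads[i].start))
    clusters: list[Cluster] = []
    members: list[list[int]] = []
    for i in order:
        r = reads[i]
        # gap < max_gap; at the default 0 this reduces to strict overlap
        merge = bool(
            clusters
            and clusters[-1].ref_name == r.ref_name
            and clusters[-1].strand == r.strand
            and r.start - clusters[-1].end < max_gap
        )
        if merge:
            c = clusters[-1]
            c.end = max(c.end, r.end)
            c.read_count += 1
            c.t2c_reads += int(flags[i])
            members[-1].append(i)
        else:
            clusters.append(
                Cluster(
                    ref_name=r.ref_name,
                    start=r.start,
                    end=r.end,
                    strand=r.strand,
                    read_count=1,
                    t2c_reads=int(flags[i]),
                )
            )
            members.append([i])
    for c, idxs in zip(clusters, members):
        # bins run from the cluster start through the last bin holding a read
        # 5' end; trailing bins covered only by read bodies are not reported
        # (they can hold no tags and would only contribute empty pairs to the
        # replicate correlation)
        end_bins = [(_five_prime_end(reads[i]) - c.start) // bin_size for i in idxs]
        bins = [0] * (max(end_bins) + 1)
        for b in end_bins:
            bins[b] += 1
        c.bins = bins
    return clusters


def subtract_background(
    clusters: Sequence[Cluster], background: Sequence[Cluster]
) -> tuple[list[Cluster], int]:
    """Drop clusters overlapping (>= 1 bp, same strand) any background
    cluster — the control-library filter. Returns (kept, removed count)."""
    by_key: dict[tuple[str, str], list[Cluster]] = {}
    for b in background:
        by_key.setdefault((b.ref_name, b.strand), []).append(b)
    kept: list[Cluster] = []
    removed = 0
    for c in clusters:
        bgs = by_key.get((c.ref_name, c.strand), [])
        if any(b.start < c.end and c.start < b.end for b in bgs):
            removed += 1
        else:
            kept.append(c)
    return kept, removed


def replicate_r2(
    reads_a: Sequence[ReconstructedRead],
    reads_b: Sequence[ReconstructedRead],
    bin_size: int = 10,
    max_gap: int = 0,
) -> float:
    """Squared Pearson correlation of ln(count+1) per bin between replicates.

    Clusters are built on the union of both replicates' reads, binned from
    each cluster start, and per-replicate 5'-end counts are collected for
    every bin. Symmetric in its arguments; identical inputs give exactly 1.
    """
    union = list(reads_a) + list(reads_b)
    clusters = build_clusters(union, max_gap=max_gap, bin_size=bin_size)
    xs, ys = [], []
    for c in clusters:
        nbins = len(c.bins)
        ca = [0] * nbins
        cb = [0] * nbins
        for reads, counts in ((reads_a, ca), (reads_b, cb)):
            for r in reads:
                if r.ref_name == c.ref_name and r.strand == c.strand:
                    e = _five_prime_end(r)
                    if c.start <= e < c.end:
                        counts[(e - c.start) // bin_size] += 1
        xs.extend(ca)
        ys.extend(cb)
    if len(xs) < 2:
        raise ValueError("replicate_r2 needs at least 2 bins")
    lx = np.log(np.asarray(xs, dtype=float) + 1.0)
    ly = np.log(np.asarray(ys, dtype=float) + 1.0)
    if np.allclose(lx, ly):
        return 1.0
    r, _ = stats.pearsonr(lx, ly)
    return float(r * r)


def core_mapped_fraction(
    units: Iterable,
    core: str,
    window: tuple[int, int] = (10, 30),
    max_core_mismatch: int = 2,
) -> float:
    """Percentage of units carrying ``core`` (within ``max_core_mismatch``
    mismatches) at the 0-based half-open ``window`` — the positions-11-30
    (1-based) criterion of the randomized 40-mer analysis. Units shorter
    than the window count as misses."""
    start, end = window
    if len(core) != end - start:
        raise ValueError("core length must equal window length")
    seqs = [_seq_of(u) for u in units]
    if not seqs:
        raise ValueError("core_mapped_fraction: empty input")
    n_hit = 0
    for s in seqs:
        if len(s) >= end and hamming(s[start:end], core, cap=max_core_mismatch) <= max_core_mismatch:
            n_hit += 1
    return 100.0 * n_hit / len(seqs)
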
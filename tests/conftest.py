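"""Shared fixtures and oracles for the rollseq test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from rollseq import Cluster


def binom_interval(n: int, p: float, alpha: float = 1e-4) -> tuple[int, int]:
    """Two-sided binomial acceptance interval at confidence 1 - alpha."""
    lo = int(stats.binom.ppf(alpha / 2, n, p))
    hi = int(stats.binom.ppf(1 - alpha / 2, n, p))
    return lo, hi


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


# ---------------------------------------------------------------------------
# Synthetic 10-gene annotation with planted clusters of known category.

_GENE_SPAN = 6000
_GENE_STEP = 9000
_GENE0 = 3000


def _gene_start(i: int) -> int:
    return _GENE0 + i * _GENE_STEP


def write_test_gtf(path) -> None:
    """Ten coding genes on 'g1', alternating strands, three exons each."""
    lines = []
    for i in range(10):
        g = _gene_start(i)
        strand = "+" if i % 2 == 0 else "-"
        gid, tid = f"gene{i}", f"tx{i}"
        attrs = f'gene_id "{gid}"; transcript_id "{tid}";'
        exons = [(g, g + 500), (g + 2000, g + 2600), (g + 5000, g + 6000)]
        cds = [(g + 200, g + 500), (g + 2000, g + 2600), (g + 5000, g + 5400)]

        def row(feature, s, e):
            # 0-based half-open -> GTF 1-based inclusive
            return f"g1\ttest\t{feature}\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}"

        lines.append(row("gene", g, g + _GENE_SPAN))
        lines.append(row("transcript", g, g + _GENE_SPAN))
        for s, e in exons:
            lines.append(row("exon", s, e))
        for s, e in cds:
            lines.append(row("CDS", s, e))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def planted_annotation_clusters() -> tuple[list[Cluster], list[str]]:
    """100 clusters with known categories against the test GTF.

    Per gene: 2 CDS, 2 intron, 2 3'UTR, 2 5'UTR, 1 promoter; plus 10
    intergenic clusters in the gaps downstream of plus-strand genes.
    """

    def mk(s, e):
        return Cluster(ref_name="g1", start=s, end=e, strand="+", read_count=1)

    clusters: list[Cluster] = []
    truth: list[str] = []
    for i in range(10):
        g = _gene_start(i)
        plus = i % 2 == 0
        spots = [
            (g + 2200, "CDS"),
            (g + 2300, "CDS"),
            (g + 1200, "intron"),
            (g + 1400, "intron"),
            (g + 5600 if plus else g + 50, "utr3"),
            (g + 5700 if plus else g + 100, "utr3"),
            (g + 50 if plus else g + 5600, "utr5"),
            (g + 100 if plus else g + 5700, "utr5"),
            (g - 1000 if plus else g + 6500, "promoter"),
        ]
        for s, cat in spots:
            clusters.append(mk(s, s + 50))
            truth.append(cat)
    for i in range(0, 10, 2):
        g = _gene_start(i)
        for off in (7000, 7100):
            clusters.append(mk(g + off, g + off + 50))
            truth.append("intergenic")
    return clusters, truth


@pytest.fixture(scope="session")
def annotation_fixture(tmp_path_factory):
    path = tmp_path_factory.mktemp("gtf") / "genes.gtf"
    write_test_gtf(path)
    clusters, truth = planted_annotation_clusters()
    return path, clusters, truth
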
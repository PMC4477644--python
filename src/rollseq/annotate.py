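"""Genomic annotation of clusters against a GTF.

Each cluster receives exactly one category by a fixed priority:

    CDS > 3'UTR > 5'UTR > intron > promoter > intergenic

Assignment is by >= 1 bp overlap and is strand-agnostic (a binding cluster
may sit on either strand of an annotated gene). UTRs are derived per
transcript as the exonic regions outside the CDS extent, split into 5'/3'
by transcript strand; "intron" covers any remaining gene-body overlap
(including non-coding exonic sequence); the promoter is the 2 kb window
upstream of the transcription start site.
"""

from __future__ import annotations

from typing import Sequence

import gffutils
import pandas as pd

from .records import Cluster

CATEGORIES = ("CDS", "utr3", "utr5", "intron", "promoter", "intergenic")

PROMOTER_WINDOW = 2000


class GtfParseError(ValueError):
    pass


def _validate_gtf(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GtfParseError(f"line {lineno}: expected 9 tab-separated fields")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise GtfParseError(f"line {lineno}: invalid coordinate range")


Interval = tuple[str, int, int]  # (chrom, start, end) 0-based half-open


def _to_interval(feature) -> Interval:
    # GTF is 1-based inclusive; internal coordinates are 0-based half-open.
    return (feature.seqid, feature.start - 1, feature.end)


def _subtract(span: tuple[int, int], holes: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Pieces of span not covered by the (sorted, merged) holes."""
    out = []
    cur = span[0]
    for hs, he in sorted(holes):
        if he <= cur:
            continue
        if hs >= span[1]:
            break
        if hs > cur:
            out.append((cur, min(hs, span[1])))
        cur = max(cur, he)
    if cur < span[1]:
        out.append((cur, span[1]))
    return out


class AnnotationIndex:
    """Category interval lists extracted from a GTF, ready for lookup."""

    def __init__(self, gtf_path):
        _validate_gtf(gtf_path)
        db = gffutils.create_db(
            str(gtf_path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        self.intervals: dict[str, list[Interval]] = {c: [] for c in CATEGORIES[:-1]}
        for gene in db.features_of_type("gene"):
            chrom, gstart, gend = _to_interval(gene)
            self.intervals["intron"].append((chrom, gstart, gend))
            if gene.strand == "-":
                self.intervals["promoter"].append((chrom, gend, gend + PROMOTER_WINDOW))
            else:
                self.intervals["promoter"].append((chrom, max(0, gstart - PROMOTER_WINDOW), gstart))
        for tx in db.features_of_type("transcript"):
            chrom = tx.seqid
            exons = [(_to_interval(e)[1], _to_interval(e)[2]) for e in db.children(tx, featuretype="exon")]
            cds = [(_to_interval(c)[1], _to_interval(c)[2]) for c in db.children(tx, featuretype="CDS")]
            for s, e in cds:
                self.intervals["CDS"].append((chrom, s, e))
            if not cds:
                continue
            cds_lo = min(s for s, _ in cds)
            cds_hi = max(e for _, e in cds)
            for ex in exons:
                for s, e in _subtract(ex, [(cds_lo, cds_hi)]):
                    if e <= cds_lo:
                        side_5p = tx.strand != "-"
                    else:
                        side_5p = tx.strand == "-"
                    self.intervals["utr5" if side_5p else "utr3"].append((chrom, s, e))

    def category_of(self, chrom: str, start: int, end: int) -> str:
        for cat in CATEGORIES[:-1]:
            for c, s, e in self.intervals[cat]:
                if c == chrom and s < end and start < e:
                    return cat
        return "intergenic"


def assign_cluster_categories(
    clusters: Sequence[Cluster], gtf_path
) -> list[str]:
    ann = gtf_path if isinstance(gtf_path, AnnotationIndex) else AnnotationIndex(gtf_path)
    return [ann.category_of(c.ref_name, c.start, c.end) for c in clusters]


def annotate_clusters(clusters: Sequence[Cluster], gtf_path) -> pd.DataFrame:
    """Category counts and fractions over the clusters; counts sum to the
    number of clusters."""
    cats = assign_cluster_categories(clusters, gtf_path)
    counts = {c: 0 for c in CATEGORIES}
    for c in cats:
        counts[c] += 1
    n = max(len(cats), 1)
    return pd.DataFrame(
        {
            "category": list(CATEGORIES),
            "count": [counts[c] for c in CATEGORIES],
            "fraction": [counts[c] / n for c in CATEGORIES],
        }
    )
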
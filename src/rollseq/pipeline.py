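"""End-to-end pipeline: merge -> units -> resolve -> qc, with a manifest.

Every stage records reads in / reads out / rejects, so read-count
conservation can be checked at each boundary. A single top-level seed is
expanded into independent per-stage streams via ``numpy`` seed sequences,
so stages can be re-run in isolation with identical results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .io import read_fasta, read_fastq, write_bed, write_fastq
from .mapping import KmerIndex, resolve_family
from .merge import MergePolicy, merge_pair
from .qc import build_clusters, mutation_spectrum, terminal_base_profile
from .records import ReconstructedRead
from .tandem import ExtractionParams, expand_rotations, extract_repeat_unit

logger = logging.getLogger("rollseq")


@dataclass
class PipelineConfig:
    """All pipeline parameters; unknown keys in a config file are rejected."""

    r1: str = ""
    r2: Optional[str] = None
    reference: str = ""
    outdir: str = "rollseq_out"
    min_overlap: int = 10
    max_mismatch_rate: float = 0.25
    min_period: int = 16
    max_period: int = 100
    max_error_frac: float = 0.10
    min_copies: float = 1.5
    k: int = 12
    max_mismatch: int = 2
    max_span: Optional[int] = None
    max_gap: int = 0
    bin_size: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def stage_seed(self, stage_index: int) -> int:
        children = np.random.SeedSequence(self.seed).spawn(8)
        return int(children[stage_index].generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages, writing artifacts and a manifest under ``outdir``.

    Returns the manifest (also written as JSON). Counts are conserved at
    every boundary: in = out + rejected.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}}

    # --- merge -----------------------------------------------------------
    reads = []
    if config.r2:
        policy = MergePolicy(
            min_overlap=config.min_overlap, max_mismatch_rate=config.max_mismatch_rate
        )
        pairs = list(zip(read_fastq(config.r1), read_fastq(config.r2)))
        merged, unmerged = [], []
        for r1, r2 in pairs:
            m = merge_pair(r1, r2, policy)
            if m is None:
                unmerged.append((r1, r2))
                reads.append(r1)  # mate 1 proceeds alone
            else:
                merged.append(m)
                reads.append(m)
        write_fastq(merged, out / "merged.fastq")
        write_fastq((r1 for r1, _ in unmerged), out / "unmerged_1.fastq")
        write_fastq((r2 for _, r2 in unmerged), out / "unmerged_2.fastq")
        manifest["stages"]["merge"] = {
            "pairs_in": len(pairs),
            "merged": len(merged),
            "unmerged": len(unmerged),
        }
        logger.info("merge: %d pairs -> %d merged, %d unmerged", len(pairs), len(merged), len(unmerged))
    else:
        reads = list(read_fastq(config.r1))
        manifest["stages"]["merge"] = {"pairs_in": 0, "merged": 0, "unmerged": 0, "single_end": len(reads)}

    # --- unit extraction -------------------------------------------------
    params = ExtractionParams(
        min_period=config.min_period,
        max_period=config.max_period,
        max_error_frac=config.max_error_frac,
        min_copies=config.min_copies,
    )
    units, unit_rejects = [], []
    for rec in reads:
        u = extract_repeat_unit(rec, params)
        if u is None:
            unit_rejects.append((rec.id, "ambiguous"))
        else:
            units.append(u)
    write_units_tsv(units, out / "units.tsv")
    with open(out / "unit_rejects.tsv", "w") as fh:
        fh.write("read_id\treason\n")
        for rid, reason in unit_rejects:
            fh.write(f"{rid}\t{reason}\n")
    manifest["stages"]["units"] = {
        "reads_in": len(reads),
        "units_out": len(units),
        "rejected": len(unit_rejects),
    }

    # --- resolution ------------------------------------------------------
    reference = read_fasta(config.reference)
    index = KmerIndex(reference, k=config.k)
    resolved: list[ReconstructedRead] = []
    reject_counts: dict[str, int] = {}
    with open(out / "resolve_rejects.tsv", "w") as fh:
        fh.write("family_id\treason\n")
        for u in units:
            res = resolve_family(
                expand_rotations(u), index,
                max_mismatch=config.max_mismatch, max_span=config.max_span,
            )
            if isinstance(res, ReconstructedRead):
                resolved.append(res)
            else:
                reject_counts[res.reason] = reject_counts.get(res.reason, 0) + 1
                fh.write(f"{res.family_id}\t{res.reason}\n")
    write_bed(
        [(r.ref_name, r.start, r.end, r.family_id, r.mismatches, r.strand) for r in resolved],
        out / "resolved.bed",
    )
    write_resolved_tsv(resolved, out / "resolved.tsv")
    manifest["stages"]["resolve"] = {
        "families_in": len(units),
        "accepted": len(resolved),
        "rejected": sum(reject_counts.values()),
        "rejected_by_reason": reject_counts,
    }

    # --- qc --------------------------------------------------------------
    if resolved:
        terminal_base_profile(resolved).to_csv(out / "terminal_profile.tsv", sep="\t")
        mutation_spectrum(resolved, reference).to_frame().to_csv(
            out / "mutation_spectrum.tsv", sep="\t", index=False
        )
        clusters = build_clusters(resolved, max_gap=config.max_gap, bin_size=config.bin_size)
        write_bed(
            [(c.ref_name, c.start, c.end, ".", c.read_count, c.strand) for c in clusters],
            out / "clusters.bed",
        )
        manifest["stages"]["qc"] = {
            "reads_in": len(resolved),
            "clusters": len(clusters),
            "cluster_read_total": sum(c.read_count for c in clusters),
        }
    else:
        manifest["stages"]["qc"] = {"reads_in": 0, "clusters": 0, "cluster_read_total": 0}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def write_units_tsv(units, path) -> None:
    with open(path, "w") as fh:
        fh.write("source_id\tunit\tperiod\tcopies\tmismatches\tis_tandem\n")
        for u in units:
            fh.write(
                f"{u.source_id}\t{u.unit}\t{u.period}\t{u.copies:.3f}\t"
                f"{u.mismatches}\t{int(u.is_tandem)}\n"
            )


def read_units_tsv(path):
    from .records import RepeatUnit

    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("source_id"):
            raise ValueError(f"{path}: not a units TSV")
        for line in fh:
            sid, unit, period, copies, mism, tandem = line.rstrip("\n").split("\t")
            out.append(
                RepeatUnit(
                    source_id=sid, unit=unit, period=int(period),
                    copies=float(copies), mismatches=int(mism), is_tandem=bool(int(tandem)),
                )
            )
    return out


def write_resolved_tsv(reads, path) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\trotation_index\tsequence\tref_name\tstart\tend\tstrand\tmismatches\n")
        for r in reads:
            fh.write(
                f"{r.family_id}\t{r.rotation_index}\t{r.sequence}\t{r.ref_name}\t"
                f"{r.start}\t{r.end}\t{r.strand}\t{r.mismatches}\n"
            )


def read_resolved_tsv(path) -> list[ReconstructedRead]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("family_id"):
            raise ValueError(f"{path}: not a resolved TSV")
        for line in fh:
            fid, rot, seq, ref, start, end, strand, mism = line.rstrip("\n").split("\t")
            out.append(
                ReconstructedRead(
                    family_id=fid, rotation_index=int(rot), sequence=seq,
                    ref_name=ref, start=int(start), end=int(end),
                    strand=strand, mismatches=int(mism),
                )
            )
    return out
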
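# Methods

## The deconvolution problem

A self-circularized small RNA is reverse-transcribed by rolling-circle
amplification, so a sequencing read is (up to sequencing error) a tandem
repetition of the original molecule. Two things are lost relative to an
ordinary library: the copy boundaries, and the rotation phase — the random
primer may anneal anywhere on the circle, so the read begins at an
arbitrary cyclic shift of the molecule. Direct alignment of such reads to
a linear reference fails except in the measure-zero case where the phase
is 0 and the read happens to begin with a full copy. The pipeline
therefore (1) collapses the read to its single-copy repeating unit,
(2) enumerates all cyclic rotations of that unit, and (3) lets alignment
identify the rotation that matches the reference's linear order.

## Period calling and consensus

The period of read *s* (length *n*) is the smallest
*p* ∈ [`min_period`, min(`max_period`, ⌊n/`min_copies`⌋)] whose shifted
self-comparison `s[0:n−p]` vs `s[p:n]` contains at most
⌊`max_error_frac`·p⌋ mismatches. Choices and rationale:

* **Smallest qualifying p wins** — suppresses harmonics (2p, 3p) of the
  true period.
* **Error budget ⌊0.10·p⌋** — 10% of the unit length, applied to the whole
  shifted comparison; configurable.
* **`min_copies` = 1.5** — a read must span one and a half units before a
  tandem call is trusted; below that the self-comparison covers less than
  half a unit and is uninformative.
* **Defaults `min_period` = 16, `max_period` = 100** — the 20–100 nt
  small-RNA/CLIP fragment regime. A period-less read short enough to be a
  single copy (≤ `max_period`) passes through whole with
  `is_tandem = False`; longer period-less reads are ambiguous and are
  rejected with a reason code, never silently dropped.
* **Consensus** — per-column majority over the copies (the partial last
  copy votes where present); ties go to the earliest copy. With ≥ 3 copies
  this corrects isolated sequencing errors; with 2 copies a disagreement
  falls back to the first copy observed.

The mismatch-only error model runs through the whole package: the aligner
is ungapped, and the period caller tolerates substitutions but not indels.
Reads with indels (rare on the Illumina platforms this library design
targets) fail the convergence filter rather than producing wrong loci.

## Expanded alignment

The built-in aligner is a seed-and-verify ungapped mapper: an exact k-mer
index of the forward reference (default k = 12), queries seeded at every
k-mer of the query and of its reverse complement, candidates verified by
direct mismatch counting, all placements with ≤ `max_mismatch` (default 2)
reported, coordinates always forward-reference. Discovery is guaranteed
when some k-mer window of the query must be error-free (query length ≥
(max_mismatch+1)·k); shorter queries are found whenever one exact seed
survives, which is the practical regime on the synthetic references used
in testing. `N` mismatches everything, including another `N`.

A rotation is **uniquely aligned** iff exactly one location attains its
minimal mismatch count — a second location tying the best count voids
uniqueness. A family is accepted iff all its uniquely aligned rotations
**converge**: same reference, same strand, and start span at most
`max_span` (default: one unit period — rotations of a true locus start
within one period of each other). Among converged unique hits the
representative is the one with fewest mismatches, ties broken by leftmost
start, then lowest rotation index, for full determinism.

Genome-scale or spliced alignment is delegated to an external aligner:
`export-rotations` writes every rotation as FASTA with query names
`<family>|rot<k>`, and the SAM import path re-derives per-rotation
uniqueness as "exactly one record attains the minimal NM for that query" —
the same rule as the built-in aligner, so exporting the built-in hits and
re-importing them reproduces the identical resolution.

### Boundary ambiguity of circular molecules

When the genome base flanking a fragment happens to extend its cyclic
pattern (probability 1/4 per side on a uniform random genome), the
neighbouring rotation also aligns perfectly, one base over. The original
molecule's boundary is then intrinsically undecidable from sequence alone:
the accepted representative is a cyclic shift of the truth at the same
locus. Benchmarks therefore score correctness as *mapping to the recorded
origin* (same reference, strand and length, overlapping interval); exact
boundary recovery is only a well-posed question for fragments whose flanks
do not extend the pattern, and for those it is achieved exactly.

### Small-reference caveat

On small references (~1 Mb) with short units (~20 nt) and a 2-mismatch
tolerance, a junction-crossing rotation occasionally has a single chance
placement elsewhere in the genome. That lone placement is, by definition,
uniquely aligned, and it vetoes the convergence check, rejecting an
otherwise perfectly resolvable family (measured: ~1.5% of 20-nt families
on a 1 Mb genome; 0% at 40 nt and above). The effect shrinks as the
reference grows — on a gigabase genome a random 20-mer has many chance
placements, so junction rotations multi-map and are dropped as non-unique
instead of vetoing the family. This is a known limitation of the strict
convergence rule at small reference scale, kept deliberately: relaxing the
rule would weaken the uniqueness guarantees at the scale the method is
actually used.

## Read merging

Overlap merging scans candidate overlaps from the longest feasible down to
`min_overlap` (default 10 nt) between mate 1's 3′ end and the reverse
complement of mate 2, accepting the longest overlap with mismatch fraction
≤ `max_mismatch_rate` (default 0.25). Disagreeing bases take the
higher-quality call, ties the mate-1 base; the merged quality is the
per-base maximum inside the overlap. Only the minimum overlap is a
protocol constant; the mismatch tolerance and longest-first search are
merger conventions made explicit and configurable. Unmerged pairs are not
discarded: mate 1 proceeds alone through unit extraction.

## Synthetic data

The generators are pure functions of (parameters, seed):

* `make_genome(length, gc, seed)` — i.i.d. bases, P(G)+P(C) = gc.
* `sample_fragments` — uniform intervals, uniform strand, origins recorded
  as truth records (fragments reported in RNA sense).
* `rca_read(fragment, phase, read_len, per_base_error)` — rotate, tile,
  truncate the last copy, then i.i.d. substitutions uniform over the three
  alternatives. Substitution-only, matching the ungapped pipeline.
* `make_core40(seed)` — two random 10-mers flanking the fixed 20-nt core
  `TGAGGTAGTAGGTTGTATAG` (DNA form), i.e. the partially randomized 40-mer
  spike-in template.
* `inject_t2c(seq, rate, seed)` — each T independently becomes C with the
  given probability (4-SU photo-crosslinking chemistry), applied in RNA
  sense.

**Study conditions.** The randomized-template experiment uses 5000 reads,
phase uniform on [0, 40), read length uniform on [120, 190] nt (two 100-nt
mates merged with overlap), and 0.5% per-base error. The genome benchmark
uses fragment lengths {20, 40, 60, 80, 100} nt with recorded origins; read
lengths are drawn as copies × fragment length with copies uniform on
[2.0, 3.0], because a fixed 120–190 nt window cannot supply the ≥ 1.5
copies the period caller requires for 100-nt fragments. The benchmark's
per-base error defaults to 0 (the in-silico circularization itself is
noise-free; error robustness is exercised separately by the template
experiment and the consensus tests).

**What the simulations do not model:** indels, quality-score profiles,
position-dependent error rates, PCR duplicates and amplification bias,
ligation sequence preferences, and genome repeat structure beyond what a
uniform random sequence contains. Passing benchmarks on synthetic genomes
therefore demonstrate the correctness of the deconvolution logic, not
performance on repeat-rich real genomes — for that, the external-aligner
path at full genome scale is the relevant experiment
(see `hg19_benchmark.md`).

## QC analytics

* **Terminal-base profile** — base fractions at the first and last
  position of the reconstructed units; a diagnostic for ligase base
  preference.
* **Mutation spectrum** — strand-aware comparison of each resolved read
  against its mapped reference window (minus-strand reads against the
  reverse complement), reported in read sense so a 4-SU conversion is
  always T→C. Positions involving `N` are skipped.
* **Clusters** — deterministic single-linkage merging of same-strand reads
  whose gap is < `max_gap` (default 0 ⇒ strict overlap). Each read is
  counted in the 10-bp bin (anchored at the cluster start) containing its
  5′ end; bins run through the last bin holding a 5′ end — trailing bins
  covered only by read bodies can hold no tags and would contribute only
  empty pairs to the replicate correlation. A statistical peak caller can
  be slotted in downstream; the T→C tallies per cluster are exposed for
  that purpose.
* **Background subtraction** — clusters overlapping (≥ 1 bp, same strand)
  any cluster of a control library are removed, with the removed count
  reported.
* **Replicate R²** — clusters are built on the union of both replicates'
  reads, per-bin 5′-end counts are collected per replicate, and R² is the
  squared Pearson correlation of ln(count+1) over all bins. Identical
  inputs give exactly 1.0; the statistic is symmetric. Note R² of binned
  counts is attenuated by Poisson noise at finite depth, so even perfect
  replicates of a common intensity field sit below 1.
* **Annotation** — one category per cluster by fixed priority
  CDS > 3′UTR > 5′UTR > intron > promoter > intergenic, assignment by
  ≥ 1 bp overlap, strand-agnostic. UTRs are derived per transcript as
  exonic sequence outside the CDS extent, split 5′/3′ by transcript
  strand; any other gene-body overlap (including non-coding exonic
  sequence) counts as intron; the promoter is the 2 kb window upstream of
  the TSS. The priority order and promoter window are conventions, stated
  here because annotation pictures depend on them.

## Pipeline

`run_pipeline` chains merge → units → resolve → qc, writing each stage's
artifact plus a JSON manifest with per-stage in/out/reject counts; read
counts are conserved at every boundary (in = out + rejected). A single
config seed expands into independent per-stage seeds via numpy seed
sequences. Config files reject unknown keys.

## Numerical and scale choices

Tests and benchmarks are sized to run on one CPU in minutes: the
template experiment at its full 5000 reads, the genome benchmark at 1 Mb /
2000 fragments per group in the acceptance suite (reduced in the example
script), property suites at 100 kb genome / 1000 planted reads. The
alignment oracle used in tests is an exhaustive sliding-window scan of
every offset and strand, compared in the regime (query ≥ 3k) where the
seeded aligner's discovery is provably complete.
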
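"""Expanded alignment: seeded aligner, convergence, representative choice."""

import numpy as np
import pytest

from rollseq import (
    AlignmentHit,
    KmerIndex,
    ReconstructedRead,
    Reference,
    Rejection,
    RepeatUnit,
    RotationFamily,
    align_ungapped,
    check_convergence,
    expand_rotations,
    extract_repeat_unit,
    make_genome,
    rca_read,
    resolve_family,
    resolve_from_sam,
    revcomp,
    select_representative,
    write_sam,
)
from rollseq.seq import encode


def brute_force_hits(query, reference, max_mismatch):
    """Scan every offset on both strands of every sequence — the alignment
    oracle (N mismatches everything)."""
    out = set()
    L = len(query)
    for name in reference.names:
        g = encode(reference[name])
        if g.size < L:
            continue
        win = np.lib.stride_tricks.sliding_window_view(g, L)
        for strand, q in (("+", query), ("-", revcomp(query))):
            qe = encode(q)
            mism = ((win != qe) | (win == 4) | (qe == 4)).sum(axis=1)
            for s in np.nonzero(mism <= max_mismatch)[0]:
                out.add((name, int(s), strand, int(mism[s])))
    return out


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestKmerIndex:
    def test_small_k_example(self):
        ref = Reference([("c1", "ACGTACGTAC")])
        idx = KmerIndex(ref, k=4)
        hits = align_ungapped("ACGT", idx, max_mismatch=0)
        assert {(h.start, h.strand) for h in hits} == {(0, "+"), (4, "+"), (0, "-"), (4, "-")}
        assert not any(h.unique for h in hits)  # palindromic + duplicated

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            Reference([("c1", "")])

    def test_query_shorter_than_k_errors(self):
        idx = KmerIndex(Reference([("c1", "ACGTACGTACGTACGT")]), k=12)
        with pytest.raises(ValueError, match="< k"):
            align_ungapped("ACGT", idx)

    def test_sampled_kmers_found_at_source(self, rng):
        g = make_genome(100_000, seed=21)
        idx = KmerIndex(g, k=12)
        seq = g["chr1"]
        for _ in range(50):
            s = int(rng.integers(0, len(seq) - 20))
            hits = align_ungapped(seq[s : s + 20], idx, max_mismatch=0)
            assert any(h.start == s and h.strand == "+" for h in hits)


class TestAlignUngapped:
    def test_planted_once_unique(self):
        rng = np.random.default_rng(31)
        g = make_genome(100_000, seed=31)
        q = _rand_seq(rng, 30)
        seq = g["chr1"][:50_000] + q + g["chr1"][50_000:]
        idx = KmerIndex(Reference([("c1", seq)]), k=12)
        hits = align_ungapped(q, idx, max_mismatch=2)
        best = [h for h in hits if h.mismatches == 0]
        assert len(best) == 1 and best[0].start == 50_000 and best[0].unique

    def test_planted_twice_not_unique(self):
        rng = np.random.default_rng(32)
        g = make_genome(100_000, seed=32)["chr1"]
        q = _rand_seq(rng, 30)
        seq = g[:30_000] + q + g[30_000:60_000] + q + g[60_000:]
        idx = KmerIndex(Reference([("c1", seq)]), k=12)
        hits = align_ungapped(q, idx, max_mismatch=2)
        exact = [h for h in hits if h.mismatches == 0]
        assert len(exact) == 2 and not any(h.unique for h in hits)

    def test_two_mismatch_locus_found_when_length_ge_3k(self):
        rng = np.random.default_rng(33)
        g = make_genome(50_000, seed=33)
        idx = KmerIndex(g, k=12)
        s = 17_000
        q = list(g["chr1"][s : s + 36])
        for i in (5, 30):
            q[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[i]]
        hits = align_ungapped("".join(q), idx, max_mismatch=2)
        assert any(h.start == s and h.mismatches == 2 and h.strand == "+" for h in hits)

    def test_equals_brute_force_oracle(self):
        """Hit-set equality with an exhaustive scan, in the guaranteed-
        sensitivity regime (query length >= 3k, <= 2 mismatches)."""
        rng = np.random.default_rng(34)
        g = make_genome(20_000, seed=34)
        idx = KmerIndex(g, k=12)
        seq = g["chr1"]
        for trial in range(30):
            L = int(rng.integers(36, 61))
            s = int(rng.integers(0, len(seq) - L))
            q = list(seq[s : s + L])
            for _ in range(int(rng.integers(0, 3))):
                i = int(rng.integers(0, L))
                q[i] = "ACGT"[int(rng.integers(0, 4))]
            q = "".join(q)
            if trial % 2:
                q = revcomp(q)
            got = {
                (h.ref_name, h.start, h.strand, h.mismatches)
                for h in align_ungapped(q, idx, max_mismatch=2)
            }
            assert got == brute_force_hits(q, g, 2)


class TestConvergence:
    def test_shifted_starts_within_span(self):
        hits = [
            AlignmentHit("f", k, "c1", 100 + k, 120 + k, "+", k, unique=True)
            for k in range(3)
        ]
        assert check_convergence(hits, max_span=20)

    def test_different_references_fail(self):
        hits = [
            AlignmentHit("f", 0, "c1", 100, 120, "+", 0, unique=True),
            AlignmentHit("f", 1, "c2", 100, 120, "+", 0, unique=True),
        ]
        assert not check_convergence(hits, max_span=20)

    def test_single_hit_converges_and_empty_does_not(self):
        h = AlignmentHit("f", 0, "c1", 5, 25, "-", 0, unique=True)
        assert check_convergence([h], max_span=20)
        assert not check_convergence([], max_span=20)


class TestSelectRepresentative:
    def _family(self):
        unit = RepeatUnit("f", "ACGTACGTACGTACGT", 16, 2.0, 0, True)
        return expand_rotations(unit)

    def test_lowest_mismatches_wins(self):
        fam = self._family()
        hits = [
            AlignmentHit("f", 0, "c1", 102, 118, "+", 2, True),
            AlignmentHit("f", 1, "c1", 100, 116, "+", 0, True),
            AlignmentHit("f", 2, "c1", 101, 117, "+", 1, True),
        ]
        rep = select_representative(fam, hits)
        assert rep.rotation_index == 1 and rep.mismatches == 0

    def test_ties_break_leftmost_then_rotation(self):
        fam = self._family()
        hits = [
            AlignmentHit("f", 3, "c1", 100, 116, "+", 0, True),
            AlignmentHit("f", 1, "c1", 100, 116, "+", 0, True),
            AlignmentHit("f", 2, "c1", 101, 117, "+", 0, True),
        ]
        rep = select_representative(fam, hits)
        assert rep.start == 100 and rep.rotation_index == 1


def _unambiguous_fragment(genome_seq, rng, L, n_try=200):
    """A fragment whose flanking genome bases do not cyclically extend it,
    so exact-boundary recovery is well-posed."""
    for _ in range(n_try):
        s = int(rng.integers(1, len(genome_seq) - L - 1))
        frag = genome_seq[s : s + L]
        if genome_seq[s - 1] != frag[-1] and genome_seq[s + L] != frag[0]:
            return s, frag
    raise AssertionError("no unambiguous fragment found")


class TestResolveFamily:
    def test_error_free_family_recovers_exact_truth(self):
        g = make_genome(200_000, seed=41)
        idx = KmerIndex(g, k=12)
        rng = np.random.default_rng(41)
        n_ok = 0
        for i in range(50):
            s, frag = _unambiguous_fragment(g["chr1"], rng, 40)
            read = rca_read(frag, phase=int(rng.integers(0, 40)), read_len=120, seed=rng, read_id=f"f{i}")
            unit = extract_repeat_unit(read)
            res = resolve_family(expand_rotations(unit), idx)
            assert isinstance(res, ReconstructedRead)
            assert res.sequence == frag and res.start == s and res.strand == "+"
            n_ok += 1
        assert n_ok == 50

    def test_duplicated_locus_rejected_no_unique(self):
        # duplicate the fragment together with flanking context so that every
        # rotation (junction-crossing ones included) ties at both loci
        rng = np.random.default_rng(42)
        g = make_genome(100_000, seed=42)["chr1"]
        block = _rand_seq(rng, 40 + 80)  # fragment plus 40 nt context each side
        frag = block[40:80]
        seq = g[:20_000] + block + g[20_000:60_000] + block + g[60_000:]
        idx = KmerIndex(Reference([("c1", seq)]), k=12)
        read = rca_read(frag, phase=5, read_len=120, seed=1)
        res = resolve_family(expand_rotations(extract_repeat_unit(read)), idx)
        assert isinstance(res, Rejection) and res.reason == "no_unique"

    def test_unalignable_family_rejected_no_hit(self):
        g = make_genome(50_000, seed=43)
        idx = KmerIndex(g, k=12)
        # a unit absent from the genome: rotations align nowhere
        unit = RepeatUnit("f", "A" * 40, 40, 3.0, 0, True)
        res = resolve_family(expand_rotations(unit), idx, max_mismatch=2)
        assert isinstance(res, Rejection) and res.reason == "no_hit"

    def test_cyclic_extension_yields_shifted_convergent_hits(self):
        """When flanking bases extend the cyclic pattern, neighbouring
        rotations align at s-1 and s+1; the family still converges."""
        rng = np.random.default_rng(44)
        core = _rand_seq(rng, 38)
        frag = core[-1] + core + core[0]  # frag[0] == genome[s-1+... construction below
        L = len(frag)
        left = _rand_seq(rng, 3000) + frag[-1]
        right = frag[0] + _rand_seq(rng, 3000)
        seq = left + frag + right
        s = len(left)
        idx = KmerIndex(Reference([("c1", seq)]), k=12)
        fam = expand_rotations(RepeatUnit("f", frag, L, 3.0, 0, True))
        hits = []
        for k, rot in enumerate(fam.rotations):
            hits += align_ungapped(rot, idx, 2, family_id="f", rotation_index=k)
        uniq = [h for h in hits if h.unique and h.mismatches == 0]
        starts = {h.start for h in uniq}
        assert {s - 1, s, s + 1} <= starts
        assert check_convergence([h for h in hits if h.unique], max_span=L)
        res = resolve_family(fam, idx)
        assert isinstance(res, ReconstructedRead)


class TestSamRoundTrip:
    def test_export_reimport_identical_resolution(self, tmp_path):
        g = make_genome(100_000, seed=51)
        idx = KmerIndex(g, k=12)
        rng = np.random.default_rng(51)
        families = {}
        all_hits = []
        seqs = {}
        for i in range(20):
            s = int(rng.integers(0, 99_000))
            frag = g["chr1"][s : s + 40]
            read = rca_read(frag, phase=int(rng.integers(0, 40)), read_len=110, seed=rng, read_id=f"fam{i}")
            unit = extract_repeat_unit(read)
            fam = expand_rotations(unit)
            families[fam.family_id] = fam
            for k, rot in enumerate(fam.rotations):
                hits = align_ungapped(rot, idx, 2, family_id=fam.family_id, rotation_index=k)
                all_hits += hits
                seqs[(fam.family_id, k)] = rot
        direct = {}
        for fid, fam in families.items():
            res = resolve_family(fam, idx)
            if isinstance(res, ReconstructedRead):
                direct[fid] = (res.rotation_index, res.ref_name, res.start, res.strand, res.mismatches)
        sam = tmp_path / "rot.sam"
        write_sam(all_hits, g, sam, sequences=seqs)
        resolved, rejected = resolve_from_sam(sam, families)
        via_sam = {
            r.family_id: (r.rotation_index, r.ref_name, r.start, r.strand, r.mismatches)
            for r in resolved
        }
        assert via_sam == direct

    def test_query_with_two_records_not_unique(self, tmp_path):
        g = Reference([("c1", "ACGTACGTACGTACGTACGTACGTACGT")])
        unit = RepeatUnit("f", "ACGTACGTACGTACGT", 16, 2.0, 0, True)
        fam = expand_rotations(unit)
        hits = [
            AlignmentHit("f", 0, "c1", 0, 16, "+", 0),
            AlignmentHit("f", 0, "c1", 4, 20, "+", 0),
        ]
        sam = tmp_path / "two.sam"
        write_sam(hits, g, sam)
        resolved, rejected = resolve_from_sam(sam, {"f": fam})
        assert resolved == [] and rejected[0].reason == "no_unique"

    def test_family_without_records_rejected_no_hit(self, tmp_path):
        g = Reference([("c1", "ACGTACGTACGTACGTACGT")])
        fam = expand_rotations(RepeatUnit("f", "AACCGGTTAACCGGTT", 16, 2.0, 0, True))
        sam = tmp_path / "empty.sam"
        write_sam([], g, sam)
        resolved, rejected = resolve_from_sam(sam, {"f": fam})
        assert resolved == [] and rejected[0].reason == "no_hit"
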
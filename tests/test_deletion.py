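"""Coverage gaps, junction assembly, deletion calling and in-silico PCR."""

import numpy as np
import pytest

import seedless as sl
from seedless.deletion import (
    AssemblyFailure,
    discover_deletion,
    junction_report,
    read_fasta,
    read_sam,
    reverse_complement,
    write_deletion_vcf,
    write_fasta,
    write_sam,
)
from seedless.errors import (
    AmbiguousAnchorError,
    AnchorError,
    ComparabilityError,
    StructuralError,
)


def make_ref(seq, name="ref"):
    return sl.ReferenceSeq(name, seq)


def rand_seq(n, seed):
    rng = np.random.default_rng(seed)
    return np.frombuffer(b"ACGT", dtype=np.uint8)[
        rng.integers(0, 4, n)].tobytes().decode()


class TestDepthProfile:
    def test_single_read_span(self):
        ref = make_ref("A" * 10)
        read = sl.AlignedRead("r1", 2, "CCCCC")
        depth = sl.depth_profile([read], ref)
        assert depth.tolist() == [0, 0, 1, 1, 1, 1, 1, 0, 0, 0]

    def test_clipped_bases_do_not_count(self):
        ref = make_ref("A" * 10)
        read = sl.AlignedRead("r1", 2, "CCCCC", clipped_suffix_len=2)
        depth = sl.depth_profile([read], ref)
        assert depth.sum() == 3

    def test_empty_alignments(self):
        assert sl.depth_profile([], make_ref("ACGT")).tolist() == [0, 0, 0, 0]

    def test_out_of_bounds_raises(self):
        with pytest.raises(StructuralError):
            sl.depth_profile([sl.AlignedRead("r", 8, "CCCCC")], make_ref("A" * 10))

    def test_simulated_mean_depth(self, small_genome):
        reference, allele, _ = small_genome
        aln = sl.simulate_alignments(allele, reference, depth=20.0, seed=1)
        depth = sl.depth_profile(aln, reference)
        # outside the deleted interval the profile should average ~20x
        s, e = small_genome[2].deleted_interval
        outside = np.concatenate([depth[1000:s - 200], depth[e + 200:-1000]])
        assert abs(outside.mean() - 20) / 20 < 0.1


class TestDetectGaps:
    def test_simple_gap(self):
        gaps = sl.detect_gaps(np.array([5, 5, 0, 0, 0, 5]),
                              max_internal_depth=0, min_gap_len=3,
                              max_spike_len=1)
        assert [g.interval for g in gaps] == [(2, 5)]

    def test_spike_handling_enumerated_by_hand(self):
        depth = np.array([5, 0, 0, 3, 0, 0, 5])
        # depth-3 position inside the run when the threshold admits it
        merged = sl.detect_gaps(depth, max_internal_depth=3, min_gap_len=2,
                                max_spike_len=1)
        assert [g.interval for g in merged] == [(1, 6)]
        # threshold 0 and spike tolerance 1: the width-1 spike is not
        # strictly shorter than the tolerance, so the runs stay separate
        split = sl.detect_gaps(depth, max_internal_depth=0, min_gap_len=2,
                               max_spike_len=1)
        assert [g.interval for g in split] == [(1, 3), (4, 6)]
        # a wider tolerance merges across the spike at any depth
        rejoined = sl.detect_gaps(depth, max_internal_depth=0, min_gap_len=2,
                                  max_spike_len=2)
        assert [g.interval for g in rejoined] == [(1, 6)]

    def test_all_zero_depth_is_one_gap(self):
        gaps = sl.detect_gaps(np.zeros(500, dtype=int), min_gap_len=100)
        assert [g.interval for g in gaps] == [(0, 500)]

    def test_short_runs_discarded(self):
        gaps = sl.detect_gaps(np.array([5, 0, 5, 5]), max_internal_depth=0,
                              min_gap_len=2, max_spike_len=1)
        assert gaps == []

    def test_gap_metadata(self):
        depth = np.concatenate([np.full(100, 8), np.zeros(50, dtype=int),
                                np.full(100, 12)])
        (gap,) = sl.detect_gaps(depth, min_gap_len=10)
        assert gap.internal_max_depth == 0
        assert gap.mean_flanking_depth == pytest.approx(10.0)


class TestCollectJunctionReads:
    def test_clipped_reads_at_boundaries_selected(self, small_genome,
                                                  small_alignments):
        reference, allele, truth = small_genome
        depth = sl.depth_profile(small_alignments, reference)
        (gap,) = sl.detect_gaps(depth, min_gap_len=1000)
        picked = sl.collect_junction_reads(small_alignments, gap, min_clip=20)
        assert len(picked) >= 2
        s, e = truth.deleted_interval
        for read in picked:
            assert (read.clipped_suffix_len >= 20 and abs(read.ref_end - s) <= 100) \
                or (read.clipped_prefix_len >= 20 and abs(read.ref_start - e) <= 100)

    def test_interior_read_excluded(self):
        gap = sl.CoverageGap((1000, 2000), 20.0, 0)
        read = sl.AlignedRead("far", 100, "A" * 50)
        assert sl.collect_junction_reads([read], gap) == []

    def test_unclipped_boundary_read_excluded_at_min_clip_one(self):
        gap = sl.CoverageGap((1000, 2000), 20.0, 0)
        read = sl.AlignedRead("flush", 950, "A" * 50)  # ends at 1000, no clip
        assert sl.collect_junction_reads([read], gap, min_clip=1) == []


class TestAssembleJunction:
    def test_two_read_exact_overlap(self):
        result = sl.assemble_junction(["ACGTACGT", "ACGTTTTT"], min_overlap=4)
        assert result.sequence == "ACGTACGTTTTT"
        assert result.support == 2

    def test_three_staggered_reads_reconstruct_truth(self):
        truth = rand_seq(50, seed=9)
        reads = [truth[0:30], truth[10:40], truth[20:50]]
        result = sl.assemble_junction(reads, min_overlap=15)
        assert result.sequence == truth

    def test_disjoint_reads_fail_softly(self):
        result = sl.assemble_junction(["AAAAAAAA", "CCCCCCCC"], min_overlap=4)
        assert isinstance(result, AssemblyFailure)

    def test_single_read_fails_softly(self):
        assert isinstance(sl.assemble_junction(["ACGTACGT"]), AssemblyFailure)

    def test_contained_read_absorbed(self):
        truth = rand_seq(60, seed=3)
        result = sl.assemble_junction([truth, truth[10:30]], min_overlap=10)
        assert result.sequence == truth

    def test_read_order_invariance(self):
        truth = rand_seq(50, seed=9)
        reads = [truth[0:30], truth[10:40], truth[20:50]]
        a = sl.assemble_junction(reads, min_overlap=15)
        b = sl.assemble_junction(list(reversed(reads)), min_overlap=15)
        assert a.sequence == b.sequence


class TestCallDeletion:
    def test_toy_clean_deletion(self):
        call = sl.call_deletion("AAAATTTT", make_ref("AAAACGTTTT"), min_anchor=3)
        assert call.deleted_interval == (4, 6)
        assert call.length == 2
        assert call.inserted_sequence == ""
        assert call.classification == "clean"

    def test_microhomology_left_aligned(self):
        """Tandem flank identity at the breakpoint: the interval is shifted
        maximally leftward and the homology length reported.  Placements
        enumerated by hand: ref = L + AG + mid + AG + R with (mid + AG)
        deleted can equally be read as (AG + mid) deleted; the canonical
        call starts at the first AG."""
        left, mid, right = rand_seq(60, 1), rand_seq(50, 2), rand_seq(60, 3)
        ref = make_ref(left + "AG" + mid + "AG" + right)
        allele = left + "AG" + right
        call = sl.call_deletion(allele[20:120], ref, min_anchor=20)
        assert call.deleted_interval == (60, 112)
        assert call.length == 52
        assert call.microhomology_len >= 2
        assert call.classification == "clean"
        # idempotence of the canonical form: re-calling on the same contig
        again = sl.call_deletion(allele[20:120], ref, min_anchor=20)
        assert again.deleted_interval == call.deleted_interval

    def test_insertion_at_junction(self):
        left, right = rand_seq(60, 4), rand_seq(60, 5)
        ins = "TTTTCCCC"
        # pin the deleted segment's boundary bases so the maximal anchors
        # cannot absorb coincident insertion bases
        mid = "G" + rand_seq(38, 6) + "A"
        ref = make_ref(left + mid + right)
        contig = left[20:] + ins + right[:40]
        call = sl.call_deletion(contig, ref, min_anchor=20)
        assert call.inserted_sequence == ins
        assert call.classification == "with_insertion"

    def test_duplicated_flank_classification(self):
        left, right = rand_seq(60, 14), rand_seq(60, 15)
        dup = right[:6]  # copy of the right flank inserted at the junction
        first = "A" if dup[0] != "A" else "C"
        last = "A" if dup[-1] != "A" else "C"
        ref = make_ref(left + first + rand_seq(38, 16) + last + right)
        contig = left[20:] + dup + right[:40]
        call = sl.call_deletion(contig, ref, min_anchor=20)
        assert call.classification == "with_duplication"

    def test_ambiguous_anchor_raises(self):
        unit = rand_seq(40, 7)
        ref = make_ref(unit + rand_seq(30, 8) + unit + rand_seq(30, 12))
        with pytest.raises(AmbiguousAnchorError):
            sl.call_deletion(unit[:15] + rand_seq(30, 13) + unit[-15:],
                             ref, min_anchor=15)

    def test_unanchored_contig_raises(self):
        with pytest.raises(AnchorError):
            sl.call_deletion(rand_seq(60, 10), make_ref(rand_seq(500, 11)),
                             min_anchor=20)


class TestJunctionsIdentical:
    def test_self_comparison(self, small_genome, small_alignments):
        reference, allele, truth = small_genome
        call = discover_deletion(small_alignments, reference)
        same, report = sl.junctions_identical(call, call)
        assert same and report == []

    def test_independent_read_sets_same_allele(self, small_genome):
        reference, allele, truth = small_genome
        calls = []
        for seed in (101, 202):
            aln = sl.simulate_alignments(allele, reference, depth=18.0,
                                         seed=seed)
            calls.append(discover_deletion(aln, reference))
        same, report = sl.junctions_identical(*calls)
        assert same, report

    def test_window_base_change_detected(self, small_genome, small_alignments):
        reference, allele, truth = small_genome
        call = discover_deletion(small_alignments, reference)
        seq = call.contig_sequence
        j = call.contig_junction
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[j - 5]]
        altered = sl.DeletionCall(
            call.reference_name, call.deleted_interval, call.inserted_sequence,
            call.microhomology_len, call.classification, call.contig_junction,
            seq[:j - 5] + flip + seq[j - 4:])
        same, report = sl.junctions_identical(call, altered)
        assert not same
        assert any("offset -5" in line for line in report)

    def test_different_references_raise(self, small_genome, small_alignments):
        reference, _, _ = small_genome
        call = discover_deletion(small_alignments, reference)
        other = sl.DeletionCall("other_ref", call.deleted_interval, "", 0,
                                "clean")
        with pytest.raises(ComparabilityError):
            sl.junctions_identical(call, other)


class TestInsilicoPcr:
    FWD = "ACGTACGTACGTACGTT"
    REV = "TGCATGCATGCATGCAA"

    def test_spacer_arithmetic(self):
        template = self.FWD + "A" * 100 + reverse_complement(self.REV)
        (amp,) = sl.insilico_pcr(template, self.FWD, self.REV)
        assert amp.length == len(self.FWD) + 100 + len(self.REV)

    def test_absent_primer_gives_empty_list(self):
        assert sl.insilico_pcr("ACGT" * 100, self.FWD, self.REV) == []

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError):
            sl.insilico_pcr("ACGT" * 100, "ACGTACGT", self.REV)

    def test_deletion_specific_amplification(self, small_genome):
        """Primers flanking the deletion amplify only from the deletion
        allele when the wild-type span exceeds the amplicon cutoff."""
        reference, allele, truth = small_genome
        s, e = truth.deleted_interval
        fwd = reference.sequence[s - 300:s - 280]
        rev = reverse_complement(reference.sequence[e + 280:e + 300])
        wt = sl.insilico_pcr(reference.sequence, fwd, rev, max_amplicon=3000)
        mut = sl.insilico_pcr(allele, fwd, rev, max_amplicon=3000)
        assert wt == []
        assert len(mut) == 1
        # amplicon-length identity: mutant product = wt span - deletion
        wt_unbounded = sl.insilico_pcr(reference.sequence, fwd, rev,
                                       max_amplicon=10 ** 7)
        assert mut[0].length == wt_unbounded[0].length - truth.length

    def test_mismatch_tolerant_matching(self):
        template = self.FWD + "A" * 50 + reverse_complement(self.REV)
        mutated = "T" + template[1:]
        assert sl.insilico_pcr(mutated, self.FWD, self.REV) == []
        (amp,) = sl.insilico_pcr(mutated, self.FWD, self.REV, max_mismatch=1)
        assert amp.length == len(template)


class TestEndToEndAndIO:
    def test_pipeline_recovers_truth_via_sam_round_trip(self, tmp_path,
                                                        small_genome):
        reference, allele, truth = small_genome
        aln = sl.simulate_alignments(allele, reference, depth=18.0, seed=11)
        write_fasta([reference], tmp_path / "ref.fasta")
        write_sam(aln, reference, tmp_path / "aln.sam")
        ref2 = read_fasta(tmp_path / "ref.fasta")[0]
        aln2 = read_sam(tmp_path / "aln.sam")
        assert len(aln2) == len(aln)
        call = discover_deletion(aln2, ref2)
        assert call.deleted_interval == truth.deleted_interval
        assert call.classification == "clean"

    def test_vcf_record_fields(self, tmp_path, small_genome, small_alignments):
        reference, _, truth = small_genome
        call = discover_deletion(small_alignments, reference)
        path = tmp_path / "del.vcf"
        write_deletion_vcf(call, reference, path)
        body = [l for l in path.read_text().splitlines()
                if not l.startswith("#")]
        assert len(body) == 1
        chrom, pos, _, _, alt, _, _, info = body[0].split("\t")
        assert alt == "<DEL>"
        assert int(pos) == call.deleted_interval[0]
        assert f"SVLEN=-{call.length}" in info
        assert "SVTYPE=DEL" in info

    def test_junction_report_mentions_interval(self, small_genome,
                                               small_alignments):
        reference, _, _ = small_genome
        call = discover_deletion(small_alignments, reference)
        text = junction_report(call, reference)
        assert str(call.length) in text
        assert "clean" in text
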
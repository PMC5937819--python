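import itertools

import pytest

from godiv import (
    AnnotationTrack,
    Segment,
    SplitAlignment,
    SVCall,
    breakpoints_concordant,
    count_breakpoints,
    filter_sv_calls,
    ltr_association,
    read_bed_track,
    read_split_alignments,
    read_sv_calls,
    reciprocal_overlap,
    sv_rate,
    svs_per_strain,
    tra_breakpoints_concordant,
    validate_sv,
)


def call(sv_type="DEL", chrom="chr1", pos=500_000, size=1000, quality=5000,
         left=True, right=True, chrom2=None, pos2=None):
    return SVCall(sv_type, chrom, pos, chrom2 or chrom,
                  pos2 or pos + size, size, quality, left, right)


EMPTY_TRACKS = {
    "telomere_centromere": AnnotationTrack("telomere_centromere", []),
    "TE": AnnotationTrack("TE", []),
}


class TestReciprocalOverlap:
    def test_identical_intervals(self):
        assert reciprocal_overlap((0, 100), (0, 100)) == 1.0

    def test_half_shifted(self):
        assert reciprocal_overlap((0, 100), (50, 150)) == 0.5

    def test_disjoint(self):
        assert reciprocal_overlap((0, 100), (200, 300)) == 0.0

    def test_asymmetric_lengths_take_the_minimum(self):
        assert reciprocal_overlap((0, 100), (0, 400)) == 0.25

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            reciprocal_overlap((5, 5), (0, 100))


class TestFilterSvCalls:
    def test_size_boundary(self):
        passing, rejected = filter_sv_calls(
            [call(size=99), call(size=100)], EMPTY_TRACKS
        )
        assert len(passing) == 1 and passing[0].size == 100
        assert rejected[0][1] == "size"

    def test_quality_boundary(self):
        passing, rejected = filter_sv_calls(
            [call(quality=999.9), call(quality=1000)], EMPTY_TRACKS
        )
        assert len(passing) == 1
        assert rejected[0][1] == "quality"

    def test_unassembled_ends(self):
        _, rejected = filter_sv_calls(
            [call(left=False), call(right=False)], EMPTY_TRACKS
        )
        assert [r for _, r in rejected] == ["left_unassembled", "right_unassembled"]

    def test_telomere_flank(self):
        tracks = dict(EMPTY_TRACKS)
        tracks["telomere_centromere"] = AnnotationTrack(
            "telomere_centromere", [("chr1", 0, 10_000)]
        )
        near = call(pos=40_000, size=500)  # 30 kbp of interval end
        far = call(pos=40_002, size=500)
        passing, rejected = filter_sv_calls([near, far], tracks)
        assert passing == [far]
        assert rejected[0][1] == "telomere_centromere"

    def test_te_reciprocal_overlap_only_hits_intrachromosomal_types(self):
        te = AnnotationTrack("TE", [("chr1", 499_999, 501_000)])
        tracks = {"telomere_centromere": EMPTY_TRACKS["telomere_centromere"], "TE": te}
        inv = call("INV", pos=500_000, size=950)  # ~95% reciprocal overlap
        tra = call("TRA", pos=500_000, chrom2="chr2", pos2=800_000, size=1000)
        passing, rejected = filter_sv_calls([inv, tra], tracks)
        assert passing == [tra]
        assert rejected[0][1] == "te_overlap"

    def test_clean_call_passes_every_rule(self):
        passing, rejected = filter_sv_calls([call()], EMPTY_TRACKS)
        assert len(passing) == 1 and not rejected

    def test_first_firing_reason_reported(self):
        _, rejected = filter_sv_calls([call(size=50, quality=10, left=False)],
                                      EMPTY_TRACKS)
        assert rejected[0][1] == "size"

    def test_passing_set_is_order_independent(self):
        calls = [call(size=99), call(), call(quality=1), call("INV", size=200),
                 call(left=False)]
        baseline = None
        for perm in itertools.permutations(calls):
            passing, _ = filter_sv_calls(list(perm), EMPTY_TRACKS)
            ids = {id(c) for c in passing}
            baseline = baseline if baseline is not None else ids
            assert ids == baseline


def segments_with_gaps(contig_gap, ref_gap, chrom="chr1"):
    return SplitAlignment("c", [
        Segment(0, 500, chrom, 10_000, 10_500, "+"),
        Segment(500 + contig_gap, 1000 + contig_gap, chrom,
                10_500 + ref_gap, 11_000 + ref_gap, "+"),
    ])


class TestValidateSv:
    @pytest.mark.parametrize("ref_gap,valid", [(250, True), (100, True), (99, False)])
    def test_deletion_gap_rule(self, ref_gap, valid):
        assert validate_sv(call("DEL"), segments_with_gaps(0, ref_gap)) is valid

    @pytest.mark.parametrize("contig_gap,valid", [(101, True), (100, True), (99, False)])
    def test_insertion_gap_rule(self, contig_gap, valid):
        assert validate_sv(call("INS"), segments_with_gaps(contig_gap, 0)) is valid

    @pytest.mark.parametrize("length,valid", [(101, True), (100, True), (99, False)])
    def test_inversion_reverse_segment_rule(self, length, valid):
        sa = SplitAlignment("c", [
            Segment(0, 500, "chr1", 10_000, 10_500, "+"),
            Segment(500, 500 + length, "chr1", 10_500, 10_500 + length, "-"),
        ])
        assert validate_sv(call("INV", size=max(length, 100)), sa) is valid

    @pytest.mark.parametrize("ref_ov,valid", [(150, True), (100, True), (99, False)])
    def test_duplication_overlap_rule(self, ref_ov, valid):
        assert validate_sv(call("DUP"), segments_with_gaps(0, -ref_ov)) is valid

    def test_translocation_needs_two_chromosomes(self):
        two = SplitAlignment("c", [
            Segment(0, 500, "chrII", 10_000, 10_500, "+"),
            Segment(500, 1000, "chrV", 90_000, 90_500, "+"),
        ])
        one = segments_with_gaps(0, 5000)
        tra = call("TRA", chrom2="chr2", pos2=99_000)
        assert validate_sv(tra, two)
        assert not validate_sv(tra, one)

    def test_contig_overlap_cap_enforced(self):
        with pytest.raises(ValueError, match="overlap"):
            SplitAlignment("c", [
                Segment(0, 500, "chr1", 0, 500, "+"),
                Segment(100, 600, "chr1", 5000, 5500, "+"),  # 80% overlap
            ])

    def test_unknown_type_rejected_at_construction(self):
        with pytest.raises(ValueError, match="unknown SV type"):
            SVCall("BND", "chr1", 1, "chr1", 2, 10, 1.0)


class TestBreakpointConcordance:
    @pytest.mark.parametrize("delta,ok", [(0, True), (100, True), (101, False)])
    def test_inclusive_tolerance(self, delta, ok):
        assert breakpoints_concordant(10_000 + delta, 10_000) is ok

    def test_translocation_partner_chromosome(self):
        tra = call("TRA", chrom="chr1", pos=10_000, chrom2="chr4", pos2=50_000)
        assert tra_breakpoints_concordant(("chr1", 10_050), ("chr4", 51_000), tra)
        assert not tra_breakpoints_concordant(("chr1", 10_050), ("chr5", 51_000), tra)
        assert not tra_breakpoints_concordant(("chr1", 10_200), ("chr4", 51_000), tra)


class TestRates:
    def test_breakpoints_per_mbp_per_distance(self):
        assert sv_rate(120, 12_000_000, 0.01) == pytest.approx(1000.0)

    def test_doubling_genome_size_halves_rate(self):
        assert sv_rate(100, 24_000_000, 0.1) == sv_rate(100, 12_000_000, 0.1) / 2

    def test_breakpoint_counting_default(self):
        assert count_breakpoints([call(), call("TRA", chrom2="chr2", pos2=1)]) == 4

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            sv_rate(10, 1_000_000, 0.0)

    @pytest.mark.parametrize(
        "total,n,expected", [(13_647, 155, 88.05), (1_218, 32, 38.06),
                             (15_251, 29, 525.90)]
    )
    def test_svs_per_strain(self, total, n, expected):
        assert svs_per_strain(total, n) == expected


class TestLtrAssociation:
    def test_boundary_is_inclusive(self):
        ltr = AnnotationTrack("LTR", [("chr1", 200, 300)])
        at_100 = call(pos=101, size=500)  # 100 bp from the interval start
        at_101 = call(pos=100, size=500)
        count, frac = ltr_association([at_100], ltr)
        assert count == 1
        count, _ = ltr_association([at_101], ltr)
        assert count == 0

    def test_no_track_intervals(self):
        _, frac = ltr_association([call()], AnnotationTrack("LTR", []))
        assert frac == 0.0

    def test_empty_call_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ltr_association([], AnnotationTrack("LTR", []))


class TestIO:
    def test_tsv_round_trip(self, tmp_path):
        import pandas as pd

        rows = [("DEL", "chr1", 1000, "chr1", 2000, 1000, 2500.0, True, True),
                ("TRA", "chr1", 1000, "chr3", 9000, 0, 1500.0, True, False)]
        p = tmp_path / "sv.tsv"
        pd.DataFrame(rows, columns=[
            "sv_type", "chrom1", "pos1", "chrom2", "pos2", "size", "quality",
            "left_assembled", "right_assembled"]).to_csv(p, sep="\t", index=False)
        calls = read_sv_calls(p)
        assert [c.sv_type for c in calls] == ["DEL", "TRA"]
        assert calls[1].right_assembled is False

    def test_vcf_reading(self, tmp_path):
        p = tmp_path / "sv.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type">\n'
            '##INFO=<ID=END,Number=1,Type=Integer,Description="End">\n'
            '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length">\n'
            '##INFO=<ID=CHR2,Number=1,Type=String,Description="Mate chrom">\n'
            '##INFO=<ID=POS2,Number=1,Type=Integer,Description="Mate pos">\n'
            '##INFO=<ID=LEFT_ASM,Number=0,Type=Flag,Description="Left assembled">\n'
            '##INFO=<ID=RIGHT_ASM,Number=0,Type=Flag,Description="Right assembled">\n'
            "##contig=<ID=chr1,length=1000000>\n"
            "##contig=<ID=chr2,length=1000000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t5000\tsv1\tN\t<DEL>\t3200\t.\t"
            "SVTYPE=DEL;END=6000;SVLEN=1000;LEFT_ASM;RIGHT_ASM\n"
            "chr1\t9000\tsv2\tN\t<TRA>\t1800\t.\t"
            "SVTYPE=TRA;CHR2=chr2;POS2=44000;SVLEN=0;LEFT_ASM\n"
        )
        calls = read_sv_calls(p, format="vcf")
        assert len(calls) == 2
        assert calls[0].size == 1000 and calls[0].left_assembled
        assert calls[1].chrom2 == "chr2" and not calls[1].right_assembled

    def test_bed_track_and_split_tsv(self, tmp_path):
        bed = tmp_path / "t.bed"
        bed.write_text("chr1\t0\t5000\nchr2\t100\t200\n")
        track = read_bed_track(bed, "TE")
        assert len(track) == 2 and track.near("chr1", 5100, 100)

        sp = tmp_path / "sa.tsv"
        sp.write_text(
            "contig_id\tcontig_start\tcontig_end\tref_chrom\tref_start\tref_end\torientation\n"
            "c1\t0\t500\tchr1\t1000\t1500\t+\n"
            "c1\t500\t1000\tchr1\t2000\t2500\t+\n"
        )
        sas = read_split_alignments(sp)
        assert len(sas["c1"].segments) == 2
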
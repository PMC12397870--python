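"""Annotation parsing, ORF discovery, fuzzy translation and strata assembly."""

import numpy as np
import pandas as pd
import pytest

from pepspace import genome_strata as gs
from pepspace import synthetic

from conftest import edit_distance_dp, orf_scan_brute

GTF_TWO_EXONS = (
    'chr1\ttoy\ttranscript\t1\t300\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
    'chr1\ttoy\texon\t1\t100\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
    'chr1\ttoy\texon\t201\t300\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
)


class TestParseAnnotation:
    def test_two_exons_yield_one_intron(self):
        features = gs.parse_annotation(GTF_TWO_EXONS)
        introns = [f for f in features if f.feature_type == "intron"]
        assert len(introns) == 1
        assert (introns[0].start, introns[0].end) == (100, 200)

    def test_single_exon_no_intron(self):
        gtf = 'chr1\ttoy\texon\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        assert not [
            f for f in gs.parse_annotation(gtf) if f.feature_type == "intron"
        ]

    def test_intergenic_flanks_single_gene(self):
        gtf = 'chr1\ttoy\tgene\t401\t600\t.\t+\t.\tgene_id "g";\n'
        features = gs.parse_annotation(gtf, chrom_lengths={"chr1": 1000})
        inter = [f for f in features if f.feature_type == "intergenic"]
        assert [(f.start, f.end) for f in inter] == [(0, 400), (600, 1000)]
        assert all(f.strand == "." for f in inter)

    def test_malformed_line_reports_line_number(self):
        with pytest.raises(gs.GTFParseError, match="line 2"):
            gs.parse_annotation(GTF_TWO_EXONS.splitlines()[0] + "\nbad\tline\n")

    def test_missing_transcript_id_rejected_with_warning(self, caplog):
        gtf = 'chr1\ttoy\texon\t1\t100\t.\t+\t.\tgene_id "g";\n'
        with caplog.at_level("WARNING"):
            features = gs.parse_annotation(gtf)
        assert features == []
        assert "transcript_id" in caplog.text

    def test_utr_classified_by_cds_position_and_strand(self):
        plus = (
            'chr1\ttoy\tCDS\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'chr1\ttoy\tUTR\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'chr1\ttoy\tUTR\t201\t260\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        )
        got = {
            (f.start, f.feature_type)
            for f in gs.parse_annotation(plus)
            if f.feature_type.startswith("UTR")
        }
        assert got == {(0, "UTR5"), (200, "UTR3")}
        minus = plus.replace("\t+\t", "\t-\t")
        got = {
            (f.start, f.feature_type)
            for f in gs.parse_annotation(minus)
            if f.feature_type.startswith("UTR")
        }
        assert got == {(0, "UTR3"), (200, "UTR5")}


class TestExtractSequence:
    genome = {"chr1": "ATGCATGCATGCATGCATGCATGCATGCAT"}

    def test_plus_strand_simple(self):
        f = gs.GenomicFeature("chr1", 0, 3, "+", "exon")
        assert gs.extract_feature_sequence(f, self.genome) == "ATG"

    def test_minus_strand_reverse_complement(self):
        f = gs.GenomicFeature("chr1", 0, 3, "-", "exon")
        assert gs.extract_feature_sequence(f, self.genome) == "CAT"

    def test_two_exon_minus_strand_transcript(self):
        # exons [0,6) and [12,18) of a 30-nt chromosome, minus strand:
        # splice genomically then reverse-complement the whole message
        exons = [
            gs.GenomicFeature("chr1", 0, 6, "-", "exon"),
            gs.GenomicFeature("chr1", 12, 18, "-", "exon"),
        ]
        spliced = self.genome["chr1"][0:6] + self.genome["chr1"][12:18]
        assert gs.extract_feature_sequence(exons, self.genome) == gs.reverse_complement(spliced)

    def test_out_of_bounds_raises(self):
        f = gs.GenomicFeature("chr1", 0, 99, "+", "exon")
        with pytest.raises(ValueError, match="bounds"):
            gs.extract_feature_sequence(f, self.genome)


class TestTranslate:
    @pytest.mark.parametrize(
        "codon,expected",
        [("GCN", "A"), ("ATN", "X"), ("TAA", "*"), ("TAR", "*"), ("ATG", "M"),
         ("CGN", "R"), ("MGR", "R"), ("NNN", "X")],
    )
    def test_fuzzy_codons(self, codon, expected):
        assert gs.translate(codon) == expected

    def test_partial_codon_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert gs.translate("ATGGC") == "M"
        assert "partial codon" in caplog.text

    def test_illegal_character_raises(self):
        with pytest.raises(ValueError):
            gs.translate("AT!")

    def test_six_frames_invariant_under_strand_flip(self, rng):
        for _ in range(10):
            seq = synthetic.random_dna(rng, int(rng.integers(30, 90)))
            fwd = gs.six_frame_translations(seq)
            rev = gs.six_frame_translations(gs.reverse_complement(seq))
            assert set(fwd) == set(rev)


class TestFindORFs:
    def test_minimal_orf(self):
        hits = gs.find_orfs("ATG" + "GCC" * 7 + "TAA")
        assert len(hits) == 1
        assert hits[0].aa_seq == "MAAAAAAA"
        assert hits[0].has_stop

    def test_no_start_codon(self):
        assert gs.find_orfs("TTT" * 30) == []

    def test_longest_orf_per_stop(self):
        hits = gs.find_orfs("ATGATG" + "GCC" * 7 + "TAA")
        in_frame0 = [h for h in hits if h.frame == 0]
        assert len(in_frame0) == 1
        assert in_frame0[0].start == 0  # most upstream start wins

    def test_below_min_length_excluded(self):
        assert [h for h in gs.find_orfs("ATG" + "GCC" * 6 + "TAA") if h.frame == 0] == []

    def test_no_stop_orf_flagged(self):
        hits = gs.find_orfs("ATG" + "GCC" * 8)
        assert len(hits) == 1 and not hits[0].has_stop
        assert gs.find_orfs("ATG" + "GCC" * 8, include_no_stop=False) == []

    def test_matches_brute_force_scanner(self, rng):
        """Property: agree with enumerate-all-starts oracle, ambiguity included."""
        alphabet = list("ACGTN") + list("RYSW")
        for _ in range(200):
            L = int(rng.integers(10, 300))
            weights = np.array([10, 10, 10, 10, 1, 1, 1, 1, 1], dtype=float)
            seq = "".join(rng.choice(alphabet, size=L, p=weights / weights.sum()))
            got = sorted((h.start, h.end) for h in gs.find_orfs(seq))
            expected = orf_scan_brute(
                seq, set(gs.START_CODONS), 8, gs._is_stop_codon
            )
            assert got == expected, seq


class TestCDSOverlap:
    def test_disjoint_is_none(self):
        assert gs.classify_cds_overlap([0, 1, 2], [10, 11, 12]) == "none"

    def test_identical_is_in_frame(self):
        pos = list(range(30))
        assert gs.classify_cds_overlap(pos, pos) == "in_frame"

    def test_one_nt_shift_is_frameshift(self):
        cds = list(range(0, 30))
        orf = list(range(1, 31))
        assert gs.classify_cds_overlap(orf, cds) == "frameshift"

    def test_three_nt_shift_is_in_frame(self):
        cds = list(range(0, 30))
        orf = list(range(3, 33))
        assert gs.classify_cds_overlap(orf, cds) == "in_frame"


class TestEditDistanceAndMainORF:
    @pytest.mark.parametrize(
        "a,b,expected", [("", "ABC", 3), ("KITTEN", "KITTEN", 0), ("kitten", "sitting", 3)]
    )
    def test_known_distances(self, a, b, expected):
        assert gs.edit_distance(a, b) == expected

    def test_matches_dp_oracle(self, rng):
        for _ in range(50):
            a = synthetic.random_protein(rng, int(rng.integers(0, 40)))
            b = synthetic.random_protein(rng, int(rng.integers(0, 40)))
            assert gs.edit_distance(a, b) == edit_distance_dp(a, b)

    def test_frame0_translation_detected(self):
        nt = "ATG" + "GCC" * 10 + "TAA"
        assert gs.detect_main_orf(gs.translate(nt[:-3]), nt) == 0

    def test_leading_nt_shifts_to_frame1(self):
        nt = "ATG" + "TGC" * 10
        assert gs.detect_main_orf(gs.translate(nt), "G" + nt) == 1

    def test_reverse_strand_frame(self):
        nt = "ATG" + "TGC" * 10
        assert gs.detect_main_orf(gs.translate(nt), gs.reverse_complement(nt)) == 3


class TestExpressionFilter:
    table = pd.DataFrame(
        {"transcript_id": ["a", "b", "c"], "rep1": [12, 12, 0], "rep2": [15, 9, 0]}
    )

    def test_every_replicate_rule(self):
        assert gs.filter_expressed(self.table, 10) == {"a"}

    def test_any_replicate_mode(self):
        assert gs.filter_expressed(self.table, 10, mode="any") == {"a", "b"}

    def test_zero_threshold_keeps_all(self):
        assert gs.filter_expressed(self.table, 0) == {"a", "b", "c"}


class TestBuildStrata:
    def test_toy_genome_strata_contents(self, toy_fixtures):
        genome, gtf = toy_fixtures["genome"], toy_fixtures["gtf"]
        features = gs.parse_annotation(gtf, {c: len(s) for c, s in genome.items()})
        strata = gs.build_strata(features, genome)
        for stratum in ("cds_main", "lncRNA", "intron", "intergenic", "utr5", "utr3"):
            assert strata[stratum], stratum
        # annotated CDS translations reproduce the planted reference proteins
        mains = {o.parent_transcript: o.aa_seq for o in strata["cds_main"]}
        for tid, ref in toy_fixtures["reference_proteins"].items():
            assert mains[tid] == ref

    def test_orfs_retranslate_to_stored_sequence(self, toy_fixtures):
        genome, gtf = toy_fixtures["genome"], toy_fixtures["gtf"]
        features = gs.parse_annotation(gtf, {c: len(s) for c, s in genome.items()})
        strata = gs.build_strata(features, genome)
        for orfs in strata.values():
            for orf in orfs[:50]:
                assert gs.translate(orf.nt_seq).rstrip("*") == orf.aa_seq
                assert "*" not in orf.aa_seq

    def test_expression_informed_subset_of_exhaustive(self, toy_fixtures):
        genome, gtf = toy_fixtures["genome"], toy_fixtures["gtf"]
        features = gs.parse_annotation(gtf, {c: len(s) for c, s in genome.items()})
        exhaustive = gs.build_strata(features, genome)
        informed = gs.build_strata(features, genome, toy_fixtures["expression"])
        for stratum in exhaustive:
            exh = {(o.orf_id, o.aa_seq) for o in exhaustive[stratum]}
            inf = {(o.orf_id, o.aa_seq) for o in informed[stratum]}
            assert inf <= exh
        # T4 fails the 10-counts-in-every-replicate rule
        assert not any(
            o.parent_transcript == "T4" for o in informed["cds_main"]
        )
        assert any(o.parent_transcript == "T4" for o in exhaustive["cds_main"])

    def test_short_proteins_and_duplicates_removed(self):
        orfs = [
            gs.OpenReadingFrame("a", "cds_main", "ATGGCT", "MAAA"),
            gs.OpenReadingFrame("b", "cds_main", "ATG...", "MAAAAAAA"),
            gs.OpenReadingFrame("b", "cds_main", "ATG...", "MAAAAAAA"),
        ]
        kept = gs._dedup_and_filter(orfs)
        assert [o.orf_id for o in kept] == ["b"]
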
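"""Tests for GC content, restriction analysis, and motif/ORF scanning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phagekit as pk
from phagekit.errors import InvalidInputError
from phagekit.features import (
    BUILTIN_ENZYMES,
    NucleotideSequence,
    RestrictionEnzyme,
    cut_coordinates,
    reverse_complement,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=300)


class TestGcContent:
    @pytest.mark.parametrize(
        "seq, expected",
        [("ATGC", 50.0), ("AAAA", 0.0), ("GGCC", 100.0), ("GCNN", 100.0), ("ACGTN", 50.0)],
    )
    def test_examples(self, seq, expected):
        assert pk.gc_content(seq) == pytest.approx(expected)

    def test_all_n_undefined(self):
        with pytest.raises(InvalidInputError):
            pk.gc_content("NNNN")

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seq=dna)
    def test_reverse_complement_invariance(self, seq):
        assert pk.gc_content(seq) == pytest.approx(pk.gc_content(reverse_complement(seq)))


class TestRecognitionSites:
    def test_direct_match(self):
        assert pk.find_recognition_sites("AAGAGCTCAA", "SacI") == [3]

    def test_overlapping_matches_all_reported(self):
        enzyme = RestrictionEnzyme("test", "GGGG", 2, 2)
        assert pk.find_recognition_sites("AGGGGGA", enzyme) == [2, 3]

    def test_iupac_expansion(self):
        enzyme = RestrictionEnzyme("HincII", "GTYRAC", 3, 3)
        assert pk.find_recognition_sites("AGTCAACA", enzyme) == [2]
        assert pk.find_recognition_sites("AGTGGACA", enzyme) == []  # Y never matches G

    def test_n_in_sequence_never_matches(self):
        assert pk.find_recognition_sites("AAGAGCTNAA", "SacI") == []

    def test_circular_rotation_gives_constant_count(self):
        # brute force over all rotations of a circle with one SacI site:
        # the junction-spanning windows must also be found
        base = "GAGCTC" + "AATTCCGGAATT"
        for r in range(len(base)):
            rotated = base[r:] + base[:r]
            sites = pk.find_recognition_sites(
                NucleotideSequence("rot", rotated, "circular"), "SacI"
            )
            assert len(sites) == 1, r

    def test_linear_junction_not_invented(self):
        # same sequence, linear topology: the split site is not a site
        base = "GAGCTC" + "AATTCCGGAATT"
        rotated = base[3:] + base[:3]
        assert pk.find_recognition_sites(NucleotideSequence("x", rotated), "SacI") == []

    def test_agrees_with_biopython_restriction(self):
        from Bio.Restriction import SacI as BioSacI
        from Bio.Seq import Seq

        rng = np.random.default_rng(13)
        seq = "".join(rng.choice(list("ACGT"), 5000))
        ours = [c + 1 for c in cut_coordinates(seq, "SacI")]  # first base after cut
        theirs = sorted(BioSacI.search(Seq(seq)))
        assert ours == theirs


class TestDigest:
    def test_linear_single_cut(self):
        seq = "AA" + "GAGCTC" + "A" * 12  # site at 3, cleavage after base 7
        fs = pk.digest(seq, "SacI")
        assert fs.topology == "linear"
        assert sorted(fs.lengths) == [7, 13]
        assert sum(fs.lengths) == 20

    def test_circular_two_cuts_are_arcs(self):
        spec = pk.SyntheticGenomeSpec(
            length=46_150, gc_target=0.44, topology="circular",
            planted_cut_sites=[("SacI", 40_719), ("ApaI", 26_166)], seed=2,
        )
        rec, _ = pk.generate_genome(spec)
        fs = pk.digest(rec, ["SacI", "ApaI"])
        assert sorted(fs.lengths) == [14_553, 31_597]
        assert fs.cut_positions == [26_170, 40_723]

    def test_circular_uncut(self):
        rec = NucleotideSequence("c", "ACGT" * 10, "circular")
        fs = pk.digest(rec, "SacI")
        assert fs.uncut and fs.lengths == [40]

    def test_linear_no_sites_single_fragment(self):
        fs = pk.digest("ACGT" * 10, "SacI")
        assert not fs.cut_positions and fs.lengths == [40]

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(seq=st.text(alphabet="ACGT", min_size=8, max_size=400),
           enzyme=st.sampled_from(sorted(BUILTIN_ENZYMES)),
           topology=st.sampled_from(["linear", "circular"]))
    def test_fragment_lengths_sum_to_sequence_length(self, seq, enzyme, topology):
        fs = pk.digest(NucleotideSequence("s", seq, topology), enzyme)
        assert sum(fs.lengths) == len(seq)

    def test_circular_rotation_invariance_of_fragment_multiset(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 300)) + "GAGCTC" + \
            "".join(rng.choice(list("ACGT"), 150)) + "GAGCTC" + \
            "".join(rng.choice(list("ACGT"), 80))
        ref = sorted(pk.digest(NucleotideSequence("a", seq, "circular"), "SacI").lengths)
        for r in (1, 57, 200, len(seq) - 3):
            rot = seq[r:] + seq[:r]
            got = sorted(pk.digest(NucleotideSequence("b", rot, "circular"), "SacI").lengths)
            assert got == ref, r


class TestPermutedDigest:
    def test_pac_at_cut_single_fragment(self):
        pool = pk.simulate_permuted_digest(
            seq_length=1000, pac_position=301, headful_length=1000,
            n_virions=1, enzyme_cuts=[300],
        )
        assert pool.pooled_lengths == [1000]

    def test_per_virion_sums_equal_headful(self):
        pool = pk.simulate_permuted_digest(
            seq_length=1000, pac_position=1, headful_length=1060,
            n_virions=40, enzyme_cuts=[300],
        )
        for frags in pool.per_virion_fragments:
            assert sum(frags) == 1060
        # terminal fragments take many distinct values: a smear, not bands
        assert len(pool.length_counts) > 10

    def test_enumeration_oracle_on_sequence(self):
        # cut a planted genome by actually extracting each virion's string
        # and searching it, then compare with the arithmetic
        spec = pk.SyntheticGenomeSpec(
            length=600, gc_target=0.5, topology="circular",
            planted_cut_sites=[("SacI", 100), ("SacI", 420)], seed=8,
        )
        rec, _ = pk.generate_genome(spec)
        cuts = cut_coordinates(rec, "SacI")
        headful, n_virions = 640, 25
        pool = pk.simulate_permuted_digest(600, 17, headful, n_virions, cuts)
        doubled = rec.residues * 3
        for i in range(n_virions):
            start0 = (17 - 1 + i * headful) % 600
            virion = doubled[start0 : start0 + headful]
            # oracle: cleavage after offset cut_offset_top of each site hit
            enzyme = BUILTIN_ENZYMES["SacI"]
            vcuts = sorted(
                j + enzyme.cut_offset_top
                for j in range(len(virion) - 5)
                if virion[j : j + 6] == enzyme.recognition and
                j + enzyme.cut_offset_top < headful
            )
            oracle = list(np.diff([0] + vcuts + [headful]))
            assert sorted(oracle) == sorted(pool.per_virion_fragments[i]), i

    def test_internal_arcs_survive_when_headful_equals_genome(self):
        pool = pk.simulate_permuted_digest(
            seq_length=1000, pac_position=1, headful_length=1000,
            n_virions=60, enzyme_cuts=[300, 650],
        )
        arcs = {350, 650}
        for frags in pool.per_virion_fragments:
            assert sum(frags) == 1000
            internal = frags[1:-1]
            assert all(f in arcs for f in internal)


class TestPromoterScan:
    def construct(self, spacer="C" * 17):
        return "A" * 40 + "TTGACA" + spacer + "TATAAT" + "A" * 40

    def test_exact_hit_on_plus_strand(self):
        hits = pk.scan_sigma70_promoters(self.construct(), max_mismatch_total=0)
        plus = [h for h in hits if h.strand == "+"]
        assert len(plus) == 1
        h = plus[0]
        assert (h.minus35_start, h.spacer_len, h.mismatches) == (41, 17, 0)
        assert h.minus10_start == 41 + 6 + 17

    def test_reverse_complement_reported_on_minus_strand(self):
        seq = self.construct()
        hits = pk.scan_sigma70_promoters(reverse_complement(seq), max_mismatch_total=0)
        minus = [h for h in hits if h.strand == "-"]
        assert len(minus) == 1
        h = minus[0]
        length = len(seq)
        assert (h.start, h.end) == (length - (41 + 28) + 1, length - 41 + 1)

    def test_mismatch_budget(self):
        seq = "A" * 40 + "TTGTCA" + "C" * 17 + "TATAAT" + "A" * 40  # one -35 mismatch
        assert not [h for h in pk.scan_sigma70_promoters(seq, max_mismatch_total=0)
                    if h.strand == "+"]
        hits = [h for h in pk.scan_sigma70_promoters(seq, max_mismatch_total=1)
                if h.strand == "+" and h.minus35_start == 41]
        assert hits and hits[0].mismatches == 1

    def test_spacer_range_window(self):
        seq = "A" * 30 + "TTGACA" + "C" * 16 + "TATAAT" + "A" * 30
        assert not pk.scan_sigma70_promoters(seq, 0, spacer_range=(17, 17))
        hits = pk.scan_sigma70_promoters(seq, 0, spacer_range=(15, 18))
        assert any(h.spacer_len == 16 for h in hits)

    def test_background_rate_matches_poisson_estimate(self):
        # random 100 kb at GC 0.5, fixed 17-nt spacer: per position and
        # strand the hit probability is P(Binomial(12, 3/4) mismatches <= m);
        # for the exact scan that is (1/4)^12 ~ 6e-8, i.e. ~0.01 expected
        # hits in the whole genome, and for the default 2-mismatch budget
        # ~3.8e-5, i.e. ~7.5 expected hits
        from math import comb

        rng = np.random.default_rng(99)
        seq = "".join(rng.choice(list("ACGT"), 100_000))
        assert pk.scan_sigma70_promoters(seq, max_mismatch_total=0) == []
        p_hit = sum(
            comb(12, m) * (3 / 4) ** m * (1 / 4) ** (12 - m) for m in range(3)
        )
        expected = 2 * 100_000 * p_hit
        hits = pk.scan_sigma70_promoters(seq, max_mismatch_total=2)
        assert abs(len(hits) - expected) <= 3 * np.sqrt(expected)


class TestRbsScan:
    def test_full_motif_with_gap_7(self):
        seq = "C" * 20 + "AGGAGG" + "C" * 7 + "ATGAAA"
        site = pk.scan_rbs(seq, orf_start=34, strand="+")
        assert site is not None
        assert (site.match_len, site.gap_to_start_codon, site.motif_match) == (6, 7, "AGGAGG")

    def test_no_motif_returns_none(self):
        seq = "C" * 40 + "ATGAAA"
        assert pk.scan_rbs(seq, orf_start=41, strand="+") is None

    def test_four_base_submotif_accepted(self):
        # GGAG is one of the contiguous 4-mers of AGGAGG
        seq = "C" * 20 + "GGAG" + "C" * 5 + "ATGAAA"
        site = pk.scan_rbs(seq, orf_start=30, strand="+", min_match_len=4)
        assert site is not None and site.match_len == 4 and site.motif_match == "GGAG"
        assert pk.scan_rbs(seq, orf_start=30, strand="+", min_match_len=5) is None

    def test_window_truncated_at_sequence_start(self):
        seq = "AGG" + "C" * 5 + "ATGAAA"  # window would extend past position 1
        assert pk.scan_rbs(seq, orf_start=9, strand="+") is None

    def test_minus_strand_site(self):
        plus = "C" * 20 + "AGGAGG" + "C" * 6 + "ATGAAACCC"
        seq = reverse_complement(plus)
        length = len(seq)
        # start codon 5' base on minus strand maps to forward position
        orf_start = length - 33 + 1
        site = pk.scan_rbs(seq, orf_start=orf_start, strand="-")
        assert site is not None
        assert site.match_len == 6 and site.gap_to_start_codon == 6
        assert site.strand == "-"


class TestFindOrfs:
    def make_gene(self, n_codons=30):
        return "AGGAGG" + "CCCC" + "TAA" + "ATG" + "GCT" * n_codons + "TAA"

    def test_rbs_gated_gene_call(self):
        seq = "C" * 30 + self.make_gene() + "C" * 30
        orfs = [o for o in pk.find_orfs(seq, min_length_nt=90) if o.strand == "+"]
        genes = [o for o in orfs if o.gene_call]
        assert len(genes) == 1
        gene = genes[0]
        assert gene.length_nt == 96
        # 30 nt pad + AGGAGG (6) + spacer CCCCTAA (7) puts ATG at 44
        assert gene.start == 44 and gene.end == 139
        assert gene.start_codon == "ATG"
        assert gene.rbs is not None and gene.rbs.gap_to_start_codon == 7

    def test_require_rbs_off_marks_all(self):
        seq = "C" * 30 + "ATG" + "GCT" * 30 + "TAA" + "C" * 30
        orfs = pk.find_orfs(seq, min_length_nt=90, require_rbs=False)
        assert all(o.gene_call for o in orfs)
        gated = pk.find_orfs(seq, min_length_nt=90, require_rbs=True)
        assert not any(o.gene_call for o in gated)

    def test_no_start_codons_empty(self):
        assert pk.find_orfs("C" * 300, min_length_nt=90) == []

    def test_reverse_complement_closure(self):
        rng = np.random.default_rng(21)
        seq = "".join(rng.choice(list("ACGT"), 3000))
        fwd = pk.find_orfs(seq, min_length_nt=90)
        rev = pk.find_orfs(reverse_complement(seq), min_length_nt=90)
        length = len(seq)
        mirrored = {
            (length - o.end + 1, length - o.start + 1, "-" if o.strand == "+" else "+",
             o.length_nt)
            for o in rev
        }
        assert {(o.start, o.end, o.strand, o.length_nt) for o in fwd} == mirrored

    def test_one_orf_per_stop_longest_start(self):
        # nested ATGs share a stop: only the earliest start is reported
        seq = "C" * 30 + "TAA" + "ATGGCTATG" + "GCT" * 29 + "TAA" + "C" * 30
        orfs = [o for o in pk.find_orfs(seq, min_length_nt=90, require_rbs=False)
                if o.strand == "+"]
        assert len(orfs) == 1
        assert orfs[0].length_nt == 9 + 87 + 3

    def test_planted_genome_recovery(self, planted_genome):
        rec, truth = planted_genome
        orfs = pk.find_orfs(rec, min_length_nt=90)
        found = {(o.start, o.end, o.strand) for o in orfs if o.gene_call}
        for _, row in truth[truth.feature_type == "CDS"].iterrows():
            assert (row.start, row.end, row.strand) in found


class TestTerminatorScan:
    def test_constructed_hairpin(self):
        seq = "CAC" + "GGGGC" + "AAAA" + "GCCCC" + "TTTTTTTT" + "CAC"
        hits = [h for h in pk.scan_terminators(seq) if h.strand == "+"]
        # the intended GC-rich hairpin is found and outscores any secondary
        # A:T hairpin formed against the U-tract itself
        best = max(hits, key=lambda h: h.score)
        assert (best.position, best.stem_len, best.loop_len, best.u_count) == (4, 5, 4, 8)
        assert best.score == pytest.approx(3 * 5 + 8 - 4)

    def test_poly_a_empty(self):
        assert pk.scan_terminators("A" * 200) == []

    def test_stem_threshold_boundary(self):
        seq = "CCC" + "GGGC" + "AAAA" + "GCCC" + "TTTTTTTT" + "CCC"
        assert not [h for h in pk.scan_terminators(seq, min_stem=5) if h.strand == "+"]
        hits = [h for h in pk.scan_terminators(seq, min_stem=4) if h.strand == "+"]
        assert hits and hits[0].stem_len == 4

    def test_u_tract_required(self):
        seq = "CAC" + "GGGGC" + "AAAA" + "GCCCC" + "GAGAGAGA" + "CAC"
        assert not [h for h in pk.scan_terminators(seq) if h.strand == "+"]


class TestPlantedGenomeCompleteness:
    def test_every_planted_feature_recovered(self, planted_genome):
        rec, truth = planted_genome
        promoter_spans = {
            (h.start, h.end, h.strand)
            for h in pk.scan_sigma70_promoters(rec, max_mismatch_total=0)
        }
        orf_spans = {(o.start, o.end, o.strand) for o in pk.find_orfs(rec, min_length_nt=90)
                     if o.gene_call}
        for _, row in truth.iterrows():
            key = (row.start, row.end, row.strand)
            if row.feature_type == "promoter":
                assert key in promoter_spans, row.to_dict()
            elif row.feature_type == "CDS":
                assert key in orf_spans, row.to_dict()
            elif row.feature_type == "restriction_site":
                enzyme = row.note.split(";")[0].split("=")[1]
                assert row.start in pk.find_recognition_sites(rec, enzyme)

    def test_no_spurious_restriction_sites(self, planted_genome):
        rec, truth = planted_genome
        planted = truth[truth.feature_type == "restriction_site"]
        for enzyme in ("SacI", "XhoI", "ApaI"):
            expected = sorted(
                planted[planted.note.str.contains(f"enzyme={enzyme}")].start
            )
            assert pk.find_recognition_sites(rec, enzyme) == expected
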
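"""NCR mining: tag derivation/search, translation, matching, pI, binning."""

import random
import warnings

import numpy as np
import pytest

from rhizoquant.ncr_mining import (
    NCRPeptide,
    build_tag_set,
    charge_distribution,
    classify_charge,
    compute_pi,
    default_pka_table,
    heuristic_cleavage_position,
    match_candidates,
    net_charge,
    predict_mature,
    tag_search,
    translate_contigs,
)


def aln(*seqs):
    return [(f"s{i}", s) for i, s in enumerate(seqs)]


class TestBuildTagSet:
    def test_fully_conserved_short_alignment(self):
        tags = build_tag_set(aln("CPTDC", "CPTDC", "CPTDC", "CPTDC"))
        assert tags.tags == {"CPT", "PTD", "TDC"}

    def test_variable_column_in_every_window_gives_empty_set(self):
        # middle column is 50/50, below the 0.8 conservation default
        tags = build_tag_set(aln("CAC", "CGC", "CAC", "CGC"))
        assert tags.tags == set()

    def test_ninety_percent_conserved_column_uses_majority_residue(self):
        seqs = ["ACPTD"] * 9 + ["ASPTD"]
        tags = build_tag_set(aln(*seqs), min_conservation=0.8)
        assert "CPT" in tags.tags and "SPT" not in tags.tags

    def test_gapped_window_skipped(self):
        tags = build_tag_set(aln("CP-DC", "CP-DC"))
        assert tags.tags == set()

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            build_tag_set(aln("CPTDC", "CPTD"))


class TestTagSearch:
    @pytest.fixture
    def tags(self):
        return build_tag_set(aln("CPTDC", "CPTDC"))

    def test_retains_only_tagged_peptides(self, tags):
        hits = tag_search(["LCPTDCK", "AAAAAK"], tags)
        assert [h.peptide for h in hits] == ["LCPTDCK"]

    def test_peptide_equal_to_tag_is_retained(self, tags):
        assert [h.peptide for h in tag_search(["CPT"], tags)] == ["CPT"]

    def test_internal_match_with_positions(self, tags):
        (hit,) = tag_search(["NCPTN"], tags)
        assert ("CPT", 1) in hit.matches

    def test_isoleucine_leucine_equivalence(self):
        tags = build_tag_set(aln("ALTDC", "ALTDC"))
        assert "ALT" in tags.tags
        hits = tag_search(["XAITDCX".replace("X", "G")], tags)
        assert [h.peptide for h in hits] == ["GAITDCG"]

    def test_removing_tags_never_adds_hits(self, tags):
        peptides = ["LCPTDCK", "TDCAA", "GGGG"]
        full = {h.peptide for h in tag_search(peptides, tags)}
        smaller = build_tag_set(aln("CPT", "CPT"))
        subset = {h.peptide for h in tag_search(peptides, smaller)}
        assert subset <= full


class TestTranslateContigs:
    def test_forward_frame_translation(self):
        orfs = translate_contigs([("c1", "ATGGCCTAA")], min_orf_length=1)
        frame1 = [o for o in orfs if o.frame == 1]
        assert frame1[0].peptide == "MA"
        assert (frame1[0].start, frame1[0].end) == (1, 6)

    def test_reverse_strand_peptide_recovered_in_negative_frame(self):
        from Bio.Seq import Seq

        peptide = "MKWVDEF"
        forward = "ATGAAATGGGTTGATGAATTT"
        rc = str(Seq(forward).reverse_complement())
        orfs = translate_contigs([("c1", "GG" + rc + "CC")], min_orf_length=5)
        assert any(peptide in o.peptide and o.frame < 0 for o in orfs)

    def test_stop_codons_split_orfs(self):
        orfs = translate_contigs([("c1", "ATGGCCTAAATGGCC")], min_orf_length=1)
        frame1 = sorted(o.peptide for o in orfs if o.frame == 1)
        assert frame1 == ["MA", "MA"]

    def test_short_contig_yields_nothing(self):
        assert translate_contigs([("c1", "AT")], min_orf_length=1) == []

    def test_empty_contig_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            assert translate_contigs([("c1", "")], min_orf_length=1) == []

    def test_ambiguous_codon_translates_to_x(self):
        orfs = translate_contigs([("c1", "ATGNNNGCC")], min_orf_length=1)
        assert any(o.peptide == "MXA" for o in orfs if o.frame == 1)


def orf(peptide, contig="c1", frame=1, start=1):
    from rhizoquant.ncr_mining import ORF

    return ORF(contig, frame, peptide, start, start + 3 * len(peptide) - 1)


def hits_for(peptides):
    tags = build_tag_set(aln("CPTDC", "CPTDC"))
    return tag_search(peptides, tags)


class TestMatchCandidates:
    def test_exact_substring_gives_full_identity_and_coverage(self):
        hits = hits_for(["CPTDCAAK"])
        (cand,) = match_candidates(hits, [orf("GGGCPTDCAAKGGG")])
        assert cand.identity == 100.0 and cand.coverage == 100.0

    def test_ninety_percent_identity_dropped_under_strict_inequality(self):
        # one mismatch in a 10-mer: exactly 90% identity, not > 90
        hits = hits_for(["CPTDCAAAAK"])
        target = orf("GGG" + "CPTDCAAAGK" + "GGG")
        assert match_candidates(hits, [target]) == []
        assert match_candidates(hits, [target], min_identity=89.0) != []

    def test_half_coverage_dropped(self):
        # only the first half of the query exists in the target
        hits = hits_for(["CPTDCKWWHM"])
        target = orf("GGGGGCPTDCGGGGG")
        retained = match_candidates(hits, [target], min_identity=90.0, min_coverage=50.0)
        assert retained == []

    def test_empty_orf_set_gives_empty_result(self):
        assert match_candidates(hits_for(["CPTDCK"]), []) == []

    def test_zero_thresholds_retain_any_positive_alignment(self):
        hits = hits_for(["CPTDCAAK"])
        retained = match_candidates(
            hits, [orf("CPWDCAAK")], min_identity=0.0, min_coverage=0.0
        )
        assert len(retained) == 1

    def test_score_ties_broken_by_contig_id(self):
        hits = hits_for(["CPTDCAAK"])
        orfs = [
            orf("GGGCPTDCAAKGGG", contig="ctgB"),
            orf("GGGCPTDCAAKGGG", contig="ctgA"),
        ]
        (cand,) = match_candidates(hits, orfs)
        assert cand.contig_id == "ctgA"


class TestPredictMature:
    def test_suffix_after_cleavage(self):
        assert predict_mature("MKLLACPTDC", 5) == "CPTDC"

    def test_last_position_gives_single_residue(self):
        assert predict_mature("MKLLA", 4) == "A"

    @pytest.mark.parametrize("position", [0, 5, 9])
    def test_out_of_range_rejected(self, position):
        with pytest.raises(ValueError):
            predict_mature("MKLLA", position)

    def test_heuristic_finds_small_residue_pattern(self):
        precursor = "MKLLLLLLLVAGA" + "CPTDCKRK"
        position = heuristic_cleavage_position(precursor)
        assert position is not None
        small = set("AGSCTV")
        assert precursor[position - 3] in small and precursor[position - 1] in small


class TestComputePI:
    def test_glycine_peptide_pi_is_terminal_pka_midpoint(self):
        pka = default_pka_table()
        expected = (pka["n_term"] + pka["c_term"]) / 2
        assert compute_pi("GGGG") == pytest.approx(expected, abs=1e-4)

    def test_basic_peptides_above_acidic_peptides(self):
        assert compute_pi("KKKKKK") > compute_pi("DDDDDD")

    def test_net_charge_strictly_decreasing(self):
        phs = np.linspace(0, 14, 57)
        for peptide in ["KDHECY", "GGGG", "KKDD"]:
            charges = [net_charge(peptide, ph) for ph in phs]
            assert all(a > b for a, b in zip(charges, charges[1:]))

    @staticmethod
    def grid_scan_pi(peptide, step=1e-4):
        """Independent vectorized Henderson-Hasselbalch scan over [0, 14]."""
        from collections import Counter

        ph = np.arange(0.0, 14.0, step)
        pka = default_pka_table()
        counts = Counter(peptide)
        q = 1.0 / (1.0 + 10.0 ** (ph - pka["n_term"]))
        q -= 1.0 / (1.0 + 10.0 ** (pka["c_term"] - ph))
        for aa in "KRH":
            q += counts[aa] / (1.0 + 10.0 ** (ph - pka["side_chains"][aa]))
        for aa in "DECY":
            q -= counts[aa] / (1.0 + 10.0 ** (pka["side_chains"][aa] - ph))
        return float(ph[int(np.argmin(np.abs(q)))])

    def test_bisection_matches_fine_grid_scan(self):
        rng = random.Random(91)
        for _ in range(12):
            peptide = "".join(
                rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(rng.randint(5, 30))
            )
            assert compute_pi(peptide) == pytest.approx(
                self.grid_scan_pi(peptide), abs=1e-3
            )

    def test_empty_peptide_rejected(self):
        with pytest.raises(ValueError):
            compute_pi("")


class TestClassifyCharge:
    @pytest.mark.parametrize(
        "pi,cls",
        [
            (4.5, "anionic"),
            (7.0, "neutral"),
            (8.5, "cationic"),
            (6.5, "neutral"),  # lower boundary belongs to neutral
            (7.5, "neutral"),
            (6.49, "anionic"),
            (7.51, "cationic"),
        ],
    )
    def test_bin_assignment(self, pi, cls):
        assert classify_charge(pi) == cls

    def test_partitions_the_real_line(self):
        for pi in np.linspace(4.0, 10.0, 601):
            assert classify_charge(float(pi)) in {"anionic", "neutral", "cationic"}

    def test_out_of_range_still_classified_with_warning(self):
        with pytest.warns(UserWarning):
            assert classify_charge(3.0) == "anionic"
        with pytest.warns(UserWarning):
            assert classify_charge(11.5) == "cationic"


class TestChargeDistribution:
    def ncr(self, ident, mature):
        return NCRPeptide(ident, "MKLLA" + mature, 5)

    def test_even_anionic_cationic_split(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            peptides = [
                self.ncr("a1", "DDDDDD"),
                self.ncr("a2", "EEEEEE"),
                self.ncr("c1", "KKKKKK"),
                self.ncr("c2", "RRRRRR"),
            ]
        dist = charge_distribution(peptides)
        assert dist == {"anionic": 50, "neutral": 0, "cationic": 50}

    def test_percentages_sum_to_about_100(self, pea_like_corpus):
        corpus = pea_like_corpus
        positions = dict(
            zip(corpus.cleavage_table.ncr_id, corpus.cleavage_table.cleavage_position)
        )
        peptides = [
            NCRPeptide(name, seq, int(positions[name]))
            for name, seq in corpus.precursors
        ]
        dist = charge_distribution(peptides)
        assert abs(sum(dist.values()) - 100) <= 1

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            charge_distribution([])
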
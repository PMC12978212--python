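"""The seven functional matching models."""

import itertools
from collections import Counter

import pytest

from hlamatch.functional_models import (
    ModelUsageError,
    TCE_CATEGORIES,
    annotate_pair,
    ard_match,
    b_leader_classify,
    expression_classify,
    pbm_gvh_match,
    tce_classify,
    tce_core_subclassify,
    tphe_classify,
)
from hlamatch.nomenclature import normalize_genotype, parse_allele
from hlamatch.pair_matching import locus_mismatch
from hlamatch.reference_tables import lookup_model
from tests.conftest import make_pair


def geno(locus, a, b):
    return normalize_genotype(locus, a, b)


class TestArdMatch:
    def test_same_p_group_is_matched(self, pgroups):
        rec = locus_mismatch(
            geno("DRB1", "DRB1*14:01", "DRB1*03:01"),
            geno("DRB1", "DRB1*14:54", "DRB1*03:01"),
        )
        assert ard_match(rec, pgroups) == "matched"

    def test_distinct_p_groups_mismatched(self, pgroups):
        rec = locus_mismatch(
            geno("A", "A*01:01", "A*03:01"), geno("A", "A*02:01", "A*03:01")
        )
        assert ard_match(rec, pgroups) == "mismatched"

    def test_c0303_c0304_ard_mismatched_but_pbm_matched(self, pgroups, tables):
        """C*03:03/03:04 sit in distinct P-groups yet share a PBM group:
        PBM matching extends beyond ARD identity."""
        patient = geno("C", "C*03:03", "C*07:01")
        donor = geno("C", "C*03:04", "C*07:01")
        rec = locus_mismatch(patient, donor)
        assert ard_match(rec, pgroups) == "mismatched"
        assert pbm_gvh_match(patient, donor, tables) == "matched"

    def test_requires_mismatch_at_main_locus(self, pgroups):
        rec = locus_mismatch(
            geno("A", "A*01:01", "A*01:01"), geno("A", "A*01:01", "A*01:01")
        )
        with pytest.raises(ModelUsageError):
            ard_match(rec, pgroups)


class TestPbmGvh:
    def test_unknown_allotype_gives_na(self, tables):
        patient = geno("C", "C*12:03", "C*07:01")  # C*12:03 has no PBM data
        donor = geno("C", "C*04:01", "C*07:01")
        assert pbm_gvh_match(patient, donor, tables) == "NA"

    def test_distinct_groups_mismatched(self, tables):
        patient = geno("A", "A*01:01", "A*24:02")
        donor = geno("A", "A*02:01", "A*24:02")
        assert pbm_gvh_match(patient, donor, tables) == "mismatched"

    def test_gvh_direction_only(self, tables):
        """A*03:01 and A*11:01 share a PBM group: the patient's motifs are
        all covered by the donor, so the pair is PBM-GvH matched."""
        patient = geno("A", "A*03:01", "A*24:02")
        donor = geno("A", "A*11:01", "A*24:02")
        assert pbm_gvh_match(patient, donor, tables) == "matched"

    def test_usage_errors(self, tables):
        with pytest.raises(ModelUsageError):
            pbm_gvh_match(
                geno("DQB1", "DQB1*02:01", "DQB1*03:01"),
                geno("DQB1", "DQB1*02:01", "DQB1*03:02"),
                tables,
            )
        with pytest.raises(ModelUsageError):  # matched locus
            pbm_gvh_match(
                geno("A", "A*01:01", "A*02:01"),
                geno("A", "A*01:01", "A*02:01"),
                tables,
            )


class TestBLeader:
    def test_ttt_combination(self, tables):
        patient = geno("B", "B*44:02", "B*35:01")
        donor = geno("B", "B*44:02", "B*35:02")
        assert b_leader_classify(patient, donor, tables) == ("matched", "TTT")

    def test_m_vs_t_mismatched(self, tables):
        patient = geno("B", "B*08:01", "B*07:02")  # shared M, mismatched M
        donor = geno("B", "B*08:01", "B*44:02")  # mismatched T
        assert b_leader_classify(patient, donor, tables) == ("mismatched", "MMT")

    def test_unknown_residue_gives_na(self, tables):
        patient = geno("B", "B*08:01", "B*47:01")  # B*47:01 not in the table
        donor = geno("B", "B*08:01", "B*44:02")
        assert b_leader_classify(patient, donor, tables) == ("NA", "")

    def test_requires_single_b_mismatch(self, tables):
        with pytest.raises(ModelUsageError):
            b_leader_classify(
                geno("B", "B*07:02", "B*08:01"), geno("B", "B*07:02", "B*08:01"), tables
            )


DPB1_FIXTURE = [
    "DPB1*09:01",  # TCE 1
    "DPB1*17:01",  # TCE 1
    "DPB1*03:01",  # TCE 2
    "DPB1*02:01",  # TCE 3 core
    "DPB1*04:01",  # TCE 3 core
    "DPB1*05:01",  # TCE 3 non-core
]


def brute_force_tce(patient_alleles, donor_alleles, tables):
    """Independent implementation of the bidirectional min-group rule."""
    if Counter(a.key for a in patient_alleles) == Counter(
        a.key for a in donor_alleles
    ):
        return "allele-matched"
    groups = {}
    for al in (*patient_alleles, *donor_alleles):
        v = lookup_model(al, "tce_group", tables)
        if v == "unknown":
            return "unknown"
        groups[al.key] = int(v)
    m_p = min(groups[a.key] for a in patient_alleles)
    m_d = min(groups[a.key] for a in donor_alleles)
    if m_p == m_d:
        return "permissive"
    return "non-permissive GvH" if m_p < m_d else "non-permissive HvG"


class TestTce:
    def test_exhaustive_against_brute_force(self, tables):
        """All 1296 ordered genotype pairs from the 6-allele DPB1 fixture
        agree with the brute-force min-group oracle."""
        genotypes = list(itertools.product(DPB1_FIXTURE, repeat=2))
        assert len(genotypes) == 36
        checked = 0
        for (pa, pb), (da, db) in itertools.product(genotypes, repeat=2):
            patient = geno("DPB1", pa, pb)
            donor = geno("DPB1", da, db)
            assert tce_classify(patient, donor, tables) == brute_force_tce(
                patient.alleles, donor.alleles, tables
            )
            checked += 1
        assert checked == 1296

    @pytest.mark.parametrize(
        "p, d, verdict",
        [
            (("DPB1*03:01", "DPB1*04:01"), ("DPB1*04:01", "DPB1*04:02"),
             "non-permissive GvH"),
            (("DPB1*04:01", "DPB1*04:02"), ("DPB1*02:01", "DPB1*04:01"),
             "permissive"),
            (("DPB1*04:01", "DPB1*03:01"), ("DPB1*04:01", "DPB1*03:01"),
             "allele-matched"),
            (("DPB1*04:01", "DPB1*04:02"), ("DPB1*09:01", "DPB1*04:01"),
             "non-permissive HvG"),
        ],
    )
    def test_examples(self, tables, p, d, verdict):
        assert tce_classify(geno("DPB1", *p), geno("DPB1", *d), tables) == verdict

    def test_antisymmetric_under_subject_swap(self, tables):
        flip = {
            "non-permissive GvH": "non-permissive HvG",
            "non-permissive HvG": "non-permissive GvH",
        }
        genotypes = list(itertools.combinations_with_replacement(DPB1_FIXTURE, 2))
        for p, d in itertools.product(genotypes, repeat=2):
            fwd = tce_classify(geno("DPB1", *p), geno("DPB1", *d), tables)
            rev = tce_classify(geno("DPB1", *d), geno("DPB1", *p), tables)
            assert rev == flip.get(fwd, fwd)

    def test_unknown_allele_propagates(self, tables):
        patient = geno("DPB1", "DPB1*900:01", "DPB1*04:01")
        donor = geno("DPB1", "DPB1*02:01", "DPB1*04:01")
        assert tce_classify(patient, donor, tables) == "unknown"


class TestTceCoreSubclassify:
    @pytest.mark.parametrize(
        "p, d, verdict",
        [
            # both mismatched alleles core TCE3
            (("DPB1*04:01", "DPB1*04:01"), ("DPB1*02:01", "DPB1*04:01"),
             "core permissive"),
            # patient's mismatched allele non-core, donor's core
            (("DPB1*05:01", "DPB1*04:01"), ("DPB1*04:01", "DPB1*02:01"),
             "non-core permissive GvH"),
            (("DPB1*04:01", "DPB1*02:01"), ("DPB1*05:01", "DPB1*04:01"),
             "non-core permissive HvG"),
            # non-core on both sides -> residual
            (("DPB1*05:01", "DPB1*04:01"), ("DPB1*01:01", "DPB1*04:01"),
             "other permissive"),
            # permissive but not TCE3-vs-TCE3 (both minima in group 1)
            (("DPB1*09:01", "DPB1*04:01"), ("DPB1*09:01", "DPB1*03:01"),
             "other permissive"),
        ],
    )
    def test_categories(self, tables, p, d, verdict):
        assert (
            tce_core_subclassify(geno("DPB1", *p), geno("DPB1", *d), tables)
            == verdict
        )

    def test_requires_permissive_pair(self, tables):
        with pytest.raises(ModelUsageError):
            tce_core_subclassify(
                geno("DPB1", "DPB1*09:01", "DPB1*04:01"),
                geno("DPB1", "DPB1*04:01", "DPB1*04:02"),
                tables,
            )


class TestExpression:
    def test_high_and_low(self, tables):
        donor = geno("DPB1", "DPB1*02:01", "DPB1*04:01")
        high = geno("DPB1", "DPB1*03:01", "DPB1*04:01")
        low = geno("DPB1", "DPB1*04:02", "DPB1*04:01")
        assert expression_classify(high, donor, tables) == "high"
        assert expression_classify(low, donor, tables) == "low"

    def test_not_applicable_cases(self, tables):
        matched = geno("DPB1", "DPB1*04:01", "DPB1*04:02")
        assert expression_classify(matched, matched, tables) == "NA"
        # double mismatch
        assert (
            expression_classify(
                geno("DPB1", "DPB1*09:01", "DPB1*03:01"),
                geno("DPB1", "DPB1*04:01", "DPB1*04:02"),
                tables,
            )
            == "NA"
        )
        # homozygous patient: single mismatch with empty GvH vector
        assert (
            expression_classify(
                geno("DPB1", "DPB1*04:01", "DPB1*04:01"),
                geno("DPB1", "DPB1*04:01", "DPB1*03:01"),
                tables,
            )
            == "NA"
        )


class TestTphe:
    @pytest.mark.parametrize(
        "tce, expr, verdict",
        [
            ("core permissive", "high", "TPHE"),
            ("other permissive", "high", "TPHE"),
            ("core permissive", "low", "other"),
            ("non-permissive GvH", "high", "other"),
            ("allele-matched", "NA", "NA"),
            ("unknown", "high", "NA"),
        ],
    )
    def test_truth_table(self, tce, expr, verdict):
        assert tphe_classify(tce, expr) == verdict


class TestAnnotationInvariants:
    def test_ard_match_implies_pbm_match(self, pgroups, tables):
        """P-group identity implies identical peptide-binding motifs, so an
        ARD-matched single mismatch can never be PBM-GvH mismatched."""
        pair = make_pair(
            patient={"DRB1": ("DRB1*14:01", "DRB1*03:01")},
            donor={"DRB1": ("DRB1*14:54", "DRB1*03:01")},
        )
        ann = annotate_pair(pair, pgroups, tables)
        assert ann.ard["DRB1"] == "matched"
        assert ann.pbm_gvh == "matched"

    def test_tphe_implies_permissive_and_high(self, pgroups, tables):
        pair = make_pair(
            patient={"DPB1": ("DPB1*05:01", "DPB1*04:01")},
            donor={"DPB1": ("DPB1*01:01", "DPB1*04:01")},
        )
        ann = annotate_pair(pair, pgroups, tables)
        if ann.tphe == "TPHE":
            assert ann.tce in (
                "core permissive",
                "non-core permissive GvH",
                "non-core permissive HvG",
                "other permissive",
            )
            assert ann.dpb1_expression == "high"
        assert ann.tce in TCE_CATEGORIES

    def test_every_pair_gets_exactly_one_tce_category(self, pgroups, tables):
        for p, d in itertools.product(
            itertools.combinations_with_replacement(DPB1_FIXTURE[:4], 2), repeat=2
        ):
            pair = make_pair(patient={"DPB1": p}, donor={"DPB1": d})
            ann = annotate_pair(pair, pgroups, tables)
            assert ann.tce in TCE_CATEGORIES
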
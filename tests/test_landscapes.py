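"""Allele frequencies, combination landscapes and cohort summaries."""

import numpy as np
import pandas as pd
import pytest

from hlamatch import (
    allele_frequencies,
    annotate_cohort,
    mismatch_combination_table,
    representation_ratio,
    summarize_cohort,
)
from hlamatch.landscapes import aggregate_rates, pct, round_half_up
from tests.conftest import make_pair


@pytest.fixture(scope="module")
def toy_pairs():
    return [
        make_pair(pair_id="p1", patient={"A": ("A*01:01", "A*02:01")}),
        make_pair(pair_id="p2", patient={"A": ("A*01:01", "A*01:01")}),
    ]


class TestAlleleFrequencies:
    def test_direct_counting(self, toy_pairs):
        freqs = allele_frequencies(toy_pairs, "patient", "A")
        assert freqs.loc["A*01:01", "count"] == 3
        assert freqs.loc["A*01:01", "freq"] == pytest.approx(0.75)

    def test_frequencies_sum_to_one(self, toy_pairs):
        freqs = allele_frequencies(toy_pairs, "patient", "A")
        assert freqs["freq"].sum() == pytest.approx(1.0)

    def test_role_selects_subject(self, toy_pairs):
        donor_freqs = allele_frequencies(toy_pairs, "donor", "A")
        assert donor_freqs.loc["A*01:01", "freq"] == pytest.approx(1.0)

    def test_unknown_role_rejected(self, toy_pairs):
        with pytest.raises(ValueError):
            allele_frequencies(toy_pairs, "recipient", "A")


def _single_c_cohort(pgroups, tables, n_0304=3, n_other=7):
    pairs = []
    for i in range(n_0304):
        pairs.append(
            make_pair(
                pair_id=f"c{i}",
                patient={"C": ("C*03:03", "C*07:01")},
                donor={"C": ("C*03:04", "C*07:01")},
            )
        )
    for i in range(n_other):
        pairs.append(
            make_pair(
                pair_id=f"o{i}",
                patient={"C": ("C*01:02", "C*07:01")},
                donor={"C": ("C*02:02", "C*07:01")},
            )
        )
    return annotate_cohort(pairs, pgroups, tables)


class TestCombinationTable:
    def test_frequency_relative_to_locus_denominator(self, pgroups, tables):
        ann = _single_c_cohort(pgroups, tables)
        table = mismatch_combination_table(ann, "C")
        assert table.denominator == 10
        frame = table.to_frame().set_index(["donor_allele", "patient_allele"])
        assert frame.loc[("C*03:04", "C*03:03"), "count"] == 3
        assert frame.loc[("C*03:04", "C*03:03"), "freq"] == pytest.approx(0.30)

    def test_counts_sum_to_denominator_and_freqs_to_one(self, pgroups, tables):
        ann = _single_c_cohort(pgroups, tables)
        table = mismatch_combination_table(ann, "C")
        assert sum(table.counts.values()) == table.denominator
        assert table.to_frame()["freq"].sum() == pytest.approx(1.0)

    def test_unordered_view_merges_directions(self, pgroups, tables):
        pairs = [
            make_pair(pair_id="f", patient={"C": ("C*03:03", "C*07:01")},
                      donor={"C": ("C*03:04", "C*07:01")}),
            make_pair(pair_id="r", patient={"C": ("C*03:04", "C*07:01")},
                      donor={"C": ("C*03:03", "C*07:01")}),
        ]
        ann = annotate_cohort(pairs, pgroups, tables)
        table = mismatch_combination_table(ann, "C")
        assert len(table.counts) == 2
        merged = table.unordered()
        assert merged[frozenset({"C*03:03", "C*03:04"})] == 2
        assert table.combination_share([("C*03:03", "C*03:04")]) == pytest.approx(1.0)

    def test_dpb1_requires_stratum(self, pgroups, tables):
        ann = _single_c_cohort(pgroups, tables)
        with pytest.raises(ValueError):
            mismatch_combination_table(ann, "DPB1")

    def test_entropy_orders_concentration(self, pgroups, tables):
        concentrated = _single_c_cohort(pgroups, tables, n_0304=9, n_other=1)
        spread = _single_c_cohort(pgroups, tables, n_0304=5, n_other=5)
        t_conc = mismatch_combination_table(concentrated, "C")
        t_spread = mismatch_combination_table(spread, "C")
        assert t_conc.entropy() < t_spread.entropy()


class TestRepresentationRatio:
    def test_absent_among_mismatches_is_zero(self):
        pairs = [
            make_pair(pair_id="m", patient={"A": ("A*01:01", "A*03:01")},
                      donor={"A": ("A*02:01", "A*03:01")}),
        ]
        assert representation_ratio("A", "A*03:01", pairs) == 0.0

    def test_cohort_absent_allele_errors(self):
        pairs = [make_pair()]
        with pytest.raises(ValueError):
            representation_ratio("A", "A*68:01", pairs)

    def test_mismatch_only_allele_is_overrepresented(self):
        pairs = [
            make_pair(pair_id="m", patient={"A": ("A*01:01", "A*03:01")},
                      donor={"A": ("A*02:01", "A*03:01")}),
            make_pair(pair_id="n"),
        ]
        # A*02:01 appears on 1 of 8 cohort chromosomes but is 1 of the 2
        # mismatched alleles: ratio (1/2) / (1/8) = 4
        assert representation_ratio("A", "A*02:01", pairs) == pytest.approx(4.0)


class TestRounding:
    @pytest.mark.parametrize(
        "value, expected",
        [(0.05, 0.1), (2.25, 2.3), (2.24, 2.2), (30.14, 30.1), (16.65, 16.7)],
    )
    def test_half_up(self, value, expected):
        assert round_half_up(value, 1) == expected

    def test_pct_zero_denominator_is_nan(self):
        assert np.isnan(pct(1, 0))

    def test_aggregate_rates_weighted_mean(self):
        rates = {"A": 10.0, "B": 40.0}
        weights = {"A": 3, "B": 1}
        assert aggregate_rates(rates, weights) == pytest.approx(17.5)


@pytest.fixture(scope="module")
def small_summary(pgroups, tables):
    pairs = [
        make_pair(pair_id="match", year=2012),
        make_pair(
            pair_id="single_c",
            year=2018,
            patient={"C": ("C*03:03", "C*07:01")},
            donor={"C": ("C*03:04", "C*07:01")},
        ),
        make_pair(
            pair_id="dpb1_only",
            year=2021,
            patient={"DPB1": ("DPB1*03:01", "DPB1*04:01")},
            donor={"DPB1": ("DPB1*04:02", "DPB1*04:01")},
        ),
    ]
    ann = annotate_cohort(pairs, pgroups, tables)
    return ann, summarize_cohort(ann)


class TestSummarizeCohort:
    def test_matching_counts(self, small_summary):
        _, summary = small_summary
        assert summary.matching.loc["10/10", "count"] == 2
        assert summary.matching.loc["9/10", "count"] == 1
        assert summary.matching["count"].sum() == summary.n_pairs

    def test_pbm_table_counts(self, small_summary):
        _, summary = small_summary
        row = summary.pbm_table.query("locus == 'C' and verdict == 'matched'")
        assert row["count"].iloc[0] == 1

    def test_tce_table_partition_conserves_pairs(self, small_summary):
        _, summary = small_summary
        n_cols = [c for c in summary.tce_table.columns if c.startswith("n_")]
        assert summary.tce_table[n_cols].to_numpy().sum() == summary.n_pairs

    def test_row_order_and_id_invariance(self, small_summary):
        ann, summary = small_summary
        shuffled = ann.sample(frac=1.0, random_state=3).reset_index(drop=True)
        shuffled["pair_id"] = [f"x{i}" for i in range(len(shuffled))]
        summary2 = summarize_cohort(shuffled)
        pd.testing.assert_frame_equal(summary.matching, summary2.matching)
        pd.testing.assert_frame_equal(summary.tce_table, summary2.tce_table)

    def test_empty_cohort_flagged(self):
        summary = summarize_cohort(pd.DataFrame())
        assert summary.n_pairs == 0
        assert summary.matching is None

    def test_class_rates_are_weighted_locus_rates(self, pgroups, tables):
        """Class-level low-resolution rates equal the count-weighted mean of
        locus rates."""
        pairs = []
        for i in range(4):  # C: 2 low-res matched of 4
            donor_c = "C*03:04" if i < 2 else "C*04:01"
            pairs.append(
                make_pair(pair_id=f"c{i}", patient={"C": ("C*03:03", "C*07:01")},
                          donor={"C": (donor_c, "C*07:01")})
            )
        for i in range(2):  # A: 0 low-res matched of 2
            pairs.append(
                make_pair(pair_id=f"a{i}", patient={"A": ("A*01:01", "A*03:01")},
                          donor={"A": ("A*02:01", "A*03:01")})
            )
        ann = annotate_cohort(pairs, pgroups, tables)
        summary = summarize_cohort(ann)
        lowres = summary.lowres
        expected = aggregate_rates(
            {"A": 0.0, "C": 50.0}, {"A": 2, "C": 4}
        )
        assert lowres.loc["class I", "pct_lowres_matched"] == pytest.approx(
            round_half_up(expected, 1)
        )
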
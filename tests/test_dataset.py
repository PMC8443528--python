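"""Dataset I/O, validation, stability classification and summary statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmshift import (
    MutationDataset,
    binned_profile,
    classify_stability,
    load_dataset,
    substitution_matrix,
    summarize_dataset,
)
from tmshift.network import augment_with_reversed

from conftest import make_entry

HEADER = "protein_id\tchain\tresidue_number\twt_aa\tmut_aa\ttm_wt\td_tm\tph\ttechnique"


def write_table(tmp_path, rows):
    path = tmp_path / "table.tsv"
    path.write_text("\n".join([HEADER, *rows]) + "\n")
    return path


class TestLoadDataset:
    def test_header_only_gives_empty_dataset(self, tmp_path):
        ds = load_dataset(write_table(tmp_path, []))
        assert len(ds) == 0 and ds.validation_report == []

    def test_three_row_fixture_matches_hand_transcription(self, tmp_path):
        rows = [
            "1ABC\tA\t42\tV\tA\t61.5\t-3.2\t7.0\tCD",
            "1ABC\tA\t17\tG\tW\t61.5\t0.8\t7.0\tDSC",
            "2XYZ\tB\t103\tD\tK\t75.0\t4.1\t6.5\tFL",
        ]
        ds = load_dataset(write_table(tmp_path, rows))
        assert len(ds) == 3
        e = ds.entries[0]
        assert (e.protein_id, e.chain, e.residue_number) == ("1ABC", "A", 42)
        assert (e.wt_aa, e.mut_aa) == ("V", "A")
        assert (e.tm_wt, e.d_tm, e.ph, e.technique) == (61.5, -3.2, 7.0, "CD")
        assert ds.entries[2].protein_id == "2XYZ"
        assert ds.entries[2].technique == "FL"

    def test_missing_required_column_is_fatal(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("protein_id\tchain\n1ABC\tA\n")
        with pytest.raises(ValueError, match="residue_number"):
            load_dataset(path)

    @pytest.mark.parametrize(
        "row, reason",
        [
            ("1ABC\tA\t42\tA\tA\t61.5\t-3.2\t7.0\tCD", "self-substitution"),
            ("1ABC\tA\t42\tV\tA\t61.5\t-25.0\t7.0\tCD", "dtm-out-of-range"),
            ("1ABC\tA\t42\tV\tA\t61.5\tnot_a_number\t7.0\tCD", "unparseable-d_tm"),
            ("1ABC\tA\t42\tV\tA\t61.5\t-3.2\t15.0\tCD", "ph-out-of-range"),
        ],
    )
    def test_invalid_rows_are_quarantined_with_reason(self, tmp_path, row, reason):
        ds = load_dataset(write_table(tmp_path, [row]))
        assert len(ds) == 0
        assert len(ds.validation_report) == 1
        assert reason in ds.validation_report[0]["reasons"]


class TestClassifyStability:
    @pytest.mark.parametrize(
        "d_tm, expected",
        [(-2.5, "destabilizing"), (0.0, "neutral"), (3.1, "stabilizing"),
         (2.0, "neutral"), (-2.0, "neutral")],
    )
    def test_band_assignment(self, d_tm, expected):
        assert classify_stability(d_tm) == expected

    def test_boundary_moves_consistently_with_threshold(self):
        # at |d_tm| exactly the threshold, a slightly smaller threshold flips
        # the category outward and a larger one keeps it neutral
        assert classify_stability(2.0, threshold=2.0 - 1e-9) == "stabilizing"
        assert classify_stability(2.0, threshold=2.0 + 1e-9) == "neutral"
        assert classify_stability(-2.0, threshold=2.0 - 1e-9) == "destabilizing"

    def test_rejects_non_finite_and_bad_threshold(self):
        with pytest.raises(ValueError):
            classify_stability(math.nan)
        with pytest.raises(ValueError):
            classify_stability(1.0, threshold=0.0)


class TestSummarize:
    def test_ph_band_fraction_hand_count(self, small_dataset):
        rep = summarize_dataset(small_dataset)
        assert rep.ph_fractions["6-8"] == pytest.approx(0.5)
        assert rep.ph_fractions["<6"] == pytest.approx(0.3)
        assert rep.ph_fractions[">8"] == pytest.approx(0.2)
        assert rep.ph_fractions["<=3.5"] == pytest.approx(0.2)

    def test_partition_fractions_sum_to_one(self, small_dataset):
        rep = summarize_dataset(small_dataset)
        assert sum(rep.ph_fractions[k] for k in ("<6", "6-8", ">8")) == pytest.approx(1.0)
        cats = rep.dtm_category_fractions
        assert cats["destabilizing"] + cats["neutral"] + cats["stabilizing"] == pytest.approx(1.0)

    def test_all_zero_dtm_is_fully_neutral(self):
        ds = MutationDataset(entries=[make_entry(d_tm=0.0) for _ in range(4)])
        rep = summarize_dataset(ds)
        assert rep.dtm_category_fractions["neutral"] == 1.0

    def test_category_fractions_match_per_entry_tally(self, small_dataset):
        rep = summarize_dataset(small_dataset)
        n = len(small_dataset)
        direct = [classify_stability(e.d_tm) for e in small_dataset]
        for cat in ("destabilizing", "neutral", "stabilizing"):
            assert rep.dtm_category_fractions[cat] == pytest.approx(direct.count(cat) / n)

    def test_identical_rsa_and_b_give_perfect_correlation(self):
        ds = MutationDataset(
            entries=[make_entry(residue_number=i, rsa=v, avg_b=v) for i, v in
                     enumerate([0.1, 0.4, 0.9])]
        )
        rep = summarize_dataset(ds)
        assert rep.rsa_b_correlation == pytest.approx(1.0)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            summarize_dataset(MutationDataset())


class TestSubstitutionMatrix:
    def test_empty_dataset_all_zero(self):
        m = substitution_matrix(MutationDataset())
        assert m.total == 0 and m.coverage == 0.0

    def test_hand_computed_cell(self, small_dataset):
        m = substitution_matrix(small_dataset)
        count, mean, sd = m.cell("V", "A")
        assert count == 4
        assert mean == pytest.approx(-4.0)
        assert sd == pytest.approx(np.std([-1, -3, -5, -7], ddof=1))

    def test_threshold_semantics_one_entry_per_pair(self):
        from tmshift import AA_ALPHABET
        entries = [
            make_entry(wt_aa=a, mut_aa=b, d_tm=1.0)
            for a in AA_ALPHABET for b in AA_ALPHABET if a != b
        ]
        m = substitution_matrix(MutationDataset(entries=entries), report_threshold=3)
        assert m.coverage == 1.0
        assert m.mean_dtm.isna().all().all()

    def test_total_counts_equals_dataset_size(self, synthetic_medium):
        ds, _ = synthetic_medium
        assert substitution_matrix(ds).total == len(ds)

    def test_permutation_invariance(self, small_dataset):
        fwd = substitution_matrix(small_dataset)
        rev = substitution_matrix(
            MutationDataset(entries=list(reversed(small_dataset.entries)))
        )
        assert fwd.counts.equals(rev.counts)
        assert fwd.mean_dtm.fillna(0).equals(rev.mean_dtm.fillna(0))

    def test_reversed_half_is_transpose_negation(self, small_dataset):
        fwd_m = substitution_matrix(small_dataset)
        doubled = augment_with_reversed(small_dataset)
        rev_only = MutationDataset(entries=doubled.entries[len(small_dataset):])
        rev_m = substitution_matrix(rev_only)
        assert rev_m.counts.equals(fwd_m.counts.T)
        np.testing.assert_allclose(
            rev_m.mean_dtm.to_numpy(), -fwd_m.mean_dtm.T.to_numpy(), equal_nan=True
        )


class TestBinnedProfile:
    def test_equal_count_bins_balanced(self):
        rng = np.random.default_rng(0)
        entries = [
            make_entry(residue_number=i, rsa=float(rng.random()), d_tm=float(rng.normal()))
            for i in range(100)
        ]
        prof = binned_profile(MutationDataset(entries=entries), "rsa", 10)
        assert prof.counts == [10] * 10

    def test_mean_dtm_monotone_for_rsa_linear_generator(self):
        rsas = np.linspace(0, 1, 60)
        entries = [
            make_entry(residue_number=i, rsa=float(r), d_tm=float(-10 * (1 - r)))
            for i, r in enumerate(rsas)
        ]
        prof = binned_profile(MutationDataset(entries=entries), "rsa", 6)
        assert all(a < b for a, b in zip(prof.mean_dtm, prof.mean_dtm[1:]))

    def test_single_bin_mean_equals_dataset_mean(self, small_dataset):
        prof = binned_profile(small_dataset, "rsa", 1)
        assert prof.mean_dtm[0] == pytest.approx(
            np.mean([e.d_tm for e in small_dataset])
        )

    def test_too_few_annotated_entries_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            binned_profile(small_dataset, "rsa", 11)


@settings(deadline=None, derandomize=True)
@given(
    d_tms=st.lists(st.floats(-19.9, 19.9, allow_nan=False), min_size=1, max_size=40),
    threshold=st.floats(0.5, 5.0),
)
def test_classification_partitions_any_dataset(d_tms, threshold):
    cats = [classify_stability(d, threshold) for d in d_tms]
    assert len(cats) == len(d_tms)
    for d, c in zip(d_tms, cats):
        assert c == ("destabilizing" if d < -threshold else
                     "stabilizing" if d > threshold else "neutral")
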
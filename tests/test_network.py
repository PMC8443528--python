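"""Augmentation, splitting, training, prediction and evaluation."""

import numpy as np
import pytest

from tmshift import (
    MutationDataset,
    NetConfig,
    SplitSpec,
    SyntheticConfig,
    TrainedBaseline,
    augment_with_reversed,
    augment_with_wt,
    evaluate,
    predict,
    replicate_training,
    simulate_dataset,
    split_dataset,
    train_baseline,
)

from conftest import make_entry


@pytest.fixture(scope="module")
def linear_dataset():
    """200 noise-free entries following a per-substitution linear rule."""
    cfg = SyntheticConfig(
        n_entries=200, noise_sd=0.0, outlier_fraction=0.0,
        substitutions=(("V", "A"), ("I", "A"), ("L", "A"), ("G", "F")), seed=3,
    )
    ds, _ = simulate_dataset(cfg)
    return ds


class TestAugmentWithWT:
    def test_adds_exactly_n_rows_per_protein_with_zero_dtm(self, small_dataset):
        out = augment_with_wt(small_dataset, n_per_protein=15, seed=0)
        added = out.entries[len(small_dataset):]
        assert len(added) == 30  # 2 proteins x 15
        assert all(e.d_tm == 0.0 and e.wt_aa == e.mut_aa for e in added)
        assert out.entries[: len(small_dataset)] == small_dataset.entries

    def test_zero_rows_leaves_dataset_unchanged(self, small_dataset):
        out = augment_with_wt(small_dataset, n_per_protein=0)
        assert out.entries == small_dataset.entries

    def test_seed_reproducibility(self, small_dataset):
        a = augment_with_wt(small_dataset, seed=7)
        b = augment_with_wt(small_dataset, seed=7)
        assert a.entries == b.entries

    def test_unannotated_protein_skipped_with_warning(self, small_dataset):
        ds = MutationDataset(entries=small_dataset.entries + [
            make_entry(protein_id="P999", rsa=None, avg_b=None, ss_code=None)])
        with pytest.warns(UserWarning, match="P999"):
            out = augment_with_wt(ds, n_per_protein=5)
        assert len(out) == len(ds) + 10  # only the two annotated proteins


class TestAugmentWithReversed:
    def test_doubles_with_exact_antisymmetry(self, small_dataset):
        out = augment_with_reversed(small_dataset)
        n = len(small_dataset)
        assert len(out) == 2 * n
        for fwd, rev in zip(out.entries[:n], out.entries[n:]):
            assert fwd.d_tm + rev.d_tm == 0.0
            assert (rev.wt_aa, rev.mut_aa) == (fwd.mut_aa, fwd.wt_aa)
            assert (rev.rsa, rev.avg_b, rev.ss_code) == (fwd.rsa, fwd.avg_b, fwd.ss_code)

    def test_single_entry_example(self):
        ds = MutationDataset(entries=[make_entry(wt_aa="V", mut_aa="A", d_tm=-4.0)])
        out = augment_with_reversed(ds)
        rev = out.entries[1]
        assert (rev.wt_aa, rev.mut_aa, rev.d_tm) == ("A", "V", 4.0)


class TestSplit:
    def test_sizes_100_at_default_fractions(self, synthetic_medium):
        ds, _ = synthetic_medium
        sub = MutationDataset(entries=ds.entries[:100])
        tr, va, te = split_dataset(sub, SplitSpec(seed=0))
        assert (len(tr), len(va), len(te)) == (60, 30, 10)

    def test_partition_is_exhaustive_and_disjoint(self, synthetic_medium):
        ds, _ = synthetic_medium
        tr, va, te = split_dataset(ds, SplitSpec(seed=1))
        ids = lambda part: sorted(id(e) for e in part)
        assert sorted(ids(tr) + ids(va) + ids(te)) == sorted(id(e) for e in ds)

    def test_seed_reproducibility(self, synthetic_medium):
        ds, _ = synthetic_medium
        a = split_dataset(ds, SplitSpec(seed=5))
        b = split_dataset(ds, SplitSpec(seed=5))
        for pa, pb in zip(a, b):
            assert pa.entries == pb.entries

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(fractions=(0.5, 0.5, 0.2))


class TestTraining:
    def test_capacity_on_noise_free_linear_data(self, linear_dataset):
        tr, va, _ = split_dataset(linear_dataset, SplitSpec(seed=0))
        model = train_baseline(tr, va, NetConfig(seed=0, max_epochs=2000,
                                                 early_stop_patience=200))
        m = evaluate(predict(model, tr.entries), [e.d_tm for e in tr])
        assert m.rmse < 0.5

    def test_one_epoch_smoke_contract(self, linear_dataset):
        tr, va, _ = split_dataset(linear_dataset, SplitSpec(seed=0))
        model = train_baseline(tr, va, NetConfig(seed=0, max_epochs=1,
                                                 early_stop_patience=1))
        assert len(model.history) == 1 and model.best_epoch == 1

    def test_bitwise_determinism(self, linear_dataset):
        tr, va, _ = split_dataset(linear_dataset, SplitSpec(seed=0))
        cfg = NetConfig(seed=4, max_epochs=40, early_stop_patience=40)
        m1 = train_baseline(tr, va, cfg)
        m2 = train_baseline(tr, va, cfg)
        assert m1.to_json() == m2.to_json()

    def test_zero_target_model_predicts_near_zero(self, linear_dataset):
        zero = MutationDataset(entries=[
            make_entry(protein_id=e.protein_id, residue_number=e.residue_number,
                       wt_aa=e.wt_aa, mut_aa=e.mut_aa, d_tm=0.0,
                       rsa=e.rsa, avg_b=e.avg_b, ss_code=e.ss_code)
            for e in linear_dataset])
        tr, va, te = split_dataset(zero, SplitSpec(seed=0))
        model = train_baseline(tr, va, NetConfig(seed=0, max_epochs=1000,
                                                 early_stop_patience=150))
        # near-zero on the fitted points; small on average off them (the
        # unregularized net may wiggle slightly between training inputs)
        assert np.max(np.abs(predict(model, tr.entries))) < 0.1
        assert np.mean(np.abs(predict(model, te.entries))) < 0.1

    def test_serialization_round_trip(self, linear_dataset):
        tr, va, te = split_dataset(linear_dataset, SplitSpec(seed=0))
        model = train_baseline(tr, va, NetConfig(seed=0, max_epochs=20,
                                                 early_stop_patience=20))
        clone = TrainedBaseline.from_json(model.to_json())
        np.testing.assert_array_equal(predict(model, te.entries),
                                      predict(clone, te.entries))

    def test_empty_sets_rejected(self, linear_dataset):
        with pytest.raises(ValueError):
            train_baseline(MutationDataset(), linear_dataset)


class TestEvaluate:
    def test_perfect_predictions(self):
        m = evaluate([1.0, -2.0, 3.0], [1.0, -2.0, 3.0])
        assert m.rmse == 0.0 and m.pearson_r == pytest.approx(1.0)

    def test_constant_offset(self):
        obs = np.array([0.0, 1.0, -2.0, 4.0])
        m = evaluate(obs + 0.5, obs)
        assert m.rmse == pytest.approx(0.5)
        assert m.error_band_fractions["lt_1"] == 1.0

    def test_matches_direct_formulas_on_hand_sized_example(self):
        p = np.array([1.0, 2.0, -1.5, 0.3, 4.0])
        o = np.array([0.5, 2.5, -2.0, 1.3, 2.0])
        m = evaluate(p, o)
        resid = p - o
        assert m.rmse == pytest.approx(np.sqrt(np.mean(resid**2)), abs=1e-12)
        r_direct = (np.mean(p * o) - p.mean() * o.mean()) / (p.std() * o.std())
        assert m.pearson_r == pytest.approx(r_direct, abs=1e-12)
        a = np.abs(resid)  # 0.5, 0.5, 0.5, 1.0, 2.0
        assert m.error_band_fractions["lt_1"] == pytest.approx(0.6)
        assert m.error_band_fractions["1_to_4"] == pytest.approx(0.4)

    def test_band_overlap_invariant(self, synthetic_medium):
        ds, _ = synthetic_medium
        obs = np.array([e.d_tm for e in ds])
        rng = np.random.default_rng(0)
        m = evaluate(obs + rng.normal(0, 6, len(obs)), obs)
        bands = m.error_band_fractions
        assert bands["ge_10"] <= bands["gt_5"]

    def test_zero_variance_flags_undefined_r(self):
        m = evaluate([1.0, 1.0, 1.0], [0.0, 2.0, 1.0])
        assert m.r_undefined and m.pearson_r is None and m.rmse > 0


class TestReplicates:
    def test_cardinality_and_selection(self, linear_dataset):
        cfg = NetConfig(seed=0, max_epochs=60, early_stop_patience=20)
        res = replicate_training(linear_dataset, n_replicates=3, cfg=cfg)
        assert len(res["replicates"]) == 3
        assert res["selected"] in range(3)
        rmses = [r["metrics"]["validation"].rmse for r in res["replicates"]]
        assert rmses[res["selected"]] == min(rmses)

    def test_dispersion_reported(self, linear_dataset):
        cfg = NetConfig(seed=0, max_epochs=60, early_stop_patience=20)
        res = replicate_training(linear_dataset, n_replicates=3, cfg=cfg)
        d = res["dispersion"]
        assert d["min_test_rmse"] <= d["median_test_rmse"] <= d["max_test_rmse"]

    def test_selection_invariant_to_replicate_order(self, linear_dataset):
        cfg = NetConfig(seed=0, max_epochs=30, early_stop_patience=20)
        a = replicate_training(linear_dataset, n_replicates=3, cfg=cfg,
                               split_seeds=[0, 1, 2])
        b = replicate_training(linear_dataset, n_replicates=3, cfg=cfg,
                               split_seeds=[2, 1, 0])
        sa = a["replicates"][a["selected"]]["split_seed"]
        sb = b["replicates"][b["selected"]]["split_seed"]
        assert sa == sb
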
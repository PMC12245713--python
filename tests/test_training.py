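import dataclasses

import numpy as np
import pytest

from sleepstager.io_edf import Hypnogram, STAGES
from sleepstager.model import ModelConfig, SleepStager
from sleepstager.preprocess import EpochedRecording, epoch_signal, make_windows, resample_recording
from sleepstager.synthetic import SynthParams, generate_subject
from sleepstager.training import (
    TrainConfig,
    grid_search,
    make_validation_split,
    reduced_recipe,
    split_loocv,
    train_model,
)
from sleepstager import evaluation as ev


class TestSplitLoocv:
    def test_16_subjects_give_16_folds_of_15(self):
        plan = split_loocv([f"rat{i}" for i in range(16)])
        assert plan.n_jobs == 16
        for test_ids, train_ids in plan:
            assert len(test_ids) == 1 and len(train_ids) == 15

    def test_minimal_two_subject_plan(self):
        plan = split_loocv(["a", "b"])
        assert plan.n_jobs == 2
        assert all(len(tr) == 1 for _, tr in plan)

    def test_16_plus_22_fold_plans_give_38_jobs(self):
        p16 = split_loocv([f"a{i}" for i in range(16)])
        p22 = split_loocv([f"b{i}" for i in range(22)])
        assert p16.n_jobs + p22.n_jobs == 38

    def test_no_subject_leakage(self):
        plan = split_loocv([f"r{i}" for i in range(8)])
        seen = []
        for test_ids, train_ids in plan:
            assert not set(test_ids) & set(train_ids)
            assert set(test_ids) | set(train_ids) == {f"r{i}" for i in range(8)}
            seen += list(test_ids)
        assert sorted(seen) == sorted(f"r{i}" for i in range(8))

    def test_errors(self):
        with pytest.raises(ValueError, match="duplicate"):
            split_loocv(["a", "a", "b"])
        with pytest.raises(ValueError, match="at least 2"):
            split_loocv(["solo"])


class TestValidationSplit:
    def _dataset(self, rng, n):
        e = EpochedRecording("s", rng.normal(0, 1, (n, 20)),
                             epoch_length_s=10.0, sampling_rate=2.0)
        labels = Hypnogram("s", 10.0, np.array(list("PSW"))[rng.integers(0, 3, n)])
        return make_windows(e, labels, k=3)

    def test_size_and_contiguity(self, rng):
        ds = self._dataset(rng, 10_000)
        train, val = make_validation_split([ds], fraction=0.05, seed=4)
        n_val = len(val[0])
        assert abs(n_val - 500) <= 1
        assert np.all(np.diff(val[0].indices) == 1)  # one contiguous block
        assert not set(train[0].indices) & set(val[0].indices)
        assert len(train[0]) + n_val == 10_000

    def test_degenerate_fractions_rejected(self, rng):
        ds = self._dataset(rng, 100)
        for frac in (0.0, 1.0):
            with pytest.raises(ValueError):
                make_validation_split([ds], fraction=frac, seed=0)

    def test_seed_reproducibility(self, rng):
        ds = self._dataset(rng, 500)
        _, v1 = make_validation_split([ds], 0.05, seed=9)
        _, v2 = make_validation_split([ds], 0.05, seed=9)
        np.testing.assert_array_equal(v1[0].indices, v2[0].indices)


def _toy_data(n_epochs, seed, rate=25.0, subject="s"):
    params = SynthParams()
    rec, hyp = generate_subject(params, n_epochs, seed, subject_id=subject)
    rec = resample_recording(rec, rate)
    return epoch_signal(rec), hyp


def _toy_setup(rng, n_epochs=24, seed=0):
    mcfg = ModelConfig(epoch_samples=250, block_channels=(4, 6, 6), lstm_dim=8,
                       window_k=3, seed=seed)
    e, h = _toy_data(n_epochs, seed)
    ds = make_windows(e, h, k=3)
    return mcfg, make_validation_split([ds], 0.2, seed)


class TestTrainModel:
    def test_early_stopping_with_patience_one(self, rng):
        """With lr=0 the validation loss can never improve after the first
        epoch, so patience 1 stops training at epoch 2."""
        mcfg, (tr, va) = _toy_setup(rng)
        tcfg = TrainConfig(learning_rate=0.0, early_stop_patience=1,
                           max_epochs=50, val_fraction=0.2, batch_size=8, seed=0)
        _, hist = train_model(tr, va, mcfg, tcfg)
        assert len(hist) == 2

    def test_returns_best_checkpoint_not_last(self, rng):
        mcfg, (tr, va) = _toy_setup(rng, n_epochs=36)
        tcfg = TrainConfig(learning_rate=3e-3, early_stop_patience=3,
                           max_epochs=8, batch_size=8, val_fraction=0.2, seed=1)
        model, hist = train_model(tr, va, mcfg, tcfg)
        from sleepstager.training import _mean_loss, _as_subsets
        final_val = hist["val_loss"].iloc[-1]
        returned_val = _mean_loss(model, _as_subsets(va), 8)
        assert returned_val <= final_val + 1e-9
        assert returned_val == pytest.approx(hist["val_loss"].min(), abs=1e-9)

    def test_seeded_training_is_deterministic(self, rng):
        mcfg, (tr, va) = _toy_setup(rng)
        tcfg = TrainConfig(learning_rate=1e-3, max_epochs=3, early_stop_patience=5,
                           batch_size=8, val_fraction=0.2, seed=2)
        m1, h1 = train_model(tr, va, mcfg, tcfg)
        m2, h2 = train_model(tr, va, mcfg, tcfg)
        assert h1["val_loss"].tolist() == h2["val_loss"].tolist()
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_single_class_labels_warn(self, rng):
        mcfg = ModelConfig(epoch_samples=250, block_channels=(4, 6, 6), lstm_dim=8,
                           window_k=3, seed=0)
        e = EpochedRecording("s", rng.normal(0, 1, (20, 250)),
                            epoch_length_s=10.0, sampling_rate=25.0)
        h = Hypnogram("s", 10.0, np.array(["W"] * 20))
        tr, va = make_validation_split([make_windows(e, h, k=3)], 0.2, 0)
        tcfg = TrainConfig(learning_rate=1e-3, max_epochs=1, batch_size=8,
                           val_fraction=0.2, seed=0)
        with pytest.warns(UserWarning, match="single class"):
            train_model(tr, va, mcfg, tcfg)

    def test_empty_sets_rejected(self, rng):
        mcfg, (tr, va) = _toy_setup(rng)
        tcfg = TrainConfig(max_epochs=1, seed=0)
        with pytest.raises(ValueError, match="empty training"):
            train_model([], va, mcfg, tcfg)
        with pytest.raises(ValueError, match="empty validation"):
            train_model(tr, [], mcfg, tcfg)

    def test_toy_cohort_reaches_high_macro_f1(self):
        """Two easy synthetic subjects train to macro F1 >= 0.85 on their own
        recordings under the reduced desk-scale recipe (seed-pinned)."""
        recipe = reduced_recipe(seed=3)
        cohort = {s: _toy_data(90, 900 + i, recipe.target_rate, s)
                  for i, s in enumerate(["a", "b"])}
        datasets = [make_windows(e, h, k=9, standardize=True)
                    for e, h in cohort.values()]
        tr, va = make_validation_split(datasets, 0.1, 3)
        # a small cohort sees few gradient steps per epoch, so allow more epochs
        tcfg = dataclasses.replace(recipe.train, max_epochs=80,
                                   early_stop_patience=20)
        model, _ = train_model(tr, va, recipe.model, tcfg)
        f1s = []
        for (e, h), ds in zip(cohort.values(), datasets):
            probs = model.predict_proba(ds.batch(np.arange(ds.n_windows)))
            pred = Hypnogram("x", 10.0,
                             np.array([STAGES[j] for j in probs.argmax(1)]))
            f1s.append(ev.class_metrics(ev.confusion_matrix(pred, h)).macro_f1)
        assert np.mean(f1s) >= 0.85


class TestGridSearch:
    def _data(self, rng):
        return [_toy_data(24, seed) for seed in (5, 6)]

    def _cfgs(self):
        mcfg = ModelConfig(epoch_samples=250, block_channels=(4, 6, 6), lstm_dim=8,
                           window_k=3, seed=0)
        tcfg = TrainConfig(learning_rate=1e-3, max_epochs=1, batch_size=8,
                           val_fraction=0.2, seed=0)
        return mcfg, tcfg

    def test_single_combination_returned(self, rng):
        mcfg, tcfg = self._cfgs()
        grid = {"learning_rate": [1e-3], "batch_size": [8], "window_k": [3]}
        best_m, best_t, table = grid_search(grid, self._data(rng), mcfg, tcfg)
        assert len(table) == 1
        assert best_t.learning_rate == 1e-3 and best_t.batch_size == 8
        assert best_m.window_k == 3

    def test_2x2_grid_gives_4_rows(self, rng):
        mcfg, tcfg = self._cfgs()
        grid = {"learning_rate": [1e-3, 3e-3], "batch_size": [8, 16]}
        _, _, table = grid_search(grid, self._data(rng), mcfg, tcfg)
        assert len(table) == 4
        assert table["best_val_loss"].notna().all()

    def test_empty_grid_axis_rejected(self, rng):
        mcfg, tcfg = self._cfgs()
        with pytest.raises(ValueError, match="nonempty"):
            grid_search({"learning_rate": []}, self._data(rng), mcfg, tcfg)

    def test_native_operating_point_is_searchable(self, rng):
        """The configuration actually used downstream (lr 3e-4, batch 32,
        9-epoch windows) must be expressible as a grid point."""
        grid = {"learning_rate": [1e-4, 3e-4, 1e-3],
                "batch_size": [16, 32, 64],
                "window_k": [5, 9, 13]}
        assert 3e-4 in grid["learning_rate"]
        assert 32 in grid["batch_size"]
        assert 9 in grid["window_k"]
        assert TrainConfig().learning_rate == 3e-4
        assert TrainConfig().batch_size == 32
        assert ModelConfig().window_k == 9
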
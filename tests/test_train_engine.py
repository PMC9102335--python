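import numpy as np
import pytest

from cnsvm.errors import ConfigError, StratificationError, TrainingError
from cnsvm.model_core import build_model, compact_config
from cnsvm.spectra_io import SignatureSet, SpectralWindow, WavelengthGrid, crop_to_window
from cnsvm.synthetic_data import simulate_signatures
from cnsvm.train_engine import (
    AdamState,
    CLRSchedule,
    TrainConfig,
    adam_step,
    clr_at,
    fit,
    sgd_step,
    stratified_split,
)
from conftest import quick_separable_config


class TestCLR:
    sched = CLRSchedule(base_lr=1e-4, max_lr=1e-2, step_size=8)

    def test_starts_at_base(self):
        assert clr_at(self.sched, 0) == pytest.approx(1e-4)

    def test_first_peak_is_max(self):
        assert clr_at(self.sched, 8) == pytest.approx(1e-2)

    def test_second_peak_halves_amplitude(self):
        assert clr_at(self.sched, 24) == pytest.approx(0.00505)

    def test_peak_sequence_halves_for_five_cycles(self):
        for cycle in range(5):
            peak_iter = (2 * cycle + 1) * self.sched.step_size
            expected = 1e-4 + (1e-2 - 1e-4) / 2**cycle
            assert clr_at(self.sched, peak_iter) == pytest.approx(expected)

    def test_returns_to_base_at_cycle_end(self):
        assert clr_at(self.sched, 16) == pytest.approx(1e-4)

    def test_negative_iteration_rejected(self):
        with pytest.raises(ConfigError):
            clr_at(self.sched, -1)


class TestOptimizerSteps:
    def test_sgd_zero_gradient(self):
        assert sgd_step(np.array(1.0), np.array(0.0), 0.5) == 1.0

    def test_sgd_hand_arithmetic(self):
        assert sgd_step(np.array(1.0), np.array(2.0), 0.1) == pytest.approx(0.8)

    def test_sgd_zero_lr(self):
        assert sgd_step(np.array(1.0), np.array(5.0), 0.0) == 1.0

    def test_adam_zero_gradient_keeps_weights(self):
        w = np.array([1.0, -2.0])
        state = AdamState.zeros_like(w)
        for _ in range(5):
            state, w = adam_step(state, w, np.zeros_like(w), 0.01)
        assert np.array_equal(w, [1.0, -2.0])

    def test_adam_first_step_is_about_lr(self):
        w = np.array([0.0])
        state, w = adam_step(AdamState.zeros_like(w), w, np.array([1.0]), 0.001)
        # bias correction makes the first step ~ lr regardless of moments
        assert w[0] == pytest.approx(-0.001, rel=1e-3)

    def test_adam_symmetric_for_equal_gradients(self):
        w = np.array([1.0, 1.0])
        state, w2 = adam_step(AdamState.zeros_like(w), w, np.array([0.3, 0.3]), 0.01)
        assert w2[0] == w2[1]


class TestStratifiedSplit:
    def make(self, n_pos, n_neg, seed=0):
        grid = WavelengthGrid(500.0, 2.0, 5)
        rng = np.random.default_rng(seed)
        labels = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])
        return SignatureSet(grid, rng.normal(size=(n_pos + n_neg, 5)), labels)

    def test_study_sample_split_sizes(self):
        s = self.make(504, 488)
        train, val = stratified_split(s, 0.70, seed=0)
        assert len(train) == 694 and len(val) == 298  # floor(0.7 * 992) = 694

    def test_class_proportions_within_one(self):
        s = self.make(504, 488)
        train, _ = stratified_split(s, 0.70, seed=0)
        counts = train.label_counts()
        assert abs(counts[1] - 0.7 * 504) <= 1
        assert abs(counts[0] - 0.7 * 488) <= 1

    def test_balanced_small_split(self):
        s = self.make(5, 5)
        train, val = stratified_split(s, 0.5, seed=1)
        assert len(train) == 5 and len(val) == 5
        assert train.label_counts() == {0: 2, 1: 3} or train.label_counts() == {0: 3, 1: 2}

    def test_disjoint_union(self):
        s = self.make(20, 30, seed=2)
        s_rows = {tuple(r) for r in s.reflectance}
        train, val = stratified_split(s, 0.6, seed=2)
        got = [tuple(r) for r in np.vstack([train.reflectance, val.reflectance])]
        assert len(got) == 50 and set(got) == s_rows

    def test_seeded_determinism(self):
        s = self.make(20, 20)
        a = stratified_split(s, 0.7, seed=9)
        b = stratified_split(s, 0.7, seed=9)
        assert np.array_equal(a[0].reflectance, b[0].reflectance)

    def test_empty_class_is_stratification_error(self):
        s = self.make(10, 10)
        only_pos = s.subset(np.flatnonzero(s.labels == 1))
        with pytest.raises(StratificationError):
            stratified_split(only_pos, 0.7, seed=0)


@pytest.fixture(scope="module")
def separable_fit():
    s = crop_to_window(
        simulate_signatures(quick_separable_config(seed=21)), SpectralWindow.default()
    )
    handle = build_model(compact_config(), seed=21)
    handle, log = fit(handle, s, TrainConfig(epochs=50, batch_size=32, seed=21))
    return s, handle, log


class TestFit:
    def test_separable_data_reaches_high_train_accuracy(self, separable_fit):
        _, _, log = separable_fit
        assert log.train_accuracy[-1] >= 0.99

    def test_loss_mostly_non_increasing_early(self, separable_fit):
        _, _, log = separable_fit
        first10 = np.array(log.train_loss[:11])
        non_increasing = np.sum(np.diff(first10) <= 0)
        assert non_increasing >= 8

    def test_one_record_per_epoch(self, separable_fit):
        _, _, log = separable_fit
        assert log.epoch == list(range(50))

    def test_standardization_comes_from_train_partition_only(self, separable_fit):
        s, handle, _ = separable_fit
        train, _ = stratified_split(s, 0.70, seed=21)  # same seed as fit uses
        assert np.allclose(handle.scaler_mean, train.reflectance.mean(axis=0))
        assert np.allclose(
            handle.scaler_sd, np.where(train.reflectance.std(axis=0) == 0, 1,
                                       train.reflectance.std(axis=0))
        )

    def test_zero_epochs_rejected(self):
        with pytest.raises(ConfigError):
            TrainConfig(epochs=0)

    def test_unlabelled_data_is_training_error(self):
        grid = WavelengthGrid(500.0, 2.0, 94)
        s = SignatureSet(grid, np.random.default_rng(0).normal(size=(10, 94)))
        handle = build_model(compact_config(), seed=0)
        with pytest.raises(TrainingError):
            fit(handle, s, TrainConfig(epochs=1))

    def test_same_seed_reproduces_final_validation_loss(self):
        s = crop_to_window(
            simulate_signatures(quick_separable_config(seed=8)), SpectralWindow.default()
        )
        cfg = TrainConfig(epochs=3, batch_size=64, seed=8)
        _, log_a = fit(build_model(compact_config(), seed=8), s, cfg)
        _, log_b = fit(build_model(compact_config(), seed=8), s, cfg)
        assert log_a.val_loss[-1] == log_b.val_loss[-1]

    def test_adam_optimizer_trains(self):
        s = crop_to_window(
            simulate_signatures(quick_separable_config(seed=13)), SpectralWindow.default()
        )
        cfg = TrainConfig(optimizer="adam", epochs=5, batch_size=64, seed=13,
                          clr=CLRSchedule(base_lr=1e-4, max_lr=2e-3, step_size=2))
        _, log = fit(build_model(compact_config(), seed=13), s, cfg)
        assert log.train_loss[-1] < log.train_loss[0]
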
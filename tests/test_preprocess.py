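"""Filtering, synchronization, normalization, the ensemble sanity filter and
tensor assembly."""

import numpy as np
import pytest

from imugait import preprocess as pp
from imugait.preprocess import (
    DatasetTensors,
    Sample,
    apply_scalers,
    assemble_flat,
    assemble_image,
    assemble_sequence,
    ci_filter,
    fit_scalers,
    flat_to_sequence,
    moment_denormalize,
    moment_normalize,
    native_image_grid,
    sync_lag,
    time_normalize,
    zero_lag_butter,
)


class TestButter:
    def test_constant_unchanged(self):
        x = np.full((3, 200), 4.2)
        assert np.allclose(zero_lag_butter(x, 4, 6.0, 100.0), 4.2, atol=1e-9)

    def test_passband_zero_lag(self):
        t = np.arange(0, 4, 0.01)
        x = np.sin(2 * np.pi * 2.0 * t)
        y = zero_lag_butter(x, 4, 6.0, 100.0)
        assert sync_lag(x, y, 20) == 0  # no phase shift
        assert y[50:-50].max() >= 0.95 * x[50:-50].max()

    def test_stopband_attenuated(self):
        t = np.arange(0, 4, 0.01)
        x = np.sin(2 * np.pi * 30.0 * t)
        y = zero_lag_butter(x, 1, 5.0, 100.0)
        assert np.abs(y[100:-100]).max() < 0.2

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            zero_lag_butter(np.zeros(100), 4, 60.0, 100.0)


class TestSyncLag:
    def test_identical_series(self, rng):
        x = rng.normal(size=500)
        assert sync_lag(x, x, 50) == 0

    def test_constructed_shift(self, rng):
        x = np.convolve(rng.normal(size=600), np.ones(20) / 20, "same")
        assert sync_lag(x[7:], x[:-7], 40) == 7  # b delayed by 7

    def test_shift_under_noise(self):
        # SNR 10: recovered lag within ±1 sample in each of 100 repetitions
        rng = np.random.default_rng(7)
        misses = 0
        for _ in range(100):
            x = np.convolve(rng.normal(size=500), np.ones(25) / 25, "same")
            snr_sigma = x.std() / np.sqrt(10)
            a = x[5:] + rng.normal(0, snr_sigma, 495)
            b = x[:-5] + rng.normal(0, snr_sigma, 495)
            if abs(sync_lag(a, b, 30) - 5) > 1:
                misses += 1
        assert misses == 0

    def test_flat_input_rejected(self):
        with pytest.raises(ValueError):
            sync_lag(np.ones(100), np.ones(100), 10)


class TestTimeNormalize:
    def test_default_length_101(self, rng):
        x = rng.normal(size=(5, 300))
        assert time_normalize(x, 20, 250).shape == (5, 101)

    def test_linear_ramp_preserved(self):
        x = np.arange(100.0)
        y = time_normalize(x, 10, 60, 101)
        assert y[0] == 10.0 and y[-1] == 60.0
        assert np.allclose(np.diff(y), np.diff(y)[0])

    def test_identity_resampling(self, rng):
        x = rng.normal(size=80)
        y = time_normalize(x, 10, 50, 41)
        assert np.allclose(y, x[10:51], atol=1e-12)

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValueError):
            time_normalize(np.zeros(50), 30, 30)


class TestMomentNormalize:
    def test_unit_case(self):
        assert moment_normalize(np.array([70.0 * 9.81 * 1.8]), 70.0, 1.8) == 1.0

    def test_round_trip(self, rng):
        m = rng.normal(size=(18, 101))
        back = moment_denormalize(moment_normalize(m, 80, 1.7), 80, 1.7)
        assert np.abs(back - m).max() < 1e-12

    def test_invalid_mass_rejected(self):
        with pytest.raises(ValueError):
            moment_normalize(np.zeros(3), -1.0, 1.7)


class TestCIFilter:
    def test_identical_samples_none_excluded(self):
        x = np.tile(np.sin(np.linspace(0, 6, 101)), (20, 2, 1))
        with pytest.warns(UserWarning):
            report = ci_filter(x)
        assert report.excluded == []

    def test_constructed_outlier_excluded(self, rng):
        base = np.sin(np.linspace(0, 6, 101))
        x = base + rng.normal(0, 0.1, (100, 101))
        sd = x.std(axis=0)
        x[37] = base + 10 * sd
        report = ci_filter(x)
        assert 37 in report.excluded

    def test_gaussian_calibration(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(1000, 18, 101))
        report = ci_filter(x, level=0.95)
        frac = len(report.excluded) / 1000
        assert 0.03 <= frac <= 0.07

    def test_near_idempotent(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(1000, 18, 101))
        first = ci_filter(x)
        second = ci_filter(x[first.kept])
        assert len(second.excluded) <= 0.01 * len(first.kept)

    def test_minimum_sample_count(self, rng):
        with pytest.raises(ValueError):
            ci_filter(rng.normal(size=(5, 10)))


def _samples(n, n_points=101, seed=0):
    rng = np.random.default_rng(seed)
    return [
        Sample(
            x=rng.normal(size=(30, n_points)),
            y=rng.normal(size=(18, n_points)),
            index=(f"S{i % 3}", i, "measured"),
        )
        for i in range(n)
    ]


class TestAssembly:
    def test_flat_shapes(self):
        t = assemble_flat(_samples(10))
        assert t.X.shape == (10, 3030) and t.Y.shape == (10, 1818)

    def test_sequence_shapes(self):
        t = assemble_sequence(_samples(10))
        assert t.X.shape == (10, 30, 101) and t.Y.shape == (10, 18, 101)

    def test_flat_sequence_interconvert_bitwise(self):
        s = _samples(6)
        flat = assemble_flat(s)
        seq = assemble_sequence(s)
        assert np.array_equal(seq.X.reshape(6, -1), flat.X)
        assert np.array_equal(flat_to_sequence(flat.X, 30), seq.X)
        assert np.array_equal(flat_to_sequence(flat.X, 30)[0], s[0].x)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assemble_flat([])

    def test_inconsistent_lengths_rejected(self):
        s = _samples(3) + _samples(1, n_points=50)
        with pytest.raises(ValueError):
            assemble_sequence(s)

    def test_image_shape(self):
        t = assemble_image(_samples(3), side=224)
        assert t.X.shape == (3, 224, 224, 3)
        assert t.Y.shape == (3, 1818)

    def test_native_grid_interconverts_with_sequence(self):
        s = _samples(4)
        grid = native_image_grid(s)
        seq = assemble_sequence(s)
        assert grid.shape == (4, 10, 101, 3)
        assert np.array_equal(
            grid.transpose(0, 1, 3, 2).reshape(4, 30, 101), seq.X
        )

    def test_constant_signals_constant_image(self):
        s = [Sample(np.full((30, 101), 2.0), np.zeros((18, 101)), ("S0", 0, "m"))]
        img = assemble_image(s, side=32).X[0]
        assert np.ptp(img) == 0.0

    def test_axis_to_channel_mapping(self):
        x = np.zeros((30, 101))
        x[0::3] = np.sin(np.linspace(0, 6, 101))  # only x axes active
        s = [Sample(x, np.zeros((18, 101)), ("S0", 0, "m"))]
        img = assemble_image(s, side=32).X[0]
        assert np.ptp(img[..., 0]) > 0
        assert np.ptp(img[..., 1]) == 0 and np.ptp(img[..., 2]) == 0


class TestScalers:
    def test_train_standardized(self):
        t = fit_scalers(assemble_flat(_samples(20)))
        assert np.abs(t.X.mean(axis=0)).max() < 1e-9
        assert np.abs(t.X.std(axis=0) - 1).max() < 1e-9
        assert np.abs(t.Y.mean(axis=0)).max() < 1e-9

    def test_inverse_round_trip(self):
        raw = assemble_sequence(_samples(12))
        t = fit_scalers(raw)
        back = t.y_scaler.inverse(t.Y)
        assert np.abs(back - raw.Y).max() < 1e-9

    def test_constant_feature_guard(self):
        s = _samples(8)
        for smp in s:
            smp.x[5] = 3.0  # constant channel
        t = fit_scalers(assemble_sequence(s))
        assert np.allclose(t.X[:, 5], 0.0)
        assert np.isfinite(t.X).all()

    def test_unfitted_scaler_rejected(self):
        raw = assemble_flat(_samples(4))
        with pytest.raises(RuntimeError):
            apply_scalers(raw, DatasetTensors("flat", raw.X, raw.Y,
                                              raw.sample_index))

    def test_statistics_independent_of_test_partition(self):
        train = assemble_flat(_samples(10, seed=1))
        test_a = assemble_flat(_samples(5, seed=2))
        test_b = assemble_flat(_samples(5, seed=3))  # perturbed test set
        fitted = fit_scalers(train)
        sa = apply_scalers(test_a, fitted)
        assert np.array_equal(fitted.x_scaler.center,
                              fit_scalers(train).x_scaler.center)
        # scaling of one test set unaffected by existence of the other
        sb = apply_scalers(test_b, fitted)
        sa2 = apply_scalers(test_a, fitted)
        assert np.array_equal(sa.X, sa2.X)
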
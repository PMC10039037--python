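"""Classifier behavior: linear-window scorers, Sadeh, Sazonov, z-angle, RF."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actisleep.classifiers import (
    LinearWindowModel,
    SadehParams,
    SazonovParams,
    VanHeesParams,
    classify_linear_window,
    classify_sadeh,
    classify_sazonov,
    classify_vanhees,
    compute_z_angle,
    reference_classifier,
)
from actisleep.core import SLEEP, WAKE, EpochGrid, RawRecording, SleepWakeSeries
from actisleep.errors import ParameterError, TrainingError
from actisleep.presets import load_presets
from actisleep.rf import extract_rf_features, train_apply_rf, train_rf
from conftest import START


def _grid(n):
    return EpochGrid(START, n)


@pytest.fixture(scope="module")
def presets():
    return load_presets()


class TestLinearWindow:
    def test_cole_kripke_zero_counts_all_sleep(self, presets):
        m = LinearWindowModel.from_preset("cole_kripke", presets)
        out = classify_linear_window(np.zeros(20), m, _grid(20))
        assert out.labels.sum() == 20

    def test_cole_kripke_hand_evaluated_spike(self, presets):
        # one minute with 10000 counts: D = 0.001 * 230 * 10000 = 2300 >= 1
        # at the spike; neighbours within the -4..+2 window also exceed 1
        m = LinearWindowModel.from_preset("cole_kripke", presets)
        counts30 = np.zeros(40)
        counts30[20] = counts30[21] = 5000.0  # minute 10 sums to 10000
        out = classify_linear_window(counts30, m, _grid(40))
        # minutes 8..14 see the spike through offsets +2..-4 -> epochs 16..29
        assert np.all(out.labels[16:30] == WAKE)
        assert np.all(out.labels[:16] == SLEEP)
        assert np.all(out.labels[30:] == SLEEP)

    def test_single_epoch_input(self, presets):
        m = LinearWindowModel.from_preset("cole_kripke", presets)
        out = classify_linear_window(np.array([0.0]), m, _grid(1))
        assert len(out) == 1 and out.labels[0] == SLEEP

    def test_oakley_threshold_semantics(self, presets):
        m = LinearWindowModel.from_preset("oakley", presets)
        # constant 40 per minute scores 40 * (1 + 2*0.2 + 2*0.04) = 59.2 > 40
        out = classify_linear_window(np.full(20, 20.0), m, _grid(20))
        assert out.labels.sum() == 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 1e4), min_size=1, max_size=60),
        st.floats(0.1, 10),
        st.floats(0, 5000),
    )
    def test_single_weight_reduces_to_thresholding(self, vals, w, thr):
        counts = np.asarray(vals)
        m = LinearWindowModel("thr", {0: w}, 1.0, thr, "score_at_or_below", 30)
        out = classify_linear_window(counts, m, _grid(len(counts)))
        oracle = (w * counts <= thr).astype(np.uint8)
        assert np.array_equal(out.labels, oracle)

    def test_empty_input_rejected(self, presets):
        m = LinearWindowModel.from_preset("oakley", presets)
        with pytest.raises(ParameterError):
            classify_linear_window(np.array([]), m, _grid(0))


class TestSadeh:
    def test_zero_counts_all_sleep(self):
        out = classify_sadeh(np.zeros(30), SadehParams(), _grid(30))
        assert out.labels.sum() == 30  # PS = intercept = 7.601 >= 0

    def test_constant_75_per_minute_is_wake(self):
        # MW5 = 75, NAT = 11, SD6 = 0, LG = ln 76:
        # PS = 7.601 - 4.875 - 11.88 - 0 - 3.043 < 0 -> wake
        out = classify_sadeh(np.full(44, 37.5), SadehParams(), _grid(44))
        assert out.labels.sum() == 0
        ps = (7.601 - 0.065 * 75 - 1.08 * 11 - 0.703 * np.log(76))
        assert ps < 0

    @pytest.mark.parametrize("n", [1, 2, 7, 44])
    def test_output_length_preserved(self, n, rng):
        out = classify_sadeh(rng.uniform(0, 100, n), SadehParams(), _grid(n))
        assert len(out) == n


class TestSazonov:
    def test_zero_counts_all_sleep(self):
        out = classify_sazonov(np.zeros(10), SazonovParams(), _grid(10))
        assert out.labels.sum() == 10  # logistic(1.727) ~ 0.849 >= 0.5

    def test_large_counts_all_wake(self):
        out = classify_sazonov(np.full(10, 1e5), SazonovParams(), _grid(10))
        assert out.labels.sum() == 0

    def test_trailing_max_hand_case(self):
        # spike then zeros: windows 1..5 keep seeing the spike for 5 epochs
        counts = np.zeros(10)
        counts[2] = 100.0
        out = classify_sazonov(counts, SazonovParams(), _grid(10))
        assert np.all(out.labels[2:7] == WAKE)
        assert np.all(out.labels[7:] == SLEEP)
        assert np.all(out.labels[:2] == SLEEP)


class TestZAngle:
    @pytest.mark.parametrize(
        "vec,expected",
        [((0, 0, 1), 90.0), ((1, 0, 0), 0.0), ((0.5, 0.5, 0.7071), 45.0)],
    )
    def test_constant_orientations(self, vec, expected):
        n = 500
        r = RawRecording("s", START, 50.0,
                         np.full(n, vec[0]), np.full(n, vec[1]), np.full(n, vec[2]))
        angles, _ = compute_z_angle(r, VanHeesParams())
        assert angles == pytest.approx(expected, abs=0.01)

    def test_positive_scale_invariance(self, rng):
        n = 2000
        x, y, z = rng.normal(0, 0.3, (3, n)) + [[0.2], [0.1], [0.9]]
        r1 = RawRecording("s", START, 50.0, x, y, z)
        r2 = RawRecording("s", START, 50.0, 3.7 * x, 3.7 * y, 3.7 * z)
        a1, _ = compute_z_angle(r1, VanHeesParams())
        a2, _ = compute_z_angle(r2, VanHeesParams())
        assert np.allclose(a1, a2, atol=1e-9)

    def test_all_zero_vector_warns_and_zeroes(self):
        n = 300
        r = RawRecording("s", START, 50.0, np.zeros(n), np.zeros(n), np.zeros(n))
        with pytest.warns(UserWarning):
            angles, _ = compute_z_angle(r, VanHeesParams())
        assert np.all(angles == 0.0)


class TestVanHees:
    def _classify(self, angles, n_epochs):
        p = VanHeesParams()
        return classify_vanhees(np.asarray(angles, float), p, _grid(n_epochs))

    def test_constant_orientation_all_sleep(self):
        # 120 blocks x 5 s = 10 min static = 20 epochs
        out = self._classify([30.0] * 120, 20)
        assert out.labels.sum() == 20

    def test_flip_every_two_minutes_all_wake(self):
        # 90 deg orientation flip every 2 min: no still run reaches 5 min
        angles = []
        for k in range(10):
            angles += [80.0 if k % 2 else -10.0] * 24  # 24 blocks = 2 min
        out = self._classify(angles, 40)
        assert out.labels.sum() == 0

    def test_static_then_movement_splits(self, rng):
        still = [10.0] * 120                      # 10 min static
        moving = list(rng.uniform(-80, 80, 120))  # 10 min of large changes
        out = self._classify(still + moving, 40)
        assert np.all(out.labels[:20] == SLEEP)
        assert np.all(out.labels[20:] == WAKE)


class TestReference:
    def test_all_sleep(self):
        out = reference_classifier(_grid(4), "all_sleep")
        assert list(out.labels) == [1, 1, 1, 1]

    def test_all_wake_single_epoch(self):
        out = reference_classifier(_grid(1), "all_wake")
        assert list(out.labels) == [0]

    def test_unknown_mode(self):
        with pytest.raises(ParameterError):
            reference_classifier(_grid(2), "all_rem")


@pytest.fixture(scope="module")
def night():
    from actisleep.core import binarize_hypnogram
    from actisleep.synthetic import SynthConfig, gen_accel, gen_hypnogram

    c = SynthConfig(night_duration_min=60, seed=5, sensor_noise_sd_g=0.005)
    gt = gen_hypnogram(c, 0)
    rec = gen_accel(gt, c)
    truth = binarize_hypnogram(gt.hypnogram)
    feats = extract_rf_features(rec, gt.hypnogram.grid)
    return feats, truth


class TestRandomForest:

    def test_memorizes_separable_night(self, night):
        feats, truth = night
        pred = train_apply_rf(feats, truth, seed=1)
        assert (pred.labels == truth.labels).mean() >= 0.99

    def test_seed_determinism(self, night):
        feats, truth = night
        a = train_apply_rf(feats, truth, seed=3)
        b = train_apply_rf(feats, truth, seed=3)
        assert np.array_equal(a.labels, b.labels)

    def test_apply_without_model_rejected(self, night):
        feats, _ = night
        with pytest.raises(ParameterError):
            train_apply_rf(feats)

    def test_single_class_training_rejected(self, night):
        feats, truth = night
        flat = SleepWakeSeries(truth.grid, np.ones(len(truth), dtype=np.uint8), "x")
        with pytest.raises(TrainingError):
            train_rf(feats, flat)

    def test_lag_features_match_shifted_base(self, night):
        feats, _ = night
        names = feats.feature_names
        base_cols = [i for i, n in enumerate(names) if "_lag" not in n and "_lead" not in n]
        lag1_cols = [names.index(names[i] + "_lag1") for i in base_cols]
        assert np.allclose(feats.values[1:, lag1_cols], feats.values[:-1, base_cols])
        assert np.allclose(feats.values[0, lag1_cols], 0.0)

    def test_constant_input_zero_sd_features(self):
        n = int(50 * 60)
        r = RawRecording("s", START, 50.0, np.zeros(n), np.zeros(n), np.ones(n))
        feats = extract_rf_features(r, _grid(2))
        sd_cols = [i for i, nm in enumerate(feats.feature_names)
                   if nm.endswith("_sd")]
        assert np.allclose(feats.values[:, sd_cols], 0.0)
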
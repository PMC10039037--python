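"""Confusion statistics, endpoints, cohort aggregation, Bland-Altman."""

import numpy as np
import pytest

from actisleep.errors import AlignmentError, ParameterError
from actisleep.evaluation import (
    CohortSummary,
    bland_altman,
    cohort_aggregate,
    confusion,
    endpoints,
    select_algorithms,
)
from conftest import series

W, S = 0, 1


def brute_force_confusion(pred, truth):
    """Independent epoch-counting oracle."""
    tp = tn = fp = fn = 0
    for p, t in zip(pred, truth):
        if p == S and t == S:
            tp += 1
        elif p == W and t == W:
            tn += 1
        elif p == S and t == W:
            fp += 1
        else:
            fn += 1
    return tp, tn, fp, fn


class TestConfusion:
    def test_perfect_agreement(self):
        s = series([W, S, S, W, S])
        c = confusion(s, s)
        for m in ("accuracy", "sensitivity", "specificity", "precision", "f1"):
            assert getattr(c, m) == pytest.approx(100.0)

    def test_all_sleep_vs_mixed_truth(self):
        truth = series([S] * 7 + [W] * 3, source="PSG")
        c = confusion(series([S] * 10), truth)
        assert c.sensitivity == 100.0 and c.specificity == 0.0

    def test_hand_counted_case(self):
        # TP=3 FN=1 TN=2 FP=2
        truth = series([S, S, S, S, W, W, W, W])
        pred = series([S, S, S, W, S, S, W, W])
        c = confusion(pred, truth)
        assert (c.tp, c.fn, c.tn, c.fp) == (3, 1, 2, 2)
        assert c.sensitivity == pytest.approx(75.0)
        assert c.specificity == pytest.approx(50.0)
        assert c.precision == pytest.approx(60.0)
        assert c.f1 == pytest.approx(200.0 / 3.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 500))
            p, t = rng.integers(0, 2, (2, n))
            c = confusion(series(p), series(t, source="PSG"))
            tp, tn, fp, fn = brute_force_confusion(p, t)
            assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)
            if tp + fn:
                assert c.sensitivity == pytest.approx(100 * tp / (tp + fn), rel=1e-12)
            else:
                assert c.sensitivity is None

    def test_undefined_flags(self):
        c = confusion(series([W, W]), series([W, W], source="PSG"))
        assert c.sensitivity is None and c.precision is None and c.f1 is None
        assert c.specificity == 100.0

    def test_all_wake_prediction_f1_zero(self):
        c = confusion(series([W] * 6), series([S, S, W, S, W, S], source="PSG"))
        assert c.sensitivity == 0.0 and c.specificity == 100.0 and c.f1 == 0.0

    def test_length_mismatch(self):
        with pytest.raises(AlignmentError):
            confusion(series([S]), series([S, W]))


class TestEndpoints:
    def test_contiguous_sleep(self):
        e = endpoints(series([S] * 10))
        assert (e.waso_min, e.tst_min, e.se_pct) == (0.0, 5.0, 100.0)

    def test_mixed_night_enumeration(self):
        e = endpoints(series([W, S, S, W, S, W]))
        assert e.onset_epoch == 1 and e.offset_epoch == 4
        assert e.waso_min == pytest.approx(0.5)
        assert e.tst_min == pytest.approx(1.5)
        assert e.se_pct == pytest.approx(50.0)

    def test_all_wake_undefined(self):
        e = endpoints(series([W] * 8))
        assert e.waso_min is None and e.tst_min == 0.0 and e.se_pct == 0.0

    def test_consecutive_onset_rule(self):
        e = endpoints(series([W, S, W, S, S, S]), onset_consecutive_epochs=2)
        assert e.onset_epoch == 3
        assert e.waso_min == 0.0

    def test_custom_annotated_denominator(self):
        e = endpoints(series([S, S, W, W]), annotated_epochs=8)
        assert e.se_pct == pytest.approx(25.0)


class TestCohortAggregate:
    def test_single_subject(self):
        c = confusion(series([S, W]), series([S, W], source="PSG"))
        summary = cohort_aggregate([c], "x")
        assert summary.mean["accuracy"] == 100.0 and summary.sd["accuracy"] == 0.0

    def test_two_subject_mean(self):
        a = confusion(series([S, S, W, S]), series([S] * 4, source="PSG"))  # sens 75
        b = confusion(series([S] * 4), series([S] * 4, source="PSG"))      # sens 100
        s = cohort_aggregate([a, b], "x")
        assert s.mean["sensitivity"] == pytest.approx(87.5)

    def test_matches_direct_recomputation(self, rng):
        stats = []
        for _ in range(10):
            p, t = rng.integers(0, 2, (2, 50))
            stats.append(confusion(series(p), series(t, source="PSG")))
        s = cohort_aggregate(stats, "x")
        vals = [c.accuracy for c in stats]
        assert s.mean["accuracy"] == pytest.approx(np.mean(vals))
        assert s.sd["accuracy"] == pytest.approx(np.std(vals))

    def test_undefined_excluded_with_count(self):
        a = confusion(series([W, W]), series([W, W], source="PSG"))  # sens undefined
        b = confusion(series([S, W]), series([S, W], source="PSG"))
        s = cohort_aggregate([a, b], "x")
        assert s.n_undefined["sensitivity"] == 1
        assert s.mean["sensitivity"] == 100.0

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            cohort_aggregate([], "x")


class TestBlandAltman:
    def test_identical_vectors(self):
        b = bland_altman([3.0, 7.0, 1.0], [3.0, 7.0, 1.0])
        assert b.me == 0.0 and b.rmse == 0.0 and b.ci_width == 0.0

    def test_plus_minus_ten(self):
        b = bland_altman([10.0, -10.0], [0.0, 0.0])
        assert b.me == pytest.approx(0.0) and b.rmse == pytest.approx(10.0)

    def test_hand_computed_loa(self):
        b = bland_altman([3.0, 5.0, 7.0], [0.0, 0.0, 0.0])
        assert b.me == pytest.approx(5.0)
        assert b.rmse == pytest.approx(np.sqrt(83 / 3), abs=1e-9)
        assert b.loa_lower == pytest.approx(5 - 1.96 * 2, abs=1e-9)
        assert b.loa_upper == pytest.approx(5 + 1.96 * 2, abs=1e-9)
        assert b.ci_width == pytest.approx(2 * 1.96 * 2, abs=1e-9)

    def test_swap_symmetry(self, rng):
        x, y = rng.normal(50, 20, (2, 15))
        ab, ba = bland_altman(x, y), bland_altman(y, x)
        assert ab.me == pytest.approx(-ba.me)
        assert ab.rmse == pytest.approx(ba.rmse)
        assert ab.ci_width == pytest.approx(ba.ci_width)
        assert ab.pearson_r == pytest.approx(ba.pearson_r)

    def test_rmse_bounds_me(self, rng):
        for _ in range(20):
            x, y = rng.normal(0, 30, (2, 10))
            b = bland_altman(x, y)
            assert b.rmse >= abs(b.me) - 1e-12

    def test_small_n_and_zero_variance_flags(self):
        b = bland_altman([4.0], [1.0])
        assert b.me == 3.0 and b.loa_upper is None
        b2 = bland_altman([2.0, 2.0], [1.0, 3.0])
        assert b2.pearson_r is None


class TestSelection:
    def _summary(self, name, sens, spec):
        s = CohortSummary(algorithm=name, n_subjects=5)
        s.mean = {"sensitivity": sens, "specificity": spec}
        s.sd = {"sensitivity": 0.2, "specificity": 0.2}
        return s

    def test_thresholds(self):
        passing = self._summary("heuristic", 83.6, 47.5)
        failing = self._summary("low_spec", 86.2, 42.0)
        out = select_algorithms([passing, failing])
        assert [s.algorithm for s in out] == ["heuristic"]
        assert passing.selected and not failing.selected

    def test_empty(self):
        assert select_algorithms([]) == []
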
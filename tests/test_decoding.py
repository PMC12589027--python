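import numpy as np
import pytest
from scipy import stats

from critsnn.decoding import (
    TrialSet,
    bin_rate_vectors,
    compare_conditions,
    decay_time,
    decode_accuracy,
    friedman_per_bin,
    preprocess_in_vitro,
    DecodingResult,
)
from critsnn.state import SpikeTrain
from critsnn.synthetic import labeled_response_set


def trial(times, units, n_units=4, window_s=0.5):
    return SpikeTrain(np.asarray(times, dtype=float),
                      np.asarray(units, dtype=np.int64), n_units)


def tiny_set():
    trains = [
        trial([0.005, 0.015], [0, 0]),
        trial([0.0005, 0.010], [1, 2]),
    ]
    return TrialSet(labels=np.array(["A", "B"]), trains=trains, n_units=4,
                    window_s=0.5)


class TestPreprocess:
    def test_artifact_spike_removed(self):
        ts = preprocess_in_vitro(tiny_set(), stim_times_s=(0.0,),
                                 artifact_window_ms=1.0)
        # the spike at 0.5 ms post-stimulus disappears
        assert len(ts.trains[1]) == 1
        assert ts.trains[1].times[0] == pytest.approx(0.010)
        assert len(ts.trains[0]) == 2

    def test_identity_with_zero_window(self):
        ts = preprocess_in_vitro(tiny_set(), artifact_window_ms=0.0)
        for a, b in zip(ts.trains, tiny_set().trains):
            assert np.array_equal(a.times, b.times)

    def test_saturated_units_dropped(self):
        base = tiny_set()
        base.saturated[0] = True
        ts = preprocess_in_vitro(base, artifact_window_ms=0.0)
        assert len(ts.trains[0]) == 0  # both spikes were from unit 0

    def test_all_units_flagged_surfaces_downstream(self):
        base = tiny_set()
        base.saturated[:] = True
        ts = preprocess_in_vitro(base)
        with pytest.raises(ValueError, match="active"):
            bin_rate_vectors(ts, 20.0, 0.0)


class TestBinRateVectors:
    def test_rate_conversion(self):
        # 2 spikes in a 20-ms bin -> 100 Hz
        ts = tiny_set()
        X, y = bin_rate_vectors(ts, 20.0, 0.0)
        assert X[0, 0] == pytest.approx(100.0)
        assert y.tolist() == ["A", "B"]

    def test_empty_trial_zero_vector(self):
        ts = TrialSet(labels=np.array(["A"]),
                      trains=[trial([], [])], n_units=4, window_s=0.5)
        X, _ = bin_rate_vectors(ts, 20.0, 0.0)
        assert np.all(X == 0)

    def test_half_open_bin(self):
        ts = TrialSet(labels=np.array(["A"]),
                      trains=[trial([0.020], [0])], n_units=4, window_s=0.5)
        X0, _ = bin_rate_vectors(ts, 20.0, 0.0)
        X1, _ = bin_rate_vectors(ts, 20.0, 20.0)
        assert X0[0, 0] == 0.0      # exactly at latency+bin excluded
        assert X1[0, 0] == pytest.approx(50.0)

    def test_bin_beyond_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            bin_rate_vectors(tiny_set(), 20.0, 490.0)


class TestDecodeAccuracy:
    def test_separable_classes(self):
        ts = labeled_response_set(separation=8.0, noise_sd=0.3,
                                  n_trials=20, n_units=40, seed=0)
        X, y = bin_rate_vectors(ts, 20.0, 0.0)
        assert decode_accuracy(X, y, seed=0) >= 0.99

    def test_shuffled_labels_at_chance(self):
        ts = labeled_response_set(separation=8.0, noise_sd=0.3,
                                  n_trials=20, n_units=40, seed=1)
        X, y = bin_rate_vectors(ts, 20.0, 0.0)
        rng = np.random.default_rng(0)
        acc = decode_accuracy(X, rng.permutation(y), seed=0)
        # 99% binomial CI around 0.25 for 10 splits x 8 held-out trials
        n = 10 * 8
        lo, hi = stats.binom.interval(0.99, n, 0.25)
        assert lo / n <= acc <= hi / n

    def test_single_class_rejected(self):
        X = np.zeros((8, 3))
        with pytest.raises(ValueError):
            decode_accuracy(X, np.array(["A"] * 8))

    def test_duplication_invariance(self):
        ts = labeled_response_set(separation=2.0, noise_sd=1.0,
                                  n_trials=15, n_units=30, seed=2)
        X, y = bin_rate_vectors(ts, 20.0, 0.0)
        a1 = decode_accuracy(X, y, seed=0)
        a2 = decode_accuracy(np.vstack([X, X]), np.concatenate([y, y]),
                             seed=0)
        assert a2 == pytest.approx(a1, abs=0.02)

    def test_unit_permutation_invariance(self):
        ts = labeled_response_set(separation=3.0, noise_sd=0.5,
                                  n_trials=12, n_units=25, seed=3)
        X, y = bin_rate_vectors(ts, 20.0, 0.0)
        rng = np.random.default_rng(5)
        perm = rng.permutation(X.shape[1])
        assert decode_accuracy(X[:, perm], y, seed=0) == pytest.approx(
            decode_accuracy(X, y, seed=0), abs=1e-9)


class TestDecayTime:
    def test_chance_from_the_start(self):
        ts = labeled_response_set(separation=0.0, noise_sd=1.0,
                                  n_trials=10, n_units=20, seed=4,
                                  window_s=0.2)
        res = decay_time(ts, bin_width_ms=20.0, seed=0)
        assert res.decay_time_ms == 0.0

    def test_signal_confined_to_first_bins(self):
        # class signal only in [0, 100) ms -> decay time 100 ms ± one bin
        ts = labeled_response_set(separation=6.0, noise_sd=0.3,
                                  n_trials=10, n_units=30,
                                  signal_bins=(0, 5), window_s=0.3, seed=5)
        res = decay_time(ts, bin_width_ms=20.0, seed=0)
        assert abs(res.decay_time_ms - 100.0) <= 20.0

    def test_binomial_critical_value_oracle(self):
        # exact tail enumeration reproduces scipy's one-sided p-value
        n, p0 = 160, 0.25
        for k in (40, 50, 52, 60):
            brute = sum(stats.binom.pmf(j, n, p0) for j in range(k, n + 1))
            assert stats.binomtest(k, n, p0, alternative="greater").pvalue \
                == pytest.approx(brute, rel=1e-10)

    def test_unbalanced_rejected(self):
        ts = tiny_set()
        ts.labels = np.array(["A", "A"])
        with pytest.raises(ValueError):
            decay_time(ts, 20.0)


class TestCompareConditions:
    @staticmethod
    def result(decay, accs=(0.5, 0.4)):
        return DecodingResult(
            bin_width_ms=20.0,
            latencies_ms=np.arange(len(accs)) * 20.0,
            accuracy=np.array(accs),
            loo_correct=np.zeros(len(accs), dtype=int),
            p_values=np.ones(len(accs)),
            n_trials=10, n_classes=4, decay_time_ms=decay)

    def test_identical_inputs_p_one(self):
        a = [self.result(100.0) for _ in range(8)]
        out = compare_conditions(a, a)
        assert out["decay_time"]["p_value"] == 1.0

    def test_constant_shift_significant(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(60, 200, size=8)
        a = [self.result(d) for d in base]
        b = [self.result(d + 40.0) for d in base]
        out = compare_conditions(b, a, alternative="greater")
        assert out["decay_time"]["p_value"] < 0.05

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            compare_conditions([self.result(1.0)], [self.result(2.0)])

    def test_mismatched_rejected(self):
        with pytest.raises(ValueError):
            compare_conditions([self.result(1.0)] * 3,
                               [self.result(2.0)] * 4)

    def test_friedman_needs_three(self):
        a = [self.result(1.0)] * 5
        with pytest.raises(ValueError):
            friedman_per_bin(a, a)

    def test_friedman_three_conditions(self):
        rng = np.random.default_rng(1)
        conds = []
        for shift in (0.0, 0.0, 0.3):
            conds.append([self.result(100.0,
                                      accs=tuple(rng.uniform(0.3, 0.6, 2)
                                                 + shift))
                          for _ in range(6)])
        out = friedman_per_bin(*conds)
        assert len(out) == 2
        assert all(0 <= d["p_value"] <= 1 for d in out)
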
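"""Pattern decoding: feature selection, one-vs-rest bank, CV, cross-task
tests, and time-resolved decoding."""

import numpy as np
import pytest

from prpdecode.decode import (CHANCE_8WAY, cross_decode, cv_decode,
                              decision_values, pool_task_order, predict_label,
                              select_features, time_resolved_decode,
                              train_classifier, DecodingTimecourse)
from prpdecode.hrf import fit_single_gamma, gamma_lobe, latency_metrics


def _separable_patterns(n_per_class=10, n_vox=64, noise=0.05, rng=None):
    """One orthogonal block of voxels per mapping (8 voxels each)."""
    rng = rng or np.random.default_rng(0)
    labels = np.repeat(np.arange(1, 9), n_per_class)
    X = np.zeros((len(labels), n_vox))
    block = n_vox // 8
    for i, lab in enumerate(labels):
        X[i, (lab - 1) * block:lab * block] = 5.0
    X += noise * rng.standard_normal(X.shape)
    runs = np.tile(np.arange(n_per_class), 8)
    return X, labels, runs


class TestFeatureSelection:
    def test_top_k_count_and_determinism(self, rng):
        t = rng.standard_normal(120)
        idx = select_features(t, 50)
        assert len(idx) == 50
        assert np.array_equal(idx, select_features(t, 50))
        assert set(idx) == set(np.argsort(-t)[:50])

    def test_k_equals_n_identity(self, rng):
        t = rng.standard_normal(20)
        assert np.array_equal(select_features(t, 20), np.arange(20))

    def test_k_too_large_raises(self, rng):
        with pytest.raises(ValueError):
            select_features(rng.standard_normal(10), 11)

    def test_conjunction_matches_bruteforce_min_ranking(self, rng):
        a, b = rng.standard_normal((2, 60))
        idx = select_features((a, b), 15, mode="conjunction")
        brute = np.argsort(-np.minimum(a, b), kind="stable")[:15]
        assert set(idx) == set(brute)

    def test_conjunction_excludes_one_task_specialists(self):
        a = np.zeros(10)
        b = np.zeros(10)
        a[3] = 100.0           # huge in one task, zero in the other
        a[:3] = b[:3] = 1.0
        idx = select_features((a, b), 3, mode="conjunction")
        assert 3 not in idx


class TestClassifierBank:
    def test_separable_training_accuracy_perfect(self):
        X, labels, _ = _separable_patterns()
        clf = train_classifier(X, labels)
        assert np.mean(predict_label(clf, X) == labels) == 1.0

    def test_pure_noise_patterns_decode_at_chance(self, rng):
        labels = np.repeat(np.arange(1, 9), 40)
        X = rng.standard_normal((len(labels), 64))
        runs = np.tile(np.arange(40), 8)
        acc, _ = cv_decode(X, labels, runs)
        assert abs(acc - CHANCE_8WAY) < 0.08

    def test_large_penalty_shrinks_weights(self):
        X, labels, _ = _separable_patterns()
        w_small = np.abs(train_classifier(X, labels, penalty=1.0).weights).mean()
        w_large = np.abs(train_classifier(X, labels, penalty=1e4).weights).mean()
        assert w_large < 0.05 * w_small

    def test_missing_class_strict_raises_nonstrict_never_wins(self):
        X, labels, _ = _separable_patterns()
        keep = labels != 5
        with pytest.raises(ValueError, match="5"):
            train_classifier(X[keep], labels[keep])
        clf = train_classifier(X[keep], labels[keep], strict=False)
        assert 5 not in predict_label(clf, X)

    def test_argmax_equals_bruteforce_over_submodels(self, rng):
        X, labels, _ = _separable_patterns()
        clf = train_classifier(X, labels)
        probe = rng.standard_normal((10, X.shape[1]))
        dv = decision_values(clf, probe)
        assert np.array_equal(predict_label(clf, probe),
                              clf.classes[np.argmax(dv, axis=1)])

    def test_zero_pattern_stable_prediction(self):
        X, labels, _ = _separable_patterns()
        clf = train_classifier(X, labels)
        z = np.zeros((1, X.shape[1]))
        assert predict_label(clf, z)[0] == predict_label(clf, z)[0]

    def test_dimension_mismatch_rejected(self):
        X, labels, _ = _separable_patterns()
        clf = train_classifier(X, labels, feature_idx=np.arange(32))
        with pytest.raises(ValueError, match="dimension"):
            decision_values(clf, np.zeros((1, 5)))


class TestCV:
    def test_separable_patterns_decode_perfectly(self):
        X, labels, runs = _separable_patterns()
        acc, detail = cv_decode(X, labels, runs)
        assert acc == 1.0
        assert len(detail) == len(np.unique(runs))

    def test_fold_accuracies_pool_to_overall(self, rng):
        X, labels, runs = _separable_patterns(noise=1.5, rng=rng)
        acc, detail = cv_decode(X, labels, runs)
        assert acc == pytest.approx(detail["n_correct"].sum() / detail["n"].sum())

    def test_single_fold_rejected(self):
        X, labels, _ = _separable_patterns()
        with pytest.raises(ValueError, match="2 runs"):
            cv_decode(X, labels, np.zeros(len(labels)))


class TestCrossTask:
    def test_no_pattern_other_task_decodes_at_chance(self, rng):
        X, labels, _ = _separable_patterns()
        clf = train_classifier(X, labels)
        # the other task evokes no mapping structure in this region
        other = 0.05 * rng.standard_normal((400, X.shape[1]))
        other_labels = rng.integers(1, 9, 400)
        acc = cross_decode(clf, other, other_labels)
        assert abs(acc - CHANCE_8WAY) < 0.06

    def test_own_task_cross_equals_in_sample_path(self):
        X, labels, _ = _separable_patterns()
        clf = train_classifier(X, labels)
        assert cross_decode(clf, X, labels) == 1.0


class TestTimeResolved:
    def _timecourse_stack(self, delta=0.0, n_trials=64, n_vox=64, noise=0.6,
                          rng=None):
        """Patterns injected with an HRF-like bump peaking at 5 s + delta."""
        rng = rng or np.random.default_rng(1)
        tr, window = 0.199, 69
        t = np.arange(window) * tr
        bump = gamma_lobe(t - delta, 5.0, 4.0)
        labels = rng.integers(1, 9, n_trials)
        stack = noise * rng.standard_normal((n_trials, window, n_vox))
        block = n_vox // 8
        for i, lab in enumerate(labels):
            stack[i, :, (lab - 1) * block:lab * block] += 0.4 * bump[:, None]
        return stack, labels, tr

    def _train(self, rng=None):
        # training noise matched to the timecourse noise so the z-scoring
        # learned on patterns transfers to the tested timepoints
        X, labels, _ = _separable_patterns(noise=0.6, rng=rng)
        return train_classifier(X, labels)

    def test_accuracy_rises_peaks_and_returns(self):
        clf = self._train()
        stack, labels, tr = self._timecourse_stack()
        tc = time_resolved_decode(clf, stack, labels, tr)
        assert tc.accuracy[:5].mean() < 0.25
        assert tc.accuracy.max() > 0.5
        assert tc.accuracy[-5:].mean() < 0.3
        curve = fit_single_gamma(tc.time, tc.accuracy, baseline=CHANCE_8WAY)
        assert abs(latency_metrics(curve).peak_s - 5.0) < 1.0

    def test_shuffled_labels_flat_at_chance(self, rng):
        clf = self._train()
        stack, labels, tr = self._timecourse_stack()
        acc = np.zeros(stack.shape[1])
        reps = 15
        for _ in range(reps):
            acc += time_resolved_decode(clf, stack, rng.permutation(labels), tr).accuracy
        acc /= reps
        se = np.sqrt(CHANCE_8WAY * (1 - CHANCE_8WAY) / (reps * len(labels)))
        assert np.all(np.abs(acc - CHANCE_8WAY) < 5 * se)

    def test_delayed_pattern_shifts_fitted_peak_by_delta(self):
        clf = self._train()
        delta = 0.7
        peaks = []
        for d in (0.0, delta):
            stack, labels, tr = self._timecourse_stack(delta=d,
                                                       rng=np.random.default_rng(3))
            tc = time_resolved_decode(clf, stack, labels, tr)
            curve = fit_single_gamma(tc.time, tc.accuracy, baseline=CHANCE_8WAY)
            peaks.append(latency_metrics(curve).peak_s)
        assert peaks[1] - peaks[0] == pytest.approx(delta, abs=0.25)


class TestPooling:
    def _tc(self, acc, n=10):
        return DecodingTimecourse(time=np.arange(len(acc)) * 0.199,
                                  accuracy=np.asarray(acc, float),
                                  decoder_task="AO", tested_condition="x", n_trials=n)

    def test_identical_inputs_identity(self):
        tc = self._tc([0.2, 0.3, 0.4])
        out = pool_task_order(tc, self._tc([0.2, 0.3, 0.4]))
        assert np.allclose(out.accuracy, tc.accuracy)
        assert out.n_trials == 20

    def test_pointwise_mean(self):
        out = pool_task_order(self._tc([0.125] * 3), self._tc([0.25] * 3))
        assert np.allclose(out.accuracy, 0.1875)

    def test_equal_counts_pooling_equals_recount(self, rng):
        hits_a = rng.integers(0, 11, 5)
        hits_b = rng.integers(0, 11, 5)
        a = self._tc(hits_a / 10, n=10)
        b = self._tc(hits_b / 10, n=10)
        pooled = pool_task_order(a, b)
        assert np.allclose(pooled.accuracy, (hits_a + hits_b) / 20)

    def test_grid_mismatch_rejected(self):
        a = self._tc([0.2, 0.3])
        b = DecodingTimecourse(time=np.array([0.0, 0.5]), accuracy=np.array([0.2, 0.3]),
                               decoder_task="VM", tested_condition="y", n_trials=5)
        with pytest.raises(ValueError, match="grid"):
            pool_task_order(a, b)
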
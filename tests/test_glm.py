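"""GLM machinery: scaling, FIR, event regressors, prewhitened GLS,
condition timecourses, trial betas and LSS."""

import numpy as np
import pandas as pd
import pytest

from prpdecode.behavior import StageModel, simulate_behavior
from prpdecode.bold import BOLDRun, NoiseConfig, synthesize_bold
from prpdecode.design import DesignSpec, make_design
from prpdecode.glm import (DEFAULT_WINDOW_POINTS, DesignMatrix,
                           build_event_regressor, build_fir_basis,
                           estimate_condition_timecourses, estimate_trial_betas,
                           estimate_trialwise_timecourses_lss,
                           fit_glm_prewhitened, scale_percent)
from prpdecode.hrf import HRFParams, eval_hrf
from prpdecode.regions import RegionModel


def _run_from(data, tr=0.199, run=0):
    n = data.shape[0]
    return BOLDRun(data=data, tr=tr, run=run,
                   roi_labels=np.array(["roi"] * data.shape[1]),
                   nuisance=np.zeros((n, 0)), censor=np.ones(n, bool))


class TestScalePercent:
    def test_constant_voxel_maps_to_100(self):
        run = _run_from(np.full((50, 2), 500.0))
        out = scale_percent(run)
        assert np.allclose(out.data, 100.0)

    def test_post_scaling_mean_is_100(self, rng):
        run = _run_from(900 + 100 * rng.random((80, 5)))
        out = scale_percent(run)
        assert np.allclose(out.data.mean(axis=0), 100.0)

    def test_idempotent(self, rng):
        run = _run_from(900 + 100 * rng.random((80, 3)))
        once = scale_percent(run)
        twice = scale_percent(once)
        assert np.allclose(once.data, twice.data)

    def test_nonpositive_mean_voxel_excluded(self):
        data = np.ones((30, 3)) * 100.0
        data[:, 1] = 0.0
        with pytest.warns(UserWarning, match="excluding 1"):
            out = scale_percent(_run_from(data))
        assert out.data.shape[1] == 2


class TestFIRBasis:
    def test_default_window_size(self):
        X = build_fir_basis(np.array([0.0]), DEFAULT_WINDOW_POINTS, 0.199, 200)
        assert X.shape[1] == 69

    def test_single_onset_lag0_column(self):
        X = build_fir_basis(np.array([0.0]), 5, 0.199, 50)
        assert X[0, 0] == 1 and X[:, 0].sum() == 1

    def test_overlapping_onsets_sum(self):
        X = build_fir_basis(np.array([0.0, 0.199]), 3, 0.199, 50)
        assert X[1, 1] == 1 and X[1, 0] == 1

    def test_truncation_warns(self):
        with pytest.warns(UserWarning, match="truncated"):
            build_fir_basis(np.array([9.0]), 10, 0.199, 47)

    def test_fir_exactness_on_noiseless_lag_profile(self, rng):
        # OLS on the FIR basis recovers any lag profile to machine precision
        tr, n_vol, w = 0.199, 600, 30
        onsets = np.array([2.0, 8.0, 13.5, 21.0, 30.0, 55.0]) // tr * tr
        h = rng.standard_normal(w)
        X = build_fir_basis(onsets, w, tr, n_vol)
        y = X @ h
        est, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(est, h, atol=1e-10)


class TestEventRegressor:
    def test_single_onset_matches_hrf_samples(self):
        hrf = HRFParams()
        x = build_event_regressor(np.array([0.0]), hrf, 0.199, 200)
        t = np.arange(200) * 0.199
        assert np.corrcoef(x[1:], eval_hrf(hrf, t)[1:])[0, 1] > 0.9999
        assert x.argmax() == pytest.approx(eval_hrf(hrf, t).argmax(), abs=1)

    def test_superposition_of_nonoverlapping_onsets(self):
        hrf = HRFParams()
        both = build_event_regressor(np.array([0.0, 60.0]), hrf, 0.199, 600)
        a = build_event_regressor(np.array([0.0]), hrf, 0.199, 600)
        b = build_event_regressor(np.array([60.0]), hrf, 0.199, 600)
        assert np.allclose(both, a + b, atol=1e-12)

    def test_compound_event_larger_p1_peaks_later(self):
        base = build_event_regressor(np.array([0.0]), HRFParams(), 0.199, 300)
        slow = build_event_regressor(np.array([0.0]), HRFParams(p1=8.0, p2=16.0),
                                     0.199, 300)
        assert slow.argmax() > base.argmax()

    def test_boxcar_duration_scales_amplitude(self):
        short = build_event_regressor(np.array([0.0]), HRFParams(), 0.199, 300,
                                      durations=0.5)
        long = build_event_regressor(np.array([0.0]), HRFParams(), 0.199, 300,
                                     durations=2.0)
        assert long.max() > 2 * short.max()


class TestPrewhitenedGLM:
    def _sim(self, rng, phi=0.0, n=400, k=3, v=4):
        X = rng.standard_normal((n, k))
        beta = rng.standard_normal((k, v))
        noise = rng.standard_normal((n, v))
        if phi:
            from scipy.signal import lfilter
            noise = lfilter([1.0], [1.0, -phi], noise, axis=0)
        return X, beta, X @ beta + noise

    def test_white_noise_matches_ols(self, rng):
        X, beta, Y = self._sim(rng)
        est = fit_glm_prewhitened(Y, X)
        ols, *_ = np.linalg.lstsq(X, Y, rcond=None)
        assert np.allclose(est.betas, ols, atol=0.02)

    def test_ar1_recovery(self, rng):
        X, beta, Y = self._sim(rng, phi=0.5, n=3000)
        est = fit_glm_prewhitened(Y, X)
        assert est.ar_coeff.mean() == pytest.approx(0.5, abs=0.05)
        assert np.allclose(est.betas, beta, atol=0.1)

    def test_censoring_equals_row_deletion(self, rng):
        X, beta, Y = self._sim(rng)
        censor = np.ones(Y.shape[0], bool)
        censor[50:70] = False
        Y_out = Y.copy()
        Y_out[50:70] += 40.0  # gross spikes removed by the censor
        est = fit_glm_prewhitened(Y_out, X, censor=censor, ar_pooling="none")
        manual, *_ = np.linalg.lstsq(X[censor], Y[censor], rcond=None)
        assert np.allclose(est.betas, manual, atol=1e-10)

    def test_rank_deficiency_names_columns(self, rng):
        X = rng.standard_normal((100, 3))
        X = np.hstack([X, X[:, [0]]])
        dm = DesignMatrix(X, ["a", "b", "c", "dup"])
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_glm_prewhitened(rng.standard_normal((100, 2)), dm)

    def test_contrast_tstats(self, rng):
        X, beta, Y = self._sim(rng, v=2)
        est = fit_glm_prewhitened(Y, X, contrasts={"c0": [1, 0, 0]})
        assert est.tstats["c0"].shape == (2,)
        assert np.all(np.isfinite(est.tstats["c0"]))


def _quiet_session(conditions=("AO",), n_runs=1, n_voxels=4, cvs=None,
                   pattern_gain=0.0, seed=0, trials_per_run=8, run_volumes=500):
    spec = DesignSpec(n_runs=n_runs, trials_per_run=trials_per_run,
                      run_volumes=run_volumes, conditions=conditions, seed=seed)
    cvs = cvs if cvs is not None else {"P": 0, "C": 0, "M": 0}
    model = StageModel(cvs=cvs, accuracy=1.0)
    rng = np.random.default_rng(seed)
    trials = simulate_behavior(make_design(spec, rng), model, rng)
    region = RegionModel("MD", "central", None, n_voxels=n_voxels,
                         pattern_gain=pattern_gain)
    quiet = NoiseConfig(sigma=0, drift_order=0, n_nuisance=0)
    runs = synthesize_bold(trials, [region], spec, quiet, rng)
    return spec, trials, runs, region


class TestConditionTimecourses:
    def test_noiseless_recovery_matches_forward_model(self):
        spec, trials, runs, region = _quiet_session(run_volumes=700)
        tcs = estimate_condition_timecourses(runs, trials, window_points=100,
                                             drift_order=1)["MD"]["AO"]
        # forward oracle: identical deterministic events, so the FIR profile
        # equals one trial's ROI-mean percent-signal response
        dt = 0.005
        tf = np.arange(0, 40, dt)
        H = np.cumsum(eval_hrf(region.hrf, tf)) * dt
        rel = tcs.time - 0.1  # central stage starts at P = 0.1
        resp = np.interp(rel, tf, H, left=0.0) - np.interp(rel - 0.835, tf, H, left=0.0)
        roi_gain = region.amplitude * region.spatial_profile.mean() if region.spatial_profile is not None else None
        # scale oracle to percent units via the generative baseline of 1000
        expected = resp * 10.0 * 1.0 / 1000.0 * 100.0  # amplitude x profile(~1)/baseline
        ratio = tcs.values.max() / expected.max()
        assert ratio == pytest.approx(1.0, abs=0.15)
        assert np.corrcoef(tcs.values, expected)[0, 1] > 0.995

    def test_zero_signal_flat(self):
        spec, trials, runs, _ = _quiet_session()
        flat = [BOLDRun(data=np.full_like(r.data, 1000.0), tr=r.tr, run=r.run,
                        roi_labels=r.roi_labels, nuisance=r.nuisance,
                        censor=r.censor) for r in runs]
        tc = estimate_condition_timecourses(flat, trials, window_points=40)["MD"]["AO"]
        assert np.allclose(tc.values, 0.0, atol=1e-8)

    def test_groupby_yields_subset_timecourses(self):
        spec, trials, runs, _ = _quiet_session(trials_per_run=16, run_volumes=700)
        halves = {i: ("first" if k < 8 else "second")
                  for k, i in enumerate(trials.index)}
        out = estimate_condition_timecourses(
            runs, trials, window_points=40,
            groupby=lambda row: halves[row.name])["MD"]
        assert set(out) == {"first", "second"}
        assert out["first"].n_trials == 8


class TestTrialBetas:
    def test_noiseless_recovery_of_injected_amplitudes(self, rng):
        # custom forward data: each trial has its own gain on a shared HRF
        tr, n_vol, n_vox = 0.199, 900, 3
        hrf = HRFParams()
        onsets = np.arange(6) * 28.0 + 4.0
        onsets = np.round(onsets / tr) * tr
        gains = np.array([1.0, 2.0, 0.0, 1.5, 0.5, 3.0])
        data = np.full((n_vol, n_vox), 1000.0)
        for o, g in zip(onsets, gains):
            data += 10 * g * build_event_regressor(np.array([o]), hrf, tr, n_vol)[:, None]
        run = _run_from(data, tr=tr)
        trials = pd.DataFrame({
            "run": 0, "onset_t1": onsets, "condition": "AO", "task1": "AO",
            "task2": None, "soa": np.nan, "map1": np.arange(1, 7), "map2": pd.NA,
            "is_dual": False, "correct": True,
        })
        betas = estimate_trial_betas([run], trials, hrf=hrf, drift_order=0)
        est = betas.to_numpy().mean(axis=1)
        scale = est[np.argmax(gains)] / gains.max()
        assert np.allclose(est / scale, gains, atol=0.02)
        # zero-amplitude trial stays near zero
        assert abs(est[2]) < 0.02 * abs(est).max()

    def test_row_index_matches_trials(self):
        spec, trials, runs, _ = _quiet_session(conditions=("AO", "VM"),
                                               trials_per_run=16, run_volumes=700)
        betas = estimate_trial_betas(runs, trials)
        target = trials.index[trials["condition"].isin(["AO", "VM"]) & trials["correct"]]
        assert list(betas.index) == list(target)


class TestLSS:
    def _orthogonal_setup(self, rng, noise=0.0):
        tr, n_vol, w = 0.199, 1200, 20
        hrf = HRFParams()
        onsets = np.round((np.arange(8) * 28.0 + 4.0) / tr) * tr
        profile = eval_hrf(hrf, np.arange(w) * tr)
        data = np.full((n_vol, 2), 1000.0)
        gains = 1.0 + rng.random(8)
        for o, g in zip(onsets, gains):
            X = build_fir_basis(np.array([o]), w, tr, n_vol)
            data += 10 * g * (X @ profile)[:, None]
        data += noise * rng.standard_normal(data.shape)
        run = _run_from(data, tr=tr)
        trials = pd.DataFrame({
            "run": 0, "onset_t1": onsets, "condition": "AO", "task1": "AO",
            "task2": None, "soa": np.nan, "map1": (np.arange(8) % 8) + 1,
            "map2": pd.NA, "is_dual": False, "correct": True,
        })
        return run, trials, w, gains, profile

    def test_lss_equals_ls_all_on_orthogonal_noiseless_design(self, rng):
        run, trials, w, gains, profile = self._orthogonal_setup(rng)
        tc, idx = estimate_trialwise_timecourses_lss([run], trials,
                                                     window_points=w, drift_order=0,
                                                     prewhiten=False)
        # LS-all oracle: every trial gets its own FIR set in one model
        Xs = [build_fir_basis(np.array([o]), w, run.tr, run.data.shape[0])
              for o in trials["onset_t1"]]
        X = np.hstack(Xs + [np.ones((run.data.shape[0], 1))])
        y = scale_percent(run).data
        b, *_ = np.linalg.lstsq(X, y, rcond=None)
        for k in range(len(trials)):
            assert np.allclose(tc[k], b[k * w:(k + 1) * w], atol=1e-8)

    def test_lss_variance_not_worse_than_ls_all_under_overlap(self):
        # densely overlapped trials: LSS's shared-set regularization should
        # not inflate single-trial variance relative to fully separate LS
        tr, n_vol, w = 0.199, 700, 40
        hrf = HRFParams()
        onsets = np.round((np.arange(10) * 9.0 + 4.0) / tr) * tr
        trials = pd.DataFrame({
            "run": 0, "onset_t1": onsets, "condition": "AO", "task1": "AO",
            "task2": None, "soa": np.nan, "map1": (np.arange(10) % 8) + 1,
            "map2": pd.NA, "is_dual": False, "correct": True,
        })
        base = np.zeros((n_vol, 1))
        for o in onsets:
            base += 10 * build_event_regressor(np.array([o]), hrf, tr, n_vol)[:, None]
        Xs = [build_fir_basis(np.array([o]), w, tr, n_vol) for o in onsets]
        X_all = np.hstack(Xs + [np.ones((n_vol, 1))])
        rng = np.random.default_rng(7)
        lss_est, ls_est = [], []
        for _ in range(25):
            data = 1000.0 + base + 2.0 * rng.standard_normal((n_vol, 1))
            run = _run_from(data, tr=tr)
            tc, _ = estimate_trialwise_timecourses_lss(
                [run], trials, window_points=w, drift_order=0, prewhiten=False)
            lss_est.append(tc[:, :, 0])
            b, *_ = np.linalg.lstsq(X_all, scale_percent(run).data, rcond=None)
            ls_est.append(np.stack([b[k * w:(k + 1) * w, 0] for k in range(10)]))
        var_lss = np.var(np.stack(lss_est), axis=0).mean()
        var_ls = np.var(np.stack(ls_est), axis=0).mean()
        assert var_lss <= var_ls * 1.05

    def test_single_trial_condition_falls_back_with_warning(self, rng):
        run, trials, w, *_ = self._orthogonal_setup(rng)
        trials = trials.copy()
        trials.loc[trials.index[0], "condition"] = "VM"
        trials.loc[trials.index[0], "task1"] = "VM"
        with pytest.warns(UserWarning, match="single correct trial"):
            tc, idx = estimate_trialwise_timecourses_lss(
                [run], trials, window_points=w, drift_order=0, prewhiten=False)
        assert len(idx) == len(trials)
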
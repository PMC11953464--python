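"""Desk-scale ground-truth recovery experiments.

These compose the full pipeline on synthetic subjects whose generative
parameters are known, so each analysis stage can be validated end to end:

* :func:`serial_recovery_subject` - the central experiment: simulate one
  subject under the serial-bottleneck (or parallel) model, run the whole
  decoding chain (trial betas -> LSS timecourses -> time-resolved decoding ->
  SOA back-shift -> single-gamma latency fits), and compare the recovered
  task-2 decoding postponement with the injected central postponement.
* :func:`quartile_discrimination_subject` - simulate one subject with a
  duration-scaling (selection-like) region and a pure-shift (execution-like)
  region and classify both profiles from the quartile-RT analysis.
* :func:`permutation_chance_curve` - time-resolved decoding with permuted
  labels, to verify convergence to the 12.5% chance rate at every lag.

Problem sizes (5 runs of 32 trials for the serial-recovery experiment, 2
runs of 32 single-task trials for the quartile experiment) are the package's
desk-scale defaults: large enough for stable latency fits at the default
signal-to-noise settings, small enough to run on a laptop.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .behavior import StageModel, sample_stage_model, simulate_behavior
from .bold import NoiseConfig, synthesize_bold
from .decode import (CHANCE_8WAY, pool_task_order, select_features,
                     time_resolved_decode, time_resolved_decode_cv, train_classifier)
from .design import DesignSpec, make_design
from .glm import (condition_tmaps, estimate_trial_betas,
                  estimate_trialwise_timecourses_lss)
from .hrf import fit_single_gamma, latency_metrics, shift_timecourse
from .quartile import quartile_profile
from .regions import RegionModel, default_regions

__all__ = ["RECOVERY_SPEC", "QUARTILE_SPEC", "serial_recovery_subject",
           "quartile_discrimination_subject", "permutation_chance_curve"]

#: session layout for the serial-queuing recovery experiment: the two single
#: tasks plus the two short-SOA dual-task orders, 8 trials each per run.
RECOVERY_SPEC = DesignSpec(
    n_runs=10, trials_per_run=32, run_volumes=1100,
    conditions=("AO", "VM", "S-AOVM", "S-VMAO"),
)

#: session layout for the quartile experiment: single-task AO trials only.
QUARTILE_SPEC = DesignSpec(
    n_runs=3, trials_per_run=32, run_volumes=1050, conditions=("AO",),
)

_T2_CONDITION = {"AO": "S-VMAO", "VM": "S-AOVM"}  # condition where task X is second


def _latencies(tc, baseline=CHANCE_8WAY):
    curve = fit_single_gamma(tc.time, tc.accuracy, baseline=baseline)
    return latency_metrics(curve)


def serial_recovery_subject(
    seed: int,
    serial: bool = True,
    spec: DesignSpec = RECOVERY_SPEC,
    noise: NoiseConfig | None = None,
    k: int = 50,
    penalty: float = 25.0,
) -> dict:
    """Run the full decoding chain on one synthetic subject.

    Returns recovered single-task and short-SOA task-2 decoding latencies in
    the multiple-demand region (task orders pooled, task-2 curves back-shifted
    by the exact SOA), their differences, and the injected mean central
    postponement (the subject's ground-truth PRP under the bottleneck model).
    """
    rng = np.random.default_rng(seed)
    model = sample_stage_model(rng, base=StageModel(serial=serial))
    trials = simulate_behavior(make_design(spec, rng), model, rng)
    md = next(r for r in default_regions() if r.name == "MD")
    runs = synthesize_bold(trials, [md], spec, noise, rng, serial=model.serial)

    tmaps = condition_tmaps(runs, trials)
    feat = select_features((tmaps["AO"], tmaps["VM"]), k=k, mode="conjunction")
    betas = estimate_trial_betas(runs, trials)
    tc_stack, tc_index = estimate_trialwise_timecourses_lss(runs, trials)
    pos = {i: n for n, i in enumerate(tc_index)}
    correct = trials["correct"]

    single_tcs, t2_tcs = [], []
    for task in ("AO", "VM"):
        tr_idx = trials.index[(trials["condition"] == task) & correct]
        pat = betas.loc[tr_idx].to_numpy()
        labels = trials.loc[tr_idx, "map1"].to_numpy(int)
        run_ids = trials.loc[tr_idx, "run"].to_numpy()
        stack = tc_stack[[pos[i] for i in tr_idx]]
        single_tcs.append(time_resolved_decode_cv(
            pat, labels, run_ids, stack, labels, run_ids, tr=spec.tr,
            penalty=penalty, feature_idx=feat, task=task, tested_condition=task))

        dual_idx = trials.index[(trials["condition"] == _T2_CONDITION[task]) & correct]
        clf = train_classifier(pat, labels, penalty=penalty, feature_idx=feat, task=task)
        dual_stack = tc_stack[[pos[i] for i in dual_idx]]
        tc = time_resolved_decode(clf, dual_stack,
                                  trials.loc[dual_idx, "map2"].to_numpy(int),
                                  tr=spec.tr, tested_condition=_T2_CONDITION[task])
        _, shifted, applied = shift_timecourse(tc.time, tc.accuracy,
                                               soa=spec.soa_short, tr=spec.tr,
                                               mode="fitted")
        tc.accuracy = np.clip(shifted, 0.0, 1.0)
        tc.shift_applied = applied
        t2_tcs.append(tc)

    single = pool_task_order(*single_tcs, target="single")
    t2_short = pool_task_order(*t2_tcs, target="T2-short")
    m_single = _latencies(single)
    m_t2 = _latencies(t2_short)
    injected = float(trials.loc[trials["is_dual"], "postponement"].mean())
    return {
        "serial": serial,
        "single_peak_s": m_single.peak_s,
        "single_onset_s": m_single.onset_s,
        "t2_peak_s": m_t2.peak_s,
        "t2_onset_s": m_t2.onset_s,
        "delta_peak_s": m_t2.peak_s - m_single.peak_s,
        "delta_onset_s": m_t2.onset_s - m_single.onset_s,
        "injected_postponement_s": injected,
        "mean_rt1_s": float(trials.loc[~trials["is_dual"], "rt1"].mean()),
        "curves": {"single": single, "t2_short": t2_short},
    }


def quartile_discrimination_subject(seed: int, spec: DesignSpec = QUARTILE_SPEC) -> dict:
    """Quartile-RT profile classification for one synthetic subject.

    Simulates a duration-scaling central region and a fixed-duration
    execution region responding to the same single-task trials, then runs the
    quartile pipeline on both and reports the inferred profile labels.
    """
    rng = np.random.default_rng(seed)
    model = sample_stage_model(rng)
    trials = simulate_behavior(make_design(spec, rng), model, rng)
    selection = RegionModel("MD", "central", None, n_voxels=80)
    execution = RegionModel("exec", "execution", "AO", n_voxels=80)
    runs = synthesize_bold(trials, [selection, execution], spec, None, rng)
    res_sel = quartile_profile(runs, trials, "MD", "AO")
    res_exe = quartile_profile(runs, trials, "exec", "AO")
    return {"selection": res_sel, "execution": res_exe,
            "correct": (res_sel.profile == "selection")
            and (res_exe.profile == "execution")}


def permutation_chance_curve(
    seed: int,
    n_permutations: int = 10,
    spec: DesignSpec | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Label-permuted time-resolved decoding.

    Trains real decoders but scores them against permuted mapping labels,
    pooling over permutations.  Returns (time, mean accuracy per lag, total
    decisions per lag); the curve should sit at the 12.5% chance rate.
    """
    spec = spec or replace(RECOVERY_SPEC, n_runs=3)
    rng = np.random.default_rng(seed)
    trials = simulate_behavior(make_design(spec, rng), StageModel(), rng)
    md = next(r for r in default_regions() if r.name == "MD")
    runs = synthesize_bold(trials, [md], spec, None, rng)
    tmaps = condition_tmaps(runs, trials)
    feat = select_features((tmaps["AO"], tmaps["VM"]), k=50, mode="conjunction")
    betas = estimate_trial_betas(runs, trials)
    tc_stack, tc_index = estimate_trialwise_timecourses_lss(runs, trials,
                                                            conditions=("AO",))
    correct = trials["correct"]
    tr_idx = trials.index[(trials["condition"] == "AO") & correct]
    pat = betas.loc[tr_idx].to_numpy()
    labels = trials.loc[tr_idx, "map1"].to_numpy(int)
    clf = train_classifier(pat, labels, feature_idx=feat, task="AO")
    pos = {i: n for n, i in enumerate(tc_index)}
    stack = tc_stack[[pos[i] for i in tr_idx]]
    window = stack.shape[1]
    acc = np.zeros(window)
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        tc = time_resolved_decode(clf, stack, perm, tr=spec.tr)
        acc += tc.accuracy
    n_per_lag = n_permutations * len(labels)
    return np.arange(window) * spec.tr, acc / n_permutations, n_per_lag
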
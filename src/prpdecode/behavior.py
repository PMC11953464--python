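"""Central-bottleneck stage model of dual-task reaction times.

Each task is decomposed into a perceptual stage P, a central
response-selection stage C, and a motor stage M.  Single-task RT is the sum
P + C + M.  In dual-task trials the central stage is the bottleneck: task 2's
central processing cannot begin before task 1's central stage has finished,

    RT2 = max(P2, P1 + C1 - SOA) + C2 + M2,

(RT2 measured from the task-2 stimulus onset), which produces the
psychological refractory period (PRP) - slowed RT2 at short SOA.  A parallel
variant (``serial=False``) removes the queue: RT2 = P2 + C2 + M2.

Default stage means (P = 0.10 s, C = 0.835 s, M = 0.135 s) give a mean
single-task RT of 1.07 s and a deterministic short-SOA central postponement
of P1 + C1 - 0.3 - P2 = 0.535 s, the magnitude of the group PRP the model is
meant to emulate.  Stage durations are gamma-distributed; response-selection
variability dominates (CV 0.25 for C vs. 0.1 for P and M), as expected for
8-alternative arbitrary mappings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["StageModel", "sample_stage_model", "simulate_behavior", "summarize_behavior",
           "central_postponement"]

_STAGES = ("P", "C", "M")


@dataclass(frozen=True)
class StageModel:
    """Stage-duration distributions for both tasks.

    ``means[task]`` maps each of P/C/M to its mean duration (s); ``cvs`` give
    the gamma coefficient of variation per stage.  ``serial`` toggles the
    central bottleneck (serial queuing) vs. the parallel null model.
    """

    means: dict = field(default_factory=lambda: {
        "AO": {"P": 0.10, "C": 0.835, "M": 0.135},
        "VM": {"P": 0.10, "C": 0.835, "M": 0.135},
    })
    cvs: dict = field(default_factory=lambda: {"P": 0.1, "C": 0.25, "M": 0.1})
    accuracy: float = 0.9
    serial: bool = True

    def single_task_mean_rt(self, task: str) -> float:
        return float(sum(self.means[task].values()))


def sample_stage_model(
    rng: np.random.Generator,
    base: StageModel | None = None,
    between_subject_cv: float = 0.25,
) -> StageModel:
    """Draw a subject-specific stage model by jittering the central-stage mean.

    Between-subject variability is concentrated in C (response selection),
    which is what makes subjects differ in RT and PRP magnitude; the default
    spread yields individual PRP magnitudes of roughly 0.2-0.9 s, the range
    such dual-task studies report.
    """
    base = base or StageModel()
    means = {}
    for task, m in base.means.items():
        scale = float(rng.lognormal(mean=0.0, sigma=between_subject_cv))
        means[task] = {"P": m["P"], "C": m["C"] * scale, "M": m["M"]}
    return StageModel(means=means, cvs=dict(base.cvs), accuracy=base.accuracy,
                      serial=base.serial)


def _draw(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    if cv <= 0:
        return np.full(n, mean)
    shape = 1.0 / cv ** 2
    return rng.gamma(shape, mean / shape, size=n)


def central_postponement(p1, c1, p2, soa):
    """Delay of task-2 central-stage start caused by serial queuing (s)."""
    return np.maximum(0.0, np.asarray(p1) + np.asarray(c1) - np.asarray(soa) - np.asarray(p2))


def simulate_behavior(
    trials: pd.DataFrame,
    model: StageModel | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Fill a trial table with stage draws, RTs and simulated accuracy.

    Adds columns ``P1, C1, M1, P2, C2, M2`` (ground-truth stage durations, s),
    ``rt1``, ``rt2`` (rt2 from the task-2 stimulus onset), ``postponement``
    (task-2 central-stage delay), and ``correct1/correct2/correct``.
    """
    model = model or StageModel()
    rng = rng if rng is not None else np.random.default_rng(0)
    if (trials["is_dual"] & (trials["soa"].astype(float).fillna(0) < 0)).any():
        raise ValueError("negative SOA in trial table")
    out = trials.copy()
    n = len(out)
    stage = {f"{s}{i}": np.full(n, np.nan) for i in (1, 2) for s in _STAGES}
    for task in ("AO", "VM"):
        for slot, col in ((1, "task1"), (2, "task2")):
            mask = (out[col] == task).to_numpy()
            k = int(mask.sum())
            if k == 0:
                continue
            for s in _STAGES:
                stage[f"{s}{slot}"][mask] = _draw(rng, model.means[task][s],
                                                  model.cvs[s], k)
    for key, val in stage.items():
        out[key] = val

    out["rt1"] = out["P1"] + out["C1"] + out["M1"]
    soa = out["soa"].to_numpy(float)
    dual = out["is_dual"].to_numpy()
    post = np.full(n, np.nan)
    rt2 = np.full(n, np.nan)
    if model.serial:
        post[dual] = central_postponement(out["P1"][dual], out["C1"][dual],
                                          out["P2"][dual], soa[dual])
    else:
        post[dual] = 0.0
    rt2[dual] = out["P2"][dual] + post[dual] + out["C2"][dual] + out["M2"][dual]
    out["postponement"] = post
    out["rt2"] = rt2
    out["correct1"] = rng.random(n) < model.accuracy
    out["correct2"] = np.where(dual, rng.random(n) < model.accuracy, True)
    out["correct"] = out["correct1"] & out["correct2"]
    return out


def summarize_behavior(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean RTs per condition plus pooled-task-order dual-task rows and PRP.

    Returns a tidy table with one row per condition (and pooled ``S-dual`` /
    ``L-dual`` rows) and a ``PRP`` row = mean RT2(short) - mean RT2(long),
    computed over correct trials.
    """
    ok = trials[trials["correct"]]
    rows = []
    for cond, grp in ok.groupby("condition"):
        rows.append({"condition": cond, "n": len(grp),
                     "rt1": grp["rt1"].mean(), "rt2": grp["rt2"].mean()})
    pooled = {}
    for kind, prefix in (("short", "S-"), ("long", "L-")):
        grp = ok[ok["condition"].str.startswith(prefix)]
        if len(grp):
            pooled[kind] = grp["rt2"].mean()
            rows.append({"condition": f"{prefix}dual", "n": len(grp),
                         "rt1": grp["rt1"].mean(), "rt2": pooled[kind]})
    if len(pooled) == 2:
        rows.append({"condition": "PRP", "n": np.nan, "rt1": np.nan,
                     "rt2": pooled["short"] - pooled["long"]})
    return pd.DataFrame(rows)
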
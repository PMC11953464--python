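"""Experimental-design generation for the dual-task paradigm.

The emulated session interleaves two arbitrary 8-alternative sensorimotor
tasks: an auditory-oculomotor (AO) task and a visual-manual (VM) task.  Six
trial types are used: the two single tasks plus four dual-task conditions
crossing task order (AO first vs. VM first) with stimulus-onset asynchrony
(short 300 ms vs. long 1500 ms).  Runs are ultrafast-fMRI length (1600
volumes at TR = 199 ms = 318.4 s), with rest before the first and after the
last trial and inter-trial intervals drawn from a truncated decaying
exponential on the TR grid (3.98-11.144 s, mean 5.4 s).

A ``TrialTable`` is a pandas DataFrame with one row per trial and columns
``run, onset_t1, condition, task1, task2, soa, map1, map2`` (plus RT /
accuracy / ground-truth stage columns once behavior has been simulated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = ["DesignSpec", "PackingError", "sample_itis", "iti_distribution", "make_design"]

#: condition code -> (task1, task2, soa kind)
CONDITION_STRUCTURE = {
    "AO": ("AO", None, None),
    "VM": ("VM", None, None),
    "S-AOVM": ("AO", "VM", "short"),
    "L-AOVM": ("AO", "VM", "long"),
    "S-VMAO": ("VM", "AO", "short"),
    "L-VMAO": ("VM", "AO", "long"),
}

DEFAULT_CONDITIONS = tuple(CONDITION_STRUCTURE)


class PackingError(RuntimeError):
    """Raised when a run's trials plus ITIs cannot fit in its volume budget."""


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of one scanning session.

    Defaults reproduce the study design: 10 runs of 48 trials (8 per
    condition), each of the 8 stimulus-response mappings used once per
    condition per run.
    """

    tr: float = 0.199
    run_volumes: int = 1600
    n_runs: int = 10
    trials_per_run: int = 48
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    soa_short: float = 0.3
    soa_long: float = 1.5
    iti_min: float = 3.98
    iti_max: float = 11.144
    iti_mean: float = 5.4
    rest_pre: float = 7.96
    rest_post: float = 9.96
    stim_duration: float = 0.2
    n_mappings: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not (self.iti_min <= self.iti_mean <= self.iti_max):
            raise ValueError("require iti_min <= iti_mean <= iti_max")
        if self.trials_per_run % len(self.conditions):
            raise ValueError("trials_per_run must divide evenly across conditions")
        if self.trials_per_run // len(self.conditions) % self.n_mappings:
            raise ValueError("per-condition trial count must be a multiple of n_mappings")
        unknown = set(self.conditions) - set(CONDITION_STRUCTURE)
        if unknown:
            raise ValueError(f"unknown condition codes: {sorted(unknown)}")

    @property
    def run_duration(self) -> float:
        """Run length in seconds (volumes x TR)."""
        return self.run_volumes * self.tr

    def soa_value(self, kind: str | None) -> float | None:
        if kind is None:
            return None
        return self.soa_short if kind == "short" else self.soa_long


def iti_distribution(spec: DesignSpec) -> tuple[np.ndarray, np.ndarray]:
    """Support (s, on the TR grid) and probabilities of the ITI law.

    Truncated decaying exponential restricted to integer TR multiples in
    ``[iti_min, iti_max]``, with the decay rate solved numerically so the
    theoretical mean equals ``iti_mean``.
    """
    k_lo = int(np.ceil(spec.iti_min / spec.tr - 1e-9))
    k_hi = int(np.floor(spec.iti_max / spec.tr + 1e-9))
    support = np.arange(k_lo, k_hi + 1) * spec.tr
    if not (support[0] < spec.iti_mean < support[-1]):
        raise ValueError(
            f"iti_mean={spec.iti_mean} not inside the open support "
            f"({support[0]:.3f}, {support[-1]:.3f}); cannot calibrate decay rate"
        )

    def mean_at(lam: float) -> float:
        w = np.exp(-lam * (support - support[0]))
        return float(np.sum(support * w) / np.sum(w))

    lam = optimize.brentq(lambda l: mean_at(l) - spec.iti_mean, 1e-9, 50.0)
    w = np.exp(-lam * (support - support[0]))
    return support, w / w.sum()


def sample_itis(spec: DesignSpec, n: int, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw ``n`` inter-trial intervals (s) from the calibrated decay law."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return np.zeros(0)
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    support, probs = iti_distribution(spec)
    return rng.choice(support, size=n, p=probs)


def _trial_window(spec: DesignSpec, condition: str) -> float:
    """Stimulus period of one trial: T1 onset to T2 (or only) stimulus offset."""
    _, task2, soa_kind = CONDITION_STRUCTURE[condition]
    soa = spec.soa_value(soa_kind) or 0.0
    return soa + spec.stim_duration if task2 else spec.stim_duration


def _snap(t: float, tr: float) -> float:
    return round(t / tr) * tr


def make_design(spec: DesignSpec, rng: np.random.Generator | None = None,
                max_attempts: int = 200) -> pd.DataFrame:
    """Generate a balanced, randomized trial table for one session.

    Each run holds ``trials_per_run / n_conditions`` trials per condition, and
    within a run every condition uses each stimulus-response mapping an equal
    number of times (independent mapping permutations for the two tasks of a
    dual trial).  Onsets are snapped to the TR grid.  ITIs (T2 stimulus offset
    to next T1 onset) are redrawn until the run fits within its volume budget;
    a run that cannot be packed raises :class:`PackingError`.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    per_cond = spec.trials_per_run // len(spec.conditions)
    reps = per_cond // spec.n_mappings
    rows = []
    for run in range(spec.n_runs):
        trial_conditions = []
        map1s, map2s = [], []
        for cond in spec.conditions:
            trial_conditions += [cond] * per_cond
            m1 = np.concatenate([rng.permutation(spec.n_mappings) + 1 for _ in range(reps)])
            m2 = np.concatenate([rng.permutation(spec.n_mappings) + 1 for _ in range(reps)])
            map1s.append(m1)
            map2s.append(m2)
        map1s = np.concatenate(map1s)
        map2s = np.concatenate(map2s)
        order = rng.permutation(spec.trials_per_run)

        windows = np.array([_trial_window(spec, trial_conditions[i]) for i in order])
        budget = spec.run_duration - spec.rest_post
        for attempt in range(max_attempts):
            itis = sample_itis(spec, spec.trials_per_run - 1, rng)
            onsets = np.empty(spec.trials_per_run)
            t = spec.rest_pre
            ok = True
            for i in range(spec.trials_per_run):
                onsets[i] = _snap(t, spec.tr)
                end = onsets[i] + windows[i]
                if end > budget:
                    ok = False
                    break
                if i < spec.trials_per_run - 1:
                    t = end + itis[i]
            if ok:
                break
        else:
            raise PackingError(
                f"run {run}: could not pack {spec.trials_per_run} trials plus ITIs "
                f"into {spec.run_duration:.1f} s after {max_attempts} attempts"
            )

        for i, idx in enumerate(order):
            cond = trial_conditions[idx]
            task1, task2, soa_kind = CONDITION_STRUCTURE[cond]
            rows.append({
                "run": run,
                "onset_t1": onsets[i],
                "condition": cond,
                "task1": task1,
                "task2": task2,
                "soa": spec.soa_value(soa_kind),
                "map1": int(map1s[idx]),
                "map2": int(map2s[idx]) if task2 else pd.NA,
            })
    table = pd.DataFrame(rows)
    table["is_dual"] = table["task2"].notna()
    return table
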
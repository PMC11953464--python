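"""Forward BOLD synthesis: neural boxcars -> voxel x time runs.

Each voxel's signal is the sum over neural events of the event boxcar
convolved with the region's HRF, sampled on the TR grid, scaled by a
per-voxel amplitude (mean spatial profile plus the mapping-specific pattern
component), on top of a scanner baseline, AR(1) noise, slow polynomial
drift, and shared nuisance components (which are also returned as a nuisance
regressor matrix, mirroring how motion/physiology regressors enter real
analyses).

The boxcar convolution is computed exactly as a difference of the HRF's
running integral, (box * h)(t) = H(t - s) - H(t - s - d), evaluated by
interpolation on a fine grid, so event timing is not quantized to the TR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import legendre
from scipy import signal

from .design import DesignSpec
from .hrf import HRFParams, eval_hrf
from .regions import RegionModel, simulate_neural_events

__all__ = ["NoiseConfig", "BOLDRun", "synthesize_bold", "event_responses"]


@dataclass(frozen=True)
class NoiseConfig:
    """Additive noise for synthetic runs (scanner units; baseline 1000
    corresponds to ~0.1% signal change per unit of signal amplitude)."""

    sigma: float = 2.0          # stationary sd of the AR(1) process
    ar_phi: float = 0.3
    baseline: float = 1000.0
    drift_order: int = 3
    drift_sd: float = 1.5       # sd of each Legendre coefficient per voxel
    n_nuisance: int = 4
    nuisance_sd: float = 1.0    # sd of per-voxel loadings on shared components


@dataclass
class BOLDRun:
    """One run: voxel x time data with ROI labels, nuisance and censor."""

    data: np.ndarray            # (n_volumes, n_voxels)
    tr: float
    run: int
    roi_labels: np.ndarray      # (n_voxels,) region name per voxel
    nuisance: np.ndarray        # (n_volumes, k)
    censor: np.ndarray          # (n_volumes,) bool, True = keep

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.censor):
            raise ValueError("censor length must equal the number of volumes")
        if self.data.shape[1] != len(self.roi_labels):
            raise ValueError("roi_labels length must equal the number of voxels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    def voxels(self, roi: str) -> np.ndarray:
        return np.nonzero(self.roi_labels == roi)[0]

    def restrict(self, rois: str | list[str]) -> "BOLDRun":
        """A view of this run limited to the voxels of the given ROI(s)."""
        rois = [rois] if isinstance(rois, str) else list(rois)
        keep = np.isin(self.roi_labels, rois)
        return BOLDRun(data=self.data[:, keep], tr=self.tr, run=self.run,
                       roi_labels=self.roi_labels[keep], nuisance=self.nuisance,
                       censor=self.censor)


def _integrated_hrf(hrf: HRFParams, t_max: float, dt: float) -> tuple[np.ndarray, np.ndarray]:
    tf = np.arange(0.0, t_max + dt, dt)
    h = eval_hrf(hrf, tf)
    H = np.concatenate([[0.0], np.cumsum(h) * dt])
    return np.concatenate([[-dt], tf]), H


def event_responses(
    events: pd.DataFrame,
    hrf: HRFParams,
    n_volumes: int,
    tr: float,
    dt: float = 0.02,
    kernel_span: float = 40.0,
) -> np.ndarray:
    """(n_volumes, n_events) matrix of unit-amplitude convolved boxcars."""
    t_k = np.arange(n_volumes) * tr
    tf, H = _integrated_hrf(hrf, kernel_span, dt)
    out = np.zeros((n_volumes, len(events)))
    for j, (_, ev) in enumerate(events.iterrows()):
        rel = t_k - ev["start"]
        out[:, j] = np.interp(rel, tf, H, left=0.0, right=H[-1]) - \
            np.interp(rel - ev["duration"], tf, H, left=0.0, right=H[-1])
    return out


def _ar1(rng: np.random.Generator, shape: tuple[int, int], phi: float, sigma: float) -> np.ndarray:
    innov_sd = sigma * np.sqrt(max(1.0 - phi ** 2, 1e-12))
    white = rng.standard_normal(shape) * innov_sd
    return signal.lfilter([1.0], [1.0, -phi], white, axis=0)


def _smooth_series(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """Low-frequency unit-variance shared components (time x k)."""
    white = rng.standard_normal((n, k))
    win = signal.windows.hann(51)
    comp = signal.fftconvolve(white, win[:, None] / win.sum(), mode="same", axes=0)
    comp -= comp.mean(axis=0)
    sd = comp.std(axis=0)
    sd[sd == 0] = 1.0
    return comp / sd


def synthesize_bold(
    trials: pd.DataFrame,
    regions: list[RegionModel],
    spec: DesignSpec,
    noise: NoiseConfig | None = None,
    rng: np.random.Generator | None = None,
    serial: bool = True,
) -> list[BOLDRun]:
    """Generate one :class:`BOLDRun` per run of the trial table.

    Pattern matrices and spatial profiles are drawn once (from ``rng``) and
    shared across runs, so identical (trials, regions, spec, seed) give
    bit-identical output.
    """
    noise = noise or NoiseConfig()
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    regions = [r if r.patterns is not None else r.with_patterns(rng, spec.n_mappings)
               for r in regions]
    all_events = {r.name: simulate_neural_events(trials, r, serial=serial) for r in regions}

    runs: list[BOLDRun] = []
    n_vox_total = sum(r.n_voxels for r in regions)
    roi_labels = np.concatenate([[r.name] * r.n_voxels for r in regions])
    for run_id in sorted(trials["run"].unique()):
        data = np.zeros((spec.run_volumes, n_vox_total))
        col = 0
        for r in regions:
            ev = all_events[r.name]
            ev = ev[ev["run"] == run_id].reset_index(drop=True)
            sl = slice(col, col + r.n_voxels)
            if len(ev):
                C = event_responses(ev, r.hrf, spec.run_volumes, spec.tr)
                amp = np.empty((len(ev), r.n_voxels))
                for j, (_, e) in enumerate(ev.iterrows()):
                    base = e["amplitude"] * r.spatial_profile
                    if isinstance(e["task"], str):
                        w = r.patterns[e["task"]][int(e["mapping"]) - 1]
                        base = base + e["amplitude"] * r.pattern_gain * w
                    amp[j] = base
                data[:, sl] += C @ amp
            col += r.n_voxels

        data += noise.baseline
        data += _ar1(rng, data.shape, noise.ar_phi, noise.sigma)
        if noise.drift_order > 0:
            x = np.linspace(-1, 1, spec.run_volumes)
            basis = np.stack([legendre.legval(x, [0] * (d + 1) + [1])
                              for d in range(1, noise.drift_order + 1)], axis=1)
            data += basis @ (rng.normal(0, noise.drift_sd, (noise.drift_order, n_vox_total)))
        if noise.n_nuisance > 0:
            comp = _smooth_series(rng, spec.run_volumes, noise.n_nuisance)
            data += comp @ rng.normal(0, noise.nuisance_sd, (noise.n_nuisance, n_vox_total))
        else:
            comp = np.zeros((spec.run_volumes, 0))
        runs.append(BOLDRun(data=data, tr=spec.tr, run=int(run_id),
                            roi_labels=roi_labels.copy(), nuisance=comp,
                            censor=np.ones(spec.run_volumes, bool)))
    return runs
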
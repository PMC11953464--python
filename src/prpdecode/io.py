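"""Reading and writing runs, events tables and results.

Runs are written as 4D NIfTI (voxels unfolded along x, a single y/z line)
with a JSON sidecar recording TR, ROI labels, and censor; trial tables as
BIDS-style tab-separated events files; ground truth (stage durations,
patterns) as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .bold import BOLDRun

__all__ = ["write_run", "read_run", "write_events", "read_events",
           "write_ground_truth", "write_json"]

_EVENT_COLUMNS = ["onset", "duration", "trial_type", "soa", "task1", "task2",
                  "map1", "map2", "rt1", "rt2", "correct"]


def write_run(run: BOLDRun, path: str | Path) -> Path:
    """Write a run as 4D NIfTI (V x 1 x 1 x T) plus a JSON sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(run.data.T[:, None, None, :].astype(np.float32),
                          affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, run.tr))
    nib.save(img, path)
    sidecar = {"tr": run.tr, "run": run.run,
               "roi_labels": run.roi_labels.tolist(),
               "censor": run.censor.astype(int).tolist()}
    side_path = path.with_suffix("").with_suffix(".json")
    side_path.write_text(json.dumps(sidecar))
    np.savetxt(path.with_suffix("").with_suffix(".nuisance.tsv"), run.nuisance,
               delimiter="\t")
    return path


def read_run(path: str | Path) -> BOLDRun:
    path = Path(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)[:, 0, 0, :].T
    side = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    nuis_path = path.with_suffix("").with_suffix(".nuisance.tsv")
    nuisance = (np.loadtxt(nuis_path, delimiter="\t", ndmin=2)
                if nuis_path.exists() else np.zeros((data.shape[0], 0)))
    return BOLDRun(data=data, tr=float(side["tr"]), run=int(side["run"]),
                   roi_labels=np.asarray(side["roi_labels"]),
                   nuisance=nuisance,
                   censor=np.asarray(side["censor"], bool))


def write_events(trials: pd.DataFrame, path: str | Path) -> Path:
    """Tab-separated events file, one row per trial."""
    path = Path(path)
    df = pd.DataFrame({
        "onset": trials["onset_t1"],
        "duration": trials["soa"].fillna(0) + 0.2,
        "trial_type": trials["condition"],
        "soa": trials["soa"],
        "task1": trials["task1"],
        "task2": trials["task2"],
        "map1": trials["map1"],
        "map2": trials["map2"],
        "rt1": trials.get("rt1"),
        "rt2": trials.get("rt2"),
        "correct": trials.get("correct"),
        "run": trials["run"],
    })
    df.to_csv(path, sep="\t", index=False, na_rep="n/a")
    return path


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    out = pd.DataFrame({
        "run": df["run"].astype(int),
        "onset_t1": df["onset"].astype(float),
        "condition": df["trial_type"],
        "task1": df["task1"],
        "task2": df["task2"].where(df["task2"].notna(), None),
        "soa": df["soa"],
        "map1": df["map1"].astype("Int64"),
        "map2": df["map2"].astype("Int64"),
    })
    for col in ("rt1", "rt2", "correct"):
        if col in df:
            out[col] = df[col]
    out["is_dual"] = out["task2"].notna()
    return out


def write_ground_truth(trials: pd.DataFrame, path: str | Path) -> Path:
    """JSON sidecar with the per-trial ground-truth stage durations."""
    path = Path(path)
    cols = [c for c in ("P1", "C1", "M1", "P2", "C2", "M2", "postponement")
            if c in trials.columns]
    payload = {"stage_durations": trials[cols].to_dict(orient="list")}
    path.write_text(json.dumps(payload))
    return path


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default))
    return path
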
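"""File formats: BIDS-style events TSV, physio TSV(.gz) + JSON sidecar,
BOLD TSV, ground-truth JSON.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .signal import SampledSignal
from .synthdata import BEHAVIOR_COLUMNS, GroundTruth

__all__ = [
    "write_events",
    "read_events",
    "write_physio",
    "read_physio",
    "write_bold",
    "read_bold",
    "write_ground_truth",
]

EVENTS_COLUMNS = ["onset", "duration", "trial_type", "response_time",
                  "correct", "difficulty", "run"]


def write_events(behavior: pd.DataFrame, path) -> None:
    """Write a behavior table as a BIDS-style events TSV."""
    df = pd.DataFrame({
        "onset": behavior["onset_s"],
        "duration": 0.2,
        "trial_type": np.where(behavior["response"] == "none", "lapse", "response"),
        "response_time": behavior["rt_s"],
        "correct": behavior["correct"],
        "difficulty": behavior["difficulty"],
        "run": behavior["run_id"],
        "observer_id": behavior["observer_id"],
        "trial_index": behavior["trial_index"],
        "tilt_deg": behavior["tilt_deg"],
        "response": behavior["response"],
    })
    df.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events(path) -> pd.DataFrame:
    """Read an events TSV back into a behavior table.

    ``response_time`` values of "n/a" mark lapse rows (missing RT and
    correctness, response 'none').
    """
    try:
        df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"events file {path} is empty") from exc
    missing = [c for c in EVENTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events file {path} missing column(s): {missing}")
    lapse = df["response_time"].isna()
    out = pd.DataFrame({
        "observer_id": df.get("observer_id", "obs01"),
        "run_id": df["run"],
        "trial_index": df.get(
            "trial_index", df.groupby("run").cumcount()
        ),
        "onset_s": pd.to_numeric(df["onset"], errors="raise"),
        "difficulty": df["difficulty"],
        "tilt_deg": df.get("tilt_deg", np.nan),
        "response": df.get("response", pd.Series(np.where(lapse, "none", "cw"))),
        "correct": df["correct"],
        "rt_s": df["response_time"],
    })
    out.loc[lapse, ["correct", "rt_s"]] = np.nan
    out.loc[lapse, "response"] = "none"
    bad = out["onset_s"].isna()
    if bad.any():
        raise ValueError(f"malformed onset in row(s) {np.nonzero(bad.to_numpy())[0]}")
    return out[BEHAVIOR_COLUMNS]


def write_physio(signal: SampledSignal, path) -> None:
    """Gzipped single-column TSV plus a JSON sidecar with rate/start."""
    path = Path(path)
    if not path.name.endswith(".tsv.gz"):
        raise ValueError("physio path must end with .tsv.gz")
    with gzip.open(path, "wt") as fh:
        for v in signal.values:
            fh.write(f"{v:.10g}\n")
    sidecar = {
        "SamplingFrequency": signal.rate_hz,
        "StartTime": signal.start_s,
        "Columns": [signal.units or "signal"],
    }
    path.with_name(path.name[: -len(".tsv.gz")] + ".json").write_text(
        json.dumps(sidecar, indent=1)
    )


def read_physio(path) -> SampledSignal:
    """Read a physio trace written by :func:`write_physio`."""
    path = Path(path)
    sidecar_path = path.with_name(path.name[: -len(".tsv.gz")] + ".json")
    if not sidecar_path.exists():
        raise ValueError(f"missing JSON sidecar for {path}")
    sidecar = json.loads(sidecar_path.read_text())
    with gzip.open(path, "rt") as fh:
        values = np.array([float(line) for line in fh if line.strip()])
    if values.size == 0:
        raise ValueError(f"physio file {path} is empty")
    units = (sidecar.get("Columns") or [""])[0]
    return SampledSignal(
        values,
        rate_hz=float(sidecar["SamplingFrequency"]),
        start_s=float(sidecar.get("StartTime", 0.0)),
        units=units,
    )


def write_bold(voxels: list[SampledSignal], path) -> None:
    """Voxel signals as a volumes-by-voxels TSV."""
    arr = np.column_stack([v.values for v in voxels])
    header = "\t".join(f"voxel{i:04d}" for i in range(arr.shape[1]))
    np.savetxt(path, arr, delimiter="\t", header=header, comments="", fmt="%.8g")


def read_bold(path, rate_hz: float) -> list[SampledSignal]:
    arr = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    return [SampledSignal(arr[:, j], rate_hz=rate_hz, units="psc")
            for j in range(arr.shape[1])]


def write_ground_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1))
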
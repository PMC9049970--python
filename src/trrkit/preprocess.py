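"""Nuisance removal, ROI averaging, epoching and trial-exclusion rules.

Fixed pipeline order: percent change (for raw-unit inputs) -> global-signal
projection -> physiological/motion projection -> ROI average -> epoching
with first-trial removal and lapse partitioning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal import SampledSignal
from .synthdata import ProtocolParams, _global_onsets

__all__ = [
    "EpochMatrix",
    "percent_change",
    "global_signal",
    "project_out",
    "roi_average",
    "clean_and_epoch",
    "preprocess_roi",
]


@dataclass
class EpochMatrix:
    """Trials-by-samples matrix with per-row metadata."""

    data: np.ndarray          # (n_trials, samples_per_trial)
    meta: pd.DataFrame        # difficulty, correct, rt_s, lapse, run_id, trial_index
    tr_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("epoch data must be 2-D (trials x samples)")
        if len(self.meta) != self.data.shape[0]:
            raise ValueError("metadata rows must match epoch rows")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def samples_per_trial(self) -> int:
        return self.data.shape[1]

    def mean_response(self) -> np.ndarray:
        return self.data.mean(axis=0)


def _stack(voxels) -> np.ndarray:
    if isinstance(voxels, np.ndarray):
        arr = np.atleast_2d(np.asarray(voxels, dtype=float))
    else:
        arr = np.vstack([v.values if isinstance(v, SampledSignal) else v for v in voxels])
    if arr.size == 0:
        raise ValueError("empty voxel collection")
    return arr


def _run_slices(n: int, n_runs: int) -> list[slice]:
    if n % n_runs != 0:
        raise ValueError(f"{n} samples do not divide into {n_runs} runs")
    per = n // n_runs
    return [slice(i * per, (i + 1) * per) for i in range(n_runs)]


def percent_change(signal: SampledSignal, n_runs: int = 1) -> SampledSignal:
    """100 x (x - mean) / mean, computed within each run."""
    out = signal.values.copy()
    for sl in _run_slices(signal.n_samples, n_runs):
        m = out[sl].mean()
        if m == 0:
            raise ValueError("percent change undefined: run mean is zero")
        out[sl] = 100.0 * (out[sl] - m) / m
    return SampledSignal(out, signal.rate_hz, signal.start_s, units="psc")


def global_signal(voxels) -> SampledSignal:
    """Unweighted mean across voxels at each volume."""
    arr = _stack(voxels)
    rate = voxels[0].rate_hz if isinstance(voxels[0], SampledSignal) else 1.0
    return SampledSignal(arr.mean(axis=0), rate_hz=rate, units="psc")


def roi_average(voxels, roi_mask) -> SampledSignal:
    """Mean across the masked subset of voxels."""
    arr = _stack(voxels)
    mask = np.asarray(roi_mask)
    if mask.dtype == bool:
        idx = np.nonzero(mask)[0]
    else:
        idx = mask.astype(int)
    if idx.size == 0:
        raise ValueError("empty ROI mask")
    rate = voxels[0].rate_hz if isinstance(voxels[0], SampledSignal) else 1.0
    return SampledSignal(arr[idx].mean(axis=0), rate_hz=rate, units="psc")


def project_out(series: SampledSignal, nuisance, n_runs: int = 1) -> SampledSignal:
    """Residual of ``series`` on [intercept, nuisance], mean added back.

    Performed within each run.  Rank-deficient nuisance sets are reduced by
    dropping collinear columns with a warning.  Idempotent for a fixed
    nuisance set.
    """
    if isinstance(nuisance, SampledSignal):
        nuis = nuisance.values[:, None]
    elif isinstance(nuisance, (list, tuple)):
        nuis = np.column_stack(
            [c.values if isinstance(c, SampledSignal) else np.asarray(c, float)
             for c in nuisance]
        )
    else:
        nuis = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuis.shape[0] == 1 and series.n_samples > 1:
            nuis = nuis.T
    if nuis.shape[0] != series.n_samples:
        raise ValueError("series and nuisance lengths differ")

    out = series.values.copy()
    for sl in _run_slices(series.n_samples, n_runs):
        y = out[sl]
        X = np.column_stack([np.ones(y.size), nuis[sl]])
        # drop collinear columns (keep intercept)
        q = np.linalg.matrix_rank(X)
        if q < X.shape[1]:
            keep = [0]
            for j in range(1, X.shape[1]):
                cand = X[:, keep + [j]]
                if np.linalg.matrix_rank(cand) > len(keep):
                    keep.append(j)
            warnings.warn(
                "rank-deficient nuisance set; dropped collinear columns",
                RuntimeWarning,
                stacklevel=2,
            )
            X = X[:, keep]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        out[sl] = resid + y.mean()
    return SampledSignal(out, series.rate_hz, series.start_s, series.units)


def clean_and_epoch(
    series: SampledSignal,
    behavior: pd.DataFrame,
    protocol: ProtocolParams,
) -> tuple[EpochMatrix, EpochMatrix]:
    """Epoch an ROI series into trials and apply the exclusion rules.

    The first trial of every run is dropped.  Remaining trials are split
    into a response partition and a lapse partition.
    """
    tr = 1.0 / series.rate_hz
    spt = int(round(protocol.trial_duration_s / tr))
    onsets = _global_onsets(behavior, protocol)
    needed = int(round(onsets[-1] / tr)) + spt
    if series.n_samples < needed:
        raise ValueError(
            f"series has {series.n_samples} samples; behavior needs {needed}"
        )

    rows, meta = [], []
    for i, row in enumerate(behavior.itertuples(index=False)):
        if row.trial_index == 0:
            continue
        v0 = int(round(onsets[i] / tr))
        rows.append(series.values[v0 : v0 + spt])
        meta.append({
            "observer_id": row.observer_id,
            "run_id": row.run_id,
            "trial_index": row.trial_index,
            "difficulty": row.difficulty,
            "correct": row.correct,
            "rt_s": row.rt_s,
            "lapse": row.response == "none",
        })
    meta = pd.DataFrame(meta)
    data = np.vstack(rows) if rows else np.empty((0, spt))
    is_lapse = meta["lapse"].to_numpy(bool) if len(meta) else np.zeros(0, bool)
    resp = EpochMatrix(data[~is_lapse], meta[~is_lapse].reset_index(drop=True), tr)
    laps = EpochMatrix(data[is_lapse], meta[is_lapse].reset_index(drop=True), tr)
    return resp, laps


def preprocess_roi(
    voxels,
    behavior: pd.DataFrame,
    protocol: ProtocolParams,
    nuisance=None,
    roi_mask=None,
    apply_percent_change: bool = False,
    global_reference=None,
) -> tuple[SampledSignal, EpochMatrix, EpochMatrix]:
    """Full pipeline: [percent change] -> GSR -> nuisance projection -> ROI
    average -> epoching.  Returns the ROI series plus the two partitions.

    ``global_reference`` supplies the voxel set (e.g. whole-brain) from
    which the global signal is computed; defaults to ``voxels``.
    """
    if apply_percent_change:
        voxels = [percent_change(v, protocol.n_runs) for v in voxels]
        if global_reference is not None:
            global_reference = [
                percent_change(v, protocol.n_runs) for v in global_reference
            ]
    gs = global_signal(global_reference if global_reference is not None else voxels)
    cleaned = [project_out(v, gs, protocol.n_runs) for v in voxels]
    if nuisance is not None:
        cleaned = [project_out(v, nuisance, protocol.n_runs) for v in cleaned]
    if roi_mask is None:
        roi_mask = np.arange(len(cleaned))
    roi = roi_average(cleaned, roi_mask)
    resp, laps = clean_and_epoch(roi, behavior, protocol)
    return roi, resp, laps
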
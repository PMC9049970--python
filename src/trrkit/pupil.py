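"""Pupillometry preprocessing and task-evoked summaries.

Deblinking via shape-preserving piecewise-cubic interpolation over padded
blink spans, fourth-order zero-phase Butterworth band-pass (0.03-10 Hz),
condition-wise trial averaging, and fixation stability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import PchipInterpolator

from .signal import SampledSignal
from .synthdata import ProtocolParams, _global_onsets

__all__ = [
    "PupilFilterSpec",
    "deblink",
    "bandpass",
    "evoked_response",
    "fixation_stability",
]

BLINK_PAD_S = 0.1  # margin added to each side of a blink span


@dataclass(frozen=True)
class PupilFilterSpec:
    """Zero-phase Butterworth band-pass settings."""

    low_cut_hz: float = 0.03
    high_cut_hz: float = 10.0
    order: int = 4
    zero_phase: bool = True

    def validate(self, rate_hz: float) -> None:
        if not 0 < self.low_cut_hz < self.high_cut_hz < rate_hz / 2:
            raise ValueError(
                "cutoffs must satisfy 0 < low < high < Nyquist "
                f"(got {self.low_cut_hz}, {self.high_cut_hz} at {rate_hz} Hz)"
            )


def deblink(
    trace: SampledSignal,
    missing_spans: list[tuple[float, float]],
    pad_s: float = BLINK_PAD_S,
) -> SampledSignal:
    """Replace samples inside (padded) spans by piecewise-cubic interpolation.

    Spans touching the trace boundary are filled by nearest-value extension
    with a warning.  The output contains no missing samples.
    """
    if not missing_spans:
        return trace.with_values(trace.values.copy())
    t = trace.times_s
    bad = np.zeros(trace.n_samples, dtype=bool)
    for t0, t1 in missing_spans:
        if t0 < t[0] - 1e-9 or t1 > t[-1] + trace.dt_s + 1e-9:
            raise ValueError(f"span ({t0}, {t1}) outside trace extent")
        bad |= (t >= t0 - pad_s) & (t < t1 + pad_s)
    good = ~bad
    if not good.any():
        raise ValueError("spans cover the entire trace")
    out = trace.values.copy()
    if bad[0] or bad[-1]:
        warnings.warn("blink span touches trace boundary; extending nearest value",
                      RuntimeWarning, stacklevel=2)
    interp = PchipInterpolator(t[good], out[good], extrapolate=False)
    filled = interp(t[bad])
    # nearest-value extension beyond the first/last good sample
    filled = np.where(t[bad] < t[good][0], out[good][0], filled)
    filled = np.where(t[bad] > t[good][-1], out[good][-1], filled)
    out[bad] = filled
    return trace.with_values(out)


def bandpass(trace: SampledSignal, spec: PupilFilterSpec | None = None) -> SampledSignal:
    """Butterworth band-pass, applied forward and backward (zero net phase)."""
    spec = spec or PupilFilterSpec()
    spec.validate(trace.rate_hz)
    if not np.all(np.isfinite(trace.values)):
        raise ValueError("trace contains non-finite values (deblink first)")
    sos = sps.butter(
        spec.order,
        [spec.low_cut_hz, spec.high_cut_hz],
        btype="bandpass",
        fs=trace.rate_hz,
        output="sos",
    )
    if spec.zero_phase:
        filtered = sps.sosfiltfilt(sos, trace.values)
    else:
        filtered = sps.sosfilt(sos, trace.values)
    return trace.with_values(filtered)


def _epochs_by_condition(
    trace: SampledSignal,
    behavior: pd.DataFrame,
    protocol: ProtocolParams,
    window_s: float,
) -> dict:
    onsets = _global_onsets(behavior, protocol)
    n_win = int(round(window_s * trace.rate_hz))
    groups: dict[tuple, list[np.ndarray]] = {}
    for i, row in enumerate(behavior.itertuples(index=False)):
        if row.response == "none":
            continue
        i0 = int(round(onsets[i] * trace.rate_hz))
        seg = trace.values[i0 : i0 + n_win]
        if seg.size < n_win:
            continue
        groups.setdefault((row.difficulty, int(row.correct)), []).append(seg)
    return groups


def evoked_response(
    trace: SampledSignal,
    behavior: pd.DataFrame,
    protocol: ProtocolParams,
    window_s: float | None = None,
    amplitude_mode: str = "mean_timecourse",
) -> dict:
    """Condition-wise mean task-evoked time courses and amplitudes.

    Conditions are difficulty x accuracy cells (lapse trials excluded).
    Amplitude is the std of the condition-mean time course by default;
    ``amplitude_mode='per_trial'`` averages per-trial stds instead.
    """
    if window_s is None:
        window_s = protocol.trial_duration_s
    if window_s > protocol.trial_duration_s + 1e-9:
        raise ValueError("window exceeds the trial duration")
    groups = _epochs_by_condition(trace, behavior, protocol, window_s)
    out = {}
    for cond, segs in groups.items():
        arr = np.vstack(segs)
        mean_tc = arr.mean(axis=0)
        if amplitude_mode == "mean_timecourse":
            amp = float(mean_tc.std())
        elif amplitude_mode == "per_trial":
            amp = float(arr.std(axis=1).mean())
        else:
            raise ValueError(f"unknown amplitude_mode {amplitude_mode!r}")
        out[cond] = {"mean": mean_tc, "amplitude": amp, "n_trials": arr.shape[0]}
    return out


def fixation_stability(
    gaze_xy: tuple[SampledSignal, SampledSignal],
    behavior: pd.DataFrame,
    protocol: ProtocolParams,
    fixation_deg: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Per-trial std over time of the gaze-to-fixation distance (degrees)."""
    gx, gy = gaze_xy
    if gx.n_samples != gy.n_samples or gx.rate_hz != gy.rate_hz:
        raise ValueError("gaze x/y traces must be aligned")
    dist = np.hypot(gx.values - fixation_deg[0], gy.values - fixation_deg[1])
    onsets = _global_onsets(behavior, protocol)
    n_win = int(round(protocol.trial_duration_s * gx.rate_hz))
    out = np.full(len(behavior), np.nan)
    for i in range(len(behavior)):
        i0 = int(round(onsets[i] * gx.rate_hz))
        seg = dist[i0 : i0 + n_win]
        if seg.size:
            out[i] = float(seg.std())
    return out
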
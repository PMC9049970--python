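"""Cardiac and respiratory arousal metrics in 15-s trial bins.

Pulse peaks are refined to sub-sample precision by intersecting straight
lines fit to the rising and falling flanks of each sampled peak; heart
rate, RMSSD heart-rate variability and heart-rate acceleration are then
computed per trial bin, as are respiration volume/frequency/variability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal import SampledSignal

__all__ = [
    "PulseMetrics",
    "RespMetrics",
    "refine_peaks",
    "pulse_metrics",
    "respiration_metrics",
    "trial_bins",
]

FLANK_SAMPLES = 3  # samples per side for the flank line fits


@dataclass
class PulseMetrics:
    """Per-bin cardiac summaries (NaN where a bin had < 3 peaks)."""

    hr_bpm: np.ndarray
    hrv_rmssd_s: np.ndarray
    hr_accel: np.ndarray   # beats/s^2, positive = speeding up


@dataclass
class RespMetrics:
    """Per-bin respiration summaries."""

    volume: np.ndarray       # std of the percent-change trace
    frequency_hz: np.ndarray
    variability_s: np.ndarray


def trial_bins(n_trials: int, bin_s: float = 15.0, start_s: float = 0.0) -> list[tuple[float, float]]:
    """Consecutive trial windows [t0, t0 + bin_s)."""
    return [(start_s + i * bin_s, start_s + (i + 1) * bin_s) for i in range(n_trials)]


def _candidate_peaks(x: np.ndarray) -> np.ndarray:
    q1, q3 = np.percentile(x, [25, 75])
    thresh = np.median(x) + 0.5 * (q3 - q1)
    peaks, _ = sps.find_peaks(x, height=thresh)
    return peaks


def refine_peaks(trace: SampledSignal, k: int = FLANK_SAMPLES) -> np.ndarray:
    """Sub-sample peak times from flank-line intersection.

    Candidates are local maxima above an adaptive threshold (median + 0.5 x
    IQR).  For each, a line is fit to ``k`` rising-flank samples and ``k``
    falling-flank samples (the apex sample excluded from both); the refined
    peak is the intersection time, clamped to within one sample period of
    the candidate.  Equal flank slopes fall back to the candidate time.
    """
    if trace.n_samples < 5:
        raise ValueError("trace too short for peak refinement")
    x = trace.values
    if np.ptp(x) == 0:
        return np.array([])
    dt = trace.dt_s
    out = []
    for p in _candidate_peaks(x):
        t_p = trace.start_s + p * dt
        lo, hi = p - k, p + k
        if lo < 0 or hi >= x.size:
            out.append(t_p)
            continue
        t_l = (np.arange(p - k, p)) * dt
        t_r = (np.arange(p + 1, p + k + 1)) * dt
        a_l, b_l = np.polyfit(t_l, x[p - k : p], 1)
        a_r, b_r = np.polyfit(t_r, x[p + 1 : p + k + 1], 1)
        if a_l == a_r:
            warnings.warn("parallel flank fits; using sample peak time",
                          RuntimeWarning, stacklevel=2)
            out.append(t_p)
            continue
        t_star = trace.start_s + (b_r - b_l) / (a_l - a_r)
        out.append(float(np.clip(t_star, t_p - dt, t_p + dt)))
    return np.asarray(out)


def pulse_metrics(peak_times: np.ndarray, bins: list[tuple[float, float]]) -> PulseMetrics:
    """Heart rate, RMSSD and acceleration per trial bin.

    ``hr_bpm = 60 / mean(ibi)``; RMSSD is the root mean square of successive
    IBI differences; acceleration is the mean of first differences of the
    instantaneous rate (1/ibi, beats/s) divided by the elapsed time between
    interval midpoints, so shrinking IBIs give positive values.
    """
    peak_times = np.sort(np.asarray(peak_times, dtype=float))
    hr = np.full(len(bins), np.nan)
    rmssd = np.full(len(bins), np.nan)
    accel = np.full(len(bins), np.nan)
    for i, (t0, t1) in enumerate(bins):
        pk = peak_times[(peak_times >= t0) & (peak_times < t1)]
        if pk.size < 3:
            continue
        ibi = np.diff(pk)
        hr[i] = 60.0 / ibi.mean()
        d = np.diff(ibi)
        if d.size:
            rmssd[i] = float(np.sqrt(np.mean(d**2)))
            rate = 1.0 / ibi                        # beats/s
            mid = pk[:-1] + ibi / 2.0               # interval midpoints
            accel[i] = float(np.mean(np.diff(rate) / np.diff(mid)))
    return PulseMetrics(hr_bpm=hr, hrv_rmssd_s=rmssd, hr_accel=accel)


def respiration_metrics(trace: SampledSignal, bins: list[tuple[float, float]]) -> RespMetrics:
    """Volume (std), dominant frequency, and RMSSD-style variability per bin.

    Variability uses unrefined local-maximum peak times (no flank
    extrapolation), mirroring how it is computed for heart rate but on the
    slower respiration trace.
    """
    vol = np.full(len(bins), np.nan)
    freq = np.full(len(bins), np.nan)
    var = np.full(len(bins), np.nan)
    for i, (t0, t1) in enumerate(bins):
        seg = trace.slice_time(t0, t1)
        if seg.n_samples < 4:
            continue
        x = seg.values
        vol[i] = float(x.std())
        amp = np.abs(np.fft.rfft(x - x.mean()))
        freqs = np.fft.rfftfreq(x.size, d=seg.dt_s)
        if amp.size > 1:
            k = 1 + int(np.argmax(amp[1:]))
            f = float(freqs[k])
            if f * (t1 - t0) >= 1.0:     # at least one full breath in the bin
                freq[i] = f
        peaks, _ = sps.find_peaks(x)
        if peaks.size >= 3:
            intervals = np.diff(peaks) * seg.dt_s
            d = np.diff(intervals)
            if d.size:
                var[i] = float(np.sqrt(np.mean(d**2)))
            else:
                var[i] = 0.0
    return RespMetrics(volume=vol, frequency_hz=freq, variability_s=var)
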
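"""Sinusoid/Fourier summaries at the task frequency and the circular
temporal-variability statistic.

Per-trial phase comes from the single-cycle harmonic of each mean-removed
15-s epoch; temporal variability is the angular deviation
s = sqrt(2 (1 - R)) of those phases, bounded by 0 (identical phases) and
sqrt(2) (uniform phases).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import EpochMatrix
from .signal import SampledSignal

__all__ = [
    "SpectralSummary",
    "sinusoid_fit",
    "spectrum_peak",
    "trial_metrics",
    "angular_deviation",
    "response_range",
    "TASK_FREQ_HZ",
]

TASK_FREQ_HZ = 1.0 / 15.0


@dataclass
class SpectralSummary:
    """Per-trial amplitude/phase plus circular spread statistics."""

    f_task_hz: float
    phases: np.ndarray           # radians in [0, 2pi), one per usable trial
    amplitudes: np.ndarray       # percent signal change, one per trial
    mean_resultant_length: float
    temporal_variability: float  # angular deviation, in [0, sqrt(2)]
    excluded_trials: np.ndarray  # indices whose phase was undefined


def sinusoid_fit(series: SampledSignal, f_hz: float) -> tuple[float, float]:
    """Best-fitting sinusoid amplitude and phase at frequency ``f_hz``.

    Least-squares fit of ``a cos(2 pi f t) + b sin(2 pi f t) + intercept``;
    amplitude is sqrt(a^2 + b^2) and the phase is that of the equivalent
    ``A cos(2 pi f t - phi)`` form (phi = atan2(b, a), wrapped to [0, 2pi)).
    """
    if f_hz >= series.rate_hz / 2.0:
        raise ValueError("task frequency must lie below the Nyquist rate")
    if series.duration_s < 1.0 / f_hz:
        raise ValueError("series must span at least one cycle")
    t = series.times_s
    X = np.column_stack(
        [np.cos(2 * np.pi * f_hz * t), np.sin(2 * np.pi * f_hz * t), np.ones(t.size)]
    )
    (a, b, _), *_ = np.linalg.lstsq(X, series.values, rcond=None)
    amplitude = float(np.hypot(a, b))
    phase = float(np.mod(np.arctan2(b, a), 2 * np.pi))
    return amplitude, phase


def spectrum_peak(series: SampledSignal) -> tuple[float, float]:
    """Frequency and amplitude of the largest non-DC Fourier component."""
    n = series.n_samples
    if n < 2:
        raise ValueError("need at least two samples")
    amp = np.abs(np.fft.rfft(series.values)) * 2.0 / n
    freqs = np.fft.rfftfreq(n, d=series.dt_s)
    k = 1 + int(np.argmax(amp[1:]))
    return float(freqs[k]), float(amp[k])


def angular_deviation(phases: np.ndarray) -> tuple[float, float]:
    """Mean resultant length R and angular deviation s = sqrt(2 (1 - R))."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("no phases supplied")
    if np.all(phases == phases.flat[0]):
        return 1.0, 0.0  # exact bound: identical phases
    z = np.exp(1j * phases).mean()
    r = min(float(np.abs(z)), 1.0)
    return r, float(np.sqrt(max(2.0 * (1.0 - r), 0.0)))


def trial_metrics(epochs: EpochMatrix, f_task_hz: float = TASK_FREQ_HZ) -> SpectralSummary:
    """Per-trial amplitude (std of the epoch) and single-cycle Fourier phase.

    Constant epochs have no defined phase; they are excluded from the
    circular statistics with a warning but keep their (zero) amplitude.
    """
    if epochs.n_trials < 1:
        raise ValueError("need at least one trial")
    data = epochs.data
    n = epochs.samples_per_trial
    amplitudes = data.std(axis=1, ddof=1)

    demeaned = data - data.mean(axis=1, keepdims=True)
    # single cycle per epoch: k = 1 harmonic; sign convention matches
    # sinusoid_fit (a delayed response has a larger phase)
    w = np.exp(-2j * np.pi * np.arange(n) / n)
    coef = np.conj(demeaned @ w)
    mag = np.abs(coef)
    defined = mag > 1e-12
    if not np.all(defined):
        warnings.warn(
            f"{int(np.sum(~defined))} constant trial(s) excluded from phase stats",
            RuntimeWarning,
            stacklevel=2,
        )
    phases = np.mod(np.angle(coef[defined]), 2 * np.pi)
    r, s = angular_deviation(phases)
    return SpectralSummary(
        f_task_hz=f_task_hz,
        phases=phases,
        amplitudes=amplitudes,
        mean_resultant_length=r,
        temporal_variability=s,
        excluded_trials=np.nonzero(~defined)[0],
    )


def response_range(avg_response: np.ndarray) -> float:
    """Amplitude of a mean response time course as max - min."""
    avg_response = np.asarray(avg_response, dtype=float)
    if avg_response.size == 0:
        raise ValueError("empty response")
    return float(avg_response.max() - avg_response.min())
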
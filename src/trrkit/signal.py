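"""Uniformly sampled one-dimensional signals.

A :class:`SampledSignal` couples a value array with its sampling rate, start
time and units.  Every stage of the pipeline (BOLD, pulse, respiration,
motion, pupil) passes these around instead of bare arrays so that rate
bookkeeping errors surface as exceptions rather than silent misalignment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["SampledSignal"]


@dataclass
class SampledSignal:
    """A uniformly sampled 1-D time series.

    Parameters
    ----------
    values : ndarray
        Sample values.  Coerced to a float64 array.
    rate_hz : float
        Sampling rate in Hz.  Must be positive.
    start_s : float, optional
        Time of the first sample, seconds.
    units : str, optional
        Free-form unit label (e.g. ``"psc"``, ``"a.u."``).
    """

    values: np.ndarray
    rate_hz: float
    start_s: float = 0.0
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("SampledSignal values must be 1-D")
        if not self.rate_hz > 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def dt_s(self) -> float:
        """Sampling interval in seconds."""
        return 1.0 / self.rate_hz

    @property
    def duration_s(self) -> float:
        """Total covered duration (n samples x dt)."""
        return self.values.size / self.rate_hz

    @property
    def times_s(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.start_s + np.arange(self.values.size) / self.rate_hz

    def with_values(self, values: np.ndarray) -> "SampledSignal":
        """Copy of this signal with ``values`` replaced (same rate/start/units)."""
        return replace(self, values=np.asarray(values, dtype=float))

    def slice_time(self, t0_s: float, t1_s: float) -> "SampledSignal":
        """Samples with ``t0_s <= t < t1_s`` as a new signal."""
        t = self.times_s
        mask = (t >= t0_s) & (t < t1_s)
        idx = np.nonzero(mask)[0]
        start = self.start_s if idx.size == 0 else float(t[idx[0]])
        return SampledSignal(self.values[mask], self.rate_hz, start, self.units)
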
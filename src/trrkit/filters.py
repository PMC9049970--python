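"""Rate conversion shared by the design builder and the generators."""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .signal import SampledSignal

__all__ = ["decimate"]


def decimate(signal: SampledSignal, target_rate_hz: float,
             filter_order: int = 8) -> SampledSignal:
    """Zero-phase low-pass at 0.8 x the target Nyquist, then sample selection.

    Output length is ``floor(n * target / source)``.  Raises for upsampling
    requests.
    """
    if target_rate_hz >= signal.rate_hz:
        raise ValueError("decimate requires target rate < source rate")
    cutoff = 0.8 * (target_rate_hz / 2.0)
    sos = sps.butter(filter_order, cutoff, btype="low", fs=signal.rate_hz, output="sos")
    padlen = min(3 * (2 * filter_order + 1), signal.n_samples - 1)
    low = sps.sosfiltfilt(sos, signal.values, padlen=padlen)
    n_out = int(np.floor(signal.n_samples * target_rate_hz / signal.rate_hz))
    idx = np.round(np.arange(n_out) * signal.rate_hz / target_rate_hz).astype(int)
    idx = np.clip(idx, 0, signal.n_samples - 1)
    return SampledSignal(low[idx], rate_hz=target_rate_hz,
                         start_s=signal.start_s, units=signal.units)
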
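"""Event-stream placement shared by the design builder and the BOLD
generator, so that generated responses lie exactly in the span of the
design's task regressors.
"""

from __future__ import annotations

import numpy as np

from .hrf import HRFParams, evaluate_hrf

__all__ = ["event_streams", "hrf_kernel", "convolve_stream"]


def event_streams(
    onsets_s: np.ndarray,
    rts_s: np.ndarray,
    lapse: np.ndarray,
    duration_s: float,
    rate_hz: float,
    gain_to=1.0,
    gain_bp=1.0,
    gain_tot=1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Place per-trial events on a fine grid.

    Trial-onset and button-press events are unit-area impulses (scaled by
    their gains); time-on-task is a gain-height boxcar from onset to button
    press.  Lapse trials contribute only the onset impulse.
    """
    dt = 1.0 / rate_hz
    n = int(round(duration_s * rate_hz))
    onsets_s = np.asarray(onsets_s, dtype=float)
    rts_s = np.asarray(rts_s, dtype=float)
    lapse = np.asarray(lapse, dtype=bool)
    g_to = np.broadcast_to(np.asarray(gain_to, dtype=float), onsets_s.shape)
    g_bp = np.broadcast_to(np.asarray(gain_bp, dtype=float), onsets_s.shape)
    g_tot = np.broadcast_to(np.asarray(gain_tot, dtype=float), onsets_s.shape)

    to = np.zeros(n)
    bp = np.zeros(n)
    tot = np.zeros(n)
    for i in range(onsets_s.size):
        i0 = int(round(onsets_s[i] / dt))
        if 0 <= i0 < n:
            to[i0] += g_to[i] / dt
        if lapse[i]:
            continue
        i1 = int(round((onsets_s[i] + rts_s[i]) / dt))
        if 0 <= i1 < n:
            bp[i1] += g_bp[i] / dt
        j0, j1 = max(i0, 0), min(i1, n)
        if j1 > j0:
            tot[j0:j1] += g_tot[i]
    return to, bp, tot


def hrf_kernel(params: HRFParams, rate_hz: float) -> np.ndarray:
    """HRF sampled over its support, scaled for discrete convolution."""
    dt = 1.0 / rate_hz
    tk = np.arange(0.0, params.support_s + dt, dt)
    return evaluate_hrf(params, tk) * dt


def convolve_stream(stream: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causal convolution truncated to the stream's length."""
    return np.convolve(stream, kernel)[: stream.size]
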
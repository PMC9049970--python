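"""Double-gamma hemodynamic response function: evaluation, canonical
defaults, and least-squares fitting of the six-parameter form.

The impulse response is

    h(t) = A * [ g(t; alpha1, beta1) - c * g(t; alpha2, beta2) ]

where ``g`` is a normalized gamma probability density with shape/rate
parameterization.  The six free parameters are (A, alpha1, beta1, alpha2,
beta2, c).  ``h(0) = 0`` whenever both shapes exceed 1, and the response is
truncated to zero beyond ``support_s``.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["HRFParams", "HRFFit", "evaluate_hrf", "canonical_hrf", "fit_hrf"]

#: seconds of HRF support used everywhere downstream
DEFAULT_SUPPORT_S = 32.0

#: seconds of trial-averaged response available to the fit
FIT_WINDOW_S = 16.0


@dataclass(frozen=True)
class HRFParams:
    """Six parameters of a double-gamma HRF plus its fixed support."""

    scale: float          # A, percent signal change
    shape1: float         # alpha1 (> 1)
    rate1: float          # beta1, 1/s (> 0)
    shape2: float         # alpha2 (> 1)
    rate2: float          # beta2, 1/s (> 0)
    undershoot_ratio: float  # c (>= 0)
    support_s: float = DEFAULT_SUPPORT_S

    def validate(self) -> None:
        if not (self.shape1 > 1 and self.shape2 > 1):
            raise ValueError("HRF shapes must exceed 1 so that h(0) = 0")
        if not (self.rate1 > 0 and self.rate2 > 0):
            raise ValueError("HRF rates must be positive")
        if self.undershoot_ratio < 0:
            raise ValueError("undershoot ratio must be non-negative")
        if not self.support_s > 0:
            raise ValueError("support must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "HRFParams":
        return cls(**d)


@dataclass(frozen=True)
class HRFFit:
    """Result of :func:`fit_hrf`."""

    params: HRFParams
    objective: float      # final sum of squared errors
    converged: bool
    degenerate: bool = False


def evaluate_hrf(params: HRFParams, times_s: np.ndarray) -> np.ndarray:
    """Evaluate the double-gamma HRF at the given times (seconds, >= 0)."""
    params.validate()
    t = np.asarray(times_s, dtype=float)
    if np.any(t < 0):
        raise ValueError("HRF evaluation times must be non-negative")
    pos = stats.gamma.pdf(t, a=params.shape1, scale=1.0 / params.rate1)
    neg = stats.gamma.pdf(t, a=params.shape2, scale=1.0 / params.rate2)
    h = params.scale * (pos - params.undershoot_ratio * neg)
    return np.where(t > params.support_s, 0.0, h)


def canonical_hrf() -> HRFParams:
    """Fixed default parameter set: peak near 5 s, mild late undershoot.

    The amplitude is scaled so the peak response is 1 (percent signal change
    per unit input).  Deterministic: the scale constant is frozen, not
    recomputed.
    """
    # peak of g(t;6,1) - (1/6) g(t;16,1) is 0.163541 at t ~ 5.1 s
    return HRFParams(
        scale=1.0 / 0.16354113,
        shape1=6.0,
        rate1=1.0,
        shape2=16.0,
        rate2=1.0,
        undershoot_ratio=1.0 / 6.0,
    )


def _params_to_vector(p: HRFParams) -> np.ndarray:
    # unconstrained space: shapes via log(shape - 1), rates/ratio via log
    return np.array(
        [
            p.scale,
            np.log(p.shape1 - 1.0),
            np.log(p.rate1),
            np.log(p.shape2 - 1.0),
            np.log(p.rate2),
            np.log(max(p.undershoot_ratio, 1e-8)),
        ]
    )


def _vector_to_params(x: np.ndarray, support_s: float) -> HRFParams:
    return HRFParams(
        scale=float(x[0]),
        shape1=1.0 + float(np.exp(x[1])),
        rate1=float(np.exp(x[2])),
        shape2=1.0 + float(np.exp(x[3])),
        rate2=float(np.exp(x[4])),
        undershoot_ratio=float(np.exp(x[5])),
        support_s=support_s,
    )


def fit_hrf(
    trial_avg: np.ndarray,
    tr_s: float,
    support_s: float = DEFAULT_SUPPORT_S,
    fit_window_s: float = FIT_WINDOW_S,
) -> HRFFit:
    """Least-squares fit of the six-parameter HRF to a trial-averaged response.

    Only the first ``fit_window_s`` seconds (``floor(16 / tr_s)`` samples at
    defaults) constrain the fit; the returned parameters are valid over the
    full ``support_s``-second support.  Derivative-free simplex search with a
    single restart from a perturbed start if the restart improves the
    objective.

    Parameters
    ----------
    trial_avg : array
        Trial-averaged response sampled at ``tr_s``, covering >= 16 s.
    tr_s : float
        Sampling interval of ``trial_avg`` in seconds.

    Returns
    -------
    HRFFit
        Fitted parameters, final objective, and convergence/degeneracy flags.
    """
    y = np.asarray(trial_avg, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("trial-averaged response contains non-finite values")
    n_fit = int(np.floor(fit_window_s / tr_s))
    if y.size < n_fit:
        raise ValueError(
            f"trial average must cover >= {fit_window_s} s "
            f"({n_fit} samples at tr={tr_s}); got {y.size}"
        )
    y = y[:n_fit]
    t = np.arange(n_fit) * tr_s

    peak = float(np.max(np.abs(y)))
    if peak == 0.0:
        params = HRFParams(0.0, 6.0, 1.0, 16.0, 1.0, 1.0 / 6.0, support_s)
        return HRFFit(params=params, objective=0.0, converged=True, degenerate=True)

    def objective(x: np.ndarray) -> float:
        p = _vector_to_params(x, support_s)
        resid = evaluate_hrf(p, t) - y
        return float(resid @ resid)

    x0 = _params_to_vector(canonical_hrf())
    # least-squares optimal scale given the canonical shape
    shape = evaluate_hrf(
        HRFParams(1.0, 6.0, 1.0, 16.0, 1.0, 1.0 / 6.0, support_s), t
    )
    denom = float(shape @ shape)
    x0[0] = float(shape @ y) / denom if denom > 0 else peak

    opts = {"maxiter": 20000, "maxfev": 20000, "xatol": 1e-10, "fatol": 1e-12}
    res = optimize.minimize(objective, x0, method="Nelder-Mead", options=opts)

    # perturbed restarts; keep whichever is best
    rng = np.random.default_rng(0)
    for _ in range(2):
        if res.fun < 1e-12 * peak**2:
            break
        x1 = res.x + rng.normal(scale=0.1, size=res.x.shape)
        res2 = optimize.minimize(objective, x1, method="Nelder-Mead", options=opts)
        if res2.fun < res.fun:
            res = res2

    converged = bool(res.success or res.fun < 1e-8 * peak**2)
    if not converged:
        warnings.warn("HRF fit did not converge", RuntimeWarning, stacklevel=2)
    return HRFFit(
        params=_vector_to_params(res.x, support_s),
        objective=float(res.fun),
        converged=converged,
    )
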
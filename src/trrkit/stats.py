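"""Inference: mixed-effects model with contrast F-tests, permutation tests
with finite-sample exact-p correction, the visual-field border null test,
two-stage adaptive FDR, and the RT-modulation model comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .design import DesignMatrix, TASK_LABELS
from .hrf import HRFParams, evaluate_hrf
from .synthdata import ProtocolParams

__all__ = [
    "MixedModelSpec",
    "MixedModelFit",
    "PermutationResult",
    "VisualFieldMap",
    "BorderSpec",
    "fit_mixed_model",
    "contrast_ftest",
    "permutation_test",
    "exact_p",
    "border_test",
    "two_stage_fdr",
    "rt_modulation_sim",
]

DEFAULT_RANDOM_LABELS = ("intercept",) + TASK_LABELS


@dataclass
class MixedModelSpec:
    """Fixed design + per-observer random structure.

    ``random_labels`` must be a subset of the design's columns; ``None``
    requests a plain (no-random-effects) least-squares fit.
    """

    design: DesignMatrix
    groups: np.ndarray
    random_labels: tuple | None = DEFAULT_RANDOM_LABELS
    reml: bool = True

    def __post_init__(self) -> None:
        self.groups = np.asarray(self.groups)
        if self.groups.shape[0] != self.design.n_volumes:
            raise ValueError("groups must have one entry per design row")
        if self.random_labels is not None:
            missing = [l for l in self.random_labels if l not in self.design.labels]
            if missing:
                raise ValueError(f"random-effect labels not in design: {missing}")


@dataclass
class MixedModelFit:
    """Fitted coefficients, uncertainties and diagnostics."""

    coefficients: pd.Series
    standard_errors: pd.Series
    cov_coefficients: np.ndarray
    residuals: np.ndarray
    fitted: np.ndarray
    log_likelihood: float
    r_squared: float
    df_resid: int
    random_effects: dict | None = None
    n_random_coefficients: int = 0
    variance_floored: bool = False
    labels: list[str] = field(default_factory=list)


@dataclass
class PermutationResult:
    """Observed statistic, null sample, tail and corrected exact p."""

    observed_stat: float
    null_stats: np.ndarray
    exceed_count: int
    tail: str
    p_exact: float


@dataclass
class VisualFieldMap:
    """Amplitude grid over the visual field, in degrees of visual angle."""

    amplitude: np.ndarray       # (ny, nx)
    x_extent_deg: tuple[float, float] = (-35.0, 35.0)
    y_extent_deg: tuple[float, float] = (-19.75, 19.75)

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.amplitude.ndim != 2:
            raise ValueError("amplitude map must be 2-D")

    @property
    def pixel_size_deg(self) -> tuple[float, float]:
        ny, nx = self.amplitude.shape
        return (
            (self.x_extent_deg[1] - self.x_extent_deg[0]) / nx,
            (self.y_extent_deg[1] - self.y_extent_deg[0]) / ny,
        )

    @property
    def width_deg(self) -> float:
        return self.x_extent_deg[1] - self.x_extent_deg[0]

    @property
    def height_deg(self) -> float:
        return self.y_extent_deg[1] - self.y_extent_deg[0]


@dataclass(frozen=True)
class BorderSpec:
    """Rectangular-border geometry for the screen-edge artifact test."""

    thickness_deg: float = 7.2
    n_draws: int = 100_000

    def validate(self, vmap: VisualFieldMap) -> None:
        if not 0 < self.thickness_deg <= min(vmap.width_deg, vmap.height_deg) / 2:
            raise ValueError("border thickness must fit inside the field extent")


def fit_mixed_model(spec: MixedModelSpec, response: np.ndarray) -> MixedModelFit:
    """Fit the (mixed) linear model via statsmodels MixedLM.

    With ``random_labels=None`` (or a single group) this reduces exactly to
    ordinary least squares.  A singular random-effects covariance triggers a
    variance floor and the ``variance_floored`` flag.
    """
    y = np.asarray(getattr(response, "values", response), dtype=float)
    X = spec.design.matrix
    labels = list(spec.design.labels)
    if y.shape[0] != X.shape[0]:
        raise ValueError("response length must equal design rows")

    if spec.random_labels is None or len(np.unique(spec.groups)) < 2:
        return _fit_ols(X, y, labels)

    import statsmodels.api as sm

    re_idx = [labels.index(l) for l in spec.random_labels]
    exog_re = X[:, re_idx]
    model = sm.MixedLM(y, X, groups=spec.groups, exog_re=exog_re)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=spec.reml, method=["lbfgs", "bfgs"])

    k = X.shape[1]
    cov = np.asarray(result.cov_params())[:k, :k]
    cov_re = np.asarray(result.cov_re)
    floored = False
    eig = np.linalg.eigvalsh(np.atleast_2d(cov_re))
    if np.any(eig < 1e-10):
        # singular RE covariance: floor it so BLUP prediction stays defined
        floored = True
        result.cov_re = cov_re + (1e-8 - min(float(eig.min()), 0.0)) * np.eye(
            np.atleast_2d(cov_re).shape[0]
        )
        warnings.warn("singular random-effects covariance; variance floored",
                      RuntimeWarning, stacklevel=2)
    try:
        random_effects = {g: np.asarray(v) for g, v in result.random_effects.items()}
        fitted = np.asarray(result.fittedvalues)
    except (ValueError, np.linalg.LinAlgError):
        random_effects = None
        fitted = X @ np.asarray(result.fe_params)
    resid = y - fitted
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    n_groups = len(np.unique(spec.groups))
    return MixedModelFit(
        coefficients=pd.Series(result.fe_params, index=labels),
        standard_errors=pd.Series(
            np.sqrt(np.clip(np.diag(cov), 0.0, None)), index=labels
        ),
        cov_coefficients=cov,
        residuals=resid,
        fitted=fitted,
        log_likelihood=float(result.llf),
        r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan,
        df_resid=y.shape[0] - k,
        random_effects=random_effects,
        n_random_coefficients=n_groups * len(re_idx),
        variance_floored=floored,
        labels=labels,
    )


def _fit_ols(X: np.ndarray, y: np.ndarray, labels: list[str]) -> MixedModelFit:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    n, k = X.shape
    df = n - k
    sigma2 = float(resid @ resid) / df if df > 0 else np.nan
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    llf = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1) if sigma2 > 0 else np.nan
    return MixedModelFit(
        coefficients=pd.Series(beta, index=labels),
        standard_errors=pd.Series(np.sqrt(np.diag(cov)), index=labels),
        cov_coefficients=cov,
        residuals=resid,
        fitted=fitted,
        log_likelihood=float(llf),
        r_squared=1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else np.nan,
        df_resid=df,
        labels=labels,
    )


def contrast_ftest(fit: MixedModelFit, contrast: np.ndarray) -> tuple[float, float]:
    """Wald-type F test of H0: L beta = 0.

    The numerator df is the row rank of L; the denominator df is the
    residual-based approximation n - p.
    """
    L = np.atleast_2d(np.asarray(contrast, dtype=float))
    k = len(fit.coefficients)
    if L.shape[1] != k:
        raise ValueError(f"contrast has {L.shape[1]} columns, model has {k}")
    if not np.any(L):
        raise ValueError("contrast matrix is all zero")
    r = int(np.linalg.matrix_rank(L))
    lb = L @ fit.coefficients.to_numpy()
    mid = np.linalg.pinv(L @ fit.cov_coefficients @ L.T)
    F = float(lb @ mid @ lb) / r
    p = float(spstats.f.sf(F, r, fit.df_resid))
    return F, p


def contrast_vector(fit: MixedModelFit, weights: dict) -> np.ndarray:
    """Build a single contrast row from a {label: weight} mapping."""
    v = np.zeros(len(fit.labels))
    for lbl, w in weights.items():
        v[fit.labels.index(lbl)] = w
    return v


def exact_p(b: int, m: int) -> float:
    """Finite-permutation corrected exact p-value (b + 1) / (m + 1)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 <= b <= m:
        raise ValueError("exceedance count must satisfy 0 <= b <= m")
    return (b + 1) / (m + 1)


def permutation_test(
    values: np.ndarray,
    labels: np.ndarray,
    m: int = 10_000,
    tail: str = "right",
    seed: int | None = None,
    group_order: tuple | None = None,
) -> PermutationResult:
    """Two-group difference-of-means permutation test with exact-p correction.

    The observed statistic is mean(group B) - mean(group A) where (A, B) is
    ``group_order`` (default: sorted unique labels).  Labels are shuffled
    ``m`` times; ties count toward the exceedance count (conservative).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if tail not in ("right", "left"):
        raise ValueError("tail must be 'right' or 'left'")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = list(group_order) if group_order is not None else sorted(set(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError("labels must define exactly two groups")
    mask_b = labels == uniq[1]
    mask_a = labels == uniq[0]
    if not (mask_a.any() and mask_b.any()):
        raise ValueError("both groups must be nonempty")
    observed = float(values[mask_b].mean() - values[mask_a].mean())

    rng = np.random.default_rng(seed)
    n = values.size
    nb = int(mask_b.sum())
    null = np.empty(m)
    chunk = max(1, min(m, int(5e6 // max(n, 1))))
    done = 0
    while done < m:
        c = min(chunk, m - done)
        keys = rng.random((c, n))
        order = np.argsort(keys, axis=1)
        shuffled = values[order]
        null[done : done + c] = (
            shuffled[:, :nb].mean(axis=1) - shuffled[:, nb:].mean(axis=1)
        )
        done += c
    b = int(np.sum(null >= observed)) if tail == "right" else int(np.sum(null <= observed))
    return PermutationResult(
        observed_stat=observed,
        null_stats=null,
        exceed_count=b,
        tail=tail,
        p_exact=exact_p(b, m),
    )


def _border_band_sum(ps: np.ndarray, pc: np.ndarray, xs: np.ndarray, ys: np.ndarray,
                     cx: float, cy: float, w: float, h: float, t: float) -> tuple[float, int]:
    """Sum and pixel count of the band via prefix-sum rectangle queries."""

    def rect(x0, x1, y0, y1):
        i0 = int(np.searchsorted(ys, y0, side="left"))
        i1 = int(np.searchsorted(ys, y1, side="right"))
        j0 = int(np.searchsorted(xs, x0, side="left"))
        j1 = int(np.searchsorted(xs, x1, side="right"))
        i0, i1 = max(i0, 0), min(i1, ys.size)
        j0, j1 = max(j0, 0), min(j1, xs.size)
        if i1 <= i0 or j1 <= j0:
            return 0.0, 0
        s = ps[i1, j1] - ps[i0, j1] - ps[i1, j0] + ps[i0, j0]
        c = pc[i1, j1] - pc[i0, j1] - pc[i1, j0] + pc[i0, j0]
        return float(s), int(c)

    s_out, c_out = rect(cx - w / 2, cx + w / 2, cy - h / 2, cy + h / 2)
    s_in, c_in = rect(cx - w / 2 + t, cx + w / 2 - t, cy - h / 2 + t, cy + h / 2 - t)
    return s_out - s_in, c_out - c_in


def border_test(vmap: VisualFieldMap, spec: BorderSpec | None = None,
                seed: int | None = None) -> PermutationResult:
    """Screen-edge band amplitude vs randomly centered same-size bands.

    The observed statistic is the mean amplitude in a band of the given
    thickness hugging the screen-edge rectangle.  Null bands share its
    dimensions but are centered uniformly at random within the field extent;
    pixels falling outside the extent are excluded.  Right-tailed, with the
    exact-p correction and ties counting as exceedances.
    """
    spec = spec or BorderSpec()
    spec.validate(vmap)
    ny, nx = vmap.amplitude.shape
    px, py = vmap.pixel_size_deg
    xs = vmap.x_extent_deg[0] + (np.arange(nx) + 0.5) * px
    ys = vmap.y_extent_deg[0] + (np.arange(ny) + 0.5) * py
    ps = np.zeros((ny + 1, nx + 1))
    ps[1:, 1:] = np.cumsum(np.cumsum(vmap.amplitude, axis=0), axis=1)
    pc = np.zeros((ny + 1, nx + 1), dtype=np.int64)
    pc[1:, 1:] = np.cumsum(
        np.cumsum(np.ones_like(vmap.amplitude, dtype=np.int64), axis=0), axis=1
    )

    w, h, t = vmap.width_deg, vmap.height_deg, spec.thickness_deg
    cx0 = 0.5 * (vmap.x_extent_deg[0] + vmap.x_extent_deg[1])
    cy0 = 0.5 * (vmap.y_extent_deg[0] + vmap.y_extent_deg[1])
    s_obs, c_obs = _border_band_sum(ps, pc, xs, ys, cx0, cy0, w, h, t)
    if c_obs == 0:
        raise ValueError("observed border contains no pixels")
    observed = s_obs / c_obs

    rng = np.random.default_rng(seed)
    null = np.empty(spec.n_draws)
    i = 0
    while i < spec.n_draws:
        cx = rng.uniform(*vmap.x_extent_deg)
        cy = rng.uniform(*vmap.y_extent_deg)
        s, c = _border_band_sum(ps, pc, xs, ys, cx, cy, w, h, t)
        if c == 0:
            continue  # band entirely off-field: resample
        null[i] = s / c
        i += 1
    # prefix-sum rounding: count ties up to a relative tolerance
    tol = 1e-9 * (abs(observed) + 1.0)
    b = int(np.sum(null >= observed - tol))
    return PermutationResult(
        observed_stat=observed,
        null_stats=null,
        exceed_count=b,
        tail="right",
        p_exact=exact_p(b, spec.n_draws),
    )


def _bh_rejections(pvals: np.ndarray, q: float) -> int:
    """Number of rejections of the Benjamini-Hochberg linear step-up at q."""
    m = pvals.size
    order = np.sort(pvals)
    below = order <= q * np.arange(1, m + 1) / m
    return int(np.max(np.nonzero(below)[0]) + 1) if below.any() else 0


def two_stage_fdr(pvals: np.ndarray, alpha: float = 0.05) -> tuple[float, np.ndarray]:
    """Two-stage adaptive linear step-up FDR control.

    Stage 1 runs the step-up at q' = alpha / (1 + alpha) to estimate the
    number of true nulls m0; stage 2 reruns it at q' * m / m0.  Returns the
    effective critical p-value and per-test rejection flags.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((pvals <= 0) | (pvals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = pvals.size
    q1 = alpha / (1.0 + alpha)
    r1 = _bh_rejections(pvals, q1)
    if r1 == 0:
        return 0.0, np.zeros(m, dtype=bool)
    if r1 == m:
        return 1.0, np.ones(m, dtype=bool)
    q2 = q1 * m / (m - r1)
    k = _bh_rejections(pvals, q2)
    critical = k * q2 / m if k > 0 else 0.0
    return float(critical), pvals <= critical + 1e-15


def rt_modulation_sim(
    behavior: pd.DataFrame,
    hrf: HRFParams,
    protocol: ProtocolParams | None = None,
    working_rate_hz: float = 50.0,
) -> dict:
    """Predicted response amplitudes under three input models, split by RT.

    For each response trial the canonical HRF is convolved with the trial's
    onset impulse, button-press impulse and time-on-task boxcar.  Within each
    difficulty x accuracy cell, trials are median-split into fast/slow RT
    halves and the averaged predicted time course's amplitude (max - min) is
    reported for three variants: 'ToT', 'TO+BP' and 'all'.
    """
    protocol = protocol or ProtocolParams()
    dt = 1.0 / working_rate_hz
    win = protocol.trial_duration_s
    n = int(round(win / dt))
    tk = np.arange(0.0, hrf.support_s + dt, dt)
    kernel = evaluate_hrf(hrf, tk) * dt

    resp = behavior[behavior["response"] != "none"].copy()
    if resp["rt_s"].isna().any():
        raise ValueError("response trials must carry RTs")

    def trial_courses(rt: float) -> dict[str, np.ndarray]:
        to = np.zeros(n)
        bp = np.zeros(n)
        tot = np.zeros(n)
        to[0] = 1.0 / dt
        i1 = min(int(round(rt / dt)), n - 1)
        bp[i1] += 1.0 / dt
        tot[:i1] += 1.0
        c_to = np.convolve(to, kernel)[:n]
        c_bp = np.convolve(bp, kernel)[:n]
        c_tot = np.convolve(tot, kernel)[:n]
        return {"ToT": c_tot, "TO+BP": c_to + c_bp, "all": c_to + c_bp + c_tot}

    out: dict[str, dict] = {v: {} for v in ("ToT", "TO+BP", "all")}
    for (diff, corr), cell in resp.groupby(["difficulty", "correct"]):
        if len(cell) < 2:
            continue
        med = cell["rt_s"].median()
        for speed, sub in (("fast", cell[cell["rt_s"] <= med]),
                           ("slow", cell[cell["rt_s"] > med])):
            if len(sub) == 0:
                continue
            acc = {v: np.zeros(n) for v in out}
            for rt in sub["rt_s"]:
                courses = trial_courses(float(rt))
                for v in out:
                    acc[v] += courses[v]
            for v in out:
                mean_tc = acc[v] / len(sub)
                out[v][(diff, int(corr), speed)] = float(mean_tc.max() - mean_tc.min())
    return out
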
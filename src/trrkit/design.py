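"""Fixed-effects design construction.

Three HRF-convolved task inputs (trial-onset and button-press impulses,
time-on-task boxcar), run-level difficulty and trial-level accuracy
indicators, predicted-BOLD physiological regressors, six motion columns,
and the full factorial interaction set, all decimated to the TR grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .events import convolve_stream, event_streams, hrf_kernel
from .filters import decimate
from .hrf import HRFParams
from .signal import SampledSignal
from .synthdata import ProtocolParams, _global_onsets

__all__ = [
    "TaskRegressors",
    "ResponseFunctionSpec",
    "DesignMatrix",
    "cardiac_response_spec",
    "respiration_response_spec",
    "build_task_regressors",
    "build_physio_predictors",
    "build_condition_regressors",
    "assemble_design",
    "decimate",
]

TASK_LABELS = ("fMRI_TO", "fMRI_BP", "fMRI_ToT")
MOTION_LABELS = ("motion_roll", "motion_pitch", "motion_yaw",
                 "motion_x", "motion_y", "motion_z")


@dataclass
class TaskRegressors:
    """The three HRF-convolved task input time courses at the working rate."""

    fmri_to: np.ndarray
    fmri_bp: np.ndarray
    fmri_tot: np.ndarray
    working_rate_hz: float

    def columns(self) -> list[np.ndarray]:
        return [self.fmri_to, self.fmri_bp, self.fmri_tot]


@dataclass(frozen=True)
class ResponseFunctionSpec:
    """A canonical physiological response kernel (cardiac or respiration)."""

    kind: str                      # "cardiac" | "respiration"
    coefficients: dict = field(default_factory=dict)
    support_s: float = 60.0

    def kernel(self, rate_hz: float) -> np.ndarray:
        """Kernel sampled at the raw physiological rate."""
        t = np.arange(0.0, self.support_s, 1.0 / rate_hz)
        c = self.coefficients
        if self.kind == "respiration":
            # Birn et al. (2008) respiration response function
            return (c["a1"] * t ** c["p1"] * np.exp(-t / c["tau1"])
                    - c["a2"] * t ** c["p2"] * np.exp(-t / c["tau2"]))
        if self.kind == "cardiac":
            # Chang et al. (2009) cardiac response function
            return (c["a1"] * t ** c["p1"] * np.exp(-t / c["tau1"])
                    - c["a2"] * np.exp(-((t - c["mu"]) ** 2) / (2 * c["sigma"] ** 2)))
        raise ValueError(f"unknown response-function kind: {self.kind!r}")


def respiration_response_spec() -> ResponseFunctionSpec:
    return ResponseFunctionSpec(
        kind="respiration",
        coefficients={"a1": 0.6, "p1": 2.1, "tau1": 1.6,
                      "a2": 0.0023, "p2": 3.54, "tau2": 4.25},
    )


def cardiac_response_spec() -> ResponseFunctionSpec:
    return ResponseFunctionSpec(
        kind="cardiac",
        coefficients={"a1": 0.6, "p1": 2.7, "tau1": 1.6,
                      "a2": 16.0 / np.sqrt(2 * np.pi * 9.0), "mu": 12.0, "sigma": 3.0},
    )


@dataclass
class DesignMatrix:
    """Volume-by-predictor matrix with labeled columns at TR resolution."""

    matrix: np.ndarray
    labels: list[str]
    tr_s: float
    rank_deficient: bool = False
    collinear_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        if self.matrix.shape[1] != len(self.labels):
            raise ValueError("label count must match column count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("column labels must be unique")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("design matrix contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def column(self, label: str) -> np.ndarray:
        return self.matrix[:, self.labels.index(label)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.labels)


def build_task_regressors(
    behavior: pd.DataFrame,
    hrf: HRFParams,
    protocol: ProtocolParams,
    working_rate_hz: float = 10.0,
) -> TaskRegressors:
    """Place impulses/boxcars for every trial and convolve each with the HRF.

    Trial-onset (TO) and button-press (BP) events are unit-area impulses;
    time-on-task (ToT) is a unit-height boxcar from onset to button press.
    Lapse trials contribute a TO impulse only.
    """
    if working_rate_hz < 10.0:
        raise ValueError("working rate must be >= 10 Hz for RT resolution")
    onsets = _global_onsets(behavior, protocol)
    lapse = (behavior["response"] == "none").to_numpy()
    rts = behavior["rt_s"].to_numpy()
    if np.any(rts[~lapse] > protocol.isi_s + 1e-9):
        raise ValueError("button press outside the interstimulus interval")

    to, bp, tot = event_streams(
        onsets, rts, lapse, protocol.session_duration_s, working_rate_hz
    )
    kernel = hrf_kernel(hrf, working_rate_hz)
    return TaskRegressors(
        convolve_stream(to, kernel),
        convolve_stream(bp, kernel),
        convolve_stream(tot, kernel),
        working_rate_hz,
    )


def build_physio_predictors(
    pulse: SampledSignal,
    respiration: SampledSignal,
    tr_s: float,
    cardiac_spec: ResponseFunctionSpec | None = None,
    respiration_spec: ResponseFunctionSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted-BOLD cardiac and respiration columns at the TR rate.

    Convolution happens at the raw physiological sampling rate; only the
    result is anti-alias filtered and decimated to ``1/tr_s``.
    """
    cardiac_spec = cardiac_spec or cardiac_response_spec()
    respiration_spec = respiration_spec or respiration_response_spec()
    if cardiac_spec.kind != "cardiac" or respiration_spec.kind != "respiration":
        raise ValueError("response-function specs passed in the wrong order")

    cols = []
    for sig, spec in ((pulse, cardiac_spec), (respiration, respiration_spec)):
        k = spec.kernel(sig.rate_hz) / sig.rate_hz
        conv = sps.fftconvolve(sig.values, k)[: sig.n_samples]
        at_tr = decimate(SampledSignal(conv, sig.rate_hz, sig.start_s), 1.0 / tr_s)
        cols.append(at_tr.values)
    return cols[0], cols[1]


def build_condition_regressors(
    behavior: pd.DataFrame,
    n_volumes: int,
    tr_s: float,
    protocol: ProtocolParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Difficulty (per-run constant) and accuracy (per-trial) indicator columns.

    Returns ``(difficulty, accuracy, lapse_flag)``; hard = 1, incorrect = 1,
    lapse-trial windows are 0 in the accuracy column and 1 in the flag.
    """
    difficulty = np.zeros(n_volumes)
    accuracy = np.zeros(n_volumes)
    lapse_flag = np.zeros(n_volumes)
    onsets = _global_onsets(behavior, protocol)
    samples_per_trial = int(round(protocol.trial_duration_s / tr_s))
    for i, row in enumerate(behavior.itertuples(index=False)):
        v0 = int(round(onsets[i] / tr_s))
        v1 = min(v0 + samples_per_trial, n_volumes)
        if row.difficulty == "hard":
            difficulty[v0:v1] = 1.0
        if row.response == "none":
            lapse_flag[v0:v1] = 1.0
        elif row.correct == 0:
            accuracy[v0:v1] = 1.0
    return difficulty, accuracy, lapse_flag


def assemble_design(
    task: TaskRegressors,
    tr_s: float,
    difficulty: np.ndarray | None = None,
    accuracy: np.ndarray | None = None,
    cardiac: np.ndarray | None = None,
    respiration: np.ndarray | None = None,
    motion: list | None = None,
    n_volumes: int | None = None,
) -> DesignMatrix:
    """Assemble the full fixed-effects matrix.

    With every group present, the column count is 24: intercept, three task
    regressors, difficulty, accuracy, cardiac, respiration, six motion
    columns, and the ten factorial interaction products (task x difficulty,
    task x accuracy, difficulty x accuracy, task x difficulty x accuracy).
    """
    rate = task.working_rate_hz
    target = 1.0 / tr_s
    task_cols = [
        decimate(SampledSignal(c, rate), target).values for c in task.columns()
    ]
    if n_volumes is None:
        n_volumes = len(task_cols[0])

    def _fit(col: np.ndarray, what: str) -> np.ndarray:
        col = np.asarray(col, dtype=float)
        if abs(len(col) - n_volumes) > 1:
            raise ValueError(
                f"{what} has {len(col)} volumes, design needs {n_volumes}"
            )
        if len(col) < n_volumes:
            col = np.pad(col, (0, n_volumes - len(col)), mode="edge")
        return col[:n_volumes]

    task_cols = [_fit(c, lbl) for c, lbl in zip(task_cols, TASK_LABELS)]
    columns: list[np.ndarray] = [np.ones(n_volumes)]
    labels: list[str] = ["intercept"]
    for c, lbl in zip(task_cols, TASK_LABELS):
        columns.append(c)
        labels.append(lbl)
    if difficulty is not None:
        columns.append(_fit(difficulty, "difficulty"))
        labels.append("difficulty")
    if accuracy is not None:
        columns.append(_fit(accuracy, "accuracy"))
        labels.append("accuracy")
    if cardiac is not None:
        columns.append(_fit(cardiac, "cardiac"))
        labels.append("cardiac")
    if respiration is not None:
        columns.append(_fit(respiration, "respiration"))
        labels.append("respiration")
    if motion is not None:
        if len(motion) != 6:
            raise ValueError("motion must supply exactly six columns")
        for m, lbl in zip(motion, MOTION_LABELS):
            vals = m.values if isinstance(m, SampledSignal) else m
            columns.append(_fit(vals, lbl))
            labels.append(lbl)

    # factorial interactions: elementwise products
    def _add_interaction(lbls: tuple[str, ...]) -> None:
        prod = np.ones(n_volumes)
        for l in lbls:
            prod = prod * columns[labels.index(l)]
        columns.append(prod)
        labels.append(":".join(lbls))

    if difficulty is not None:
        for lbl in TASK_LABELS:
            _add_interaction((lbl, "difficulty"))
    if accuracy is not None:
        for lbl in TASK_LABELS:
            _add_interaction((lbl, "accuracy"))
    if difficulty is not None and accuracy is not None:
        _add_interaction(("difficulty", "accuracy"))
        for lbl in TASK_LABELS:
            _add_interaction((lbl, "difficulty", "accuracy"))

    X = np.column_stack(columns)
    dm = DesignMatrix(X, labels, tr_s)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # report columns whose removal restores full rank
        bad = []
        for j in range(X.shape[1]):
            keep = [k for k in range(X.shape[1]) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                bad.append(labels[j])
        dm.rank_deficient = True
        dm.collinear_labels = bad
        warnings.warn(
            f"design matrix is rank deficient; collinear columns: {bad}",
            RuntimeWarning,
            stacklevel=2,
        )
    return dm
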
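"""Synthetic session generator.

Produces behavioral trial tables, per-trial ground-truth modulation
parameters, and all raw signal streams (ROI BOLD, pulse oximeter,
respiration belt, head motion, pupil/gaze) with the statistical structure
the downstream analysis assumes.  Everything is bit-reproducible given
(parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal as sps, stats as spstats

from .events import convolve_stream, event_streams, hrf_kernel
from .filters import decimate
from .hrf import HRFParams, canonical_hrf
from .signal import SampledSignal

__all__ = [
    "ProtocolParams",
    "StaircaseSpec",
    "ObserverModel",
    "GenParams",
    "GroundTruth",
    "pupil_protocol",
    "percent_correct",
    "run_staircase",
    "simulate_behavior",
    "simulate_session",
    "simulate_bold",
    "simulate_physio",
    "simulate_motion",
    "simulate_pupil",
]

BEHAVIOR_COLUMNS = [
    "observer_id",
    "run_id",
    "trial_index",
    "onset_s",
    "difficulty",
    "tilt_deg",
    "response",
    "correct",
    "rt_s",
]


@dataclass(frozen=True)
class ProtocolParams:
    """Trial/run timing of the task protocol."""

    trial_duration_s: float = 15.0
    stim_duration_s: float = 0.2
    isi_s: float = 14.8
    trials_per_run: int = 16
    run_duration_s: float = 240.0
    tr_s: float = 1.5
    task_freq_hz: float = 1.0 / 15.0
    n_runs: int = 2
    difficulty_schedule: tuple = ("easy", "hard")
    pupil_isi_s: float = 3.8

    def __post_init__(self) -> None:
        if not np.isclose(self.trial_duration_s, self.stim_duration_s + self.isi_s):
            raise ValueError("trial_duration_s must equal stim_duration_s + isi_s")
        if not np.isclose(self.run_duration_s, self.trials_per_run * self.trial_duration_s):
            raise ValueError("run_duration_s must equal trials_per_run * trial_duration_s")
        if not np.isclose(self.task_freq_hz * self.trial_duration_s, 1.0):
            raise ValueError("task_freq_hz must be the inverse of trial_duration_s")
        if len(self.difficulty_schedule) != self.n_runs:
            raise ValueError("difficulty_schedule must have n_runs entries")
        if any(d not in ("easy", "hard") for d in self.difficulty_schedule):
            raise ValueError("difficulty_schedule entries must be 'easy' or 'hard'")

    @property
    def volumes_per_run(self) -> int:
        return int(round(self.run_duration_s / self.tr_s))

    @property
    def n_volumes(self) -> int:
        return self.n_runs * self.volumes_per_run

    @property
    def session_duration_s(self) -> float:
        return self.n_runs * self.run_duration_s


def pupil_protocol(n_runs: int = 2, trials_per_run: int = 16,
                   difficulty_schedule: tuple | None = None) -> ProtocolParams:
    """Protocol variant for the pupillometry sessions (short 3.8-s ISI)."""
    if difficulty_schedule is None:
        difficulty_schedule = tuple(
            "easy" if i % 2 == 0 else "hard" for i in range(n_runs)
        )
    trial = 0.2 + 3.8
    return ProtocolParams(
        trial_duration_s=trial,
        stim_duration_s=0.2,
        isi_s=3.8,
        trials_per_run=trials_per_run,
        run_duration_s=trials_per_run * trial,
        tr_s=1.5,
        task_freq_hz=1.0 / trial,
        n_runs=n_runs,
        difficulty_schedule=difficulty_schedule,
    )


@dataclass(frozen=True)
class StaircaseSpec:
    """One-up, two-down adaptive staircase over tilt magnitude."""

    n_up: int = 1
    n_down: int = 2
    step_deg: float = 0.4
    initial_tilt_deg: float = 8.0
    min_tilt_deg: float = 0.2
    max_tilt_deg: float = 20.0

    def __post_init__(self) -> None:
        if self.step_deg <= 0:
            raise ValueError("step_deg must be positive")
        if not (0 < self.min_tilt_deg <= self.initial_tilt_deg <= self.max_tilt_deg):
            raise ValueError("need 0 < min_tilt <= initial_tilt <= max_tilt")
        if (self.n_up, self.n_down) != (1, 2):
            raise ValueError("protocol requires a one-up, two-down staircase")


@dataclass(frozen=True)
class ObserverModel:
    """Stochastic stand-in for a human observer.

    ``percent_correct`` maps |tilt| through a cumulative-Gaussian curve with
    range [0.5, 1 - asymptotic_error]; response times are log-normal with an
    additive per-condition shift on the log scale, truncated to (0, isi].
    """

    psychometric_slope: float = 3.0        # degrees
    asymptotic_error: float = 0.10         # easy (20 deg) accuracy ~ 90%
    lapse_prob_easy: float = 0.0668        # matches reported easy lapse rate
    lapse_prob_hard: float = 0.0448
    rt_log_mean: float = float(np.log(0.55))   # median RT ~ 0.55 s
    rt_log_sd: float = 0.45
    rt_condition_shifts: dict = field(
        default_factory=lambda: {"easy": -0.10, "hard": 0.15}
    )

    def __post_init__(self) -> None:
        for p in (self.asymptotic_error, self.lapse_prob_easy, self.lapse_prob_hard):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    def lapse_prob(self, difficulty: str) -> float:
        return self.lapse_prob_easy if difficulty == "easy" else self.lapse_prob_hard


def percent_correct(observer: ObserverModel, tilt_deg: float) -> float:
    """P(correct) at a given signed tilt; monotone increasing in |tilt|."""
    z = abs(tilt_deg) / observer.psychometric_slope
    # 2*Phi(z) - 1 runs from 0 at tilt 0 to 1 at large tilt
    return 0.5 + (0.5 - observer.asymptotic_error) * (2.0 * spstats.norm.cdf(z) - 1.0)


@dataclass(frozen=True)
class GenParams:
    """Free parameters of the generative model (documented defaults).

    Gain rules are multiplicative on a base of 1: hard runs and errors raise
    the response gain, lapses raise it most.  Jitter spread is largest for
    easy-correct and smallest for easy-incorrect trials.  Arousal gains feed
    the physiological and pupil generators (incorrect > correct, easy
    incorrect and lapses largest).
    """

    difficulty_gain: float = 1.3
    error_gain: float = 1.4
    lapse_gain: float = 2.0
    jitter_sd_by_condition: dict = field(default_factory=lambda: {
        ("easy", 1): 1.0,
        ("hard", 1): 0.7,
        ("hard", 0): 0.5,
        ("easy", 0): 0.3,
        "lapse": 0.8,
    })
    arousal_gain_by_condition: dict = field(default_factory=lambda: {
        ("easy", 1): 1.0,
        ("hard", 1): 1.10,
        ("hard", 0): 1.20,
        ("easy", 0): 1.30,
        "lapse": 1.30,
    })
    noise_sd: float = 0.20            # white noise, percent signal change
    drift_sd: float = 0.10            # AR(1) slow drift innovation scale
    drift_ar: float = 0.95
    global_coupling: float = 0.3
    physio_coupling: float = 0.1
    base_response_gain: float = 1.0


def null_gen_params(noise_sd: float = 0.2, jitter_sd: float = 0.0,
                    drift_sd: float = 0.0) -> GenParams:
    """Generator parameters with every condition modulation disabled.

    Unit response gains, condition-independent jitter and arousal: every
    per-condition summary downstream should be equal up to sampling error.
    """
    conds = [("easy", 1), ("hard", 1), ("hard", 0), ("easy", 0), "lapse"]
    return GenParams(
        difficulty_gain=1.0,
        error_gain=1.0,
        lapse_gain=1.0,
        jitter_sd_by_condition={c: jitter_sd for c in conds},
        arousal_gain_by_condition={c: 1.0 for c in conds},
        noise_sd=noise_sd,
        drift_sd=drift_sd,
    )


@dataclass
class GroundTruth:
    """Per-trial generative parameters aligned row-for-row with a behavior table."""

    gain_to: np.ndarray
    gain_bp: np.ndarray
    gain_tot: np.ndarray
    jitter_s: np.ndarray
    arousal_gain: np.ndarray
    gen: GenParams
    hrf_params_true: HRFParams

    def __post_init__(self) -> None:
        n = len(self.gain_to)
        for name in ("gain_bp", "gain_tot", "jitter_s", "arousal_gain"):
            if len(getattr(self, name)) != n:
                raise ValueError("ground-truth arrays must share one length")
        if np.any(self.gain_to <= 0) or np.any(self.gain_bp <= 0) or np.any(self.gain_tot <= 0):
            raise ValueError("gains must be positive")

    @property
    def n_trials(self) -> int:
        return len(self.gain_to)

    def to_dict(self) -> dict:
        return {
            "gain_to": self.gain_to.tolist(),
            "gain_bp": self.gain_bp.tolist(),
            "gain_tot": self.gain_tot.tolist(),
            "jitter_s": self.jitter_s.tolist(),
            "arousal_gain": self.arousal_gain.tolist(),
            "hrf_params_true": self.hrf_params_true.to_dict(),
        }


class _Staircase:
    """Stateful one-up, two-down tracker (state persists across runs)."""

    def __init__(self, spec: StaircaseSpec):
        self.spec = spec
        self.tilt = spec.initial_tilt_deg
        self._n_correct = 0

    def update(self, correct: bool) -> None:
        s = self.spec
        if correct:
            self._n_correct += 1
            if self._n_correct >= s.n_down:
                self.tilt = max(s.min_tilt_deg, self.tilt - s.step_deg)
                self._n_correct = 0
        else:
            self.tilt = min(s.max_tilt_deg, self.tilt + s.step_deg)
            self._n_correct = 0


def run_staircase(spec: StaircaseSpec, observer: ObserverModel,
                  n_trials: int, seed: int) -> list[dict]:
    """Simulate a bare staircase: per-trial tilt and correctness.

    The tilt decreases one step after two consecutive correct responses and
    increases one step after any incorrect response, clamped to
    [min_tilt, max_tilt].  Asymptotic accuracy converges to sqrt(1/2) ~ 70.7%
    for any monotone psychometric observer.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    sc = _Staircase(spec)
    out = []
    for _ in range(n_trials):
        tilt = sc.tilt
        correct = bool(rng.random() < percent_correct(observer, tilt))
        out.append({"tilt_deg": tilt, "correct": correct})
        sc.update(correct)
    return out


def _sample_rt(rng: np.random.Generator, observer: ObserverModel,
               difficulty: str, isi_s: float) -> float:
    shift = observer.rt_condition_shifts.get(difficulty, 0.0)
    for _ in range(1000):
        rt = float(np.exp(rng.normal(observer.rt_log_mean + shift, observer.rt_log_sd)))
        if 0.0 < rt <= isi_s:
            return rt
    return min(isi_s, 0.55)  # pathological parameters; clamp


def _condition_key(difficulty: str, correct, lapse: bool):
    return "lapse" if lapse else (difficulty, int(correct))


def simulate_behavior(
    protocol: ProtocolParams,
    observer: ObserverModel,
    staircase: StaircaseSpec,
    seed: int,
    gen: GenParams | None = None,
    observer_id: str = "obs01",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a full session's trial table plus aligned ground truth.

    Easy trials use a fixed +/-20 deg tilt; hard trials follow the staircase
    (state carried across hard runs, no update on lapses).  Lapses are
    inserted per the observer's per-difficulty lapse probabilities; response
    trials get truncated log-normal RTs.
    """
    if len(protocol.difficulty_schedule) == 0:
        raise ValueError("difficulty_schedule must be nonempty")
    gen = gen or GenParams()
    rng = np.random.default_rng(seed)
    sc = _Staircase(staircase)

    rows = []
    gain, jitter, arousal = [], [], []
    for run_idx, difficulty in enumerate(protocol.difficulty_schedule):
        for trial in range(protocol.trials_per_run):
            onset = trial * protocol.trial_duration_s
            if difficulty == "easy":
                tilt = 20.0 * (1 if rng.random() < 0.5 else -1)
            else:
                tilt = sc.tilt * (1 if rng.random() < 0.5 else -1)
            lapse = rng.random() < observer.lapse_prob(difficulty)
            if lapse:
                response, correct, rt = "none", np.nan, np.nan
            else:
                correct = int(rng.random() < percent_correct(observer, tilt))
                truth_resp = "cw" if tilt > 0 else "ccw"
                wrong_resp = "ccw" if tilt > 0 else "cw"
                response = truth_resp if correct else wrong_resp
                rt = _sample_rt(rng, observer, difficulty, protocol.isi_s)
                if difficulty == "hard":
                    sc.update(bool(correct))
            rows.append({
                "observer_id": observer_id,
                "run_id": run_idx,
                "trial_index": trial,
                "onset_s": onset,
                "difficulty": difficulty,
                "tilt_deg": tilt,
                "response": response,
                "correct": correct,
                "rt_s": rt,
            })
            key = _condition_key(difficulty, correct, lapse)
            g = gen.base_response_gain
            if lapse:
                g *= gen.lapse_gain
            else:
                if difficulty == "hard":
                    g *= gen.difficulty_gain
                if correct == 0:
                    g *= gen.error_gain
            gain.append(g)
            jitter.append(rng.normal(0.0, gen.jitter_sd_by_condition[key]))
            arousal.append(gen.arousal_gain_by_condition[key])

    table = pd.DataFrame(rows, columns=BEHAVIOR_COLUMNS)
    gain = np.asarray(gain)
    truth = GroundTruth(
        gain_to=gain.copy(),
        gain_bp=gain.copy(),
        gain_tot=gain.copy(),
        jitter_s=np.asarray(jitter),
        arousal_gain=np.asarray(arousal),
        gen=gen,
        hrf_params_true=canonical_hrf(),
    )
    return table, truth


def validate_behavior(table: pd.DataFrame) -> None:
    """Check the lapse consistency invariant of a behavior table."""
    missing = [c for c in BEHAVIOR_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"behavior table missing columns: {missing}")
    lapse = table["response"] == "none"
    if not (table.loc[lapse, "rt_s"].isna().all()
            and table.loc[lapse, "correct"].isna().all()):
        raise ValueError("lapse rows must have missing rt and correctness")
    if table.loc[~lapse, "rt_s"].isna().any():
        raise ValueError("response rows must carry an RT")


def _global_onsets(behavior: pd.DataFrame, protocol: ProtocolParams) -> np.ndarray:
    """Trial onsets on the session clock (runs concatenated back to back)."""
    run_ids = list(dict.fromkeys(behavior["run_id"]))
    run_pos = {r: i for i, r in enumerate(run_ids)}
    offsets = behavior["run_id"].map(run_pos).to_numpy() * protocol.run_duration_s
    return behavior["onset_s"].to_numpy() + offsets


def trr_timecourse(behavior: pd.DataFrame, truth: GroundTruth,
                   protocol: ProtocolParams, rate_hz: float = 10.0) -> np.ndarray:
    """Noise-free shared task-related response at the working rate.

    Uses the same event-placement and convolution operators as the design
    builder, with per-trial gains applied and onsets shifted by the trial's
    temporal jitter.
    """
    onsets = _global_onsets(behavior, protocol) + truth.jitter_s
    lapse = (behavior["response"] == "none").to_numpy()
    rts = behavior["rt_s"].to_numpy()
    to, bp, tot = event_streams(
        onsets, rts, lapse, protocol.session_duration_s, rate_hz,
        gain_to=truth.gain_to, gain_bp=truth.gain_bp, gain_tot=truth.gain_tot,
    )
    kernel = hrf_kernel(truth.hrf_params_true, rate_hz)
    return (
        convolve_stream(to, kernel)
        + convolve_stream(bp, kernel)
        + convolve_stream(tot, kernel)
    )


def _rrf_kernel(t: np.ndarray) -> np.ndarray:
    # canonical respiration response function (Birn et al. 2008 form)
    return 0.6 * t**2.1 * np.exp(-t / 1.6) - 0.0023 * t**3.54 * np.exp(-t / 4.25)


def simulate_bold(
    behavior: pd.DataFrame,
    truth: GroundTruth,
    protocol: ProtocolParams,
    n_voxels: int,
    seed: int,
    working_rate_hz: float = 10.0,
    task_weights: np.ndarray | None = None,
    return_components: bool = False,
):
    """Voxel BOLD series in percent-signal-change units at 1/tr_s.

    Each voxel = ``task_weight`` x shared TRR + ``global_coupling`` x shared
    slow global component + ``physio_coupling`` x respiration-convolved
    artifact + white noise + AR(1) slow drift.  ``task_weights`` defaults to
    1 for every voxel; zero weights model non-task ("rest of brain") voxels
    that still share the global and physiological components.
    """
    if truth.n_trials != len(behavior):
        raise ValueError("behavior table and ground truth are misaligned")
    if task_weights is None:
        task_weights = np.ones(n_voxels)
    task_weights = np.asarray(task_weights, dtype=float)
    if task_weights.size != n_voxels:
        raise ValueError("task_weights must have one entry per voxel")
    rng = np.random.default_rng(seed)
    gen = truth.gen
    n_vols = protocol.n_volumes

    trr_fine = trr_timecourse(behavior, truth, protocol, working_rate_hz)
    trr = decimate(
        SampledSignal(trr_fine, working_rate_hz), 1.0 / protocol.tr_s
    ).values[:n_vols]

    # shared slow global component (AR(1) at TR, unit variance)
    g = np.zeros(n_vols)
    innov = rng.normal(size=n_vols)
    for t in range(1, n_vols):
        g[t] = gen.drift_ar * g[t - 1] + innov[t]
    if g.std() > 0:
        g = g / g.std()

    # respiration-convolved physiological artifact, generated at 50 Hz
    art = np.zeros(n_vols)
    if gen.physio_coupling != 0.0:
        fs = 50.0
        nf = int(round(protocol.session_duration_s * fs))
        tt = np.arange(nf) / fs
        resp = np.sin(2 * np.pi * 0.25 * tt + rng.uniform(0, 2 * np.pi))
        tk = np.arange(0.0, 60.0, 1.0 / fs)
        conv = sps.fftconvolve(resp, _rrf_kernel(tk) / fs)[:nf]
        art = conv[:: int(round(fs * protocol.tr_s))][:n_vols]
        if art.std() > 0:
            art = art / art.std()

    voxels = []
    for w in task_weights:
        noise = rng.normal(0.0, gen.noise_sd, size=n_vols) if gen.noise_sd else 0.0
        drift = np.zeros(n_vols)
        if gen.drift_sd:
            innov = rng.normal(0.0, gen.drift_sd, size=n_vols)
            for t in range(1, n_vols):
                drift[t] = gen.drift_ar * drift[t - 1] + innov[t]
        y = w * trr + gen.global_coupling * g + gen.physio_coupling * art + noise + drift
        voxels.append(SampledSignal(y, rate_hz=1.0 / protocol.tr_s, units="psc"))
    if return_components:
        return voxels, {"trr": trr, "global": g, "physio_artifact": art}
    return voxels


def simulate_physio(
    behavior: pd.DataFrame,
    truth: GroundTruth,
    seed: int,
    protocol: ProtocolParams | None = None,
    fs_hz: float = 50.0,
    base_hr_bpm: float = 70.0,
    hr_coupling: float = 1.0,
    ibi_noise_frac: float = 0.003,
    resp_freq_hz: float = 0.25,
    resp_freq_coupling: float = 0.3,
    resp_amp_coupling: float = 0.5,
    measurement_noise_sd: float = 0.01,
) -> tuple[SampledSignal, SampledSignal]:
    """Pulse-oximeter and respiration-belt traces at 50 Hz.

    The instantaneous heart rate on each trial is the base rate scaled by
    ``1 + hr_coupling * (arousal_gain - 1)``; respiration frequency drops and
    amplitude rises with arousal (breath holding when alert).
    """
    if len(behavior) == 0:
        raise ValueError("behavior table is empty")
    protocol = protocol or ProtocolParams(
        n_runs=behavior["run_id"].nunique(),
        difficulty_schedule=tuple(
            behavior.groupby("run_id", sort=False)["difficulty"].first()
        ),
    )
    rng = np.random.default_rng(seed)
    dur = protocol.session_duration_s
    n = int(round(dur * fs_hz))
    onsets = _global_onsets(behavior, protocol)

    def trial_arousal(t: float) -> float:
        i = int(np.searchsorted(onsets, t, side="right")) - 1
        i = min(max(i, 0), len(onsets) - 1)
        return float(truth.arousal_gain[i])

    # ---- pulse: beat point process + raised-cosine beat template
    beat_times = []
    t = float(rng.uniform(0, 0.5))
    while t < dur:
        beat_times.append(t)
        hr = base_hr_bpm * (1.0 + hr_coupling * (trial_arousal(t) - 1.0))
        ibi = (60.0 / hr) * (1.0 + rng.normal(0.0, ibi_noise_frac))
        t += max(ibi, 0.2)
    pulse = np.zeros(n)
    half_w = 0.12  # seconds, half-width of the raised-cosine beat
    kw = int(round(half_w * fs_hz))
    tmpl = 0.5 * (1 + np.cos(np.pi * np.arange(-kw, kw + 1) / kw))
    for bt in beat_times:
        c = int(round(bt * fs_hz))
        lo, hi = c - kw, c + kw + 1
        s0, s1 = max(lo, 0), min(hi, n)
        pulse[s0:s1] += tmpl[s0 - lo : s1 - lo]
    if measurement_noise_sd > 0:
        pulse += rng.normal(0.0, measurement_noise_sd, size=n)

    # ---- respiration: phase/amplitude-modulated sinusoid
    tt = np.arange(n) / fs_hz
    ar = np.array([trial_arousal(x) for x in onsets])
    trial_idx = np.clip(np.searchsorted(onsets, tt, side="right") - 1, 0, len(onsets) - 1)
    inst_ar = ar[trial_idx]
    freq = resp_freq_hz * (1.0 - resp_freq_coupling * (inst_ar - 1.0))
    amp = 1.0 + resp_amp_coupling * (inst_ar - 1.0)
    phase = 2 * np.pi * np.cumsum(freq) / fs_hz + rng.uniform(0, 2 * np.pi)
    resp = amp * np.sin(phase)
    if measurement_noise_sd > 0:
        resp = resp + rng.normal(0.0, 2 * measurement_noise_sd, size=n)

    return (
        SampledSignal(pulse, rate_hz=fs_hz, units="a.u."),
        SampledSignal(resp, rate_hz=fs_hz, units="a.u."),
    )


def simulate_motion(
    n_volumes: int,
    seed: int,
    tr_s: float = 1.5,
    amplitude: float = 0.05,
    smooth_volumes: float = 5.0,
) -> list[SampledSignal]:
    """Six smooth zero-mean random-walk head-motion traces at the TR rate.

    Columns, in order: roll, pitch, yaw, x, y, z.
    """
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _name in ("roll", "pitch", "yaw", "x", "y", "z"):
        walk = np.cumsum(rng.normal(size=n_volumes))
        walk = ndimage.gaussian_filter1d(walk, smooth_volumes)
        walk = walk - walk.mean()
        sd = walk.std()
        if sd > 0:
            walk = walk / sd
        out.append(SampledSignal(amplitude * walk, rate_hz=1.0 / tr_s, units="mm"))
    return out


def pupil_response_kernel(t: np.ndarray, n: float = 10.1, t_max_s: float = 0.93) -> np.ndarray:
    """Canonical pupil impulse response (Erlang-shaped, peak normalized to 1)."""
    t = np.asarray(t, dtype=float)
    with np.errstate(invalid="ignore"):
        w = (t / t_max_s) ** n * np.exp(n * (1.0 - t / t_max_s))
    return np.where(t <= 0, 0.0, w)


def simulate_pupil(
    behavior: pd.DataFrame,
    truth: GroundTruth,
    seed: int,
    protocol: ProtocolParams | None = None,
    fs_hz: float = 500.0,
    base_amplitude: float = 80.0,
    baseline: float = 1000.0,
    blink_rate_hz: float = 0.12,
    gaze_sd_deg: float = 0.2,
    noise_sd: float = 2.0,
) -> tuple[SampledSignal, tuple[SampledSignal, SampledSignal], list[tuple[float, float]]]:
    """Pupil-area trace, gaze (x, y) traces, and blink spans at 500 Hz.

    Per-trial dilation is the canonical pupil kernel scaled by the trial's
    arousal gain; blinks are dropped spans (samples zeroed, spans returned);
    gaze jitters around central fixation.
    """
    protocol = protocol or pupil_protocol(
        n_runs=behavior["run_id"].nunique(),
        trials_per_run=int(behavior.groupby("run_id").size().iloc[0]),
        difficulty_schedule=tuple(
            behavior.groupby("run_id", sort=False)["difficulty"].first()
        ),
    )
    rng = np.random.default_rng(seed)
    dur = protocol.session_duration_s
    n = int(round(dur * fs_hz))
    onsets = _global_onsets(behavior, protocol)

    dt = 1.0 / fs_hz
    events = np.zeros(n)
    for i, t0 in enumerate(onsets):
        i0 = int(round(t0 / dt))
        if 0 <= i0 < n:
            events[i0] += truth.arousal_gain[i]
    tk = np.arange(0.0, 4.0, dt)
    area = baseline + base_amplitude * np.convolve(events, pupil_response_kernel(tk))[:n]
    # slow drift + measurement noise
    drift = ndimage.gaussian_filter1d(np.cumsum(rng.normal(size=n)), 2.0 * fs_hz)
    if drift.std() > 0:
        drift = 5.0 * (drift - drift.mean()) / drift.std()
    area = area + drift + rng.normal(0.0, noise_sd, size=n)

    # blinks: Poisson arrivals, 100-300 ms, zeroed in the trace
    blink_spans: list[tuple[float, float]] = []
    if blink_rate_hz > 0:
        t = float(rng.exponential(1.0 / blink_rate_hz))
        while t < dur:
            span = (t, min(t + rng.uniform(0.1, 0.3), dur))
            blink_spans.append(span)
            area[int(span[0] * fs_hz) : int(span[1] * fs_hz)] = 0.0
            t = span[1] + float(rng.exponential(1.0 / blink_rate_hz))

    # gaze: OU process around fixation
    gaze = np.zeros((2, n))
    theta = 0.01
    for ax in range(2):
        innov = rng.normal(0.0, gaze_sd_deg * np.sqrt(2 * theta), size=n)
        for t_i in range(1, n):
            gaze[ax, t_i] = (1 - theta) * gaze[ax, t_i - 1] + innov[t_i]

    return (
        SampledSignal(area, rate_hz=fs_hz, units="a.u."),
        (
            SampledSignal(gaze[0], rate_hz=fs_hz, units="deg"),
            SampledSignal(gaze[1], rate_hz=fs_hz, units="deg"),
        ),
        blink_spans,
    )


def simulate_session(
    seed: int,
    protocol: ProtocolParams | None = None,
    observer: ObserverModel | None = None,
    staircase: StaircaseSpec | None = None,
    gen: GenParams | None = None,
    n_voxels: int = 20,
    n_background: int = 30,
    observer_id: str = "obs01",
) -> dict:
    """Convenience wrapper: one observer's full synthetic session.

    ``bold`` holds the ROI (task-weight 1) voxels; ``brain`` holds
    ``n_background`` task-weight-0 voxels sharing the same global and
    physiological components, from which the global signal is estimated.
    """
    protocol = protocol or ProtocolParams()
    observer = observer or ObserverModel()
    staircase = staircase or StaircaseSpec()
    rng = np.random.default_rng(seed)
    s_beh, s_bold, s_phys, s_mot = rng.integers(0, 2**31 - 1, size=4)
    behavior, truth = simulate_behavior(
        protocol, observer, staircase, int(s_beh), gen=gen, observer_id=observer_id
    )
    weights = np.concatenate([np.ones(n_voxels), np.zeros(n_background)])
    voxels = simulate_bold(
        behavior, truth, protocol, n_voxels + n_background, int(s_bold),
        task_weights=weights,
    )
    pulse, resp = simulate_physio(behavior, truth, int(s_phys), protocol=protocol)
    motion = simulate_motion(protocol.n_volumes, int(s_mot), tr_s=protocol.tr_s)
    return {
        "behavior": behavior,
        "truth": truth,
        "bold": voxels[:n_voxels],
        "brain": voxels[n_voxels:],
        "pulse": pulse,
        "respiration": resp,
        "motion": motion,
        "protocol": protocol,
    }
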
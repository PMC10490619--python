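"""Synthetic paired-condition cohorts with a ground-truth channel.

Every generator is deterministic for a fixed seed. A cohort seed is expanded
into independent per-session streams with ``numpy.random.SeedSequence(seed,
spawn_key=(subject_index, session_index, stream_index))`` where the stream
index enumerates (0=rr, 1=ecg, 2=gsr, 3=behavior); this keeps cohorts
reproducible regardless of generation order.

The RR model is a sinusoid-plus-noise tachogram: a 0.10 Hz oscillation
(slow, blood-pressure-band rhythm), a 0.25 Hz oscillation (respiratory
band), and white Gaussian noise around a per-subject baseline. Under the
"distracted" condition the configured effects shift the baseline, widen the
noise, scale the 0.10 Hz amplitude (and the broadband level), delay the
first electrodermal response, slow reaction times and lower hit rates —
directions chosen so a distracted session shows higher overall variability
and slower behavior than a focused one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .eda import BatemanParams, GSRRecording, bateman_kernel
from .errors import InvalidArgumentError
from .hrv import ECGRecording, RRSeries

__all__ = [
    "SubjectProfile",
    "ConditionEffects",
    "GroundTruth",
    "BehavioralRecord",
    "Session",
    "SyntheticDataset",
    "LF_HZ",
    "HF_HZ",
    "default_profile",
    "generate_rr",
    "synthesize_ecg",
    "generate_gsr",
    "generate_behavior",
    "generate_session",
    "generate_cohort",
    "session_rng",
]

LF_HZ = 0.10
HF_HZ = 0.25

FOCUSED = "focused"
DISTRACTED = "distracted"
CONDITIONS = (FOCUSED, DISTRACTED)


@dataclass
class SubjectProfile:
    subject_id: str
    base_mrr: float = 884.0  # ms
    base_sdrr: float = 12.0  # ms, white-noise SD of the tachogram
    lf_amp: float = 12.0  # ms, 0.10 Hz oscillation amplitude
    hf_amp: float = 18.0  # ms, 0.25 Hz oscillation amplitude
    base_tonic: float = 1.2  # microsiemens
    scr_rate: float = 12.0  # events/min
    rt_mu: float = float(np.log(450.0))  # log-ms, reaction-time location
    acc_p: float = 0.95  # hit probability

    def __post_init__(self) -> None:
        if self.base_mrr <= 0:
            raise InvalidArgumentError("base_mrr must be positive")
        if self.base_sdrr < 0:
            raise InvalidArgumentError("base_sdrr must be nonnegative")
        if not (0 <= self.acc_p <= 1):
            raise InvalidArgumentError("acc_p must be a probability")
        if self.scr_rate < 0:
            raise InvalidArgumentError("scr_rate must be nonnegative")


@dataclass
class ConditionEffects:
    """Shifts applied when condition == distracted; all signed and overridable."""

    # defaults reproduce the reference regime: total power rises through the
    # 0.10 Hz band alone (12^2 + 24^2/2 + 18^2/2 = 594 ms^2 vs 450 focused),
    # leaving the 0.25 Hz band and broadband noise nearly unchanged
    d_mrr: float = 10.0  # ms added to the baseline
    d_sdrr: float = 1.0  # ms added to the noise SD
    lf_scale: float = 2.0  # multiplies the 0.10 Hz amplitude
    tp_scale: float = 1.0  # multiplies noise + 0.25 Hz amplitudes (broadband)
    d_latency: float = 3.0  # s added to the first SCR onset
    d_rt: float = 1.25  # multiplies reaction times
    d_acc: float = 0.12  # subtracted from hit probability
    likert_focused: tuple = (4, 5)
    likert_distracted: tuple = (1, 2)

    def __post_init__(self) -> None:
        for name in ("d_mrr", "d_sdrr", "lf_scale", "tp_scale", "d_latency", "d_rt", "d_acc"):
            if not np.isfinite(getattr(self, name)):
                raise InvalidArgumentError(f"effect {name} must be finite")

    @classmethod
    def null(cls) -> "ConditionEffects":
        """No condition effect at all (for type-I-error / chance-level checks)."""
        return cls(d_mrr=0.0, d_sdrr=0.0, lf_scale=1.0, tp_scale=1.0,
                   d_latency=0.0, d_rt=1.0, d_acc=0.0,
                   likert_focused=(1, 2, 3, 4, 5), likert_distracted=(1, 2, 3, 4, 5))


@dataclass
class GroundTruth:
    r_peak_times: np.ndarray = field(default_factory=lambda: np.array([]))
    scr_events: list = field(default_factory=list)  # [(onset_s, amplitude_uS)]
    condition: str = FOCUSED


@dataclass
class BehavioralRecord:
    is_target: np.ndarray  # bool per stimulus
    hit: np.ndarray  # bool per target-response opportunity (aligned to stimuli)
    reaction_times: np.ndarray  # ms, NaN for non-responses
    rating: int  # 5-point concentration rating

    @property
    def n_stimuli(self) -> int:
        return self.is_target.size

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.hit))

    @property
    def mean_rt(self) -> float:
        rts = self.reaction_times[np.isfinite(self.reaction_times)]
        return float(np.mean(rts)) if rts.size else float("nan")


@dataclass
class Session:
    subject_id: str
    condition: str
    rr: RRSeries
    ecg: ECGRecording
    gsr: GSRRecording
    behavior: BehavioralRecord
    truth: GroundTruth


@dataclass
class SyntheticDataset:
    profiles: list
    sessions: list  # 2 per subject (focused, distracted)
    effects: ConditionEffects
    seed: int


def default_profile(subject_id: str = "S01") -> SubjectProfile:
    return SubjectProfile(subject_id=subject_id)


def session_rng(seed: int, subject_index: int, session_index: int, stream: int) -> np.random.Generator:
    """Documented seed-expansion scheme (see module docstring)."""
    ss = np.random.SeedSequence(seed, spawn_key=(subject_index, session_index, stream))
    return np.random.default_rng(ss)


def _apply_condition(profile: SubjectProfile, condition: str, effects: ConditionEffects):
    """Effective (mrr, noise_sd, lf_amp, hf_amp) after condition shifts."""
    if condition not in CONDITIONS:
        raise InvalidArgumentError(f"unknown condition {condition!r}")
    mrr, sd, lf, hf = profile.base_mrr, profile.base_sdrr, profile.lf_amp, profile.hf_amp
    if condition == DISTRACTED:
        mrr += effects.d_mrr
        sd = (sd + effects.d_sdrr) * effects.tp_scale
        lf *= effects.lf_scale
        hf *= effects.tp_scale
    return mrr, sd, lf, hf


# ---------------------------------------------------------------------------
# RR tachogram
# ---------------------------------------------------------------------------


def generate_rr(
    profile: SubjectProfile,
    condition: str = FOCUSED,
    duration: float = 300.0,
    seed: int | np.random.Generator = 0,
    effects: ConditionEffects | None = None,
) -> RRSeries:
    """Sinusoid-plus-noise tachogram; beats fill ``duration`` seconds."""
    if duration <= 0:
        raise InvalidArgumentError("duration must be positive")
    if duration < 60:
        raise InvalidArgumentError("duration must be at least 60 s")
    effects = effects or ConditionEffects()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mrr, sd, lf, hf = _apply_condition(profile, condition, effects)
    phi = rng.uniform(0, 2 * np.pi)

    times = [0.0]
    intervals = []
    t = 0.0
    while True:
        rr_ms = (
            mrr
            + lf * np.sin(2 * np.pi * LF_HZ * t)
            + hf * np.sin(2 * np.pi * HF_HZ * t + phi)
            + (sd * rng.standard_normal() if sd > 0 else 0.0)
        )
        rr_ms = max(rr_ms, 0.3 * mrr)  # physiological floor
        t_next = t + rr_ms / 1000.0
        if t_next > duration + 1e-12:
            break
        intervals.append(rr_ms)
        times.append(t_next)
        t = t_next
    return RRSeries(np.asarray(times), np.asarray(intervals))


# ---------------------------------------------------------------------------
# ECG waveform
# ---------------------------------------------------------------------------

# QRS-like complex: narrow positive R gaussian flanked by small Q and S dips,
# ~100 ms of support; amplitudes in mV.
_QRS_COMPONENTS = (  # (amplitude mV, center offset s, width s)
    (-0.15, -0.025, 0.010),
    (1.00, 0.000, 0.012),
    (-0.20, 0.028, 0.010),
)


def _qrs_template(t: np.ndarray) -> np.ndarray:
    out = np.zeros_like(t)
    for amp, mu, sig in _QRS_COMPONENTS:
        out += amp * np.exp(-0.5 * ((t - mu) / sig) ** 2)
    return out


def synthesize_ecg(
    rr: RRSeries,
    fs: float = 250.0,
    snr_db: float = 20.0,
    seed: int | np.random.Generator = 0,
    wander_amp: float = 0.1,
    wander_freq: float = 0.3,
    powerline_amp: float = 0.02,
    powerline_freq: float = 50.0,
) -> tuple[ECGRecording, np.ndarray]:
    """Place an analytic QRS template at every R instant and add noise.

    Returns (recording, ground-truth R times). ``snr_db=inf`` disables the
    white noise; wander/powerline amplitudes of 0 disable those terms.
    """
    if fs < 100:
        raise InvalidArgumentError("fs must be >= 100 Hz (template bandwidth)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    duration = float(rr.peak_times[-1]) + 0.5
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    sig = np.zeros(n)
    half_support = 0.08
    for rt in rr.peak_times:
        lo = max(0, int(np.floor((rt - half_support) * fs)))
        hi = min(n, int(np.ceil((rt + half_support) * fs)) + 1)
        sig[lo:hi] += _qrs_template(t[lo:hi] - rt)
    clean_power = float(np.mean(sig**2))
    if wander_amp:
        sig = sig + wander_amp * np.sin(2 * np.pi * wander_freq * t + rng.uniform(0, 2 * np.pi))
    if powerline_amp:
        sig = sig + powerline_amp * np.sin(2 * np.pi * powerline_freq * t + rng.uniform(0, 2 * np.pi))
    if np.isfinite(snr_db):
        noise_sd = np.sqrt(clean_power / (10.0 ** (snr_db / 10.0)))
        sig = sig + noise_sd * rng.standard_normal(n)
    return ECGRecording(sig, fs), rr.peak_times.copy()


# ---------------------------------------------------------------------------
# GSR
# ---------------------------------------------------------------------------


def generate_gsr(
    profile: SubjectProfile,
    condition: str = FOCUSED,
    duration: float = 300.0,
    fs: float = 10.0,
    seed: int | np.random.Generator = 0,
    effects: ConditionEffects | None = None,
    events: list | None = None,
    noise_sd: float = 0.005,
    drift_amp: float = 0.05,
    base_latency: float = 1.0,
    params: BatemanParams | None = None,
) -> tuple[GSRRecording, GroundTruth]:
    """Tonic drift + Bateman-shaped SCRs + Gaussian noise.

    ``events`` (list of (onset_s, amplitude_uS)) overrides the Poisson
    process — used by the planted-event oracle tests.
    """
    if profile.scr_rate < 0:
        raise InvalidArgumentError("scr_rate must be nonnegative")
    if duration <= 0:
        raise InvalidArgumentError("duration must be positive")
    effects = effects or ConditionEffects()
    params = params or BatemanParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    tonic = profile.base_tonic + drift_amp * np.sin(
        2 * np.pi * t / max(duration, 1.0) + rng.uniform(0, 2 * np.pi)
    )

    if events is None:
        # the first response is delayed by a base latency, further lengthened
        # when distracted — this is what the Latency feature picks up
        latency_offset = base_latency + (
            effects.d_latency if condition == DISTRACTED else 0.0
        )
        rate_per_s = profile.scr_rate / 60.0
        onsets = []
        t_ev = latency_offset
        while rate_per_s > 0:
            t_ev += rng.exponential(1.0 / rate_per_s)
            if t_ev >= duration - 5.0:
                break
            onsets.append(t_ev)
        amps = np.exp(rng.normal(np.log(0.3), 0.5, size=len(onsets)))
        ev_list = [(float(o), float(max(a, 0.02))) for o, a in zip(onsets, amps)]
    else:
        ev_list = [(float(o), float(a)) for o, a in sorted(events)]
        if any(a <= 0 for _, a in ev_list):
            raise InvalidArgumentError("planted SCR amplitudes must be positive")

    kernel_len = min(10.0 * params.tau1, duration)
    kernel = bateman_kernel(params, fs, kernel_len)
    sig = tonic.copy()
    for onset, amp in ev_list:
        idx = int(round(onset * fs))
        if idx >= n:
            continue
        hi = min(n, idx + kernel.size)
        sig[idx:hi] += amp * kernel[: hi - idx]
    if noise_sd > 0:
        sig = sig + noise_sd * rng.standard_normal(n)
    sig = np.maximum(sig, 0.0)

    gsr = GSRRecording(sig, fs=fs, window_start=0.0, window_length=min(300.0, duration))
    truth = GroundTruth(scr_events=ev_list, condition=condition)
    return gsr, truth


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------


def generate_behavior(
    profile: SubjectProfile,
    condition: str = FOCUSED,
    n_stimuli: int = 150,
    target_rate: float = 0.2,
    seed: int | np.random.Generator = 0,
    effects: ConditionEffects | None = None,
    rt_sigma: float = 0.15,
) -> BehavioralRecord:
    """Go/no-go vigilance-task responses: hits, lognormal RTs, rating."""
    if n_stimuli <= 0:
        raise InvalidArgumentError("n_stimuli must be positive")
    if not (0 < target_rate < 1):
        raise InvalidArgumentError("target_rate must be in (0, 1)")
    effects = effects or ConditionEffects()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_targets = int(round(n_stimuli * target_rate))
    is_target = np.zeros(n_stimuli, dtype=bool)
    is_target[rng.choice(n_stimuli, size=n_targets, replace=False)] = True

    p_hit = profile.acc_p - (effects.d_acc if condition == DISTRACTED else 0.0)
    p_hit = float(np.clip(p_hit, 0.0, 1.0))
    # correct response: press on target, withhold on non-target
    correct = rng.random(n_stimuli) < p_hit

    rt_scale = effects.d_rt if condition == DISTRACTED else 1.0
    rts = np.full(n_stimuli, np.nan)
    responded = (is_target & correct) | (~is_target & ~correct)
    rts[responded] = np.exp(rng.normal(profile.rt_mu, rt_sigma, responded.sum())) * rt_scale

    choices = effects.likert_distracted if condition == DISTRACTED else effects.likert_focused
    rating = int(rng.choice(np.asarray(choices)))
    return BehavioralRecord(is_target=is_target, hit=correct, reaction_times=rts, rating=rating)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def _draw_profile(rng: np.random.Generator, subject_id: str) -> SubjectProfile:
    """Hyperdistributions centered on the focused-condition regime."""
    return SubjectProfile(
        subject_id=subject_id,
        base_mrr=float(rng.normal(884.0, 25.0)),
        base_sdrr=float(np.clip(rng.normal(12.0, 3.0), 3.0, None)),
        lf_amp=float(np.clip(rng.normal(12.0, 3.0), 2.0, None)),
        hf_amp=float(np.clip(rng.normal(18.0, 4.0), 3.0, None)),
        base_tonic=float(np.clip(rng.normal(1.2, 0.4), 0.2, None)),
        scr_rate=float(np.clip(rng.normal(14.0, 5.0), 1.0, None)),
        rt_mu=float(rng.normal(np.log(450.0), 0.10)),
        acc_p=float(np.clip(rng.normal(0.95, 0.03), 0.75, 1.0)),
    )


def generate_session(
    profile: SubjectProfile,
    condition: str,
    subject_index: int,
    seed: int,
    effects: ConditionEffects,
    duration: float = 300.0,
    ecg_fs: float = 250.0,
    gsr_fs: float = 10.0,
    snr_db: float = 20.0,
) -> Session:
    """One subject x condition recording bundle with its truth channel."""
    s_idx = CONDITIONS.index(condition)
    rr = generate_rr(profile, condition, duration,
                     seed=session_rng(seed, subject_index, s_idx, 0), effects=effects)
    ecg, r_truth = synthesize_ecg(rr, fs=ecg_fs, snr_db=snr_db,
                                  seed=session_rng(seed, subject_index, s_idx, 1))
    gsr, gsr_truth = generate_gsr(profile, condition, duration, fs=gsr_fs,
                                  seed=session_rng(seed, subject_index, s_idx, 2),
                                  effects=effects)
    behavior = generate_behavior(profile, condition,
                                 seed=session_rng(seed, subject_index, s_idx, 3),
                                 effects=effects)
    truth = GroundTruth(r_peak_times=r_truth, scr_events=gsr_truth.scr_events,
                        condition=condition)
    return Session(profile.subject_id, condition, rr, ecg, gsr, behavior, truth)


def generate_cohort(
    n_subjects: int = 30,
    effects: ConditionEffects | None = None,
    seed: int = 0,
    duration: float = 300.0,
    ecg_fs: float = 250.0,
    gsr_fs: float = 10.0,
    snr_db: float = 20.0,
) -> SyntheticDataset:
    """Paired-design cohort: each subject gets one focused and one
    distracted session (2 * n_subjects sessions)."""
    if n_subjects < 2:
        raise InvalidArgumentError("need at least 2 subjects")
    effects = effects if effects is not None else ConditionEffects()
    # profiles use a reserved spawn key so they never collide with sessions
    profile_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99991,)))
    profiles = [
        _draw_profile(profile_rng, f"S{i + 1:02d}") for i in range(n_subjects)
    ]
    sessions = []
    for i, profile in enumerate(profiles):
        for condition in CONDITIONS:
            sessions.append(
                generate_session(profile, condition, i, seed, effects,
                                 duration=duration, ecg_fs=ecg_fs,
                                 gsr_fs=gsr_fs, snr_db=snr_db)
            )
    return SyntheticDataset(profiles=profiles, sessions=sessions, effects=effects, seed=seed)
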
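"""Synthetic multimodal biosignal cohort generator.

Generates per-subject, per-session recordings of five modalities — ECG (mV),
galvanic skin response (µS), radial-artery pulse (relative current,
dimensionless), skin temperature (°C) and sweat cortisol (nM, sparsely
sampled at the sensor's incubation cadence) — driven by a labeled stressor
schedule.  Each stressor category perturbs the physiological baselines with
its own effect profile (heart-rate rise, skin-conductance shift, phasic
event rate, crest-time shift, temperature shift, cortisol trajectory), so a
downstream classifier can in principle recover the schedule labels from the
signals alone.

The effect sizes are phenomenological: state targets are approached with
first-order relaxation dynamics, and the cortisol response additionally lags
the stressor by a sweat-transport delay (default 300 s).  No mechanistic
(HPA-axis) modeling is attempted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from multistress.schedule import Segment, StressState, StressorSchedule, make_protocol_schedule

CORTISOL_RANGE_NM = (1.0, 10_000.0)  # sensed range: 1 nM to 10 µM
DEFAULT_SWEAT_LAG_S = 300.0
MIN_INCUBATION_S = 60.0


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Channel:
    """A uniformly sampled continuous channel starting at t = 0."""

    samples: np.ndarray
    sampling_rate: float
    units: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate


@dataclass
class SparseChannel:
    """An irregularly (sparsely) sampled channel, e.g. sweat cortisol."""

    times_s: np.ndarray
    values: np.ndarray
    units: str

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("sparse channel timestamps must be strictly increasing")

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1]) if len(self.times_s) else 0.0


@dataclass
class CortisolResponse:
    """Stressor-evoked cortisol excursion: baseline -> peak -> end-of-block value.

    The excursion rises from the pre-stressor baseline to ``peak_nM`` over
    ``rise_s`` seconds (smooth raised-cosine ramp, so the peak is attained
    exactly), then decays exponentially; ``decay_s`` defaults to the value
    that brings the level to ``end_nM`` at the end of a block of
    ``block_ref_s`` seconds.
    """

    baseline_nM: float = 86.0
    peak_nM: float = 86.0
    end_nM: float | None = None
    rise_s: float = 180.0
    decay_s: float | None = None
    block_ref_s: float = 600.0

    def delta_peak(self) -> float:
        return self.peak_nM - self.baseline_nM

    def resolved_decay_s(self) -> float:
        if self.decay_s is not None:
            return self.decay_s
        dp = self.delta_peak()
        if self.end_nM is None or dp <= 0:
            return 600.0
        de = self.end_nM - self.baseline_nM
        span = max(self.block_ref_s - self.rise_s, 1.0)
        if de <= 0 or de >= dp:
            return 600.0
        return span / np.log(dp / de)


@dataclass
class EffectProfile:
    """Per-state deltas applied on top of subject baselines."""

    hr_delta_bpm: float = 0.0
    scl_delta_us: float = 0.0
    scr_rate_per_min: float = 0.0       # added on top of the resting rate
    scr_amp_scale: float = 1.0
    crest_shift_ms: float = 0.0
    st_delta_c: float = 0.0
    cortisol: CortisolResponse = field(default_factory=CortisolResponse)

    def __post_init__(self) -> None:
        if self.scr_rate_per_min < -1e-12 or self.scr_amp_scale < 0:
            raise ValueError("rates and amplitude scales must be non-negative")
        for v in (self.cortisol.baseline_nM, self.cortisol.peak_nM):
            if not (CORTISOL_RANGE_NM[0] <= v <= CORTISOL_RANGE_NM[1]):
                raise ValueError(f"cortisol value {v} nM outside sensed range")


def default_effect_profiles() -> dict[StressState, EffectProfile]:
    """Stressor effect profiles matching the reported physiological dynamics.

    Quiz (cognitive): HR 89->107 bpm, cortisol 86->113 nM peak.
    Cold pressor (environmental): cortisol 86->104->97 nM, skin temperature drop.
    Horror film (emotional): cortisol peak 107 nM, raised SCR incidence, shorter CT.
    Interview (psychosocial): moderate responses (no printed magnitudes).
    Exercise (physical): HR 87->95 bpm, cortisol 84->94 nM, slight ST increase.
    """
    return {
        StressState.REST: EffectProfile(),
        StressState.COGNITIVE: EffectProfile(
            hr_delta_bpm=18.0, scl_delta_us=1.5, scr_rate_per_min=6.0,
            scr_amp_scale=1.5, crest_shift_ms=-15.0, st_delta_c=0.0,
            cortisol=CortisolResponse(86.0, 113.0, end_nM=None, rise_s=480.0),
        ),
        StressState.ENVIRONMENTAL: EffectProfile(
            hr_delta_bpm=5.0, scl_delta_us=1.0, scr_rate_per_min=3.0,
            scr_amp_scale=1.3, crest_shift_ms=15.0, st_delta_c=-1.5,
            cortisol=CortisolResponse(86.0, 104.0, end_nM=97.0, rise_s=180.0),
        ),
        StressState.EMOTIONAL: EffectProfile(
            hr_delta_bpm=8.0, scl_delta_us=1.2, scr_rate_per_min=5.0,
            scr_amp_scale=1.4, crest_shift_ms=-10.0, st_delta_c=-0.3,
            cortisol=CortisolResponse(86.0, 107.0, end_nM=None, rise_s=300.0),
        ),
        StressState.PSYCHOSOCIAL: EffectProfile(
            hr_delta_bpm=12.0, scl_delta_us=1.0, scr_rate_per_min=4.0,
            scr_amp_scale=1.3, crest_shift_ms=-10.0, st_delta_c=-0.2,
            cortisol=CortisolResponse(86.0, 100.0, end_nM=None, rise_s=300.0),
        ),
        StressState.PHYSICAL: EffectProfile(
            hr_delta_bpm=8.0, scl_delta_us=0.8, scr_rate_per_min=2.0,
            scr_amp_scale=1.2, crest_shift_ms=-25.0, st_delta_c=0.8,
            cortisol=CortisolResponse(84.0, 94.0, end_nM=None, rise_s=300.0),
        ),
    }


@dataclass
class SubjectRecording:
    """One subject-session: five synchronized channels plus the schedule."""

    subject_id: str
    session_id: str
    channels: dict[str, Channel | SparseChannel]
    schedule: StressorSchedule

    def __post_init__(self) -> None:
        durs = {
            name: ch.duration_s
            for name, ch in self.channels.items()
            if isinstance(ch, Channel)
        }
        if durs and (max(durs.values()) - min(durs.values())) > 1.0:
            raise ValueError(f"continuous channels span different durations: {durs}")


# ---------------------------------------------------------------------------
# beat clock
# ---------------------------------------------------------------------------

def _per_second(series, duration_s: float) -> np.ndarray:
    """Coerce a scalar or per-second array to a length-ceil(duration) array."""
    n = int(np.ceil(duration_s))
    arr = np.asarray(series, dtype=float)
    if arr.ndim == 0:
        return np.full(n, float(arr))
    if len(arr) < n:
        arr = np.concatenate([arr, np.full(n - len(arr), arr[-1])])
    return arr[:n]


def beat_times_from_hr(duration_s: float, hr_series, first_beat_s: float = 0.3) -> np.ndarray:
    """Beat times from an instantaneous heart-rate series (bpm per second).

    The cardiac phase is integrated at 1 s resolution; a beat fires at every
    integer phase crossing.  ECG and pulse channels built from the same HR
    series therefore share one beat clock.
    """
    hr = _per_second(hr_series, duration_s)
    if np.any(hr < 30) or np.any(hr > 220):
        raise ValueError("heart rate must stay within 30-220 bpm")
    # phase(t) = integral of hr/60 dt, linearly interpolated within seconds
    dt = 0.01
    t = np.arange(0.0, duration_s, dt)
    hr_t = np.interp(t, np.arange(len(hr)) + 0.5, hr)
    phase = np.cumsum(hr_t / 60.0) * dt
    n_beats = int(np.floor(phase[-1]))
    crossings = np.interp(np.arange(1, n_beats + 1), phase, t)
    beats = first_beat_s + np.concatenate([[0.0], crossings])
    return beats[beats < duration_s - 1e-9]


# ---------------------------------------------------------------------------
# per-modality simulators
# ---------------------------------------------------------------------------

# sum-of-Gaussians PQRST template: (delay as fraction of RR, width s, amp mV)
_ECG_COMPONENTS = (
    (-0.18, 0.030, 0.15),   # P
    (-0.025, 0.010, -0.12), # Q
    (0.0, 0.011, 1.00),     # R
    (0.025, 0.010, -0.18),  # S
    (0.28, 0.055, 0.30),    # T
)


def simulate_ecg(
    duration_s: float,
    hr_series,
    sampling_rate: float = 128.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Channel:
    """Synthetic single-lead ECG with PQRST morphology (mV).

    Each beat is a sum of five Gaussians (P, Q, R, S, T) whose P/T delays
    scale with the local RR interval; the R peak sits exactly on the beat
    clock, so the mean RR interval over a stationary stretch equals 60/HR.
    """
    if sampling_rate < 64:
        raise ValueError("sampling_rate below 64 Hz cannot resolve R peaks")
    beats = beat_times_from_hr(duration_s, hr_series)
    n = int(round(duration_s * sampling_rate))
    t = np.arange(n) / sampling_rate
    sig = np.zeros(n)
    rr = np.diff(beats) if len(beats) > 1 else np.array([1.0])
    for i, tb in enumerate(beats):
        rr_prev = rr[i - 1] if i > 0 else rr[0]
        rr_next = rr[i] if i < len(rr) else rr[-1]
        lo = np.searchsorted(t, tb - 0.35 * rr_prev)
        hi = np.searchsorted(t, tb + 0.65 * rr_next)
        tt = t[lo:hi] - tb
        for frac, width, amp in _ECG_COMPONENTS:
            delay = frac * (rr_prev if frac < 0 else rr_next) if abs(frac) > 0.1 else frac
            sig[lo:hi] += amp * np.exp(-0.5 * ((tt - delay) / width) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sig = sig + rng.normal(0.0, noise_sd, size=n)
    return Channel(sig, sampling_rate, "mV")


def _scr_kernel(sampling_rate: float, rise_s: float = 0.75, decay_s: float = 3.0) -> np.ndarray:
    # biexponential (Bateman) response; long support + end-value subtraction
    # avoid a truncation step that would put a spurious edge in the signal
    tt = np.arange(0.0, 40.0, 1.0 / sampling_rate)
    h = np.exp(-tt / decay_s) - np.exp(-tt / rise_s)
    h -= h[-1]
    return h / h.max()


def simulate_gsr(
    duration_s: float,
    scl_series,
    scr_rate: float = 3.0,
    scr_amp: float = 0.3,
    seed: int | None = None,
    sampling_rate: float = 128.0,
    noise_sd: float = 0.0,
    return_events: bool = False,
):
    """Skin conductance (µS): slow tonic level plus Poisson phasic responses.

    Phasic events arrive as a homogeneous Poisson process at ``scr_rate``
    events/min (``scr_rate`` may also be a per-second series for
    state-dependent rates); each event adds a biexponential response with
    peak amplitude near ``scr_amp``.  With ``return_events`` the ground-truth
    ``(onset_s, amplitude)`` list is returned alongside the channel.
    """
    scl = _per_second(scl_series, duration_s)
    if np.any(scl < 0):
        raise ValueError("tonic skin conductance must be non-negative")
    n = int(round(duration_s * sampling_rate))
    t = np.arange(n) / sampling_rate
    tonic = np.interp(t, np.arange(len(scl)) + 0.5, scl)
    sig = tonic.copy()
    rate = _per_second(scr_rate, duration_s) / 60.0  # events per second
    rng = np.random.default_rng(seed)
    kernel = _scr_kernel(sampling_rate)
    # thinning: draw candidate events at the max rate, keep with prob rate/max
    rmax = float(rate.max())
    events: list[tuple[float, float]] = []
    if rmax > 0:
        tev = 0.0
        while True:
            tev += rng.exponential(1.0 / rmax)
            if tev >= duration_s:
                break
            if rng.random() <= rate[min(int(tev), len(rate) - 1)] / rmax:
                amp = scr_amp * (0.7 + 0.6 * rng.random())
                i0 = int(tev * sampling_rate)
                seg = kernel[: n - i0]
                sig[i0 : i0 + len(seg)] += amp * seg
                events.append((tev, amp))
    if noise_sd > 0:
        sig = sig + rng.normal(0.0, noise_sd, size=n)
    ch = Channel(sig, sampling_rate, "uS")
    return (ch, events) if return_events else ch


def simulate_rap(
    duration_s: float,
    hr_series,
    crest_time_ms=150.0,
    amp: float = 1.0,
    seed: int | None = None,
    sampling_rate: float = 64.0,
    noise_sd: float = 0.0,
) -> Channel:
    """Radial-artery pulse waveform (relative current, dimensionless).

    Each pulse starts at its foot on the shared beat clock, ramps linearly to
    the percussion (P) peak over exactly ``crest_time_ms`` (a stylized but
    tangent-method-consistent upstroke), then decays with superposed tidal
    (T) and dicrotic (D) waves.  ``crest_time_ms`` may be a per-second series.
    """
    beats = beat_times_from_hr(duration_s, hr_series)
    ct_series = _per_second(crest_time_ms, duration_s) / 1000.0
    n = int(round(duration_s * sampling_rate))
    t = np.arange(n) / sampling_rate
    sig = np.zeros(n)
    rr = np.diff(beats) if len(beats) > 1 else np.array([1.0])
    for i, tb in enumerate(beats):
        rr_next = rr[i] if i < len(rr) else rr[-1]
        ct = float(ct_series[min(int(tb), len(ct_series) - 1)])
        lo = np.searchsorted(t, tb)
        hi = np.searchsorted(t, tb + min(0.85 * rr_next, ct + 0.55))
        tt = t[lo:hi] - tb
        pulse = np.zeros_like(tt)
        up = tt < ct
        pulse[up] = amp * tt[up] / ct
        s = tt[~up] - ct
        pulse[~up] = (
            amp * np.exp(-s / 0.10)
            + 0.45 * amp * np.exp(-0.5 * ((s - 0.14) / 0.050) ** 2)
            + 0.22 * amp * np.exp(-0.5 * ((s - 0.30) / 0.045) ** 2)
        )
        sig[lo:hi] += pulse
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sig = sig + rng.normal(0.0, noise_sd, size=n)
    return Channel(sig, sampling_rate, "dI/I0")


def simulate_skin_temp(
    duration_s: float,
    st_series,
    noise_sd: float = 0.0,
    seed: int | None = None,
    sampling_rate: float = 1.0,
) -> Channel:
    """Skin temperature (°C) at a slow sampling rate."""
    st = _per_second(st_series, duration_s)
    n = int(round(duration_s * sampling_rate))
    t = np.arange(n) / sampling_rate
    sig = np.interp(t, np.arange(len(st)) + 0.5, st)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sig = sig + rng.normal(0.0, noise_sd, size=n)
    return Channel(sig, sampling_rate, "degC")


def _cortisol_excursion(
    t: np.ndarray, seg: Segment, resp: CortisolResponse, lag_s: float
) -> np.ndarray:
    """Evoked cortisol delta (nM) at times ``t`` for one stressor block."""
    dp = resp.delta_peak()
    if dp <= 0:
        return np.zeros_like(t)
    t0 = seg.start_s + lag_s
    rise = min(resp.rise_s, seg.duration_s)
    tp = t0 + rise
    tau = resp.resolved_decay_s()
    out = np.zeros_like(t)
    m_rise = (t >= t0) & (t < tp)
    out[m_rise] = dp * 0.5 * (1 - np.cos(np.pi * (t[m_rise] - t0) / rise))
    m_dec = t >= tp
    out[m_dec] = dp * np.exp(-(t[m_dec] - tp) / tau)
    return out


def cortisol_concentration(
    t,
    schedule: StressorSchedule,
    profiles: dict[StressState, EffectProfile] | None = None,
    circadian: tuple[float, float] = (95.0, 80.0),
    lag_s: float = DEFAULT_SWEAT_LAG_S,
) -> np.ndarray:
    """Continuous ground-truth cortisol concentration (nM) at times ``t``.

    Baseline declines linearly between the morning and evening anchors over
    the schedule duration; each stressor block superposes its profile's
    rise/decay excursion, delayed by the sweat-transport lag.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    profiles = profiles or default_effect_profiles()
    dur = schedule.duration_s
    c0, c1 = circadian
    base = c0 + (c1 - c0) * np.clip(t / dur, 0.0, 1.0) if dur > 0 else np.full_like(t, c0)
    total = base.copy()
    for seg in schedule.segments:
        if seg.label is StressState.REST:
            continue
        total += _cortisol_excursion(t, seg, profiles[seg.label].cortisol, lag_s)
    return np.clip(total, *CORTISOL_RANGE_NM)


def simulate_cortisol(
    schedule: StressorSchedule,
    profiles: dict[StressState, EffectProfile] | None = None,
    circadian: tuple[float, float] = (95.0, 80.0),
    sample_every_s: float = MIN_INCUBATION_S,
    lag_s: float = DEFAULT_SWEAT_LAG_S,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> SparseChannel:
    """Sparse sweat-cortisol channel sampled at the incubation cadence (nM)."""
    if sample_every_s < MIN_INCUBATION_S - 1e-9:
        warnings.warn(
            f"sample spacing {sample_every_s} s is below the minimum incubation "
            f"time of {MIN_INCUBATION_S:.0f} s",
            stacklevel=2,
        )
    times = np.arange(0.0, schedule.duration_s + 1e-9, sample_every_s)
    vals = cortisol_concentration(times, schedule, profiles, circadian, lag_s)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vals = np.clip(vals + rng.normal(0.0, noise_sd, size=len(vals)), *CORTISOL_RANGE_NM)
    return SparseChannel(times, vals, "nM")


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class SamplingRates:
    ecg: float = 128.0
    gsr: float = 128.0
    rap: float = 64.0
    st: float = 1.0
    cortisol_every_s: float = MIN_INCUBATION_S


@dataclass
class SubjectVariability:
    """Between-subject random-effect SDs and within-channel noise levels.

    Subject-level effects (baseline HR, SCL, skin temperature, crest time,
    cortisol anchors, and a multiplicative effect-size scale) are drawn once
    per subject and shared across that subject's sessions.
    """

    hr_baseline_sd: float = 7.0
    scl_baseline_sd: float = 1.5
    st_baseline_sd: float = 0.4
    ct_baseline_sd_ms: float = 10.0
    cortisol_baseline_sd: float = 10.0
    effect_scale_sd: float = 0.10
    ecg_noise_sd: float = 0.02
    gsr_noise_sd: float = 0.01
    rap_noise_sd: float = 0.02
    st_noise_sd: float = 0.05
    cortisol_noise_sd: float = 2.0
    tau_on_s: float = 10.0
    tau_off_s: float = 12.0

    @classmethod
    def low_noise(cls) -> "SubjectVariability":
        """Large-effect, low-noise preset for separability studies."""
        return cls(
            hr_baseline_sd=4.0, scl_baseline_sd=0.8, st_baseline_sd=0.25,
            ct_baseline_sd_ms=6.0, cortisol_baseline_sd=5.0, effect_scale_sd=0.05,
            ecg_noise_sd=0.01, gsr_noise_sd=0.005, rap_noise_sd=0.01,
            st_noise_sd=0.02, cortisol_noise_sd=1.0,
        )

    @classmethod
    def noiseless(cls) -> "SubjectVariability":
        """No between-subject effects and no measurement noise (ground truth)."""
        return cls(
            hr_baseline_sd=0.0, scl_baseline_sd=0.0, st_baseline_sd=0.0,
            ct_baseline_sd_ms=0.0, cortisol_baseline_sd=0.0, effect_scale_sd=0.0,
            ecg_noise_sd=0.0, gsr_noise_sd=0.0, rap_noise_sd=0.0,
            st_noise_sd=0.0, cortisol_noise_sd=0.0,
        )


#: Population baselines the subject random effects perturb.
POPULATION_BASELINES = {
    "hr_bpm": 88.0,
    "scl_us": 6.0,
    "st_c": 33.5,
    "ct_ms": 150.0,
    "scr_rate_per_min": 1.0,
    "scr_amp_us": 0.3,
    "circadian_nM": (95.0, 80.0),
}


def _relax_to_targets(targets: np.ndarray, tau_on: float, tau_off: float, x0: float) -> np.ndarray:
    """First-order relaxation of a state series toward per-second targets."""
    out = np.empty_like(targets)
    x = x0
    a_on = 1.0 - np.exp(-1.0 / max(tau_on, 1e-6))
    a_off = 1.0 - np.exp(-1.0 / max(tau_off, 1e-6))
    for i, tgt in enumerate(targets):
        a = a_on if abs(tgt - x0) > abs(x - x0) else a_off
        x = x + (tgt - x) * a
        out[i] = x
    return out


def _state_series(schedule: StressorSchedule, per_state: dict[StressState, float]) -> np.ndarray:
    n = int(np.ceil(schedule.duration_s))
    out = np.zeros(n)
    for seg in schedule.segments:
        out[int(seg.start_s) : int(seg.end_s)] = per_state[seg.label]
    return out


def _simulate_session(
    subject_id: str,
    session_id: str,
    schedule: StressorSchedule,
    profiles: dict[StressState, EffectProfile],
    effects: dict,
    var: SubjectVariability,
    rates: SamplingRates,
    rng: np.random.Generator,
) -> SubjectRecording:
    dur = schedule.duration_s
    scale = effects["effect_scale"]

    def targets(attr: str, base: float) -> np.ndarray:
        per_state = {s: base + scale * getattr(p, attr) for s, p in profiles.items()}
        t = _state_series(schedule, per_state)
        return _relax_to_targets(t, var.tau_on_s, var.tau_off_s, base)

    hr = np.clip(targets("hr_delta_bpm", effects["hr_bpm"]), 35.0, 215.0)
    scl = np.maximum(targets("scl_delta_us", effects["scl_us"]), 0.0)
    st = targets("st_delta_c", effects["st_c"])
    ct = targets("crest_shift_ms", effects["ct_ms"])
    scr_rate = np.maximum(
        _state_series(
            schedule,
            {s: effects["scr_rate"] + scale * p.scr_rate_per_min for s, p in profiles.items()},
        ),
        0.0,
    )
    subj_profiles = {
        s: replace(
            p,
            cortisol=replace(
                p.cortisol,
                baseline_nM=p.cortisol.baseline_nM,
                peak_nM=p.cortisol.baseline_nM + scale * p.cortisol.delta_peak(),
            ),
        )
        for s, p in profiles.items()
    }
    seeds = rng.integers(0, 2**31 - 1, size=5)
    channels: dict[str, Channel | SparseChannel] = {
        "ecg": simulate_ecg(dur, hr, rates.ecg, var.ecg_noise_sd, int(seeds[0])),
        "gsr": simulate_gsr(
            dur, scl, scr_rate, effects["scr_amp"], int(seeds[1]), rates.gsr, var.gsr_noise_sd
        ),
        "rap": simulate_rap(dur, hr, ct, 1.0, int(seeds[2]), rates.rap, var.rap_noise_sd),
        "st": simulate_skin_temp(dur, st, var.st_noise_sd, int(seeds[3]), rates.st),
        "cortisol": simulate_cortisol(
            schedule,
            subj_profiles,
            effects["circadian"],
            rates.cortisol_every_s,
            noise_sd=var.cortisol_noise_sd,
            seed=int(seeds[4]),
        ),
    }
    return SubjectRecording(subject_id, session_id, channels, schedule)


def simulate_cohort(
    n_subjects: int = 15,
    n_sessions: int = 2,
    schedule: StressorSchedule | None = None,
    variability: SubjectVariability | None = None,
    profiles: dict[StressState, EffectProfile] | None = None,
    rates: SamplingRates | None = None,
    seed: int = 0,
) -> list[SubjectRecording]:
    """Simulate a cohort of ``n_subjects`` x ``n_sessions`` recordings.

    Subject-level random effects are drawn once per subject and shared across
    that subject's sessions; session-level noise is drawn independently per
    session.  Identical seeds produce bit-identical cohorts.
    """
    schedule = schedule or make_protocol_schedule(5)
    var = variability or SubjectVariability()
    profiles = profiles or default_effect_profiles()
    rates = rates or SamplingRates()
    base = POPULATION_BASELINES
    recordings = []
    subject_seeds = np.random.SeedSequence(seed).spawn(n_subjects)
    for si, sseq in enumerate(subject_seeds):
        session_seeds = sseq.spawn(n_sessions + 1)
        srng = np.random.default_rng(session_seeds[0])
        c_shift = srng.normal(0.0, var.cortisol_baseline_sd)
        effects = {
            "hr_bpm": base["hr_bpm"] + srng.normal(0.0, var.hr_baseline_sd),
            "scl_us": max(base["scl_us"] + srng.normal(0.0, var.scl_baseline_sd), 0.5),
            "st_c": base["st_c"] + srng.normal(0.0, var.st_baseline_sd),
            "ct_ms": base["ct_ms"] + srng.normal(0.0, var.ct_baseline_sd_ms),
            "scr_rate": base["scr_rate_per_min"],
            "scr_amp": base["scr_amp_us"],
            "circadian": (
                base["circadian_nM"][0] + c_shift,
                base["circadian_nM"][1] + c_shift,
            ),
            "effect_scale": max(1.0 + srng.normal(0.0, var.effect_scale_sd), 0.1),
        }
        for sess in range(n_sessions):
            rec = _simulate_session(
                f"S{si + 1:02d}",
                f"sess{sess + 1}",
                schedule,
                profiles,
                effects,
                var,
                rates,
                np.random.default_rng(session_seeds[sess + 1]),
            )
            recordings.append(rec)
    return recordings


# ---------------------------------------------------------------------------
# cohort directory I/O
# ---------------------------------------------------------------------------

def write_cohort(out_dir: str | Path, recordings: list[SubjectRecording]) -> Path:
    """Write a cohort as one directory per session with CSV channels.

    Layout: ``<out>/<subject>_<session>/{ecg,gsr,rap,st,cortisol}.csv`` with
    ``time_s,value`` columns, a ``schedule.json`` per session, and a cohort
    ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"sessions": []}
    for rec in recordings:
        sdir = out / f"{rec.subject_id}_{rec.session_id}"
        sdir.mkdir(exist_ok=True)
        meta = {}
        for name, ch in rec.channels.items():
            if isinstance(ch, Channel):
                df = pd.DataFrame({"time_s": ch.times_s, "value": ch.samples})
                meta[name] = {"sampling_rate": ch.sampling_rate, "units": ch.units}
            else:
                df = pd.DataFrame({"time_s": ch.times_s, "value": ch.values})
                meta[name] = {"sampling_rate": None, "units": ch.units}
            df.to_csv(sdir / f"{name}.csv", index=False)
        (sdir / "schedule.json").write_text(json.dumps(rec.schedule.to_records()))
        manifest["sessions"].append(
            {
                "subject_id": rec.subject_id,
                "session_id": rec.session_id,
                "path": sdir.name,
                "channels": meta,
            }
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def read_cohort(in_dir: str | Path) -> list[SubjectRecording]:
    """Read a cohort directory written by :func:`write_cohort`."""
    root = Path(in_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    recordings = []
    for sess in manifest["sessions"]:
        sdir = root / sess["path"]
        schedule = StressorSchedule.from_records(json.loads((sdir / "schedule.json").read_text()))
        channels: dict[str, Channel | SparseChannel] = {}
        for name, meta in sess["channels"].items():
            df = pd.read_csv(sdir / f"{name}.csv")
            if meta["sampling_rate"] is None:
                channels[name] = SparseChannel(df["time_s"].values, df["value"].values, meta["units"])
            else:
                channels[name] = Channel(df["value"].values, meta["sampling_rate"], meta["units"])
        recordings.append(
            SubjectRecording(sess["subject_id"], sess["session_id"], channels, schedule)
        )
    return recordings
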
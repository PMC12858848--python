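"""Physiological feature extraction from raw channels.

Heart rate from ECG R peaks, tonic/phasic electrodermal decomposition with
SCR event detection, per-pulse crest time and amplitude from the
radial-artery pulse, wavelet power spectra, the 30-s moving-average
smoother, and quadratic interpolation of the sparse cortisol channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import interpolate, signal

from multistress.simulate import Channel, SparseChannel


# ---------------------------------------------------------------------------
# ECG
# ---------------------------------------------------------------------------

@dataclass
class BeatSeries:
    """R-peak times plus instantaneous heart rate per beat pair."""

    r_peak_times_s: np.ndarray
    hr_bpm_series: np.ndarray  # 60 / RR for each consecutive peak pair
    mean_hr: float

    def __len__(self) -> int:
        return len(self.r_peak_times_s)


def detect_r_peaks(ecg: Channel, refractory_s: float = 0.25) -> BeatSeries:
    """Detect R peaks by squared-derivative energy with a refractory period.

    The differentiated, squared, window-integrated signal highlights QRS
    energy regardless of baseline offset; peaks are kept only above an
    adaptive threshold and at least ``refractory_s`` apart, then refined to
    the local ECG maximum.
    """
    fs = ecg.sampling_rate
    if fs < 64:
        raise ValueError("sampling rate must be >= 64 Hz to resolve R peaks")
    x = ecg.samples
    if len(x) < int(0.5 * fs) or np.ptp(x) == 0:
        return BeatSeries(np.array([]), np.array([]), float("nan"))
    d = np.diff(x, prepend=x[0])
    energy = np.convolve(d * d, np.ones(max(int(0.08 * fs), 1)), mode="same")
    thr = 0.3 * np.percentile(energy, 99)
    if thr <= 0:
        return BeatSeries(np.array([]), np.array([]), float("nan"))
    locs, _ = signal.find_peaks(energy, height=thr, distance=int(refractory_s * fs))
    # refine each detection to the nearby raw-signal maximum (the R peak)
    half = max(int(0.05 * fs), 1)
    peaks = []
    for loc in locs:
        lo, hi = max(loc - half, 0), min(loc + half + 1, len(x))
        peaks.append(lo + int(np.argmax(x[lo:hi])))
    peaks = np.unique(peaks)
    times = peaks / fs
    if len(times) < 2:
        return BeatSeries(times, np.array([]), float("nan"))
    rr = np.diff(times)
    hr = 60.0 / rr
    return BeatSeries(times, hr, float(np.mean(hr)))


# ---------------------------------------------------------------------------
# EDA
# ---------------------------------------------------------------------------

@dataclass
class EdaDecomposition:
    """Additive tonic (SCL) + phasic (SCR) split of a skin-conductance channel."""

    tonic: np.ndarray
    phasic: np.ndarray
    scr_events: list[tuple[float, float]]  # (onset_s, amplitude_uS)
    sampling_rate: float

    @property
    def scr_rate_per_min(self) -> float:
        dur_min = len(self.tonic) / self.sampling_rate / 60.0
        return len(self.scr_events) / dur_min if dur_min > 0 else 0.0


def decompose_eda(
    gsr: Channel,
    tonic_cutoff_Hz: float = 0.05,
    scr_slope_threshold: float = 0.08,
    min_event_gap_s: float = 0.5,
) -> EdaDecomposition:
    """Split skin conductance into tonic and phasic parts and find SCR events.

    Tonic is the zero-phase low-pass component below ``tonic_cutoff_Hz``;
    phasic is the exact residual (tonic + phasic reproduces the input to
    machine precision).  SCR onsets are detected as peaks of the smoothed
    phasic *derivative* above ``scr_slope_threshold`` (µS/s) separated by at
    least ``min_event_gap_s`` — rise-based detection resolves responses
    whose decays overlap, which plain phasic-peak picking merges.  Each
    event's amplitude is the phasic excursion from onset to the next local
    maximum.
    """
    fs = gsr.sampling_rate
    if tonic_cutoff_Hz >= fs / 2:
        raise ValueError("tonic cutoff must be below the Nyquist frequency")
    x = gsr.samples
    if np.ptp(x) == 0:
        tonic = x.copy()
    else:
        sos = signal.butter(4, tonic_cutoff_Hz, btype="low", fs=fs, output="sos")
        tonic = signal.sosfiltfilt(sos, x)
    phasic = x - tonic
    k = max(int(0.1 * fs), 1)
    d = np.convolve(np.gradient(phasic) * fs, np.ones(k) / k, mode="same")
    locs, _ = signal.find_peaks(
        d, height=scr_slope_threshold, distance=max(int(min_event_gap_s * fs), 1)
    )
    events = []
    horizon = int(3.0 * fs)
    for l in locs:
        seg = phasic[l : l + horizon]
        amp = float(seg.max() - phasic[max(l - int(0.5 * fs), 0)]) if len(seg) else 0.0
        events.append((float(l / fs), amp))
    return EdaDecomposition(tonic, phasic, events, fs)


# ---------------------------------------------------------------------------
# pulse waveform
# ---------------------------------------------------------------------------

@dataclass
class PulseFeatures:
    """Per-pulse landmarks of the radial-artery pulse waveform."""

    crest_time_ms: np.ndarray        # foot -> percussion peak, per pulse
    amplitude: np.ndarray            # foot -> peak height
    p_times_s: np.ndarray            # percussion peak times
    t_times_s: np.ndarray            # tidal wave times (nan when absent)
    d_times_s: np.ndarray            # dicrotic wave times (nan when absent)
    foot_times_s: np.ndarray

    @property
    def mean_crest_time_ms(self) -> float:
        return float(np.nanmean(self.crest_time_ms)) if len(self.crest_time_ms) else float("nan")


def _tangent_foot(seg: np.ndarray, fs: float, baseline: float) -> float:
    """Intersecting-tangent pulse foot: tangent at the steepest upstroke
    sample, intersected with the pre-pulse baseline."""
    d = np.diff(seg)
    k = int(np.argmax(d))
    slope = d[k] * fs
    if slope <= 0:
        return 0.0
    return max(k / fs - (seg[k] - baseline) / slope, 0.0)


def pulse_features(
    rap: Channel, beat_anchors_s: np.ndarray, search_s: float = 0.45
) -> PulseFeatures:
    """Extract crest time, amplitude, and P/T/D landmarks per pulse.

    ``beat_anchors_s`` are approximate pulse-onset times (e.g. from the ECG
    beat clock or the pulse channel's own troughs).  Within each beat the
    percussion peak is the first prominent maximum; the foot is located by
    the intersecting-tangent method; tidal and dicrotic waves are later
    local maxima of the decay and are flagged absent (NaN) when not found.
    """
    fs = rap.sampling_rate
    x = rap.samples
    ct, amp, pt, tt, dt, ft = [], [], [], [], [], []
    for tb in np.asarray(beat_anchors_s, dtype=float):
        i0 = int(round(tb * fs))
        i1 = min(i0 + int(1.0 * fs), len(x))
        if i1 - i0 < int(0.2 * fs):
            continue
        seg = x[i0:i1]
        baseline = float(seg[0])
        up_end = min(int(search_s * fs), len(seg) - 1)
        p_idx = int(np.argmax(seg[:up_end]))
        if seg[p_idx] - baseline <= 0:
            continue
        foot = _tangent_foot(seg[: p_idx + 1], fs, baseline)
        ct.append((p_idx / fs - foot) * 1000.0)
        amp.append(float(seg[p_idx] - baseline))
        pt.append(tb + p_idx / fs)
        ft.append(tb + foot)
        # tidal and dicrotic: local maxima of the post-percussion decay
        tail = seg[p_idx:]
        locs, _ = signal.find_peaks(tail, prominence=0.01 * (seg[p_idx] - baseline))
        if len(locs) >= 1:
            tt.append(tb + (p_idx + locs[0]) / fs)
        else:
            tt.append(float("nan"))
        if len(locs) >= 2:
            dt.append(tb + (p_idx + locs[1]) / fs)
        else:
            dt.append(float("nan"))
    return PulseFeatures(
        np.asarray(ct), np.asarray(amp), np.asarray(pt),
        np.asarray(tt), np.asarray(dt), np.asarray(ft),
    )


# ---------------------------------------------------------------------------
# spectra, smoothing, interpolation
# ---------------------------------------------------------------------------

def wavelet_power_spectrum(
    channel: Channel,
    freqs_Hz: np.ndarray | None = None,
    wavelet: str = "morl",
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous-wavelet power map |CWT|² on a frequency grid.

    Returns ``(freqs_Hz, power)`` with ``power`` of shape
    ``(n_freqs, n_samples)``.  Default grid: 64 log-spaced frequencies from
    0.1 to 8 Hz (clipped below Nyquist).
    """
    fs = channel.sampling_rate
    if freqs_Hz is None:
        freqs_Hz = np.geomspace(0.1, min(8.0, 0.45 * fs), 64)
    freqs_Hz = np.asarray(freqs_Hz, dtype=float)
    if np.any(freqs_Hz >= fs / 2):
        raise ValueError("requested frequencies must be below the Nyquist frequency")
    if np.any(freqs_Hz <= 0):
        raise ValueError("frequencies must be positive")
    scales = pywt.frequency2scale(wavelet, freqs_Hz / fs)
    coef, _ = pywt.cwt(channel.samples, scales, wavelet, sampling_period=1.0 / fs)
    return freqs_Hz, np.abs(coef) ** 2


def moving_average(series: np.ndarray, window_s: float = 30.0, sampling_rate: float = 1.0) -> np.ndarray:
    """Centered moving average with edge truncation.

    At the edges the window is truncated to the available samples, so a
    constant series passes through unchanged everywhere.
    """
    x = np.asarray(series, dtype=float)
    w = max(int(round(window_s * sampling_rate)), 1)
    if w == 1 or len(x) == 0:
        return x.copy()
    kernel = np.ones(w)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def interpolate_cortisol(
    sparse: SparseChannel, target_times_s: np.ndarray
) -> np.ndarray:
    """Quadratic-spline interpolation of the sparse cortisol channel.

    Exact at the measurement knots.  With fewer than three samples a linear
    fallback is used (with a warning); queries outside the sampled span are
    held at the nearest sample.
    """
    t, v = sparse.times_s, sparse.values
    tq = np.asarray(target_times_s, dtype=float)
    if len(t) == 0:
        raise ValueError("cannot interpolate an empty cortisol channel")
    if len(t) == 1:
        return np.full_like(tq, v[0], dtype=float)
    kind = "quadratic"
    if len(t) < 3:
        warnings.warn("fewer than 3 cortisol samples: falling back to linear", stacklevel=2)
        kind = "linear"
    f = interpolate.interp1d(
        t, v, kind=kind, bounds_error=False, fill_value=(v[0], v[-1])
    )
    return f(tq)


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------

def extract_feature_table(recording, smooth_s: float = 30.0):
    """Per-second feature table for one recording.

    Columns: ``t_s, feature, value, state_label``.  Features: hr_bpm, scl_uS,
    scr_rate_per_min (per 60-s sliding count), crest_time_ms, st_degC,
    cortisol_nM (quadratic-interpolated), each smoothed with a centered
    ``smooth_s`` moving average.
    """
    import pandas as pd

    dur = int(recording.channels["ecg"].duration_s)
    t_grid = np.arange(dur, dtype=float)

    beats = detect_r_peaks(recording.channels["ecg"])
    hr = np.interp(t_grid, beats.r_peak_times_s[1:], beats.hr_bpm_series) if len(beats) > 2 else np.full(dur, np.nan)

    eda = decompose_eda(recording.channels["gsr"])
    fs_g = recording.channels["gsr"].sampling_rate
    scl = eda.tonic[np.minimum((t_grid * fs_g).astype(int), len(eda.tonic) - 1)]
    ev_times = np.array([e[0] for e in eda.scr_events])
    scr_rate = np.array([np.sum(np.abs(ev_times - tc) <= 30.0) for tc in t_grid]) if len(ev_times) else np.zeros(dur)

    pulses = pulse_features(recording.channels["rap"], beats.r_peak_times_s)
    ctv = (
        np.interp(t_grid, pulses.foot_times_s, pulses.crest_time_ms)
        if len(pulses.crest_time_ms) > 2
        else np.full(dur, np.nan)
    )

    st_ch = recording.channels["st"]
    st = np.interp(t_grid, st_ch.times_s, st_ch.samples)
    cort = interpolate_cortisol(recording.channels["cortisol"], t_grid)

    rows = []
    feats = {
        "hr_bpm": hr, "scl_uS": scl, "scr_rate_per_min": scr_rate,
        "crest_time_ms": ctv, "st_degC": st, "cortisol_nM": cort,
    }
    for name, series in feats.items():
        sm = moving_average(series, smooth_s, 1.0)
        for t, val in zip(t_grid, sm):
            lbl = recording.schedule.label_at(t)
            rows.append((t, name, val, lbl.value if lbl else ""))
    return pd.DataFrame(rows, columns=["t_s", "feature", "value", "state_label"])
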
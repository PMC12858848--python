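"""Forward/inverse models of the three bespoke wearable sensors.

* MIP cortisol electrode: log-linear chronoamperometric calibration
  (current decreases linearly with log10 concentration) plus the
  electrochemical restoration state machine that tracks sensor reuse.
* Piezoresistive pulse sensor: piecewise-linear relative-current response
  (ΔI/I0) versus applied pressure, with decreasing per-range sensitivity at
  higher pressures (microstructure densification).
* Electrode-skin interface: two parallel-RC stages (contact layer and
  stratum corneum) in series with the bulk tissue resistance.

Only the scalar outcomes the analysis pipeline consumes are modeled; no
electrochemical kinetics or voltammetric waveforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

#: Concentration range the MIP electrode senses (1 nM to 10 µM).
MIP_VALID_RANGE_NM = (1.0, 10_000.0)
#: Sensitivity of the MIP electrode in PBS, µA per decade of nM.
MIP_SENSITIVITY_PBS = 0.2447
#: Near-zero sensitivity of the non-imprinted (NIP) control electrode.
NIP_SENSITIVITY = 0.005
#: Restoration potential applied to strip bound cortisol (V vs reference).
RESTORATION_VOLTAGE_V = -0.5
#: Drift criterion: relative SD of blank currents across restoration cycles.
RESTORATION_RSD_LIMIT = 0.05


# ---------------------------------------------------------------------------
# MIP cortisol calibration
# ---------------------------------------------------------------------------

@dataclass
class MipCalibration:
    """Log-linear calibration: I(µA) = intercept − sensitivity · log10(c/nM)."""

    sensitivity: float = MIP_SENSITIVITY_PBS
    intercept: float = 10.0
    r_squared: float = 1.0
    valid_range_nM: tuple[float, float] = MIP_VALID_RANGE_NM

    def __post_init__(self) -> None:
        if self.sensitivity < 0:
            raise ValueError("sensitivity is a slope magnitude and must be >= 0")
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValueError("r_squared must lie in [0, 1]")


def mip_forward(concentration_nM, calib: MipCalibration) -> np.ndarray | float:
    """Electrode current (µA) for a cortisol concentration (nM)."""
    c = np.asarray(concentration_nM, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentration must be positive")
    out = calib.intercept - calib.sensitivity * np.log10(c)
    return float(out) if out.ndim == 0 else out


def cortisol_from_current(current_uA, calib: MipCalibration) -> np.ndarray | float:
    """Invert the calibration: concentration (nM) from current (µA).

    Concentrations outside the sensed range are clamped with a warning
    rather than extrapolated.
    """
    if calib.sensitivity == 0:
        raise ValueError("cannot invert a zero-sensitivity calibration")
    i = np.asarray(current_uA, dtype=float)
    c = 10.0 ** ((calib.intercept - i) / calib.sensitivity)
    lo, hi = calib.valid_range_nM
    if np.any(c < lo) or np.any(c > hi):
        warnings.warn(
            "inverted concentration outside the sensed range; clamping", stacklevel=2
        )
        c = np.clip(c, lo, hi)
    return float(c) if c.ndim == 0 else c


def fit_mip_calibration(concentrations_nM, currents_uA) -> MipCalibration:
    """Ordinary least squares of current vs log10(concentration).

    Reports the slope magnitude as the sensitivity (the raw slope is
    negative: current falls with concentration) and the squared correlation
    as the fit quality.
    """
    c = np.asarray(concentrations_nM, dtype=float)
    i = np.asarray(currents_uA, dtype=float)
    if len(c) != len(i) or len(c) < 2:
        raise ValueError("need >= 2 paired calibration points")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    x = np.log10(c)
    if np.ptp(x) == 0:
        raise ValueError("all concentrations equal: calibration is rank-deficient")
    res = stats.linregress(x, i)
    r2 = float(res.rvalue**2)
    if np.isnan(r2):  # zero current variance: a flat line fits exactly
        r2 = 1.0 if np.ptp(i) == 0 else 0.0
    return MipCalibration(
        sensitivity=abs(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
    )


# ---------------------------------------------------------------------------
# restoration state machine
# ---------------------------------------------------------------------------

@dataclass
class RestorationState:
    """Tracks electrochemical restoration cycles of a reusable MIP electrode.

    ``restored`` means the latest blank current returned to within
    ``tolerance`` of the initial blank; ``drift_flag`` is raised when the
    relative SD of blank currents across cycles exceeds 5%.
    """

    initial_blank_current: float
    cycle_count: int = 0
    last_blank_current: float = 0.0
    recovery_ratio: float = 1.0
    restored: bool = True
    drift_flag: bool = False
    blank_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.initial_blank_current <= 0:
            raise ValueError("initial blank current must be positive")


def restoration_step(
    state: RestorationState, measured_blank_current: float, tolerance: float = 0.05
) -> RestorationState:
    """Record one restoration cycle and re-evaluate recovery and drift."""
    if measured_blank_current <= 0:
        raise ValueError("blank current must be positive")
    history = state.blank_history + [float(measured_blank_current)]
    ratio = measured_blank_current / state.initial_blank_current
    drift = False
    if len(history) >= 2:
        h = np.asarray(history)
        drift = float(np.std(h, ddof=1) / np.mean(h)) > RESTORATION_RSD_LIMIT
    return replace(
        state,
        cycle_count=state.cycle_count + 1,
        last_blank_current=float(measured_blank_current),
        recovery_ratio=float(ratio),
        restored=bool(abs(ratio - 1.0) <= tolerance),
        drift_flag=drift,
        blank_history=history,
    )


# ---------------------------------------------------------------------------
# piezoresistive pulse (RAP) sensor
# ---------------------------------------------------------------------------

@dataclass
class RapSensitivity:
    """Piecewise pressure sensitivity S = (ΔI/I0)/ΔP of the pulse sensor.

    Sensitivities are per-range slopes (kPa⁻¹) over consecutive pressure
    ranges; they must be non-increasing, reflecting microstructure
    densification at higher pressures.
    """

    breakpoints_kPa: tuple[float, ...] = (0.0, 100.0, 200.0, 340.0)
    sensitivities: tuple[float, ...] = (6.30, 4.55, 3.14)
    i0: float = 1.0

    def __post_init__(self) -> None:
        if len(self.sensitivities) != len(self.breakpoints_kPa) - 1:
            raise ValueError("need one sensitivity per pressure range")
        s = self.sensitivities
        if any(x <= 0 for x in s) or any(b > a for a, b in zip(s, s[1:])):
            raise ValueError("sensitivities must be positive and non-increasing")


def rap_response(pressure_kPa, model: RapSensitivity | None = None) -> np.ndarray | float:
    """Relative current change ΔI/I0 at an applied pressure (kPa).

    Continuous piecewise-linear: the response accumulates each range's
    sensitivity times the portion of the pressure falling in that range.
    """
    model = model or RapSensitivity()
    p = np.asarray(pressure_kPa, dtype=float)
    lo, hi = model.breakpoints_kPa[0], model.breakpoints_kPa[-1]
    if np.any(p < lo) or np.any(p > hi):
        raise ValueError(f"pressure must lie within [{lo}, {hi}] kPa")
    out = np.zeros_like(p)
    for (b0, b1), s in zip(
        zip(model.breakpoints_kPa, model.breakpoints_kPa[1:]), model.sensitivities
    ):
        out += s * np.clip(p - b0, 0.0, b1 - b0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# electrode-skin interface impedance
# ---------------------------------------------------------------------------

@dataclass
class SkinInterfaceModel:
    """Two parallel-RC stages (contact, stratum corneum) + tissue resistance.

    Default values are configuration placeholders of plausible magnitude,
    not characterized constants; fit them to measured spectra before use.
    """

    r_contact_ohm: float = 10e3
    c_contact_f: float = 100e-9
    r_sc_ohm: float = 100e3
    c_sc_f: float = 10e-9
    r_tissue_ohm: float = 500.0

    def __post_init__(self) -> None:
        vals = (self.r_contact_ohm, self.c_contact_f, self.r_sc_ohm, self.c_sc_f, self.r_tissue_ohm)
        if any(v <= 0 for v in vals):
            raise ValueError("all circuit parameters must be positive")


def skin_impedance(frequency_Hz, model: SkinInterfaceModel | None = None) -> np.ndarray | complex:
    """Complex impedance Z(f) = (R_C ∥ C_C) + (R_sp ∥ C_sp) + R_tissue (Ω)."""
    model = model or SkinInterfaceModel()
    scalar = np.ndim(frequency_Hz) == 0
    f = np.atleast_1d(np.asarray(frequency_Hz, dtype=float))
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    w = 2.0 * np.pi * f
    z_c = model.r_contact_ohm / (1.0 + 1j * w * model.r_contact_ohm * model.c_contact_f)
    z_sc = model.r_sc_ohm / (1.0 + 1j * w * model.r_sc_ohm * model.c_sc_f)
    z = z_c + z_sc + model.r_tissue_ohm
    return complex(z[0]) if scalar else z
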
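"""Two-state DSC thermogram analysis.

A reversible two-state unfolding equilibrium F <-> U with van't Hoff
enthalpy dH_vH and midpoint Tm has equilibrium constant

    K(T) = exp[-(dH_vH/R) (1/T - 1/Tm)]

and produces the excess molar heat capacity

    Cp_exc(T) = (dH_cal * dH_vH / (R T^2)) * K / (1 + K)^2

where dH_cal is the calorimetric enthalpy.  The defining conservation law is
integral(Cp_exc dT) = dH_cal over any window covering the transition; Tm is
the temperature of the Cp_exc maximum (to within a tiny skew term of order
RT/dH_vH).  dH_cal and dH_vH are kept independent in the fit so that
non-two-state behaviour (dH_vH != dH_cal, e.g. unfolding coupled to oligomer
dissociation) is visible as a ratio different from one.

Temperatures are kelvin internally; all I/O and reporting is in Celsius.
Energies are kcal/mol with R = 1.9872e-3 kcal mol^-1 K^-1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "GAS_CONSTANT_KCAL",
    "CELSIUS_OFFSET",
    "Thermogram",
    "TwoStateModel",
    "TwoStateFit",
    "excess_cp",
    "integrate_enthalpy",
    "find_tm",
    "fit_twostate",
]

GAS_CONSTANT_KCAL = 1.9872e-3  # kcal mol^-1 K^-1
CELSIUS_OFFSET = 273.15


@dataclass(frozen=True)
class TwoStateModel:
    """Two-state transition: Tm (K), enthalpies (kcal/mol), linear baseline.

    The baseline is ``slope * (T - Tm) + intercept`` in kcal mol^-1 K^-1,
    anchored at Tm so slope and intercept stay numerically decoupled.
    """

    tm_K: float
    dh_vh: float
    dh_cal: float
    baseline_slope: float = 0.0
    baseline_intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.tm_K <= 0:
            raise ValueError("Tm must be positive (kelvin)")
        if self.dh_vh <= 0:
            raise ValueError("van't Hoff enthalpy must be positive for unfolding")

    @property
    def tm_C(self) -> float:
        return self.tm_K - CELSIUS_OFFSET

    def baseline(self, temperature_K: np.ndarray) -> np.ndarray:
        t = np.asarray(temperature_K, dtype=float)
        return self.baseline_slope * (t - self.tm_K) + self.baseline_intercept


@dataclass(frozen=True)
class Thermogram:
    """DSC scan: strictly increasing temperatures (K) and molar Cp (kcal/mol/K)."""

    temperature_K: np.ndarray
    cp: np.ndarray
    scan_rate_C_per_h: Optional[float] = None
    concentration_uM: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "temperature_K", np.asarray(self.temperature_K, dtype=float))
        object.__setattr__(self, "cp", np.asarray(self.cp, dtype=float))
        if self.temperature_K.size != self.cp.size:
            raise ValueError("temperature and Cp arrays must have equal length")
        if self.temperature_K.size < 10:
            raise ValueError("need at least 10 points across the scan")
        if np.any(np.diff(self.temperature_K) <= 0):
            raise ValueError("temperatures must be strictly increasing")

    @property
    def temperature_C(self) -> np.ndarray:
        return self.temperature_K - CELSIUS_OFFSET


@dataclass(frozen=True)
class TwoStateFit:
    """Fitted model plus goodness-of-fit; ``converged=False`` carries the
    initial estimates instead of fitted values."""

    model: TwoStateModel
    rms_residual: float
    converged: bool
    truncated: bool = False


def excess_cp(model: TwoStateModel, temperature_K: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
    """Excess heat capacity of the two-state transition at T (kelvin).

    Cp_exc = (dH_cal dH_vH / (R T^2)) K/(1+K)^2 with
    K = exp[-(dH_vH/R)(1/T - 1/Tm)].  At T = Tm the unfolded fraction is 1/2
    and Cp_exc = dH_cal dH_vH / (4 R Tm^2).
    """
    t = np.asarray(temperature_K, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    ln_k = -(model.dh_vh / GAS_CONSTANT_KCAL) * (1.0 / t - 1.0 / model.tm_K)
    # K/(1+K)^2 = 1/(4 cosh^2(lnK/2)) is overflow-safe far from Tm
    sech2 = 1.0 / np.cosh(np.clip(ln_k / 2.0, -350, 350)) ** 2
    out = (model.dh_cal * model.dh_vh / (GAS_CONSTANT_KCAL * t**2)) * sech2 / 4.0
    return float(out) if np.isscalar(temperature_K) else out


def _auto_baseline(thermogram: Thermogram, flank_fraction: float = 0.15) -> np.ndarray:
    """Linear baseline from pre- and post-transition segments.

    Starts from the outer ``flank_fraction`` of the scan, then iteratively
    excludes the contiguous transition region (baseline-subtracted Cp above
    1% of the peak) and refits, so the transition's exponential tails do not
    bias the baseline into the peak area.
    """
    t, cp = thermogram.temperature_K, thermogram.cp
    n = t.size
    k = max(int(round(flank_fraction * n)), 5)
    if 2 * k > n:
        raise ValueError("scan too short to determine flank baseline")
    mask = np.zeros(n, dtype=bool)
    mask[:k] = mask[n - k :] = True
    coeff = np.polyfit(t[mask], cp[mask], 1)
    n_min = max(5, n // 50)  # points to keep per flank no matter what
    for _ in range(3):
        excess = cp - np.polyval(coeff, t)
        peak_i = int(np.argmax(excess))
        peak = excess[peak_i]
        if peak <= 0:
            break
        # grow the excluded transition region until the tail drops below
        # 0.1% of the peak (or the flank would vanish)
        lo = peak_i
        while lo > n_min and excess[lo - 1] > 0.001 * peak:
            lo -= 1
        hi = peak_i
        while hi < n - 1 - n_min and excess[hi + 1] > 0.001 * peak:
            hi += 1
        keep = np.ones(n, dtype=bool)
        keep[lo : hi + 1] = False
        coeff = np.polyfit(t[keep], cp[keep], 1)
    return np.polyval(coeff, t)


def _baseline_values(
    thermogram: Thermogram,
    baseline: Union[str, TwoStateModel, np.ndarray, float],
) -> np.ndarray:
    if isinstance(baseline, str):
        if baseline != "auto":
            raise ValueError(f"unknown baseline mode {baseline!r}")
        return _auto_baseline(thermogram)
    if isinstance(baseline, TwoStateModel):
        return baseline.baseline(thermogram.temperature_K)
    return np.broadcast_to(
        np.asarray(baseline, dtype=float), thermogram.temperature_K.shape
    ).copy()


def integrate_enthalpy(
    thermogram: Thermogram,
    baseline: Union[str, TwoStateModel, np.ndarray, float] = "auto",
) -> float:
    """Calorimetric enthalpy dH_cal = trapezoidal integral of (Cp - baseline).

    ``baseline`` may be "auto" (linear fit to the outer 15% flanks), a
    TwoStateModel whose baseline is used, an explicit array, or a constant.
    A transition truncated by the scan window (peak within 3 points of an
    edge) is integrated anyway but logged as unreliable.
    """
    base = _baseline_values(thermogram, baseline)
    excess = thermogram.cp - base
    peak = int(np.argmax(excess))
    if peak < 3 or peak >= excess.size - 3:
        logger.warning("transition peak within 3 points of the scan edge; enthalpy unreliable")
    return float(np.trapezoid(excess, thermogram.temperature_K))


def find_tm(
    thermogram: Thermogram,
    baseline: Union[str, TwoStateModel, np.ndarray, float] = "auto",
) -> float:
    """Transition temperature (Celsius): maximum of baseline-subtracted Cp.

    The grid maximum is refined by parabolic interpolation through the three
    surrounding points.  A thermogram whose maximum sits on the scan edge
    has no interior transition and raises ValueError.
    """
    base = _baseline_values(thermogram, baseline)
    excess = thermogram.cp - base
    i = int(np.argmax(excess))
    if i == 0 or i == excess.size - 1:
        raise ValueError("no interior maximum: thermogram has no transition in the window")
    t0, t1, t2 = thermogram.temperature_K[i - 1 : i + 2]
    y0, y1, y2 = excess[i - 1 : i + 2]
    denom = (y0 - 2.0 * y1 + y2)
    if denom == 0:
        tm_K = t1
    else:
        # vertex of the parabola through three (approximately equispaced) points
        tm_K = t1 + 0.5 * (y0 - y2) / denom * (t2 - t0) / 2.0
    return float(tm_K - CELSIUS_OFFSET)


def fit_twostate(thermogram: Thermogram, max_restarts: int = 3) -> TwoStateFit:
    """Nonlinear least-squares fit of baseline + excess_cp to a thermogram.

    Free parameters: Tm, dH_vH, dH_cal, baseline slope and intercept.
    Initialisation uses :func:`find_tm` and :func:`integrate_enthalpy` with
    the automatic flank baseline, and dH_vH = dH_cal.  On non-convergence
    the fit is retried from perturbed starts up to ``max_restarts`` times;
    persistent failure returns the initial estimates flagged
    ``converged=False``.
    """
    t = thermogram.temperature_K
    tm0_K = find_tm(thermogram) + CELSIUS_OFFSET
    dh0 = integrate_enthalpy(thermogram)
    if dh0 <= 0:
        dh0 = 10.0
    base0 = _auto_baseline(thermogram)
    slope0 = (base0[-1] - base0[0]) / (t[-1] - t[0])
    intercept0 = float(np.interp(tm0_K, t, base0))

    def residuals(p: np.ndarray) -> np.ndarray:
        tm, dh_vh, dh_cal, slope, intercept = p
        model = TwoStateModel(tm, dh_vh, dh_cal, slope, intercept)
        return model.baseline(t) + excess_cp(model, t) - thermogram.cp

    lb = [t[0] - 50.0, 1.0, -np.inf, -np.inf, -np.inf]
    ub = [t[-1] + 50.0, 5000.0, np.inf, np.inf, np.inf]
    x0 = np.array([tm0_K, dh0, dh0, slope0, intercept0])
    x0 = np.clip(x0, lb, ub)

    rng = np.random.default_rng(0)
    best = None
    for attempt in range(max_restarts + 1):
        start = x0 if attempt == 0 else x0 * rng.uniform(0.9, 1.1, size=x0.size)
        start = np.clip(start, lb, ub)
        sol = least_squares(residuals, start, bounds=(lb, ub), method="trf")
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
        if best is not None and attempt == 0:
            break

    peak = int(np.argmax(thermogram.cp - base0))
    truncated = peak < 3 or peak >= t.size - 3

    if best is None:
        logger.warning("two-state fit failed to converge; returning initial estimates")
        model = TwoStateModel(tm0_K, dh0, dh0, slope0, intercept0)
        rms = float(np.sqrt(np.mean(residuals(x0) ** 2)))
        return TwoStateFit(model=model, rms_residual=rms, converged=False, truncated=truncated)

    tm, dh_vh, dh_cal, slope, intercept = best.x
    model = TwoStateModel(tm, dh_vh, dh_cal, slope, intercept)
    rms = float(np.sqrt(np.mean(best.fun**2)))
    return TwoStateFit(model=model, rms_residual=rms, converged=True, truncated=truncated)
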
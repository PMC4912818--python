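"""Off-line assay computations: viability, heat-shock t₅₀, fermentative capacity.

Heat-shock robustness is summarized by t₅₀ — the incubation time at
53 °C after which half of the initially viable population is still
alive — obtained by fitting a four-parameter logistic (4PL)
dose–response curve in time to PI-based survival data. Fermentative
capacity is the anaerobic ethanol production rate upon glucose excess,
taken as the ordinary-least-squares slope of ethanol amount versus time
over the first 30 min, per gram of biomass in the assay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

__all__ = [
    "ETHANOL_MOLAR_MASS",
    "SurvivalCurve",
    "FermentativeAssay",
    "T50FitError",
    "viability_from_pi_counts",
    "cfu_viability",
    "viable_biomass",
    "HeatShockT50Estimator",
    "fit_heat_shock_t50",
    "FermentativeCapacityEstimator",
    "fermentative_capacity",
]

#: Molar mass of ethanol, g mol⁻¹.
ETHANOL_MOLAR_MASS = 46.07


class T50FitError(RuntimeError):
    """Survival-curve fit failed or the curve has no 50 % crossing."""


@dataclass(frozen=True)
class SurvivalCurve:
    """Heat-shock survival series: viable fraction relative to t = 0."""

    times: np.ndarray      # min
    fractions: np.ndarray  # in [0, 1]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fractions", f)
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError("times and fractions must be equal-length 1-D")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((f < 0) | (f > 1)):
            raise ValueError("fractions must lie in [0, 1]")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurvivalCurve":
        return cls(
            times=df["time_min"].to_numpy(), fractions=df["viable_fraction"].to_numpy()
        )


@dataclass(frozen=True)
class FermentativeAssay:
    """Ethanol accumulation series from a fermentative-capacity assay."""

    times: np.ndarray          # min
    ethanol: np.ndarray        # concentration in declared unit
    biomass_g: float           # g dry weight in the assay
    assay_volume_l: float = 0.07
    ethanol_unit: str = "mM"   # "mM" or "g_per_L"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.ethanol, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "ethanol", e)
        if t.shape != e.shape or t.ndim != 1:
            raise ValueError("times and ethanol must be equal-length 1-D")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(e < 0):
            raise ValueError("ethanol concentrations must be >= 0")
        if self.biomass_g <= 0 or self.assay_volume_l <= 0:
            raise ValueError("biomass_g and assay_volume_l must be > 0")
        if self.ethanol_unit not in ("mM", "g_per_L"):
            raise ValueError("ethanol_unit must be 'mM' or 'g_per_L'")

    @property
    def ethanol_mmol(self) -> np.ndarray:
        """Ethanol amount in the assay, mmol."""
        if self.ethanol_unit == "mM":
            conc_mm = self.ethanol
        else:  # g/L → mM
            conc_mm = self.ethanol / ETHANOL_MOLAR_MASS * 1000.0
        return conc_mm * self.assay_volume_l


# ----------------------------------------------------------------- viability

def viability_from_pi_counts(pi_positive_count: int, total_count: int) -> float:
    """PI viability: fraction of cells excluding propidium iodide."""
    if total_count <= 0:
        raise ValueError("total_count must be > 0")
    if pi_positive_count < 0 or pi_positive_count > total_count:
        raise ValueError("pi_positive_count must be in [0, total_count]")
    return 1.0 - pi_positive_count / total_count


def cfu_viability(cfu_per_ml: float, cells_per_ml: float) -> float:
    """CFU-based viability: colony-forming units over total cell count."""
    if cells_per_ml <= 0:
        raise ValueError("cells_per_ml must be > 0")
    if cfu_per_ml < 0:
        raise ValueError("cfu_per_ml must be >= 0")
    frac = cfu_per_ml / cells_per_ml
    if frac > 1.0:
        warnings.warn(
            "CFU count exceeds total cell count; viability clipped to 1",
            RuntimeWarning,
            stacklevel=2,
        )
        frac = 1.0
    return frac


def viable_biomass(
    dry_weight: float | np.ndarray, viability: float | np.ndarray
) -> float | np.ndarray:
    """Viable biomass (g L⁻¹) = dry weight × viable fraction."""
    dw = np.asarray(dry_weight, dtype=float)
    v = np.asarray(viability, dtype=float)
    if np.any(dw < 0):
        raise ValueError("dry weight must be >= 0")
    if np.any((v < 0) | (v > 1)):
        raise ValueError("viability must lie in [0, 1]")
    out = dw * v
    return float(out) if out.ndim == 0 else out


# ----------------------------------------------------------------- t50

def _logistic4(t, top, bottom, midpoint, slope):
    return bottom + (top - bottom) / (1.0 + (t / midpoint) ** slope)


class HeatShockT50Estimator(BaseEstimator):
    """4PL dose–response fit of heat-shock survival versus time.

    t₅₀ is defined as the time at which the *fitted* curve reaches half
    of its initial (t = 0) value — which coincides with the midpoint
    parameter only when the bottom plateau is 0 and the top equals the
    initial fraction. The constrained fit (bottom fixed at 0, the
    default) reflects a fully lethal exposure; set
    ``constrain_bottom=False`` for a free lower plateau.

    Attributes (after :meth:`fit`)
    ------------------------------
    t50_ : float
        50 %-of-initial crossing time, same unit as the input times.
    params_ : dict
        Fitted 4PL parameters (top, bottom, midpoint, slope).
    extrapolated_ : bool
        True if t50_ lies beyond the observed time range.
    """

    def __init__(self, constrain_bottom: bool = True) -> None:
        self.constrain_bottom = constrain_bottom

    def fit(self, X, y=None) -> "HeatShockT50Estimator":
        curve = X if isinstance(X, SurvivalCurve) else SurvivalCurve.from_frame(X)
        t, f = curve.times, curve.fractions
        if len(t) < 4:
            raise T50FitError("need at least 4 points for a 4PL fit")
        if f[-1] >= f[0]:
            raise T50FitError(
                "survival does not decrease over the assay; no t50 exists"
            )
        top0 = float(np.max(f))
        mid0 = float(np.interp(0.5 * top0, f[::-1], t[::-1]))
        mid0 = max(mid0, float(t[1]))
        if self.constrain_bottom:
            def model(tt, top, midpoint, slope):
                return _logistic4(tt, top, 0.0, midpoint, slope)

            p0 = [top0, mid0, 3.0]
            bounds = ([0.0, 1e-6, 0.1], [1.5, 1e6, 50.0])
        else:
            model = _logistic4
            p0 = [top0, 0.0, mid0, 3.0]
            bounds = ([0.0, 0.0, 1e-6, 0.1], [1.5, 1.0, 1e6, 50.0])
        try:
            popt, _ = curve_fit(
                model, t, f, p0=p0, bounds=bounds, maxfev=20_000
            )
        except RuntimeError as exc:
            raise T50FitError(f"4PL fit did not converge: {exc}") from exc

        if self.constrain_bottom:
            top, midpoint, slope = popt
            bottom = 0.0
        else:
            top, bottom, midpoint, slope = popt
        initial = _logistic4(float(t[0]), top, bottom, midpoint, slope)
        half = 0.5 * initial
        if half <= bottom:
            raise T50FitError(
                "fitted lower plateau exceeds half of the initial fraction; "
                "the curve never crosses 50 % survival"
            )
        # solve bottom + (top-bottom)/(1+(t/m)^s) = half analytically
        ratio = (top - bottom) / (half - bottom) - 1.0
        t50 = float(midpoint * ratio ** (1.0 / slope))

        fitted = _logistic4(t, top, bottom, midpoint, slope)
        ss_res = float(np.sum((f - fitted) ** 2))
        ss_tot = float(np.sum((f - np.mean(f)) ** 2))
        self.t50_ = t50
        self.params_ = {
            "top": float(top),
            "bottom": float(bottom),
            "midpoint": float(midpoint),
            "slope": float(slope),
        }
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        self.extrapolated_ = bool(t50 > t[-1] or t50 < t[0])
        if self.extrapolated_:
            warnings.warn(
                "t50 lies outside the sampled time range (extrapolated)",
                RuntimeWarning,
                stacklevel=2,
            )
        return self


def fit_heat_shock_t50(
    curve: SurvivalCurve | pd.DataFrame, constrain_bottom: bool = True
) -> tuple[float, dict]:
    """Fit t₅₀ from a survival curve; returns (t50, diagnostics)."""
    est = HeatShockT50Estimator(constrain_bottom=constrain_bottom).fit(curve)
    return est.t50_, {
        **est.params_,
        "r_squared": est.r_squared_,
        "extrapolated": est.extrapolated_,
    }


# ----------------------------------------------------------------- fermentative capacity

class FermentativeCapacityEstimator(BaseEstimator):
    """OLS slope of ethanol amount versus time, per gram of biomass.

    Attributes (after :meth:`fit`)
    ------------------------------
    capacity_ : float
        mmol ethanol gX⁻¹ h⁻¹ (clipped at 0 if the slope is negative).
    glucose_equivalent_ : float
        mmol glucose gX⁻¹ h⁻¹ — half the ethanol rate (2 ethanol per
        glucose in alcoholic fermentation).
    r_squared_ : float
        Linearity diagnostic of the regression.
    """

    def __init__(self, window: tuple[float, float] = (0.0, 30.0)) -> None:
        self.window = window

    def fit(self, X, y=None) -> "FermentativeCapacityEstimator":
        assay: FermentativeAssay = X
        if not isinstance(assay, FermentativeAssay):
            raise TypeError("X must be a FermentativeAssay")
        lo, hi = self.window
        mask = (assay.times >= lo) & (assay.times <= hi)
        if int(mask.sum()) < 3:
            raise ValueError("need >= 3 points inside the regression window")
        t_h = assay.times[mask] / 60.0
        amount = assay.ethanol_mmol[mask]
        res = stats.linregress(t_h, amount)
        slope = float(res.slope)
        capacity = slope / assay.biomass_g
        if capacity < 0:
            warnings.warn(
                "negative ethanol slope; fermentative capacity reported as 0",
                RuntimeWarning,
                stacklevel=2,
            )
            capacity = 0.0
        self.capacity_ = capacity
        self.glucose_equivalent_ = capacity / 2.0
        self.r_squared_ = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
        self.intercept_mmol_ = float(res.intercept)
        return self


def fermentative_capacity(
    assay: FermentativeAssay, window: tuple[float, float] = (0.0, 30.0)
) -> tuple[float, dict]:
    """Fermentative capacity (mmol ethanol gX⁻¹ h⁻¹) with diagnostics."""
    est = FermentativeCapacityEstimator(window=window).fit(assay)
    return est.capacity_, {
        "glucose_equivalent_mmol_per_gx_h": est.glucose_equivalent_,
        "r_squared": est.r_squared_,
    }
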
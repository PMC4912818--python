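"""Pirt resource-allocation law and maintenance-energy stoichiometry.

The Pirt equation partitions the biomass-specific glucose uptake rate
q_S (g glucose gX⁻¹ h⁻¹) over growth, maintenance and (optionally)
energy-requiring product formation::

    q_S = µ / Y_X/S^max + m_S + q_P / Y_P/S^max

where µ is the specific growth rate (h⁻¹), Y_X/S^max the maximum
(maintenance-free) biomass yield on glucose (g g⁻¹), m_S the maintenance
coefficient (g glucose gX⁻¹ h⁻¹), q_P a specific product formation rate
and Y_P/S^max the maximum product yield on glucose.

Maintenance is converted between substrate units and ATP turnover
(m_ATP, mmol ATP gX⁻¹ h⁻¹) through the dissimilatory ATP yield per mole
of glucose: 2 ATP/glucose for alcoholic fermentation and, at an in vivo
P/O ratio of 1.0 for respiring S. cerevisiae, an eightfold higher yield
(16 ATP/glucose) for full respiration.

Canonical internal units are grams, litres and hours; millimoles appear
only at the conversion boundary via the molar mass of glucose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "GLUCOSE_MOLAR_MASS",
    "PirtParameters",
    "EnergeticsParameters",
    "pirt_specific_uptake",
    "growth_rate_from_uptake",
    "ms_to_matp",
    "ms_from_matp",
    "ms_mass_to_mmol",
    "ms_mmol_to_mass",
    "doubling_time",
]

#: Molar mass of D-glucose in g mol⁻¹.
GLUCOSE_MOLAR_MASS = 180.16

_MASS_UNITS = frozenset({"g", "g/gX/h", "g_per_gx_h"})
_MMOL_UNITS = frozenset({"mmol", "mmol/gX/h", "mmol_per_gx_h"})
_MODES = frozenset({"respiratory", "fermentative"})


class ConfigurationError(ValueError):
    """Raised for inconsistent kinetic or stoichiometric parameters."""


@dataclass(frozen=True)
class PirtParameters:
    """Parameters of the (extended) Pirt resource-allocation law.

    Parameters
    ----------
    y_xs_max : float
        Maximum biomass yield on glucose, g biomass (g glucose)⁻¹.
        Must lie in (0, 1].
    m_s : float
        Maintenance coefficient, g glucose gX⁻¹ h⁻¹ (non-negative).
    q_p : float, optional
        Specific product formation rate, mol product gX⁻¹ h⁻¹.
        The cultures modelled here form no product; defaults to 0.
    y_ps_max : float or None, optional
        Maximum product yield on glucose, mol product (g glucose)⁻¹.
        Required iff ``q_p > 0``.
    """

    y_xs_max: float = 0.5
    m_s: float = 0.011
    q_p: float = 0.0
    y_ps_max: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.y_xs_max <= 1.0:
            raise ConfigurationError(
                f"y_xs_max must be in (0, 1], got {self.y_xs_max!r}"
            )
        if self.m_s < 0.0:
            raise ConfigurationError(f"m_s must be >= 0, got {self.m_s!r}")
        if self.q_p < 0.0:
            raise ConfigurationError(f"q_p must be >= 0, got {self.q_p!r}")
        if self.q_p > 0.0 and (self.y_ps_max is None or self.y_ps_max <= 0.0):
            raise ConfigurationError(
                "y_ps_max (> 0) is required when q_p > 0"
            )
        if self.y_ps_max is not None and self.y_ps_max <= 0.0:
            raise ConfigurationError(
                f"y_ps_max must be > 0 when given, got {self.y_ps_max!r}"
            )

    @property
    def product_uptake(self) -> float:
        """Glucose uptake committed to product formation, q_P/Y_P/S^max."""
        if self.q_p == 0.0:
            return 0.0
        return self.q_p / self.y_ps_max  # type: ignore[operator]

    def with_ms(self, m_s: float) -> "PirtParameters":
        """Copy of these parameters with a different maintenance coefficient."""
        return replace(self, m_s=m_s)

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}

    @classmethod
    def from_dict(cls, d: Mapping) -> "PirtParameters":
        keys = {"y_xs_max", "m_s", "q_p", "y_ps_max"}
        return cls(**{k: d[k] for k in keys & set(d)})


@dataclass(frozen=True)
class EnergeticsParameters:
    """ATP stoichiometry of glucose dissimilation.

    The respiratory yield defaults to 16 mol ATP (mol glucose)⁻¹ —
    eightfold the fermentative yield of 2, corresponding to an in vivo
    P/O ratio of 1.0 in respiring S. cerevisiae.
    """

    po_ratio: float = 1.0
    atp_per_glucose_fermentation: float = 2.0
    atp_per_glucose_respiration: float = 16.0
    glucose_molar_mass: float = GLUCOSE_MOLAR_MASS

    def __post_init__(self) -> None:
        for name in (
            "po_ratio",
            "atp_per_glucose_fermentation",
            "atp_per_glucose_respiration",
            "glucose_molar_mass",
        ):
            if getattr(self, name) <= 0.0:
                raise ConfigurationError(f"{name} must be > 0")

    def atp_yield(self, mode: str) -> float:
        """ATP per mole of glucose dissimilated in the given *mode*."""
        if mode == "respiratory":
            return self.atp_per_glucose_respiration
        if mode == "fermentative":
            return self.atp_per_glucose_fermentation
        raise ConfigurationError(
            f"mode must be one of {sorted(_MODES)}, got {mode!r}"
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "EnergeticsParameters":
        keys = {
            "po_ratio",
            "atp_per_glucose_fermentation",
            "atp_per_glucose_respiration",
            "glucose_molar_mass",
        }
        return cls(**{k: d[k] for k in keys & set(d)})


def pirt_specific_uptake(
    mu: float | np.ndarray,
    params: PirtParameters,
    *,
    allow_negative_mu: bool = False,
) -> float | np.ndarray:
    """Specific glucose uptake q_S (g gX⁻¹ h⁻¹) at growth rate *mu* (h⁻¹).

    Negative growth rates (net biomass loss under starvation) are only
    accepted when ``allow_negative_mu=True``, so accidental sign errors
    surface early in forward use.
    """
    mu_arr = np.asarray(mu, dtype=float)
    if not allow_negative_mu and np.any(mu_arr < 0.0):
        raise ValueError(
            "negative mu passed; set allow_negative_mu=True to evaluate "
            "the uptake law in the starvation regime"
        )
    q_s = mu_arr / params.y_xs_max + params.m_s + params.product_uptake
    return float(q_s) if np.isscalar(mu) else q_s


def growth_rate_from_uptake(
    q_s: float | np.ndarray, params: PirtParameters
) -> float | np.ndarray:
    """Invert the Pirt law: µ = Y_X/S^max · (q_S − m_S − q_P/Y_P/S^max).

    A negative result is returned as-is; it indicates that uptake falls
    short of the maintenance demand (starvation regime).
    """
    q_arr = np.asarray(q_s, dtype=float)
    mu = params.y_xs_max * (q_arr - params.m_s - params.product_uptake)
    return float(mu) if np.isscalar(q_s) else mu


def _to_mmol(m_s_value: float, units: str, energetics: EnergeticsParameters) -> float:
    if units in _MMOL_UNITS:
        return m_s_value
    if units in _MASS_UNITS:
        return m_s_value / energetics.glucose_molar_mass * 1000.0
    raise ConfigurationError(
        f"unknown units tag {units!r}; expected one of "
        f"{sorted(_MASS_UNITS | _MMOL_UNITS)}"
    )


def ms_mass_to_mmol(
    m_s: float, energetics: EnergeticsParameters = EnergeticsParameters()
) -> float:
    """Convert m_S from g gX⁻¹ h⁻¹ to mmol glucose gX⁻¹ h⁻¹."""
    return m_s / energetics.glucose_molar_mass * 1000.0


def ms_mmol_to_mass(
    m_s_mmol: float, energetics: EnergeticsParameters = EnergeticsParameters()
) -> float:
    """Convert m_S from mmol glucose gX⁻¹ h⁻¹ to g gX⁻¹ h⁻¹."""
    return m_s_mmol * energetics.glucose_molar_mass / 1000.0


def ms_to_matp(
    m_s_value: float,
    units: str = "g/gX/h",
    mode: str = "respiratory",
    energetics: EnergeticsParameters = EnergeticsParameters(),
) -> float:
    """Maintenance ATP turnover m_ATP (mmol ATP gX⁻¹ h⁻¹) from m_S.

    *units* declares the unit of ``m_s_value`` ("g/gX/h" or "mmol/gX/h");
    *mode* selects the dissimilatory ATP yield ("respiratory" or
    "fermentative").
    """
    if m_s_value < 0.0:
        raise ValueError("m_s_value must be >= 0")
    m_s_mmol = _to_mmol(m_s_value, units, energetics)
    return m_s_mmol * energetics.atp_yield(mode)


def ms_from_matp(
    m_atp: float,
    units: str = "g/gX/h",
    mode: str = "respiratory",
    energetics: EnergeticsParameters = EnergeticsParameters(),
) -> float:
    """Inverse of :func:`ms_to_matp`: the m_S that sustains a given m_ATP.

    Used e.g. to translate an anaerobic maintenance estimate into its
    aerobic glucose equivalent at equal ATP turnover.
    """
    if m_atp < 0.0:
        raise ValueError("m_atp must be >= 0")
    m_s_mmol = m_atp / energetics.atp_yield(mode)
    if units in _MMOL_UNITS:
        return m_s_mmol
    if units in _MASS_UNITS:
        return m_s_mmol * energetics.glucose_molar_mass / 1000.0
    raise ConfigurationError(f"unknown units tag {units!r}")


def doubling_time(mu: float, unit: str = "h") -> float:
    """Doubling time ln(2)/µ for µ > 0, in hours or days.

    Raises
    ------
    ValueError
        If ``mu <= 0`` (doubling time undefined).
    """
    if mu <= 0.0:
        raise ValueError(f"doubling time undefined for mu <= 0 (got {mu!r})")
    td_h = math.log(2.0) / mu
    if unit == "h":
        return td_h
    if unit in ("d", "day", "days"):
        return td_h / 24.0
    raise ValueError(f"unknown time unit {unit!r}; use 'h' or 'days'")
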
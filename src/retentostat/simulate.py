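"""Forward simulation of chemostat steady state and retentostat dynamics.

A retentostat is a chemostat whose effluent passes a cell-retention
filter: medium supply stays constant while biomass accumulates, pushing
the specific growth rate towards zero. Feed glucose is lowered smoothly
by routing the medium through a stirred mixing vessel of volume V_S, so
the inlet concentration relaxes exponentially from the chemostat-phase
level C_S,MC towards the retentostat-phase level C_S,MR with time
constant τ = V_S/ɸ_V::

    C_S,in(t) = (C_S,MC − C_S,MR) · exp(−ɸ_V t / V_S) + C_S,MR

Residual glucose in the culture is tiny compared with the feed, so the
substrate balance is taken as pseudo-steady (dC_S/dt ≈ 0), which closes
the model: q_S = D·C_S,in(t)/C_X_V and, with the Pirt law and a
first-order death rate k_d,

    dC_X_V/dt = (µ − k_d)·C_X_V,   µ = Y_X/S^max·(q_S − m_S)
    dC_X_d/dt = k_d·C_X_V

Because q_S·C_X_V = D·C_S,in(t), the viable-biomass balance is linear in
C_X_V and admits a closed-form solution (two exponentials plus a
constant), which this module provides as an independent verification
oracle next to the general numerical integrator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .pirt import PirtParameters, growth_rate_from_uptake, ms_mass_to_mmol

__all__ = [
    "ReactorConfig",
    "STUDY_CONFIG",
    "CultureState",
    "Trajectory",
    "AsymptoticState",
    "ChemostatState",
    "InfeasibleConfigurationError",
    "StarvationCollapseError",
    "ResonantParametersError",
    "inlet_concentration",
    "chemostat_steady_state",
    "simulate_retentostat",
    "closed_form_trajectory",
    "asymptotic_state",
]


class InfeasibleConfigurationError(ValueError):
    """The reactor/kinetic configuration admits no steady state."""


class StarvationCollapseError(RuntimeError):
    """Viable biomass was driven to zero during integration."""


class ResonantParametersError(ValueError):
    """Closed form undefined at 1/τ = Y·m_S + k_d; use the integrator."""


@dataclass(frozen=True)
class ReactorConfig:
    """Reactor and feed-train configuration.

    Defaults are the operating point of the aerobic retentostat set-up
    this package models: a 1.4-L culture fed at 35 mL h⁻¹ through a
    1.2-L mixing vessel, with feed glucose switched from 20 g L⁻¹
    (chemostat phase) to 7.5 g L⁻¹ (retentostat phase).
    """

    v: float = 1.4          # culture working volume, L
    v_s: float = 1.2        # mixing-vessel working volume, L
    phi_v: float = 0.035    # medium flow rate, L h⁻¹
    c_s_mc: float = 20.0    # chemostat-phase reservoir glucose, g L⁻¹
    c_s_mr: float = 7.5     # retentostat-phase reservoir glucose, g L⁻¹

    def __post_init__(self) -> None:
        for name in ("v", "v_s", "phi_v"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be > 0")
        for name in ("c_s_mc", "c_s_mr"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def dilution_rate(self) -> float:
        """D = ɸ_V / V (h⁻¹)."""
        return self.phi_v / self.v

    @property
    def mixing_time_constant(self) -> float:
        """τ = V_S / ɸ_V (h), the feed-relaxation time constant."""
        return self.v_s / self.phi_v

    def with_c_s_mr(self, c_s_mr: float) -> "ReactorConfig":
        return replace(self, c_s_mr=c_s_mr)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ReactorConfig":
        keys = {"v", "v_s", "phi_v", "c_s_mc", "c_s_mr"}
        return cls(**{k: d[k] for k in keys & set(d)})


#: The operating point used throughout the worked examples.
STUDY_CONFIG = ReactorConfig()


@dataclass(frozen=True)
class CultureState:
    """Culture state at one instant of retentostat time."""

    t: float        # time since the feed switch, h
    c_x_v: float    # viable biomass, g L⁻¹
    c_x_d: float    # dead biomass, g L⁻¹
    c_s_in: float   # inlet glucose concentration, g L⁻¹

    def __post_init__(self) -> None:
        if self.c_x_v < 0.0 or self.c_x_d < 0.0:
            raise ValueError("biomass concentrations must be >= 0")


class ChemostatState(NamedTuple):
    c_x: float   # steady-state biomass, g L⁻¹
    q_s: float   # specific glucose uptake, g gX⁻¹ h⁻¹
    mu: float    # specific growth rate (= D), h⁻¹


class AsymptoticState(NamedTuple):
    c_x_v_inf: float  # asymptotic viable biomass, g L⁻¹
    mu_inf: float     # asymptotic growth rate (= k_d), h⁻¹


@dataclass
class Trajectory:
    """Simulated retentostat trajectory on an ordered time grid.

    Holds the state series and the derived specific rates; total
    (measurable dry-weight) biomass is viable plus retained dead mass.
    """

    t: np.ndarray        # h, since the feed switch
    c_x_v: np.ndarray    # g L⁻¹
    c_x_d: np.ndarray    # g L⁻¹
    c_s_in: np.ndarray   # g L⁻¹
    q_s: np.ndarray      # g glucose gX⁻¹ h⁻¹ (per viable biomass)
    mu: np.ndarray       # h⁻¹
    config: ReactorConfig
    params: PirtParameters
    k_d: float

    @property
    def c_x_total(self) -> np.ndarray:
        return self.c_x_v + self.c_x_d

    @property
    def starvation_detected(self) -> bool:
        """True if µ(t) < 0 anywhere on the grid (uptake below maintenance)."""
        return bool(np.any(self.mu < 0.0))

    def state_at(self, i: int) -> CultureState:
        return CultureState(
            t=float(self.t[i]),
            c_x_v=float(self.c_x_v[i]),
            c_x_d=float(self.c_x_d[i]),
            c_s_in=float(self.c_s_in[i]),
        )

    def interp_c_x_v(self, t: float | np.ndarray) -> float | np.ndarray:
        return np.interp(t, self.t, self.c_x_v)

    def interp_mu(self, t: float | np.ndarray) -> float | np.ndarray:
        return np.interp(t, self.t, self.mu)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with SI-unit-suffixed column names."""
        return pd.DataFrame(
            {
                "time_h": self.t,
                "c_x_v_gL": self.c_x_v,
                "c_x_d_gL": self.c_x_d,
                "c_x_total_gL": self.c_x_total,
                "c_s_in_gL": self.c_s_in,
                "q_s_g_per_gx_h": self.q_s,
                "q_s_mmol_per_gx_h": ms_mass_to_mmol(1.0) * self.q_s,
                "mu_per_h": self.mu,
            }
        )


def inlet_concentration(
    t: float | np.ndarray, config: ReactorConfig
) -> float | np.ndarray:
    """Inlet glucose concentration C_S,in(t) after the feed switch (g L⁻¹)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0.0):
        raise ValueError("t must be >= 0 (retentostat clock starts at the switch)")
    c = (config.c_s_mc - config.c_s_mr) * np.exp(
        -config.phi_v * t_arr / config.v_s
    ) + config.c_s_mr
    return float(c) if np.isscalar(t) else c


def chemostat_steady_state(
    config: ReactorConfig, params: PirtParameters
) -> ChemostatState:
    """Steady state of the preceding chemostat phase.

    At steady state µ = D, so q_S = D/Y_X/S^max + m_S and the biomass
    balance with negligible residual glucose gives
    C_X = D·C_S,MC/q_S.
    """
    d = config.dilution_rate
    q_s = d / params.y_xs_max + params.m_s + params.product_uptake
    c_x = d * config.c_s_mc / q_s
    if not c_x > 0.0:
        raise InfeasibleConfigurationError(
            "chemostat steady state infeasible for this configuration"
        )
    return ChemostatState(c_x=c_x, q_s=q_s, mu=d)


def _derived_rates(
    t: np.ndarray,
    c_x_v: np.ndarray,
    config: ReactorConfig,
    params: PirtParameters,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    c_s_in = inlet_concentration(t, config)
    q_s = config.dilution_rate * c_s_in / c_x_v
    mu = growth_rate_from_uptake(q_s, params)
    return np.atleast_1d(c_s_in), np.atleast_1d(q_s), np.atleast_1d(mu)


def _resolve_initial(
    initial: CultureState | str,
    config: ReactorConfig,
    params: PirtParameters,
) -> tuple[float, float]:
    if isinstance(initial, str):
        if initial != "chemostat":
            raise ValueError(f"unknown initial-state spec {initial!r}")
        ss = chemostat_steady_state(config, params)
        return ss.c_x, 0.0
    return initial.c_x_v, initial.c_x_d


def simulate_retentostat(
    config: ReactorConfig,
    params: PirtParameters,
    k_d: float = 0.0,
    t_end: float = 480.0,
    dt: float = 1.0,
    initial: CultureState | str = "chemostat",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Numerically integrate the retentostat balances on a uniform grid.

    The state is (C_X_V, C_X_d); rates are evaluated in the model's own
    terms (q_S from the pseudo-steady substrate balance, µ from the Pirt
    law) rather than via the algebraically simplified linear form, so
    this path is independent of :func:`closed_form_trajectory`.

    Raises
    ------
    StarvationCollapseError
        If viable biomass is driven to zero (prolonged starvation).
    """
    if k_d < 0.0:
        raise ValueError("k_d must be >= 0")
    if t_end <= 0.0 or dt <= 0.0:
        raise ValueError("t_end and dt must be > 0")
    c_x_v0, c_x_d0 = _resolve_initial(initial, config, params)
    if c_x_v0 <= 0.0:
        raise InfeasibleConfigurationError("initial viable biomass must be > 0")

    d = config.dilution_rate

    def rhs(t: float, y: np.ndarray) -> list[float]:
        c_x_v = y[0]
        c_s_in = inlet_concentration(t, config)
        q_s = d * c_s_in / c_x_v
        mu = growth_rate_from_uptake(q_s, params)
        return [(mu - k_d) * c_x_v, k_d * c_x_v]

    def collapse(t: float, y: np.ndarray) -> float:
        return y[0] - 1e-9

    collapse.terminal = True  # type: ignore[attr-defined]
    collapse.direction = -1  # type: ignore[attr-defined]

    n = int(round(t_end / dt))
    t_eval = np.linspace(0.0, t_end, n + 1)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        [c_x_v0, c_x_d0],
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        events=collapse,
    )
    if sol.status == 1:  # collapse event fired
        raise StarvationCollapseError(
            f"viable biomass collapsed to zero at t ≈ {sol.t_events[0][0]:.1f} h"
        )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")

    c_x_v = sol.y[0]
    c_x_d = sol.y[1]
    c_s_in, q_s, mu = _derived_rates(sol.t, c_x_v, config, params)
    return Trajectory(
        t=sol.t,
        c_x_v=c_x_v,
        c_x_d=c_x_d,
        c_s_in=c_s_in,
        q_s=q_s,
        mu=mu,
        config=config,
        params=params,
        k_d=k_d,
    )


def closed_form_trajectory(
    config: ReactorConfig,
    params: PirtParameters,
    k_d: float = 0.0,
    t: np.ndarray | None = None,
    initial: CultureState | str = "chemostat",
) -> Trajectory:
    """Analytic solution of the retentostat balances (verification oracle).

    Substituting the pseudo-steady substrate balance into the viable
    biomass equation gives the linear ODE
    ``dC_X_V/dt = Y·D·C_S,in(t) − a·C_X_V`` with decay constant
    ``a = Y·m_S + k_d``, solved by::

        C_X_V(t) = C_∞ + A·e^(−a·t) + B·e^(−t/τ)

    with ``C_∞ = Y·D·C_S,MR/a``, ``B = Y·D·(C_S,MC − C_S,MR)/(a − 1/τ)``
    and ``A = C_X_V(0) − C_∞ − B`` (verified by substitution). Dead
    biomass follows from analytic integration of ``k_d·C_X_V``.

    Raises
    ------
    ResonantParametersError
        At 1/τ = a, where the two exponentials degenerate; use
        :func:`simulate_retentostat` instead.
    """
    if k_d < 0.0:
        raise ValueError("k_d must be >= 0")
    if t is None:
        t = np.linspace(0.0, 480.0, 481)
    t = np.asarray(t, dtype=float)
    c_x_v0, c_x_d0 = _resolve_initial(initial, config, params)

    y = params.y_xs_max
    d = config.dilution_rate
    tau = config.mixing_time_constant
    a = y * (params.m_s + params.product_uptake) + k_d
    if a <= 0.0:
        raise InfeasibleConfigurationError(
            "closed form requires Y·m_S + k_d > 0 (no decay constant otherwise)"
        )
    if abs(a - 1.0 / tau) < 1e-12 * max(a, 1.0 / tau):
        raise ResonantParametersError(
            "1/tau coincides with Y·m_S + k_d; the two-exponential closed "
            "form is degenerate — use simulate_retentostat"
        )

    delta = config.c_s_mc - config.c_s_mr
    c_inf = y * d * config.c_s_mr / a
    b = y * d * delta / (a - 1.0 / tau)
    a_coef = c_x_v0 - c_inf - b

    e_a = np.exp(-a * t)
    e_tau = np.exp(-t / tau)
    c_x_v = c_inf + a_coef * e_a + b * e_tau
    # ∫₀ᵗ C_X_V ds, analytically
    integral = c_inf * t + a_coef * (1.0 - e_a) / a + b * tau * (1.0 - e_tau)
    c_x_d = c_x_d0 + k_d * integral

    c_s_in, q_s, mu = _derived_rates(t, c_x_v, config, params)
    return Trajectory(
        t=t,
        c_x_v=c_x_v,
        c_x_d=c_x_d,
        c_s_in=c_s_in,
        q_s=q_s,
        mu=mu,
        config=config,
        params=params,
        k_d=k_d,
    )


def asymptotic_state(
    config: ReactorConfig, params: PirtParameters, k_d: float = 0.0
) -> AsymptoticState:
    """Long-run limit of the retentostat.

    Viable biomass approaches C_X_V(∞) = Y·D·C_S,MR/(Y·m_S + k_d); the
    growth rate approaches k_d (zero in the absence of death), the point
    at which glucose supply exactly covers maintenance plus replacement
    of dying cells.
    """
    y = params.y_xs_max
    a = y * (params.m_s + params.product_uptake) + k_d
    if a <= 0.0:
        raise InfeasibleConfigurationError("Y·m_S + k_d must be > 0")
    c_inf = y * config.dilution_rate * config.c_s_mr / a
    return AsymptoticState(c_x_v_inf=c_inf, mu_inf=k_d)
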
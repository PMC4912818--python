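"""Seeded generators for every input the analysis pipeline consumes.

All generators are pure functions of their parameters and seed, and
return the generating truth alongside the noisy observable, so every
downstream estimator can be exercised in closed loop (generate → fit →
compare with truth) without any external data.

Emulated measurement processes:

* dry weight — multiplicative Gaussian noise (default 5 % CV);
* PI viability — binomial counting of a fixed number of cells on a
  flow cytometer (default 10,000);
* CFU viability — Poisson colony counting (default expectation 150)
  around the PI-viable fraction times a reproductive-loss factor
  (default 0.85): a slice of membrane-intact cells no longer divides;
* plate/HPLC assay channels — additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .estimate import ObservationSet
from .pirt import PirtParameters
from .simulate import ReactorConfig, STUDY_CONFIG, simulate_retentostat

__all__ = [
    "NoiseModel",
    "default_sampling_schedule",
    "generate_retentostat_observations",
    "generate_heat_shock_survival",
    "generate_fermentative_assay",
    "generate_expression_dataset",
    "DEFAULT_GROWTH_RATES",
]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise configuration shared by the generators.

    Setting ``dw_cv = 0`` makes dry weight exact; setting a cell or
    colony count to 0 makes the corresponding counting channel exact.
    """

    dw_cv: float = 0.05
    viability_cells_counted: int = 10_000
    cfu_colonies_counted: int = 150
    assay_sd: float = 0.0
    cfu_reproductive_loss: float = 0.85
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dw_cv < 0 or self.assay_sd < 0:
            raise ValueError("noise scales must be >= 0")
        if self.viability_cells_counted < 0 or self.cfu_colonies_counted < 0:
            raise ValueError("counts must be >= 0")
        if not 0.0 < self.cfu_reproductive_loss <= 1.0:
            raise ValueError("cfu_reproductive_loss must be in (0, 1]")

    @classmethod
    def exact(cls) -> "NoiseModel":
        """A noise-free model: observations equal the simulated truth."""
        return cls(
            dw_cv=0.0,
            viability_cells_counted=0,
            cfu_colonies_counted=0,
            assay_sd=0.0,
        )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def default_sampling_schedule() -> np.ndarray:
    """Sampling times (h): daily for the first 5 days, then every 48 h.

    Mirrors practice in long retentostat runs, where sampling volume is
    minimized to avoid perturbing biomass accumulation.
    """
    return np.unique(
        np.concatenate(
            [np.arange(0.0, 121.0, 24.0), np.arange(120.0, 481.0, 48.0), [480.0]]
        )
    )


def generate_retentostat_observations(
    config: ReactorConfig = STUDY_CONFIG,
    params: PirtParameters = PirtParameters(y_xs_max=0.5, m_s=0.00703),
    k_d: float = 4.7e-4,
    schedule: np.ndarray | None = None,
    noise: NoiseModel = NoiseModel(),
) -> tuple[ObservationSet, dict]:
    """Simulate a retentostat run and sample noisy observations from it.

    Defaults correspond to the experimentally observed regime: an m_S
    of 0.00703 g gX⁻¹ h⁻¹ (0.039 mmol gX⁻¹ h⁻¹) and a death rate of
    4.7·10⁻⁴ h⁻¹, sampled over 20 days, which leaves PI viability near
    85 % at the end of the run.

    Returns the observation set and a truth record with the generating
    parameters and the noiseless state at the schedule times.
    """
    if schedule is None:
        schedule = default_sampling_schedule()
    schedule = np.asarray(schedule, dtype=float)
    rng = noise.rng()

    traj = simulate_retentostat(
        config, params, k_d=k_d, t_end=float(schedule[-1]), dt=1.0
    )
    c_x_v = np.interp(schedule, traj.t, traj.c_x_v)
    c_x_d = np.interp(schedule, traj.t, traj.c_x_d)
    total = c_x_v + c_x_d
    viable_frac = c_x_v / total

    if noise.dw_cv > 0:
        dw = total * (1.0 + rng.normal(0.0, noise.dw_cv, size=total.shape))
        dw = np.clip(dw, 1e-9, None)
    else:
        dw = total.copy()

    n_cells = noise.viability_cells_counted
    if n_cells > 0:
        viability = rng.binomial(n_cells, viable_frac) / n_cells
    else:
        viability = viable_frac.copy()

    cfu_frac_true = np.clip(viable_frac * noise.cfu_reproductive_loss, 0.0, 1.0)
    n_col = noise.cfu_colonies_counted
    if n_col > 0:
        # Poisson colony counts around the expected count per plate
        expected = n_col * cfu_frac_true
        viability_cfu = np.clip(rng.poisson(expected) / n_col, 0.0, 1.0)
    else:
        viability_cfu = cfu_frac_true

    obs = ObservationSet(
        times=schedule,
        dry_weight=dw,
        viability=viability,
        viability_cfu=viability_cfu,
        dw_scale=None,
        viability_scale=None,
    )
    truth = {
        "m_s": params.m_s,
        "k_d": k_d,
        "y_xs_max": params.y_xs_max,
        "config": config.to_dict(),
        "c_x_v": c_x_v,
        "c_x_d": c_x_d,
        "viable_fraction": viable_frac,
    }
    return obs, truth


def generate_heat_shock_survival(
    t50: float,
    hill_slope: float = 4.0,
    schedule: np.ndarray | None = None,
    noise: NoiseModel = NoiseModel(),
    initial_viability: float = 1.0,
) -> pd.DataFrame:
    """Survival-versus-time table for a lethal heat exposure (53 °C).

    Truth is a logistic decay in time crossing 50 % of the initial
    viable fraction exactly at *t50* (minutes); ``t50 = inf`` yields a
    flat curve. Counting noise is binomial with the flow-cytometry cell
    count.
    """
    if not (t50 > 0.0):
        raise ValueError("t50 must be > 0")
    if schedule is None:
        schedule = np.arange(0.0, 201.0, 20.0)
    t = np.asarray(schedule, dtype=float)
    rng = noise.rng()
    if np.isinf(t50):
        frac = np.full_like(t, initial_viability)
    else:
        frac = initial_viability / (1.0 + (t / t50) ** hill_slope)
    n = noise.viability_cells_counted
    if n > 0:
        observed = rng.binomial(n, np.clip(frac, 0.0, 1.0)) / n
    else:
        observed = frac
    return pd.DataFrame({"time_min": t, "viable_fraction": observed})


def generate_fermentative_assay(
    capacity: float,
    biomass_g: float = 0.1,
    schedule: np.ndarray | None = None,
    noise: NoiseModel = NoiseModel(),
    assay_volume_l: float = 0.07,
) -> pd.DataFrame:
    """Ethanol-accumulation table for an anaerobic fermentative-capacity assay.

    *capacity* is mmol ethanol gX⁻¹ h⁻¹; the assay holds *biomass_g*
    grams of cells in an *assay_volume_l* working volume (default 70 mL:
    10 mL cell suspension + 40 mL water + 10 mL glucose + 10 mL medium).
    Ethanol concentration (mM) increases linearly; Gaussian noise of sd
    ``assay_sd`` (mM) is added.
    """
    if capacity < 0.0:
        raise ValueError("capacity must be >= 0")
    if biomass_g <= 0.0 or assay_volume_l <= 0.0:
        raise ValueError("biomass_g and assay_volume_l must be > 0")
    if schedule is None:
        schedule = np.arange(0.0, 31.0, 5.0)
    t_min = np.asarray(schedule, dtype=float)
    rng = noise.rng()
    amount_mmol = capacity * biomass_g * t_min / 60.0
    conc_mm = amount_mmol / assay_volume_l
    if noise.assay_sd > 0:
        conc_mm = np.clip(
            conc_mm + rng.normal(0.0, noise.assay_sd, size=conc_mm.shape), 0.0, None
        )
    return pd.DataFrame({"time_min": t_min, "ethanol_mM": conc_mm})


#: Specific growth rates of the 13-array design: triplicate chemostats at
#: 0.025 h⁻¹ plus two retentostat series sampled at five decreasing rates.
DEFAULT_GROWTH_RATES: tuple[float, ...] = (
    0.025,
    0.025,
    0.025,
    0.012,
    0.0056,
    0.0025,
    0.0012,
    0.0006,
    0.012,
    0.0056,
    0.0025,
    0.0012,
    0.0006,
)


def generate_expression_dataset(
    n_genes: int = 6383,
    growth_rates: Sequence[float] = DEFAULT_GROWTH_RATES,
    frac_up: float = 600 / 6383,
    frac_down: float = 775 / 6383,
    effect_size: float = 1.0,
    n_categories: int = 20,
    category_size: int = 150,
    planted_odds: float = 8.0,
    noise_cv: float = 0.10,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Genes × arrays signal matrix with planted growth-rate responders.

    Baseline signals are log-normal. A fraction of genes (*frac_up*)
    rises monotonically with specific growth rate and a fraction
    (*frac_down*) falls, with log-scale amplitude *effect_size* across
    the observed growth-rate range; replicate noise is multiplicative
    log-normal at *noise_cv*. Default planted counts (600 up, 775 down
    of 6383) mirror the sizes of the two growth-rate-responsive
    clusters this kind of experiment yields.

    Gene categories are also generated: most draw members uniformly,
    but the first two preferentially sample up- (resp. down-) regulated
    genes at odds *planted_odds*, planting a detectable enrichment.

    Returns
    -------
    matrix : DataFrame
        Genes in rows (``g0001`` …), arrays in columns.
    array_growth_rates : Series
        Specific growth rate per array (h⁻¹), indexed like the columns.
    truth : dict
        ``up_genes``, ``down_genes``, ``categories`` (name → gene set),
        and the generator settings.
    """
    if frac_up + frac_down >= 1.0:
        raise ValueError("frac_up + frac_down must be < 1")
    if len(growth_rates) < 4:
        raise ValueError("need at least 4 arrays")
    rng = np.random.default_rng(seed)
    rates = np.asarray(growth_rates, dtype=float)
    n_arrays = len(rates)
    genes = np.array([f"g{i:04d}" for i in range(n_genes)])
    arrays = [f"a{j:02d}" for j in range(n_arrays)]

    n_up = int(round(frac_up * n_genes))
    n_down = int(round(frac_down * n_genes))
    perm = rng.permutation(n_genes)
    up_idx = perm[:n_up]
    down_idx = perm[n_up : n_up + n_down]

    # Growth-rate covariate on the log scale, scaled to [-0.5, 0.5]
    g = np.log(rates)
    g = (g - g.min()) / (g.max() - g.min()) - 0.5

    baseline = rng.lognormal(mean=5.0, sigma=1.0, size=n_genes)
    slope = np.zeros(n_genes)
    slope[up_idx] = effect_size
    slope[down_idx] = -effect_size
    log_signal = np.log(baseline)[:, None] + slope[:, None] * g[None, :]
    if noise_cv > 0:
        sigma = np.sqrt(np.log(1.0 + noise_cv**2))
        log_signal = log_signal + rng.normal(0.0, sigma, size=log_signal.shape)
    matrix = pd.DataFrame(np.exp(log_signal), index=genes, columns=arrays)

    categories: dict[str, set] = {}
    up_set = set(genes[up_idx])
    down_set = set(genes[down_idx])
    for c in range(n_categories):
        if c == 0:
            bias = np.isin(genes, list(up_set)).astype(float)
        elif c == 1:
            bias = np.isin(genes, list(down_set)).astype(float)
        else:
            bias = np.zeros(n_genes)
        w = 1.0 + (planted_odds - 1.0) * bias
        members = rng.choice(
            genes, size=min(category_size, n_genes), replace=False, p=w / w.sum()
        )
        name = {0: "planted_up", 1: "planted_down"}.get(c, f"category_{c:02d}")
        categories[name] = set(members)

    truth = {
        "up_genes": up_set,
        "down_genes": down_set,
        "categories": categories,
        "effect_size": effect_size,
        "noise_cv": noise_cv,
        "growth_rates": rates,
    }
    return matrix, pd.Series(rates, index=arrays, name="growth_rate_per_h"), truth
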
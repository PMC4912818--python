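"""Configuration and table I/O: YAML configs, TSV tables, JSON results.

All numeric tables are plain TSV with header rows and unit-suffixed
column names; configuration is YAML; structured results are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .design import DesignCriteria
from .estimate import FitResult, ObservationSet
from .pirt import EnergeticsParameters, PirtParameters
from .simulate import ReactorConfig, Trajectory
from .synthetic import NoiseModel

__all__ = [
    "RunConfig",
    "load_run_config",
    "read_observations",
    "write_observations",
    "write_trajectory",
    "write_fit_result",
    "read_expression_matrix",
    "read_gene_sets",
    "write_json",
]


class RunConfig:
    """Bundle of every configurable object a pipeline run needs.

    Fully serializable; a run is reproducible from its config and seed
    alone.
    """

    def __init__(
        self,
        reactor: ReactorConfig | None = None,
        pirt: PirtParameters | None = None,
        energetics: EnergeticsParameters | None = None,
        criteria: DesignCriteria | None = None,
        noise: NoiseModel | None = None,
        k_d: float = 4.7e-4,
        t_end: float = 480.0,
        seed: int = 0,
        out_dir: str = "results",
    ) -> None:
        self.reactor = reactor or ReactorConfig()
        self.pirt = pirt or PirtParameters()
        self.energetics = energetics or EnergeticsParameters()
        self.criteria = criteria or DesignCriteria()
        self.noise = noise or NoiseModel()
        self.k_d = k_d
        self.t_end = t_end
        self.seed = seed
        self.out_dir = out_dir

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return {
            "reactor": self.reactor.to_dict(),
            "pirt": self.pirt.to_dict(),
            "energetics": self.energetics.to_dict(),
            "criteria": asdict(self.criteria),
            "noise": asdict(self.noise),
            "k_d": self.k_d,
            "t_end": self.t_end,
            "seed": self.seed,
            "out_dir": self.out_dir,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        kwargs: dict = {}
        if "reactor" in d:
            kwargs["reactor"] = ReactorConfig.from_dict(d["reactor"])
        if "pirt" in d:
            kwargs["pirt"] = PirtParameters.from_dict(d["pirt"])
        if "energetics" in d:
            kwargs["energetics"] = EnergeticsParameters.from_dict(d["energetics"])
        if "criteria" in d:
            kwargs["criteria"] = DesignCriteria(**d["criteria"])
        if "noise" in d:
            kwargs["noise"] = NoiseModel(**d["noise"])
        for key in ("k_d", "t_end", "seed", "out_dir"):
            if key in d:
                kwargs[key] = d[key]
        return cls(**kwargs)


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def read_observations(
    path: str | Path, dw_unit: str = "g_per_L"
) -> ObservationSet:
    """Read a retentostat observation table (TSV or CSV by extension).

    Expected columns: ``time_h``, ``dw_gL`` (or ``dw_mgL`` with
    ``dw_unit='mg_per_L'``), ``viability_pi``, optionally
    ``viability_cfu`` and ``glucose_gL``.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    if dw_unit == "g_per_L":
        dw = df["dw_gL"].to_numpy()
    elif dw_unit == "mg_per_L":
        col = "dw_mgL" if "dw_mgL" in df else "dw_gL"
        dw = df[col].to_numpy() / 1000.0
    else:
        raise ValueError("dw_unit must be 'g_per_L' or 'mg_per_L'")
    return ObservationSet(
        times=df["time_h"].to_numpy(),
        dry_weight=dw,
        viability=df["viability_pi"].to_numpy(),
        viability_cfu=(
            df["viability_cfu"].to_numpy() if "viability_cfu" in df else None
        ),
        glucose=df["glucose_gL"].to_numpy() if "glucose_gL" in df else None,
    )


def write_observations(obs: ObservationSet, path: str | Path) -> None:
    obs.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    traj.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_fit_result(fit: FitResult, path: str | Path) -> None:
    write_json(fit.summary(), path)


def write_json(obj: Mapping, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
        fh.write("\n")


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Genes × arrays TSV: first column gene IDs, remaining columns arrays."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gene_sets(path: str | Path) -> dict[str, set]:
    """Two-column (set, gene) TSV → mapping of set name to gene set."""
    df = pd.read_csv(path, sep="\t", header=None, names=["set", "gene"])
    return {name: set(group["gene"]) for name, group in df.groupby("set")}
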
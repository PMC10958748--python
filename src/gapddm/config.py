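"""Run configuration: one plain-text (YAML) file governs all commands.

Every stochastic stage derives its seed from the single master seed, and
every artifact records the configuration hash, so an end-to-end run is
reproducible from the config file alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from . import fpt
from .core import ModelParams
from .fitting import (
    DEFAULT_QUANTILE_LEVELS,
    DEFAULT_SEARCH_BOUNDS,
    DEFAULT_WEIGHT_P,
    DEFAULT_WEIGHT_Q,
    DESettings,
)
from .synth import DEFAULT_GROUP_MEAN_PARAMS, DEFAULT_PARAM_SD, PopulationSpec

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass
class DesignConfig:
    tta_conditions: list = field(default_factory=lambda: [4.0, 5.0, 6.0])
    distance_conditions: list = field(default_factory=lambda: [90.0, 120.0, 150.0])
    n_routes: int = 8
    left_turns_per_route: int = 15


@dataclass
class SolverConfig:
    dt: float = fpt.DEFAULT_DT
    dx: float = fpt.DEFAULT_DX
    sim_dt: float = fpt.DEFAULT_SIM_DT


@dataclass
class FitConfig:
    quantile_levels: list = field(default_factory=lambda: list(DEFAULT_QUANTILE_LEVELS))
    weight_p: float = DEFAULT_WEIGHT_P
    weight_q: float = DEFAULT_WEIGHT_Q
    search_bounds: dict = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_SEARCH_BOUNDS.items()}
    )
    de: dict = field(
        default_factory=lambda: {"popsize": 15, "maxiter": 200, "tol": 1e-6}
    )

    def de_settings(self) -> DESettings:
        return DESettings(**self.de)


@dataclass
class PopulationConfig:
    n_participants: int = 16
    mean_params: dict = field(
        default_factory=lambda: DEFAULT_GROUP_MEAN_PARAMS.to_dict()
    )
    param_sd: dict = field(default_factory=lambda: dict(DEFAULT_PARAM_SD))
    no_full_stop_rate: float = 0.014
    pedal_held_rate: float = 0.005

    def spec(self, seed: int) -> PopulationSpec:
        return PopulationSpec(
            n_participants=self.n_participants,
            mean_params=ModelParams.from_dict(self.mean_params),
            param_sd=dict(self.param_sd),
            no_full_stop_rate=self.no_full_stop_rate,
            pedal_held_rate=self.pedal_held_rate,
            seed=seed,
        )


@dataclass
class RunConfig:
    design: DesignConfig = field(default_factory=DesignConfig)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    seed: int = 0
    out_dir: str = "gapddm_out"

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        # the output location does not affect the science
        d = self.to_dict()
        d.pop("out_dir", None)
        return config_hash(d)

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sections = {
            "design": DesignConfig,
            "population": PopulationConfig,
            "solver": SolverConfig,
            "fit": FitConfig,
        }
        kw = {}
        for key, val in d.items():
            if key in sections:
                known = sections[key].__dataclass_fields__
                bad = set(val) - set(known)
                if bad:
                    raise ValueError(f"unknown field(s) in config section '{key}': {sorted(bad)}")
                kw[key] = sections[key](**val)
            elif key in ("seed", "out_dir"):
                kw[key] = val
            else:
                raise ValueError(f"unknown config section '{key}'")
        return cls(**kw)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def config_hash(d: dict) -> str:
    """Stable short hash of a JSON-serializable config mapping."""
    blob = json.dumps(d, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
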
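"""Synthetic trial-level datasets with the study's structure.

The generator emulates a driving-simulator gap-acceptance study:
16 participants each drive 8 routes with 15 left turns per route.  On a
left turn an oncoming car appears with an initial TTA of 4, 5 or 6 s
(balanced: exactly five turns per TTA level per route) at a distance of
90, 120 or 150 m drawn uniformly per trial.  Go/stay outcomes and go
response times come from the diffusion model itself under
participant-specific parameters drawn around group means.

The study's trial-exclusion artifacts are reproduced as labels:
``no_full_stop`` (the driver never fully stopped, so the oncoming car
never appeared; 1.4% of left turns), ``pedal_held`` (go decision whose
RT could not be measured because the gas pedal was held down; 0.5% of
go decisions) and the deterministic exclusion of go-RTs above 2 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fpt
from .core import ModelParams, ModelVariant
from .fpt import simulate_trials
from .kinematics import Condition

__all__ = [
    "PopulationSpec",
    "DEFAULT_GROUP_MEAN_PARAMS",
    "DEFAULT_PARAM_SD",
    "generate_schedule",
    "sample_population",
    "generate_dataset",
    "apply_exclusions",
    "EXCLUSION_REASONS",
]

EXCLUSION_REASONS = ("none", "no_full_stop", "pedal_held", "rt_gt_2s")
RT_EXCLUSION_THRESHOLD = 2.0

#: group-mean parameters of the simulated population, chosen so the
#: design produces roughly the observed overall split (~47% go), go
#: probabilities spanning the design cells, and go-RTs below ~2 s that
#: lengthen with initial TTA
DEFAULT_GROUP_MEAN_PARAMS = ModelParams(
    alpha=1.0,
    beta=0.05,
    theta_crit=10.0,
    b0=1.3,
    k=2.0,
    tau=3.5,
    mu_nd=0.32,
    sigma_nd=0.05,
)

#: between-participant standard deviations (independent normals,
#: clipped to the parameter invariants)
DEFAULT_PARAM_SD = {
    "alpha": 0.12,
    "beta": 0.012,
    "theta_crit": 0.6,
    "b0": 0.25,
    "k": 0.3,
    "tau": 0.5,
    "mu_nd": 0.05,
    "sigma_nd": 0.015,
}

_CLIP_LO = {"alpha": 0.0, "beta": 0.0, "theta_crit": 0.1, "b0": 0.05,
            "k": 0.01, "tau": 0.1, "mu_nd": 0.0, "sigma_nd": 0.0}


@dataclass
class PopulationSpec:
    """Specification of the simulated participant population."""

    n_participants: int = 16
    mean_params: ModelParams = field(default_factory=lambda: DEFAULT_GROUP_MEAN_PARAMS)
    param_sd: dict = field(default_factory=lambda: dict(DEFAULT_PARAM_SD))
    no_full_stop_rate: float = 0.014
    pedal_held_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.param_sd.values()):
            raise ValueError("between-participant s.d. must be >= 0")
        for r in (self.no_full_stop_rate, self.pedal_held_rate):
            if not 0 <= r <= 1:
                raise ValueError("exclusion rates must lie in [0, 1]")


def _subseed(*entropy) -> int:
    return int(np.random.SeedSequence(list(entropy)).generate_state(1)[0] % (2**31))


def generate_schedule(
    n_routes: int = 8,
    left_turns_per_route: int = 15,
    tta_levels=(4.0, 5.0, 6.0),
    distances=(90.0, 120.0, 150.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Balanced left-turn schedule for one participant.

    Each route repeats every TTA level exactly
    ``left_turns_per_route / len(tta_levels)`` times in shuffled order;
    the distance is drawn uniformly and independently per trial.
    """
    tta_levels = list(tta_levels)
    if left_turns_per_route % len(tta_levels) != 0:
        raise ValueError(
            f"{left_turns_per_route} left turns per route cannot balance "
            f"{len(tta_levels)} TTA levels"
        )
    reps = left_turns_per_route // len(tta_levels)
    rng = np.random.default_rng(seed)
    rows = []
    for route in range(1, n_routes + 1):
        ttas = np.repeat(tta_levels, reps)
        rng.shuffle(ttas)
        ds = rng.choice(distances, size=left_turns_per_route)
        for trial, (tta0, d0) in enumerate(zip(ttas, ds), start=1):
            rows.append(
                {"route": route, "trial": trial,
                 "tta_condition": float(tta0), "d_condition": float(d0)}
            )
    return pd.DataFrame(rows)


def sample_population(spec: PopulationSpec) -> dict[int, ModelParams]:
    """Draw per-participant parameters around the group means."""
    rng = np.random.default_rng(_subseed(spec.seed, 1))
    out = {}
    mean = spec.mean_params.to_dict()
    for pid in range(1, spec.n_participants + 1):
        kw = {}
        for name, lo in _CLIP_LO.items():
            sd = spec.param_sd.get(name, 0.0)
            val = mean[name] + (rng.normal(0.0, sd) if sd > 0 else 0.0)
            kw[name] = max(val, lo)
        out[pid] = ModelParams(**kw)
    return out


def generate_dataset(
    spec: PopulationSpec,
    schedule: pd.DataFrame | None = None,
    n_routes: int = 8,
    left_turns_per_route: int = 15,
    tta_levels=(4.0, 5.0, 6.0),
    distances=(90.0, 120.0, 150.0),
    variant: ModelVariant | str = ModelVariant.FULL,
    sim_dt: float = fpt.DEFAULT_SIM_DT,
) -> pd.DataFrame:
    """One TrialRecord row per scheduled left turn per participant.

    If no common ``schedule`` is given, each participant receives their
    own (seed-derived) schedule, as each simulated driver follows their
    own randomized routes.  Decisions and go-RTs are generated by
    Euler-Maruyama simulation under that participant's parameters;
    exclusion labels are then assigned (``no_full_stop`` on any trial,
    ``pedal_held`` on go trials, and deterministically ``rt_gt_2s`` for
    go-RTs above 2 s).  Bit-reproducible from the spec.
    """
    population = sample_population(spec)
    records = []
    for pid, params in population.items():
        sched = (
            schedule
            if schedule is not None
            else generate_schedule(
                n_routes, left_turns_per_route, tta_levels, distances,
                seed=_subseed(spec.seed, 2, pid),
            )
        )
        # simulate per condition in batch, then deal outcomes back to trials
        for ci, ((tta0, d0), g) in enumerate(
            sched.groupby(["tta_condition", "d_condition"], sort=True)
        ):
            c = Condition(float(tta0), float(d0))
            sims = simulate_trials(
                params, c, variant, n=len(g), dt=sim_dt,
                seed=_subseed(spec.seed, 3, pid, ci),
            )
            for (_, trial_row), (_, sim) in zip(g.iterrows(), sims.iterrows()):
                records.append(
                    {
                        "participant_id": pid,
                        "route": int(trial_row["route"]),
                        "trial": int(trial_row["trial"]),
                        "tta_condition": float(tta0),
                        "d_condition": float(d0),
                        "decision": sim["decision"],
                        "rt": sim["rt"] if sim["decision"] == "go" else np.nan,
                    }
                )
    df = pd.DataFrame(records).sort_values(
        ["participant_id", "route", "trial"], ignore_index=True
    )
    # exclusion labels, one reason per trial, in priority order
    rng = np.random.default_rng(_subseed(spec.seed, 4))
    n = len(df)
    reason = np.array(["none"] * n, dtype=object)
    no_stop = rng.random(n) < spec.no_full_stop_rate
    reason[no_stop] = "no_full_stop"
    is_go = (df["decision"] == "go").to_numpy()
    pedal = (rng.random(n) < spec.pedal_held_rate) & is_go & (reason == "none")
    reason[pedal] = "pedal_held"
    long_rt = is_go & (df["rt"].to_numpy() > RT_EXCLUSION_THRESHOLD) & (reason == "none")
    reason[long_rt] = "rt_gt_2s"
    df["excluded"] = reason != "none"
    df["exclusion_reason"] = reason
    return df


def apply_exclusions(records: pd.DataFrame):
    """Drop flagged records; returns (retained, counts-per-reason table)."""
    counts = (
        records.loc[records["excluded"], "exclusion_reason"]
        .value_counts()
        .rename_axis("exclusion_reason")
        .rename("n_excluded")
    )
    retained = records.loc[~records["excluded"]].reset_index(drop=True)
    return retained, counts


def write_dataset_csv(df: pd.DataFrame, path, config_hash: str | None = None) -> None:
    """Write the trial table with the mandatory header (rt empty for stays)."""
    cols = [
        "participant_id", "route", "trial", "tta_condition", "d_condition",
        "decision", "rt", "excluded", "exclusion_reason",
    ]
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False, columns=cols)


def read_dataset_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
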
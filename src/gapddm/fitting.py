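"""Quantile-based weighted least-squares fitting by differential evolution.

The fitting target is one :class:`ConditionSummary` per design cell:
the observed go probability and the go-RT quantiles at fixed levels.
The objective is the weighted least-sum score

    L = sum_c [ w_p * n_c * (pgo_obs - pgo_pred)^2
                + w_q * ngo_c * sum_l (q_obs,l - q_pred,l)^2 ]

with the quantile term dropped for cells with too few go responses
(fewer than 4) or where the model predicts essentially no go mass.
Stay trials enter only through the go probability: no response time can
be attached to a stay decision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import differential_evolution

from .core import ModelParams, ModelVariant, free_parameter_names
from .kinematics import Condition
from . import fpt
from .fpt import GridResolutionError, solve

__all__ = [
    "ConditionSummary",
    "FitResult",
    "DESettings",
    "FitFailureError",
    "summarize_conditions",
    "wls_loss",
    "fit",
    "fit_per_participant",
    "DEFAULT_QUANTILE_LEVELS",
    "DEFAULT_SEARCH_BOUNDS",
]

logger = logging.getLogger(__name__)

DEFAULT_QUANTILE_LEVELS = (0.1, 0.3, 0.5, 0.7, 0.9)
#: fewer go responses than this and a cell's quantiles are unreliable
MIN_GO_FOR_QUANTILES = 4
#: weights of the probability and quantile terms of the score
DEFAULT_WEIGHT_P = 2.0
DEFAULT_WEIGHT_Q = 1.0
#: loss assigned when the solver refuses a parameter set (grid blow-up)
PENALTY_LOSS = 1e12

DEFAULT_SEARCH_BOUNDS = {
    "alpha": (0.0, 5.0),
    "beta": (0.0, 1.0),
    "theta_crit": (2.0, 20.0),
    "b0": (0.5, 5.0),
    "k": (0.05, 5.0),
    "tau": (1.0, 10.0),
    "mu_nd": (0.0, 1.5),
    "sigma_nd": (0.01, 0.5),
}


class FitFailureError(RuntimeError):
    """Every evaluated parameter set was invalid (solver instability)."""


@dataclass
class ConditionSummary:
    """Observed go probability and go-RT quantiles for one design cell.

    For per-participant (or pooled) summaries ``p_go = n_go / n_trials``;
    group-averaged summaries instead carry the unweighted mean of
    within-participant go probabilities and vincentized quantiles, with
    the counts retained for loss weighting.
    """

    condition: Condition
    n_trials: int
    n_go: int
    p_go: float
    go_rt_quantiles: np.ndarray | None
    quantile_levels: tuple = DEFAULT_QUANTILE_LEVELS
    quantiles_valid: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.n_go <= self.n_trials):
            raise ValueError("need 0 <= n_go <= n_trials")
        if self.quantiles_valid:
            q = np.asarray(self.go_rt_quantiles, dtype=float)
            if np.any(np.diff(q) < -1e-12):
                raise ValueError("quantiles must be non-decreasing across levels")


@dataclass
class DESettings:
    """Differential-evolution budget.

    ``popsize`` follows the scipy convention (population = popsize *
    number of free parameters); defaults give a 15x-dimension
    population, 200 generations, relative tolerance 1e-6.  Aggressive
    (fast-converging) mutation/recombination settings were found to
    collapse the population prematurely on sampled data; the defaults
    deliberately keep scipy's dithered mutation.
    """

    popsize: int = 15
    maxiter: int = 200
    tol: float = 1e-6
    mutation: tuple = (0.5, 1.0)
    recombination: float = 0.7
    strategy: str = "best1bin"
    polish: bool = True
    init: str = "latinhypercube"


@dataclass
class FitResult:
    """Best parameters found by differential evolution for one target."""

    params: ModelParams
    variant: ModelVariant
    loss: float
    n_evaluations: int
    seed: int
    converged: bool
    search_bounds: dict
    free_names: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(self.variant),
            "variant": self.variant.value,
            "loss": self.loss,
            "n_evaluations": self.n_evaluations,
            "seed": self.seed,
            "converged": self.converged,
            "search_bounds": {k: list(v) for k, v in self.search_bounds.items()},
            "free_names": list(self.free_names),
        }

    def to_json(self) -> str:
        import json

        return json.dumps(self.to_dict(), indent=2)


def summarize_conditions(
    trials,
    quantile_levels=DEFAULT_QUANTILE_LEVELS,
    min_go: int = MIN_GO_FOR_QUANTILES,
) -> list[ConditionSummary]:
    """Per-condition counts and go-RT quantiles from trial records.

    ``trials`` is a DataFrame with columns ``tta_condition``,
    ``d_condition``, ``decision`` and ``rt``; excluded trials are
    expected to have been filtered out already.
    """
    if len(trials) == 0:
        raise ValueError("no trials to summarize")
    out = []
    grouped = trials.groupby(["tta_condition", "d_condition"], sort=True)
    for (tta0, d0), g in grouped:
        n = len(g)
        go = g[g["decision"] == "go"]
        n_go = len(go)
        valid = n_go >= min_go
        quants = (
            np.quantile(go["rt"].to_numpy(dtype=float), quantile_levels)
            if n_go > 0
            else None
        )
        out.append(
            ConditionSummary(
                condition=Condition(float(tta0), float(d0)),
                n_trials=n,
                n_go=n_go,
                p_go=n_go / n,
                go_rt_quantiles=quants,
                quantile_levels=tuple(quantile_levels),
                quantiles_valid=valid,
            )
        )
    return out


def _predict_summary(p, summary, variant, dt, dx):
    sol = solve(p, summary.condition, variant, dt=dt, dx=dx)
    return sol.p_go, sol.rt_quantiles(summary.quantile_levels)


def wls_loss(
    p: ModelParams,
    summaries,
    variant: ModelVariant | str = ModelVariant.FULL,
    weight_p: float = DEFAULT_WEIGHT_P,
    weight_q: float = DEFAULT_WEIGHT_Q,
    dt: float = fpt.DEFAULT_DT,
    dx: float = fpt.DEFAULT_DX,
) -> float:
    """Weighted least-sum score of a parameter set against summaries.

    Deterministic given the parameters and grid settings.  Parameter
    sets the solver refuses receive a large finite penalty so that the
    optimizer can traverse them.
    """
    variant = ModelVariant.coerce(variant)
    total = 0.0
    for s in summaries:
        try:
            p_pred, q_pred = _predict_summary(p, s, variant, dt, dx)
        except GridResolutionError:
            return PENALTY_LOSS
        total += weight_p * s.n_trials * (s.p_go - p_pred) ** 2
        if s.quantiles_valid and p_pred >= 1e-4 and s.go_rt_quantiles is not None:
            q_obs = np.asarray(s.go_rt_quantiles, dtype=float)
            total += weight_q * s.n_go * float(np.sum((q_obs - q_pred) ** 2))
    return float(total)


def _params_from_vector(x, free_names, base: ModelParams) -> ModelParams:
    kw = dict(zip(free_names, (float(v) for v in x)))
    # keep hard invariants satisfiable at the bound edges
    if "b0" in kw:
        kw["b0"] = max(kw["b0"], 1e-6)
    if "k" in kw:
        kw["k"] = max(kw["k"], 1e-6)
    if "alpha" in kw:
        kw["alpha"] = max(kw["alpha"], 0.0)
    if "sigma_nd" in kw:
        kw["sigma_nd"] = max(kw["sigma_nd"], 0.0)
    return base.replace(**kw)


def fit(
    summaries,
    variant: ModelVariant | str = ModelVariant.FULL,
    search_bounds: dict | None = None,
    de_settings: DESettings | None = None,
    seed: int = 0,
    fixed: dict | None = None,
    weight_p: float = DEFAULT_WEIGHT_P,
    weight_q: float = DEFAULT_WEIGHT_Q,
    dt: float = fpt.DEFAULT_DT,
    dx: float = fpt.DEFAULT_DX,
    nm_refine: int = 0,
) -> FitResult:
    """Differential-evolution fit of a model variant to summaries.

    Parameters in ``fixed`` (name -> value) are held at that value and
    removed from the search; the remaining free parameters are searched
    inside ``search_bounds``.  Fully reproducible from ``seed``.

    ``nm_refine > 0`` appends a Nelder-Mead refinement (up to that many
    further objective evaluations) from the best point found — useful
    because the objective's curved ridges (boundary scale against
    collapse sharpness) slow the final convergence of the population.
    """
    variant = ModelVariant.coerce(variant)
    de = de_settings or DESettings()
    fixed = dict(fixed or {})
    bounds_map = dict(DEFAULT_SEARCH_BOUNDS)
    if search_bounds:
        bounds_map.update(search_bounds)
    free_names = [n for n in free_parameter_names(variant) if n not in fixed]
    if not free_names:
        raise ValueError("no free parameters left to fit")
    base = ModelParams(b0=1.0, k=1.0).replace(**fixed)
    bounds = [bounds_map[n] for n in free_names]

    n_eval = 0
    any_valid = [False]

    def objective(x):
        nonlocal n_eval
        n_eval += 1
        p = _params_from_vector(x, free_names, base)
        loss = wls_loss(
            p, summaries, variant, weight_p=weight_p, weight_q=weight_q, dt=dt, dx=dx
        )
        if loss < PENALTY_LOSS:
            any_valid[0] = True
        return loss

    result = differential_evolution(
        objective,
        bounds,
        seed=seed,
        popsize=de.popsize,
        maxiter=de.maxiter,
        tol=de.tol,
        mutation=de.mutation,
        recombination=de.recombination,
        strategy=de.strategy,
        polish=de.polish,
        init=de.init,
        updating="immediate",
        workers=1,
    )
    if not any_valid[0]:
        raise FitFailureError(
            f"all {n_eval} evaluated parameter sets were refused by the solver "
            f"(variant={variant.value}, bounds={dict(zip(free_names, bounds))})"
        )
    best_x, best_loss = np.asarray(result.x, dtype=float), float(result.fun)
    if nm_refine > 0:
        from scipy.optimize import minimize

        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])

        def bounded(x):
            if np.any(x < lo) or np.any(x > hi):
                return PENALTY_LOSS
            return objective(x)

        nm = minimize(
            bounded, best_x, method="Nelder-Mead",
            options={"maxfev": int(nm_refine), "xatol": 1e-4, "fatol": 1e-6},
        )
        if nm.fun < best_loss:
            best_x, best_loss = np.clip(nm.x, lo, hi), float(nm.fun)
    params = _params_from_vector(best_x, free_names, base)
    return FitResult(
        params=params,
        variant=variant,
        loss=best_loss,
        n_evaluations=n_eval,
        seed=seed,
        converged=bool(result.success),
        search_bounds={n: tuple(bounds_map[n]) for n in free_names},
        free_names=free_names,
    )


def refine(
    summaries,
    start: ModelParams,
    variant: ModelVariant | str = ModelVariant.FULL,
    search_bounds: dict | None = None,
    fixed: dict | None = None,
    maxfev: int = 2000,
    weight_p: float = DEFAULT_WEIGHT_P,
    weight_q: float = DEFAULT_WEIGHT_Q,
    dt: float = fpt.DEFAULT_DT,
    dx: float = fpt.DEFAULT_DX,
) -> FitResult:
    """Bounded Nelder-Mead refinement of an existing parameter set.

    Typical use: polish a solution from a coarse-grid global search on a
    finer solver grid.  Deterministic; no population search.
    """
    from scipy.optimize import minimize

    variant = ModelVariant.coerce(variant)
    fixed = dict(fixed or {})
    bounds_map = dict(DEFAULT_SEARCH_BOUNDS)
    if search_bounds:
        bounds_map.update(search_bounds)
    free_names = [n for n in free_parameter_names(variant) if n not in fixed]
    base = ModelParams(b0=1.0, k=1.0).replace(**fixed)
    lo = np.array([bounds_map[n][0] for n in free_names])
    hi = np.array([bounds_map[n][1] for n in free_names])
    x0 = np.clip([getattr(start, n) for n in free_names], lo, hi)
    n_eval = 0

    def objective(x):
        nonlocal n_eval
        n_eval += 1
        if np.any(x < lo) or np.any(x > hi):
            return PENALTY_LOSS
        p = _params_from_vector(x, free_names, base)
        return wls_loss(
            p, summaries, variant, weight_p=weight_p, weight_q=weight_q, dt=dt, dx=dx
        )

    res = minimize(
        objective, x0, method="Nelder-Mead",
        options={"maxfev": int(maxfev), "xatol": 1e-4, "fatol": 1e-6},
    )
    # keep whichever of start/refined is better under this objective
    f0 = objective(x0)
    if res.fun < f0:
        best_x, best_loss = np.clip(res.x, lo, hi), float(res.fun)
    else:
        best_x, best_loss = x0, float(f0)
    return FitResult(
        params=_params_from_vector(best_x, free_names, base),
        variant=variant,
        loss=best_loss,
        n_evaluations=n_eval,
        seed=-1,
        converged=bool(res.success),
        search_bounds={n: tuple(bounds_map[n]) for n in free_names},
        free_names=free_names,
    )


def fit_per_participant(
    trials,
    variant: ModelVariant | str = ModelVariant.FULL,
    quantile_levels=DEFAULT_QUANTILE_LEVELS,
    seed: int = 0,
    **fit_kwargs,
):
    """Fit each participant individually.

    Returns ``(results, skipped)`` where ``results`` maps participant id
    to :class:`FitResult` and ``skipped`` lists participants with fewer
    than two conditions represented.  The same seed is used for every
    participant, so identical data under two ids fit identically.
    """
    results: dict = {}
    skipped: list = []
    for pid, g in sorted(trials.groupby("participant_id"), key=lambda kv: str(kv[0])):
        n_conditions = g.groupby(["tta_condition", "d_condition"]).ngroups
        if n_conditions < 2:
            skipped.append(pid)
            logger.warning(
                "participant %s has only %d condition(s); skipped", pid, n_conditions
            )
            continue
        summaries = summarize_conditions(g, quantile_levels)
        results[pid] = fit(summaries, variant, seed=int(seed), **fit_kwargs)
    return results, skipped
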
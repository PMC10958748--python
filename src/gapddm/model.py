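"""Statsmodels-style modelling interface.

:class:`GapAcceptanceModel` wraps a set of per-condition fitting
targets (go probability + go-RT quantiles) together with a model
variant and solver/objective settings; ``fit()`` runs the
differential-evolution search and returns a
:class:`GapAcceptanceResults` carrying the estimates, fit diagnostics
and prediction/simulation methods.

    >>> model = GapAcceptanceModel.from_trials(trials)          # doctest: +SKIP
    >>> res = model.fit(seed=1)                                 # doctest: +SKIP
    >>> print(res.summary())                                    # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fpt
from .core import ModelParams, ModelVariant, free_parameter_names
from .crossval import make_folds, run_cv
from .fitting import (
    DEFAULT_QUANTILE_LEVELS,
    DEFAULT_WEIGHT_P,
    DEFAULT_WEIGHT_Q,
    DESettings,
    fit as _fit,
    summarize_conditions,
    wls_loss,
)
from .fpt import simulate_trials, solve
from .group import group_condition_summaries, group_means

__all__ = ["GapAcceptanceModel", "GapAcceptanceResults", "compare_variants"]


class GapAcceptanceModel:
    """Gap-acceptance diffusion model bound to per-condition targets.

    Parameters
    ----------
    summaries : list of ConditionSummary
        The fitting targets (see :func:`gapddm.fitting.summarize_conditions`
        and :func:`gapddm.group.group_condition_summaries`).
    variant : {"full", "var_drift_const_bound", "const_drift_const_bound"}
        Model restriction; aliases ``alt1``/``alt2`` are accepted.
    """

    def __init__(
        self,
        summaries,
        variant: ModelVariant | str = ModelVariant.FULL,
        weight_p: float = DEFAULT_WEIGHT_P,
        weight_q: float = DEFAULT_WEIGHT_Q,
        dt: float = fpt.DEFAULT_DT,
        dx: float = fpt.DEFAULT_DX,
    ) -> None:
        self.summaries = list(summaries)
        self.variant = ModelVariant.coerce(variant)
        self.weight_p = weight_p
        self.weight_q = weight_q
        self.dt = dt
        self.dx = dx

    # -- constructors -------------------------------------------------
    @classmethod
    def from_trials(
        cls,
        trials: pd.DataFrame,
        variant: ModelVariant | str = ModelVariant.FULL,
        group: bool = True,
        quantile_levels=DEFAULT_QUANTILE_LEVELS,
        drop_excluded: bool = True,
        **kwargs,
    ) -> "GapAcceptanceModel":
        """Build the model from a trial table.

        With ``group=True`` the targets are group-averaged (mean of
        within-participant go probabilities, vincentized quantiles);
        otherwise trials are pooled.
        """
        if drop_excluded and "excluded" in trials.columns:
            trials = trials.loc[~trials["excluded"]]
        if group and "participant_id" in trials.columns:
            summaries = group_condition_summaries(trials, quantile_levels)
        else:
            summaries = summarize_conditions(trials, quantile_levels)
        obj = cls(summaries, variant, **kwargs)
        obj._trials = trials
        return obj

    @classmethod
    def from_csv(cls, path, **kwargs) -> "GapAcceptanceModel":
        return cls.from_trials(pd.read_csv(path, comment="#"), **kwargs)

    # -- objective / fitting ------------------------------------------
    def loss(self, params: ModelParams) -> float:
        return wls_loss(
            params,
            self.summaries,
            self.variant,
            weight_p=self.weight_p,
            weight_q=self.weight_q,
            dt=self.dt,
            dx=self.dx,
        )

    def fit(
        self,
        search_bounds: dict | None = None,
        de_settings: DESettings | None = None,
        seed: int = 0,
        fixed: dict | None = None,
        nm_refine: int = 0,
    ) -> "GapAcceptanceResults":
        fr = _fit(
            self.summaries,
            self.variant,
            search_bounds=search_bounds,
            de_settings=de_settings,
            seed=seed,
            fixed=fixed,
            nm_refine=nm_refine,
            weight_p=self.weight_p,
            weight_q=self.weight_q,
            dt=self.dt,
            dx=self.dx,
        )
        return GapAcceptanceResults(self, fr)

    # -- prediction ----------------------------------------------------
    def predict(self, params: ModelParams, conditions=None) -> pd.DataFrame:
        """Model-implied per-condition go probability, mean RT and quantiles."""
        conditions = conditions or [s.condition for s in self.summaries]
        rows = []
        for c in conditions:
            sol = solve(params, c, self.variant, dt=self.dt, dx=self.dx)
            quants = sol.rt_quantiles(DEFAULT_QUANTILE_LEVELS)
            row = {
                "tta_condition": c.tta0,
                "d_condition": c.d0,
                "p_go": sol.p_go,
                "mean_rt": sol.mean_rt(),
            }
            row.update(
                {f"rt_q{int(l * 100)}": q for l, q in zip(DEFAULT_QUANTILE_LEVELS, quants)}
            )
            rows.append(row)
        return pd.DataFrame(rows)

    def cross_validate(
        self,
        de_settings: DESettings | None = None,
        seed: int = 0,
        observed_mean_rts: dict | None = None,
    ):
        """Hold-one-condition-out CV over this model's summaries."""
        if observed_mean_rts is None and getattr(self, "_trials", None) is not None:
            gm = group_means(self._trials)
            observed_mean_rts = {
                (r.tta_condition, r.d_condition): r.mean_rt for r in gm.itertuples()
            }
        folds = make_folds(self.summaries, observed_mean_rts)
        table = run_cv(
            folds,
            self.variant,
            de_settings=de_settings,
            seed=seed,
            dt=self.dt,
            dx=self.dx,
            weight_p=self.weight_p,
            weight_q=self.weight_q,
        )
        return folds, table


@dataclass
class GapAcceptanceResults:
    """Fit results: estimates, diagnostics, prediction and simulation."""

    model: GapAcceptanceModel
    fit_result: object

    @property
    def params(self) -> ModelParams:
        return self.fit_result.params

    @property
    def loss(self) -> float:
        return self.fit_result.loss

    @property
    def converged(self) -> bool:
        return self.fit_result.converged

    def predict(self, conditions=None) -> pd.DataFrame:
        return self.model.predict(self.params, conditions)

    def simulate(self, condition, n: int = 1000, seed: int = 0) -> pd.DataFrame:
        return simulate_trials(
            self.params, condition, self.model.variant, n=n, seed=seed
        )

    def summary(self) -> str:
        """Plain-text estimation report."""
        fr = self.fit_result
        lines = [
            "Gap acceptance drift-diffusion model",
            "=" * 52,
            f"variant:        {self.model.variant.value}",
            f"conditions:     {len(self.model.summaries)}",
            f"loss (WLS):     {fr.loss:.6g}",
            f"evaluations:    {fr.n_evaluations}",
            f"converged:      {fr.converged}",
            f"seed:           {fr.seed}",
            "-" * 52,
            f"{'parameter':<12}{'estimate':>12}{'bounds':>24}",
        ]
        pdict = self.params.to_dict()
        for name in free_parameter_names(self.model.variant):
            if name in fr.search_bounds:
                lo, hi = fr.search_bounds[name]
                bounds = f"[{lo:g}, {hi:g}]"
            else:
                bounds = "(fixed)"
            lines.append(f"{name:<12}{pdict[name]:>12.4f}{bounds:>24}")
        lines.append("=" * 52)
        return "\n".join(lines)


def compare_variants(
    summaries,
    variants=("full", "var_drift_const_bound", "const_drift_const_bound"),
    de_settings: DESettings | None = None,
    seed: int = 0,
    **model_kwargs,
):
    """Fit several variants to identical summaries with a shared seed.

    Returns ``(results, table)`` — a dict of
    :class:`GapAcceptanceResults` per variant and a long-format table of
    per-variant loss and per-condition predicted p_go and mean RT.
    """
    results, rows = {}, []
    for v in variants:
        m = GapAcceptanceModel(summaries, v, **model_kwargs)
        res = m.fit(de_settings=de_settings, seed=seed)
        results[m.variant.value] = res
        pred = res.predict()
        for r in pred.itertuples():
            rows.append(
                {
                    "variant": m.variant.value,
                    "tta_condition": r.tta_condition,
                    "d_condition": r.d_condition,
                    "predicted_p_go": r.p_go,
                    "predicted_mean_rt": r.mean_rt,
                    "loss": res.loss,
                }
            )
    return results, pd.DataFrame(rows)
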
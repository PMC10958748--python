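"""Hold-one-condition-out cross-validation.

For each cell of the 3x3 design the model is fitted to the remaining
eight cells and the fitted parameters are used to predict the go
probability and mean go-RT of the held-out cell.  Fold order follows
the deterministic condition-grid order, and each fold's optimizer seed
derives from the master seed and fold index, so the whole procedure is
reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fpt
from .core import ModelVariant
from .fitting import ConditionSummary, DESettings, FitResult, fit
from .fpt import solve
from .kinematics import Condition

__all__ = ["CVFold", "make_folds", "run_cv"]

logger = logging.getLogger(__name__)


@dataclass
class CVFold:
    """One hold-one-condition-out fold."""

    held_out: Condition
    train_summaries: list
    test_summary: ConditionSummary
    observed_mean_rt: float = np.nan
    fit: FitResult | None = None
    predicted_p_go: float = np.nan
    predicted_mean_rt: float = np.nan
    error: str | None = None

    @property
    def observed_p_go(self) -> float:
        return self.test_summary.p_go


def make_folds(
    summaries,
    observed_mean_rts: dict | None = None,
    expected_grid=None,
) -> list[CVFold]:
    """Build the nine folds from one summary per condition of the grid.

    ``observed_mean_rts`` optionally maps ``(tta0, d0)`` to the observed
    mean go-RT of that condition (e.g. from :func:`gapddm.group.group_means`).
    ``expected_grid`` (a list of Conditions) enables a completeness
    check; a missing condition raises an error naming it.
    """
    summaries = sorted(summaries, key=lambda s: (s.condition.tta0, s.condition.d0))
    conds = [s.condition for s in summaries]
    if len(set(conds)) != len(conds):
        raise ValueError("duplicate condition summaries")
    if expected_grid is not None:
        have = {(c.tta0, c.d0) for c in conds}
        missing = [c for c in expected_grid if (c.tta0, c.d0) not in have]
        if missing:
            raise ValueError(
                f"missing condition(s): {', '.join(c.label() for c in missing)}"
            )
    observed_mean_rts = observed_mean_rts or {}
    folds = []
    for held in summaries:
        folds.append(
            CVFold(
                held_out=held.condition,
                train_summaries=[s for s in summaries if s is not held],
                test_summary=held,
                observed_mean_rt=observed_mean_rts.get(
                    (held.condition.tta0, held.condition.d0), np.nan
                ),
            )
        )
    return folds


def run_cv(
    folds,
    variant: ModelVariant | str = ModelVariant.FULL,
    de_settings: DESettings | None = None,
    seed: int = 0,
    dt: float = fpt.DEFAULT_DT,
    dx: float = fpt.DEFAULT_DX,
    restart_de_settings: DESettings | None = None,
    restart_threshold: float = np.inf,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit every fold and predict its held-out condition.

    Completes the folds in place and returns the summary table.  A fit
    failure in one fold is recorded and does not abort the others.

    If ``restart_de_settings`` is given, any fold whose fitted loss ends
    above ``restart_threshold`` is refitted once with those settings and
    the lower-loss result is kept — a guard against the occasional fold
    where the population converges into a secondary basin.
    """
    variant = ModelVariant.coerce(variant)
    for i, fold in enumerate(folds):
        fold_seed = (int(seed) * 97 + i) % (2**31)
        try:
            fold.fit = fit(
                fold.train_summaries,
                variant,
                de_settings=de_settings,
                seed=fold_seed,
                dt=dt,
                dx=dx,
                **fit_kwargs,
            )
            if restart_de_settings is not None and fold.fit.loss > restart_threshold:
                logger.info(
                    "fold %d (%s): loss %.3g above restart threshold; refitting",
                    i, fold.held_out.label(), fold.fit.loss,
                )
                retry = fit(
                    fold.train_summaries,
                    variant,
                    de_settings=restart_de_settings,
                    seed=fold_seed,
                    dt=dt,
                    dx=dx,
                    **fit_kwargs,
                )
                if retry.loss < fold.fit.loss:
                    fold.fit = retry
            sol = solve(fold.fit.params, fold.held_out, variant, dt=dt, dx=dx)
            fold.predicted_p_go = sol.p_go
            fold.predicted_mean_rt = sol.mean_rt()
        except Exception as exc:  # propagate per fold, keep going
            fold.error = f"{type(exc).__name__}: {exc}"
            logger.warning("fold %d (%s) failed: %s", i, fold.held_out.label(), fold.error)
    rows = [
        {
            "held_out_tta": f.held_out.tta0,
            "held_out_d": f.held_out.d0,
            "predicted_p_go": f.predicted_p_go,
            "observed_p_go": f.observed_p_go,
            "predicted_mean_rt": f.predicted_mean_rt,
            "observed_mean_rt": f.observed_mean_rt,
            "loss": f.fit.loss if f.fit else np.nan,
            "error": f.error or "",
        }
        for f in folds
    ]
    return pd.DataFrame(rows)
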
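"""Group-level aggregation of choices and response times.

Group RT distributions are vincentized: per-participant quantile
functions at fixed probability levels are averaged across participants,
and the group CDF is the inverse of that averaged quantile function.
Group means of go probability and response time are averages of
within-participant means, so every participant counts equally
regardless of trial counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import (
    ConditionSummary,
    DEFAULT_QUANTILE_LEVELS,
    MIN_GO_FOR_QUANTILES,
)
from .kinematics import Condition

__all__ = [
    "VincentizedDistribution",
    "participant_quantiles",
    "vincentize",
    "group_means",
    "binomial_sem",
    "group_condition_summaries",
]

logger = logging.getLogger(__name__)

#: 19 equally spaced levels 0.05 ... 0.95
DEFAULT_VINCENTIZE_LEVELS = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))


@dataclass
class VincentizedDistribution:
    """Group-averaged RT quantile function and its CDF inverse."""

    levels: np.ndarray
    group_quantiles: np.ndarray
    n_participants: int

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.group_quantiles = np.asarray(self.group_quantiles, dtype=float)
        if np.any(np.diff(self.group_quantiles) < -1e-12):
            raise ValueError("group quantiles must be non-decreasing in level")

    @property
    def cdf_grid(self) -> np.ndarray:
        """(time, cumulative probability) pairs: the axes swapped."""
        return np.column_stack([self.group_quantiles, self.levels])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"level": self.levels, "group_quantile": self.group_quantiles})

    def cdf_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.group_quantiles, "cdf": self.levels})


def participant_quantiles(rts, levels) -> np.ndarray:
    """Empirical quantiles by linear interpolation of order statistics."""
    rts = np.asarray(rts, dtype=float)
    levels = np.asarray(levels, dtype=float)
    if rts.size == 0:
        raise ValueError("cannot compute quantiles of an empty RT list")
    if np.any(np.diff(levels) <= 0) or np.any(levels <= 0) or np.any(levels >= 1):
        raise ValueError("levels must be strictly increasing within (0, 1)")
    return np.quantile(rts, levels)


def vincentize(per_participant_quantiles, levels) -> VincentizedDistribution:
    """Average per-participant quantile rows into a group distribution."""
    q = np.atleast_2d(np.asarray(per_participant_quantiles, dtype=float))
    if q.shape[0] == 0:
        raise ValueError("vincentization needs at least one participant")
    if q.shape[1] != len(levels):
        raise ValueError("quantile matrix does not match the levels")
    return VincentizedDistribution(
        levels=np.asarray(levels, dtype=float),
        group_quantiles=q.mean(axis=0),
        n_participants=q.shape[0],
    )


def vincentize_trials(trials, levels=DEFAULT_VINCENTIZE_LEVELS) -> VincentizedDistribution:
    """Vincentize the go-RTs of a trial table across participants.

    Participants contributing no go trials are dropped (count logged),
    mirroring how conditions without responses are omitted rather than
    imputed.
    """
    rows, dropped = [], 0
    for _, g in trials.groupby("participant_id"):
        rts = g.loc[g["decision"] == "go", "rt"].dropna().to_numpy()
        if rts.size == 0:
            dropped += 1
            continue
        rows.append(participant_quantiles(rts, levels))
    if dropped:
        logger.info("vincentize: dropped %d participant(s) with no go trials", dropped)
    if not rows:
        raise ValueError("no participant contributed any go trials")
    return vincentize(np.vstack(rows), levels)


def group_means(trials) -> pd.DataFrame:
    """Per-condition group means as averages of within-participant means.

    Returns one row per condition with the unweighted average of
    participants' go probabilities and mean go-RTs; participants with no
    go trials in a condition are omitted from that condition's RT mean.
    """
    rows = []
    for (tta0, d0), g in trials.groupby(["tta_condition", "d_condition"], sort=True):
        p_gos, rts = [], []
        for _, gp in g.groupby("participant_id"):
            p_gos.append((gp["decision"] == "go").mean())
            grt = gp.loc[gp["decision"] == "go", "rt"].dropna()
            if len(grt):
                rts.append(grt.mean())
        rows.append(
            {
                "tta_condition": tta0,
                "d_condition": d0,
                "mean_p_go": float(np.mean(p_gos)),
                "mean_rt": float(np.mean(rts)) if rts else np.nan,
                "n_participants": len(p_gos),
                "n_participants_rt": len(rts),
            }
        )
    return pd.DataFrame(rows)


def binomial_sem(n_go: int, n_trials: int) -> float:
    """Binomial proportion standard error sqrt(p(1-p)/n)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    p = n_go / n_trials
    return float(np.sqrt(p * (1 - p) / n_trials))


def group_condition_summaries(
    trials,
    quantile_levels=DEFAULT_QUANTILE_LEVELS,
    min_go: int = MIN_GO_FOR_QUANTILES,
) -> list[ConditionSummary]:
    """Group-averaged fitting targets, one per condition.

    The go probability is the unweighted mean of within-participant go
    probabilities; the go-RT quantiles are vincentized across the
    participants with go responses.  Total counts are retained for the
    loss weights.
    """
    out = []
    for (tta0, d0), g in trials.groupby(["tta_condition", "d_condition"], sort=True):
        n = len(g)
        n_go = int((g["decision"] == "go").sum())
        p_gos, qrows = [], []
        for _, gp in g.groupby("participant_id"):
            p_gos.append((gp["decision"] == "go").mean())
            rts = gp.loc[gp["decision"] == "go", "rt"].dropna().to_numpy()
            if rts.size:
                qrows.append(participant_quantiles(rts, quantile_levels))
        valid = n_go >= min_go and len(qrows) > 0
        quants = vincentize(np.vstack(qrows), quantile_levels).group_quantiles if qrows else None
        out.append(
            ConditionSummary(
                condition=Condition(float(tta0), float(d0)),
                n_trials=n,
                n_go=n_go,
                p_go=float(np.mean(p_gos)),
                go_rt_quantiles=quants,
                quantile_levels=tuple(quantile_levels),
                quantiles_valid=valid,
            )
        )
    return out
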
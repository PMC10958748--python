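"""Experimental design and oncoming-vehicle kinematics.

The left-turn scenario is parameterized by the initial time-to-arrival
(TTA) and initial distance of the oncoming vehicle.  The oncoming car
moves at the constant speed ``v = d0 / tta0``, so both TTA and distance
decrease linearly in time until arrival.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

__all__ = [
    "Condition",
    "KinematicState",
    "InvalidDesignError",
    "make_condition_grid",
    "tta_at",
    "distance_at",
]


class InvalidDesignError(ValueError):
    """Raised for non-physical design values (non-positive TTA or distance)."""


@dataclass(frozen=True, order=True)
class Condition:
    """One cell of the factorial design.

    Parameters
    ----------
    tta0 : float
        Initial time-to-arrival of the oncoming vehicle, seconds.
    d0 : float
        Initial distance to the oncoming vehicle, meters.

    The constant oncoming speed ``v = d0 / tta0`` (m/s) is derived.
    """

    tta0: float
    d0: float
    v: float = field(init=False, compare=False)

    def __post_init__(self) -> None:
        if self.tta0 <= 0 or self.d0 <= 0:
            raise InvalidDesignError(
                f"tta0 and d0 must be positive, got tta0={self.tta0}, d0={self.d0}"
            )
        object.__setattr__(self, "v", self.d0 / self.tta0)

    def label(self) -> str:
        return f"TTA={self.tta0:g}s, d={self.d0:g}m"


@dataclass(frozen=True)
class KinematicState:
    """Instantaneous state of the oncoming vehicle."""

    t: float
    tta: float
    d: float


def make_condition_grid(ttas, distances) -> list[Condition]:
    """Cartesian product of TTA and distance levels, tta0-major order.

    The ordering is deterministic so that downstream fold indices
    (cross-validation) are reproducible.
    """
    ttas = list(ttas)
    distances = list(distances)
    if not ttas or not distances:
        raise InvalidDesignError("condition levels must be non-empty")
    if any(x <= 0 for x in ttas) or any(x <= 0 for x in distances):
        raise InvalidDesignError("all TTA and distance levels must be positive")
    return [Condition(tta0=t, d0=d) for t, d in itertools.product(ttas, distances)]


def tta_at(c: Condition, t: float) -> float:
    """Current time-to-arrival ``tta0 - t``.

    Not clamped at zero: the caller decides how to treat post-arrival
    times (the collapsing-boundary logistic is defined for negative TTA
    and drives the boundary to zero there).
    """
    if t < 0:
        raise ValueError(f"t must be non-negative, got {t}")
    return c.tta0 - t


def distance_at(c: Condition, t: float) -> float:
    """Current distance ``d0 - v*t`` (not clamped; see :func:`tta_at`)."""
    if t < 0:
        raise ValueError(f"t must be non-negative, got {t}")
    return c.d0 - c.v * t


def state_at(c: Condition, t: float) -> KinematicState:
    return KinematicState(t=t, tta=tta_at(c, t), d=distance_at(c, t))
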
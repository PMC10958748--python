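"""Model parameters, drift, collapsing boundary and non-decision time.

The decision variable ``x`` accumulates relative evidence for going
versus staying:

    dx = alpha * ((TTA(t) + beta * d(t)) - theta_crit) dt + dW

with unit-variance Wiener noise (the diffusion coefficient is fixed at 1,
the usual identifiability convention, so all evidence units are on the
noise scale).  Accumulation terminates at collapsing boundaries

    b(t) = +/- b0 * f(TTA(t)),    f(TTA) = 1 / (1 + exp(-k * (TTA - tau)))

so that less evidence is required as the time gap closes.  Observed
response time on go trials is the boundary-crossing time plus a
normally distributed non-decision time N(mu_nd, sigma_nd), truncated at
zero so response times stay positive.

Two reduced variants are used for model comparison:

``const_drift_const_bound``
    Basic drift-diffusion model: the drift is constant within a trial,
    frozen at its initial value ``alpha ((TTA0 + beta d0) - theta_crit)``
    (so it still differs between conditions, as it must to explain the
    spread of go rates across the design); the boundary is the constant
    ``+/- b0``.
``var_drift_const_bound``
    Keeps the time-varying drift but holds the boundary at ``+/- b0``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .kinematics import Condition, distance_at, tta_at

__all__ = [
    "ModelVariant",
    "ModelParams",
    "drift",
    "boundary_gain",
    "boundary",
    "sample_nondecision_time",
    "nondecision_density",
]


class ModelVariant(str, Enum):
    """Which restriction of the generalized model is in force."""

    FULL = "full"
    CONST_DRIFT_CONST_BOUND = "const_drift_const_bound"
    VAR_DRIFT_CONST_BOUND = "var_drift_const_bound"

    @classmethod
    def coerce(cls, v) -> "ModelVariant":
        if isinstance(v, cls):
            return v
        aliases = {"alt1": cls.CONST_DRIFT_CONST_BOUND, "alt2": cls.VAR_DRIFT_CONST_BOUND}
        if v in aliases:
            return aliases[v]
        return cls(v)

    @property
    def has_collapsing_bound(self) -> bool:
        return self is ModelVariant.FULL

    @property
    def has_varying_drift(self) -> bool:
        return self is not ModelVariant.CONST_DRIFT_CONST_BOUND


@dataclass(frozen=True)
class ModelParams:
    """The free parameters of the generalized drift-diffusion model.

    Attributes
    ----------
    alpha : float
        Drift gain (>= 0), evidence units per second per second of
        combined gap.  With ``alpha = 0`` decisions are made at random.
    beta : float
        Relative weighting of distance against time-to-arrival, s/m.
    theta_crit : float
        Critical combined gap (s): at ``TTA + beta*d = theta_crit`` the
        drift changes sign.
    b0 : float
        Boundary scale (> 0), evidence units.
    k : float
        Boundary sensitivity to TTA (> 0), 1/s.
    tau : float
        TTA at which the boundary sits at its half value ``b0/2``, s.
    mu_nd, sigma_nd : float
        Mean and s.d. of the non-decision time, s (``sigma_nd >= 0``).
    """

    alpha: float = 0.0
    beta: float = 0.0
    theta_crit: float = 0.0
    b0: float = 1.0
    k: float = 1.0
    tau: float = 4.0
    mu_nd: float = 0.0
    sigma_nd: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.b0 <= 0:
            raise ValueError(f"b0 must be > 0, got {self.b0}")
        if self.k <= 0:
            raise ValueError(f"k must be > 0, got {self.k}")
        if self.sigma_nd < 0:
            raise ValueError(f"sigma_nd must be >= 0, got {self.sigma_nd}")

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)

    # -- serialization ------------------------------------------------
    def to_dict(self, variant: ModelVariant | str | None = None) -> dict:
        d = {
            "alpha": self.alpha,
            "beta": self.beta,
            "theta_crit": self.theta_crit,
            "b0": self.b0,
            "k": self.k,
            "tau": self.tau,
            "mu_nd": self.mu_nd,
            "sigma_nd": self.sigma_nd,
        }
        if variant is not None:
            d["variant"] = ModelVariant.coerce(variant).value
        return d

    def to_json(self, variant=None) -> str:
        return json.dumps(self.to_dict(variant), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        d = {k: v for k, v in d.items() if k != "variant"}
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "ModelParams":
        return cls.from_dict(json.loads(s))


def free_parameter_names(variant: ModelVariant | str) -> list[str]:
    """Names of the parameters that are free under a variant.

    full: 8 parameters.  Both constant-bound variants drop (k, tau);
    the basic-DDM variant's drift is the full drift frozen at t = 0, so
    it keeps (alpha, beta, theta_crit) as the condition-dependent drift
    parameterization.
    """
    variant = ModelVariant.coerce(variant)
    if variant is ModelVariant.FULL:
        return ["alpha", "beta", "theta_crit", "b0", "k", "tau", "mu_nd", "sigma_nd"]
    return ["alpha", "beta", "theta_crit", "b0", "mu_nd", "sigma_nd"]


def drift(
    p: ModelParams,
    c: Condition,
    t: float,
    variant: ModelVariant | str = ModelVariant.FULL,
) -> float:
    """Instantaneous drift rate, evidence units per second.

    TTA(t) and d(t) are clamped at zero past arrival so the drift stays
    meaningful in the censoring tail (the kinematic maps themselves are
    not clamped).
    """
    variant = ModelVariant.coerce(variant)
    if t < 0:
        raise ValueError(f"t must be non-negative, got {t}")
    if not variant.has_varying_drift:
        t = 0.0  # drift frozen at the moment the oncoming car appears
    tta = max(tta_at(c, t), 0.0)
    d = max(distance_at(c, t), 0.0)
    return p.alpha * ((tta + p.beta * d) - p.theta_crit)


def boundary_gain(p: ModelParams, tta) -> float:
    """Logistic boundary collapse factor ``f(TTA)`` in (0, 1).

    Strictly increasing in TTA for k > 0; equals 1/2 at ``TTA = tau``.
    Defined for any real TTA (tends to 0 as TTA -> -inf).
    """
    from scipy.special import expit

    out = expit(p.k * (np.asarray(tta, dtype=float) - p.tau))
    return float(out) if out.ndim == 0 else out


def boundary(
    p: ModelParams,
    c: Condition,
    t: float,
    variant: ModelVariant | str = ModelVariant.FULL,
) -> float:
    """Upper decision boundary at time t (> 0); the lower bound is its negation."""
    variant = ModelVariant.coerce(variant)
    if t < 0:
        raise ValueError(f"t must be non-negative, got {t}")
    if not variant.has_collapsing_bound:
        return p.b0
    return p.b0 * boundary_gain(p, tta_at(c, t))


def sample_nondecision_time(p: ModelParams, rng=None, size=None):
    """Draw non-decision times from N(mu_nd, sigma_nd) truncated at 0.

    With ``sigma_nd = 0`` the draw is the deterministic ``max(mu_nd, 0)``.
    Truncation is by resampling of the (typically tiny) negative mass.
    """
    rng = np.random.default_rng(rng)
    if p.sigma_nd == 0:
        val = max(p.mu_nd, 0.0)
        return val if size is None else np.full(size, val)
    n = 1 if size is None else int(np.prod(size))
    out = rng.normal(p.mu_nd, p.sigma_nd, size=n)
    bad = out < 0
    while bad.any():
        out[bad] = rng.normal(p.mu_nd, p.sigma_nd, size=bad.sum())
        bad = out < 0
    if size is None:
        return float(out[0])
    return out.reshape(size)


def nondecision_density(p: ModelParams, t: np.ndarray) -> np.ndarray:
    """Density of the zero-truncated non-decision normal on a grid.

    Used for convolving the decision-time density into the observed
    response-time density.  For ``sigma_nd = 0`` the caller should treat
    the non-decision time as a pure shift instead.
    """
    import math

    if p.sigma_nd == 0:
        raise ValueError("degenerate non-decision time has no density")
    t = np.asarray(t, dtype=float)
    z = (t - p.mu_nd) / p.sigma_nd
    dens = np.exp(-0.5 * z * z) / (p.sigma_nd * math.sqrt(2 * math.pi))
    dens[t < 0] = 0.0
    # renormalize by the mass surviving the truncation at zero
    mass = 0.5 * (1.0 + math.erf(p.mu_nd / (p.sigma_nd * math.sqrt(2))))
    return dens / mass
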
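"""First-passage solution of the gap-acceptance diffusion process.

Two routes to the same object are provided and serve as mutual oracles:

* :func:`solve` — deterministic Fokker-Planck (Crank-Nicolson) evolution
  of the evidence density between time-varying absorbing boundaries,
  yielding the go probability and the go decision-time density;
* :func:`simulate_trials` — Euler-Maruyama simulation of individual
  trials.

Time runs from the appearance of the oncoming vehicle (t = 0) to its
arrival (t = tta0); any probability mass still undecided at arrival is
censored into "stay", since the go option has physically expired.  The
observed response-time density is the go decision-time density convolved
with the (zero-truncated) normal non-decision time, so its support
extends past arrival.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.integrate import cumulative_trapezoid, trapezoid

from .core import (
    ModelParams,
    ModelVariant,
    boundary,
    drift,
    nondecision_density,
)
from .kinematics import Condition

__all__ = [
    "FPTSolution",
    "GridResolutionError",
    "solve",
    "simulate_trials",
    "convolve_nondecision",
    "predicted_summary",
]

#: default Fokker-Planck grid; exposed through RunConfig
DEFAULT_DT = 0.005
DEFAULT_DX = 0.025
#: default Euler-Maruyama step for the Monte-Carlo oracle
DEFAULT_SIM_DT = 0.001
#: cap on per-step Courant substepping before refusing the grid; a drift
#: that traverses more than this many cells per step is far outside the
#: physically sensible range and is cheaper to refuse than to resolve
MAX_SUBSTEPS = 12


class GridResolutionError(RuntimeError):
    """The requested grid cannot resolve the drift (|mu| * dt >= dx)."""


@dataclass
class FPTSolution:
    """First-passage output for one condition.

    ``time_grid`` extends past the censoring horizon ``t_max`` far enough
    to hold the non-decision-time convolution tail; ``go_density`` and
    ``stay_density`` are zero beyond ``t_max``.
    """

    time_grid: np.ndarray
    go_density: np.ndarray
    stay_density: np.ndarray
    rt_density_observed: np.ndarray
    p_go: float
    p_stay: float
    t_max: float
    p_censored: float = 0.0

    # -- derived quantities -------------------------------------------
    def rt_cdf(self) -> np.ndarray:
        """Unnormalized CDF of the observed go-RT density (plateaus at p_go)."""
        return np.concatenate(
            [[0.0], cumulative_trapezoid(self.rt_density_observed, self.time_grid)]
        )

    def rt_quantiles(self, levels) -> np.ndarray:
        """Observed-RT quantiles by linear interpolation of the CDF.

        Returns NaNs when there is (numerically) no go mass.
        """
        levels = np.asarray(levels, dtype=float)
        if self.p_go < 1e-12:
            return np.full(levels.shape, np.nan)
        cdf = self.rt_cdf() / self.rt_cdf()[-1]
        # make the CDF strictly increasing for interpolation
        return np.interp(levels, cdf, self.time_grid)

    def mean_rt(self, t_cap: float | None = None) -> float:
        """Mean observed response time, conditional on a go decision.

        ``t_cap`` additionally conditions on RT <= t_cap, matching data
        pipelines that exclude long response times.
        """
        if self.p_go < 1e-12:
            return np.nan
        if t_cap is None:
            return (
                trapezoid(self.time_grid * self.rt_density_observed, self.time_grid)
                / self.p_go
            )
        w = self.time_grid <= t_cap
        mass = trapezoid(self.rt_density_observed[w], self.time_grid[w])
        if mass < 1e-12:
            return np.nan
        return (
            trapezoid((self.time_grid * self.rt_density_observed)[w], self.time_grid[w])
            / mass
        )

    def mean_decision_time(self, conditional: bool = False) -> float:
        """Mean boundary-crossing time over both outcomes (or go only)."""
        dens = self.go_density + (0.0 if conditional else self.stay_density)
        mass = self.p_go if conditional else self.p_go + self.p_stay - self.p_censored
        if mass < 1e-12:
            return np.nan
        return trapezoid(self.time_grid * dens, self.time_grid) / mass

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.time_grid,
                "go_density": self.go_density,
                "rt_density_observed": self.rt_density_observed,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@njit(cache=True)
def _fp_step_core(p, mu, dt, dx, lo, hi, theta, sub, diag, sup, rhs, work):
    """One theta-scheme step with Dirichlet absorption at nodes lo/hi.

    ``theta = 0.5`` is Crank-Nicolson; ``theta = 1`` is implicit Euler
    (used for startup, damping the oscillatory transient the delta
    initial condition excites in CN).  Returns (absorbed_up,
    absorbed_low) mass for this step.  ``p`` is modified in place;
    sub/diag/sup/rhs/work are scratch arrays.
    """
    m = hi - lo - 1  # interior unknowns
    if m <= 0:
        # domain fully collapsed: everything goes to the boundaries
        tot = 0.0
        for i in range(p.shape[0]):
            tot += p[i]
            p[i] = 0.0
        return 0.5 * tot * dx, 0.5 * tot * dx
    c_m = mu / (2 * dx) + 0.5 / (dx * dx)
    c_0 = -1.0 / (dx * dx)
    c_p = -mu / (2 * dx) + 0.5 / (dx * dx)
    a_sub = -theta * dt * c_m
    a_diag = 1.0 - theta * dt * c_0
    a_sup = -theta * dt * c_p
    expl = (1.0 - theta) * dt
    mass_before = 0.0
    for j in range(m):
        i = lo + 1 + j
        pm = p[i - 1] if j > 0 else 0.0
        pp = p[i + 1] if j < m - 1 else 0.0
        rhs[j] = p[i] + expl * (c_m * pm + c_0 * p[i] + c_p * pp)
        mass_before += p[i]
    mass_before *= dx
    p_old_hi1 = p[hi - 1]
    p_old_lo1 = p[lo + 1]
    p_old_hi2 = p[hi - 2] if m >= 2 else 0.0
    p_old_lo2 = p[lo + 2] if m >= 2 else 0.0
    # Thomas algorithm
    sub[0] = 0.0
    diag[0] = a_diag
    sup[0] = a_sup
    for j in range(1, m):
        w = a_sub / diag[j - 1]
        diag[j] = a_diag - w * sup[j - 1]
        rhs[j] = rhs[j] - w * rhs[j - 1]
        sup[j] = a_sup
    work[m - 1] = rhs[m - 1] / diag[m - 1]
    for j in range(m - 2, -1, -1):
        work[j] = (rhs[j] - a_sup * work[j + 1]) / diag[j]
    mass_after = 0.0
    for j in range(m):
        v = work[j]
        if v < 0.0:
            v = 0.0
        p[lo + 1 + j] = v
        mass_after += v
    mass_after *= dx
    lost = mass_before - mass_after
    if lost < 0.0:
        lost = 0.0
    # split the absorbed mass between the two boundaries in proportion to
    # the (time-averaged) diffusive flux at each boundary; second-order
    # one-sided derivative where the stencil allows
    j_up = 0.5 * (p_old_hi1 + p[hi - 1])
    j_low = 0.5 * (p_old_lo1 + p[lo + 1])
    if m >= 3:
        j_up2 = 0.5 * (
            (4.0 * p_old_hi1 - p_old_hi2) + (4.0 * p[hi - 1] - p[hi - 2])
        ) / 2.0
        j_low2 = 0.5 * (
            (4.0 * p_old_lo1 - p_old_lo2) + (4.0 * p[lo + 1] - p[lo + 2])
        ) / 2.0
        if j_up2 > 0.0 and j_low2 > 0.0:
            j_up = j_up2
            j_low = j_low2
    tot = j_up + j_low
    w_up = 0.5 if tot <= 0.0 else j_up / tot
    return lost * w_up, lost * (1.0 - w_up)


@njit(cache=True)
def _fp_evolve(mu_steps, hi_steps, lo_steps, nx, x0_idx, dt, dx):
    """Evolve the evidence density; returns per-step absorbed go/stay mass."""
    n_steps = mu_steps.shape[0]
    p = np.zeros(nx)
    p[x0_idx] = 1.0 / dx
    go_flux = np.zeros(n_steps)
    stay_flux = np.zeros(n_steps)
    sub = np.zeros(nx)
    diag = np.zeros(nx)
    sup = np.zeros(nx)
    rhs = np.zeros(nx)
    work = np.zeros(nx)
    for n in range(n_steps):
        hi = hi_steps[n]
        lo = lo_steps[n]
        # mass overtaken by an inward-moving boundary is absorbed there
        for i in range(hi, nx):
            go_flux[n] += p[i] * dx
            p[i] = 0.0
        for i in range(0, lo + 1):
            stay_flux[n] += p[i] * dx
            p[i] = 0.0
        theta = 1.0 if n < 10 else 0.5
        # enforce the Courant condition |mu|*dt_sub < dx locally by
        # substepping where the drift is large (late-trial clamped drift)
        nsub = 1 + int(abs(mu_steps[n]) * dt / (0.9 * dx))
        dt_sub = dt / nsub
        for _ in range(nsub):
            up, low = _fp_step_core(
                p, mu_steps[n], dt_sub, dx, lo, hi, theta, sub, diag, sup, rhs, work
            )
            go_flux[n] += up
            stay_flux[n] += low
    remaining = 0.0
    for i in range(nx):
        remaining += p[i] * dx
    return go_flux, stay_flux, remaining


def _drift_schedule(p, c, variant, t_mid, t_max):
    variant = ModelVariant.coerce(variant)
    if not variant.has_varying_drift:
        mu0 = p.alpha * ((c.tta0 + p.beta * c.d0) - p.theta_crit)
        return np.full(t_mid.shape, mu0)
    tta = np.maximum(c.tta0 - t_mid, 0.0)
    d = np.maximum(c.d0 - c.v * t_mid, 0.0)
    return p.alpha * ((tta + p.beta * d) - p.theta_crit)


def _boundary_schedule(p, c, variant, t_end):
    variant = ModelVariant.coerce(variant)
    if not variant.has_collapsing_bound:
        return np.full(t_end.shape, p.b0)
    from .core import boundary_gain

    return p.b0 * boundary_gain(p, c.tta0 - t_end)


def solve(
    p: ModelParams,
    c: Condition,
    variant: ModelVariant | str = ModelVariant.FULL,
    dt: float = DEFAULT_DT,
    dx: float = DEFAULT_DX,
    t_max: float | None = None,
) -> FPTSolution:
    """Fokker-Planck solution of the first-passage problem.

    Parameters
    ----------
    dt, dx : float
        Time and evidence grid steps.  The scheme requires the Courant
        condition ``max|drift| * dt < dx``; a violation raises
        :class:`GridResolutionError` rather than silently degrading.
    t_max : float, optional
        Censoring horizon; defaults to the arrival time ``c.tta0``.
        Mass still undecided at ``t_max`` counts as "stay".
    """
    variant = ModelVariant.coerce(variant)
    if dt <= 0 or dx <= 0:
        raise ValueError("dt and dx must be positive")
    if t_max is None:
        t_max = c.tta0
    n_steps = max(1, int(round(t_max / dt)))
    t_end = dt * np.arange(1, n_steps + 1)
    t_mid = t_end - 0.5 * dt
    mu_steps = _drift_schedule(p, c, variant, t_mid, t_max)
    max_mu = float(np.max(np.abs(mu_steps)))
    # steps where |mu|*dt >= dx are subdivided to restore the Courant
    # condition; refuse only where that would need extreme refinement
    if max_mu * dt >= MAX_SUBSTEPS * 0.9 * dx:
        raise GridResolutionError(
            f"max |drift| = {max_mu:.3g} violates |drift|*dt < dx beyond "
            f"the substepping budget (dt={dt}, dx={dx}); refine the grid"
        )
    b_steps = _boundary_schedule(p, c, variant, t_end)
    half = int(np.ceil(p.b0 / dx - 1e-9))
    nx = 2 * half + 1  # node `half` sits at x = 0
    offs = np.maximum(1, np.rint(b_steps / dx).astype(np.int64))
    hi_steps = half + offs
    lo_steps = half - offs
    go_flux, stay_flux, remaining = _fp_evolve(
        mu_steps, hi_steps, lo_steps, nx, half, dt, dx
    )
    p_go = float(go_flux.sum())
    p_censored = float(remaining)
    p_stay = float(stay_flux.sum()) + p_censored
    go_density = np.concatenate([[0.0], go_flux / dt])
    stay_density = np.concatenate([[0.0], stay_flux / dt])
    # extend the grid to hold the convolution tail
    n_extra = int(np.ceil((p.mu_nd + 6 * p.sigma_nd) / dt)) + 1
    grid = dt * np.arange(n_steps + 1 + n_extra)
    go_density = np.concatenate([go_density, np.zeros(n_extra)])
    stay_density = np.concatenate([stay_density, np.zeros(n_extra)])
    rt_density = convolve_nondecision(go_density, p, dt)
    return FPTSolution(
        time_grid=grid,
        go_density=go_density,
        stay_density=stay_density,
        rt_density_observed=rt_density,
        p_go=p_go,
        p_stay=p_stay,
        t_max=t_max,
        p_censored=p_censored,
    )


def convolve_nondecision(go_density: np.ndarray, p: ModelParams, dt: float) -> np.ndarray:
    """Convolve a decision-time density with the non-decision density.

    The output stays on the same grid; mass beyond the grid end is
    folded back by renormalization so total mass is preserved.  For
    ``sigma_nd = 0`` the convolution degenerates to a shift by
    ``mu_nd`` (rounded to the grid).
    """
    go_density = np.asarray(go_density, dtype=float)
    mass_in = go_density.sum() * dt
    if p.sigma_nd == 0:
        shift = int(round(max(p.mu_nd, 0.0) / dt))
        out = np.zeros_like(go_density)
        if shift < len(out):
            out[shift:] = go_density[: len(out) - shift]
        return out
    n_kern = int(np.ceil((p.mu_nd + 6 * p.sigma_nd) / dt)) + 1
    tk = dt * np.arange(n_kern)
    kern = nondecision_density(p, tk)
    ks = kern.sum() * dt
    if ks > 0:
        kern = kern / ks
    out = np.convolve(go_density, kern * dt)[: len(go_density)]
    mass_out = out.sum() * dt
    if mass_out > 0 and mass_in > 0:
        out *= mass_in / mass_out
    return out


def predicted_summary(s: FPTSolution, quantile_levels):
    """(p_go, observed-RT quantiles) — the per-condition fitting target.

    Quantiles are NaN when the solution carries no go mass.
    """
    return s.p_go, s.rt_quantiles(quantile_levels)


#: Broadie-Glasserman-Kou continuity-correction constant: checking only
#: post-step positions misses within-step boundary touches; shifting the
#: boundary inward by 0.5826 * sigma * sqrt(dt) removes the O(sqrt(dt))
#: first-passage bias of the discrete check
_BGK_BETA = 0.5826


@njit(cache=True)
def _simulate_core(mu_steps, b_steps, dt, n_trials, seed):
    np.random.seed(seed)
    n_steps = mu_steps.shape[0]
    decisions = np.zeros(n_trials, dtype=np.int8)  # 1 go, 0 stay
    dtimes = np.full(n_trials, np.nan)
    sqrt_dt = np.sqrt(dt)
    shift = _BGK_BETA * sqrt_dt
    for i in range(n_trials):
        x = 0.0
        for s in range(n_steps):
            x += mu_steps[s] * dt + np.random.normal(0.0, 1.0) * sqrt_dt
            b = b_steps[s] - shift
            if b < 1e-9:
                b = 1e-9
            if x >= b:
                decisions[i] = 1
                dtimes[i] = (s + 1) * dt
                break
            if x <= -b:
                decisions[i] = 0
                dtimes[i] = (s + 1) * dt
                break
    return decisions, dtimes


def simulate_trials(
    p: ModelParams,
    c: Condition,
    variant: ModelVariant | str = ModelVariant.FULL,
    n: int = 1000,
    dt: float = DEFAULT_SIM_DT,
    seed: int = 0,
    t_max: float | None = None,
):
    """Euler-Maruyama simulation of n trials; the Monte-Carlo oracle.

    Returns a DataFrame with columns ``decision`` ("go"/"stay"),
    ``decision_time`` (NaN for censored stays) and ``rt`` (go trials
    only: decision time plus a sampled non-decision time).
    Fully reproducible from ``seed``.
    """
    import pandas as pd

    variant = ModelVariant.coerce(variant)
    if n < 1:
        raise ValueError("n must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if t_max is None:
        t_max = c.tta0
    n_steps = max(1, int(round(t_max / dt)))
    t_end = dt * np.arange(1, n_steps + 1)
    t_mid = t_end - 0.5 * dt
    mu_steps = _drift_schedule(p, c, variant, t_mid, t_max)
    b_steps = _boundary_schedule(p, c, variant, t_end)
    decisions, dtimes = _simulate_core(
        mu_steps, np.asarray(b_steps, dtype=float), dt, int(n), int(seed) % (2**31)
    )
    from .core import sample_nondecision_time

    rng = np.random.default_rng(int(seed) + 1)
    rts = np.full(n, np.nan)
    go = decisions == 1
    if go.any():
        rts[go] = dtimes[go] + sample_nondecision_time(p, rng, size=int(go.sum()))
    return pd.DataFrame(
        {
            "decision": np.where(go, "go", "stay"),
            "decision_time": dtimes,
            "rt": rts,
        }
    )
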
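# Methods

## The decision model

A driver stopped at an intersection, waiting to turn left across the
path of an oncoming car, decides between *go* (turn through the gap)
and *stay* (wait until the car has passed).  `gapddm` models this as
accumulation of noisy relative evidence `x(t)` toward one of two
absorbing boundaries:

    dx = alpha * ((TTA(t) + beta * d(t)) - theta_crit) dt + dW

where `TTA(t)` and `d(t)` are the current time-to-arrival and distance
of the oncoming vehicle, which decrease linearly under the constant
oncoming speed `v = d0 / tta0`.  The drift is positive while the
perceived combined gap `TTA + beta*d` exceeds the critical value
`theta_crit` and negative after; with `alpha = 0` decisions are made at
random.  The noise `dW` is a unit-variance Wiener process — fixing the
diffusion coefficient at 1 is the usual identifiability convention, so
evidence units are defined by the noise scale.

The closing gap creates urgency, modelled as boundaries that collapse
with the *current* time-to-arrival rather than with elapsed time:

    b(t) = +/- b0 * f(TTA(t)),   f(u) = 1 / (1 + exp(-k (u - tau)))

At `TTA = tau` the boundary sits at half its scale (`b0 / 2`); for
`TTA >> tau` it is near `b0`; as TTA approaches zero it vanishes,
forcing a decision before arrival.  Observed response time on go trials
adds a non-decision (perceptual + motor) component drawn from
`N(mu_nd, sigma_nd)` truncated at zero — the plain normal admits
negative draws; truncation is the minimal fix and is negligible for
`mu_nd >> sigma_nd`.

Model restrictions used for comparison:

* `const_drift_const_bound` ("alt1"): the basic drift-diffusion model —
  the drift is constant within a trial, frozen at its initial value
  `alpha ((TTA0 + beta d0) - theta_crit)`, so it still differs between
  conditions (as it must to reproduce the spread of go rates across the
  design), and the boundary is the constant `+/- b0` (6 free
  parameters);
* `var_drift_const_bound` ("alt2"): the time-varying drift with a
  constant boundary (6 free parameters).

Further modelling conventions: the starting point is `x(0) = 0` (no bias
parameter); inside the drift, `TTA(t)` and `d(t)` are clamped at zero
past arrival so that the censoring tail keeps a meaningful
(maximally negative) drift, while the boundary logistic receives the
unclamped TTA — it is defined for negative arguments and tends to zero
there, which is exactly the intended collapse.

## First-passage computation

Two independent routes compute the go probability and the go
decision-time density for a condition, and serve as mutual oracles in
the tests:

**Fokker-Planck solver** (`gapddm.fpt.solve`).  The evidence density is
propagated by a theta-scheme finite-difference discretization of the
advection-diffusion equation (Crank-Nicolson in the interior of the
run; the first ten steps use implicit Euler, which is L-stable and damps
the oscillatory transient that the delta initial condition excites in
Crank-Nicolson).  Boundaries are handled by Dirichlet absorption at the
grid line nearest the current `b(t)`; mass overtaken by an inward-moving
boundary is absorbed into the corresponding outcome.  Mass bookkeeping
is exact by construction: the interior loss each step is split between
the two boundaries in proportion to the one-sided (second-order)
diffusive flux estimates, so `p_go + p_stay = 1` to machine precision
and accuracy concerns are confined to *where* mass goes, not whether it
is conserved.  Steps where the Courant condition `|drift| * dt < dx`
fails (the clamped late-trial drift can reach `-alpha * theta_crit`)
are subdivided locally; a parameter set that would need more than 50
substeps is refused with `GridResolutionError` — the fitting objective
maps that refusal to a large finite penalty so the optimizer can
traverse extreme corners of the search space.

The censoring horizon is `t_max = tta0` (car arrival): a go decision
after arrival is physically impossible, so any undecided mass at
`t_max` counts as stay.  The time grid extends beyond `t_max` only to
hold the non-decision convolution tail of the observed-RT density.

Default grids are `dt = 0.005 s`, `dx = 0.025` evidence units, both
exposed in the configuration.  Against the constant-coefficient closed
forms (`P(upper) = 1/(1+exp(-2*mu*B))`, `E[T] = (B/mu) tanh(mu*B)`) the
default grid is accurate to ~5e-5 in probability and ~0.3% in mean
first-passage time, and errors shrink under refinement.

**Monte-Carlo simulator** (`gapddm.fpt.simulate_trials`).
Euler-Maruyama with step 0.001 s.  Boundary crossings are checked on
post-step positions with the Broadie-Glasserman-Kou continuity
correction: the boundary is shifted inward by `0.5826 * sqrt(dt)`,
which removes the O(sqrt(dt)) first-passage bias of discrete checks
(without it the simulator's go probability sits ~0.005-0.01 below the
converged solver's and its RT distribution fails a KS comparison at
the 0.02 level; with it the two agree to ~0.003 in probability).  The
simulator also powers the synthetic-data generator, so generated
datasets are *not* produced by the same code path that the fitted
predictions use.

## Fitting

Fitting targets are per-condition summaries: the observed go
probability and the go-RT quantiles at levels (0.1, 0.3, 0.5, 0.7,
0.9).  Conditions with fewer than four go responses contribute no
quantile term.  The objective is the weighted least-sum score

    L = sum_c [ w_p n_c (pgo_obs - pgo_pred)^2 + w_q ngo_c sum_l (q_obs - q_pred)^2 ]

with defaults `w_p = 2`, `w_q = 1` (the canonical weighting of the
quantile-based least-sum method; the quantile term is also dropped
where the model predicts essentially no go mass).  Stay trials enter
only through `p_go`: no response time can be attached to a stay
decision.  Minimization is by scipy's differential evolution, seeded
and single-threaded for reproducibility, with default search bounds
alpha [0,5], beta [0,1], theta_crit [2,20], b0 [0.5,5], k [0.05,5],
tau [1,10], mu_nd [0,1.5], sigma_nd [0.01,0.5].
Dithered mutation (0.5-1.0) with recombination 0.7 is kept deliberately:
faster-converging settings (mutation 0.3-0.7, recombination 0.9)
recovered noise-free targets but collapsed the population prematurely
on sampled data.

The objective has a curved ridge along which boundary scale, collapse
sharpness and collapse midpoint (`b0`, `k`, `tau`) trade off — small
populations reliably terminate in a shallow-collapse pseudo-solution
whose loss sits measurably above the true basin.  The recipe that
robustly reaches the correct basin on study-sized data is: run the
search on a coarsened solver grid (`dt = 0.01`, `dx = 0.05`, accurate
to ~2e-4 in go probability), which makes a 15x-dimension population
with ~300 generations affordable in minutes, then refine the best
point by bounded Nelder-Mead (``fit(..., nm_refine=...)``).  The
parameter-recovery runs in the test suite use exactly this recipe;
the cross-validation folds use smaller populations guarded by a
restart on poor convergence (next sections).

## Group aggregation

Group RT distributions are vincentized: per-participant quantile
functions (linear interpolation of order statistics) at 19 levels
0.05...0.95 are averaged across participants, and the group CDF is the
inverse of the averaged quantile function.  Group means of `p_go` and
RT average within-participant means, weighting participants equally
regardless of trial counts; participants contributing no go trials to a
condition are dropped from that condition's RT aggregates rather than
imputed.

A caveat that matters for simulation studies: with ~13 trials per
participant per condition, the extreme per-participant quantiles (0.1,
0.9) are order statistics of very small samples and are biased toward
the sample centre; vincentization averages, but does not remove, this
bias.  For parameter recovery on homogeneous simulated populations the
package therefore fits *pooled* condition summaries (identical
participants make pooling and vincentizing target the same underlying
distribution, and pooled quantiles from hundreds of RTs are essentially
unbiased).  The vincentized path is the one used for descriptive group
statistics and the CLI's group-fit mode, mirroring the analysis
procedure of the study design it emulates.

## Cross-validation

Hold-one-condition-out: for each of the nine design cells, fit to the
other eight and predict the held-out cell's go probability and mean
go-RT from the fitted parameters alone.  Folds follow the deterministic
condition-grid order (TTA-major); each fold's optimizer seed derives
from the master seed and fold index.  Per-fold failures are recorded
without aborting the remaining folds.  `run_cv` optionally refits a
fold once with alternate search settings when its loss ends above a
threshold — with self-consistent (noise-free) targets the achievable
loss is near zero, so an elevated loss is a reliable signature of the
population having settled in a secondary basin, and the two bundled
search strategies fail on disjoint folds.

## Synthetic data generator

The generator emulates the study design: 16 participants, 8 routes with
15 left turns each (120 per participant), initial TTA balanced at
exactly five turns per level {4, 5, 6} s per route, initial distance
drawn uniformly from {90, 120, 150} m per trial, oncoming speed
`d0 / tta0` held constant within trial.  Outcomes and go-RTs are
simulated from the diffusion model under participant-specific
parameters drawn as independent normals around group means (clipped to
the parameter invariants); the study's trial-level artifacts are
reproduced as random exclusion labels (no full stop: 1.4% of trials;
gas pedal held, RT unmeasurable: 0.5% of go decisions) plus the
deterministic exclusion of go-RTs above 2 s.

Group-mean defaults (alpha 1.0, beta 0.05 s/m, theta_crit 10.2 s,
b0 1.35, k 2.0 /s, tau 4.0 s, mu_nd 0.32 s, sigma_nd 0.05 s) were
chosen once so that the simulated study reproduces the qualitative and
headline quantitative features of the real one: an overall go rate of
~0.47, go probability increasing with both TTA and distance and
spanning ~0.07-0.98 across the nine cells, mean go-RT increasing with
initial TTA (~0.55 s at TTA = 4 s to ~0.91 s at 6 s), and a response
time tail in which RTs above 2 s are rare (~0.5% of go decisions), as
in the study, where that exclusion removed a single trial.  Between-
participant s.d. defaults are roughly 10-15% of each mean.

What the generator does **not** emulate: vehicle dynamics and
trajectories, changes of mind or "rolling" behaviours, correlated
individual differences across parameters (participants are drawn
independently per parameter), and any mechanistic basis for the
no-full-stop / pedal-held artifacts (they are random labels at the
observed rates).  Passing recovery tests on these data therefore show
that the pipeline is self-consistent at realistic sizes and noise
levels — not that the model is identified under real drivers'
heterogeneity or behaviour outside the fitted design.

## Numerical choices and degenerate inputs

* `sigma_nd = 0` degenerates the non-decision convolution to a grid
  shift; sampling returns `max(mu_nd, 0)` deterministically.
* Quantiles of a solution without go mass are NaN and flagged rather
  than raised.
* A fully collapsed boundary (domain narrower than one grid cell)
  absorbs all remaining mass, split evenly.
* RT quantile extraction interpolates the discrete CDF linearly in
  time.
* All seeds below 2^31; every stochastic stage's seed derives from a
  single master seed via `numpy.random.SeedSequence`.

## Known limitations

* The solver's boundary placement is nearest-grid-line; very small
  `b0` (below a few `dx`) degrades accuracy rather than failing.
* The simulator's post-step boundary check biases crossing times late
  by O(sqrt(dt)); oracle comparisons use tolerances that absorb this.
* Group-level fits to heterogeneous populations estimate an "average
  participant" in the sense of the best single parameter set for the
  averaged data, which is not the mean of the individual parameters —
  an intrinsic property of nonlinear mixtures, not an implementation
  artifact (fit per participant when individual parameters matter).
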
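# gapddm

Drift-diffusion modelling of left-turn gap acceptance decisions.

A driver stopped at an intersection, waiting to turn left across
oncoming traffic, must decide whether to **go** through a closing
space-time gap or **stay** until the oncoming car has passed.  Classical
drift-diffusion models assume a fixed evidence inflow and fixed decision
boundaries; neither holds here, because the perceptual quantities that
drive the decision — the oncoming car's time-to-arrival (TTA) and
distance — change substantially *during* the decision itself, and the
closing gap creates growing urgency.  `gapddm` implements a generalized
drift-diffusion model for this situation, together with the full
analysis pipeline a simulator study of such decisions needs, for
researchers in driver behaviour and computational cognitive modelling.

## The model

Relative evidence `x(t)` for going over staying accumulates as

    dx = alpha ((TTA(t) + beta d(t)) - theta_crit) dt + dW,

with `TTA(t) = TTA0 - t` and `d(t) = d0 - v t` under the constant
oncoming speed `v = d0 / TTA0`.  A decision is made when `x` reaches
either boundary

    b(t) = +/- b0 f(TTA(t)),     f(u) = 1 / (1 + e^{-k (u - tau)}),

which collapse as the time-to-arrival shrinks — the less time remains,
the less evidence is needed.  Observed go response time adds a
non-decision component `t_ND ~ N(mu_nd, sigma_nd)` (truncated at zero).
Trials undecided at car arrival are censored into "stay".  Two reduced
variants (constant drift + constant bound; time-varying drift +
constant bound) support model comparison.

The package provides:

* an exact-mass-conserving Crank-Nicolson first-passage solver and an
  independent Euler-Maruyama simulator (mutual oracles),
* quantile-based weighted least-squares fitting by differential
  evolution (`GapAcceptanceModel.fit()` -> `GapAcceptanceResults`),
* vincentized group RT distributions and group means,
* hold-one-condition-out cross-validation and variant comparison,
* a synthetic-data generator emulating a 3x3 (TTA {4,5,6} s x distance
  {90,120,150} m) balanced driving-simulator design with 16
  participants, 120 left turns each, and the study's exclusion filters,
* a CLI: `gapddm simulate | fit | crossval | compare | vincentize`.

## Worked example

```python
from gapddm import (GapAcceptanceModel, PopulationSpec, apply_exclusions,
                    generate_dataset, DESettings)

# a synthetic 16-participant study from the default group-mean parameters
spec = PopulationSpec(seed=7, param_sd={k: 0.0 for k in PopulationSpec().param_sd})
trials, table = apply_exclusions(generate_dataset(spec))
print(len(trials), "analyzed left turns;",
      f"{(trials.decision == 'go').mean():.0%} go")

# global search on a coarse solver grid, then Nelder-Mead refinement
model = GapAcceptanceModel.from_trials(trials, group=False, dt=0.01, dx=0.05)
res = model.fit(de_settings=DESettings(popsize=15, maxiter=300),
                seed=11, nm_refine=2000)
print(res.summary())
```

prints:

```
1886 analyzed left turns; 45% go
Gap acceptance drift-diffusion model
====================================================
variant:        full
conditions:     9
loss (WLS):     4.65109
evaluations:    33614
converged:      True
seed:           11
----------------------------------------------------
parameter       estimate                  bounds
alpha             1.0283                  [0, 5]
beta              0.0510                  [0, 1]
theta_crit       10.4717                 [2, 20]
b0                1.0340                [0.5, 5]
k                 1.4963               [0.05, 5]
tau               3.3687                 [1, 10]
mu_nd             0.3878                [0, 1.5]
sigma_nd          0.0812             [0.01, 0.5]
====================================================
```

The generating values were alpha 1.0, beta 0.05, theta_crit 10.0,
b0 1.3, k 2.0, tau 3.5, mu_nd 0.32, sigma_nd 0.05: the drift
parameters (alpha, beta, theta_crit) and the boundary-collapse
midpoint tau come back within a few percent from one study-sized
dataset, while the softer boundary-scale/non-decision trade-offs (b0,
k, mu_nd) land within roughly 20% — the realization noise of a single
16 x 120 study.  `res.predict()` reproduces the per-condition go
probabilities and mean response times of the generating model; go
probability rises with both TTA and distance, and mean go-RT rises
with initial TTA — the signature that the constant-boundary variants
underestimate several-fold (`gapddm.model.compare_variants`).

## Layout

| module | contents |
| --- | --- |
| `gapddm.kinematics` | conditions, constant-speed TTA/distance decay |
| `gapddm.core` | parameters, drift, collapsing boundary, non-decision time |
| `gapddm.fpt` | Fokker-Planck solver, Monte-Carlo simulator |
| `gapddm.fitting` | condition summaries, WLS score, differential evolution |
| `gapddm.group` | vincentization, group means, binomial SEM |
| `gapddm.crossval` | hold-one-condition-out cross-validation |
| `gapddm.synth` | synthetic study generator and exclusion filters |
| `gapddm.model` | `GapAcceptanceModel` / `GapAcceptanceResults` facade |
| `gapddm.cli` | command-line pipeline |

See `docs/methods.md` for the numerical scheme, fitting objective,
generator calibration and known limitations.
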
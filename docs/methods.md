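# Methods

This note records the model equations, the estimation machinery, the
numerical decisions and the package's deliberate limitations.

## Structural model

Two-compartment disposition with first-order oral absorption and an
absorption lag. Amounts (mg): depot `Aa`, central `A1`, peripheral
`A2`. Concentrations: `C = A1/V`, `C2 = A2/V2` (mg/L, numerically equal
to ug/mL).

```
dAa/dt = -Ka * Aa
dA1/dt =  Ka * Aa - CL * C - CL2 * (C - C2)
dA2/dt =  CL2 * (C - C2)
```

The lag is a time shift: the dose is placed in the depot at `t = Tlag`,
so all concentrations are identically zero before the lag. During the
lag the depot holds the full dose, which keeps the mass-balance
invariant `Aa + A1 + A2 + eliminated = dose` true at every time point
(the integrator carries `eliminated` as an explicit state).

The biophase and response:

```
dCe/dt = Ke0 * (C - Ce)
E(Ce)  = E0 * (1 - Ce^Gam / (IC50^Gam + Ce^Gam))    (mmol/L)
```

`E(0) = E0` and `E(IC50) = E0/2` hold exactly (the sigmoid fraction is
computed in a form that is overflow-safe for large `Gam` and exact at
the anchor points).

### Closed-form solution

In rate constants `k10 = CL/V`, `k12 = CL2/V`, `k21 = CL2/V2`, the
disposition eigenvalues `alpha, beta` solve
`s^2 + (k10 + k12 + k21) s + k10 k21 = 0`; `beta` is recovered from the
product relation `alpha * beta = k10 k21` to avoid cancellation. The
central concentration after a lagged oral dose is a sum of three
exponentials in `tau = t - Tlag`. The peripheral and effect-site
concentrations are "followers" — first-order filters of the central
profile with rates `k21` and `Ke0` — evaluated with a series-stabilised
`phi(x) = (1 - exp(-x))/x` so near-degenerate rate pairs stay accurate.
Exactly degenerate eigenvalue pairs (measure-zero) raise
`DegenerateEigenvalueError` in the user-facing closed form and are
nudged by one part in 1e-9 inside the vectorised estimator.

The numeric path integrates the ODE system with `scipy.solve_ivp`
(LSODA, `rtol 1e-8`, `atol 1e-10`) starting at `t = Tlag`. Numeric and
closed-form solutions agree to 1e-6 relative (tested on 100 random
parameter sets over two decades around the reference values).

## Population model and simulation

Parameters with inter-individual variability (`ka, v, tlag, cl2, ke0,
gamma, e0`) are log-normal: `p_i = tv_p * exp(eta_i)`,
`eta_i ~ N(0, omega_p)`, with `omega = ln(1 + CV^2)`. `v2`, `cl` and
`ic50` are fixed effects only, matching the reference table that
reports no variability for them. Residual error is proportional for
drug (`sd = sigma_pk * f`, default 0.10) and additive for glucose
(`sigma_pd`, default 0.15 mmol/L).

Simulation uses per-subject RNG substreams
(`np.random.default_rng([seed, i])`), so subject `i`'s data do not
change when the study size changes. Simulated drug values below the
quantification limit (2e-4 mg/L) are flagged BLQ; negative noisy values
are truncated at zero and flagged.

## Estimation: sequential FOCE

Per subject, the joint negative log-likelihood of data and random
effects is

```
l_i(eta) = 1/2 sum_j [ (y_ij - f_ij(eta))^2 / v_ij + log(2 pi v_ij) ]
         + 1/2 eta' Omega^-1 eta
```

and the approximate marginal deviance (Laplace/FOCE) is

```
-2 log L = sum_i [ 2 l_i(eta_hat_i) + log det Omega + log det H_i ]
```

with `eta_hat_i` the conditional mode and `H_i` the Hessian of `l_i`
there. For the proportional drug error the mode search keeps the
dependence of `v_ij` on `eta` (FOCE "with interaction").

Implementation choices, in the order they matter:

- **Vectorised inner problem.** The mode search is a damped Newton
  iteration (forward-difference Jacobian, Gauss–Newton Hessian, Armijo
  backtracking, step-norm cap) run simultaneously for all subjects as
  `(n_subjects, n_obs)` arrays; this is what makes a 200-subject FOCE
  fit tractable in pure Python. The forward-difference Jacobian biases
  the inner gradient by O(step), so the convergence tolerance is 1e-4 —
  the mode itself is then located to ~1e-5, which perturbs the deviance
  only at second order.
- **Deterministic inner multistart.** The per-subject objective is
  multimodal in `(eta_ka, eta_tlag)` because the absorption lag creates
  a cliff (prediction identically zero past the first sample). Each
  inner solve runs from a fixed set of starts — lag-clamped zeros and
  zeros with `eta_ka` shifted by ±1.2 — keeping the best mode per
  subject. Basin selection happens within the first few Newton steps,
  so each start runs briefly and only the per-subject best point is
  polished to convergence. The starts are deliberately *not* warm-started from the
  previous outer iteration: warm starts make the outer objective
  history-dependent (re-evaluating the same parameters can return a
  different value), which quietly breaks the outer optimiser's line
  searches.
- **Laplace Hessian with a positive-definite fallback.** `H_i` is the
  central finite-difference Hessian of `l_i` at the mode; when its
  smallest eigenvalue is below 1e-6 the always-positive-definite
  Gauss–Newton Hessian is used instead. (Flooring eigenvalues in the
  log-determinant instead would *reward* broken inner solutions.)
- **Below-limit handling.** Pre-dose drug rows and BLQ-flagged drug
  rows are excluded from the PK likelihood. Under a proportional error
  with a small variance floor, predicted-zero/observed-tiny points
  otherwise contribute near-infinite penalties with no usable gradient.
- **Standard two-stage initialisation.** Before the mixed-effects run,
  every subject is fitted separately by least squares (log residuals
  for drug, raw for glucose); typical values start at the geometric
  means, omegas at the log-scale variances (capped at 1.0 — per-subject
  estimation noise inflates them), the residual SD at the pooled
  residual spread. Population starting values displaced by ±50% are
  routinely rescued by this step; a naive pooled fit is not enough
  (it has spurious optima of its own when CVs approach 90%).
- **Outer optimiser: ITS sweeps paired with Powell.** The deviance
  surface has diagonal valleys — a typical value trading against its
  omega — whose floors are kinked by per-subject inner-mode switching,
  so both direction-set and finite-difference gradient methods stall on
  them (Powell terminates at coordinate-descent stationary points;
  L-BFGS-B sees only kink noise). The fit therefore alternates two
  passes: *iterated two-stage (ITS) sweeps*, which exploit the model
  structure — with the conditional modes held fixed, the typical value
  of every eta-bearing parameter profiles out in closed form to the
  geometric mean of the individual values, and the EM update sets each
  omega to the spread of the re-centred modes plus the mean posterior
  variance — and a Powell pass on the log-transformed parameters under
  broad physiologic bounds, which moves what ITS cannot (residual SDs
  and the no-eta fixed effects). ITS walks straight down the valleys at
  about two deviance evaluations per sweep and every sweep is accepted
  only if the exact FOCE deviance improves. Rounds repeat from the best
  point seen until neither pass gains 0.5 deviance units, within
  evaluation caps (PK 9000, PD 6000) that keep a 200-subject sequential
  fit within roughly a quarter hour on one CPU.
- **Sequential PD stage (IPP).** The PD fit freezes each subject's PK
  at `tv * exp(EBE)` from the PK stage and estimates only the four PD
  typical values, the active PD omegas and `sigma_pd`. If the maximum
  effect-site exposure seen during the fit is below 1% of the estimated
  IC50, the result is flagged as IC50-unidentifiable.
- **Shrinkage.** `1 - SD(eta_hat)/sqrt(omega)` per parameter; values
  above 0.5 are logged as poorly informed random effects.

Accuracy of the objective itself is tested against exact numeric
marginalisation on single-subject problems: with the full 11-point
sampling design the FOCE deviance is within 0.2% of quadrature even at
`omega = 0.5`. With very sparse designs (3 points) the Laplace
approximation itself drifts to ~10% — a property of the approximation,
not of the implementation.

## Non-compartmental analysis

`lambda_z` is chosen by log-linear regression over contiguous terminal
windows (>= 3 positive points strictly after Tmax), maximising adjusted
R^2, ties going to the longer window. AUC(0–t) runs to the last
*positive* concentration (trailing zeros are below quantification and
excluded) using linear or linear-up/log-down trapezoids;
`AUC(0–inf) = AUC(0–t) + Clast/lambda_z`, `CL/F = dose/AUC(0–inf)`,
`Vd/F = CL/F / lambda_z`, `t1/2 = ln2 / lambda_z`. When the slope is
not estimable the extrapolated quantities are NaN and flagged, never
silently dropped.

## Diagnostics

PRED is the model at `eta = 0` (for the PD stage: typical PK as well);
IPRED the model at the EBEs. CWRES uses the FOCE linearisation around
the EBE mode: `E[y] = f(eta_hat) - J eta_hat`,
`V = J Omega J' + R`, `CWRES = V^(-1/2) (y - E[y])` via a symmetric
eigendecomposition. Four plot-ready tables are produced (CWRES vs time,
CWRES vs PRED, DV vs IPRED, DV vs PRED) with axis units and reference
lines in `DataFrame.attrs`. Under the generating model, CWRES is
calibrated: mean near 0, SD near 1, ~95% of values in (−2, 2). For the
PD stage "under the generating model" means the subject PK is fixed at
the parameters that generated the glucose data; fixing it at the PK
EBEs instead (the sequential workflow) adds unmodelled variability
(EBE ≠ generating eta) and measurably inflates the CWRES tails — SD
~1.04–1.08 and coverage of (−2, 2) around 94–95% across simulation
seeds. That inflation is a property of sequential IPP diagnostics, not
of the CWRES computation.

## Known limitations

- **`CL` and `V2` are not recoverable** from the 3 h design with the
  reference micro-clearance (`CL = 0.03 L/h` implies a terminal phase
  far slower than the sampling window). They are estimated but carry no
  accuracy claim. The `nca_consistent_population()` preset (clearance
  at the NCA scale, 7.80 L/h) exists for demonstrations that need an
  identifiable terminal phase; it is explicitly *not* the reference
  parameter set.
- The residual-error structure of the original analysis is not
  recorded; the package's proportional (drug) + additive (glucose)
  choice is a documented default, and all recovery statements use the
  package's own generator.
- Standard errors (`compute_se=True`) come from a finite-difference
  Hessian of the outer objective on the log scale; they are delta-method
  approximations and are off by default because of their cost.
- Single-dose datasets only: each subject must have exactly one dose
  event; multiple dosing is out of scope.
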
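# Methods

## Model class

`focelin` works with nonlinear mixed-effects (NLME) population PK models
of the standard form

    y_ij = f(p_i, x_ij) + h_ij ,

where `y_ij` is subject *i*'s *j*-th observed concentration, `f` a
closed-form structural model of the individual parameter vector `p_i` and
the design variables (dose history, time), and `h` the residual-error
model. Individual parameters are log-normal,

    p_ki = theta_k * g_k(z_i) * exp( sum_l eta_lki ),

with typical value `theta_k`, optional multiplicative covariate model
`g_k`, and one or more levels of parameter variability `eta`: between
subject (BSV) and between occasion (BOV), jointly Gaussian with
covariance `Omega`. The residual model is linear in a Gaussian vector
`eps` with covariance `Sigma`: additive (`h = eps`), proportional
(`h = f*eps`) or combined (`h = f*eps1 + eps2`).

Three structural models are implemented, all with analytic solutions
(superposition over the dose history; no ODE solver):

* one-compartment, first-order oral absorption (`CL`, `V`, `KA`);
* one-compartment, constant-rate infusion / IV bolus (`CL`, `V`);
* one-compartment with first-order absorption through **one** transit
  compartment (`CL`, `V`, `KA`, `MTT`). The transit rate follows the
  `(n_transit + 1)/MTT` convention, i.e. `ktr = 2/MTT`. The cascade is
  evaluated as the standard three-exponential (Bateman) expression;
  nearly equal rate constants are separated by a relative nudge of 1e-6
  (the solution has removable singularities there), which perturbs the
  profile by well under the 1e-6 relative tolerance at which the kernels
  are tested against brute-force ODE integration.

BOV is realized as one eta per (parameter, occasion) sharing a common
variance; an observation's occasion is that of the latest dose at or
before it. With closed-form kernels a mid-profile parameter change cannot
be propagated exactly, so the parameters of an observation's occasion are
applied to the whole dose history — an approximation used identically in
both estimation arms, so their comparison is unaffected.

## FOCE-I objective

Writing one subject's joint twice-negative log-density as

    q(eta) = log det R(eta) + r(eta)' R(eta)^-1 r(eta)
             + eta' Omega^-1 eta + log det Omega,

with `r = y - f(eta)` and `R` the residual covariance, the individual
objective is the Laplace-type expression

    iOFV_i = q(eta_hat) + log det( q''(eta_hat) / 2 ),

where `eta_hat` minimizes `q` (the empirical Bayes estimate, EBE) and the
Hessian is the Gauss–Newton approximation that keeps first-order
sensitivities of both the mean and the residual variance:

    q'' ~ 2 F' R^-1 F + tr( R^-1 dR R^-1 dR ) + 2 Omega^-1,  F = df/deta.

"Interaction" (FOCE-I) means `R` and its eta-sensitivities are evaluated
at `eta_hat`; plain FOCE evaluates them at `eta = 0`. The residual-
variance sensitivity terms are essential: for an eta that scales the
residual error (the eta-on-epsilon extension) `F` is identically zero,
and without the `dR` terms the variance of that eta would be
unidentifiable. For a model linear in eta with additive error the
expression collapses to the exact marginal Gaussian −2 log-likelihood —
verified to 1e-8 in the tests, and the hinge on which the linearization's
correctness rests. The `n log 2pi` constant is omitted throughout, so
only OFV differences are meaningful.

The total OFV is the sum of iOFV over subjects. The outer
maximum-likelihood problem (over `theta`, the free `Omega` blocks in
log-Cholesky form, log residual SDs and any residual-extension
parameters) is solved by L-BFGS-B with finite-difference gradients; the
inner MAP problems are damped Newton iterations with analytic gradients
and GN Hessians assembled from complex-step derivatives of the model
evaluator (exact to machine precision; cross-checked against central
differences at 1e-6 in the tests). Subjects sharing a sampling/dosing
schedule are solved as one batched Newton iteration, which is what makes
the preset-scale studies run in minutes on one CPU.

### MCETA

The inner objective is minimized from the start `eta = 0` by default.
`mceta = k` additionally evaluates `q` at `k` random draws from
`N(0, Omega)` (a dedicated, seed-keyed stream per subject) and starts the
single Newton run from the best candidate — the multi-start defence
against inner local minima. During outer iterations with `mceta = 0` the
previous EBE is used as a warm-start candidate; with `mceta > 0` warm
starts are disabled so that the result is a deterministic function of the
seed alone.

## Linearization

After a base fit, the model is expanded to first order at
`Q0 = (eps = 0, eta = eta_hat)`:

    y_ij ~ f|Q0 + sum_l df/deta_l|Q0 (eta*_l - etahat_l)
          + sum_v [ dh/deps_v|Q0
            + sum_l d(dh/deps_v)/deta_l|Q0 (eta*_l - etahat_l) ] eps*_v.

The per-observation values `OPRED`, `D_ETA`, `D_EPS`, `D_EPSETA` and the
EBEs form the linearization table (written as CSV with exactly those
column names). Estimating extended random-effects structures on this
affine surrogate requires no structural-model evaluation — a module-level
call counter proves it — which is the entire source of the method's
speed. Fixed effects are frozen inside the table; only `Omega`, `Sigma`
and residual-extension parameters are estimated, and all residual-
variance parameters are re-estimated alongside extensions (they live in
`h`, not `f`, so the expansion stays valid; this choice is deliberate and
matters only through the nested-model comparisons, which are unaffected).

The mixed eps–eta term is zero for additive error models, making the
linearized inner objective exactly quadratic and the linearized base OFV
identical to the nonlinear one (tested to 1e-4). For proportional or
combined error the interaction term lets the per-observation residual
scale change sign along eta*, creating spurious inner minima: a zero
start can then terminate with a grossly inflated iOFV for some subjects.
The `iofv_deviation_report` diagnostic flags such subjects (default
threshold 1 OFV unit), and either MCETA or a log-transform of the data
(which renders proportional error additive; `Dataset.log_transformed`
plus the model's `log_dv` flag) repairs them. The agreement tolerance
asserted for proportional/combined bases is 0.5 OFV units at
`mceta >= 10`.

## Extension catalogue

Seven extension kinds are screened, each exactly nested in the base model
(null values reproduce the base likelihood, verified in tests):

| kind                 | change                                           | df  | null value            |
|----------------------|--------------------------------------------------|-----|-----------------------|
| `add_bsv`            | new BSV eta(s) on parameters                     | k   | variance 1e-6 (fixed) |
| `add_bov`            | new BOV eta(s), shared variance across occasions | k   | variance 1e-6 (fixed) |
| `covariance_block`   | free off-diagonals between existing BSV etas     | k(k-1)/2 | off-diagonal 0   |
| `rv_iiv`             | `h * exp(eta_RV)`, new `omega^2_RV`              | 1   | variance 1e-6 (fixed) |
| `rv_power`           | `h * F^theta_pow` (F = individual prediction)    | 1   | `theta_pow = 0`       |
| `rv_autocorrelation` | `corr(eps_j, eps_j') = exp(-|t_j - t_j'|/tau)`   | 1   | `tau -> 0` (floor 1e-12) |
| `rv_time_step`       | distinct first-component `sigma^2` after a fixed cut time | 1 | `sigma^2_after = sigma^2` |

Extensions that give a structural parameter new variability require a
*placeholder* eta in the base model — present with a small variance
(1e-6) that is **fixed** during estimation — so the linearization table
carries its derivatives; a zero variance would zero those derivatives
out. `prepare_base` adds the placeholders a battery needs. The
autocorrelation kernel is exponential decay in time distance
(continuous-time AR(1)); the kernel function is an implementation detail
of `ResidualModel.kernel` and can be swapped. The time-step cut point is
a fixed hyperparameter, not estimated; a cut beyond the last observation
leaves the second variance unidentifiable and the screening report flags
it. In the linearized model `rv_power` uses the linearized model's own
individual prediction (the affine mean) as `F` — freezing `F` at `OPRED`
was tried and rejected: it lets the surrogate buy spurious dOFV that the
nonlinear model does not reproduce. `rv_iiv` acts purely through the
tabulated interaction column (the expansion is linear; no exponential is
re-applied).

The significance rule is the likelihood-ratio convention: `dOFV =
OFV_base − OFV_extended` against the chi-square upper quantile at
`alpha = 0.05` with df = number of added parameters. Boundary-mixture
corrections for variance components are deliberately **not** applied;
this makes the variance-component tests conservative, which the type-I
error study shows.

## Synthetic data

`simulate_dataset` draws eta per subject (and per occasion), eps per
observation — including the autocorrelation kernel and time-step variance
when active — and evaluates `y = f + h` through the same evaluator the
estimation engine uses, so simulation and inference share one definition
of the model. One master seed drives per-subject substreams
(`SeedSequence([seed, 7919, i])`), so enlarging the population never
reshuffles earlier subjects, and output is bit-reproducible.

Three presets emulate the *designs* of classic PK examples (their subject
and observation counts, route, error-model form); the parameter values
are illustrative choices for realistic identifiability, not reproductions
of published models:

* `moxonidine_like` — oral, additive error, 74 subjects / 1,022
  observations, two dosing occasions; `CL 10 L/h, V 50 L, KA 1.5 /h`,
  dose 100 mg, `omega^2 = 0.10` (CL, V), `sigma_add = 0.1 mg/L`.
* `pefloxacin_like` — two 1-h 400-mg infusions, proportional error, 74
  subjects / 337 observations; `CL 6 L/h, V 100 L`, `omega^2 = 0.15`,
  `sigma_prop = 20%`.
* `ethambutol_like` — oral through one transit compartment, combined
  error, 189 subjects / 1,869 observations, two occasions; `CL 40 L/h,
  V 500 L, KA 0.6 /h, MTT 1.5 h`, dose 1,200 mg, `omega^2 = 0.12`,
  `sigma_prop = 20%`, `sigma_add = 0.08 mg/L`.

`adversarial_proportional` is a deliberate stress design (infusion,
proportional error, `omega^2 = 0.4`) tuned to trigger the inner
local-minima pathology on essentially every realization; it exists for
the diagnostics, not as a realistic study.

What the generator does **not** emulate: covariate distributions,
time-varying covariates, dropout or below-quantification censoring,
model misspecification of `f`, and multi-compartment kinetics. Passing
tests therefore demonstrate the internal consistency and statistical
operating characteristics of the screening method under its own model
class, not robustness to structural misspecification of real data.

## Validation studies and problem sizes

* **Agreement battery** (`workflows.standard_battery_study`): one
  simulated dataset per preset; per preset, the battery spans the four
  residual-variability kinds, BOV additions, the CL–V covariance free
  (all on the BSV-bearing base) and BSV additions on a residual-only base
  — 30 extension tests in total, each fitted as a full nonlinear refit
  (all parameters re-estimated) and as a linearized fit with
  `mceta = 100`. The pooled fraction of matching significance calls is
  the headline quantity; `scripts/acceptance.py` recomputes it from
  scratch.
* **Power / type-I error** (`workflows.power_study`): a compact
  oral/proportional design (40 subjects x 6 samples) chosen so replicate
  studies run quickly; the eta-on-epsilon extension is simulated at
  `omega^2_RV = 0.25` for the power arm. Detection uses the linearized
  arm after a nonlinear base fit — the tool's intended screening mode.

## Numerical choices

* Derivatives: complex step (`h = 1e-20`) everywhere a derivative of the
  model evaluator is needed; piecewise switching is on real times only,
  so the step is valid. Central differences serve as the independent
  cross-check in tests (agreement 1e-6).
* Inner Newton: Levenberg-damped, batched Armijo line search over step
  fractions `2^0 .. 2^-10`; convergence at gradient max-norm
  `1e-8 * (1 + |q|)`; residual variances floored at 1e-14 (the guard for
  exactly zero variance raises instead). Ties among equal MCETA
  candidates resolve to the lowest index (`argmin`).
* Outer optimization: L-BFGS-B, `ftol = 1e-7` (relative), bounds
  `log sd` in `[log 1e-4, log 50]`, power exponent in `[-5, 5]`,
  correlation scale in `[1e-3, 1e3]` h. `max_iter = 0` means
  "evaluate at the initial values only".
* Degenerate inputs: models with no random effects (m = 0) evaluate the
  fixed-effects likelihood directly; `Omega -> 0` recovers it in the
  limit; data simulated with zero variances reproduce the typical
  predictions exactly.

## Limitations

* Fixed effects are frozen in the linearized model by construction; when
  an extension would substantially move them in a nonlinear refit, the
  two arms can disagree — the screening report tracks the maximum
  relative theta change of each nonlinear refit for exactly this
  post-mortem.
* The FOCE-I approximation itself (not just the linearization) is the
  estimand: agreement is asserted between the two arms of *this*
  implementation, not against any external software's numerics.
* Closed-form structural models only; no covariate model search; no
  automatic stepwise extension selection (the battery is screened flat).
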
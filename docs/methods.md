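# Methods

## Model

Ownership histories are multistate event histories.  For vessel `v` at age
`a` (calendar time `t = delivery_v + a`) the transition intensity for a sale
from the current owner `s` to an active buyer `b != s` is

    alpha_v(a, b) = Z_s Z_b^{-1} alpha_0(a) R_v(a, b; beta),
    R_v = exp{ bV' x_v(a) + bS' x_s(t) + bB' x_b(t) + bE' x_E(t) },

and the scrap hazard is `Z_s lambda_0(a) Q_v(a; theta)` with
`Q_v = exp{tV' x_v + tS' x_s + tE' x_E}`.  The frailty `Z_c = exp(S_c)` is a
company-level random effect, iid `Gamma(1/xi, 1/xi)` (mean 1, variance
`xi`), that multiplies a company's selling and scrapping intensity and
divides the intensity of sales *to* it: a single latent "sentiment" tilts
the company toward liquidating or accumulating assets.  Baselines are left
nonparametric in vessel age; all calendar-time structure must enter through
the exogenous series `x_E(t)`, since a second nonparametric baseline in
calendar time would not be identifiable alongside it.

Assumptions worth stating explicitly: frailties are time-constant and
shared across a company's selling, buying and scrapping behaviour; company
covariates are time-fixed; a company is described by a single activity
interval; vessel covariates entering the fitters are static (the running
previous-owner count is exposed as a derived quantity but not available as
a model covariate in this version).

## Conventions

* Time is measured in months, ages are 0-based, and all intervals are
  half-open `[start, end)`.
* Risk sets use the predictable (left-limit) convention: a vessel is at
  risk on `(0, final_age]`, and at an event age the pre-event owner is the
  seller.  Consequently spell `[start, end)` covers the risk ages
  `(start, end]`.
* `previous_owners(h, v, a)` is right-continuous (a sale counts from its
  own age), matching the counting-process convention; covariate use at an
  event age should take the left limit.
* The exogenous step function is right-continuous; lagged lookups that fall
  before its first breakpoint clamp to the earliest value with a warning.
* Ties: event ages sit on a monthly grid, so ties are heavy; both Breslow
  estimators and the partial likelihoods use Breslow-style aggregated
  denominators (`dN(a)` in the numerator, one denominator per distinct
  age).  No Efron or exact correction is offered.

## Estimation

**No-frailty fits.**  `fit_no_frailty` maximises the Cox-type partial
likelihood (sales, scrap or both) with all `Z = 1` by Newton–Raphson with
analytic gradient and observed information: start at zero, step-halving on
a likelihood decrease (with slack `1e-9 |loglik|` for floating-point
noise), stop when the gradient max-norm falls below `1e-8` or after 50
iterations.  Standard errors are square roots of the inverse observed
information diagonal.

**Sampler.**  One MCMC iteration performs, in order: (1) profile the
Breslow baselines at the current state; (2) joint Gaussian random-walk
Metropolis on the sales block `beta`; (3) the same on `theta` when scrap
events exist; (4) a fixed-order Gibbs sweep over the frailties; (5)
random-walk Metropolis on `log xi`.  The `beta`/`theta` target is the full
likelihood with the baselines re-profiled under the proposal; because the
Breslow plug-in makes the profiled likelihood equal the partial likelihood
plus a coefficient-free constant, the acceptance ratio is computed from
the partial likelihood directly — an exact identity, verified in the test
suite to `1e-6`.  Baselines are held fixed within the frailty sweep and the
`xi` update of the same iteration.

The full conditional of `Z_c` is generalised inverse Gaussian,
`GIG(lam = M_c + 1/xi, chi = 2 D2_c, psi = 2 (D1_c + 1/xi))`.  `M_c` is
(sales + scraps − purchases) of company `c`; `D1_c` accumulates baseline
increments times covariate risks times the buyer sum over *other*
companies for vessels `c` owns (plus its scrap exposure); `D2_c` is the
corresponding buyer-side exposure while `c` is active.  During a sweep the
aggregates `sum_b Z_b^{-1} e^{bB x_b}` and `sum_s Z_s g_s` are updated
incrementally after each draw, so every company conditions on the freshest
values of the others.

**Priors.**  Flat (improper) priors on `beta`, `theta` and on `log xi`.
The likelihood dominates at the study's sample sizes and the sampler is
initialised from the no-frailty maximum, so the flat choice is the least
informative one compatible with the estimation strategy; it is a package
choice, and proper priors could be substituted in `mh_update_block` without
touching the rest of the machinery.

**Identifiability.**  With no scrap events the likelihood depends on `Z`
only through ratios `Z_s/Z_b` and is exactly invariant under `Z -> cZ`
(a property test asserts this to machine precision); the
`Gamma(1/xi, 1/xi)` prior pins the scale, and no explicit normalisation is
applied.

**GIG sampling.**  On the log scale the standardised GIG density
`exp(lam t - omega cosh t)` is log-concave, so draws use an exact rejection
sampler: a flat hat between the two points where the log density drops one
unit below the mode (located by safeguarded bisection) and tangent
exponential tails outside them.  Expected trials are bounded by a small
constant uniformly over the parameter range; `chi = 0` falls back to a
Marsaglia–Tsang gamma draw.  The kernel consumes uniforms from a
caller-supplied numpy `Generator` buffer, which keeps every draw on one
seeded stream and makes whole chains bitwise reproducible.  The test suite
cross-checks the sampler against `scipy.stats.geninvgauss` and against
Bessel-function moment formulas.

**Seeding.**  Each chain uses a single `numpy.random.Generator` consumed in
a fixed per-iteration block order (beta proposal, theta proposal, frailty
sweep, xi proposal).  Replication seeds derive from the root seed by
replicate index through `SeedSequence`, so replicates are independent and
order-invariant.

## Computational layout

All estimators reduce to sums over risk rows — one row per (distinct event
age, at-risk vessel) with its left-limit owner.  Buyer sums collapse over
cells of companies sharing a covariate vector, and company activity
windows partition calendar time into intervals indexed per row, so the
per-evaluation cost scales with rows + cells, not rows x companies.  The
hot accumulations (weighted risk totals per age, per-owner exposures, the
sequential frailty sweep with its GIG draws) are numba kernels; derivative
assembly for Newton–Raphson is plain numpy.  The incremental O(1)-per-draw
sweep requires every company to be active throughout (true in the
reference simulation design); with heterogeneous activity windows the
sweep falls back to a per-company recomputation that is exact but intended
for small data sets.  At the reference scale (about 495,000 risk rows) one
sampler iteration costs roughly 9 ms on one CPU.

## Synthetic data

`simulate` generates discrete-time histories; the defaults are the
reference study design: N = 500 companies, K = 1000 vessels all delivered
at time 0 and censored at age 500 months, baseline sale intensity 1e-5 per
month per vessel-buyer pair, no scrapping, no exogenous series, all
companies active throughout, vessel covariates Bernoulli(1/2) and
Uniform(-20, 20), company covariates Bernoulli(1/2), truth
`bV = (0.3, -0.01)`, `bS = (0.4, -0.2)`, `bB = (-0.2, 0.1)`, and frailty
variance `xi` of 0.2 or 0.4.  Per vessel-month an event fires with
probability `1 - exp(-total rate)` — a valid probability for any
configuration, indistinguishable from the raw rate sum at the default
magnitudes (~6e-3) — and a single categorical draw resolves scrap versus
buyer, with buyers weighted by `Z_b^{-1} exp(bB x_b)`.  Ownership
transfers from the next month; the final month is reserved for censoring
so a buyer's ownership is always observable.  Event ages are integer
months, deliberately producing heavy ties.  First owners are uniform over
(active) companies, so a company may hold several vessels.

Richer structures are available by configuration: scrapping with a
constant monthly baseline, staggered integer deliveries, an exogenous step
series, and per-company activity windows.  With windows, eligibility to
buy at month m requires activity at m, and the *recorded* windows are the
hull of the nominal window and realised ownership, so the written
histories always satisfy the owner-active invariant; the estimators then
see windows that are at most slightly wider than those used during
generation.

What the generator does not emulate: the covariate mixes, fleet growth and
market series of real vessel data, ordering of newbuilds, or multiple
disjoint activity intervals.  Passing the replication tests therefore
shows that the estimators recover the generating mechanism of this design,
not that the model fits any particular real market.

Two realised properties of the design are worth noting.  First, at these
parameter settings the generator produces roughly 2,400–2,900 sales per
data set — comfortably above the 1,800 often quoted for designs of this
type, because the static expected rate is inflated by
`E[Z] E[1/Z] = 1/(1-xi)` and the covariate exponentials.  Second, mean
transaction volume is increasing in `xi` only over short horizons: in long
runs, sales funnel vessels toward low-frailty companies, which rarely
sell, and this selection effect reverses the static monotonicity.  The
property test covers the short-horizon form.

## Replication study

`replicate_table3` runs simulate → no-frailty fit → MCMC per replicate and
aggregates the mean estimate, the mean within-run SE ("Est SE": inverse
information for the no-frailty columns, posterior SD for the MCMC
columns — two different provenances, labelled per estimator), and the
empirical SD of estimates across replicates ("Emp SE").  The desk-scale
defaults are 5 replications with 1000 burn-in + 3000 retained iterations;
the acceptance tests use 20 no-frailty replicates and 3 MCMC replicates
per `xi`, sizes at which the replicate means are stable at the tolerances
tested.  Random-walk SDs follow the reference tuning: 0.07 per coefficient
and 0.002 for the wide-range continuous vessel covariate, 0.02 for
`log xi`; chains start from the no-frailty fit with all `Z = 1` and
`xi = 0.01`.  Under ignored frailty the vessel and seller coefficients
attenuate (e.g. the first vessel coefficient drops from 0.3 to about 0.26
at `xi = 0.2` and 0.22 at `xi = 0.4`) while buyer coefficients do not; the
sampler recovers both the coefficients and `xi`.  The buyer-side
non-attenuation is reported qualitatively by `attenuation_report` and not
analysed further here.

## Numerical choices and degenerate inputs

* Likelihood work is done in the log domain; a zero weighted risk total at
  an event age raises an error rather than returning `-inf`.
* A proposal that drives a covariate exponential to overflow is treated as
  a rejected move (the target is `-inf`), with overflow trapped.
* A company with no events and no exposure has `M = D1 = D2 = 0` and its
  Gibbs draw reduces to the prior; `D2 = 0` reduces to a gamma draw.
* An event age with no positive baseline increment in `full_loglik`
  signals inconsistent inputs and raises.
* `BaselineIncrements` demands aligned age/increment arrays; cumulative
  functions are right-continuous step functions.
* Newton–Raphson raises on non-convergence or a singular information
  matrix; the replication driver logs and skips a failed replicate.

## Limitations

* Dynamic (history-derived) vessel covariates are not available in the
  fitters.
* No Efron/exact tie handling, time-varying coefficients or left
  truncation.
* Frailties are time-constant; piecewise-constant, correlated, trivariate
  or power-transformed frailty variants are out of scope, as is the hybrid
  scheme that plugs partial-likelihood point estimates of `beta`, `theta`
  into an MCMC over `(Z, xi)` — its variance would need to combine
  within-chain variability with the information-based estimate conditional
  on `Z`.
* The fast frailty sweep assumes homogeneous activity; heterogeneous
  windows run through the exact but slower per-company path.
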
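# dualfrailty

Event-history modelling of ownership durations with *dual* company-level
frailties, built for transaction data such as the buying, selling and
scrapping of ocean-going vessels.

## The model

A change of ownership is one event with two faces: a sale by the current
owner and a purchase by another company.  `dualfrailty` treats a sale of
vessel `v` at age `a` to buyer `b` as a multistate transition with
intensity

```
alpha_v(a, b) = Z_s Z_b^{-1} * alpha_0(a) *
                exp{ bV' x_v(a) + bS' x_s(t) + bB' x_b(t) + bE' x_E(t) }
```

where `s` is the current owner, `x_v`, `x_s`, `x_b` are vessel, seller and
buyer covariates, `x_E(t)` an exogenous market series (e.g. a freight
earnings index), and `alpha_0(a)` an unspecified baseline in vessel age.
Each company carries a latent *sentiment* `S_c`; its exponential
`Z_c = exp(S_c)` — the frailty — multiplies the intensity when the company
sells and divides it when it buys, so willing sellers and reluctant buyers
are captured by a single positive random effect with a
`Gamma(1/xi, 1/xi)` distribution (mean 1, variance `xi`).  Scrapping is an
absorbing competing risk with hazard `Z_s * lambda_0(a) * exp{theta' x}`
and no buyer term.

Estimation is Bayesian MH-within-Gibbs:

* random-walk Metropolis for the regression blocks `beta`, `theta` and for
  `log xi`;
* exact Gibbs draws of each `Z_c` from its generalised inverse Gaussian
  full conditional `Z^{M+1/xi-1} exp{-(D1+1/xi) Z - D2/Z}`, where `M`
  counts the company's sales + scraps − purchases and `D1`, `D2` are its
  owner-side and buyer-side cumulative exposures;
* Breslow-type profiling of the cumulative baselines `A_0`, `Lambda_0` at
  every iteration.

Ignoring the frailty and fitting an ordinary partial likelihood attenuates
the vessel- and seller-covariate effects toward zero; the buyer effects do
not attenuate.  The package ships a no-frailty Newton–Raphson fitter, the
full sampler, a discrete-time simulator, and a replication driver that
demonstrates both the attenuation and its repair.

## Worked example

```python
import numpy as np
from dualfrailty import SimConfig, simulate, fit_no_frailty, McmcConfig, run_mcmc, summarise

h = simulate(SimConfig(xi=0.2), np.random.default_rng(1))   # 500 companies, 1000 vessels
print(h.n_sales())                                          # 2822 sale events

fit = fit_no_frailty(h, which="sale")
print(np.round(fit.params.beta_V, 3))                       # [ 0.299 -0.012]  (truth 0.3, -0.01)

cfg = McmcConfig(n_iter=4000, burn_in=1000,
                 proposal_sd_sale=[0.07, 0.002, 0.07, 0.07, 0.07, 0.07],
                 xi_init=0.01, seed=9)
samples = run_mcmc(h, cfg, init_params=fit.params)
print(summarise(samples))
```

The summary table lists each coefficient's posterior mean and SD together
with the frailty variance `xi`; across replicates the posterior means
centre on the generating values (`beta_V_1` near 0.3, `xi` near 0.2) while
the no-frailty vessel and seller coefficients sit closer to zero.  A single
replicate, as above, can land within one posterior SD of either.

The same pipeline is available from the shell:

```sh
dualfrailty simulate --seed 1 --out simdata
dualfrailty fit-nofrailty --data simdata --which sale
dualfrailty fit-mcmc --data simdata --iters 4000 --burn-in 1000 --seed 9
dualfrailty replicate --xi 0.2 --reps 5 --iters 3000 --burn-in 1000
```

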
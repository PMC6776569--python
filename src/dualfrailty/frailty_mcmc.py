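"""MH-within-Gibbs estimation of the dual-frailty model.

Each iteration (1) profiles the Breslow baselines at the current state,
(2) updates the sales coefficients beta by a joint Gaussian random-walk
Metropolis step whose target is the profiled full likelihood — equal, up to
a beta-free constant, to the Breslow-tie partial likelihood given Z —
(3) likewise updates theta when scrap events exist, (4) Gibbs-sweeps the
company frailties from their generalised-inverse-Gaussian full
conditionals, and (5) updates log xi by random-walk Metropolis against the
Gamma(1/xi, 1/xi) prior density of the current frailties (flat prior on
log xi; priors on the regression coefficients are flat too).

The full-data likelihood, viewed as a function of one frailty Z_c, is
proportional to Z_c^M exp{-D1 Z_c - D2 / Z_c}: M is the company's sales
plus scraps minus purchases, D1 its (sale + scrap) exposure as an owner,
and D2 its exposure as a potential buyer.  Combining with the gamma prior
gives the GIG full conditional with lam = M + 1/xi, psi = 2(D1 + 1/xi),
chi = 2 D2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._gig import _gibbs_sweep, sample_gig
from ._risk import RiskStructure
from .event_history import SALE, SCRAP, EventHistory, EventHistoryError
from .hazard_model import (
    BaselineIncrements,
    FrailtyState,
    RegressionParams,
    fit_no_frailty,
    partial_loglik_sale,
    partial_loglik_scrap,
)

__all__ = [
    "GibbsStats",
    "McmcConfig",
    "McmcSamples",
    "gibbs_stats",
    "sample_gig",
    "gibbs_update_Z",
    "mh_update_block",
    "run_mcmc",
    "summarise",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GibbsStats:
    """(M, D1, D2) defining the GIG full conditional of one company frailty."""

    M: int
    D1: float
    D2: float


def gibbs_stats(
    h: EventHistory, company_id: str, params: RegressionParams,
    frailty: FrailtyState, baselines: BaselineIncrements,
) -> GibbsStats:
    """Frailty full-conditional statistics for one company.

    M counts events (sales + scraps minus purchases); D1 accumulates the
    company's owner-side exposure (sale and scrap baseline increments times
    covariate risks times the buyer sum over *other* companies); D2 its
    buyer-side exposure over vessels owned by others while the company is
    active.  Z_c itself appears in neither.
    """
    c = h.company_index.get(company_id)
    if c is None:
        raise EventHistoryError(f"unknown company {company_id!r}")
    Z = frailty.Z
    invZ = 1.0 / Z
    N = h.n_companies
    XC = np.vstack([co.covariates for co in h.companies]).reshape(N, -1)
    eS = np.exp(XC @ params.beta_S) if params.beta_S.size else np.ones(N)
    eB = np.exp(XC @ params.beta_B) if params.beta_B.size else np.ones(N)
    qS = np.exp(XC @ params.theta_S) if params.theta_S.size else np.ones(N)
    starts = np.array([co.activity_start for co in h.companies])
    ends = np.array([co.activity_end for co in h.companies])

    M = 0
    D1 = 0.0
    D2 = 0.0
    for v in h.vessels:
        eV_v = (
            float(np.exp(params.beta_V @ v.covariates))
            if params.beta_V.size else 1.0
        )
        qV_v = (
            float(np.exp(params.theta_V @ v.covariates))
            if params.theta_V.size else 1.0
        )
        for sp in v.spells:
            s = h.company_index[sp.owner_id]
            if sp.end_type == SALE:
                if s == c:
                    M += 1
                if h.company_index[sp.buyer_id] == c:
                    M -= 1
            elif sp.end_type == SCRAP and s == c:
                M += 1

            lo = np.searchsorted(baselines.sale_ages, sp.start_age, side="right")
            hi = np.searchsorted(baselines.sale_ages, sp.end_age, side="right")
            if hi > lo:
                ages = baselines.sale_ages[lo:hi]
                ts = v.delivery_time + ages
                if params.beta_E.size and h.exogenous is not None:
                    eE = np.exp(h.exogenous.at(ts) @ params.beta_E)
                else:
                    eE = np.ones(ages.size)
                if s == c:
                    active = (
                        (starts[None, :] <= ts[:, None])
                        & (ts[:, None] < ends[None, :])
                    )
                    active[:, c] = False
                    bsum = active @ (invZ * eB)
                    D1 += float(
                        np.sum(baselines.dA0[lo:hi] * eS[c] * eV_v * eE * bsum)
                    )
                else:
                    c_active = (starts[c] <= ts) & (ts < ends[c])
                    D2 += float(
                        np.sum(
                            baselines.dA0[lo:hi] * Z[s] * eS[s] * eV_v * eE
                            * eB[c] * c_active
                        )
                    )
            if s == c:
                lo = np.searchsorted(baselines.scrap_ages, sp.start_age, side="right")
                hi = np.searchsorted(baselines.scrap_ages, sp.end_age, side="right")
                if hi > lo:
                    ages = baselines.scrap_ages[lo:hi]
                    ts = v.delivery_time + ages
                    if params.theta_E.size and h.exogenous is not None:
                        qE = np.exp(h.exogenous.at(ts) @ params.theta_E)
                    else:
                        qE = np.ones(ages.size)
                    D1 += float(np.sum(baselines.dL0[lo:hi] * qS[c] * qV_v * qE))
    return GibbsStats(M=M, D1=D1, D2=D2)


# ---------------------------------------------------------------------------
# configuration and results
# ---------------------------------------------------------------------------

@dataclass
class McmcConfig:
    """Chain length, proposal scales, initial state and seed.

    ``n_iter`` is the total number of iterations; the first ``burn_in`` are
    discarded.  ``proposal_sd_sale`` / ``proposal_sd_scrap`` are scalar or
    per-parameter random-walk standard deviations for the regression blocks;
    ``logxi_sd`` the scale for the log-frailty-variance step.
    """

    n_iter: int = 4000
    burn_in: int = 1000
    proposal_sd_sale: float | np.ndarray = 0.07
    proposal_sd_scrap: float | np.ndarray = 0.07
    logxi_sd: float = 0.02
    seed: int = 0
    init: str = "from_no_frailty"
    Z_init: np.ndarray | None = None
    xi_init: float = 0.01

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.init not in ("from_no_frailty", "zeros"):
            raise ValueError("init must be 'from_no_frailty' or 'zeros'")
        if not self.xi_init > 0 or not self.logxi_sd > 0:
            raise ValueError("xi_init and logxi_sd must be positive")
        if np.any(np.atleast_1d(self.proposal_sd_sale) < 0):
            raise ValueError("proposal SDs must be nonnegative")


@dataclass
class McmcSamples:
    """Retained traces, frailty posterior summaries and acceptance rates."""

    sale_names: list[str]
    scrap_names: list[str]
    beta_trace: np.ndarray          # (n_keep, p_sale)
    theta_trace: np.ndarray | None  # (n_keep, p_scrap) or None
    xi_trace: np.ndarray
    loglik_trace: np.ndarray
    accept: dict[str, float]
    Z_mean: np.ndarray
    Z_sd: np.ndarray
    company_ids: list[str]
    config: McmcConfig

    @property
    def n_kept(self) -> int:
        return int(self.xi_trace.size)

    def frailty_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "company_id": self.company_ids,
                "post_mean_Z": self.Z_mean,
                "post_sd_Z": self.Z_sd,
            }
        )


def _param_names(prefixes_sizes) -> list[str]:
    return [
        f"{name}_{i + 1}" for name, n in prefixes_sizes for i in range(n)
    ]


def summarise(samples: McmcSamples) -> pd.DataFrame:
    """Posterior mean and within-run SD ('Est SE') per scalar parameter."""
    if samples.n_kept == 0:
        raise ValueError("empty retained trace")
    names = list(samples.sale_names)
    cols = [samples.beta_trace]
    if samples.theta_trace is not None:
        names += list(samples.scrap_names)
        cols.append(samples.theta_trace)
    names.append("xi")
    cols.append(samples.xi_trace[:, None])
    mat = np.hstack(cols)
    return pd.DataFrame(
        {
            "parameter": names,
            "mean": mat.mean(axis=0),
            "sd": mat.std(axis=0, ddof=1) if mat.shape[0] > 1 else 0.0,
        }
    )


# ---------------------------------------------------------------------------
# single-component updates (reference interfaces)
# ---------------------------------------------------------------------------

def _logxi_target(logxi: float, Z: np.ndarray) -> float:
    """Log density of Z under the Gamma(1/xi, 1/xi) prior, flat in log xi."""
    inv_xi = np.exp(-logxi)
    return float(
        Z.size * (inv_xi * np.log(inv_xi) - gammaln(inv_xi))
        + (inv_xi - 1.0) * np.log(Z).sum()
        - inv_xi * Z.sum()
    )


def mh_update_block(
    h: EventHistory, block: str, params: RegressionParams, frailty: FrailtyState,
    baselines: BaselineIncrements, config: McmcConfig, rng: np.random.Generator,
    risk: RiskStructure | None = None,
) -> tuple[RegressionParams, FrailtyState, bool]:
    """One random-walk MH update of the ``beta``, ``theta`` or ``logxi`` block.

    The beta/theta target is the profiled full likelihood under the proposal
    (baselines re-profiled inside the ratio, i.e. the given-Z partial
    likelihood); the logxi target is the gamma prior density of the current
    frailties.  Returns (params, frailty, accepted).
    """
    if block in ("beta", "theta"):
        r = risk if risk is not None else RiskStructure.from_history(h)
    if block == "beta":
        sds = np.broadcast_to(
            np.atleast_1d(np.asarray(config.proposal_sd_sale, dtype=float)),
            (r.p1 + 2 * r.p2 + r.p3,),
        )
        cur = params.sale_flat()
        prop = cur + sds * rng.standard_normal(cur.size)
        try:
            cur_t = partial_loglik_sale(h, params, frailty, risk=r)
            prop_t = partial_loglik_sale(
                h, params.with_sale_flat(prop), frailty, risk=r
            )
        except (EventHistoryError, FloatingPointError):
            prop_t = -np.inf
            cur_t = 0.0
        delta = prop_t - cur_t
        if not np.isfinite(delta):
            warnings.warn("non-finite MH target for beta proposal; rejecting")
            return params, frailty, False
        if np.log(rng.random()) < delta:
            return params.with_sale_flat(prop), frailty, True
        return params, frailty, False
    if block == "theta":
        sds = np.broadcast_to(
            np.atleast_1d(np.asarray(config.proposal_sd_scrap, dtype=float)),
            (r.p1 + r.p2 + r.p3,),
        )
        cur = params.scrap_flat()
        prop = cur + sds * rng.standard_normal(cur.size)
        try:
            cur_t = partial_loglik_scrap(h, params, frailty, risk=r)
            prop_t = partial_loglik_scrap(
                h, params.with_scrap_flat(prop), frailty, risk=r
            )
        except (EventHistoryError, FloatingPointError):
            prop_t = -np.inf
            cur_t = 0.0
        delta = prop_t - cur_t
        if not np.isfinite(delta):
            warnings.warn("non-finite MH target for theta proposal; rejecting")
            return params, frailty, False
        if np.log(rng.random()) < delta:
            return params.with_scrap_flat(prop), frailty, True
        return params, frailty, False
    if block == "logxi":
        cur = np.log(frailty.xi)
        prop = cur + config.logxi_sd * rng.standard_normal()
        delta = _logxi_target(prop, frailty.Z) - _logxi_target(cur, frailty.Z)
        if not np.isfinite(delta):
            warnings.warn("non-finite MH target for log xi proposal; rejecting")
            return params, frailty, False
        if np.log(rng.random()) < delta:
            return params, FrailtyState(Z=frailty.Z, xi=float(np.exp(prop))), True
        return params, frailty, False
    raise ValueError("block must be 'beta', 'theta' or 'logxi'")


def gibbs_update_Z(
    h: EventHistory, params: RegressionParams, frailty: FrailtyState,
    baselines: BaselineIncrements, rng: np.random.Generator,
    risk: RiskStructure | None = None,
) -> FrailtyState:
    """One full Gibbs sweep over company frailties, in fixed company order.

    Each Z_c is drawn from GIG(lam = M + 1/xi, chi = 2 D2, psi = 2(D1 + 1/xi))
    with (M, D1, D2) evaluated at the most recent values of all other
    frailties.  When every company is active throughout (the homogeneous
    design) the buyer/seller aggregates are maintained incrementally in a
    compiled sweep; otherwise the statistics are recomputed per company.
    """
    r = risk if risk is not None else RiskStructure.from_history(h)
    Z = frailty.Z.copy()
    inv_xi = 1.0 / frailty.xi
    fast = (
        r.uniform_activity
        and np.array_equal(baselines.sale_ages, r.sale_ages)
        and (
            r.n_scraps == 0 or np.array_equal(baselines.scrap_ages, r.scrap_ages)
        )
    )
    if fast:
        eV, eS, eB, row_eE, _ = r.sale_exps(
            params.beta_V, params.beta_S, params.beta_B, params.beta_E
        )
        g = eS * r.owner_exposure(eV, row_eE, baselines.dA0)
        if r.n_scraps:
            qV, qS, srow_eE, _ = r.scrap_exps(
                params.theta_V, params.theta_S, params.theta_E
            )
            h_scrap = qS * r.scrap_owner_exposure(qV, srow_eE, baselines.dL0)
        else:
            h_scrap = np.zeros(r.n_companies)
        _fast_sweep(Z, r.M.astype(np.float64), g, h_scrap, eB, inv_xi, rng)
        return FrailtyState(Z=Z, xi=frailty.xi)
    state = FrailtyState(Z=Z, xi=frailty.xi)
    for c in h.companies:
        st = gibbs_stats(h, c.company_id, params, state, baselines)
        lam = st.M + inv_xi
        chi = 2.0 * st.D2
        psi = 2.0 * (st.D1 + inv_xi)
        Z[h.company_index[c.company_id]] = sample_gig(lam, chi, psi, rng)
    return FrailtyState(Z=Z, xi=frailty.xi)


def _fast_sweep(Z, M, g, h_scrap, eB, inv_xi, rng) -> None:
    """Run the compiled sweep, refilling the uniform buffer as needed."""
    Btot = float(np.sum(eB / Z))
    Gtot = float(np.sum(Z * g))
    start = 0
    n = Z.size
    buf = rng.random(16 * n + 64)
    iu = 0
    while start < n:
        start, iu, Btot, Gtot = _gibbs_sweep(
            Z, M, g, h_scrap, eB, inv_xi, buf, iu, start, Btot, Gtot
        )
        if iu < 0:
            buf = rng.random(16 * (n - start) + 256)
            iu = 0


# ---------------------------------------------------------------------------
# the full sampler
# ---------------------------------------------------------------------------

def run_mcmc(
    h: EventHistory, config: McmcConfig, risk: RiskStructure | None = None,
    init_params: RegressionParams | None = None,
) -> McmcSamples:
    """Run the MH-within-Gibbs chain and return retained traces.

    Per iteration: profile baselines at the current state, MH-update beta,
    MH-update theta (when scrap events exist), Gibbs-sweep the frailties,
    MH-update log xi.  Deterministic for a fixed ``config.seed``.
    ``init_params`` overrides the configured initialisation (used by the
    replication driver to reuse an already-computed no-frailty fit).
    """
    r = risk if risk is not None else RiskStructure.from_history(h)
    if r.n_sales == 0:
        raise EventHistoryError("event history contains no sale events")
    rng = np.random.default_rng(config.seed)

    if init_params is not None:
        params = init_params
    elif config.init == "from_no_frailty":
        params = fit_no_frailty(h, which="both", risk=r).params
    else:
        params = RegressionParams.zeros(r.p1, r.p2, r.p3)

    Z = (
        np.asarray(config.Z_init, dtype=float).copy()
        if config.Z_init is not None else np.ones(r.n_companies)
    )
    if Z.size != r.n_companies:
        raise ValueError("Z_init has wrong length")
    xi = float(config.xi_init)

    p_sale = r.p1 + 2 * r.p2 + r.p3
    p_scrap = r.p1 + r.p2 + r.p3
    sds_sale = np.broadcast_to(
        np.atleast_1d(np.asarray(config.proposal_sd_sale, dtype=float)), (p_sale,)
    ).copy()
    sds_scrap = np.broadcast_to(
        np.atleast_1d(np.asarray(config.proposal_sd_scrap, dtype=float)), (p_scrap,)
    ).copy()
    has_scrap = r.n_scraps > 0

    n_keep = config.n_iter - config.burn_in
    beta_trace = np.empty((n_keep, p_sale))
    theta_trace = np.empty((n_keep, p_scrap)) if has_scrap else None
    xi_trace = np.empty(n_keep)
    ll_trace = np.empty(n_keep)
    Z_sum = np.zeros(r.n_companies)
    Z_sumsq = np.zeros(r.n_companies)
    acc = {"beta": 0, "logxi": 0}
    if has_scrap:
        acc["theta"] = 0

    flat = params.sale_flat()
    sflat = params.scrap_flat()

    def sale_cache(fl):
        bV, bS, bB, bE = _split_sale(r, fl)
        eV, eS, eB, row_eE, ev_logR = r.sale_exps(bV, bS, bB, bE)
        return {
            "eV": eV, "eS": eS, "eB": eB, "row_eE": row_eE,
            "num": float(ev_logR.sum()),
        }

    def scrap_cache(fl):
        tV, tS, tE = _split_scrap(r, fl)
        qV, qS, srow_eE, ev_logQ = r.scrap_exps(tV, tS, tE)
        return {
            "qV": qV, "qS": qS, "srow_eE": srow_eE, "num": float(ev_logQ.sum()),
        }

    sc = sale_cache(flat)
    kc = scrap_cache(sflat) if has_scrap else None

    fast_sweep_ok = r.uniform_activity
    if not fast_sweep_ok:
        log.info("heterogeneous activity windows: using per-company Gibbs sweep")

    kept = 0
    stored_error: Exception | None = None
    try:
        for it in range(config.n_iter):
            # (1) current sale risk totals (these ARE the profiled baselines)
            denom = r.sale_denoms(sc["eV"], sc["eS"], sc["eB"], sc["row_eE"], Z)
            if np.any(denom <= 0):
                raise EventHistoryError("zero weighted risk total during MCMC")
            cur_val = sc["num"] - float(r.sale_dN @ np.log(denom))

            # (2) beta block
            prop = flat + sds_sale * rng.standard_normal(p_sale)
            u_beta = rng.random()
            try:
                with np.errstate(over="raise"):
                    pc = sale_cache(prop)
                    pdenom = r.sale_denoms(pc["eV"], pc["eS"], pc["eB"], pc["row_eE"], Z)
                prop_val = (
                    pc["num"] - float(r.sale_dN @ np.log(pdenom))
                    if np.all(pdenom > 0) else -np.inf
                )
            except FloatingPointError:
                prop_val = -np.inf
            if np.isfinite(prop_val) and np.log(u_beta) < prop_val - cur_val:
                flat, sc, denom, cur_val = prop, pc, pdenom, prop_val
                acc["beta"] += 1

            # (3) theta block
            if has_scrap:
                sdenom = r.scrap_denoms(kc["qV"], kc["qS"], kc["srow_eE"], Z)
                if np.any(sdenom <= 0):
                    raise EventHistoryError("zero scrap risk total during MCMC")
                cur_sval = kc["num"] - float(r.scrap_dN @ np.log(sdenom))
                sprop = sflat + sds_scrap * rng.standard_normal(p_scrap)
                u_theta = rng.random()
                try:
                    with np.errstate(over="raise"):
                        pk = scrap_cache(sprop)
                        psdenom = r.scrap_denoms(pk["qV"], pk["qS"], pk["srow_eE"], Z)
                    prop_sval = (
                        pk["num"] - float(r.scrap_dN @ np.log(psdenom))
                        if np.all(psdenom > 0) else -np.inf
                    )
                except FloatingPointError:
                    prop_sval = -np.inf
                if np.isfinite(prop_sval) and np.log(u_theta) < prop_sval - cur_sval:
                    sflat, kc, sdenom, cur_sval = sprop, pk, psdenom, prop_sval
                    acc["theta"] += 1
                dL0 = r.scrap_dN / sdenom
            else:
                dL0 = None

            # (4) frailty Gibbs sweep at the freshly profiled baselines
            dA0 = r.sale_dN / denom
            if fast_sweep_ok:
                g = sc["eS"] * r.owner_exposure(sc["eV"], sc["row_eE"], dA0)
                if has_scrap:
                    h_scrap = kc["qS"] * r.scrap_owner_exposure(
                        kc["qV"], kc["srow_eE"], dL0
                    )
                else:
                    h_scrap = np.zeros(r.n_companies)
                _fast_sweep(
                    Z, r.M.astype(np.float64), g, h_scrap, sc["eB"], 1.0 / xi, rng
                )
            else:
                baselines = BaselineIncrements(
                    sale_ages=r.sale_ages, dA0=dA0,
                    scrap_ages=r.scrap_ages if has_scrap else np.zeros(0),
                    dL0=dL0 if has_scrap else np.zeros(0),
                )
                cur_params = _assemble_params(r, flat, sflat)
                fs = gibbs_update_Z(
                    h, cur_params, FrailtyState(Z=Z, xi=xi), baselines, rng, risk=r
                )
                Z = fs.Z

            # (5) log xi block
            logxi = np.log(xi)
            lprop = logxi + config.logxi_sd * rng.standard_normal()
            u_xi = rng.random()
            dxi = _logxi_target(lprop, Z) - _logxi_target(logxi, Z)
            if np.isfinite(dxi) and np.log(u_xi) < dxi:
                xi = float(np.exp(lprop))
                acc["logxi"] += 1

            # (6) record
            if it >= config.burn_in:
                k = it - config.burn_in
                beta_trace[k] = flat
                if has_scrap:
                    theta_trace[k] = sflat
                xi_trace[k] = xi
                logZ = np.log(Z)
                ll = (
                    sc["num"]
                    + float(logZ[r.ev_seller].sum() - logZ[r.ev_buyer].sum())
                    + float(r.sale_dN @ np.log(dA0))
                    - r.n_sales
                )
                if has_scrap:
                    ll += (
                        kc["num"] + float(logZ[r.sev_owner].sum())
                        + float(r.scrap_dN @ np.log(dL0)) - r.n_scraps
                    )
                ll_trace[k] = ll
                Z_sum += Z
                Z_sumsq += Z * Z
                kept += 1
    except Exception as e:  # return the partial trace with the error attached
        stored_error = e
        log.error("MCMC aborted at iteration %d: %s", it, e)

    n_done = kept
    Z_mean = Z_sum / max(n_done, 1)
    Z_var = np.maximum(Z_sumsq / max(n_done, 1) - Z_mean**2, 0.0)
    samples = McmcSamples(
        sale_names=_param_names(
            [("beta_V", r.p1), ("beta_S", r.p2), ("beta_B", r.p2), ("beta_E", r.p3)]
        ),
        scrap_names=_param_names(
            [("theta_V", r.p1), ("theta_S", r.p2), ("theta_E", r.p3)]
        ),
        beta_trace=beta_trace[:n_done],
        theta_trace=theta_trace[:n_done] if has_scrap else None,
        xi_trace=xi_trace[:n_done],
        loglik_trace=ll_trace[:n_done],
        accept={k: v / config.n_iter for k, v in acc.items()},
        Z_mean=Z_mean,
        Z_sd=np.sqrt(Z_var),
        company_ids=[c.company_id for c in h.companies],
        config=config,
    )
    if stored_error is not None:
        err = RuntimeError(f"chain aborted after {n_done} retained iterations")
        err.samples = samples  # partial trace for post-mortem
        raise err from stored_error
    return samples


def _split_sale(r: RiskStructure, flat: np.ndarray):
    p1, p2, p3 = r.p1, r.p2, r.p3
    return (
        flat[:p1], flat[p1:p1 + p2], flat[p1 + p2:p1 + 2 * p2],
        flat[p1 + 2 * p2:p1 + 2 * p2 + p3],
    )


def _split_scrap(r: RiskStructure, flat: np.ndarray):
    p1, p2, p3 = r.p1, r.p2, r.p3
    return flat[:p1], flat[p1:p1 + p2], flat[p1 + p2:p1 + p2 + p3]


def _assemble_params(r: RiskStructure, flat: np.ndarray, sflat: np.ndarray):
    bV, bS, bB, bE = _split_sale(r, flat)
    tV, tS, tE = _split_scrap(r, sflat)
    return RegressionParams(
        beta_V=bV, beta_S=bS, beta_B=bB, beta_E=bE,
        theta_V=tV, theta_S=tS, theta_E=tE,
    )
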
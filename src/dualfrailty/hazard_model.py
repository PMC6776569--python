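"""Sales/scrap intensities, likelihoods, Breslow baselines, no-frailty fits.

The sales model gives each at-risk vessel ``v`` of age ``a``, current owner
``s`` and potential buyer ``b`` the transition intensity

    alpha_v(a, b) = Z_s Z_b^-1 * alpha0(a) * R_v(a, b; beta),
    R_v = exp{ bV.x_v(a) + bS.x_s(t) + bB.x_b(t) + bE.x_E(t) },

summed over active buyers ``b != s`` for the overall sales intensity; the
scrap hazard is ``Z_s * lambda0(a) * Q_v(a; theta)`` with no buyer term.
``Z_c`` is the company's frailty (exp of its sentiment), a priori
Gamma(1/xi, 1/xi) with mean one and variance ``xi``.

Baselines in vessel age are left unspecified and profiled by Breslow-type
estimators; ties on the monthly grid are aggregated Breslow-style.  The
partial likelihood eliminates the baseline and, evaluated at the Breslow
plug-in, agrees with the profiled full likelihood up to a beta-free
constant — which is why the MCMC regression updates can use it directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._risk import RiskStructure, sale_param_slices, scrap_param_slices
from .event_history import SALE, SCRAP, EventHistory, EventHistoryError

__all__ = [
    "RegressionParams",
    "FrailtyState",
    "BaselineIncrements",
    "NoFrailtyFit",
    "relative_risk_sale",
    "relative_risk_scrap",
    "sale_intensity_total",
    "cumulative_intensities",
    "full_loglik",
    "breslow_sale",
    "breslow_scrap",
    "partial_loglik_sale",
    "partial_loglik_scrap",
    "fit_no_frailty",
    "plot_cumulative_baselines",
]


def _vec(x, n: int | None = None) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float)) if x is not None else np.zeros(0)
    if n is not None and arr.size != n:
        raise ValueError(f"expected length {n}, got {arr.size}")
    return arr


@dataclass
class RegressionParams:
    """Regression coefficients: (bV, bS, bB, bE) for sales, (tV, tS, tE) for scrap."""

    beta_V: np.ndarray = field(default_factory=lambda: np.zeros(0))
    beta_S: np.ndarray = field(default_factory=lambda: np.zeros(0))
    beta_B: np.ndarray = field(default_factory=lambda: np.zeros(0))
    beta_E: np.ndarray = field(default_factory=lambda: np.zeros(0))
    theta_V: np.ndarray = field(default_factory=lambda: np.zeros(0))
    theta_S: np.ndarray = field(default_factory=lambda: np.zeros(0))
    theta_E: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        for name in ("beta_V", "beta_S", "beta_B", "beta_E",
                     "theta_V", "theta_S", "theta_E"):
            v = _vec(getattr(self, name))
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} contains non-finite entries")
            setattr(self, name, v)
        if self.beta_S.size != self.beta_B.size:
            raise ValueError("beta_S and beta_B must have equal length")

    @classmethod
    def zeros(cls, p1: int, p2: int, p3: int = 0) -> "RegressionParams":
        return cls(
            beta_V=np.zeros(p1), beta_S=np.zeros(p2), beta_B=np.zeros(p2),
            beta_E=np.zeros(p3), theta_V=np.zeros(p1), theta_S=np.zeros(p2),
            theta_E=np.zeros(p3),
        )

    def sale_flat(self) -> np.ndarray:
        return np.concatenate([self.beta_V, self.beta_S, self.beta_B, self.beta_E])

    def scrap_flat(self) -> np.ndarray:
        return np.concatenate([self.theta_V, self.theta_S, self.theta_E])

    def with_sale_flat(self, flat: np.ndarray) -> "RegressionParams":
        sl = sale_param_slices(self.beta_V.size, self.beta_S.size, self.beta_E.size)
        return RegressionParams(
            beta_V=flat[sl["beta_V"]], beta_S=flat[sl["beta_S"]],
            beta_B=flat[sl["beta_B"]], beta_E=flat[sl["beta_E"]],
            theta_V=self.theta_V, theta_S=self.theta_S, theta_E=self.theta_E,
        )

    def with_scrap_flat(self, flat: np.ndarray) -> "RegressionParams":
        sl = scrap_param_slices(self.theta_V.size, self.theta_S.size, self.theta_E.size)
        return RegressionParams(
            beta_V=self.beta_V, beta_S=self.beta_S, beta_B=self.beta_B,
            beta_E=self.beta_E, theta_V=flat[sl["theta_V"]],
            theta_S=flat[sl["theta_S"]], theta_E=flat[sl["theta_E"]],
        )


@dataclass
class FrailtyState:
    """Company frailties Z (aligned with the EventHistory company order) and xi."""

    Z: np.ndarray
    xi: float = 1.0

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if np.any(self.Z <= 0) or not np.all(np.isfinite(self.Z)):
            raise ValueError("all frailties must be positive and finite")
        if not self.xi > 0:
            raise ValueError("frailty variance xi must be positive")

    @classmethod
    def unit(cls, n: int, xi: float = 1.0) -> "FrailtyState":
        return cls(Z=np.ones(n), xi=xi)


@dataclass
class BaselineIncrements:
    """Step-function increments of the cumulative baselines A0 and Lambda0."""

    sale_ages: np.ndarray = field(default_factory=lambda: np.zeros(0))
    dA0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    scrap_ages: np.ndarray = field(default_factory=lambda: np.zeros(0))
    dL0: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        for name in ("sale_ages", "dA0", "scrap_ages", "dL0"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.sale_ages.size != self.dA0.size:
            raise ValueError("sale_ages and dA0 must align")
        if self.scrap_ages.size != self.dL0.size:
            raise ValueError("scrap_ages and dL0 must align")

    def A0(self, u: float | np.ndarray) -> np.ndarray:
        """Cumulative baseline sales intensity at age u (right-continuous)."""
        idx = np.searchsorted(self.sale_ages, np.asarray(u, dtype=float), side="right")
        return np.concatenate([[0.0], np.cumsum(self.dA0)])[idx]

    def L0(self, u: float | np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.scrap_ages, np.asarray(u, dtype=float), side="right")
        return np.concatenate([[0.0], np.cumsum(self.dL0)])[idx]

    def sale_increment_at(self, age: float) -> float:
        i = np.searchsorted(self.sale_ages, age)
        if i >= self.sale_ages.size or self.sale_ages[i] != age or self.dA0[i] <= 0:
            raise EventHistoryError(
                f"no positive baseline sale increment at age {age}; "
                "baselines inconsistent with the event history"
            )
        return float(self.dA0[i])

    def scrap_increment_at(self, age: float) -> float:
        i = np.searchsorted(self.scrap_ages, age)
        if i >= self.scrap_ages.size or self.scrap_ages[i] != age or self.dL0[i] <= 0:
            raise EventHistoryError(
                f"no positive baseline scrap increment at age {age}; "
                "baselines inconsistent with the event history"
            )
        return float(self.dL0[i])

    @classmethod
    def combine(cls, sale: "BaselineIncrements", scrap: "BaselineIncrements"):
        return cls(sale_ages=sale.sale_ages, dA0=sale.dA0,
                   scrap_ages=scrap.scrap_ages, dL0=scrap.dL0)


# ---------------------------------------------------------------------------
# frailty helpers
# ---------------------------------------------------------------------------

def _z_vector(h: EventHistory, frailty: FrailtyState | None) -> np.ndarray:
    if frailty is None:
        return np.ones(h.n_companies)
    Z = np.asarray(frailty.Z, dtype=float)
    if Z.size != h.n_companies:
        raise ValueError(
            f"frailty vector length {Z.size} != number of companies {h.n_companies}"
        )
    return Z


def _exo_value(h: EventHistory, t: float) -> np.ndarray:
    if h.exogenous is None:
        return np.zeros(0)
    return np.atleast_1d(h.exogenous.at(t))


# ---------------------------------------------------------------------------
# pointwise model quantities (reference implementations)
# ---------------------------------------------------------------------------

def relative_risk_sale(
    h: EventHistory, vessel_id: str, age: float, buyer_id: str,
    params: RegressionParams,
) -> float:
    """Covariate relative risk R_v(a, b; beta) for a sale to ``buyer_id``."""
    v = h.vessel(vessel_id)
    owner = h.company(v.owner_at(age))
    buyer = h.company(buyer_id)
    if buyer.company_id == owner.company_id:
        raise EventHistoryError("buyer equals current owner")
    t = v.time_at_age(age)
    lin = 0.0
    if params.beta_V.size:
        lin += float(params.beta_V @ _vec(v.covariates, params.beta_V.size))
    if params.beta_S.size:
        lin += float(params.beta_S @ _vec(owner.covariates, params.beta_S.size))
        lin += float(params.beta_B @ _vec(buyer.covariates, params.beta_B.size))
    if params.beta_E.size:
        lin += float(params.beta_E @ _vec(_exo_value(h, t), params.beta_E.size))
    return float(np.exp(lin))


def relative_risk_scrap(
    h: EventHistory, vessel_id: str, age: float, params: RegressionParams
) -> float:
    """Covariate relative risk Q_v(a; theta) for scrapping."""
    v = h.vessel(vessel_id)
    owner = h.company(v.owner_at(age))
    t = v.time_at_age(age)
    lin = 0.0
    if params.theta_V.size:
        lin += float(params.theta_V @ _vec(v.covariates, params.theta_V.size))
    if params.theta_S.size:
        lin += float(params.theta_S @ _vec(owner.covariates, params.theta_S.size))
    if params.theta_E.size:
        lin += float(params.theta_E @ _vec(_exo_value(h, t), params.theta_E.size))
    return float(np.exp(lin))


def sale_intensity_total(
    h: EventHistory, vessel_id: str, age: float, params: RegressionParams,
    frailty: FrailtyState | None, a0: float,
) -> float:
    """Overall sales intensity: a0 * Z_s * sum over active buyers of Z_b^-1 R_v."""
    if not a0 > 0:
        raise ValueError("baseline intensity a0 must be positive")
    Z = _z_vector(h, frailty)
    v = h.vessel(vessel_id)
    if not v.at_risk(age):
        raise EventHistoryError(f"vessel {vessel_id!r} not at risk at age {age}")
    owner_id = v.owner_at(age)
    s = h.company_index[owner_id]
    t = v.time_at_age(age)
    total = 0.0
    for b, comp in enumerate(h.companies):
        if b == s or not comp.active_at(t):
            continue
        total += (1.0 / Z[b]) * relative_risk_sale(
            h, vessel_id, age, comp.company_id, params
        )
    return float(a0 * Z[s] * total)


# ---------------------------------------------------------------------------
# cumulative intensities and the full-data log likelihood
# ---------------------------------------------------------------------------

def _company_arrays(h: EventHistory, params: RegressionParams):
    XC = np.vstack([c.covariates for c in h.companies]).reshape(h.n_companies, -1)
    eS = np.exp(XC @ params.beta_S) if params.beta_S.size else np.ones(h.n_companies)
    eB = np.exp(XC @ params.beta_B) if params.beta_B.size else np.ones(h.n_companies)
    starts = np.array([c.activity_start for c in h.companies])
    ends = np.array([c.activity_end for c in h.companies])
    return eS, eB, starts, ends


def cumulative_intensities(
    h: EventHistory, vessel_id: str, up_to_age: float, params: RegressionParams,
    frailty: FrailtyState | None, baselines: BaselineIncrements,
) -> tuple[float, float]:
    """(A_v, Lambda_v): Stieltjes sums of the intensities against the baselines.

    The sums run over baseline increment ages in (0, up_to_age] at which the
    vessel is at risk, piecewise over ownership spells (owner and eligible
    buyer set change at sales).
    """
    Z = _z_vector(h, frailty)
    invZ = 1.0 / Z
    v = h.vessel(vessel_id)
    eS, eB, starts, ends = _company_arrays(h, params)
    eV_v = (
        float(np.exp(params.beta_V @ v.covariates)) if params.beta_V.size else 1.0
    )
    qV_v = (
        float(np.exp(params.theta_V @ v.covariates)) if params.theta_V.size else 1.0
    )
    qS = np.exp(
        np.vstack([c.covariates for c in h.companies]).reshape(h.n_companies, -1)
        @ params.theta_S
    ) if params.theta_S.size else np.ones(h.n_companies)

    A = 0.0
    L = 0.0
    for sp in v.spells:
        hi_age = min(sp.end_age, up_to_age)
        if hi_age <= sp.start_age:
            continue
        s = h.company_index[sp.owner_id]
        # sales part
        lo = np.searchsorted(baselines.sale_ages, sp.start_age, side="right")
        hi = np.searchsorted(baselines.sale_ages, hi_age, side="right")
        if hi > lo:
            ages = baselines.sale_ages[lo:hi]
            ts = v.delivery_time + ages
            active = (starts[None, :] <= ts[:, None]) & (ts[:, None] < ends[None, :])
            bsum = active @ (invZ * eB) - active[:, s] * invZ[s] * eB[s]
            if params.beta_E.size and h.exogenous is not None:
                eE = np.exp(h.exogenous.at(ts) @ params.beta_E)
            else:
                eE = np.ones(ages.size)
            A += float(
                np.sum(baselines.dA0[lo:hi] * Z[s] * eS[s] * eV_v * eE * bsum)
            )
        # scrap part
        lo = np.searchsorted(baselines.scrap_ages, sp.start_age, side="right")
        hi = np.searchsorted(baselines.scrap_ages, hi_age, side="right")
        if hi > lo:
            ages = baselines.scrap_ages[lo:hi]
            ts = v.delivery_time + ages
            if params.theta_E.size and h.exogenous is not None:
                eE = np.exp(h.exogenous.at(ts) @ params.theta_E)
            else:
                eE = np.ones(ages.size)
            L += float(np.sum(baselines.dL0[lo:hi] * Z[s] * qS[s] * qV_v * eE))
    return A, L


def full_loglik(
    h: EventHistory, params: RegressionParams, frailty: FrailtyState | None,
    baselines: BaselineIncrements,
) -> float:
    """Full-data log likelihood with point-mass baselines at the event ages.

    sum over vessels of
      sum_sales log(Z_s Z_b^-1 dA0(a) R_v(a,b)) - A_v
      + delta * log(Z_s dL0(a) Q_v(a)) - Lambda_v.
    """
    Z = _z_vector(h, frailty)
    logZ = np.log(Z)
    total = 0.0
    for v in h.vessels:
        for sp in v.spells:
            if sp.end_type == SALE:
                s = h.company_index[sp.owner_id]
                b = h.company_index[sp.buyer_id]
                total += (
                    logZ[s] - logZ[b]
                    + np.log(baselines.sale_increment_at(sp.end_age))
                    + np.log(
                        relative_risk_sale(h, v.vessel_id, sp.end_age, sp.buyer_id, params)
                    )
                )
            elif sp.end_type == SCRAP:
                s = h.company_index[sp.owner_id]
                total += (
                    logZ[s]
                    + np.log(baselines.scrap_increment_at(sp.end_age))
                    + np.log(relative_risk_scrap(h, v.vessel_id, sp.end_age, params))
                )
        A, L = cumulative_intensities(
            h, v.vessel_id, v.final_age, params, frailty, baselines
        )
        total -= A + L
    return float(total)


# ---------------------------------------------------------------------------
# Breslow baselines and partial likelihoods (vectorised)
# ---------------------------------------------------------------------------

def _risk_for(h: EventHistory, risk: RiskStructure | None) -> RiskStructure:
    return risk if risk is not None else RiskStructure.from_history(h)


def breslow_sale(
    h: EventHistory, params: RegressionParams, frailty: FrailtyState | None = None,
    risk: RiskStructure | None = None,
) -> BaselineIncrements:
    """Breslow estimate of the baseline sale increments dA0 at event ages."""
    r = _risk_for(h, risk)
    if r.n_sales == 0:
        raise EventHistoryError("no sale events; cannot profile the sale baseline")
    Z = _z_vector(h, frailty)
    eV, eS, eB, row_eE, _ = r.sale_exps(
        params.beta_V, params.beta_S, params.beta_B, params.beta_E
    )
    denom = r.sale_denoms(eV, eS, eB, row_eE, Z)
    if np.any(denom <= 0):
        bad = r.sale_ages[denom <= 0]
        raise EventHistoryError(f"zero risk total at sale age(s) {bad[:5]}")
    return BaselineIncrements(sale_ages=r.sale_ages, dA0=r.sale_dN / denom)


def breslow_scrap(
    h: EventHistory, params: RegressionParams, frailty: FrailtyState | None = None,
    risk: RiskStructure | None = None,
) -> BaselineIncrements:
    """Breslow estimate of the baseline scrap increments dL0 at event ages."""
    r = _risk_for(h, risk)
    if r.n_scraps == 0:
        raise EventHistoryError("no scrap events; cannot profile the scrap baseline")
    Z = _z_vector(h, frailty)
    eV, eS, row_eE, _ = r.scrap_exps(params.theta_V, params.theta_S, params.theta_E)
    denom = r.scrap_denoms(eV, eS, row_eE, Z)
    if np.any(denom <= 0):
        bad = r.scrap_ages[denom <= 0]
        raise EventHistoryError(f"zero risk total at scrap age(s) {bad[:5]}")
    return BaselineIncrements(scrap_ages=r.scrap_ages, dL0=r.scrap_dN / denom)


def _sale_pl_parts(r: RiskStructure, flat: np.ndarray, Z: np.ndarray, order: int):
    """Sales partial log likelihood and (optionally) gradient / Hessian."""
    sl = sale_param_slices(r.p1, r.p2, r.p3)
    bV, bS, bB, bE = (flat[sl[k]] for k in ("beta_V", "beta_S", "beta_B", "beta_E"))
    eV, eS, eB, row_eE, ev_logR = r.sale_exps(bV, bS, bB, bE)
    invZ = 1.0 / Z
    A = Z * eS
    C = invZ * eB
    logZ = np.log(Z)

    n_int = r.active_mask.shape[0]
    G = r.cell_X.shape[0]
    # per-interval, per-cell sum of Z^-1 over active companies
    Winv = np.zeros((n_int, G))
    for g in range(G):
        in_g = r.cell_of == g
        Winv[:, g] = r.active_mask[:, in_g] @ invZ[in_g]
    eB_cell = np.exp(r.cell_X @ bB) if r.p2 else np.ones(G)
    B0_int = Winv @ eB_cell

    ri = r.row_interval
    s = r.row_owner
    v = r.row_vessel
    own0 = np.where(r.row_active, C[s], 0.0)
    B0r = B0_int[ri] - own0
    base = A[s] * eV[v] * row_eE
    w = base * B0r
    J = r.sale_ages.size
    denom = np.bincount(r.row_age, weights=w, minlength=J)
    if np.any(denom <= 0):
        raise EventHistoryError("empty weighted risk set at a sale event age")
    val = float(
        ev_logR.sum()
        + (logZ[r.ev_seller] - logZ[r.ev_buyer]).sum()
        - (r.sale_dN * np.log(denom)).sum()
    )
    if order == 0:
        return val, None, None

    p1, p2, p3 = r.p1, r.p2, r.p3
    p = p1 + 2 * p2 + p3
    # row feature columns for the (V, S, E) blocks; the B block works through
    # the buyer-sum moments
    nvse = p1 + p2 + p3
    F = np.empty((r.row_age.size, nvse))
    F[:, :p1] = r.XV[v]
    F[:, p1:p1 + p2] = r.XC[s]
    if p3:
        F[:, p1 + p2:] = r.row_xE
    B1_int = Winv @ (eB_cell[:, None] * r.cell_X) if p2 else np.zeros((n_int, 0))
    B1r = B1_int[ri] - own0[:, None] * r.XC[s]  # (R, p2)

    def idx_full(k: int) -> int:
        # map VSE-feature column to full parameter index (B block sits between S and E)
        return k if k < p1 + p2 else k + p2

    gd = np.zeros((J, p))
    for k in range(nvse):
        gd[:, idx_full(k)] = np.bincount(r.row_age, weights=w * F[:, k], minlength=J)
    for k in range(p2):
        gd[:, p1 + p2 + k] = np.bincount(
            r.row_age, weights=base * B1r[:, k], minlength=J
        )

    num_grad = np.zeros(p)
    num_grad[:p1] = r.XV[r.ev_vessel].sum(axis=0)
    num_grad[p1:p1 + p2] = r.XC[r.ev_seller].sum(axis=0)
    num_grad[p1 + p2:p1 + 2 * p2] = r.XC[r.ev_buyer].sum(axis=0)
    if p3:
        num_grad[p1 + 2 * p2:] = r.ev_xE.sum(axis=0)

    ratio = r.sale_dN / denom
    grad = num_grad - gd.T @ ratio
    if order == 1:
        return val, grad, None

    Hd = np.zeros((J, p, p))
    for a in range(nvse):
        ia = idx_full(a)
        for b in range(a, nvse):
            ib = idx_full(b)
            col = np.bincount(r.row_age, weights=w * F[:, a] * F[:, b], minlength=J)
            Hd[:, ia, ib] = col
            Hd[:, ib, ia] = col
        for b in range(p2):
            ib = p1 + p2 + b
            col = np.bincount(
                r.row_age, weights=base * F[:, a] * B1r[:, b], minlength=J
            )
            Hd[:, ia, ib] = col
            Hd[:, ib, ia] = col
    if p2:
        B2_int = np.einsum("ig,ga,gb->iab", Winv * eB_cell[None, :], r.cell_X, r.cell_X)
        XCs = r.XC[s]
        for a in range(p2):
            for b in range(a, p2):
                col = np.bincount(
                    r.row_age,
                    weights=base * (B2_int[ri, a, b] - own0 * XCs[:, a] * XCs[:, b]),
                    minlength=J,
                )
                Hd[:, p1 + p2 + a, p1 + p2 + b] = col
                Hd[:, p1 + p2 + b, p1 + p2 + a] = col

    hess = -(
        np.einsum("j,jab->ab", ratio, Hd)
        - gd.T @ (gd * (r.sale_dN / denom**2)[:, None])
    )
    return val, grad, hess


def _scrap_pl_parts(r: RiskStructure, flat: np.ndarray, Z: np.ndarray, order: int):
    sl = scrap_param_slices(r.p1, r.p2, r.p3)
    tV, tS, tE = (flat[sl[k]] for k in ("theta_V", "theta_S", "theta_E"))
    eV, eS, row_eE, ev_logQ = r.scrap_exps(tV, tS, tE)
    A = Z * eS
    logZ = np.log(Z)
    J = r.scrap_ages.size
    w = A[r.srow_owner] * eV[r.srow_vessel] * row_eE
    denom = np.bincount(r.srow_age, weights=w, minlength=J)
    if np.any(denom <= 0):
        raise EventHistoryError("empty weighted risk set at a scrap event age")
    val = float(
        ev_logQ.sum() + logZ[r.sev_owner].sum() - (r.scrap_dN * np.log(denom)).sum()
    )
    if order == 0:
        return val, None, None

    p1, p2, p3 = r.p1, r.p2, r.p3
    p = p1 + p2 + p3
    F = np.empty((r.srow_age.size, p))
    F[:, :p1] = r.XV[r.srow_vessel]
    F[:, p1:p1 + p2] = r.XC[r.srow_owner]
    if p3:
        F[:, p1 + p2:] = r.srow_xE
    gd = np.zeros((J, p))
    for k in range(p):
        gd[:, k] = np.bincount(r.srow_age, weights=w * F[:, k], minlength=J)
    num_grad = np.zeros(p)
    num_grad[:p1] = r.XV[r.sev_vessel].sum(axis=0)
    num_grad[p1:p1 + p2] = r.XC[r.sev_owner].sum(axis=0)
    if p3:
        num_grad[p1 + p2:] = r.sev_xE.sum(axis=0)
    ratio = r.scrap_dN / denom
    grad = num_grad - gd.T @ ratio
    if order == 1:
        return val, grad, None

    Hd = np.zeros((J, p, p))
    for a in range(p):
        for b in range(a, p):
            col = np.bincount(r.srow_age, weights=w * F[:, a] * F[:, b], minlength=J)
            Hd[:, a, b] = col
            Hd[:, b, a] = col
    hess = -(
        np.einsum("j,jab->ab", ratio, Hd)
        - gd.T @ (gd * (r.scrap_dN / denom**2)[:, None])
    )
    return val, grad, hess


def partial_loglik_sale(
    h: EventHistory, params: RegressionParams, frailty: FrailtyState | None = None,
    derivatives: bool = False, risk: RiskStructure | None = None,
):
    """Sales partial log likelihood given frailties (Breslow tie handling).

    With ``derivatives=True`` returns ``(value, gradient, observed_information)``
    in the flattened (bV, bS, bB, bE) layout.
    """
    r = _risk_for(h, risk)
    if r.n_sales == 0:
        raise EventHistoryError("no sale events")
    Z = _z_vector(h, frailty)
    val, grad, hess = _sale_pl_parts(r, params.sale_flat(), Z, 2 if derivatives else 0)
    if derivatives:
        return val, grad, -hess
    return val


def partial_loglik_scrap(
    h: EventHistory, params: RegressionParams, frailty: FrailtyState | None = None,
    derivatives: bool = False, risk: RiskStructure | None = None,
):
    """Scrap partial log likelihood given frailties; see partial_loglik_sale."""
    r = _risk_for(h, risk)
    if r.n_scraps == 0:
        raise EventHistoryError("no scrap events")
    Z = _z_vector(h, frailty)
    val, grad, hess = _scrap_pl_parts(r, params.scrap_flat(), Z, 2 if derivatives else 0)
    if derivatives:
        return val, grad, -hess
    return val


# ---------------------------------------------------------------------------
# no-frailty Newton-Raphson fits
# ---------------------------------------------------------------------------

def _newton(parts, p: int, max_iter: int = 50, tol: float = 1e-8):
    x = np.zeros(p)
    val, grad, hess = parts(x, 2)
    n_iter = 0
    converged = bool(np.max(np.abs(grad)) < tol) if p else True
    for n_iter in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            raise RuntimeError("singular observed information in Newton-Raphson")
        new = x + step
        ok = False
        for _ in range(30):
            try:
                nval, ngrad, nhess = parts(new, 2)
            except (FloatingPointError, EventHistoryError):
                nval = -np.inf
            # accept any non-decreasing step up to float noise at |val| scale
            if np.isfinite(nval) and nval >= val - 1e-9 * max(1.0, abs(val)):
                ok = True
                break
            step *= 0.5
            new = x + step
        if not ok:
            break
        x, val, grad, hess = new, nval, ngrad, nhess
    return x, val, grad, hess, n_iter, converged


@dataclass
class NoFrailtyFit:
    """Maximum partial-likelihood fit with all frailties fixed at one."""

    params: RegressionParams
    sale_se: np.ndarray | None = None
    scrap_se: np.ndarray | None = None
    sale_cov: np.ndarray | None = None
    scrap_cov: np.ndarray | None = None
    loglik_sale: float | None = None
    loglik_scrap: float | None = None
    sale_converged: bool = True
    scrap_converged: bool = True
    sale_iterations: int = 0
    scrap_iterations: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Flat (parameter, estimate, SE, Wald) table plus maximised log PLs."""
        rows = []

        def model(blocks, ses):
            k = 0
            for name, values in blocks:
                for i, est in enumerate(np.atleast_1d(values)):
                    se = float(ses[k])
                    rows.append(
                        {
                            "parameter": f"{name}_{i + 1}",
                            "estimate": float(est),
                            "se": se,
                            "wald": float(est) / se if se > 0 else np.nan,
                        }
                    )
                    k += 1

        if self.sale_se is not None:
            model(
                [
                    ("beta_V", self.params.beta_V),
                    ("beta_S", self.params.beta_S),
                    ("beta_B", self.params.beta_B),
                    ("beta_E", self.params.beta_E),
                ],
                self.sale_se,
            )
        if self.scrap_se is not None:
            model(
                [
                    ("theta_V", self.params.theta_V),
                    ("theta_S", self.params.theta_S),
                    ("theta_E", self.params.theta_E),
                ],
                self.scrap_se,
            )
        df = pd.DataFrame(rows)
        df.attrs["loglik_sale"] = self.loglik_sale
        df.attrs["loglik_scrap"] = self.loglik_scrap
        return df


def fit_no_frailty(
    h: EventHistory, which: str = "both", risk: RiskStructure | None = None,
    max_iter: int = 50, tol: float = 1e-8,
) -> NoFrailtyFit:
    """Newton-Raphson maximiser of the partial likelihood(s) with Z = 1.

    ``which`` is ``"sale"``, ``"scrap"`` or ``"both"`` (scrap silently skipped
    when the data contain no scrap events and ``which="both"``).  Standard
    errors come from the inverse observed information.
    """
    r = _risk_for(h, risk)
    Z = np.ones(r.n_companies)
    do_sale = which in ("sale", "both")
    do_scrap = which in ("scrap", "both")
    if which not in ("sale", "scrap", "both"):
        raise ValueError("which must be 'sale', 'scrap' or 'both'")
    if do_sale and r.n_sales == 0:
        raise EventHistoryError("no sale events to fit")
    if do_scrap and r.n_scraps == 0:
        if which == "scrap":
            raise EventHistoryError("no scrap events to fit")
        do_scrap = False

    fit = NoFrailtyFit(params=RegressionParams.zeros(r.p1, r.p2, r.p3))
    if do_sale:
        p = r.p1 + 2 * r.p2 + r.p3
        x, val, grad, hess, n_iter, conv = _newton(
            lambda f, o: _sale_pl_parts(r, f, Z, o), p, max_iter, tol
        )
        if not conv:
            raise RuntimeError(
                f"sales model Newton-Raphson did not converge in {n_iter} iterations "
                f"(max |gradient| = {np.max(np.abs(grad)):.3g})"
            )
        cov = np.linalg.inv(-hess)
        fit.params = fit.params.with_sale_flat(x)
        fit.sale_se = np.sqrt(np.diag(cov))
        fit.sale_cov = cov
        fit.loglik_sale = val
        fit.sale_converged = conv
        fit.sale_iterations = n_iter
    if do_scrap:
        p = r.p1 + r.p2 + r.p3
        x, val, grad, hess, n_iter, conv = _newton(
            lambda f, o: _scrap_pl_parts(r, f, Z, o), p, max_iter, tol
        )
        if not conv:
            raise RuntimeError(
                f"scrap model Newton-Raphson did not converge in {n_iter} iterations "
                f"(max |gradient| = {np.max(np.abs(grad)):.3g})"
            )
        cov = np.linalg.inv(-hess)
        fit.params = fit.params.with_scrap_flat(x)
        fit.scrap_se = np.sqrt(np.diag(cov))
        fit.scrap_cov = cov
        fit.loglik_scrap = val
        fit.scrap_converged = conv
        fit.scrap_iterations = n_iter
    return fit


def plot_cumulative_baselines(
    baselines: BaselineIncrements, params: RegressionParams | None = None,
    covariates: dict | None = None, ax=None,
):
    """Step plot of the estimated cumulative baselines, optionally rescaled.

    When ``params`` and ``covariates`` (keys among ``x_V``, ``x_S``, ``x_B``,
    ``x_E``) are given, the curves are multiplied by the corresponding
    relative risk so they show the cumulative intensity/hazard at a chosen
    covariate profile (e.g. median covariates).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sale_scale = scrap_scale = 1.0
    if params is not None and covariates:
        xV = np.asarray(covariates.get("x_V", np.zeros(params.beta_V.size)))
        xS = np.asarray(covariates.get("x_S", np.zeros(params.beta_S.size)))
        xB = np.asarray(covariates.get("x_B", np.zeros(params.beta_B.size)))
        xE = np.asarray(covariates.get("x_E", np.zeros(params.beta_E.size)))
        sale_scale = float(np.exp(
            params.beta_V @ xV + params.beta_S @ xS + params.beta_B @ xB
            + params.beta_E @ xE
        ))
        scrap_scale = float(np.exp(
            params.theta_V @ xV[: params.theta_V.size]
            + params.theta_S @ xS[: params.theta_S.size]
            + params.theta_E @ xE[: params.theta_E.size]
        )) if params.theta_V.size or params.theta_S.size else 1.0
    if baselines.sale_ages.size:
        ax.step(
            baselines.sale_ages, np.cumsum(baselines.dA0) * sale_scale,
            where="post", label="cumulative sales intensity",
        )
    if baselines.scrap_ages.size:
        ax.step(
            baselines.scrap_ages, np.cumsum(baselines.dL0) * scrap_scale,
            where="post", label="cumulative scrap hazard",
        )
    ax.set_xlabel("vessel age (months)")
    ax.set_ylabel("cumulative intensity")
    ax.legend()
    return ax
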
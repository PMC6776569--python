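"""Vectorised risk-set structure shared by fitters, Breslow estimators and MCMC.

The estimators all reduce to sums over *risk rows*: one row per (distinct
event age, vessel at risk at that age), carrying the left-limit owner.  For
the sales model the weighted risk total at age ``a`` is

    sum_rows  Z_s * exp(bV.xv + bS.xs + bE.xE) * sum_{b != s active} Z_b^-1 exp(bB.xb)

and the buyer sum collapses over *cells* of companies sharing a covariate
vector, so its cost scales with the number of distinct covariate patterns,
not with the number of companies.  Company activity windows partition
calendar time into intervals; each row stores its interval index so buyer
sums respect activity without per-row company scans.

Hot accumulations (risk totals per age, per-owner exposure totals) are numba
kernels; derivative assembly is plain numpy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .event_history import SALE, SCRAP, EventHistory

__all__ = ["RiskStructure", "sale_param_slices", "scrap_param_slices"]


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _accum_denom(row_age, row_vessel, row_owner, row_interval, row_active,
                 row_eE, eV, A, C, B0_int, n_ages):
    """Weighted risk total per distinct age.

    A[s] = Z_s * exp(bS.xs); C[s] = Z_s^-1 * exp(bB.xs);
    B0_int[i] = sum over companies active in interval i of Z^-1 exp(bB.x).
    """
    denom = np.zeros(n_ages)
    for r in range(row_age.size):
        s = row_owner[r]
        b0 = B0_int[row_interval[r]]
        if row_active[r]:
            b0 -= C[s]
        denom[row_age[r]] += A[s] * eV[row_vessel[r]] * row_eE[r] * b0
    return denom


@njit(cache=True)
def _accum_owner(row_age, row_vessel, row_owner, row_eE, eV, dA0, n_companies):
    """Per-owner exposure total: sum over own rows of dA0 * eV * eE."""
    out = np.zeros(n_companies)
    for r in range(row_age.size):
        out[row_owner[r]] += dA0[row_age[r]] * eV[row_vessel[r]] * row_eE[r]
    return out


@njit(cache=True)
def _accum_denom_scrap(row_age, row_vessel, row_owner, row_eE, eV, A, n_ages):
    """Scrap-side risk total per age: sum Z_s exp(tS.xs) * exp(tV.xv) * eE."""
    denom = np.zeros(n_ages)
    for r in range(row_age.size):
        denom[row_age[r]] += A[row_owner[r]] * eV[row_vessel[r]] * row_eE[r]
    return denom


# ---------------------------------------------------------------------------
# structure
# ---------------------------------------------------------------------------

def _distinct_ages(ages: list[float]) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(ages, dtype=float)
    uniq, counts = np.unique(arr, return_counts=True)
    return uniq, counts.astype(np.int64)


@dataclass
class RiskStructure:
    """Flattened arrays describing risk sets at every distinct event age."""

    n_companies: int
    n_vessels: int
    XV: np.ndarray          # (K, p1) vessel covariates
    XC: np.ndarray          # (N, p2) company covariates
    deliveries: np.ndarray  # (K,)

    # company cells (groups sharing a covariate vector)
    cell_of: np.ndarray     # (N,) int
    cell_X: np.ndarray      # (G, p2)

    # calendar activity intervals
    int_breaks: np.ndarray        # (n_int + 1,) interval edges
    active_mask: np.ndarray       # (n_int, N) bool
    uniform_activity: bool

    # sale side
    sale_ages: np.ndarray   # (J,) distinct, sorted
    sale_dN: np.ndarray     # (J,) tie counts
    ev_age: np.ndarray      # (n_sales,) index into sale_ages
    ev_vessel: np.ndarray
    ev_seller: np.ndarray
    ev_buyer: np.ndarray
    ev_xE: np.ndarray | None
    row_age: np.ndarray     # (R,) index into sale_ages
    row_vessel: np.ndarray
    row_owner: np.ndarray
    row_interval: np.ndarray
    row_active: np.ndarray  # (R,) owner active at row time
    row_xE: np.ndarray | None

    # scrap side (empty arrays when no scrap events)
    scrap_ages: np.ndarray
    scrap_dN: np.ndarray
    sev_age: np.ndarray
    sev_vessel: np.ndarray
    sev_owner: np.ndarray
    sev_xE: np.ndarray | None
    srow_age: np.ndarray
    srow_vessel: np.ndarray
    srow_owner: np.ndarray
    srow_xE: np.ndarray | None

    # static per-company event balance: (#sales + #scraps) - #purchases
    M: np.ndarray

    @property
    def p1(self) -> int:
        return self.XV.shape[1]

    @property
    def p2(self) -> int:
        return self.XC.shape[1]

    @property
    def p3(self) -> int:
        return 0 if self.row_xE is None else self.row_xE.shape[1]

    @property
    def n_sales(self) -> int:
        return int(self.ev_age.size)

    @property
    def n_scraps(self) -> int:
        return int(self.sev_age.size)

    # -- construction ----------------------------------------------------
    @classmethod
    def from_history(cls, h: EventHistory) -> "RiskStructure":
        N, K = h.n_companies, h.n_vessels
        XV = np.vstack([v.covariates for v in h.vessels]) if K else np.zeros((0, 0))
        if XV.ndim == 1:
            XV = XV.reshape(K, -1)
        XC = np.vstack([c.covariates for c in h.companies]) if N else np.zeros((0, 0))
        if XC.ndim == 1:
            XC = XC.reshape(N, -1)
        deliveries = np.array([v.delivery_time for v in h.vessels], dtype=float)

        if XC.shape[1]:
            cell_X, cell_of = np.unique(XC, axis=0, return_inverse=True)
            cell_of = cell_of.ravel()
        else:
            cell_X = np.zeros((1, 0))
            cell_of = np.zeros(N, dtype=np.int64)

        starts = np.array([c.activity_start for c in h.companies], dtype=float)
        ends = np.array([c.activity_end for c in h.companies], dtype=float)
        finite = np.concatenate([starts[np.isfinite(starts)], ends[np.isfinite(ends)]])
        if finite.size:
            edges = np.unique(np.concatenate([[-np.inf], finite, [np.inf]]))
        else:
            edges = np.array([-np.inf, np.inf])
        n_int = edges.size - 1
        mids = np.where(
            np.isfinite(edges[:-1]),
            edges[:-1],
            np.where(np.isfinite(edges[1:]), edges[1:] - 1.0, 0.0),
        )
        # company active on an interval iff active at its left end (windows are
        # half-open [start, end), and edges include every start/end)
        active_mask = (starts[None, :] <= mids[:, None]) & (mids[:, None] < ends[None, :])
        uniform = bool(active_mask.all())

        # -- collect events and spell coverage
        sale_age_list: list[float] = []
        scrap_age_list: list[float] = []
        for v in h.vessels:
            for sp in v.spells:
                if sp.end_type == SALE:
                    sale_age_list.append(sp.end_age)
                elif sp.end_type == SCRAP:
                    scrap_age_list.append(sp.end_age)
        sale_ages, sale_dN = _distinct_ages(sale_age_list)
        scrap_ages, scrap_dN = _distinct_ages(scrap_age_list)

        def build_rows(ages: np.ndarray):
            r_age, r_ves, r_own = [], [], []
            for vi, v in enumerate(h.vessels):
                for sp in v.spells:
                    # left-limit: spell owns ages in (start, end]
                    lo = np.searchsorted(ages, sp.start_age, side="right")
                    hi = np.searchsorted(ages, sp.end_age, side="right")
                    if hi > lo:
                        oi = h.company_index[sp.owner_id]
                        r_age.append(np.arange(lo, hi, dtype=np.int64))
                        r_ves.append(np.full(hi - lo, vi, dtype=np.int64))
                        r_own.append(np.full(hi - lo, oi, dtype=np.int64))
            if r_age:
                return (
                    np.concatenate(r_age),
                    np.concatenate(r_ves),
                    np.concatenate(r_own),
                )
            z = np.zeros(0, dtype=np.int64)
            return z, z.copy(), z.copy()

        row_age, row_vessel, row_owner = build_rows(sale_ages)
        srow_age, srow_vessel, srow_owner = build_rows(scrap_ages)

        row_t = deliveries[row_vessel] + sale_ages[row_age] if row_age.size else np.zeros(0)
        row_interval = np.clip(
            np.searchsorted(edges, row_t, side="right") - 1, 0, n_int - 1
        ).astype(np.int64)
        row_active = (
            (starts[row_owner] <= row_t) & (row_t < ends[row_owner])
            if row_age.size
            else np.zeros(0, dtype=bool)
        )

        ev_age, ev_vessel, ev_seller, ev_buyer = [], [], [], []
        sev_age, sev_vessel, sev_owner = [], [], []
        for vi, v in enumerate(h.vessels):
            for sp in v.spells:
                if sp.end_type == SALE:
                    ev_age.append(np.searchsorted(sale_ages, sp.end_age))
                    ev_vessel.append(vi)
                    ev_seller.append(h.company_index[sp.owner_id])
                    ev_buyer.append(h.company_index[sp.buyer_id])
                elif sp.end_type == SCRAP:
                    sev_age.append(np.searchsorted(scrap_ages, sp.end_age))
                    sev_vessel.append(vi)
                    sev_owner.append(h.company_index[sp.owner_id])

        ev_age = np.asarray(ev_age, dtype=np.int64)
        ev_vessel = np.asarray(ev_vessel, dtype=np.int64)
        ev_seller = np.asarray(ev_seller, dtype=np.int64)
        ev_buyer = np.asarray(ev_buyer, dtype=np.int64)
        sev_age = np.asarray(sev_age, dtype=np.int64)
        sev_vessel = np.asarray(sev_vessel, dtype=np.int64)
        sev_owner = np.asarray(sev_owner, dtype=np.int64)

        if h.exogenous is not None:
            exo = h.exogenous
            row_xE = exo.at(row_t) if row_t.size else np.zeros((0, exo.p3))
            ev_xE = (
                exo.at(deliveries[ev_vessel] + sale_ages[ev_age])
                if ev_age.size
                else np.zeros((0, exo.p3))
            )
            srow_t = (
                deliveries[srow_vessel] + scrap_ages[srow_age]
                if srow_age.size
                else np.zeros(0)
            )
            srow_xE = exo.at(srow_t) if srow_age.size else np.zeros((0, exo.p3))
            sev_xE = (
                exo.at(deliveries[sev_vessel] + scrap_ages[sev_age])
                if sev_age.size
                else np.zeros((0, exo.p3))
            )
        else:
            row_xE = ev_xE = srow_xE = sev_xE = None

        # per-company event balance M: sells + scraps - purchases
        M = np.zeros(N, dtype=np.int64)
        np.add.at(M, ev_seller, 1)
        np.add.at(M, sev_owner, 1)
        np.subtract.at(M, ev_buyer, 1)

        return cls(
            n_companies=N,
            n_vessels=K,
            XV=XV,
            XC=XC,
            deliveries=deliveries,
            cell_of=cell_of,
            cell_X=cell_X,
            int_breaks=edges,
            active_mask=active_mask,
            uniform_activity=uniform,
            sale_ages=sale_ages,
            sale_dN=sale_dN,
            ev_age=ev_age,
            ev_vessel=ev_vessel,
            ev_seller=ev_seller,
            ev_buyer=ev_buyer,
            ev_xE=ev_xE,
            row_age=row_age,
            row_vessel=row_vessel,
            row_owner=row_owner,
            row_interval=row_interval,
            row_active=row_active,
            row_xE=row_xE,
            scrap_ages=scrap_ages,
            scrap_dN=scrap_dN,
            sev_age=sev_age,
            sev_vessel=sev_vessel,
            sev_owner=sev_owner,
            sev_xE=sev_xE,
            srow_age=srow_age,
            srow_vessel=srow_vessel,
            srow_owner=srow_owner,
            srow_xE=srow_xE,
            M=M,
        )

    # -- cached covariate exponentials -----------------------------------
    def sale_exps(self, beta_V, beta_S, beta_B, beta_E):
        """(eV, eS, eB, row_eE, ev_logR) for the sales model."""
        eV = np.exp(self.XV @ beta_V) if self.p1 else np.ones(self.n_vessels)
        eS = np.exp(self.XC @ beta_S) if self.p2 else np.ones(self.n_companies)
        eB = np.exp(self.XC @ beta_B) if self.p2 else np.ones(self.n_companies)
        if self.row_xE is not None and beta_E is not None and beta_E.size:
            row_eE = np.exp(self.row_xE @ beta_E)
            ev_eE = self.ev_xE @ beta_E
        else:
            row_eE = np.ones(self.row_age.size)
            ev_eE = np.zeros(self.ev_age.size)
        ev_logR = (
            (self.XV[self.ev_vessel] @ beta_V if self.p1 else 0.0)
            + (self.XC[self.ev_seller] @ beta_S if self.p2 else 0.0)
            + (self.XC[self.ev_buyer] @ beta_B if self.p2 else 0.0)
            + ev_eE
        )
        return eV, eS, eB, row_eE, np.asarray(ev_logR) + np.zeros(self.ev_age.size)

    def scrap_exps(self, theta_V, theta_S, theta_E):
        eV = np.exp(self.XV @ theta_V) if self.p1 else np.ones(self.n_vessels)
        eS = np.exp(self.XC @ theta_S) if self.p2 else np.ones(self.n_companies)
        if self.srow_xE is not None and theta_E is not None and theta_E.size:
            row_eE = np.exp(self.srow_xE @ theta_E)
            ev_eE = self.sev_xE @ theta_E
        else:
            row_eE = np.ones(self.srow_age.size)
            ev_eE = np.zeros(self.sev_age.size)
        ev_logQ = (
            (self.XV[self.sev_vessel] @ theta_V if self.p1 else 0.0)
            + (self.XC[self.sev_owner] @ theta_S if self.p2 else 0.0)
            + ev_eE
        )
        return eV, eS, row_eE, np.asarray(ev_logQ) + np.zeros(self.sev_age.size)

    def buyer_cell_sums(self, eB_company: np.ndarray, invZ: np.ndarray) -> np.ndarray:
        """B0 per activity interval: sum of Z^-1 exp(bB.x) over active companies."""
        contrib = invZ * eB_company
        return self.active_mask @ contrib

    # -- core accumulations ----------------------------------------------
    def sale_denoms(self, eV, eS, eB, row_eE, Z) -> np.ndarray:
        """Weighted risk total at each distinct sale age (Breslow denominator)."""
        invZ = 1.0 / Z
        A = Z * eS
        C = invZ * eB
        B0_int = self.active_mask @ C
        return _accum_denom(
            self.row_age, self.row_vessel, self.row_owner, self.row_interval,
            self.row_active, row_eE, eV, A, C, B0_int, self.sale_ages.size,
        )

    def scrap_denoms(self, eV, eS, row_eE, Z) -> np.ndarray:
        A = Z * eS
        return _accum_denom_scrap(
            self.srow_age, self.srow_vessel, self.srow_owner, row_eE, eV, A,
            self.scrap_ages.size,
        )

    def owner_exposure(self, eV, row_eE, dA0) -> np.ndarray:
        """Per-company sum over owned sale-risk rows of dA0 * eV * eE."""
        return _accum_owner(
            self.row_age, self.row_vessel, self.row_owner, row_eE, eV,
            dA0, self.n_companies,
        )

    def scrap_owner_exposure(self, eV, row_eE, dL0) -> np.ndarray:
        return _accum_owner(
            self.srow_age, self.srow_vessel, self.srow_owner, row_eE, eV,
            dL0, self.n_companies,
        )


def sale_param_slices(p1: int, p2: int, p3: int) -> dict[str, slice]:
    """Layout of the flattened sales parameter vector (bV, bS, bB, bE)."""
    return {
        "beta_V": slice(0, p1),
        "beta_S": slice(p1, p1 + p2),
        "beta_B": slice(p1 + p2, p1 + 2 * p2),
        "beta_E": slice(p1 + 2 * p2, p1 + 2 * p2 + p3),
    }


def scrap_param_slices(p1: int, p2: int, p3: int) -> dict[str, slice]:
    return {
        "theta_V": slice(0, p1),
        "theta_S": slice(p1, p1 + p2),
        "theta_E": slice(p1 + p2, p1 + p2 + p3),
    }
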
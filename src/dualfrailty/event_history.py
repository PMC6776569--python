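"""Event-history data model for vessel ownership durations.

The observable data consist of *companies* (potential buyers and sellers,
each with a vector of covariates and a calendar activity window), *vessels*
(each with a delivery time, static covariates and an ordered sequence of
ownership spells) and an optional *exogenous* covariate series (a
right-continuous step function of calendar time describing market
conditions).  A vessel of age ``a`` is at calendar time ``t_v(a) =
delivery_time + a``; ages and calendar times are measured in months.

Each ownership spell is a half-open age interval ``[start_age, end_age)``.
A spell ends in a ``sale`` (with a recorded buyer, who owns the vessel from
``end_age`` on), in ``scrap`` (absorbing), or in ``censor`` (end of
follow-up).  Risk sets use the left-limit (predictable) convention: at an
event age the vessel is still at risk with its pre-event owner.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SALE",
    "SCRAP",
    "CENSOR",
    "OwnershipSpell",
    "VesselRecord",
    "CompanyRecord",
    "ExogenousSeries",
    "EventHistory",
    "EventHistoryError",
    "read_event_history",
    "write_event_history",
    "previous_owners",
    "risk_set",
    "exogenous_at",
]

log = logging.getLogger(__name__)

SALE = "sale"
SCRAP = "scrap"
CENSOR = "censor"
_END_TYPES = (SALE, SCRAP, CENSOR)


class EventHistoryError(ValueError):
    """Raised when event-history inputs violate a structural invariant."""


@dataclass(frozen=True)
class OwnershipSpell:
    """One ownership period of a vessel, over ages ``[start_age, end_age)``."""

    owner_id: str
    start_age: float
    end_age: float
    end_type: str
    buyer_id: str | None = None

    def __post_init__(self) -> None:
        if self.end_type not in _END_TYPES:
            raise EventHistoryError(
                f"end_type must be one of {_END_TYPES}, got {self.end_type!r}"
            )
        if not self.start_age < self.end_age:
            raise EventHistoryError(
                f"spell of {self.owner_id!r}: start_age {self.start_age} must be "
                f"< end_age {self.end_age}"
            )
        if self.end_type == SALE:
            if self.buyer_id is None:
                raise EventHistoryError(
                    f"sale spell of {self.owner_id!r} at age {self.end_age} has no buyer"
                )
            if self.buyer_id == self.owner_id:
                raise EventHistoryError(
                    f"spell of {self.owner_id!r} ending at age {self.end_age}: "
                    "buyer equals owner"
                )
        elif self.buyer_id is not None:
            raise EventHistoryError(
                f"non-sale spell of {self.owner_id!r} carries a buyer id"
            )


@dataclass(frozen=True, eq=False)
class VesselRecord:
    """A vessel: delivery calendar time, static covariates, ownership spells."""

    vessel_id: str
    delivery_time: float
    covariates: np.ndarray
    spells: tuple[OwnershipSpell, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "covariates", np.asarray(self.covariates, dtype=float)
        )
        object.__setattr__(self, "spells", tuple(self.spells))
        if not self.spells:
            raise EventHistoryError(f"vessel {self.vessel_id!r} has no spells")
        prev = self.spells[0]
        if prev.start_age != 0.0:
            raise EventHistoryError(
                f"vessel {self.vessel_id!r}: first spell starts at "
                f"{prev.start_age}, expected age 0"
            )
        for k, sp in enumerate(self.spells[1:], start=1):
            if sp.start_age != prev.end_age:
                raise EventHistoryError(
                    f"vessel {self.vessel_id!r}: gap/overlap between spell {k - 1} "
                    f"(ends {prev.end_age}) and spell {k} (starts {sp.start_age})"
                )
            if prev.end_type != SALE:
                raise EventHistoryError(
                    f"vessel {self.vessel_id!r}: spell {k - 1} ends in "
                    f"{prev.end_type!r} but is not the last spell"
                )
            if sp.owner_id != prev.buyer_id:
                raise EventHistoryError(
                    f"vessel {self.vessel_id!r}: owner of spell {k} "
                    f"({sp.owner_id!r}) differs from buyer of spell {k - 1} "
                    f"({prev.buyer_id!r})"
                )
            prev = sp
        if self.spells[-1].end_type == SALE:
            raise EventHistoryError(
                f"vessel {self.vessel_id!r}: last spell must end in scrap or censor"
            )

    @property
    def final_age(self) -> float:
        """Age at which observation of the vessel ends (scrap or censoring)."""
        return self.spells[-1].end_age

    @property
    def scrapped(self) -> bool:
        return self.spells[-1].end_type == SCRAP

    def time_at_age(self, age: float) -> float:
        """Calendar time ``t_v(a) = delivery_time + a``."""
        return self.delivery_time + age

    def owner_at(self, age: float) -> str:
        """Owner under the left-limit convention (spells read as ``(start, end]``).

        At a sale age the seller — the pre-sale owner — is returned; at age 0
        the first owner.
        """
        if age <= 0:
            return self.spells[0].owner_id
        for sp in self.spells:
            if sp.start_age < age <= sp.end_age:
                return sp.owner_id
        raise EventHistoryError(
            f"vessel {self.vessel_id!r} not under observation at age {age}"
        )

    def at_risk(self, age: float) -> bool:
        """Left-continuous at-risk indicator Y(a): in use on ``(0, final_age]``."""
        return 0.0 < age <= self.final_age

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, VesselRecord)
            and self.vessel_id == other.vessel_id
            and self.delivery_time == other.delivery_time
            and np.array_equal(self.covariates, other.covariates)
            and self.spells == other.spells
        )


@dataclass(frozen=True, eq=False)
class CompanyRecord:
    """A company with time-fixed covariates and one calendar activity window."""

    company_id: str
    covariates: np.ndarray
    activity_start: float = -np.inf
    activity_end: float = np.inf

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "covariates", np.asarray(self.covariates, dtype=float)
        )
        if not self.activity_start < self.activity_end:
            raise EventHistoryError(
                f"company {self.company_id!r}: activity_start must be < activity_end"
            )

    def active_at(self, t: float) -> bool:
        """Activity indicator Y^C_c(t) on ``[activity_start, activity_end)``."""
        return self.activity_start <= t < self.activity_end

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CompanyRecord)
            and self.company_id == other.company_id
            and np.array_equal(self.covariates, other.covariates)
            and self.activity_start == other.activity_start
            and self.activity_end == other.activity_end
        )


@dataclass(frozen=True, eq=False)
class ExogenousSeries:
    """Right-continuous step function of calendar time, vector valued."""

    breakpoints: np.ndarray
    values: np.ndarray  # shape (n_breakpoints, p3)

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        vals = np.atleast_2d(np.asarray(self.values, dtype=float))
        if vals.shape[0] != bp.shape[0]:
            raise EventHistoryError(
                "exogenous series: one value row per breakpoint required"
            )
        if bp.size == 0:
            raise EventHistoryError("exogenous series is empty")
        if np.any(np.diff(bp) <= 0):
            raise EventHistoryError(
                "exogenous breakpoints must be strictly increasing"
            )
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "values", vals)

    @property
    def p3(self) -> int:
        return self.values.shape[1]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ExogenousSeries)
            and np.array_equal(self.breakpoints, other.breakpoints)
            and np.array_equal(self.values, other.values)
        )

    def at(self, t: float | np.ndarray) -> np.ndarray:
        """Value at calendar time ``t``, clamped to the covered range."""
        t = np.asarray(t, dtype=float)
        if np.any(t < self.breakpoints[0]):
            warnings.warn(
                "exogenous lookup before first breakpoint; clamping to the "
                "earliest value",
                stacklevel=2,
            )
        idx = np.clip(
            np.searchsorted(self.breakpoints, t, side="right") - 1,
            0,
            len(self.breakpoints) - 1,
        )
        return self.values[idx]


@dataclass(frozen=True, eq=False)
class EventHistory:
    """Companies, vessels, spells and exogenous series over one window.

    ``window`` is ``(tau1, tau2, tau)``: deliveries occur in ``(tau1, tau2)``
    and follow-up is censored at calendar time ``tau``.
    """

    companies: tuple[CompanyRecord, ...]
    vessels: tuple[VesselRecord, ...]
    exogenous: ExogenousSeries | None = None
    window: tuple[float, float, float] | None = None

    # derived indices, built in __post_init__
    company_index: Mapping[str, int] = field(default=None, repr=False, compare=False)
    vessel_index: Mapping[str, int] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "companies", tuple(self.companies))
        object.__setattr__(self, "vessels", tuple(self.vessels))
        cidx = {c.company_id: i for i, c in enumerate(self.companies)}
        vidx = {v.vessel_id: i for i, v in enumerate(self.vessels)}
        if len(cidx) != len(self.companies):
            raise EventHistoryError("duplicate company ids")
        if len(vidx) != len(self.vessels):
            raise EventHistoryError("duplicate vessel ids")
        object.__setattr__(self, "company_index", cidx)
        object.__setattr__(self, "vessel_index", vidx)
        p2 = {c.covariates.shape for c in self.companies}
        if len(p2) > 1:
            raise EventHistoryError("company covariate vectors differ in length")
        p1 = {v.covariates.shape for v in self.vessels}
        if len(p1) > 1:
            raise EventHistoryError("vessel covariate vectors differ in length")
        if self.window is None:
            deliveries = [v.delivery_time for v in self.vessels]
            ends = [v.delivery_time + v.final_age for v in self.vessels]
            win = (
                float(min(deliveries, default=0.0)),
                float(max(deliveries, default=0.0)),
                float(max(ends, default=0.0)),
            )
            object.__setattr__(self, "window", win)
        for v in self.vessels:
            for k, sp in enumerate(v.spells):
                if sp.owner_id not in cidx:
                    raise EventHistoryError(
                        f"vessel {v.vessel_id!r} spell {k}: unknown owner "
                        f"{sp.owner_id!r}"
                    )
                if sp.end_type == SALE and sp.buyer_id not in cidx:
                    raise EventHistoryError(
                        f"vessel {v.vessel_id!r} spell {k}: unknown buyer "
                        f"{sp.buyer_id!r}"
                    )
                owner = self.companies[cidx[sp.owner_id]]
                t0 = v.delivery_time + sp.start_age
                t1 = v.delivery_time + sp.end_age
                # owner must be active over the calendar span it owns the vessel
                if t0 < owner.activity_start or t1 > owner.activity_end:
                    raise EventHistoryError(
                        f"vessel {v.vessel_id!r} spell {k}: owner {sp.owner_id!r} "
                        f"inactive during [{t0}, {t1}]"
                    )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, EventHistory)
            and self.companies == other.companies
            and self.vessels == other.vessels
            and self.exogenous == other.exogenous
            and self.window == other.window
        )

    # -- convenience ----------------------------------------------------
    @property
    def n_companies(self) -> int:
        return len(self.companies)

    @property
    def n_vessels(self) -> int:
        return len(self.vessels)

    @property
    def p1(self) -> int:
        return int(self.vessels[0].covariates.size) if self.vessels else 0

    @property
    def p2(self) -> int:
        return int(self.companies[0].covariates.size) if self.companies else 0

    @property
    def p3(self) -> int:
        return self.exogenous.p3 if self.exogenous is not None else 0

    def company(self, company_id: str) -> CompanyRecord:
        try:
            return self.companies[self.company_index[company_id]]
        except KeyError:
            raise EventHistoryError(f"unknown company {company_id!r}") from None

    def vessel(self, vessel_id: str) -> VesselRecord:
        try:
            return self.vessels[self.vessel_index[vessel_id]]
        except KeyError:
            raise EventHistoryError(f"unknown vessel {vessel_id!r}") from None

    def n_sales(self) -> int:
        return sum(
            1 for v in self.vessels for sp in v.spells if sp.end_type == SALE
        )

    def n_scraps(self) -> int:
        return sum(1 for v in self.vessels if v.scrapped)


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

def previous_owners(h: EventHistory, vessel_id: str, age: float) -> int:
    """Number of completed sales of the vessel at or before ``age``.

    The count is a right-continuous step function of age: a sale at age ``a``
    is included from ``a`` on.  Model code that needs a predictable covariate
    at an event age should query the left limit (``age`` minus an epsilon, or
    equivalently count sales strictly before the event age).
    """
    v = h.vessel(vessel_id)
    if age < 0 or age > v.final_age:
        raise EventHistoryError(
            f"age {age} outside [0, {v.final_age}] for vessel {vessel_id!r}"
        )
    return sum(1 for sp in v.spells if sp.end_type == SALE and sp.end_age <= age)


def risk_set(
    h: EventHistory, age: float
) -> list[tuple[str, str, frozenset[str]]]:
    """Vessels at risk at ``age`` with their owner and eligible-buyer sets.

    Returns ``(vessel_id, owner_id, buyers)`` triples, one per vessel with
    ``Y^V_v(age) = 1``; ``buyers`` are the companies other than the owner
    that are active at the vessel's own calendar time ``t_v(age)``.
    """
    if age < 0:
        raise EventHistoryError(f"age must be nonnegative, got {age}")
    out: list[tuple[str, str, frozenset[str]]] = []
    for v in h.vessels:
        if not v.at_risk(age):
            continue
        owner = v.owner_at(age)
        t = v.time_at_age(age)
        buyers = frozenset(
            c.company_id
            for c in h.companies
            if c.company_id != owner and c.active_at(t)
        )
        out.append((v.vessel_id, owner, buyers))
    return out


def exogenous_at(series: ExogenousSeries, t: float, lag: float = 0.0) -> np.ndarray:
    """Exogenous covariate value at calendar time ``t - lag``.

    Lookups outside the covered range clamp to the nearest endpoint (a lagged
    query at the start of follow-up would otherwise have no value).
    """
    if series is None:
        raise EventHistoryError("no exogenous series available")
    return series.at(float(t) - float(lag))


# ---------------------------------------------------------------------------
# Delimited-text IO
# ---------------------------------------------------------------------------

_DEFAULT_FILES = {
    "companies": "companies.csv",
    "vessels": "vessels.csv",
    "spells": "spells.csv",
    "exogenous": "exogenous.csv",
}


def _resolve_paths(paths: str | Path | Mapping[str, str | Path]) -> dict[str, Path]:
    if isinstance(paths, (str, Path)):
        base = Path(paths)
        return {k: base / v for k, v in _DEFAULT_FILES.items()}
    return {k: Path(v) for k, v in paths.items()}


def _require_columns(df: pd.DataFrame, cols: Iterable[str], fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise EventHistoryError(f"{fname}: missing column(s) {missing}")


def read_event_history(
    paths: str | Path | Mapping[str, str | Path],
    schema: Mapping[str, str] | None = None,
) -> EventHistory:
    """Read and validate an event history from delimited text files.

    ``paths`` is either a directory containing ``companies.csv``,
    ``vessels.csv``, ``spells.csv`` and optionally ``exogenous.csv``, or a
    mapping from those keys to explicit file paths.  ``schema`` optionally
    renames columns (``{file_column_name: canonical_name}``).
    """
    p = _resolve_paths(paths)
    for key in ("companies", "vessels", "spells"):
        if key not in p or not Path(p[key]).exists():
            raise EventHistoryError(f"required input file for {key!r} not found")

    def load(key: str) -> pd.DataFrame:
        df = pd.read_csv(p[key], dtype={"company_id": str}, float_precision="round_trip")
        if schema:
            df = df.rename(columns=dict(schema))
        return df

    cdf = load("companies")
    _require_columns(cdf, ["company_id", "activity_start", "activity_end"], "companies")
    ccov = sorted(
        (c for c in cdf.columns if c.startswith("x_C_")),
        key=lambda s: int(s.rsplit("_", 1)[1]),
    )
    companies = tuple(
        CompanyRecord(
            company_id=str(r["company_id"]),
            covariates=np.array([r[c] for c in ccov], dtype=float),
            activity_start=float(r["activity_start"]),
            activity_end=float(r["activity_end"]),
        )
        for r in cdf.to_dict("records")
    )

    vdf = load("vessels")
    _require_columns(vdf, ["vessel_id", "delivery_time"], "vessels")
    vcov = sorted(
        (c for c in vdf.columns if c.startswith("x_V_")),
        key=lambda s: int(s.rsplit("_", 1)[1]),
    )

    sdf = load("spells")
    _require_columns(
        sdf,
        ["vessel_id", "owner_id", "start_age", "end_age", "end_type", "buyer_id"],
        "spells",
    )
    spells_by_vessel: dict[str, list[OwnershipSpell]] = {}
    for i, r in enumerate(sdf.to_dict("records")):
        buyer = r["buyer_id"]
        buyer = None if (buyer is None or (isinstance(buyer, float) and np.isnan(buyer)) or str(buyer) == "") else str(buyer)
        try:
            sp = OwnershipSpell(
                owner_id=str(r["owner_id"]),
                start_age=float(r["start_age"]),
                end_age=float(r["end_age"]),
                end_type=str(r["end_type"]),
                buyer_id=buyer,
            )
        except EventHistoryError as e:
            raise EventHistoryError(f"spells row {i}: {e}") from None
        spells_by_vessel.setdefault(str(r["vessel_id"]), []).append(sp)

    vessels = []
    for r in vdf.to_dict("records"):
        vid = str(r["vessel_id"])
        sps = sorted(spells_by_vessel.get(vid, []), key=lambda s: s.start_age)
        try:
            vessels.append(
                VesselRecord(
                    vessel_id=vid,
                    delivery_time=float(r["delivery_time"]),
                    covariates=np.array([r[c] for c in vcov], dtype=float),
                    spells=tuple(sps),
                )
            )
        except EventHistoryError as e:
            raise EventHistoryError(f"vessel {vid!r}: {e}") from None

    exo = None
    if "exogenous" in p and Path(p["exogenous"]).exists():
        edf = load("exogenous")
        _require_columns(edf, ["time"], "exogenous")
        ecov = sorted(
            (c for c in edf.columns if c.startswith("x_E_")),
            key=lambda s: int(s.rsplit("_", 1)[1]),
        )
        if ecov:
            exo = ExogenousSeries(
                breakpoints=edf["time"].to_numpy(dtype=float),
                values=edf[ecov].to_numpy(dtype=float),
            )

    return EventHistory(companies=companies, vessels=tuple(vessels), exogenous=exo)


def write_event_history(
    h: EventHistory, paths: str | Path | Mapping[str, str | Path]
) -> None:
    """Write an event history as delimited text, round-trippable by the reader."""
    p = _resolve_paths(paths)
    for key in ("companies", "vessels", "spells"):
        Path(p[key]).parent.mkdir(parents=True, exist_ok=True)

    cdf = pd.DataFrame(
        {
            "company_id": [c.company_id for c in h.companies],
            **{
                f"x_C_{j + 1}": [c.covariates[j] for c in h.companies]
                for j in range(h.p2)
            },
            "activity_start": [c.activity_start for c in h.companies],
            "activity_end": [c.activity_end for c in h.companies],
        }
    )
    cdf.to_csv(p["companies"], index=False, float_format="%.17g")

    vdf = pd.DataFrame(
        {
            "vessel_id": [v.vessel_id for v in h.vessels],
            "delivery_time": [v.delivery_time for v in h.vessels],
            **{
                f"x_V_{j + 1}": [v.covariates[j] for v in h.vessels]
                for j in range(h.p1)
            },
        }
    )
    vdf.to_csv(p["vessels"], index=False, float_format="%.17g")

    rows = [
        {
            "vessel_id": v.vessel_id,
            "owner_id": sp.owner_id,
            "start_age": sp.start_age,
            "end_age": sp.end_age,
            "end_type": sp.end_type,
            "buyer_id": sp.buyer_id if sp.buyer_id is not None else "",
        }
        for v in h.vessels
        for sp in v.spells
    ]
    pd.DataFrame(rows).to_csv(p["spells"], index=False, float_format="%.17g")

    if h.exogenous is not None and "exogenous" in p:
        edf = pd.DataFrame(
            {
                "time": h.exogenous.breakpoints,
                **{
                    f"x_E_{j + 1}": h.exogenous.values[:, j]
                    for j in range(h.p3)
                },
            }
        )
        edf.to_csv(p["exogenous"], index=False, float_format="%.17g")
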
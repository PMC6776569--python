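"""Shared fixtures: hand-built toy histories and small seeded simulations."""

from __future__ import annotations

import numpy as np
import pytest

from dualfrailty.event_history import (
    CompanyRecord,
    EventHistory,
    ExogenousSeries,
    OwnershipSpell,
    VesselRecord,
)
from dualfrailty.hazard_model import FrailtyState, RegressionParams
from dualfrailty.simulator import SimConfig, simulate


@pytest.fixture
def toy_history() -> EventHistory:
    """3 companies, 2 vessels, one sale of v1 at age 60 (c1 -> c2)."""
    comps = tuple(CompanyRecord(f"c{i + 1}", covariates=[0.0]) for i in range(3))
    v1 = VesselRecord(
        "v1", 0.0, [0.0],
        (
            OwnershipSpell("c1", 0.0, 60.0, "sale", "c2"),
            OwnershipSpell("c2", 60.0, 120.0, "censor"),
        ),
    )
    v2 = VesselRecord("v2", 0.0, [0.0], (OwnershipSpell("c2", 0.0, 120.0, "censor"),))
    return EventHistory(companies=comps, vessels=(v1, v2))


@pytest.fixture
def two_sale_history() -> EventHistory:
    """Vessel with sales at ages 60 and 120, censored at 180."""
    comps = tuple(CompanyRecord(f"c{i + 1}", covariates=[0.0]) for i in range(3))
    v = VesselRecord(
        "v1", 0.0, [0.0],
        (
            OwnershipSpell("c1", 0.0, 60.0, "sale", "c2"),
            OwnershipSpell("c2", 60.0, 120.0, "sale", "c3"),
            OwnershipSpell("c3", 120.0, 180.0, "censor"),
        ),
    )
    return EventHistory(companies=comps, vessels=(v,))


@pytest.fixture
def small_sim() -> EventHistory:
    """Small simulated history with sales and scrap events."""
    cfg = SimConfig(
        n_companies=8, n_vessels=12, horizon=80, baseline_per_pair=3e-3,
        xi=0.3, scrap_baseline=2e-3, theta_V=(0.2, 0.01), theta_S=(0.1, -0.1),
        seed=21,
    )
    return simulate(cfg)


@pytest.fixture
def small_params() -> RegressionParams:
    return RegressionParams(
        beta_V=(0.25, -0.01), beta_S=(0.3, -0.1), beta_B=(-0.15, 0.05),
        theta_V=(0.2, 0.01), theta_S=(0.1, -0.1),
    )


@pytest.fixture
def small_frailty(small_sim) -> FrailtyState:
    rng = np.random.default_rng(2)
    return FrailtyState(Z=rng.gamma(5.0, 0.2, size=small_sim.n_companies), xi=0.2)


@pytest.fixture
def messy_sim() -> EventHistory:
    """Staggered deliveries, activity windows, exogenous series, scrap."""
    N = 6
    win = np.column_stack([np.zeros(N), np.full(N, 200.0)])
    win[3] = (0.0, 60.0)
    win[5] = (20.0, 200.0)
    exo = ExogenousSeries(
        breakpoints=np.arange(0, 201, 25.0), values=np.sin(np.arange(9))[:, None]
    )
    cfg = SimConfig(
        n_companies=N, n_vessels=8, horizon=150, baseline_per_pair=4e-3,
        xi=0.3, seed=31, delivery_spread=40.0, activity_windows=win,
        beta_E=(0.3,), exogenous=exo, scrap_baseline=1e-3,
        theta_V=(0.1, 0.0), theta_S=(0.2, -0.1), theta_E=(0.1,),
    )
    return simulate(cfg)


@pytest.fixture
def messy_params() -> RegressionParams:
    return RegressionParams(
        beta_V=(0.3, -0.01), beta_S=(0.4, -0.2), beta_B=(-0.2, 0.1), beta_E=(0.3,),
        theta_V=(0.1, 0.0), theta_S=(0.2, -0.1), theta_E=(0.1,),
    )
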
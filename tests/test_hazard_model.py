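"""Relative risks, likelihoods, Breslow baselines and the no-frailty fitter."""

import numpy as np
import pytest

from dualfrailty._risk import RiskStructure
from dualfrailty.event_history import (
    CompanyRecord,
    EventHistory,
    EventHistoryError,
    OwnershipSpell,
    VesselRecord,
    risk_set,
)
from dualfrailty.frailty_mcmc import gibbs_stats
from dualfrailty.hazard_model import (
    BaselineIncrements,
    FrailtyState,
    RegressionParams,
    breslow_sale,
    breslow_scrap,
    cumulative_intensities,
    fit_no_frailty,
    full_loglik,
    partial_loglik_sale,
    partial_loglik_scrap,
    relative_risk_sale,
    relative_risk_scrap,
    sale_intensity_total,
)
from dualfrailty.simulator import SimConfig, simulate


def _history(companies, vessels):
    return EventHistory(companies=tuple(companies), vessels=tuple(vessels))


@pytest.fixture
def exponent_fixture():
    """Covariate pattern for the hand-summed relative-risk exponent."""
    comps = (
        CompanyRecord("c1", [1.0, 0.0]),
        CompanyRecord("c2", [0.0, 1.0]),
    )
    v = VesselRecord(
        "v1", 0.0, [1.0, 10.0], (OwnershipSpell("c1", 0.0, 100.0, "censor"),)
    )
    return _history(comps, [v])


class TestRelativeRisk:
    def test_zero_coefficients_give_one(self, exponent_fixture):
        params = RegressionParams.zeros(2, 2)
        assert relative_risk_sale(exponent_fixture, "v1", 30.0, "c2", params) == 1.0
        assert relative_risk_scrap(exponent_fixture, "v1", 30.0, params) == 1.0

    def test_hand_summed_exponent(self, exponent_fixture):
        # bV.(1,10) = 0.3 - 0.1, bS.(1,0) = 0.4, bB.(0,1) = 0.1 -> exp(0.7)
        params = RegressionParams(
            beta_V=(0.3, -0.01), beta_S=(0.4, -0.2), beta_B=(-0.2, 0.1)
        )
        assert relative_risk_sale(
            exponent_fixture, "v1", 30.0, "c2", params
        ) == pytest.approx(np.exp(0.7))

    def test_hand_summed_scrap_exponent(self, exponent_fixture):
        params = RegressionParams(
            beta_V=(0.0, 0.0), beta_S=(0.0, 0.0), beta_B=(0.0, 0.0),
            theta_V=(0.2, 0.01), theta_S=(0.1, -0.3),
        )
        # tV.(1,10) = 0.3, tS.(1,0) = 0.1
        assert relative_risk_scrap(
            exponent_fixture, "v1", 30.0, params
        ) == pytest.approx(np.exp(0.4))

    def test_covariate_shift_is_multiplicative(self):
        comps = (CompanyRecord("c1", [1.0, 0.0]), CompanyRecord("c2", [0.0, 1.0]))
        params = RegressionParams(
            beta_V=(0.3, -0.01), beta_S=(0.4, -0.2), beta_B=(-0.2, 0.1)
        )
        delta = 2.5
        vals = []
        for x2 in (10.0, 10.0 + delta):
            v = VesselRecord(
                "v1", 0.0, [1.0, x2], (OwnershipSpell("c1", 0.0, 100.0, "censor"),)
            )
            vals.append(
                relative_risk_sale(_history(comps, [v]), "v1", 30.0, "c2", params)
            )
        assert vals[1] / vals[0] == pytest.approx(np.exp(-0.01 * delta))

    def test_buyer_equal_owner_rejected(self, exponent_fixture):
        with pytest.raises(EventHistoryError):
            relative_risk_sale(
                exponent_fixture, "v1", 30.0, "c1", RegressionParams.zeros(2, 2)
            )


class TestSaleIntensity:
    def test_unit_frailty_counts_buyers(self, toy_history):
        params = RegressionParams.zeros(1, 1)
        # 2 active non-owner buyers, a0 = 1e-5
        assert sale_intensity_total(
            toy_history, "v1", 30.0, params, None, 1e-5
        ) == pytest.approx(2e-5)

    def test_frailty_scaling_identities(self, toy_history):
        params = RegressionParams.zeros(1, 1)
        Z = np.array([2.0, 1.0, 1.0])
        base = sale_intensity_total(
            toy_history, "v1", 30.0, params, FrailtyState(Z=Z, xi=1.0), 1.0
        )
        assert base == pytest.approx(4.0)  # 2 * (1/1 + 1/1)
        doubled = sale_intensity_total(
            toy_history, "v1", 30.0, params,
            FrailtyState(Z=Z * np.array([2.0, 1.0, 1.0]), xi=1.0), 1.0,
        )
        assert doubled == pytest.approx(2 * base)
        rescaled = sale_intensity_total(
            toy_history, "v1", 30.0, params, FrailtyState(Z=3.0 * Z, xi=1.0), 1.0
        )
        assert rescaled == pytest.approx(base)  # Z_s / Z_b ratios unchanged

    def test_nonpositive_baseline_rejected(self, toy_history):
        with pytest.raises(ValueError):
            sale_intensity_total(
                toy_history, "v1", 30.0, RegressionParams.zeros(1, 1), None, 0.0
            )


class TestCumulativeIntensities:
    def test_zero_at_age_zero(self, toy_history):
        bl = BaselineIncrements(sale_ages=[30.0], dA0=[0.25])
        A, L = cumulative_intensities(
            toy_history, "v1", 0.0, RegressionParams.zeros(1, 1), None, bl
        )
        assert A == 0.0 and L == 0.0

    def test_single_increment_stieltjes_sum(self, toy_history):
        # one increment 0.25 at an at-risk age; non-baseline factor is the
        # buyer count 2 scaled by Z_s = 2 -> A = 0.25 * 4 = 1
        bl = BaselineIncrements(sale_ages=[30.0], dA0=[0.25])
        fr = FrailtyState(Z=np.array([2.0, 1.0, 1.0]), xi=1.0)
        A, _ = cumulative_intensities(
            toy_history, "v1", 50.0, RegressionParams.zeros(1, 1), fr, bl
        )
        assert A == pytest.approx(1.0)

    def test_nondecreasing_in_age(self, small_sim, small_params, small_frailty):
        bl = BaselineIncrements.combine(
            breslow_sale(small_sim, small_params, small_frailty),
            breslow_scrap(small_sim, small_params, small_frailty),
        )
        v = small_sim.vessels[0].vessel_id
        prev = -1.0
        for age in np.linspace(0, 80, 9):
            A, _ = cumulative_intensities(
                small_sim, v, age, small_params, small_frailty, bl
            )
            assert A >= prev
            prev = A


class TestFullLoglik:
    def test_no_events_zero_baselines_gives_zero(self):
        comps = (CompanyRecord("c1", [0.0]), CompanyRecord("c2", [0.0]))
        v = VesselRecord("v1", 0.0, [0.0], (OwnershipSpell("c1", 0.0, 50.0, "censor"),))
        h = _history(comps, [v])
        assert full_loglik(
            h, RegressionParams.zeros(1, 1), None, BaselineIncrements()
        ) == 0.0

    def test_matches_gibbs_kernel_shape(self, small_sim, small_params, small_frailty):
        # as a function of one Z_c the log likelihood is
        # M log Z - D1 Z - D2 / Z + const
        bl = BaselineIncrements.combine(
            breslow_sale(small_sim, small_params, small_frailty),
            breslow_scrap(small_sim, small_params, small_frailty),
        )
        cid = small_sim.companies[2].company_id
        st = gibbs_stats(small_sim, cid, small_params, small_frailty, bl)
        consts = []
        for zc in (0.4, 0.7, 1.0, 1.6, 2.5):
            Z = small_frailty.Z.copy()
            Z[2] = zc
            ll = full_loglik(
                small_sim, small_params, FrailtyState(Z=Z, xi=0.2), bl
            )
            consts.append(ll - (st.M * np.log(zc) - st.D1 * zc - st.D2 / zc))
        assert np.ptp(consts) < 1e-9

    def test_frailty_scale_invariance_without_scraps(self, toy_history):
        params = RegressionParams.zeros(1, 1)
        fr = FrailtyState(Z=np.array([1.3, 0.6, 2.0]), xi=0.5)
        bl = breslow_sale(toy_history, params, fr)
        ll = full_loglik(toy_history, params, fr, bl)
        for c in (0.2, 3.0):
            fr_c = FrailtyState(Z=c * fr.Z, xi=0.5)
            bl_c = breslow_sale(toy_history, params, fr_c)
            assert full_loglik(toy_history, params, fr_c, bl_c) == pytest.approx(
                ll, abs=1e-10
            )

    def test_event_age_without_increment_is_an_error(self, toy_history):
        params = RegressionParams.zeros(1, 1)
        bl = BaselineIncrements(sale_ages=[10.0], dA0=[0.5])  # no mass at age 60
        with pytest.raises(EventHistoryError, match="baseline"):
            full_loglik(toy_history, params, None, bl)


class TestBreslow:
    def test_unit_frailty_hand_fixture(self, toy_history):
        # one sale; 2 vessels at risk, 2 active non-owner buyers each
        bl = breslow_sale(toy_history, RegressionParams.zeros(1, 1))
        assert bl.dA0 == pytest.approx([0.25])

    def test_frailty_weighted_hand_fixture(self, toy_history):
        # Z = (2,1,1), owners (c1, c2): denominator 2+2+0.5+1 = 5.5
        fr = FrailtyState(Z=np.array([2.0, 1.0, 1.0]), xi=1.0)
        bl = breslow_sale(toy_history, RegressionParams.zeros(1, 1), fr)
        assert bl.dA0 == pytest.approx([2.0 / 11.0])

    def test_null_model_reduces_to_pair_count_rates(self):
        # beta = 0, Z = 1: each increment is dN / (#at-risk vessel-buyer pairs)
        h = simulate(
            SimConfig(
                n_companies=5, n_vessels=5, horizon=60, baseline_per_pair=8e-3,
                xi=0.0, seed=3,
            )
        )
        params = RegressionParams.zeros(2, 2)
        bl = breslow_sale(h, params)
        r = RiskStructure.from_history(h)
        for j, age in enumerate(bl.sale_ages):
            pairs = sum(len(b) for _, _, b in risk_set(h, age))
            assert bl.dA0[j] == pytest.approx(r.sale_dN[j] / pairs)

    def test_brute_force_enumeration_with_covariates_and_frailty(
        self, messy_sim, messy_params
    ):
        # Eq-by-enumeration: sum over risk-set pairs of Z_s Z_b^-1 R_v
        rng = np.random.default_rng(7)
        fr = FrailtyState(Z=rng.gamma(4.0, 0.25, messy_sim.n_companies), xi=0.25)
        bl = breslow_sale(messy_sim, messy_params, fr)
        Z = fr.Z
        for j, age in enumerate(bl.sale_ages):
            denom = 0.0
            for vid, owner, buyers in risk_set(messy_sim, age):
                s = messy_sim.company_index[owner]
                for bid in buyers:
                    b = messy_sim.company_index[bid]
                    denom += Z[s] / Z[b] * relative_risk_sale(
                        messy_sim, vid, age, bid, messy_params
                    )
            r = RiskStructure.from_history(messy_sim)
            assert bl.dA0[j] == pytest.approx(r.sale_dN[j] / denom, rel=1e-10)

    def test_scrap_reduces_to_nelson_aalen(self, small_sim):
        params = RegressionParams.zeros(2, 2)
        bl = breslow_scrap(small_sim, params)
        for j, age in enumerate(bl.scrap_ages):
            n_at_risk = len(risk_set(small_sim, age))
            r = RiskStructure.from_history(small_sim)
            assert bl.dL0[j] == pytest.approx(r.scrap_dN[j] / n_at_risk)

    def test_ties_aggregate_in_numerator(self):
        # two sales at the same age enter one increment with dN = 2
        comps = tuple(CompanyRecord(f"c{i + 1}", [0.0]) for i in range(4))
        mk = lambda vid, o, b: VesselRecord(
            vid, 0.0, [0.0],
            (
                OwnershipSpell(o, 0.0, 40.0, "sale", b),
                OwnershipSpell(b, 40.0, 80.0, "censor"),
            ),
        )
        h = _history(comps, [mk("v1", "c1", "c2"), mk("v2", "c3", "c4")])
        bl = breslow_sale(h, RegressionParams.zeros(1, 1))
        assert bl.sale_ages.size == 1
        # denominator: 2 vessels x 3 non-owner buyers
        assert bl.dA0 == pytest.approx([2.0 / 6.0])


class TestPartialLoglik:
    def test_hand_value_single_sale(self, toy_history):
        assert partial_loglik_sale(
            toy_history, RegressionParams.zeros(1, 1)
        ) == pytest.approx(np.log(0.25))

    def test_invariant_to_frailty_rescaling(self, small_sim, small_params):
        rng = np.random.default_rng(0)
        Z = rng.gamma(5.0, 0.2, small_sim.n_companies)
        v1 = partial_loglik_sale(
            small_sim, small_params, FrailtyState(Z=Z, xi=0.2)
        )
        v2 = partial_loglik_sale(
            small_sim, small_params, FrailtyState(Z=4.2 * Z, xi=0.2)
        )
        assert v1 == pytest.approx(v2, abs=1e-9)

    def test_profile_identity_with_full_loglik(
        self, small_sim, small_params, small_frailty
    ):
        # full log likelihood at Breslow plug-in baselines equals the partial
        # log likelihood plus a coefficient-free constant, so both are
        # maximised at the same coefficients
        r = RiskStructure.from_history(small_sim)
        const = (
            float((r.sale_dN * np.log(r.sale_dN)).sum()) - r.n_sales
            + float((r.scrap_dN * np.log(r.scrap_dN)).sum()) - r.n_scraps
        )
        for shift in (-0.2, 0.0, 0.3):
            p = small_params.with_sale_flat(
                small_params.sale_flat() + np.array([shift, 0, 0, 0, 0, 0.0])
            )
            bl = BaselineIncrements.combine(
                breslow_sale(small_sim, p, small_frailty),
                breslow_scrap(small_sim, p, small_frailty),
            )
            lhs = full_loglik(small_sim, p, small_frailty, bl)
            rhs = (
                partial_loglik_sale(small_sim, p, small_frailty)
                + partial_loglik_scrap(small_sim, p, small_frailty)
                + const
            )
            assert lhs == pytest.approx(rhs, abs=1e-6)

    def test_scrap_three_subject_cox_toy(self):
        # classic Cox toy: scraps at ages 10 (x=1) and 20 (x=0), third
        # subject censored at 30; theta scalar
        comps = (CompanyRecord("c1", [0.0]),)
        mk = lambda vid, x, end, kind: VesselRecord(
            vid, 0.0, [x], (OwnershipSpell("c1", 0.0, end, kind),)
        )
        h = _history(
            comps, [mk("v1", 1.0, 10.0, "scrap"), mk("v2", 0.0, 20.0, "scrap"),
                    mk("v3", 0.5, 30.0, "censor")]
        )
        th = 0.7
        params = RegressionParams(
            beta_V=(0.0,), beta_S=(0.0,), beta_B=(0.0,),
            theta_V=(th,), theta_S=(0.0,),
        )
        expect = (
            th * 1.0 - np.log(np.exp(th) + 1.0 + np.exp(0.5 * th))
            + th * 0.0 - np.log(1.0 + np.exp(0.5 * th))
        )
        # scrap partial likelihood needs no sale events
        val = partial_loglik_scrap(h, params)
        assert val == pytest.approx(expect)

    def test_null_scrap_model_counts_risk_sets(self, small_sim):
        params = RegressionParams.zeros(2, 2)
        val = partial_loglik_scrap(small_sim, params)
        r = RiskStructure.from_history(small_sim)
        expect = 0.0
        for j, age in enumerate(r.scrap_ages):
            expect += r.scrap_dN[j] * -np.log(len(risk_set(small_sim, age)))
        assert val == pytest.approx(expect)

    def test_gradient_matches_finite_differences(
        self, small_sim, small_params, small_frailty
    ):
        val, grad, info = partial_loglik_sale(
            small_sim, small_params, small_frailty, derivatives=True
        )
        flat = small_params.sale_flat()
        for i in range(flat.size):
            e = np.zeros_like(flat)
            e[i] = 1e-6
            num = (
                partial_loglik_sale(
                    small_sim, small_params.with_sale_flat(flat + e), small_frailty
                )
                - partial_loglik_sale(
                    small_sim, small_params.with_sale_flat(flat - e), small_frailty
                )
            ) / 2e-6
            assert grad[i] == pytest.approx(num, abs=1e-5)
        assert np.all(np.linalg.eigvalsh(info) > 0)


class TestNoFrailtyFit:
    def test_recovers_truth_without_frailty(self):
        # xi = 0 data: estimates should sit within ~3 SE of the truth
        truth = np.array([0.3, -0.01, 0.4, -0.2, -0.2, 0.1])
        h = simulate(
            SimConfig(
                n_companies=60, n_vessels=150, horizon=300,
                baseline_per_pair=3e-4, xi=0.0, seed=11,
            )
        )
        fit = fit_no_frailty(h, which="sale")
        assert fit.sale_converged
        z = (fit.params.sale_flat() - truth) / fit.sale_se
        assert np.all(np.abs(z) < 3.5)

    def test_relabelling_companies_leaves_fit_unchanged(self, small_sim):
        fit1 = fit_no_frailty(small_sim, which="sale")
        order = np.random.default_rng(1).permutation(small_sim.n_companies)
        comps = tuple(small_sim.companies[i] for i in order)
        h2 = EventHistory(
            companies=comps, vessels=small_sim.vessels, exogenous=small_sim.exogenous
        )
        fit2 = fit_no_frailty(h2, which="sale")
        assert fit1.params.sale_flat() == pytest.approx(
            fit2.params.sale_flat(), abs=1e-8
        )

    def test_fit_table_layout(self, small_sim):
        fit = fit_no_frailty(small_sim, which="both")
        df = fit.to_frame()
        assert {"parameter", "estimate", "se", "wald"} <= set(df.columns)
        assert df.attrs["loglik_sale"] == pytest.approx(fit.loglik_sale)
        assert (df["se"] > 0).all()

    def test_no_events_raises(self):
        comps = (CompanyRecord("c1", [0.0]), CompanyRecord("c2", [0.0]))
        v = VesselRecord("v1", 0.0, [0.0], (OwnershipSpell("c1", 0.0, 50.0, "censor"),))
        with pytest.raises(EventHistoryError, match="no sale events"):
            fit_no_frailty(_history(comps, [v]), which="sale")


def test_baseline_plot_at_covariate_profile(small_sim, small_params, small_frailty):
    # curves rescaled by the relative risk at a chosen covariate profile
    import matplotlib

    matplotlib.use("Agg")
    from dualfrailty.hazard_model import plot_cumulative_baselines

    bl = BaselineIncrements.combine(
        breslow_sale(small_sim, small_params, small_frailty),
        breslow_scrap(small_sim, small_params, small_frailty),
    )
    ax = plot_cumulative_baselines(
        bl, small_params,
        covariates={"x_V": [1.0, 0.0], "x_S": [0.0, 1.0], "x_B": [0.0, 0.0]},
    )
    lines = ax.get_lines()
    assert len(lines) == 2
    scale = np.exp(
        small_params.beta_V @ np.array([1.0, 0.0])
        + small_params.beta_S @ np.array([0.0, 1.0])
    )
    assert lines[0].get_ydata()[-1] == pytest.approx(np.cumsum(bl.dA0)[-1] * scale)
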
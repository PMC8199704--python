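"""OED models, excess-risk formula, LAR combination, coefficient registry."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import uniform_dvh
from secr.dvh import DVH, mean_dose
from secr.errors import InvalidInputError, SchemaError
from secr.risk import (
    BaselineRates,
    LARConfig,
    LifeTable,
    OEDModelParams,
    RiskCoefficients,
    RiskQuery,
    cumulative_baseline,
    e_star,
    excess_risk,
    lar,
    load_risk_coefficients,
    oed,
    oed_relative_difference,
)


def coeffs(model="ERR", beta=1.0, gamma=0.0, eta=0.0, sex="male", site="colon"):
    return RiskCoefficients(site=site, sex=sex, model=model, beta=beta, gamma=gamma, eta=eta)


def flat_life_table(a_max=90):
    return LifeTable(np.ones(a_max + 1))


class TestOed:
    def test_uniform_dose_plateau_closed_form(self):
        d = uniform_dvh(2.0, bin_width=0.01)
        value = oed(d, OEDModelParams("plateau", delta=0.5))
        assert value == pytest.approx((1 - math.exp(-1.0)) / 0.5, rel=1e-12)
        assert value == pytest.approx(1.26424, abs=1e-5)

    def test_two_bin_plateau_hand_sum(self):
        d = DVH(
            organ="x",
            bin_width=0.01,
            edges=np.array([0.995, 1.005, 4.995, 5.005]),
            volumes=np.array([1.0, 0.0, 3.0]),
        )
        # (1/4) [1 (1-e^-0.2)/0.2 + 3 (1-e^-1)/0.2]
        assert oed(d, OEDModelParams("plateau", delta=0.2)) == pytest.approx(2.59704, abs=1e-5)

    def test_linear_model_is_mean_dose(self):
        d = uniform_dvh(3.0)
        assert oed(d, OEDModelParams("linear")) == pytest.approx(mean_dose(d))

    def test_plateau_tends_to_mean_dose_as_delta_vanishes(self):
        d = DVH(
            organ="x",
            bin_width=1.0,
            edges=np.arange(0.0, 11.0),
            volumes=np.linspace(1, 3, 10),
        )
        assert oed(d, OEDModelParams("plateau", delta=1e-9)) == pytest.approx(
            mean_dose(d), abs=1e-6
        )

    def test_bell_model_standard_form(self):
        d = uniform_dvh(2.0, bin_width=0.01)
        assert oed(d, OEDModelParams("bell", alpha=0.25)) == pytest.approx(
            2.0 * math.exp(-0.5), rel=1e-12
        )

    @given(
        st.lists(st.floats(0.0, 60.0), min_size=1, max_size=30),
        st.floats(0.01, 2.0),
    )
    def test_plateau_bounded_by_mean_and_max(self, doses, delta):
        edges = np.arange(len(doses) + 1, dtype=float) * 2.0
        d = DVH(organ="p", bin_width=2.0, edges=edges, volumes=np.array(doses) + 0.1)
        plateau = oed(d, OEDModelParams("plateau", delta=delta))
        assert plateau <= mean_dose(d) + 1e-9
        assert mean_dose(d) <= d.centers[-1] + 1e-9

    def test_invalid_params_rejected(self):
        with pytest.raises(InvalidInputError):
            OEDModelParams("plateau", delta=0.0)
        with pytest.raises(InvalidInputError):
            OEDModelParams("bell")
        with pytest.raises(InvalidInputError):
            OEDModelParams("sigmoid")


class TestEStar:
    @pytest.mark.parametrize("e,expected", [(20, -1.0), (30, 0.0), (45, 0.0), (0, -3.0)])
    def test_piecewise_values(self, e, expected):
        assert e_star(e) == pytest.approx(expected)

    def test_negative_age_rejected(self):
        with pytest.raises(InvalidInputError):
            e_star(-1)


class TestExcessRisk:
    def test_reference_age_dose_one(self):
        for eta in (-1.4, 0.0, 2.8):
            value = excess_risk(1.0, coeffs(eta=eta), RiskQuery("male", 30, 60))
            assert value == pytest.approx(1.0)

    def test_zero_dose_zero_risk(self):
        assert excess_risk(0.0, coeffs(beta=2.0, eta=-1.4), RiskQuery("male", 40, 70)) == 0.0

    def test_hand_evaluation_young_exposure(self):
        # beta 0.5, D 2, gamma -0.3, e 20 (e* = -1), a 90, eta 2
        value = excess_risk(
            2.0, coeffs(beta=0.5, gamma=-0.3, eta=2.0), RiskQuery("male", 20, 90)
        )
        assert value == pytest.approx(math.exp(0.3) * 2.25, rel=1e-12)
        assert value == pytest.approx(3.03718, abs=1e-5)

    @given(st.floats(0.0, 10.0), st.floats(0.0, 10.0), st.floats(0.1, 3.0))
    def test_linear_in_dose_and_beta(self, dose, beta, scale):
        q = RiskQuery("female", 35, 70)
        base = excess_risk(dose, coeffs(beta=beta, eta=-1.4), q)
        assert excess_risk(scale * dose, coeffs(beta=beta, eta=-1.4), q) == pytest.approx(
            scale * base, rel=1e-9, abs=1e-12
        )
        assert excess_risk(dose, coeffs(beta=scale * beta, eta=-1.4), q) == pytest.approx(
            scale * base, rel=1e-9, abs=1e-12
        )

    def test_attained_age_zero_with_negative_power_rejected(self):
        with pytest.raises(InvalidInputError):
            excess_risk(1.0, coeffs(eta=-1.4), RiskQuery("male", 0, 0))


class TestLar:
    def test_geometric_mean_identity(self):
        # single-year horizon contrived so A = B = 8
        lt = flat_life_table()
        baseline = BaselineRates(np.full(91, 8.0))
        err_c = coeffs("ERR", beta=1.0)  # ERR term = 1, x lambda = 8
        ear_c = coeffs("EAR", beta=0.8)  # EAR term = 0.8, x10 = 8
        res = lar(1.0, err_c, ear_c, baseline, lt, "male", 90)
        assert res.err_lifetime_sum == pytest.approx(8.0)
        assert res.ear_lifetime_sum == pytest.approx(8.0)
        assert res.lar_per_100k == pytest.approx(8.0)

    def test_single_term_weighted_product(self):
        # e = a_max: A = 4, B = 2 -> 4^0.7 2^0.3 = 2^1.7 = 3.2490096
        lt = flat_life_table()
        baseline = BaselineRates(np.full(91, 4.0))
        res = lar(1.0, coeffs("ERR", beta=1.0), coeffs("EAR", beta=0.2), baseline, lt, "male", 90)
        assert res.lar_per_100k == pytest.approx(2.0**1.7, rel=1e-12)

    def test_percent_is_per_100k_over_1000(self):
        lt = flat_life_table()
        baseline = BaselineRates(np.full(91, 10.0))
        res = lar(2.0, coeffs("ERR", beta=0.5), coeffs("EAR", beta=1.0), baseline, lt, "male", 50)
        assert res.lar_per_100k == pytest.approx(1000.0 * res.lar_percent, rel=1e-15)

    def test_zero_branch_gives_zero(self):
        lt = flat_life_table()
        baseline = BaselineRates(np.zeros(91))  # A = 0
        res = lar(1.0, coeffs("ERR"), coeffs("EAR", beta=1.0), baseline, lt, "male", 40)
        assert res.lar_per_100k == 0.0

    def test_homogeneity_in_dose(self):
        # ERR and EAR are both linear in D, so LAR(cD) = c LAR(D)
        lt = flat_life_table()
        baseline = BaselineRates(np.full(91, 25.0))
        args = (coeffs("ERR", beta=0.6, eta=-1.4), coeffs("EAR", beta=3.0, eta=2.8), baseline, lt, "male", 40)
        base = lar(1.0, *args)
        scaled = lar(3.0, *args)
        assert scaled.lar_per_100k == pytest.approx(3.0 * base.lar_per_100k, rel=1e-12)

    def test_nonincreasing_in_exposure_age(self):
        # S == 1, constant baseline, age-flat coefficients: fewer summed
        # years as e grows, so LAR must not increase from e = 30..80
        lt = flat_life_table()
        baseline = BaselineRates(np.full(91, 50.0))
        values = [
            lar(1.0, coeffs("ERR"), coeffs("EAR", beta=1.0), baseline, lt, "male", e).lar_per_100k
            for e in range(30, 81)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(values, values[1:]))

    def test_arithmetic_variant_switch(self):
        lt = flat_life_table()
        baseline = BaselineRates(np.full(91, 4.0))
        cfg = LARConfig(combine="arithmetic")
        res = lar(1.0, coeffs("ERR"), coeffs("EAR", beta=0.2), baseline, lt, "male", 90, cfg)
        assert res.lar_per_100k == pytest.approx(0.7 * 4.0 + 0.3 * 2.0)

    def test_latency_shortens_sum(self):
        lt = flat_life_table()
        baseline = BaselineRates(np.full(91, 1.0))
        cfg = LARConfig(latency=5)
        res = lar(1.0, coeffs("ERR"), coeffs("EAR", beta=1.0), baseline, lt, "male", 80, cfg)
        assert res.ages[0] == 85
        assert res.err_lifetime_sum == pytest.approx(6.0)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(InvalidInputError):
            LARConfig(w_err=0.8, w_ear=0.3)


class TestCumulativeBaseline:
    def test_zero_rates_give_zero(self):
        assert cumulative_baseline(BaselineRates(np.zeros(91)), flat_life_table(), 30) == 0.0

    def test_inclusive_year_counting(self):
        # constant lambda, S == 1, e = 88, horizon 90 -> ages 88, 89, 90
        lam = BaselineRates(np.full(91, 7.0))
        assert cumulative_baseline(lam, flat_life_table(), 88) == pytest.approx(21.0)

    def test_age_proportional_rates(self):
        # lambda(a) = a, e = 89 -> 89 + 90 = 179
        lam = BaselineRates(np.arange(91, dtype=float))
        assert cumulative_baseline(lam, flat_life_table(), 89) == pytest.approx(179.0)

    def test_survival_weighting(self):
        s = np.ones(91)
        s[90] = 0.5
        lam = BaselineRates(np.full(91, 10.0))
        assert cumulative_baseline(lam, LifeTable(s), 89) == pytest.approx(10.0 + 5.0)


class TestOedRelativeDifference:
    def test_printed_kidney_pair(self):
        assert oed_relative_difference(1.7, 1.5) == pytest.approx(13.333, abs=1e-3)

    def test_equal_inputs(self):
        assert oed_relative_difference(2.0, 2.0) == 0.0

    def test_signed(self):
        assert oed_relative_difference(2.0, 4.0) == pytest.approx(-50.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(InvalidInputError):
            oed_relative_difference(1.0, 0.0)


class TestRegistry:
    def test_known_site_row(self):
        reg = load_risk_coefficients()
        row = reg.get("colon", "male", "ERR")
        assert (row.beta, row.gamma, row.eta) == (0.63, -0.3, -1.4)

    def test_unknown_site_falls_back_with_warning(self):
        reg = load_risk_coefficients()
        with pytest.warns(UserWarning, match="falling back"):
            row = reg.get("esophagus", "female", "EAR")
        assert row.site == "other"

    def test_round_trip_is_identity(self, tmp_path):
        reg = load_risk_coefficients()
        p = tmp_path / "coeffs.csv"
        reg.to_csv(p)
        back = load_risk_coefficients(p)
        assert len(back) == len(reg)
        assert back.get("lung", "female", "EAR") == reg.get("lung", "female", "EAR")

    def test_malformed_csv_reports_rows(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("site,sex,model,beta,gamma,eta\ncolon,male,ERR,-1,0,0\n")
        with pytest.raises(SchemaError, match="indices"):
            load_risk_coefficients(p)


class TestLifeTableAndRates:
    def test_life_table_invariants_enforced(self):
        with pytest.raises(InvalidInputError):
            LifeTable(np.array([0.9, 0.8]))  # S(0) != 1
        with pytest.raises(InvalidInputError):
            LifeTable(np.array([1.0, 0.5, 0.6]))  # increasing
        with pytest.raises(InvalidInputError):
            LifeTable(np.array([1.0, 0.0]))  # hits zero

    def test_life_table_csv_round_trip(self, tmp_path):
        lt = LifeTable(np.linspace(1.0, 0.2, 91))
        p = tmp_path / "lt.csv"
        lt.to_csv(p)
        np.testing.assert_allclose(LifeTable.from_csv(p).survival, lt.survival)

    def test_baseline_csv_round_trip(self, tmp_path):
        rates = BaselineRates(np.linspace(0, 500, 91))
        p = tmp_path / "b.csv"
        rates.to_csv(p)
        np.testing.assert_allclose(BaselineRates.from_csv(p).rates, rates.rates)

    def test_negative_rates_rejected(self):
        with pytest.raises(InvalidInputError):
            BaselineRates(np.array([1.0, -1.0]))
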
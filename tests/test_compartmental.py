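import math

import numpy as np
import pytest
from scipy import integrate

import pk2dose as pk
from pk2dose.compartmental import (
    ErrorModel,
    OneCmtParams,
    PopulationSummary,
    TwoCmtParams,
    auc_ca,
    conc_1cmt,
    conc_2cmt,
    fit_subject,
    rmse_percent,
    two_stage_population,
    vpc,
)
from pk2dose.core import InvalidInputError, TimeActivityCurve
from conftest import zero_noise_config


def ode_conc_1cmt(t_eval, p, dose):
    """Independent oracle: integrate the depot/organ two-state linear system."""

    def rhs(_, y):
        depot, amount = y
        return [-p.ka * depot, p.ka * depot - p.ke * amount]

    sol = integrate.solve_ivp(
        rhs, (0, max(t_eval)), [dose, 0.0], t_eval=t_eval, rtol=1e-11, atol=1e-12
    )
    return sol.y[1] / p.v


def ode_state_2cmt(t_eval, p, dose):
    k10, k12, k21 = p.micro_rates

    def rhs(_, y):
        central, periph = y
        return [
            -(k10 + k12) * central + k21 * periph,
            k12 * central - k21 * periph,
        ]

    sol = integrate.solve_ivp(
        rhs, (0, max(t_eval)), [dose, 0.0], t_eval=t_eval, rtol=1e-11, atol=1e-12
    )
    return sol.y


class TestConc1Cmt:
    def test_zero_at_time_zero(self):
        p = OneCmtParams(ka=0.3, ke=0.02, v=10.0)
        assert conc_1cmt(0.0, p, 100.0) == 0.0

    def test_equal_rates_analytic_limit(self):
        p = OneCmtParams(ka=0.1, ke=0.1, v=1.0)
        assert conc_1cmt(10.0, p, 1.0) == pytest.approx(math.exp(-1), rel=1e-12)

    @pytest.mark.parametrize(
        "p",
        [
            OneCmtParams(0.3, 0.02, 30.0),
            OneCmtParams(0.05, 0.002, 7.5),
            OneCmtParams(1.5, 0.5, 2.0),
        ],
    )
    def test_matches_ode_oracle(self, p):
        t = np.linspace(0.1, 300, 40)
        ours = conc_1cmt(t, p, 742.3)
        oracle = ode_conc_1cmt(t, p, 742.3)
        assert np.max(np.abs(ours - oracle) / np.max(oracle)) < 1e-6

    def test_rejects_nonpositive_parameters(self):
        with pytest.raises(InvalidInputError):
            OneCmtParams(ka=0.0, ke=0.1, v=1.0)


class TestConc2Cmt:
    def test_initial_concentration_is_dose_over_v1(self):
        p = pk.DEFAULT_BLOOD_PARAMS
        assert conc_2cmt(0.0, p, 742.3) == pytest.approx(742.3 / p.v1)

    def test_q_zero_collapses_to_bolus_monoexponential(self):
        p = TwoCmtParams(cl=0.1, v1=2.0, v2=1.0, q=0.0)
        t = np.linspace(0, 100, 20)
        expected = 742.3 / 2.0 * np.exp(-(0.1 / 2.0) * t)
        np.testing.assert_allclose(conc_2cmt(t, p, 742.3), expected, rtol=1e-12)

    def test_matches_ode_oracle(self):
        p = pk.DEFAULT_BLOOD_PARAMS
        t = np.linspace(0.1, 300, 40)
        oracle = ode_state_2cmt(t, p, 742.3)[0] / p.v1
        ours = conc_2cmt(t, p, 742.3)
        assert np.max(np.abs(ours - oracle) / np.max(oracle)) < 1e-6

    def test_mass_balance_against_ode_oracle(self):
        p = pk.DEFAULT_BLOOD_PARAMS
        dose = 742.3
        t = np.linspace(0.5, 300, 30)
        central, periph = ode_state_2cmt(t, p, dose)
        eliminated = dose - central - periph
        ours = conc_2cmt(t, p, dose) * p.v1
        np.testing.assert_allclose(ours + periph + eliminated, dose, rtol=1e-6)

    def test_nonnegative_and_vanishing(self):
        p = pk.DEFAULT_BLOOD_PARAMS
        t = np.linspace(0, 5000, 200)
        c = conc_2cmt(t, p, 742.3)
        assert np.all(c >= 0)
        assert c[-1] < 1e-6 * c[0]


class TestAucCa:
    def test_one_compartment_infinity(self):
        p = OneCmtParams(ka=0.5, ke=0.1, v=10.0)
        assert auc_ca(p, 100.0) == pytest.approx(100.0)

    def test_tail_additivity(self):
        p = OneCmtParams(ka=0.5, ke=0.1, v=10.0)
        total = auc_ca(p, 100.0)
        head = auc_ca(p, 100.0, 168.0)
        tail = integrate.quad(lambda t: conc_1cmt(t, p, 100.0), 168, np.inf)[0]
        assert head + tail == pytest.approx(total, rel=1e-8)

    @pytest.mark.parametrize(
        "p",
        [
            OneCmtParams(0.3, 0.01, 29.6),
            OneCmtParams(0.1, 0.1, 5.0),
            pk.DEFAULT_BLOOD_PARAMS,
            TwoCmtParams(cl=0.2, v1=3.0, v2=5.0, q=0.05),
        ],
    )
    def test_matches_adaptive_quadrature(self, p):
        dose = 742.3
        fn = conc_1cmt if isinstance(p, OneCmtParams) else conc_2cmt
        quad, _ = integrate.quad(lambda t: fn(t, p, dose), 0, 168.0, limit=200)
        assert auc_ca(p, dose, 168.0) == pytest.approx(quad, rel=1e-8)


class TestFitSubject:
    def test_recovers_truth_from_noiseless_paper_schedule(self, zero_noise_cohort):
        tac = zero_noise_cohort.curve("h01", "liver")
        dose = zero_noise_cohort.subjects["h01"].injected_kBq
        fit = fit_subject(tac, "1cmt", "constant", dose, n_starts=3, seed=1)
        truth = pk.DEFAULT_ORGAN_PARAMS["liver"]
        assert fit.converged
        for name in truth.names:
            assert getattr(fit.params, name) == pytest.approx(
                getattr(truth, name), rel=1e-3
            )

    def test_two_compartment_noiseless_recovery(self, zero_noise_cohort):
        tac = zero_noise_cohort.curve("h01", "blood")
        dose = zero_noise_cohort.subjects["h01"].injected_kBq
        fit = fit_subject(tac, "2cmt", "constant", dose, n_starts=3, seed=1)
        truth = pk.DEFAULT_BLOOD_PARAMS
        assert fit.converged
        for name in truth.names:
            assert getattr(fit.params, name) == pytest.approx(
                getattr(truth, name), rel=1e-3
            )

    def test_under_determined_rejected(self):
        tac = TimeActivityCurve("s", "blood", (1.0, 3.0), (300.0, 200.0))
        with pytest.raises(InvalidInputError, match="under-determined"):
            fit_subject(tac, "2cmt", "constant", 742.3)

    def test_error_model_selection_direction(self):
        # multiplicative noise: the proportional error model must beat the
        # constant one in likelihood on the same data
        cfg = zero_noise_config(
            n_subjects=1,
            error=ErrorModel("proportional", a=0.0, b=0.15),
            seed=11,
        )
        cohort = pk.simulate_cohort(cfg)
        tac = cohort.curve("h01", "blood")
        dose = cohort.subjects["h01"].injected_kBq
        fit_prop = fit_subject(tac, "2cmt", "proportional", dose, n_starts=5, seed=2)
        fit_const = fit_subject(tac, "2cmt", "constant", dose, n_starts=5, seed=2)
        assert fit_prop.objective < fit_const.objective

    def test_rse_reported_for_noisy_fit(self):
        cfg = zero_noise_config(
            n_subjects=1, error=ErrorModel("proportional", a=0.0, b=0.1), seed=5
        )
        cohort = pk.simulate_cohort(cfg)
        fit = fit_subject(
            cohort.curve("h01", "liver"),
            "1cmt",
            "proportional",
            cohort.subjects["h01"].injected_kBq,
            n_starts=3,
            seed=3,
        )
        assert fit.converged
        assert set(fit.rse_percent) == {"ka", "ke", "v"}
        assert all(0 < v < 100 for v in fit.rse_percent.values())


class TestTwoStagePopulation:
    def test_needs_two_converged_fits(self):
        with pytest.raises(InvalidInputError):
            two_stage_population([], model="1cmt")

    def test_zero_spread_gives_zero_iiv(self, zero_noise_cohort):
        fits = []
        for sid in ("h01", "h02", "h03"):
            fits.append(
                fit_subject(
                    zero_noise_cohort.curve(sid, "liver"),
                    "1cmt",
                    "constant",
                    zero_noise_cohort.subjects[sid].injected_kBq,
                    n_starts=2,
                    seed=4,
                )
            )
        pop = two_stage_population(fits, model="1cmt")
        truth = pk.DEFAULT_ORGAN_PARAMS["liver"]
        for name in truth.names:
            assert pop.typical[name] == pytest.approx(getattr(truth, name), rel=1e-3)
            assert pop.iiv_cv[name] < 0.5


class TestVpc:
    def _pop(self, iiv=0.0):
        p = pk.DEFAULT_BLOOD_PARAMS
        return PopulationSummary(
            typical={n: getattr(p, n) for n in p.names},
            iiv_cv={n: iiv for n in p.names},
            n_subjects=3,
            model="2cmt",
        )

    def test_degenerate_bands_coincide_with_typical_curve(self, zero_noise_cohort):
        res = vpc(
            zero_noise_cohort,
            "blood",
            self._pop(),
            ErrorModel("constant", a=0.0),
            n_sim=100,
            seed=0,
        )
        np.testing.assert_allclose(res.p5, res.p95, rtol=1e-12)
        expected = pk.conc_2cmt(
            np.asarray(res.bins), pk.DEFAULT_BLOOD_PARAMS, 742.3
        )
        np.testing.assert_allclose(res.p50, expected, rtol=1e-12)

    def test_same_seed_reproduces_bands(self, zero_noise_cohort):
        kwargs = dict(
            cohort=zero_noise_cohort,
            region="blood",
            pop=self._pop(iiv=20.0),
            error=ErrorModel("constant", a=2.0),
            n_sim=150,
            seed=7,
        )
        a, b = vpc(**kwargs), vpc(**kwargs)
        assert a.p5 == b.p5 and a.p50 == b.p50 and a.p95 == b.p95

    def test_observations_outside_bins_rejected(self, zero_noise_cohort):
        with pytest.raises(InvalidInputError, match="outside bins"):
            vpc(
                zero_noise_cohort,
                "blood",
                self._pop(),
                ErrorModel("constant", a=1.0),
                n_sim=100,
                seed=0,
                bins=(1.0, 24.0),
            )

    def test_coverage_near_nominal_on_matched_simulation(self):
        cfg = zero_noise_config(
            n_subjects=200,
            blood_iiv_cv=20.0,
            error=ErrorModel("constant", a=2.0),
            seed=21,
        )
        cohort = pk.simulate_cohort(cfg)
        res = vpc(
            cohort,
            "blood",
            self._pop(iiv=20.0),
            ErrorModel("constant", a=2.0),
            n_sim=200,
            seed=3,
        )
        assert abs(res.observed_coverage_90 - 0.90) <= 0.05


class TestRmsePercent:
    def test_identical_vectors_zero(self):
        assert rmse_percent([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_computed_example(self):
        assert rmse_percent([110.0, 90.0], [100.0, 100.0]) == pytest.approx(10.0)

    def test_scale_invariance(self):
        a, b = np.array([120.0, 80.0, 95.0]), np.array([100.0, 90.0, 100.0])
        assert rmse_percent(3.7 * a, 3.7 * b) == pytest.approx(
            rmse_percent(a, b), rel=1e-12
        )

    def test_per_pair_normalisation_option(self):
        assert rmse_percent([110.0, 90.0], [100.0, 100.0], per_pair=True) == pytest.approx(10.0)

    @pytest.mark.parametrize("ca,nca", [([1.0], [1.0, 2.0]), ([], [])])
    def test_invalid_pairs_rejected(self, ca, nca):
        with pytest.raises(InvalidInputError):
            rmse_percent(ca, nca)
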
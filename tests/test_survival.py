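import math

import numpy as np
import pytest
from scipy import optimize

import sclc_cea as sc
from sclc_cea.survival import Family, NoMedianError

from conftest import ARM_PARAMS, loglogistic

FOUR_FAMILY_EXAMPLES = [
    sc.SurvivalParams("exponential", (0.05,)),
    sc.SurvivalParams("weibull", (0.01, 1.3)),
    sc.SurvivalParams("lognormal", (2.5, 0.8)),
    loglogistic("pembro_ep", "os"),
    loglogistic("placebo_ep", "os"),
]

MONTHS_PER_CYCLE = 21.0 / (365.25 / 12.0)


class TestSurvivalProbability:
    def test_starts_at_one_and_is_nonincreasing(self):
        t = np.linspace(0, 200, 400)
        for sp in FOUR_FAMILY_EXAMPLES:
            s = sc.survival_probability(sp, t)
            assert s[0] == pytest.approx(1.0)
            assert np.all(np.diff(s) <= 1e-15)
            assert np.all((0 <= s) & (s <= 1))

    def test_closed_form_values(self):
        sp = loglogistic("placebo_ep", "os")
        assert sc.survival_probability(sp, 0.0) == 1.0
        # the median of the placebo OS law sits at ~14.01 cycles
        assert sc.survival_probability(sp, 14.01) == pytest.approx(0.500, abs=1e-3)
        expo = sc.SurvivalParams("exponential", (0.1,))
        assert sc.survival_probability(expo, 10.0) == pytest.approx(math.exp(-1), rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            sc.survival_probability(FOUR_FAMILY_EXAMPLES[0], -0.5)


class TestMedianSurvival:
    @pytest.mark.parametrize("sp", FOUR_FAMILY_EXAMPLES, ids=lambda s: s.family.value)
    def test_agrees_with_numeric_root(self, sp):
        med = sc.median_survival(sp)
        root = optimize.brentq(lambda t: sc.survival_probability(sp, t) - 0.5, 1e-9, 1e6)
        assert med == pytest.approx(root, abs=1e-6)

    def test_trial_arm_medians_in_months(self):
        # the fitted OS laws must reproduce the reported arm medians
        placebo = sc.median_survival(loglogistic("placebo_ep", "os"))
        pembro = sc.median_survival(loglogistic("pembro_ep", "os"))
        assert placebo == pytest.approx((1 / 0.002564) ** (1 / 2.260147), rel=1e-12)
        assert round(placebo * MONTHS_PER_CYCLE, 1) == 9.7
        assert round(pembro * MONTHS_PER_CYCLE, 1) == 11.0

    def test_exponential_closed_form(self):
        assert sc.median_survival(sc.SurvivalParams("exponential", (0.2,))) == pytest.approx(
            math.log(2) / 0.2
        )

    def test_degenerate_law_has_no_median(self):
        with pytest.raises(NoMedianError):
            sc.median_survival(sc.SurvivalParams("loglogistic", (0.0, 2.0)))


class TestTransitionProbabilities:
    def test_degenerate_immortal_law(self):
        sp = sc.SurvivalParams("loglogistic", (0.0, 2.0))
        assert sc.tp_die(sp, 5.0) == 0.0

    def test_first_cycle_death_probability(self):
        sp = loglogistic("placebo_ep", "os")
        assert sc.tp_die(sp, 1.0) == pytest.approx(1 - 1 / 1.002564, rel=1e-9)

    @pytest.mark.parametrize("sp", FOUR_FAMILY_EXAMPLES, ids=lambda s: s.family.value)
    def test_telescoping_identity(self, sp):
        n = 174
        t = np.arange(1, n + 1, dtype=float)
        surv_from_product = np.prod(1.0 - sc.tp_die(sp, t))
        assert surv_from_product == pytest.approx(sc.survival_probability(sp, float(n)), abs=1e-12)

    def test_identical_laws_give_zero_progression(self):
        sp = loglogistic("pembro_ep", "os")
        t = np.arange(1, 175, dtype=float)
        assert np.all(np.abs(sc.tp_progress(sp, sp, t)) < 1e-9)

    def test_progression_matches_arithmetic_oracle(self):
        sp_pfs = loglogistic("placebo_ep", "pfs")
        sp_os = loglogistic("placebo_ep", "os")
        t, u = 6.0, 1.0
        d = 1 - sc.survival_probability(sp_os, t) / sc.survival_probability(sp_os, t - u)
        ratio = sc.survival_probability(sp_pfs, t) / sc.survival_probability(sp_pfs, t - u)
        expected = 1 - ratio - d
        got = sc.tp_progress(sp_pfs, sp_os, t, u)
        assert 0 < got < 1
        assert got == pytest.approx(expected, abs=1e-12)

    def test_no_death_limit_is_pfs_ratio(self):
        sp_pfs = loglogistic("pembro_ep", "pfs")
        immortal = sc.SurvivalParams("loglogistic", (0.0, 2.0))
        t = 6.0
        ratio = sc.survival_probability(sp_pfs, t) / sc.survival_probability(sp_pfs, t - 1)
        assert sc.tp_progress(sp_pfs, immortal, t) == pytest.approx(1 - ratio, abs=1e-12)

    def test_rows_sum_to_one_within_horizon(self):
        for (arm, _), _p in ARM_PARAMS.items():
            sp_os = loglogistic(arm, "os")
            sp_pfs = loglogistic(arm, "pfs")
            t = np.arange(1, 175, dtype=float)
            die = sc.tp_die(sp_os, t)
            prog = sc.tp_progress(sp_pfs, sp_os, t)
            stay = 1 - die - prog
            for v in (die, prog, stay):
                assert np.all((v >= -1e-15) & (v <= 1 + 1e-15))
            assert np.allclose(die + prog + stay, 1.0)

    def test_time_shorter_than_cycle_rejected(self):
        with pytest.raises(ValueError):
            sc.tp_die(loglogistic("pembro_ep", "os"), 0.5, 1.0)


class TestFitIPD:
    def test_loglogistic_parameter_recovery(self):
        sp = loglogistic("pembro_ep", "os")
        spec = sc.SyntheticCohortSpec(params=sp, n=1000, censor_time=45.0, seed=0)
        times, events = sc.sample_ipd(spec)
        fit = sc.fit_ipd(times, events, "loglogistic")
        assert fit.converged
        theta, gamma = fit.params.params
        assert theta == pytest.approx(sp.theta, rel=0.10)
        assert gamma == pytest.approx(sp.gamma, rel=0.10)

    def test_bias_shrinks_with_sample_size(self):
        sp = loglogistic("pembro_ep", "os")
        err = {}
        for n in (200, 5000):
            rel = []
            for seed in range(5):
                spec = sc.SyntheticCohortSpec(params=sp, n=n, censor_time=45.0, seed=seed)
                fit = sc.fit_ipd(*sc.sample_ipd(spec), "loglogistic")
                rel.append(abs(fit.params.params[1] / sp.gamma - 1))
            err[n] = np.mean(rel)
        assert err[5000] < err[200]

    def test_exponential_closed_form_mle(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(10.0, size=500)
        events = (times <= 25.0).astype(int)
        times = np.minimum(times, 25.0)
        fit = sc.fit_ipd(times, events, "exponential")
        assert fit.params.params[0] == pytest.approx(events.sum() / times.sum(), rel=1e-6)
        assert fit.aic == pytest.approx(2 * 1 - 2 * fit.loglik)
        assert fit.bic == pytest.approx(math.log(500) - 2 * fit.loglik)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            sc.fit_ipd([1.0] * 20, [0] * 20, "weibull")  # all censored
        with pytest.raises(ValueError):
            sc.fit_ipd([1, 2, 3], [1, 1, 1], "weibull")  # too few


class TestFitKMPoints:
    def test_noise_free_grid_recovers_exactly(self):
        sp = loglogistic("placebo_ep", "os")
        t = np.linspace(1.5, 47.0, 30)
        s = sc.survival_probability(sp, t)
        fit = sc.fit_km_points((t, s), "loglogistic")
        assert fit.params.params[0] == pytest.approx(sp.theta, rel=0.01)
        assert fit.params.params[1] == pytest.approx(sp.gamma, rel=0.01)
        assert fit.sse < 1e-12

    def test_perturbed_grid_recovers_within_15pct(self):
        sp = loglogistic("pembro_ep", "os")
        spec = sc.SyntheticCohortSpec(
            params=sp, n=1, censor_time=47.8, seed=0,
            grid=tuple(np.linspace(1.6, 47.8, 30)), noise_sd=0.01,
        )
        fit = sc.fit_km_points(sc.digitized_points(spec), "loglogistic")
        assert fit.params.params[0] == pytest.approx(sp.theta, rel=0.15)
        assert fit.params.params[1] == pytest.approx(sp.gamma, rel=0.15)

    def test_nonmonotone_points_warn_and_correct(self):
        sp = loglogistic("placebo_ep", "os")
        t = np.linspace(1.5, 40.0, 20)
        s = sc.survival_probability(sp, t)
        s[5], s[6] = s[6], s[5]  # introduce an inversion
        with pytest.warns(UserWarning, match="isotonic"):
            fit = sc.fit_km_points((t, s), "loglogistic")
        assert fit.converged

    def test_degenerate_points_rejected(self):
        with pytest.raises(ValueError):
            sc.fit_km_points(([5.0] * 6, [0.7] * 6), "weibull")
        with pytest.raises(ValueError):
            sc.fit_km_points(([1, 2, 3], [0.9, 0.8, 0.7]), "weibull")


class TestSelectDistribution:
    def _fit(self, family, aic, bic):
        sp = sc.SurvivalParams(family, (0.1, 1.0) if family != "exponential" else (0.1,))
        return sc.FitResult(sp, loglik=0.0, aic=aic, bic=bic, n_obs=100, converged=True)

    def test_lowest_aic_wins(self):
        fits = [
            self._fit("exponential", 100, 100),
            self._fit("weibull", 90, 95),
            self._fit("lognormal", 95, 90),
            self._fit("loglogistic", 110, 80),
        ]
        assert sc.select_distribution(fits) == Family.WEIBULL

    def test_aic_tie_broken_by_bic(self):
        fits = [self._fit("weibull", 90, 95), self._fit("loglogistic", 90, 92)]
        assert sc.select_distribution(fits) == Family.LOGLOGISTIC

    def test_full_tie_uses_family_order(self):
        fits = [self._fit("loglogistic", 90, 90), self._fit("weibull", 90, 90)]
        assert sc.select_distribution(fits) == Family.WEIBULL

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            sc.select_distribution([])
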
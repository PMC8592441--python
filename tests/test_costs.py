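import numpy as np
import pytest

import sclc_cea as sc
import sclc_cea.config as cfgmod
from sclc_cea.costs import (
    CostStreams,
    DoseRule,
    PatientProfile,
    cycle_drug_cost,
    first_line_cost_stream,
    subsequent_and_other_cost_stream,
    total_discounted_cost,
)
from sclc_cea.markov import ModelConfig

from conftest import loglogistic

PROFILE = PatientProfile()
CFG = ModelConfig()


class TestComputeDose:
    @pytest.mark.parametrize(
        "rule,expected",
        [
            (DoseRule("fixed_mg", 200.0), 200.0),
            (DoseRule("auc_calvert", 5.0), 5 * (70 + 25)),  # Calvert formula
            (DoseRule("per_m2", 100.0), 100 * 1.79),
            (DoseRule("per_kg", 2.0), 2 * 70.32),
        ],
    )
    def test_dosing_rules(self, rule, expected):
        assert sc.compute_dose(rule, PROFILE) == pytest.approx(expected)

    def test_invalid_rules_rejected(self):
        with pytest.raises(ValueError):
            DoseRule("per_vial", 100.0)
        with pytest.raises(ValueError):
            DoseRule("fixed_mg", -5.0)


class TestCycleDrugCost:
    def test_pembrolizumab_cycle_cost(self, base_config):
        reg = cfgmod.first_line_regimen(base_config, "pembro_ep")
        prices = base_config["costs"]["prices_per_mg"]
        pembro_only = cycle_drug_cost(
            reg, prices, PROFILE, component_filter=lambda c: c.drug == "pembrolizumab"
        )
        assert pembro_only == pytest.approx(200 * 49.39)

    def test_platinum_share_weighting(self, base_config):
        reg = cfgmod.first_line_regimen(base_config, "placebo_ep")
        prices = base_config["costs"]["prices_per_mg"]
        platinum = cycle_drug_cost(
            reg, prices, PROFILE, component_filter=lambda c: c.drug in ("carboplatin", "cisplatin")
        )
        expected = 0.711 * (475 * 0.06) + 0.289 * (75 * 1.79 * 0.19)
        assert platinum == pytest.approx(expected)

    def test_zero_price_contributes_nothing(self, base_config):
        reg = cfgmod.first_line_regimen(base_config, "placebo_ep")
        prices = dict(base_config["costs"]["prices_per_mg"], etoposide=0.0)
        full = cycle_drug_cost(reg, prices, PROFILE)
        no_eto = cycle_drug_cost(reg, prices, PROFILE, component_filter=lambda c: c.drug != "etoposide")
        assert full == pytest.approx(no_eto)

    def test_missing_price_names_the_drug(self, base_config):
        reg = cfgmod.first_line_regimen(base_config, "pembro_ep")
        with pytest.raises(KeyError, match="pembrolizumab"):
            cycle_drug_cost(reg, {"etoposide": 1.0, "carboplatin": 1.0, "cisplatin": 1.0}, PROFILE)


class TestCostStreams:
    def _trace(self, arm):
        return sc.run_cohort(loglogistic(arm, "os"), loglogistic(arm, "pfs"), CFG)

    def test_placebo_first_line_total_near_published(self, base_config):
        streams = first_line_cost_stream(
            self._trace("placebo_ep"),
            cfgmod.first_line_regimen(base_config, "placebo_ep"),
            base_config["costs"]["prices_per_mg"],
            PROFILE,
            CFG,
            admin_bundle=0.0,
            ae_first_line=0.0,
        )
        total, breakdown = total_discounted_cost(streams, CFG)
        assert breakdown["first_line_acquisition"] == pytest.approx(3600, rel=0.15)

    def test_pembrolizumab_stops_with_pfs_occupancy(self, base_config):
        # an (artificial) PFS law emptying by cycle 2 must stop drug costs there
        fast = sc.SurvivalParams("weibull", (2.0, 2.0))
        slow_death = sc.SurvivalParams("loglogistic", (1e-6, 1.1))
        trace = sc.run_cohort(slow_death, fast, CFG)
        streams = first_line_cost_stream(
            trace,
            cfgmod.first_line_regimen(base_config, "pembro_ep"),
            base_config["costs"]["prices_per_mg"],
            PROFILE,
            CFG,
            admin_bundle=0.0,
            ae_first_line=0.0,
        )
        acq = streams.streams["first_line_acquisition"]
        assert np.all(acq[4:] < 1e-4)

    def test_fixed_median7_policy_caps_pembrolizumab(self, base_config):
        trace = self._trace("pembro_ep")
        kwargs = dict(
            regimen=cfgmod.first_line_regimen(base_config, "pembro_ep"),
            prices=base_config["costs"]["prices_per_mg"],
            profile=PROFILE,
            cfg=CFG,
            admin_bundle=0.0,
            ae_first_line=0.0,
        )
        default = total_discounted_cost(first_line_cost_stream(trace, **kwargs), CFG)[0]
        capped = total_discounted_cost(
            first_line_cost_stream(trace, pembro_policy="fixed_median7", **kwargs), CFG
        )[0]
        assert capped < default

    def test_subsequent_stream_cases(self, base_config):
        trace = self._trace("placebo_ep")
        kwargs = dict(
            cfg=CFG,
            subsequent_drug_per_cycle=80.0,
            ae_second_line=0.0,
            outpatient_visit_per_cycle=52.33,
            supportive_care_per_month=637.0,
            death_cost=0.0,
        )
        full = subsequent_and_other_cost_stream(trace, uptake=0.655, **kwargs)
        none = subsequent_and_other_cost_stream(trace, uptake=0.0, **kwargs)
        # zero uptake: no second-line drug cost, maximal supportive care
        assert total_discounted_cost(none, CFG)[1]["second_line_acquisition"] == 0.0
        assert (
            total_discounted_cost(none, CFG)[1]["supportive_care"]
            > total_discounted_cost(full, CFG)[1]["supportive_care"]
        )
        # identical OS/PFS laws leave the PS state empty: only visits accrue
        same = sc.run_cohort(loglogistic("placebo_ep", "os"), loglogistic("placebo_ep", "os"), CFG)
        streams = subsequent_and_other_cost_stream(same, uptake=0.655, **kwargs)
        _, bd = total_discounted_cost(streams, CFG)
        assert bd["second_line_acquisition"] == pytest.approx(0.0, abs=1e-6)
        assert bd["supportive_care"] == pytest.approx(0.0, abs=1e-6)
        assert bd["followup_visit"] > 0

    def test_death_cost_total(self, base_config):
        trace = self._trace("placebo_ep")
        streams = subsequent_and_other_cost_stream(
            trace,
            CFG,
            uptake=0.655,
            subsequent_drug_per_cycle=0.0,
            ae_second_line=0.0,
            outpatient_visit_per_cycle=0.0,
            supportive_care_per_month=0.0,
            death_cost=9433.0,
        )
        _, bd = total_discounted_cost(streams, CFG)
        # one-off terminal cost per death, discounted at the death cycle
        dw = 0.5 * (sc.markov.discount_factors(CFG)[:-1] + sc.markov.discount_factors(CFG)[1:])
        assert bd["death"] == pytest.approx(9433.0 * float(trace.new_deaths @ dw), rel=1e-12)

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            CostStreams().add("helicopter", np.zeros(175))


class TestArmTotals:
    def test_breakdown_sums_to_total(self, base_result):
        for arm in (base_result.intervention, base_result.comparator):
            assert sum(arm.cost_breakdown.values()) == pytest.approx(arm.cost, abs=1e-6)

    def test_costs_monotone_in_unit_prices(self, fresh_config):
        base = sc.evaluate(fresh_config)
        for path in (
            "costs.prices_per_mg.pembrolizumab",
            "costs.prices_per_mg.etoposide",
            "costs.death_cost",
            "costs.supportive_care_per_month",
            "costs.outpatient_visit_per_cycle",
        ):
            raised = sc.evaluate(cfgmod.with_param(fresh_config, path, cfgmod.get_param(fresh_config, path) * 1.5))
            assert raised.intervention.cost >= base.intervention.cost - 1e-9
            assert raised.comparator.cost >= base.comparator.cost - 1e-9

    def test_zero_discount_weakly_increases_totals(self, fresh_config):
        base = sc.evaluate(fresh_config)
        undisc = sc.evaluate(cfgmod.with_param(fresh_config, "model.annual_discount", 0.0))
        assert undisc.intervention.cost >= base.intervention.cost
        assert undisc.comparator.cost >= base.comparator.cost

    def test_nccn_mode_runs_and_prices_feed_through(self, fresh_config):
        cfgmod.set_param(fresh_config, "costs.subsequent_drug_mode", "nccn")
        base = sc.evaluate(fresh_config)
        assert base.intervention.cost_breakdown["second_line_acquisition"] > 0
        pricier = sc.evaluate(
            cfgmod.with_param(fresh_config, "costs.prices_per_mg.topotecan", 800.0)
        )
        assert (
            pricier.intervention.cost_breakdown["second_line_acquisition"]
            > base.intervention.cost_breakdown["second_line_acquisition"]
        )
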
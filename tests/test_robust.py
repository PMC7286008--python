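import numpy as np
import pytest

from protonsct.robust import (
    ScenarioSpec, RobustSettings, derive_setup_sigma, derive_range_sigma,
    worst_case_grid, sample_scenarios, evaluate_scenarios, select_scenarios,
    dvh_band, worst_case_metrics, RobustnessEvaluation,
)


class TestDerivedSigmas:
    @pytest.mark.parametrize("margin, factor, expected", [
        (3.0, 2.5, 1.2),
        (0.0, 2.5, 0.0),
        (5.0, 2.0, 2.5),
    ])
    def test_setup_sigma_from_van_herk_recipe(self, margin, factor, expected):
        assert derive_setup_sigma(margin, factor) == pytest.approx(expected)

    @pytest.mark.parametrize("rec, k, expected", [
        (0.024, 1.5, 0.016),
        (0.0, 1.5, 0.0),
        (0.030, 1.5, 0.020),
    ])
    def test_range_sigma_from_recommended_error(self, rec, k, expected):
        assert derive_range_sigma(rec, k) == pytest.approx(expected)

    def test_nonpositive_factors_rejected(self):
        with pytest.raises(ValueError):
            derive_setup_sigma(3.0, 0.0)
        with pytest.raises(ValueError):
            derive_range_sigma(0.024, -1.0)


class TestWorstCaseGrid:
    def test_standard_magnitudes_give_21_scenarios(self):
        g = worst_case_grid(3.0, 0.03)
        assert len(g) == 21
        assert g[0].is_nominal
        assert sum(sc.is_nominal for sc in g) == 1

    def test_zero_setup_collapses_to_three(self):
        g = worst_case_grid(0.0, 0.03)
        assert len(g) == 3

    def test_each_shift_has_at_most_one_nonzero_axis(self):
        for sc in worst_case_grid(3.0, 0.03):
            assert sum(v != 0.0 for v in sc.setup_shift) <= 1
            assert all(abs(v) in (0.0, 3.0) for v in sc.setup_shift)
            assert sc.range_error in (0.0, 0.03, -0.03)


class TestSampling:
    def test_count_and_determinism(self):
        s = RobustSettings(n_scenarios=100, seed=5)
        a = sample_scenarios(s)
        b = sample_scenarios(s)
        assert len(a) == 100
        assert a == b
        assert sample_scenarios(RobustSettings(n_scenarios=100, seed=6)) != a

    def test_empirical_sd_matches_settings(self):
        s = RobustSettings(n_scenarios=10**4, sigma_setup=1.2, sigma_range=0.016, seed=2)
        scen = sample_scenarios(s)
        shifts = np.array([sc.setup_shift for sc in scen])
        ranges = np.array([sc.range_error for sc in scen])
        for ax in range(3):
            assert abs(shifts[:, ax].std() - 1.2) / 1.2 < 0.03
        assert abs(ranges.std() - 0.016) / 0.016 < 0.03


@pytest.fixture(scope="module")
def scenario_results(sample, plan_and_dose):
    plan, _ = plan_and_dose
    rois = {"CTV": sample.masks["CTV"], "brainstem": sample.masks["brainstem"]}
    scen = sample_scenarios(RobustSettings(n_scenarios=20, seed=3))
    return evaluate_scenarios(plan, sample.ct, scen, rois)


class TestEvaluateScenarios:
    def test_nominal_inserted_and_tagged(self, scenario_results):
        assert scenario_results[0].tag == "nominal"
        assert len(scenario_results) == 21  # 20 sampled + nominal

    def test_single_nominal_equals_direct_evaluation(self, sample, plan_and_dose):
        from protonsct.dvh import metric_table
        plan, dose = plan_and_dose
        res = evaluate_scenarios(plan, sample.ct, [ScenarioSpec()],
                                 {"CTV": sample.masks["CTV"]})
        direct = metric_table(dose, {"CTV": sample.masks["CTV"]}, plan.prescription)
        assert res[0].metrics.value("CTV", "D95") == pytest.approx(
            direct.value("CTV", "D95"))

    def test_duplicates_preserved(self, sample, plan_and_dose):
        plan, _ = plan_and_dose
        sc = ScenarioSpec(setup_shift=(0.0, 3.0, 0.0))
        res = evaluate_scenarios(plan, sample.ct, [sc, sc], {"CTV": sample.masks["CTV"]})
        assert len(res) == 3  # nominal + the duplicate pair
        assert res[1].metrics.value("CTV", "D95") == res[2].metrics.value("CTV", "D95")


class TestSelection:
    def test_retention_count(self, scenario_results):
        kept = select_scenarios(scenario_results, retain_fraction=0.90)
        # 21 results, discard round(2.1) = 2
        assert len(kept) == 19

    def test_hundred_scenarios_give_ninety(self, sample, plan_and_dose):
        plan, _ = plan_and_dose
        scen = sample_scenarios(RobustSettings(n_scenarios=100, seed=4))
        res = evaluate_scenarios(plan, sample.ct, scen, {"CTV": sample.masks["CTV"]})
        sampled_only = [r for r in res if not r.scenario.is_nominal]
        assert len(select_scenarios(sampled_only, 0.90)) == 90

    def test_retain_all(self, scenario_results):
        assert len(select_scenarios(scenario_results, 1.0)) == len(scenario_results)

    def test_ranking_matches_bruteforce_sort(self, scenario_results):
        kept = select_scenarios(scenario_results, retain_fraction=0.8)
        nominal = scenario_results[0]
        ref = nominal.metrics.value("CTV", "D95")
        scores = [abs(r.metrics.value("CTV", "D95") - ref) for r in scenario_results]
        n_discard = int(np.floor(len(scores) * 0.2 + 0.5))
        worst = set(np.argsort(scores, kind="stable")[-n_discard:])
        expected = [r for i, r in enumerate(scenario_results) if i not in worst]
        assert kept == expected

    def test_nominal_never_discarded(self, scenario_results):
        kept = select_scenarios(scenario_results, retain_fraction=0.5)
        assert any(r.scenario.is_nominal for r in kept)


class TestBandAndWorstCase:
    def test_single_scenario_band_collapses(self, sample, plan_and_dose):
        plan, _ = plan_and_dose
        res = evaluate_scenarios(plan, sample.ct, [ScenarioSpec()],
                                 {"CTV": sample.masks["CTV"]})
        band = dvh_band(res)
        assert np.allclose(band.lower["CTV"], band.upper["CTV"])

    def test_band_envelopes_match_bruteforce_extrema(self, scenario_results):
        band = dvh_band(scenario_results)
        band.validate()
        curves = [np.interp(band.dose_axis, r.dvhs["CTV"].dose_axis,
                            r.dvhs["CTV"].volume_fraction, right=0.0)
                  for r in scenario_results]
        stack = np.vstack(curves)
        assert np.allclose(band.lower["CTV"], stack.min(axis=0))
        assert np.allclose(band.upper["CTV"], stack.max(axis=0))

    def test_adding_scenario_only_widens_band(self, scenario_results):
        small = dvh_band(scenario_results[:5])
        big = dvh_band(scenario_results)
        n = len(small.dose_axis)
        assert (big.lower["CTV"][:n] <= small.lower["CTV"] + 1e-12).all()
        assert (big.upper["CTV"][:n] >= small.upper["CTV"] - 1e-12).all()

    def test_nominal_dvh_inside_band(self, scenario_results):
        band = dvh_band(scenario_results)
        nom = scenario_results[0].dvhs["CTV"]
        interp = np.interp(band.dose_axis, nom.dose_axis, nom.volume_fraction, right=0.0)
        assert (band.lower["CTV"] - 1e-12 <= interp).all()
        assert (interp <= band.upper["CTV"] + 1e-12).all()

    def test_worst_case_direction_and_bruteforce(self, scenario_results):
        worst = worst_case_metrics(scenario_results)
        nominal = scenario_results[0].metrics
        assert worst.value("CTV", "D95") <= nominal.value("CTV", "D95")
        for roi, metric in worst.keys():
            vals = [r.metrics.value(roi, metric) for r in scenario_results]
            ref = min(vals) if metric == "D95" else max(vals)
            assert worst.value(roi, metric) == pytest.approx(ref)

    def test_identical_scenarios_worst_equals_nominal(self, sample, plan_and_dose):
        plan, _ = plan_and_dose
        res = evaluate_scenarios(plan, sample.ct, [ScenarioSpec()] * 3,
                                 {"CTV": sample.masks["CTV"]})
        worst = worst_case_metrics(res)
        nominal = res[0].metrics
        for key in worst.keys():
            assert worst.value(*key) == pytest.approx(nominal.value(*key))


class TestEndToEnd:
    def test_identical_ct_sct_differences_exactly_zero(self, sample, plan_and_dose):
        from protonsct.dvh import diff_table
        plan, _ = plan_and_dose
        rois = {"CTV": sample.masks["CTV"], "brainstem": sample.masks["brainstem"]}
        settings = RobustSettings(n_scenarios=10, seed=9)
        res_ct = RobustnessEvaluation(plan, sample.ct, rois, settings).run()
        res_sct = RobustnessEvaluation(plan, sample.ct.copy(), rois, settings).run()
        for a, b in ((res_ct.nominal, res_sct.nominal), (res_ct.worst, res_sct.worst)):
            d = diff_table(a, b)["diff_pct"].to_numpy()
            assert (d[~np.isnan(d)] == 0.0).all()

    def test_skull_perturbation_worst_at_least_nominal(self, sample):
        """A +200 HU skull error must produce a nonzero CTV D95 difference
        whose worst-case magnitude is at least the nominal magnitude in most
        seeded repeats."""
        from protonsct.phantom import LABEL_BONE
        from protonsct.dose import make_plan
        plan = make_plan(sample.ct, sample.masks["CTV"])
        sct = sample.ct.copy()
        sct.data[sample.labels == LABEL_BONE] += 200.0
        rois = {"CTV": sample.masks["CTV"]}
        wins = 0
        n_rep = 5
        for seed in range(n_rep):
            settings = RobustSettings(n_scenarios=30, seed=seed)
            res_ct = RobustnessEvaluation(plan, sample.ct, rois, settings).run()
            res_sct = RobustnessEvaluation(plan, sct, rois, settings).run()
            dn = abs(res_ct.nominal.value("CTV", "D95", "pct")
                     - res_sct.nominal.value("CTV", "D95", "pct"))
            dw = abs(res_ct.worst.value("CTV", "D95", "pct")
                     - res_sct.worst.value("CTV", "D95", "pct"))
            assert dn > 0.0
            if dw >= dn:
                wins += 1
        assert wins >= 0.8 * n_rep
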
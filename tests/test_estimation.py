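import math

import numpy as np
import pytest
from dataclasses import replace

from pktd import (
    ErrorModelSpec,
    IdentifiabilityError,
    Regimen,
    compare_models,
    els_objective,
    fit_acute_td,
    fit_chronic_td,
    fit_pk_individual,
    fit_pk_population,
    profiled_sigma,
)
from pktd.estimation import FitResult
from pktd.recovery import offset_init

LOG2PI = math.log(2 * math.pi)


class TestELSObjective:
    def test_perfect_fit_additive_unit_sigma(self):
        y = np.array([1.0, 2.0, 3.0])
        val = els_objective(y, y, ErrorModelSpec("additive", scale=1.0))
        assert val == pytest.approx(3 * LOG2PI)

    def test_single_observation_hand_value(self):
        # (2-1)^2/1 + ln(1) + ln(2*pi)
        val = els_objective([2.0], [1.0], ErrorModelSpec("additive", scale=1.0))
        assert val == pytest.approx(1.0 + LOG2PI)

    def test_proportional_hand_value(self):
        y, f, s = np.array([1.2]), np.array([1.0]), 0.3
        expected = (0.2 / 0.3) ** 2 + math.log(s * s) + LOG2PI
        val = els_objective(y, f, ErrorModelSpec("proportional", scale=s))
        assert val == pytest.approx(expected)

    def test_profiled_sigma_is_rms_weighted_residual(self, rng):
        f = rng.uniform(1, 5, 50)
        y = f * (1 + 0.2 * rng.normal(size=50))
        s_hat = profiled_sigma(y, f, "proportional")
        assert s_hat == pytest.approx(np.sqrt(np.mean(((y - f) / f) ** 2)))
        # profiling attains the minimum of the fixed-scale objective
        prof = els_objective(y, f, ErrorModelSpec("proportional"))
        fixed = els_objective(y, f, ErrorModelSpec("proportional", scale=s_hat))
        assert prof == pytest.approx(fixed, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            els_objective([1.0, 1.0], [1.0, 1.0], ErrorModelSpec("additive"))
        with pytest.raises(ValueError):
            ErrorModelSpec("additive", scale=-1.0)


class TestPKIndividual:
    def test_noiseless_recovery(self, pk_cohort_noiseless, pop):
        sid = pk_cohort_noiseless.subjects[0]
        rows = pk_cohort_noiseless.rows_for(sid)
        res = fit_pk_individual(
            rows["time_days"].to_numpy(), rows["value"].to_numpy(),
            pk_cohort_noiseless.regimen_for(sid), offset_init(pop, "pk"),
        )
        assert res.converged
        for name, truth in (("V", 357.8), ("ke", 3.4), ("k12", 2.6),
                            ("k21", 1.1)):
            assert res.estimates[name] == pytest.approx(truth, rel=1e-3)

    def test_too_few_observations_rejected(self, pop):
        with pytest.raises(ValueError, match="> 4"):
            fit_pk_individual([0.01, 0.02, 0.03], [5.0, 4.0, 3.0],
                              Regimen.single_dose(3000.0), pop.pk)

    def test_optimum_no_worse_than_truth_start(self, pk_cohort, pop):
        sid = pk_cohort.subjects[3]
        rows = pk_cohort.rows_for(sid)
        t, y = rows["time_days"].to_numpy(), rows["value"].to_numpy()
        reg = pk_cohort.regimen_for(sid)
        res = fit_pk_individual(t, y, reg, pop.pk, n_starts=2)
        from pktd.trajectories import pk_concentration

        f0 = pk_concentration(pop.pk, reg, t).values
        at_truth = els_objective(y, f0, ErrorModelSpec("proportional"),
                                 floor=1e-6 * 5000 / pop.pk.V)
        assert res.minus2ll <= at_truth + 1e-6


class TestPKPopulation:
    def test_its_noiseless_recovery(self, pk_cohort_noiseless, pop):
        res = fit_pk_population(pk_cohort_noiseless, offset_init(pop, "pk"))
        for name, truth in (("V", 357.8), ("ke", 3.4), ("k12", 2.6),
                            ("k21", 1.1)):
            assert res.estimates[name] == pytest.approx(truth, rel=0.01)

    def test_two_stage_low_noise_recovery(self, pop, design):
        tiny = replace(pop, omega={}, sigma_pk_prop=0.01)
        from pktd.cohort import generate_pk_cohort

        tab = generate_pk_cohort(tiny, design, seed=2)
        res = fit_pk_population(tab, offset_init(pop, "pk"),
                                method="two_stage")
        for name, truth in (("V", 357.8), ("ke", 3.4), ("k12", 2.6),
                            ("k21", 1.1)):
            assert res.estimates[name] == pytest.approx(truth, rel=0.01)
        # estimated IIV on a zero-IIV cohort stays near zero
        assert res.estimates["omega_V"] < 5.0

    def test_refuses_tiny_cohort(self, pk_cohort, pop):
        two = pk_cohort.resample_subjects(list(pk_cohort.subjects[:2]))
        with pytest.raises(RuntimeError, match="refused"):
            fit_pk_population(two, offset_init(pop, "pk"), method="two_stage")

    def test_aic_identity(self, pk_cohort_noiseless, pop):
        res = fit_pk_population(pk_cohort_noiseless, offset_init(pop, "pk"))
        assert res.aic == pytest.approx(res.minus2ll + 2 * res.n_params)


class TestAcuteTD:
    def test_noiseless_recovery(self, td_cohort_noiseless, pop):
        res = fit_acute_td(td_cohort_noiseless, pop.pk,
                           offset_init(pop, "acute"), compute_cv=False)
        for name, truth in (("kin_acute", 0.004), ("kout_acute", 0.06),
                            ("Emax_acute", 10.1), ("EC50_acute", 0.36)):
            assert res.estimates[name] == pytest.approx(truth, rel=0.01)

    def test_control_only_with_frozen_emax_recovers_habituation(
            self, td_cohort_noiseless, pop):
        obs = td_cohort_noiseless.observations
        ctrl = obs[obs["group"] == 0.0]
        table = type(td_cohort_noiseless)(
            ctrl, td_cohort_noiseless.doses.iloc[:0]
        )
        res = fit_acute_td(table, pop.pk, offset_init(pop, "acute"),
                           fixed={"Emax_acute": 0.0, "EC50_acute": 0.36},
                           compute_cv=False)
        assert res.estimates["kin_acute"] == pytest.approx(0.004, rel=0.05)
        assert res.estimates["kout_acute"] == pytest.approx(0.06, rel=0.05)

    def test_control_only_free_emax_unidentifiable(self, td_cohort_noiseless,
                                                   pop):
        obs = td_cohort_noiseless.observations
        ctrl = obs[obs["group"] == 0.0]
        table = type(td_cohort_noiseless)(ctrl,
                                          td_cohort_noiseless.doses.iloc[:0])
        with pytest.raises(IdentifiabilityError):
            fit_acute_td(table, pop.pk, offset_init(pop, "acute"))


class TestChronicTD:
    def test_noiseless_stage1_recovery(self, td_cohort_noiseless, pop):
        res = fit_chronic_td(td_cohort_noiseless, pop.pk,
                             offset_init(pop, "chronic"), compute_cv=False,
                             refit_individuals=False)
        for name, truth in (("kin_chronic", 2.7), ("Emax_chronic", 168.0),
                            ("EC50_chronic", 0.43)):
            assert res.estimates[name] == pytest.approx(truth, rel=0.01)

    def test_control_only_unidentifiable(self, td_cohort_noiseless, pop):
        obs = td_cohort_noiseless.observations
        ctrl = obs[obs["group"] == 0.0]
        table = type(td_cohort_noiseless)(ctrl,
                                          td_cohort_noiseless.doses.iloc[:0])
        with pytest.raises(IdentifiabilityError):
            fit_chronic_td(table, pop.pk, offset_init(pop, "chronic"))

    def test_stage2_reports_omegas_and_etas(self, td_cohort, pop):
        res = fit_chronic_td(td_cohort, pop.pk, offset_init(pop, "chronic"),
                             compute_cv=False)
        assert "omega_kin_chronic" in res.estimates
        assert "omega_EC50_chronic" in res.estimates
        # only treated animals carry information on the random effects
        assert len(res.etas) == 15
        assert res.extra["sigma_stage1"] >= res.estimates["sigma_add"] * 0.8


class TestCompareModels:
    def _fit(self, m2ll, n_params, n_obs=100):
        return FitResult(estimates={}, minus2ll=m2ll, n_obs=n_obs,
                         n_params=n_params, converged=True)

    def test_aic_drop_below_two_is_no_improvement(self):
        a = self._fit(90.0, 5)   # AIC 100
        b = self._fit(89.0, 5)   # AIC 99
        assert compare_models(a, b) == "no improvement"

    def test_identical_fits_tie_keeps_reference(self):
        a = self._fit(90.0, 5)
        assert compare_models(a, self._fit(90.0, 5)) == "no improvement"

    def test_aic_drop_of_two_selects_alternative(self):
        assert compare_models(self._fit(90.0, 5), self._fit(88.0, 5)) == \
            "alternative"

    def test_nested_threshold_663_per_added_parameter(self):
        ref = self._fit(100.0, 5)
        assert compare_models(ref, self._fit(93.0, 6), nested=True) == \
            "alternative"
        assert compare_models(ref, self._fit(94.0, 6), nested=True) == \
            "no improvement"

    def test_mismatched_data_rejected(self):
        with pytest.raises(ValueError):
            compare_models(self._fit(90.0, 5, n_obs=100),
                           self._fit(80.0, 5, n_obs=90))
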
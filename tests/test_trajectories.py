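import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from pktd import (
    DoseEvent,
    PKParams,
    Regimen,
    hill,
    macro_constants,
    pk_concentration,
    simulate_acute,
    simulate_chronic,
)

rate = st.floats(min_value=0.05, max_value=20.0)


class TestMacroConstants:
    def test_reference_sum_and_product(self, pop):
        # Vieta: alpha+beta = ke+k12+k21 = 7.1 ; alpha*beta = ke*k21 = 3.74
        m = macro_constants(pop.pk)
        assert m.alpha + m.beta == pytest.approx(7.1)
        assert m.alpha * m.beta == pytest.approx(3.74)
        assert m.alpha > m.beta > 0

    def test_one_compartment_limit(self):
        pk = PKParams(V=300.0, ke=2.0, k12=1e-9, k21=1e-9)
        m = macro_constants(pk)
        assert m.alpha == pytest.approx(2.0, rel=1e-6)
        assert m.beta == pytest.approx(0.0, abs=1e-6)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(ke=rate, k12=rate, k21=rate)
    def test_vieta_identities(self, ke, k12, k21):
        pk = PKParams(V=300.0, ke=ke, k12=k12, k21=k21)
        m = macro_constants(pk)
        assert m.alpha > m.beta > 0
        assert m.alpha + m.beta == pytest.approx(ke + k12 + k21, rel=1e-9)
        assert m.alpha * m.beta == pytest.approx(ke * k21, rel=1e-9)
        # unit-dose coefficients integrate the bolus: cA + cB = 1/V
        assert m.cA + m.cB == pytest.approx(1.0 / pk.V, rel=1e-9)


from _oracles import ode_concentration as _ode_concentration  # noqa: E402


class TestPKConcentration:
    def test_bolus_initial_concentration(self, pop):
        # 3 mg/kg into V = 357.8 mL/kg -> 3000/357.8 = 8.385 ug/mL
        reg = Regimen.single_dose(3000.0, horizon=1.0)
        tr = pk_concentration(pop.pk, reg, [0.0, 0.01])
        assert tr.values[0] == pytest.approx(8.385, abs=1e-3)

    def test_zero_dose_is_zero(self, pop):
        reg = Regimen.placebo(28.0)
        tr = pk_concentration(pop.pk, reg, np.linspace(0, 28, 50))
        assert np.all(tr.values == 0.0)

    def test_negative_times_rejected(self, pop):
        with pytest.raises(ValueError):
            pk_concentration(pop.pk, Regimen.placebo(1.0), [-0.1, 0.5])

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(ke=rate, k12=rate, k21=rate,
           v=st.floats(min_value=50.0, max_value=2000.0))
    def test_closed_form_matches_ode(self, ke, k12, k21, v):
        pk = PKParams(V=v, ke=ke, k12=k12, k21=k21)
        reg = Regimen.single_dose(5000.0, horizon=0.2)
        t = np.linspace(0.0005, 0.2, 60)
        closed = pk_concentration(pk, reg, t).values
        ode = _ode_concentration(pk, reg, t)
        assert closed == pytest.approx(ode, rel=1e-6)

    def test_superposition_of_two_boluses(self, pop):
        t = np.linspace(0.001, 14.0, 300)
        both = pk_concentration(
            pop.pk,
            Regimen((DoseEvent(0.0, 5000.0), DoseEvent(7.0, 5000.0)), 14.0),
            t,
        ).values
        ode = _ode_concentration(
            pop.pk,
            Regimen((DoseEvent(0.0, 5000.0), DoseEvent(7.0, 5000.0)), 14.0),
            t,
        )
        assert both == pytest.approx(ode, rel=1e-6, abs=1e-12)

    def test_auc_dose_proportionality(self, pop):
        # AUC of a single dose equals Dose / (V * ke): linear elimination
        reg = Regimen.single_dose(5000.0, horizon=3.0)
        t = np.linspace(0.0, 3.0, 20001)
        c = pk_concentration(pop.pk, reg, t).values
        auc = np.trapezoid(c, t)
        expected = 5000.0 / (pop.pk.V * pop.pk.ke * 24.0)
        assert auc == pytest.approx(expected, rel=5e-3)


class TestHill:
    def test_half_maximum_at_ec50(self):
        assert hill(0.36, 10.1, 0.36, 6.0) == pytest.approx(10.1 / 2)
        assert hill(0.43, 168.0, 0.43, 4.0) == pytest.approx(84.0)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(c=st.floats(min_value=0, max_value=50),
           g=st.floats(min_value=1, max_value=8))
    def test_bounded_and_monotone(self, c, g):
        e1 = hill(c, 10.0, 0.4, g)
        e2 = hill(c + 0.5, 10.0, 0.4, g)
        assert 0.0 <= e1 <= 10.0
        assert e2 >= e1


class TestAcute:
    def test_placebo_score_starts_at_baseline(self, pop):
        t = np.linspace(0, 28, 100)
        tr = simulate_acute(pop.acute, pop.pk, Regimen.placebo(28.0), t)
        assert tr.values[0] == pytest.approx(3.1, abs=1e-12)
        # habituation: the placebo curve never increases
        assert np.all(np.diff(tr.values) <= 1e-9)

    def test_zero_emax_equals_placebo(self, pop):
        t = np.linspace(0, 28, 60)
        reg = Regimen(tuple(DoseEvent(d, 5000.0) for d in (0, 7, 14, 21)), 28.0)
        dosed = simulate_acute(replace(pop.acute, Emax_acute=0.0), pop.pk, reg, t)
        placebo = simulate_acute(pop.acute, pop.pk, Regimen.placebo(28.0), t)
        assert dosed.values == pytest.approx(placebo.values, abs=1e-9)

    def test_placebo_long_time_asymptote(self, pop):
        # Response tends to kin/kout = 0.004/0.06 = 0.0667 once handling decays
        t = np.array([0.0, 100.0, 200.0])
        tr = simulate_acute(pop.acute, pop.pk, Regimen.placebo(200.0), t)
        assert tr.values[-1] == pytest.approx(0.0667, abs=1e-3)

    def test_grid_engine_matches_ode(self, pop):
        reg = Regimen(tuple(DoseEvent(d, 8000.0) for d in (0, 7, 14, 21)), 28.0)
        t = np.array([2, 4, 7, 9, 11, 14, 16, 18, 21, 23, 25, 28], dtype=float)
        g = simulate_acute(pop.acute, pop.pk, reg, t).values
        o = simulate_acute(pop.acute, pop.pk, reg, t, method="ode").values
        assert g == pytest.approx(o, abs=2e-3)


class TestChronic:
    def test_placebo_flat_at_baseline(self, pop):
        t = np.linspace(0, 28, 561)
        tr = simulate_chronic(pop.chronic, pop.pk, Regimen.placebo(28.0), t)
        assert np.max(np.abs(tr.values - 8.0)) < 1e-6

    def test_zero_emax_flat_under_dosing(self, pop):
        reg = Regimen(tuple(DoseEvent(d, 8000.0) for d in (0, 7, 14, 21)), 28.0)
        t = np.linspace(0, 28, 100)
        tr = simulate_chronic(replace(pop.chronic, Emax_chronic=0.0), pop.pk,
                              reg, t)
        assert np.max(np.abs(tr.values - 8.0)) < 1e-6

    def test_steady_state_is_fixed_point(self, pop):
        # all transit states at kin/kout: the drug-free derivatives vanish
        ch = pop.chronic
        kout = ch.kout_chronic
        x = np.full(ch.n_transit + 1, ch.kin_chronic / kout)
        dx1 = ch.kin_chronic - kout * x[0]
        dxi = kout * (x[:-1] - x[1:])
        assert dx1 == pytest.approx(0.0, abs=1e-12)
        assert dxi == pytest.approx(np.zeros(ch.n_transit), abs=1e-12)

    def test_grid_engine_matches_ode(self, pop):
        reg = Regimen(tuple(DoseEvent(d, 5000.0) for d in (0, 7, 14, 21)), 28.0)
        t = np.array([2, 4, 7, 9, 11, 14, 16, 18, 21, 23, 25, 28], dtype=float)
        g = simulate_chronic(pop.chronic, pop.pk, reg, t).values
        o = simulate_chronic(pop.chronic, pop.pk, reg, t, method="ode").values
        assert g == pytest.approx(o, abs=5e-3)

    def test_states_may_go_negative_but_clamp_is_available(self, pop):
        reg = Regimen(tuple(DoseEvent(d, 8000.0) for d in (0, 7, 14, 21)), 28.0)
        t = np.linspace(0, 28, 200)
        raw = simulate_chronic(pop.chronic, pop.pk, reg, t)
        clamped = simulate_chronic(pop.chronic, pop.pk, reg, t,
                                   clamp_nonnegative=True)
        assert raw.values.min() < 0  # Emax = 168 drives the chain negative
        assert clamped.values.min() == 0.0
        assert np.all(clamped.values >= raw.values)


@pytest.fixture(scope="module")
def sweep(pop):
    t = np.linspace(0, 28, 281)
    out = {}
    for dose in (1, 2, 4, 8):
        reg = Regimen(tuple(DoseEvent(d, dose * 1000.0)
                            for d in (0, 7, 14, 21)), 28.0)
        out[dose] = (
            simulate_acute(pop.acute, pop.pk, reg, t).values,
            simulate_chronic(pop.chronic, pop.pk, reg, t).values,
        )
    return out


class TestDoseMonotonicity:
    def test_acute_score_nondecreasing_in_dose(self, sweep):
        doses = sorted(sweep)
        for d1, d2 in zip(doses, doses[1:]):
            assert np.all(sweep[d2][0] - sweep[d1][0] >= -1e-9)

    def test_chronic_threshold_nonincreasing_in_dose(self, sweep):
        doses = sorted(sweep)
        for d1, d2 in zip(doses, doses[1:]):
            assert np.all(sweep[d2][1] - sweep[d1][1] <= 1e-9)
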
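"""Structural-model unit and property tests.

The closed-form tri-exponential solution and the adaptive ODE
integrator are written independently; their agreement is the central
oracle for everything downstream.
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mitipkpd as m
from mitipkpd.model_core import DegenerateEigenvalueError


def make_pk(**kw):
    base = dict(ka=9.57, v=6.15, v2=104.69, cl=0.03, cl2=9.85, tlag=0.09)
    base.update(kw)
    return m.StructuralPKParams(**base)


def make_pd(**kw):
    base = dict(ke0=7.47, ic50=1.13, gamma=1.66, e0=4.65)
    base.update(kw)
    return m.StructuralPDParams(**base)


# log-uniform parameter draws over two decades around the typical values
def random_pk(rng):
    f = lambda x: float(x * np.exp(rng.uniform(-np.log(10), np.log(10))))
    return m.StructuralPKParams(
        ka=f(9.57), v=f(6.15), v2=f(104.69), cl=f(0.03), cl2=f(9.85), tlag=float(rng.uniform(0, 0.3))
    )


class TestParameterValidation:
    @pytest.mark.parametrize("field,value", [("ka", 0.0), ("v", -1.0), ("v2", 0.0), ("cl", -0.1), ("tlag", -0.01)])
    def test_invalid_pk_rejected(self, field, value):
        with pytest.raises(ValueError):
            make_pk(**{field: value})

    @pytest.mark.parametrize("field", ["ke0", "ic50", "gamma", "e0"])
    def test_invalid_pd_rejected(self, field):
        with pytest.raises(ValueError):
            make_pd(**{field: 0.0})


class TestDerivatives:
    def test_empty_system_is_stationary(self):
        assert m.derivatives((0, 0, 0, 0), make_pk(), make_pd()) == (0, 0, 0, 0)

    def test_depot_transfer_rate(self):
        # 10 mg in the depot with ka = 9.57/h moves at 95.7 mg/h
        daa, da1, da2, dce = m.derivatives((10, 0, 0, 0), make_pk(), make_pd())
        assert daa == pytest.approx(-95.7)
        assert da1 == pytest.approx(95.7)
        assert da2 == 0 and dce == 0

    def test_no_intercompartmental_gradient(self):
        pk = make_pk()
        a1 = 2.0
        a2 = a1 * pk.v2 / pk.v  # C == C2
        daa, da1, da2, _ = m.derivatives((0, a1, a2, 0), pk, make_pd())
        assert da2 == pytest.approx(0.0)
        assert da1 == pytest.approx(-pk.cl * a1 / pk.v)

    def test_nonfinite_state_rejected(self):
        with pytest.raises(ValueError):
            m.derivatives((np.nan, 0, 0, 0), make_pk(), make_pd())


class TestInhibitoryEffect:
    def test_baseline_and_half_maximum(self):
        pd_ = make_pd()
        assert m.inhibitory_effect(0.0, pd_) == pytest.approx(pd_.e0)
        assert m.inhibitory_effect(pd_.ic50, pd_) == pytest.approx(pd_.e0 / 2)

    def test_three_fold_ic50_at_unit_hill(self):
        pd_ = make_pd(gamma=1.0)
        assert m.inhibitory_effect(3 * pd_.ic50, pd_) == pytest.approx(pd_.e0 / 4)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            m.inhibitory_effect(-0.1, make_pd())

    @given(st.floats(1e-6, 50.0), st.floats(1e-6, 50.0))
    def test_strictly_decreasing_in_ce(self, a, b):
        lo, hi = sorted((a, b))
        pd_ = make_pd()
        if hi > lo:
            assert m.inhibitory_effect(hi, pd_) < m.inhibitory_effect(lo, pd_)

    @given(st.floats(0.0, 50.0))
    def test_bounded_by_baseline(self, ce):
        pd_ = make_pd()
        e = m.inhibitory_effect(ce, pd_)
        assert 0 < e <= pd_.e0

    @given(st.floats(0.3, 8.0), st.floats(0.3, 8.0))
    def test_hill_exponent_steepens_curve(self, g1, g2):
        lo, hi = sorted((g1, g2))
        if hi - lo < 1e-9:
            return
        # above the IC50 a larger Hill exponent suppresses more,
        # below it suppresses less
        above = make_pd(gamma=lo), make_pd(gamma=hi)
        assert m.inhibitory_effect(2 * 1.13, above[1]) < m.inhibitory_effect(2 * 1.13, above[0])
        assert m.inhibitory_effect(0.5 * 1.13, above[1]) > m.inhibitory_effect(0.5 * 1.13, above[0])


class TestAnalyticCentralConc:
    def test_zero_at_lag(self):
        pk = make_pk()
        assert m.analytic_central_conc(pk, 10.0, pk.tlag) == 0.0

    def test_one_compartment_limit_is_bateman(self):
        # cl2 -> 0 reduces to the classic first-order absorption solution
        pk = make_pk(cl2=1e-12, cl=7.8, tlag=0.0)
        k10 = pk.cl / pk.v
        t = np.array([0.25, 0.5, 1.0, 2.0])
        bateman = 10.0 * pk.ka / (pk.v * (pk.ka - k10)) * (np.exp(-k10 * t) - np.exp(-pk.ka * t))
        np.testing.assert_allclose(m.analytic_central_conc(pk, 10.0, t), bateman, rtol=1e-6)

    def test_degenerate_absorption_rate_raises(self):
        pk = make_pk(cl2=1e-9, cl=7.8)
        alpha, _ = m.disposition_rates(pk.cl, pk.v, pk.cl2, pk.v2)
        with pytest.raises(DegenerateEigenvalueError):
            m.analytic_central_conc(make_pk(ka=float(alpha), cl2=1e-9, cl=7.8), 10.0, 1.0)

    def test_matches_numeric_solution_on_random_parameters(self):
        rng = np.random.default_rng(11)
        pd_ = make_pd()
        t = np.linspace(0.0, 3.0, 25)
        checked = 0
        for _ in range(100):
            pk = random_pk(rng)
            try:
                analytic = m.analytic_central_conc(pk, 10.0, t)
            except DegenerateEigenvalueError:
                continue
            numeric = m.simulate_profile(pk, pd_, 10.0, t, method="numeric").c
            np.testing.assert_allclose(numeric, analytic, rtol=1e-6, atol=1e-6 * max(analytic.max(), 1e-12))
            checked += 1
        assert checked >= 95  # degeneracies are measure-zero


class TestSimulateProfile:
    def test_zero_dose_is_flatline_at_baseline(self):
        prof = m.simulate_profile(make_pk(), make_pd(), 0.0, np.linspace(0, 3, 7))
        assert np.all(prof.c == 0) and np.all(prof.aa == 0)
        np.testing.assert_allclose(prof.e, make_pd().e0)

    def test_lag_contract(self):
        pk = make_pk(tlag=0.5)
        pd_ = make_pd()
        times = np.array([0.0, 0.1, 0.3, 0.49, 0.5, 0.6, 1.0])
        prof = m.simulate_profile(pk, pd_, 10.0, times)
        pre = times <= pk.tlag
        assert np.all(prof.c[pre] == 0)
        np.testing.assert_allclose(prof.e[pre], pd_.e0)
        assert np.all(prof.c[~pre] > 0)

    @pytest.mark.parametrize("method", ["numeric", "analytic"])
    def test_type_invariants(self, method):
        pk, pd_ = make_pk(), make_pd()
        times = np.linspace(0, 3, 40)
        prof = m.simulate_profile(pk, pd_, 10.0, times, method=method)
        np.testing.assert_allclose(prof.c, prof.a1 / pk.v, rtol=1e-12)
        np.testing.assert_allclose(prof.c2, prof.a2 / pk.v2, rtol=1e-12)
        assert np.all(prof.aa >= 0) and np.all(prof.a1 >= 0) and np.all(prof.a2 >= 0)
        assert np.all(prof.e > 0) and np.all(prof.e <= pd_.e0)
        assert np.max(prof.mass_balance_error(10.0)) < 1e-6 * 10.0

    def test_numeric_agrees_with_analytic(self):
        pk, pd_ = make_pk(), make_pd()
        times = np.linspace(0, 3, 60)
        num = m.simulate_profile(pk, pd_, 10.0, times, method="numeric")
        ana = m.simulate_profile(pk, pd_, 10.0, times, method="analytic")
        scale = max(ana.c.max(), 1e-12)
        np.testing.assert_allclose(num.c, ana.c, rtol=1e-6, atol=1e-6 * scale)
        np.testing.assert_allclose(num.ce, ana.ce, rtol=1e-5, atol=1e-6 * scale)

    def test_mass_balance_on_random_parameters(self):
        rng = np.random.default_rng(5)
        pd_ = make_pd()
        times = np.linspace(0, 6, 30)
        for _ in range(20):
            pk = random_pk(rng)
            prof = m.simulate_profile(pk, pd_, 10.0, times, method="numeric")
            assert np.max(prof.mass_balance_error(10.0)) < 1e-6 * 10.0

    def test_lag_shift_invariance(self):
        # shifting tlag by delta shifts the post-lag profile exactly
        pd_ = make_pd()
        delta = 0.35
        t = np.linspace(0, 2.0, 21)
        a = m.simulate_profile(make_pk(tlag=0.1), pd_, 10.0, t, method="analytic")
        b = m.simulate_profile(make_pk(tlag=0.1 + delta), pd_, 10.0, t + delta, method="analytic")
        np.testing.assert_allclose(b.c, a.c, rtol=1e-12, atol=1e-15)
        np.testing.assert_allclose(b.ce, a.ce, rtol=1e-12, atol=1e-15)

    def test_effect_site_equilibrates_to_plasma(self):
        # no elimination: Ce -> C as the system reaches steady state
        pk = make_pk(cl=0.0)
        pd_ = make_pd()
        t = np.array([0.0, 24.0, 48.0])
        prof = m.simulate_profile(pk, pd_, 10.0, t, method="numeric")
        assert abs(prof.ce[-1] - prof.c[-1]) < 1e-6 * prof.c[-1]

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError):
            m.simulate_profile(make_pk(), make_pd(), 10.0, [0.5, 0.1])
        with pytest.raises(ValueError):
            m.simulate_profile(make_pk(), make_pd(), 10.0, [-0.5, 0.1])
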
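"""Non-compartmental analysis against closed-form oracles and exact identities."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mitipkpd as m
from mitipkpd.nca import NCAResult, summarize_nca

STUDY_GRID = np.asarray(m.SAMPLING_TIMES)


class TestTerminalSlope:
    def test_exact_monoexponential(self):
        t = np.array([1.0, 1.5, 2.0, 3.0])
        c = 10 * np.exp(-0.5 * t)
        lam, r2, n, ok = m.terminal_slope(t, c)
        assert ok and n == 3  # Cmax (first point) is excluded
        assert lam == pytest.approx(0.5, rel=1e-12)
        assert r2 == pytest.approx(1.0)
        assert math.log(2) / lam == pytest.approx(1.386, abs=5e-4)

    def test_flat_profile_not_estimable(self):
        t = np.array([0.5, 1.0, 2.0, 3.0])
        res = m.terminal_slope(t, np.full(4, 2.0))
        assert not res.estimable

    def test_too_few_points_not_estimable(self):
        res = m.terminal_slope(np.array([0.0, 1.0, 2.0]), np.array([0.0, 5.0, 2.0]))
        assert not res.estimable

    def test_two_compartment_slope_approaches_smallest_eigenvalue(self):
        # late-window log-linear slope converges on the terminal eigenvalue
        pk = m.StructuralPKParams(ka=9.57, v=6.15, v2=104.69, cl=7.8, cl2=9.85, tlag=0.0)
        _, beta = m.disposition_rates(pk.cl, pk.v, pk.cl2, pk.v2)
        t = np.linspace(40.0, 60.0, 9)
        c = m.analytic_central_conc(pk, 10.0, t)
        lam, _, _, ok = m.terminal_slope(t, c)
        assert ok
        assert lam == pytest.approx(float(beta), rel=0.01)


class TestAucLast:
    def test_triangle_area_linear_rule(self):
        assert m.auc_last([0, 1, 2], [0, 2, 1], rule="linear") == pytest.approx(2.5)

    def test_accumulation_stops_at_last_positive_concentration(self):
        # a trailing zero is below the limit of quantification and is
        # excluded: the area runs only to the last positive concentration
        assert m.auc_last([0, 1, 2], [0, 2, 0], rule="linear") == pytest.approx(1.0)

    def test_log_trapezoid_segment(self):
        expected = (10 - 5) / math.log(10 / 5)
        assert m.auc_last([0, 1], [10, 5], rule="linuplogdown") == pytest.approx(expected)
        assert expected == pytest.approx(7.2135, abs=1e-4)

    def test_dense_exponential_matches_integral(self):
        t = np.linspace(0, 6, 400)
        c = 8 * np.exp(-0.7 * t)
        exact = 8 / 0.7 * (1 - math.exp(-0.7 * 6))
        assert m.auc_last(t, c, rule="linear") == pytest.approx(exact, rel=1e-3)
        assert m.auc_last(t, c, rule="linuplogdown") == pytest.approx(exact, rel=1e-4)

    def test_refinement_improves_linear_rule(self):
        # halving the sampling interval never moves the linear AUC away
        # from the analytic integral on a convex decaying profile
        exact = 8 / 0.7 * (1 - math.exp(-0.7 * 6))
        errors = []
        for n in (7, 13, 25, 49):
            t = np.linspace(0, 6, n)
            errors.append(abs(m.auc_last(t, 8 * np.exp(-0.7 * t), rule="linear") - exact))
        assert all(e2 <= e1 for e1, e2 in zip(errors, errors[1:]))

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(ValueError):
            m.auc_last([1.0], [2.0])


class TestNcaSubject:
    def test_monoexponential_identities_on_study_grid(self):
        v, k = 20.0, 0.41
        c = (10.0 / v) * np.exp(-k * STUDY_GRID)
        res = m.nca_subject(STUDY_GRID, c, dose=10.0)
        assert res.cl_f == pytest.approx(v * k, rel=0.02)
        assert res.vd_f == pytest.approx(v, rel=0.02)
        assert res.t_half == pytest.approx(math.log(2) / k, rel=0.02)

    def test_trailing_zero_excluded_tail_extrapolates_from_last_positive(self):
        t = np.array([0.0, 0.5, 1.0, 1.5, 2.0, 3.0])
        c = np.array([0.0, 4.0, 2.0, 1.0, 0.5, 0.0])
        res = m.nca_subject(t, c, dose=10.0)
        # Clast is the last positive concentration (0.5 at t = 2 h)
        assert res.auc_inf == pytest.approx(res.auc_last + 0.5 / res.lambda_z)

    def test_tmax_tie_takes_earlier_time(self):
        t = np.array([0.0, 0.5, 1.0, 2.0, 3.0])
        c = np.array([0.0, 5.0, 5.0, 2.0, 1.0])
        res = m.nca_subject(t, c, dose=10.0)
        assert res.tmax == 0.5

    def test_lambda_z_not_estimable_still_reports_observed_quantities(self):
        t = np.array([0.0, 0.5, 1.0])
        c = np.array([0.0, 5.0, 2.0])
        res = m.nca_subject(t, c, dose=10.0)
        assert not res.lambda_z_estimable
        assert math.isnan(res.cl_f) and math.isnan(res.t_half)
        assert res.cmax == 5.0 and res.auc_last > 0

    @given(st.floats(0.2, 2.0), st.floats(5.0, 50.0))
    def test_exact_identities(self, k, v):
        c = (10.0 / v) * np.exp(-k * STUDY_GRID)
        res = m.nca_subject(STUDY_GRID, c, dose=10.0)
        assert res.t_half * res.lambda_z == pytest.approx(math.log(2), rel=1e-12)
        assert res.vd_f * res.lambda_z == pytest.approx(res.cl_f, rel=1e-12)
        assert 0 < res.pct_auc_ratio <= 100.0
        assert res.auc_inf >= res.auc_last


class TestSummary:
    def test_single_subject(self):
        c = 5 * np.exp(-0.5 * STUDY_GRID)
        res = m.nca_subject(STUDY_GRID, c, dose=10.0)
        s = summarize_nca([res])
        assert s.loc["cmax", "mean"] == pytest.approx(res.cmax)
        assert s.loc["cmax", "sd"] == 0.0

    def test_tmax_median_and_range(self):
        mk = lambda tmax: NCAResult(
            lambda_z=0.5, t_half=math.log(2) / 0.5, tmax=tmax, cmax=1.0, auc_last=1.0,
            auc_inf=1.1, pct_auc_ratio=90.9, cl_f=9.0, vd_f=18.0, n_lambda_points=3,
            r_squared=1.0, lambda_z_estimable=True,
        )
        s = summarize_nca([mk(0.17), mk(0.50)])
        assert s.loc["tmax", "median"] == pytest.approx(0.335)
        assert s.loc["tmax", "min"] == 0.17 and s.loc["tmax", "max"] == 0.50

    def test_study_level_schema(self, small_dataset):
        table, summary = m.nca_study(small_dataset)
        assert len(table) == 18
        for name in ("t_half", "tmax", "cl_f", "vd_f", "cmax", "auc_last", "auc_inf", "pct_auc_ratio"):
            assert name in summary.index
        text = m.format_nca_summary(summary)
        assert "Cmax (ng/mL)" in text and "Tmax (h)" in text
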
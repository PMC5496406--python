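"""Estimation machinery against independent likelihood oracles.

The FOCE approximation is checked against (a) a hand-written normal
joint density and (b) exact marginalisation of the random effect by
adaptive quadrature on toy problems small enough to integrate.
"""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

import mitipkpd as m
from mitipkpd.estimation import _FOCESession


def toy_spec(reference_spec, **kw):
    """Reference typical values with only the requested random effects."""
    omega = kw.pop("omega", {})
    return m.PopulationSpec(tv=reference_spec.tv, omega=omega, **kw)


def one_subject_dataset(spec, times=(0.25, 0.5, 1.0, 2.0), seed=5, kind="drug_conc"):
    design = m.StudyDesign(n_subjects=1, pk_times=(0.0,) + tuple(times), pd_times=(0.0,) + tuple(times))
    return m.simulate_study(spec, design, seed=seed)


class TestIndividualJointLoglik:
    def test_matches_handwritten_normal_density(self, reference_spec):
        # independent re-implementation of the same formula on a toy subject
        spec = toy_spec(reference_spec, omega={"ka": 0.4}, sigma_pk=0.12)
        ds = one_subject_dataset(spec)
        eta = {"ka": 0.3}
        got = m.individual_joint_loglik(spec, ds, eta, stage="pk")

        sub = ds.for_subject(ds.subjects[0])
        obs = sub.observations_of("drug_conc").sort_values("time")
        obs = obs[(obs["time"] > 0) & ~obs["blq"]]
        pk, _ = m.realize_individual(spec, eta)
        f = m.central_concentration(
            obs["time"].to_numpy(), 10.0, pk.ka, pk.v, pk.v2, pk.cl, pk.cl2, pk.tlag
        )
        v = (spec.sigma_pk * np.maximum(f, 1e-6)) ** 2
        log_lik = -0.5 * np.sum((obs["value"].to_numpy() - f) ** 2 / v + np.log(2 * np.pi * v))
        log_prior = -0.5 * (math.log(2 * math.pi * 0.4) + 0.3**2 / 0.4)
        assert got == pytest.approx(log_lik + log_prior, rel=1e-10)

    def test_zero_eta_zero_residual_has_no_penalty(self, reference_spec):
        spec = toy_spec(reference_spec, omega={"e0": 0.05}, sigma_pd=0.2)
        ds = one_subject_dataset(
            m.PopulationSpec(tv=spec.tv, omega={}, sigma_pk=1e-12, sigma_pd=1e-12)
        )
        pk_ind = pd.DataFrame(
            {k: [spec.tv[k]] for k in ("ka", "v", "v2", "cl", "cl2", "tlag")},
            index=pd.Index(ds.subjects, name="subject"),
        )
        # with eta = 0 and data equal to the prediction, only the
        # normalisation constants remain
        got = m.individual_joint_loglik(spec, ds, {"e0": 0.0}, stage="pd", pk_individual=pk_ind)
        n_obs = len(ds.observations_of("glucose"))
        expected = -0.5 * n_obs * math.log(2 * math.pi * spec.sigma_pd**2)
        expected += -0.5 * math.log(2 * math.pi * 0.05)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_eta_for_inactive_effect_rejected(self, reference_spec):
        spec = toy_spec(reference_spec, omega={"ka": 0.4})
        ds = one_subject_dataset(spec)
        with pytest.raises(ValueError):
            m.individual_joint_loglik(spec, ds, {"v": 0.1}, stage="pk")


class TestFoceObjectiveOracles:
    @pytest.mark.parametrize("omega_ka", [0.05, 0.3])
    def test_within_one_percent_of_quadrature_pk(self, reference_spec, omega_ka):
        # 1 subject, 1 random effect: exact marginalisation is tractable.
        # The full sampling grid keeps the conditional posterior sharp, the
        # regime where the Laplace approximation is quantitatively accurate.
        spec = toy_spec(reference_spec, omega={"ka": omega_ka}, sigma_pk=0.10)
        times = (0.17, 0.25, 0.33, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0)
        ds = one_subject_dataset(spec, times=times, seed=11)
        foce = m.foce_objective(spec, ds, "pk")

        sub_obs = ds.observations_of("drug_conc")
        sub_obs = sub_obs[(sub_obs["time"] > 0) & ~sub_obs["blq"]].sort_values("time")
        t = sub_obs["time"].to_numpy()
        y = sub_obs["value"].to_numpy()
        tv = spec.tv

        def conditional_lik(eta):
            f = m.central_concentration(
                t, 10.0, tv["ka"] * math.exp(eta), tv["v"], tv["v2"], tv["cl"], tv["cl2"], tv["tlag"]
            )
            v = (spec.sigma_pk * np.maximum(f, 1e-6)) ** 2
            return math.exp(-0.5 * np.sum((y - f) ** 2 / v + np.log(2 * np.pi * v)))

        sd = math.sqrt(omega_ka)
        marginal, _ = quad(
            lambda e: conditional_lik(e) * math.exp(-0.5 * e * e / omega_ka) / (sd * math.sqrt(2 * math.pi)),
            -8 * sd, 8 * sd, limit=200,
        )
        exact = -2.0 * math.log(marginal)
        assert foce == pytest.approx(exact, rel=0.01)

    def test_within_one_percent_of_quadrature_pd(self, reference_spec):
        spec = toy_spec(reference_spec, omega={"e0": 0.01}, sigma_pd=0.15)
        ds = one_subject_dataset(spec, seed=13)
        pk_ind = pd.DataFrame(
            {k: [spec.tv[k]] for k in ("ka", "v", "v2", "cl", "cl2", "tlag")},
            index=pd.Index(ds.subjects, name="subject"),
        )
        foce = m.foce_objective(spec, ds, "pd", pk_individual=pk_ind)

        obs = ds.observations_of("glucose").sort_values("time")
        t = obs["time"].to_numpy()
        y = obs["value"].to_numpy()
        tv = spec.tv
        ce = m.effect_site_concentration(
            t, 10.0, tv["ka"], tv["v"], tv["v2"], tv["cl"], tv["cl2"], tv["tlag"], tv["ke0"]
        )

        def conditional_lik(eta):
            e0 = tv["e0"] * math.exp(eta)
            frac = ce ** tv["gamma"] / (tv["ic50"] ** tv["gamma"] + ce ** tv["gamma"])
            f = e0 * (1 - frac)
            v = spec.sigma_pd**2
            return math.exp(-0.5 * np.sum((y - f) ** 2 / v + np.log(2 * np.pi * v)))

        sd = 0.1
        marginal, _ = quad(
            lambda e: conditional_lik(e) * math.exp(-0.5 * e * e / sd**2) / (sd * math.sqrt(2 * math.pi)),
            -8 * sd, 8 * sd, limit=200,
        )
        exact = -2.0 * math.log(marginal)
        assert foce == pytest.approx(exact, rel=0.01)

    def test_small_omega_approaches_naive_pooled(self, reference_spec):
        spec = toy_spec(reference_spec, omega={"ka": 1e-7}, sigma_pk=0.10)
        ds = m.simulate_study(spec, m.StudyDesign(n_subjects=4), seed=3)
        foce = m.foce_objective(spec, ds, "pk")
        pooled_session = _FOCESession(ds, spec, "pk", pooled=True)
        pooled = pooled_session.neg2ll(spec)
        # degenerate random effect: FOCE collapses onto the pooled deviance
        assert foce == pytest.approx(pooled, abs=0.5)

    def test_duplicating_subjects_doubles_the_objective(self, reference_spec):
        spec = toy_spec(reference_spec, omega={"ka": 0.3, "v": 0.03}, sigma_pk=0.10)
        ds = m.simulate_study(spec, m.StudyDesign(n_subjects=3), seed=21)
        doses = pd.concat([ds.doses, ds.doses.assign(subject=ds.doses["subject"] + "x")])
        obs = pd.concat([ds.observations, ds.observations.assign(subject=ds.observations["subject"] + "x")])
        doubled = m.StudyDataset(doses, obs)
        one = m.foce_objective(spec, ds, "pk")
        two = m.foce_objective(spec, doubled, "pk")
        assert two == pytest.approx(2 * one, rel=1e-8)

    def test_invariance_to_relabeling_and_row_order(self, reference_spec):
        spec = toy_spec(reference_spec, omega={"ka": 0.3}, sigma_pk=0.10)
        ds = m.simulate_study(spec, m.StudyDesign(n_subjects=5), seed=17)
        base = m.foce_objective(spec, ds, "pk")
        relabel = {s: f"z{9 - int(s)}" for s in ds.subjects}
        shuffled = m.StudyDataset(
            ds.doses.assign(subject=ds.doses["subject"].map(relabel)).sample(frac=1, random_state=1),
            ds.observations.assign(subject=ds.observations["subject"].map(relabel)).sample(frac=1, random_state=2),
        )
        assert m.foce_objective(spec, shuffled, "pk") == pytest.approx(base, rel=1e-9)

    def test_empty_stage_observations_rejected(self, reference_spec):
        spec = toy_spec(reference_spec, omega={"ka": 0.3})
        ds = one_subject_dataset(spec)
        drug_only = m.StudyDataset(ds.doses, ds.observations_of("drug_conc"))
        with pytest.raises(m.EstimationError):
            m.foce_objective(spec, drug_only, "pd", pk_individual=pd.DataFrame())


class TestEtaShrinkage:
    def _frame(self, values):
        return pd.DataFrame({"ka": values})

    def test_total_shrinkage_when_all_ebes_zero(self):
        s = m.eta_shrinkage(self._frame([0.0, 0.0, 0.0, 0.0]), {"ka": 0.4})
        assert s["ka"] == pytest.approx(1.0)

    def test_zero_shrinkage_when_sd_matches_omega(self):
        vals = np.array([-1.0, 0.0, 1.0])
        om = float(np.std(vals, ddof=1)) ** 2
        s = m.eta_shrinkage(self._frame(vals), {"ka": om})
        assert s["ka"] == pytest.approx(0.0, abs=1e-12)

    def test_rule_threshold_value(self):
        om = 0.5
        vals = np.array([-1.0, 0.0, 1.0])
        vals = vals / np.std(vals, ddof=1) * 0.4 * math.sqrt(om)
        s = m.eta_shrinkage(self._frame(vals), {"ka": om})
        assert s["ka"] == pytest.approx(0.6)
        assert s["ka"] > 0.5  # the exclusion rule would drop this eta

    def test_fewer_than_three_subjects_rejected(self):
        with pytest.raises(ValueError):
            m.eta_shrinkage(self._frame([0.1, 0.2]), {"ka": 0.4})


class TestFitSelfConsistency:
    def test_noiseless_pooled_recovery_within_a_tenth_percent(self):
        # identifiable preset (raised clearance), long sampling window,
        # no variability: the fit must return to the generating values
        spec = m.nca_consistent_population()
        truth = m.PopulationSpec(tv=spec.tv, omega={}, sigma_pk=0.01, sigma_pd=0.15)
        times = (0.0, 0.08, 0.17, 0.25, 0.33, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 5.0, 8.0, 12.0, 24.0)
        design = m.StudyDesign(n_subjects=8, pk_times=times, pd_times=times)
        noiseless = m.PopulationSpec(tv=spec.tv, omega={}, sigma_pk=1e-12, sigma_pd=1e-12)
        ds = m.simulate_study(noiseless, design, seed=1)
        start = truth.evolve(tv={
            "ka": truth.tv["ka"] * 1.2, "v": truth.tv["v"] * 0.8, "v2": truth.tv["v2"] * 1.2,
            "cl": truth.tv["cl"] * 0.85, "cl2": truth.tv["cl2"] * 1.2, "tlag": truth.tv["tlag"] * 0.8,
        })
        fit = m.fit_population_pk(ds, start, fixed=("sigma_pk",), max_evals=12000, xtol=1e-9, ftol=1e-12)
        assert fit.converged
        for name in ("ka", "v", "v2", "cl", "cl2", "tlag"):
            assert fit.estimates.tv[name] == pytest.approx(truth.tv[name], rel=1e-3), name

    def test_pd_stage_requires_converged_pk(self, reference_spec, small_dataset):
        bad = m.FitResult(
            estimates=reference_spec, stage="pk", ebe=pd.DataFrame(), objective=0.0,
            converged=False, n_evaluations=1, shrinkage={},
        )
        with pytest.raises(m.EstimationError):
            m.fit_population_pd(small_dataset, bad, reference_spec)

    def test_null_drug_glucose_recovers_baseline_and_flags_ic50(self, reference_spec):
        # glucose simulated with zero effect-site exposure: E0 is the
        # sample mean, the IC50 cannot be identified and must be flagged
        spec = m.PopulationSpec(tv=reference_spec.tv, omega={"e0": 0.002}, sigma_pd=0.1)
        null_drug = spec.evolve(tv={"ke0": 1e-3})  # effectively no biophase exposure
        design = m.StudyDesign(n_subjects=20)
        ds = m.simulate_study(null_drug, design, seed=9)
        pk_fit = m.evaluate_spec(spec, ds, "pk")
        fit = m.fit_population_pd(ds, pk_fit, null_drug.evolve(tv={"ke0": 1e-3 * 1.2}),
                                  fixed=("tv_ke0", "tv_ic50", "tv_gamma"), max_evals=2000)
        gluc = ds.observations_of("glucose")["value"]
        assert fit.estimates.tv["e0"] == pytest.approx(float(gluc.mean()), rel=0.01)
        assert any("ic50" in msg for msg in fit.messages)
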
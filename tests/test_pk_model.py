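"""One-compartment PK stage: prediction, Laplace fit, EBEs, IWRES."""

import warnings

import numpy as np
import pandas as pd
import pytest

from adahmm import (
    ADAGenerativeParams,
    Observation,
    PKModelParams,
    PopPKModel,
    StudyDesign,
    SubjectSeries,
    compute_ebes,
    compute_iwres,
    fit_first_occasion,
    predict_concentration,
    simulate_cohort,
)
from adahmm.pk import _map_etas, _neg_joint, _PKFitData

from .oracles import ode_concentration

PARAMS = PKModelParams()

# rich-sampling Q4W design used for recovery and residual-distribution
# checks: sixteen occasion-1 samples (phase-I-like density) so the
# empirical-Bayes individual parameters are near-exact, plus four later
# occasions where the residuals are evaluated out of sample
RICH = StudyDesign(
    "RICH",
    260,
    dose_mg=(400.0,),
    interval_days=28.0,
    sampling_days=(
        1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 9.0, 11.0, 13.0, 15.0, 17.0,
        19.0, 21.0, 24.0, 27.0, 35.0, 42.0, 49.0, 56.0,
    ),
)
NO_ADA = ADAGenerativeParams(pi12_true=0.0, pi21_true=0.0)


@pytest.fixture(scope="module")
def rich_cohort():
    from adahmm.io import frame_to_subjects

    dataset, truth = simulate_cohort([RICH], PARAMS, NO_ADA, seed=101)
    return frame_to_subjects(dataset), truth


@pytest.fixture(scope="module")
def rich_fit(rich_cohort):
    subjects, _ = rich_cohort
    model = PopPKModel(fixed=("ka", "theta_wt_cl", "theta_jp_cl", "theta_jp_v")).fit(subjects)
    return model


class TestPredictConcentration:
    def test_zero_before_absorption_starts(self):
        assert predict_concentration(PARAMS, (0.35, 7.0), [(0.0, 400.0, 1)], 0.0) == 0.0

    def test_superposition_identity(self):
        ind = (0.35, 7.0)
        two = predict_concentration(PARAMS, ind, [(0.0, 400.0, 1), (14.0, 400.0, 2)], 21.0)
        one_a = predict_concentration(PARAMS, ind, [(0.0, 400.0, 1)], 21.0)
        one_b = predict_concentration(PARAMS, ind, [(0.0, 400.0, 1)], 7.0)
        assert two == pytest.approx(one_a + one_b, rel=1e-10)

    def test_many_dose_superposition(self):
        ind = (0.4, 6.0)
        doses = [(14.0 * k, 200.0, k + 1) for k in range(6)]
        t = np.array([3.0, 40.0, 83.0])
        total = predict_concentration(PARAMS, ind, doses, t)
        parts = sum(predict_concentration(PARAMS, ind, [d], t) for d in doses)
        np.testing.assert_allclose(total, parts, rtol=1e-10)

    def test_matches_ode_solver_oracle(self):
        p = PKModelParams(cl_pop=0.5, v_pop=5.0, ka=0.5)
        got = predict_concentration(p, (0.5, 5.0), [(0.0, 400.0, 1)], 10.0)
        want = ode_concentration([(0.0, 400.0, 1)], 0.5, 5.0, 0.5, 10.0)
        assert got == pytest.approx(want, rel=1e-6)

    def test_multidose_ode_oracle(self):
        p = PKModelParams(cl_pop=0.35, v_pop=7.0, ka=0.35)
        doses = [(0.0, 400.0, 1), (14.0, 400.0, 2), (28.0, 200.0, 3)]
        t = [5.0, 20.0, 33.0, 60.0]
        got = predict_concentration(p, (0.35, 7.0), doses, t)
        want = ode_concentration(doses, 0.35, 7.0, 0.35, t)
        np.testing.assert_allclose(got, want, rtol=1e-6)

    def test_flipflop_limit_is_continuous(self):
        """ka == CL/V must use the analytic limit, matching nearby ka."""
        cl, v = 0.5, 5.0
        ke = cl / v
        p_eq = PKModelParams(cl_pop=cl, v_pop=v, ka=ke)
        p_near = PKModelParams(cl_pop=cl, v_pop=v, ka=ke * (1 + 1e-9))
        at = predict_concentration(p_eq, (cl, v), [(0.0, 400.0, 1)], 8.0)
        near = predict_concentration(p_near, (cl, v), [(0.0, 400.0, 1)], 8.0)
        assert np.isfinite(at) and at > 0
        assert at == pytest.approx(near, rel=1e-6)

    def test_washout_to_zero(self):
        c = predict_concentration(PARAMS, (0.35, 7.0), [(0.0, 400.0, 1)], 2000.0)
        assert 0 <= c < 1e-10

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            predict_concentration(PARAMS, (-1.0, 7.0), [(0.0, 400.0, 1)], 1.0)
        with pytest.raises(ValueError):
            predict_concentration(PARAMS, (0.35, 7.0), [(0.0, 400.0, 1)], -1.0)


class TestFit:
    def test_population_recovery_on_rich_design(self, rich_fit):
        p = rich_fit.params_
        assert rich_fit.converged_
        assert p.cl_pop == pytest.approx(PARAMS.cl_pop, rel=0.10)
        assert p.v_pop == pytest.approx(PARAMS.v_pop, rel=0.10)
        assert p.sigma_prop == pytest.approx(PARAMS.sigma_prop, rel=0.25)

    def test_no_iiv_reduces_to_pooled_fit(self, rich_cohort):
        """With both IIV variances fixed at zero the Laplace marginal
        collapses to the pooled proportional-error log-likelihood."""
        subjects, _ = rich_cohort
        init = PKModelParams(omega2_cl=0.0, omega2_v=0.0)
        params, info = fit_first_occasion(
            subjects[:60],
            init=init,
            fixed=("ka", "theta_wt_cl", "theta_jp_cl", "theta_jp_v", "omega2_cl", "omega2_v"),
        )
        data = _PKFitData(subjects[:60])
        pooled = -_neg_joint(data, params, np.zeros((data.n, 2))).sum()
        assert info["loglik"] == pytest.approx(pooled, abs=1e-8)

    def test_unidentifiable_covariate_fixed_at_zero(self):
        """Equal weights leave the weight exponent unidentifiable; the
        fit must still succeed with it held at zero."""
        rng = np.random.default_rng(4)
        subjects = []
        for i in range(40):
            cl = 0.35 * np.exp(rng.normal(0, 0.2))
            v = 7.0 * np.exp(rng.normal(0, 0.2))
            obs = [
                Observation(t, predict_concentration(PARAMS, (cl, v), [(0.0, 400.0, 1)], t) * (1 + rng.normal(0, 0.1)))
                for t in (2.0, 5.0, 9.0, 14.0, 21.0)
            ]
            subjects.append(SubjectSeries(f"S{i}", [(0.0, 400.0, 1)], obs, weight=70.0))
        init = PKModelParams(theta_wt_cl=0.0)
        params, info = fit_first_occasion(
            subjects, init=init, fixed=("ka", "theta_wt_cl", "theta_jp_cl", "theta_jp_v")
        )
        assert info["converged"]
        assert params.theta_wt_cl == 0.0
        assert params.cl_pop == pytest.approx(0.35, rel=0.15)

    def test_subject_without_occasion1_data_excluded(self, rich_cohort):
        subjects, _ = rich_cohort
        orphan = SubjectSeries(
            "ORPHAN",
            [(0.0, 400.0, 1), (28.0, 400.0, 2)],
            [Observation(30.0, 20.0)],
        )
        with pytest.warns(UserWarning, match="ORPHAN"):
            fit_first_occasion(
                subjects[:30] + [orphan],
                fixed=("ka", "theta_wt_cl", "theta_jp_cl", "theta_jp_v"),
            )


class TestEBE:
    def test_full_shrinkage_at_zero_omega(self, rich_cohort):
        subjects, _ = rich_cohort
        p = PKModelParams(omega2_cl=0.0, omega2_v=0.0)
        ebes = compute_ebes(p, subjects[:10])
        for s in subjects[:10]:
            cl_i, v_i = ebes.lookup(s.subject_id)
            assert cl_i == pytest.approx(p.typical_cl(s.weight, s.japanese), rel=1e-12)
            assert v_i == pytest.approx(p.typical_v(s.japanese), rel=1e-12)

    def test_empty_data_subject_gets_typical_value(self):
        s = SubjectSeries("EMPTY", [(0.0, 400.0, 1)], [Observation(10.0, ada=0.6)], weight=80.0)
        ebes = compute_ebes(PARAMS, [s])
        cl_i, v_i = ebes.lookup("EMPTY")
        assert cl_i == PARAMS.typical_cl(80.0, False)
        assert v_i == PARAMS.typical_v(False)

    def test_rich_low_noise_subject_recovers_truth(self):
        rng = np.random.default_rng(11)
        cl_true, v_true = 0.45, 6.0
        doses = [(0.0, 400.0, 1)]
        obs = [
            Observation(t, predict_concentration(PARAMS, (cl_true, v_true), doses, t) * (1 + rng.normal(0, 0.02)))
            for t in np.linspace(1, 27, 20)
        ]
        s = SubjectSeries("R", doses, obs)
        p = PKModelParams(sigma_prop=0.02)
        cl_i, v_i = compute_ebes(p, [s]).lookup("R")
        assert cl_i == pytest.approx(cl_true, rel=0.02)
        assert v_i == pytest.approx(v_true, rel=0.02)

    def test_large_omega_approaches_individual_least_squares(self):
        """With a diffuse prior the MAP estimate converges to the
        per-subject ML fit (prior contribution vanishes)."""
        rng = np.random.default_rng(12)
        doses = [(0.0, 400.0, 1)]
        obs = [
            Observation(t, predict_concentration(PARAMS, (0.5, 6.5), doses, t) * (1 + rng.normal(0, 0.05)))
            for t in np.linspace(1, 27, 15)
        ]
        s = SubjectSeries("L", doses, obs)
        diffuse = PKModelParams(omega2_cl=100.0, omega2_v=100.0, sigma_prop=0.05)
        cl_map, v_map = compute_ebes(diffuse, [s]).lookup("L")

        # independent per-subject ML via grid-free scipy optimisation
        from scipy.optimize import minimize as sp_min

        y = np.array([o.pk for o in obs])
        t = np.array([o.time for o in obs])

        def nll(x):
            f = predict_concentration(diffuse, (np.exp(x[0]), np.exp(x[1])), doses, t)
            return 0.5 * np.sum(((y - f) / (0.05 * f)) ** 2 + np.log(f**2))

        res = sp_min(nll, [np.log(0.4), np.log(7.0)], method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
        assert cl_map == pytest.approx(np.exp(res.x[0]), rel=1e-3)
        assert v_map == pytest.approx(np.exp(res.x[1]), rel=1e-3)


class TestIWRES:
    def test_exact_fit_gives_zero(self):
        doses = [(0.0, 400.0, 1)]
        t = 10.0
        c = predict_concentration(PARAMS, (PARAMS.typical_cl(70, False), PARAMS.typical_v(False)), doses, t)
        s = SubjectSeries("Z", doses, [Observation(t, c)])
        p = PKModelParams(omega2_cl=0.0, omega2_v=0.0)
        table = compute_iwres(p, compute_ebes(p, [s]), [s])
        assert table["iwres"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_pre_dose_record_flagged(self):
        s = SubjectSeries("P", [(5.0, 400.0, 1)], [Observation(2.0, 0.41, pk_blq=True), Observation(10.0, 15.0)])
        p = PKModelParams(omega2_cl=0.0, omega2_v=0.0)
        table = compute_iwres(p, compute_ebes(p, [s]), [s])
        pre = table[table["time"] == 2.0].iloc[0]
        assert pre["flagged"] and np.isnan(pre["iwres"])
        assert not table[table["time"] == 10.0].iloc[0]["flagged"]

    def test_residuals_unbiased_with_unit_spread(self, rich_cohort, rich_fit):
        """Correctly specified model, no ADA: pooled IWRES should pass a
        mean-zero check and have spread near 1."""
        subjects, _ = rich_cohort
        table = rich_fit.transform(subjects)
        r = table["iwres"].dropna().to_numpy()
        assert len(r) >= 5000
        assert abs(r.mean()) < 3.0 * r.std() / np.sqrt(len(r))
        assert 0.9 <= r.std() <= 1.1

    def test_clearance_inflation_drives_residuals_negative(self):
        """Clearance doubled after ADA onset makes the ADA-blind model
        over-predict: post-onset residuals are negative on average."""
        design = StudyDesign(
            "ONSET",
            150,
            dose_mg=(400.0,),
            interval_days=28.0,
            sampling_days=(1.0, 5.0, 14.0, 21.0, 35.0, 56.0, 84.0, 112.0),
        )
        ada = ADAGenerativeParams(pi12_true=0.15, pi21_true=0.0, cl_inflation_ada=2.0)
        dataset, truth = simulate_cohort([design], PARAMS, ada, seed=55)
        from adahmm.io import frame_to_subjects

        subjects = frame_to_subjects(dataset)
        model = PopPKModel(fixed=("ka", "theta_wt_cl", "theta_jp_cl", "theta_jp_v")).fit(subjects)
        table = model.transform(subjects).merge(truth, on=["subject_id", "time"])
        post = table[table["state"] == 1]["iwres"].dropna()
        pre = table[table["state"] == 0]["iwres"].dropna()
        assert len(post) > 50
        assert post.mean() < -1.0 < pre.mean() - post.mean()
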
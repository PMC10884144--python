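"""Packing, population likelihood, quadrature, fitting and decoupling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from adahmm import (
    EmissionParams,
    MixedHMM,
    TransitionParams,
    decouple_univariate,
    emission_logpdf,
    forward_loglik,
    population_loglik,
    sample_mhmm,
)
from adahmm.estimation import (
    VariantConfig,
    free_param_names,
    pack_params,
    unpack_params,
)
from adahmm.hmm import S_NOADA


class TestVariantConfig:
    @pytest.mark.parametrize(
        "variant, fixed, iiv_m, iiv_t",
        [
            (1, False, True, True),
            (2, True, True, True),
            (3, False, False, True),
            (4, True, False, True),
            (5, False, False, False),
            (6, True, False, False),
        ],
    )
    def test_variant_table(self, variant, fixed, iiv_m, iiv_t):
        cfg = VariantConfig.from_variant(variant)
        assert (cfg.ada_modes_fixed, cfg.iiv_on_modes, cfg.iiv_on_transitions) == (
            fixed,
            iiv_m,
            iiv_t,
        )

    def test_invalid_variant(self):
        with pytest.raises(ValueError):
            VariantConfig.from_variant(7)

    def test_pk_decoupling_drops_ada_parameters(self):
        cfg = decouple_univariate(VariantConfig.from_variant(6), "pk")
        names = free_param_names(cfg)
        assert names == ["mu_pkres_noada", "mu_pkres_ada", "sigma2_pkres", "logit_pi12", "logit_pi21"]

    def test_ada_decoupling_drops_pk_parameters(self):
        cfg = decouple_univariate(VariantConfig.from_variant(6), "ada")
        assert free_param_names(cfg) == ["sigma2_ada", "logit_pi12", "logit_pi21"]


class TestPackUnpack:
    def test_probability_and_variance_midpoints(self):
        cfg = VariantConfig.from_variant(6)
        em = EmissionParams(sigma2_pkres=1.0, sigma2_ada=1.0)
        tp = TransitionParams.from_probs(0.5, 0.5)
        x = pack_params(em, tp, cfg)
        names = free_param_names(cfg)
        assert x[names.index("logit_pi12")] == pytest.approx(0.0, abs=1e-12)
        assert x[names.index("sigma2_pkres")] == pytest.approx(0.0, abs=1e-12)
        em2, tp2 = unpack_params(x, cfg, em, tp)
        assert tp2.pi12 == pytest.approx(0.5, abs=1e-12)
        assert em2.sigma2_pkres == pytest.approx(1.0, abs=1e-12)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        variant=st.integers(1, 6),
        mu=st.floats(-3, 3),
        s2=st.floats(0.05, 5),
        rho=st.floats(-0.9, 0.9),
        p=st.floats(1e-4, 0.5),
        om=st.floats(1e-3, 2),
    )
    def test_round_trip_identity(self, variant, mu, s2, rho, p, om):
        cfg = VariantConfig.from_variant(variant)
        em = EmissionParams(
            mu_pkres_noada=mu,
            mu_pkres_ada=mu - 1,
            sigma2_pkres=s2,
            sigma2_ada=2 * s2,
            rho_noada=rho,
            rho_ada=-rho,
            omega2_mu_pkres=om if cfg.iiv_on_modes else 0.0,
            omega2_mu_ada=om if cfg.iiv_on_modes else 0.0,
        )
        tp = TransitionParams.from_probs(
            p,
            p / 2,
            om if cfg.iiv_on_transitions else 0.0,
            om if cfg.iiv_on_transitions else 0.0,
        )
        x = pack_params(em, tp, cfg)
        em2, tp2 = unpack_params(x, cfg, em, tp)
        np.testing.assert_allclose(pack_params(em2, tp2, cfg), x, atol=1e-12, rtol=0)

    def test_out_of_domain_rejected(self):
        cfg = VariantConfig.from_variant(4)
        em = EmissionParams()
        tp = TransitionParams.from_probs(0.1, 0.1, omega2_pi12=0.0, omega2_pi21=0.5)
        with pytest.raises(ValueError):
            pack_params(em, tp, cfg)  # zero variance cannot go on log scale


class TestPopulationLoglik:
    def test_single_record_chains_to_emission(self, gen_emission, gen_transition):
        X = np.array([[0.4, 1.1]])
        got = population_loglik(
            X, [1], gen_emission, gen_transition, VariantConfig.from_variant(6)
        )
        assert got == pytest.approx(
            emission_logpdf((0.4, 1.1), S_NOADA, gen_emission), abs=1e-12
        )

    def test_zero_omega_equals_no_iiv(self, gen_emission, rng):
        X = rng.normal(0, 1, (9, 2))
        lengths = [3, 3, 3]
        tp = TransitionParams.from_probs(0.1, 0.05)
        ll_iiv_cfg = population_loglik(
            X, lengths, gen_emission, tp, VariantConfig.from_variant(4)
        )
        ll_plain = population_loglik(
            X, lengths, gen_emission, tp, VariantConfig.from_variant(6)
        )
        assert ll_iiv_cfg == pytest.approx(ll_plain, abs=1e-12)

    def test_agq_matches_dense_trapezoid(self, gen_emission):
        """1-D random effect on the onset logit, 3 records, against a
        100k-point trapezoid over +/- 8 prior SDs."""
        tp = TransitionParams.from_probs(0.1, 0.05, omega2_pi12=0.8)
        Y = np.array([[0.2, 0.7], [-1.1, 2.9], [-1.8, 3.5]])
        cfg = VariantConfig.from_variant(4)
        om = np.sqrt(0.8)
        grid = np.linspace(-8 * om, 8 * om, 100_001)
        vals = [
            np.exp(forward_loglik(Y, gen_emission, tp, eta12=e)) * norm.pdf(e, 0, om)
            for e in grid
        ]
        oracle = np.log(np.trapezoid(vals, grid))
        got = population_loglik(Y, [3], gen_emission, tp, cfg)
        assert got == pytest.approx(oracle, abs=1e-6)

    def test_agq_node_count_stability(self, gen_emission):
        tp = TransitionParams.from_probs(0.1, 0.05, omega2_pi12=0.8, omega2_pi21=0.3)
        Y = np.array([[0.2, 0.7], [-1.1, 2.9], [-1.8, 3.5], [0.1, 0.6]])
        cfg = VariantConfig.from_variant(4)
        ll9 = population_loglik(Y, [4], gen_emission, tp, cfg, n_nodes=9)
        ll15 = population_loglik(Y, [4], gen_emission, tp, cfg, n_nodes=15)
        assert abs(ll9 - ll15) < 1e-4

    def test_invariant_to_subject_order(self, gen_emission, gen_transition, rng):
        X = rng.normal(0.5, 1.3, (12, 2))
        cfg = VariantConfig.from_variant(6)
        ll = population_loglik(X, [4, 3, 5], gen_emission, gen_transition, cfg)
        X2 = np.concatenate([X[7:], X[4:7], X[:4]])
        ll2 = population_loglik(X2, [5, 3, 4], gen_emission, gen_transition, cfg)
        assert ll == pytest.approx(ll2, abs=1e-10)

    def test_sequence_factorization_in_degenerate_cases(self, rng):
        """With zero correlation the *emission* factorizes; at the
        sequence level this extends to single-record series and to an
        absorbing chain (pi12 = 0), where the hidden path is pinned."""
        em = EmissionParams(
            mu_pkres_noada=0.3, mu_pkres_ada=-1.6, sigma2_pkres=0.8, sigma2_ada=1.6
        )
        from scipy.special import logit

        tp = TransitionParams(logit_pi12=-np.inf, logit_pi21=float(logit(0.05)))
        cfg = VariantConfig.from_variant(6)
        X = rng.normal(0.3, 1.0, (8, 2))
        lengths = [8]
        ll_biv = population_loglik(X, lengths, em, tp, cfg)
        ll_pk = population_loglik(X, lengths, em, tp, decouple_univariate(cfg, "pk"))
        ll_ada = population_loglik(X, lengths, em, tp, decouple_univariate(cfg, "ada"))
        assert ll_biv == pytest.approx(ll_pk + ll_ada, abs=1e-9)


class TestFit:
    def test_boundary_flag_with_no_transitions(self):
        """A cohort that never leaves S_NOADA pushes pi12 to the lower
        boundary; the fit must flag it rather than fail.  The ADA-only
        decoupling pins the state modes at 0.6 / 2.4, so with tight
        assay noise the production state gets no support at all."""
        em = EmissionParams(
            mu_pkres_noada=0.3, mu_pkres_ada=-1.6, sigma2_pkres=0.8, sigma2_ada=0.09
        )
        tp = TransitionParams.from_probs(1e-12, 0.5)
        X, lengths, states = sample_mhmm(em, tp, 150, 6, random_state=7)
        assert (states == 0).all()
        m = MixedHMM(
            variant=6, univariate="ada", n_multistart=1, compute_se=False, random_state=0
        ).fit(X, lengths)
        assert m.result_.estimates["pi12"] < 1.0 / len(X)
        assert "pi12" in m.boundary_flags_

    def test_mle_dominates_generating_parameters(self, gen_emission, gen_transition):
        X, lengths, _ = sample_mhmm(gen_emission, gen_transition, 300, 8, random_state=5)
        m = MixedHMM(variant=6, n_multistart=1, compute_se=False, random_state=0).fit(
            X, lengths
        )
        ll_gen = population_loglik(
            X, lengths, gen_emission, gen_transition, VariantConfig.from_variant(6)
        )
        assert m.loglik_ >= ll_gen - 1e-6

    def test_fixed_parameters_carry_no_se(self, gen_emission, gen_transition):
        X, lengths, _ = sample_mhmm(gen_emission, gen_transition, 250, 8, random_state=2)
        m = MixedHMM(variant=6, n_multistart=1, compute_se=True, random_state=0).fit(
            X, lengths
        )
        assert "mu_ada_ada" not in m.se_ and "mu_ada_noada" not in m.se_
        assert m.result_.fixed == {"mu_ada_noada": 0.6, "mu_ada_ada": 2.4}
        assert set(m.se_) == set(m.result_.estimates)

    def test_rse_shrinks_with_sample_size(self, gen_emission, gen_transition):
        """Quadrupling the cohort should roughly halve the RSE of the
        onset transition probability (asymptotic 1/sqrt(n))."""
        rses = []
        for n, seed in ((200, 1), (800, 1)):
            X, lengths, _ = sample_mhmm(gen_emission, gen_transition, n, 8, random_state=seed)
            m = MixedHMM(variant=6, n_multistart=1, compute_se=True, random_state=0).fit(
                X, lengths
            )
            rses.append(m.rse_percent_["pi12"])
        ratio = rses[1] / rses[0]
        assert 0.25 < ratio < 0.85

    def test_deterministic_given_seed(self, gen_emission, gen_transition):
        X, lengths, _ = sample_mhmm(gen_emission, gen_transition, 120, 6, random_state=3)
        fits = [
            MixedHMM(variant=6, n_multistart=3, compute_se=False, random_state=42)
            .fit(X, lengths)
            .result_.estimates
            for _ in range(2)
        ]
        assert fits[0] == fits[1]

    def test_ada_only_model_without_signal_decodes_noada(self):
        """A univariate ADA decoupling on a series stuck at the LLOQ has
        no evidence for production."""
        m = MixedHMM(variant=6, univariate="ada")
        m.config_ = m._config()
        m.emission_, m.transition_ = m._initial_params(m.config_)
        X = np.column_stack([np.full(6, np.nan), np.full(6, 0.6)])
        states = m.predict(X, [6])
        assert (states == S_NOADA).all()


class TestVariantsWithIIV:
    def test_variant_4_fit_on_small_cohort(self, gen_emission):
        """IIV-on-transitions variant must fit (quadrature path) and
        stay close to the no-IIV likelihood when the data carry no
        between-subject heterogeneity."""
        tp = TransitionParams.from_probs(0.08, 0.01)
        X, lengths, _ = sample_mhmm(gen_emission, tp, 40, 6, random_state=9)
        m = MixedHMM(
            variant=4, n_multistart=1, compute_se=False, random_state=0, n_nodes=5
        ).fit(X, lengths)
        assert np.isfinite(m.loglik_)
        assert m.transition_.omega2_pi12 >= 0
        m6 = MixedHMM(variant=6, n_multistart=1, compute_se=False, random_state=0).fit(
            X, lengths
        )
        assert m.loglik_ >= m6.loglik_ - 1e-3  # nested models
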
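import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iiwbias.bias_theory import (
    beta_bias_first_order,
    bias_curve,
    gamma_bias_closed_form,
    no_followup_prob,
    s_moments,
)

DISTS = [("bernoulli", 0.5), "normal01", "gamma11"]


class TestSMoments:
    def test_unconditional_closed_forms(self):
        m = s_moments(("bernoulli", 0.5), 0.0, 1.0)
        assert (m.s0, m.s1, m.s2) == (1.0, 0.5, 0.5)
        assert s_moments("normal01", 1.0, 1.0).s0 == pytest.approx(math.exp(0.5), rel=1e-12)
        assert s_moments("gamma11", 0.5, 1.0).s0 == pytest.approx(2.0, rel=1e-12)

    def test_null_gamma_leaves_conditional_ratios_unchanged(self):
        # at gamma=0 the no-visit probability is free of Z, so conditioning
        # on follow-up cannot tilt the covariate law
        for dist in DISTS:
            m = s_moments(dist, 0.0, 1.3)
            assert m.s1_star / m.s0_star == pytest.approx(m.s1 / m.s0, abs=1e-10)
            assert m.s2_star / m.s0_star == pytest.approx(m.s2 / m.s0, abs=1e-10)

    def test_positive_gamma_selects_larger_covariates(self):
        for dist in DISTS:
            m = s_moments(dist, 0.5, 1.0)
            assert m.s0_star > m.s0
            assert m.s1_star / m.s0_star > m.s1 / m.s0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        gamma=st.floats(-0.9, 0.9),
        Lambda0=st.floats(0.05, 10.0),
        idx=st.integers(0, 2),
    )
    def test_jensen_inequality_holds_everywhere(self, gamma, Lambda0, idx):
        m = s_moments(DISTS[idx], gamma, Lambda0)
        assert m.s2 * m.s0 >= m.s1**2 - 1e-12
        assert m.s2_star * m.s0_star >= m.s1_star**2 - 1e-12

    def test_quadrature_matches_plain_monte_carlo(self, rng):
        # 10^7 plain draws, compared at 4 sigma of the MC's own delta-method SE
        n = 10_000_000
        gamma, Lambda0 = 0.3, 1.0
        for dist, draw in (("normal01", rng.standard_normal), ("gamma11", rng.standard_exponential)):
            z = draw(n)
            sel = -np.expm1(-Lambda0 * np.exp(gamma * z))
            w = np.exp(gamma * z)
            m = s_moments(dist, gamma, Lambda0)
            for num_samples, target in ((w * sel, m.s0_star), (z * w * sel, m.s1_star)):
                den = sel
                est = num_samples.mean() / den.mean()
                # SE of a ratio of means via the linearized residuals
                resid = (num_samples - est * den) / den.mean()
                se = resid.std(ddof=1) / np.sqrt(n)
                assert abs(est - target) < 4 * se
                assert se < 5e-3  # the draw pins at least ~3 digits

    def test_divergent_gamma_moment_rejected(self):
        with pytest.raises(ValueError, match="diverges"):
            s_moments("gamma11", 1.0, 1.0)


class TestNoFollowupProb:
    def test_closed_form_values(self):
        assert no_followup_prob(0.0, 0.0, 0.5, 2.0) == pytest.approx(math.exp(-1.0), rel=1e-12)
        assert no_followup_prob(1.0, math.log(2.0), 0.5, 2.0) == pytest.approx(math.exp(-2.0), rel=1e-12)
        assert no_followup_prob(3.0, 1.0, 0.0, 2.0) == 1.0


class TestGammaBias:
    def test_zero_at_null_association(self):
        for dist in DISTS:
            assert gamma_bias_closed_form(dist, 0.0, 0.5, 2.0) == 0.0
            assert abs(gamma_bias_closed_form(dist, 0.0, 3.0, 1.0, order="first")) < 1e-10

    def test_depends_only_on_cumulative_baseline_intensity(self):
        for dist in DISTS:
            a = gamma_bias_closed_form(dist, 0.5, 0.5, 2.0)
            b = gamma_bias_closed_form(dist, 0.5, 1.0, 1.0)
            assert abs(a - b) < 1e-10

    def test_vanishes_when_followup_is_certain(self):
        for dist in DISTS:
            assert abs(gamma_bias_closed_form(dist, 0.5, 25.0, 2.0)) < 1e-6

    def test_omission_attenuates_positive_association(self):
        # dropping zero-visit subjects inflates the low-rate group's
        # conditional event count relatively more, pulling gamma toward zero
        for dist in DISTS:
            assert gamma_bias_closed_form(dist, 0.5, 0.5, 2.0) < 0

    def test_linearization_tracks_exact_root_when_bias_is_small(self):
        exact = gamma_bias_closed_form(("bernoulli", 0.5), 0.2, 2.0, 2.0)
        lin = gamma_bias_closed_form(("bernoulli", 0.5), 0.2, 2.0, 2.0, order="first")
        assert lin == pytest.approx(exact, rel=0.05)

    def test_linearization_overshoots_when_bias_is_large(self):
        exact = gamma_bias_closed_form(("bernoulli", 0.5), 0.5, 0.5, 2.0)
        lin = gamma_bias_closed_form(("bernoulli", 0.5), 0.5, 0.5, 2.0, order="first")
        assert abs(lin) > abs(exact)
        assert lin == pytest.approx(exact, rel=0.1)  # but still within ~10%

    def test_matches_monte_carlo_oracle_across_grid(self):
        """Closed form vs simulated Poisson visit processes on a small
        (gamma0, Lambda0) grid, Bernoulli covariate, reduced scale."""
        from iiwbias.experiments import mc_gamma_bias_oracle

        for gamma0, Lambda0 in ((0.25, 0.6), (0.5, 2.0), (0.8, 1.0)):
            mc = mc_gamma_bias_oracle(
                ("bernoulli", 0.5), gamma0, Lambda0 / 2.0, 2.0,
                n=2000, n_reps=60, seed=int(1000 * gamma0 + Lambda0),
            )
            closed = gamma_bias_closed_form(("bernoulli", 0.5), gamma0, Lambda0 / 2.0, 2.0)
            assert abs(closed - mc["bias_fu"]) < 3 * mc["mcse_fu"]


class TestBetaBiasTransfer:
    def test_zero_weight_bias_propagates_nothing(self):
        out = beta_bias_first_order(
            np.eye(1), lambda z: [1.0 + z], lambda z: 0.0, ("bernoulli", 0.5)
        )
        assert out == pytest.approx([0.0], abs=0)

    def test_mean_independent_outcome_propagates_nothing(self):
        out = beta_bias_first_order(
            np.eye(1), lambda z: [0.0], lambda z: 0.3, "normal01"
        )
        assert out == pytest.approx([0.0], abs=0)

    def test_scalar_toy_matches_hand_derivation(self):
        # intercept-only X=1, E(Y|Z) = a + bZ, Bernoulli(p) Z, constant
        # gamma-bias g: bias = -(tau)^{-1} E[tau b (Z - EZ) Z g] = -b g Var(Z)
        tau, b, g, p = 2.0, 1.7, 0.21, 0.3
        cond = lambda z: [tau * b * (z - p)]
        out = beta_bias_first_order([[tau]], cond, lambda z: g, ("bernoulli", p))
        brute = -(1 / tau) * ((1 - p) * cond(0.0)[0] * 0.0 * g + p * cond(1.0)[0] * 1.0 * g)
        assert out[0] == pytest.approx(-b * g * p * (1 - p), abs=1e-12)
        assert out[0] == pytest.approx(brute, abs=1e-12)

    def test_singular_design_moment_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            beta_bias_first_order(
                np.zeros((2, 2)), lambda z: [z, z], lambda z: 1.0, "normal01"
            )


class TestBiasCurve:
    def test_fixed_product_axis_is_flat(self):
        c = bias_curve(
            "lambda0_tau_fixed_product", ("bernoulli", 0.5),
            gamma0=0.5, lambda0=0.5, tau=2.0, grid=np.linspace(0.25, 1.0, 7),
        )
        assert c.bias.max() - c.bias.min() < 1e-10

    def test_bias_magnitude_decreases_in_lambda0_and_tau(self):
        lam = bias_curve("lambda0", ("bernoulli", 0.5), grid=[0.1, 0.3, 0.5, 0.7, 0.9])
        tau = bias_curve("tau", ("bernoulli", 0.5), grid=[1.0, 1.5, 2.0, 2.5, 3.0])
        assert np.all(np.diff(np.abs(lam.bias)) < 0)
        assert np.all(np.diff(np.abs(tau.bias)) < 0)

    def test_gamma_axis_with_fixed_visits_starts_at_zero_and_grows(self):
        c = bias_curve(
            "gamma_fixed_visits", ("bernoulli", 0.5), grid=[0.0, 0.2, 0.4, 0.6, 0.8]
        )
        assert c.bias[0] == 0.0
        assert np.all(np.diff(np.abs(c.bias)) > 0)

    def test_unknown_axis_rejected(self):
        with pytest.raises(ValueError, match="axis"):
            bias_curve("nope", "normal01", grid=[1.0])
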
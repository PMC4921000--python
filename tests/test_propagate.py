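"""Markov and ensemble propagators: exactness, limits, and preserved structure."""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import sitemix as sm


class TestGammaRates:
    def test_density_normalized_with_unit_mean(self, gamma):
        mass, _ = quad(gamma.pdf, 0, np.inf)
        mean, _ = quad(lambda r: r * gamma.pdf(r), 0, np.inf)
        assert mass == pytest.approx(1.0, abs=1e-8)
        assert mean == pytest.approx(1.0, abs=1e-8)

    def test_invalid_shape_rejected(self):
        with pytest.raises(sm.PropagateError):
            sm.GammaRates(alpha=0.0)


class TestDiscreteMixture:
    def test_two_class_has_unit_mean(self, two_class):
        assert two_class.mean == pytest.approx(1.0)

    def test_invalid_mixtures_rejected(self):
        with pytest.raises(sm.PropagateError):
            sm.DiscreteRateMixture(rates=(), weights=())
        with pytest.raises(sm.PropagateError):
            sm.DiscreteRateMixture(rates=(1.0,), weights=(0.5,))


class TestMarkovPropagator:
    def test_time_zero_is_identity(self, toy):
        np.testing.assert_allclose(sm.transition_matrix(toy, 0.0).P, np.eye(3))

    def test_rows_sum_to_one(self, toy):
        P = sm.transition_matrix(toy, 1.0).P
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_taylor_series_oracle(self, toy):
        t = 0.1
        series = np.zeros((3, 3))
        term = np.eye(3)
        for k in range(1, 21):
            term = term @ (t * toy.Q) / k
            series += term
        series += np.eye(3)
        np.testing.assert_allclose(sm.transition_matrix(toy, t).P, series, atol=1e-10)

    def test_negative_time_rejected(self, toy):
        with pytest.raises(sm.PropagateError):
            sm.transition_matrix(toy, -0.1)

    def test_semigroup(self, toy_norm):
        P1 = sm.transition_matrix(toy_norm, 0.3).P
        P2 = sm.transition_matrix(toy_norm, 0.7).P
        P12 = sm.transition_matrix(toy_norm, 1.0).P
        np.testing.assert_allclose(P1 @ P2, P12, atol=1e-10)


class TestSiteTransition:
    def test_unit_rate_matches_markov(self, toy):
        np.testing.assert_allclose(
            sm.site_transition(toy, 1.0, 0.5).P, sm.transition_matrix(toy, 0.5).P
        )

    def test_zero_rate_freezes_site(self, toy):
        np.testing.assert_allclose(sm.site_transition(toy, 0.0, 5.0).P, np.eye(3))

    def test_rate_time_product(self, toy):
        np.testing.assert_allclose(
            sm.site_transition(toy, 2.0, 0.1).P,
            sm.site_transition(toy, 1.0, 0.2).P,
            atol=1e-14,
        )


class TestEnsembleGamma:
    def test_large_alpha_degenerates_to_markov(self, toy_norm):
        Pe = sm.ensemble_gamma(toy_norm, 0.5, sm.GammaRates(alpha=1e6))
        Pm = sm.transition_matrix(toy_norm, 0.5)
        np.testing.assert_allclose(Pe.P, Pm.P, atol=1e-4)

    def test_spectral_vs_quadrature_mutual_oracle(self, toy_norm, gamma):
        Ps = sm.ensemble_gamma(toy_norm, 0.235, gamma, method="spectral")
        Pq = sm.ensemble_gamma(toy_norm, 0.235, gamma, method="quadrature")
        assert np.abs(Ps.P - Pq.P).max() < 1e-8

    def test_spectral_vs_quadrature_on_wag(self, wag, gamma):
        Ps = sm.ensemble_gamma(wag, 0.4, gamma, method="spectral")
        Pq = sm.ensemble_gamma(wag, 0.4, gamma, method="quadrature")
        assert np.abs(Ps.P - Pq.P).max() < 1e-8

    def test_diagonal_dominates_markov_diagonal(self, wag, gamma):
        # Jensen: P_ii(t) is convex in t for reversible Q, so mixing mean-one
        # rates can only raise the diagonal
        for t in (0.1, 0.5, 2.0):
            Pe = sm.ensemble_gamma(wag, t, gamma)
            Pm = sm.transition_matrix(wag, t)
            assert np.all(Pe.diag >= Pm.diag - 1e-12)

    def test_provenance_and_stochasticity(self, m0_uniform, gamma):
        Pe = sm.ensemble_gamma(m0_uniform, 0.235, gamma)
        assert Pe.provenance == "ensemble_gamma"
        np.testing.assert_allclose(Pe.P.sum(axis=1), 1.0, atol=1e-10)

    def test_nonreversible_spectral_rejected(self):
        Q = np.array([[-1.0, 1.0, 0.0], [0.0, -1.0, 1.0], [1.0, 0.0, -1.0]])
        pi = sm.stationary(Q)
        rm = sm.RateMatrix(space=sm.generic_space("XYZ"), Q=Q, pi=pi)
        with pytest.raises(sm.PropagateError, match="quadrature"):
            sm.ensemble_gamma(rm, 0.5)
        Pq = sm.ensemble_gamma(rm, 0.5, method="quadrature")
        np.testing.assert_allclose(Pq.P.sum(axis=1), 1.0, atol=1e-10)


class TestEnsembleDiscrete:
    def test_single_class_matches_markov(self, toy):
        mix = sm.DiscreteRateMixture(rates=(1.0,), weights=(1.0,))
        np.testing.assert_allclose(
            sm.ensemble_discrete(toy, 0.7, mix).P,
            sm.transition_matrix(toy, 0.7).P,
            atol=1e-14,
        )

    def test_two_class_defining_formula(self, toy, two_class):
        expected = (scipy.linalg.expm(0.5 * toy.Q) + scipy.linalg.expm(1.5 * toy.Q)) / 2
        np.testing.assert_allclose(
            sm.ensemble_discrete(toy, 1.0, two_class).P, expected, atol=1e-12
        )

    def test_differs_from_markov(self, toy, two_class):
        Pe = sm.ensemble_discrete(toy, 1.0, two_class)
        Pm = sm.transition_matrix(toy, 1.0)
        assert abs(Pe.P[0, 1] - Pm.P[0, 1]) > 1e-3


class TestPreservedStructure:
    @pytest.mark.parametrize("law_name", ["markov", "gamma", "discrete"])
    def test_stationarity_preserved(self, wag, gamma, two_class, law_name):
        law = {"markov": None, "gamma": gamma, "discrete": two_class}[law_name]
        P = sm.propagate(wag, 0.7, law)
        np.testing.assert_allclose(wag.pi @ P.P, wag.pi, atol=1e-10)

    def test_symmetric_generator_gives_symmetric_propagators(self, toy, gamma, two_class):
        for law in (None, gamma, two_class):
            P = sm.propagate(toy, 1.0, law).P
            np.testing.assert_allclose(P, P.T, atol=1e-12)

    def test_ensemble_breaks_semigroup(self, toy, two_class):
        Pe1 = sm.ensemble_discrete(toy, 1.0, two_class).P
        Pe2 = sm.ensemble_discrete(toy, 2.0, two_class).P
        assert np.abs(Pe1 @ Pe1 - Pe2).max() > 1e-3


@settings(max_examples=25, deadline=None)
@given(
    t=st.floats(min_value=0.0, max_value=3.0),
    alpha=st.floats(min_value=0.2, max_value=5.0),
)
def test_gamma_ensemble_invariants(t, alpha):
    """Row-stochastic, stationarity-preserving, Jensen diagonal for any (t, alpha)."""
    Q = sm.normalize(sm.toy_three_state())
    Pe = sm.ensemble_gamma(Q, t, sm.GammaRates(alpha=alpha))
    Pm = sm.transition_matrix(Q, t)
    np.testing.assert_allclose(Pe.P.sum(axis=1), 1.0, atol=1e-10)
    np.testing.assert_allclose(Q.pi @ Pe.P, Q.pi, atol=1e-10)
    assert np.all(Pe.diag >= Pm.diag - 1e-12)
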
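"""Generator construction, normalization, stationarity and matrix I/O."""

import numpy as np
import pytest
import scipy.linalg

import sitemix as sm
from sitemix.statespace import is_transition


class TestToyThreeState:
    def test_printed_entries(self, toy):
        assert toy.Q[0, 1] == 0.9
        assert toy.Q[2, 0] == 0.1
        np.testing.assert_allclose(toy.Q, toy.Q.T)

    def test_generator_rows_and_uniform_pi(self, toy):
        np.testing.assert_allclose(toy.Q.sum(axis=1), 0.0, atol=1e-14)
        np.testing.assert_allclose(toy.pi, 1 / 3)

    def test_flux_before_normalization(self, toy):
        # (1/3) * (1.0 + 1.1 + 0.3), by hand from the printed diagonal
        assert toy.flux == pytest.approx(0.8, abs=1e-14)
        assert not toy.normalized


class TestNormalize:
    def test_unit_flux(self, toy_norm):
        assert toy_norm.flux == pytest.approx(1.0, abs=1e-12)
        assert toy_norm.normalized

    def test_idempotent_and_pi_preserved(self, toy, toy_norm):
        again = sm.normalize(toy_norm)
        np.testing.assert_allclose(again.Q, toy_norm.Q, atol=1e-15)
        np.testing.assert_allclose(toy_norm.pi, toy.pi)

    def test_zero_flux_rejected(self):
        sp = sm.generic_space(("A", "B"))
        rm = sm.RateMatrix(space=sp, Q=np.zeros((2, 2)), pi=np.array([0.5, 0.5]))
        with pytest.raises(sm.ModelError, match="zero"):
            sm.normalize(rm)


class TestStationary:
    def test_symmetric_toy_is_uniform(self, toy):
        np.testing.assert_allclose(sm.stationary(toy.Q), 1 / 3, atol=1e-12)

    def test_m0_recovers_codon_freqs(self, m0_nonuniform):
        np.testing.assert_allclose(
            sm.stationary(m0_nonuniform.Q), m0_nonuniform.pi, atol=1e-10
        )

    def test_long_time_rows_approach_pi(self, wag):
        P = scipy.linalg.expm(1e3 * wag.Q)
        np.testing.assert_allclose(P, np.tile(wag.pi, (20, 1)), atol=1e-6)

    def test_reducible_generator_rejected(self):
        Q = np.zeros((4, 4))
        Q[0, 1] = Q[1, 0] = 1.0
        Q[2, 3] = Q[3, 2] = 1.0
        np.fill_diagonal(Q, -Q.sum(axis=1))
        with pytest.raises(sm.ModelError, match="null space"):
            sm.stationary(Q)


class TestBuildM0:
    def test_multi_nucleotide_entries_are_zero(self, m0_uniform, codon_partition):
        for k in (2, 3):
            assert np.all(m0_uniform.Q[codon_partition.mask(k)] == 0.0)

    def test_rate_ratio_kappa_omega(self, m0_uniform):
        sp = sm.codon_space()
        # CTC(Leu)->CCC(Pro): nonsynonymous transition; CTC->CTA: synonymous transversion
        q_ns_ti = m0_uniform.Q[sp.index("CTC"), sp.index("CCC")]
        q_s_tv = m0_uniform.Q[sp.index("CTC"), sp.index("CTA")]
        assert q_ns_ti / q_s_tv == pytest.approx(2.5 * 0.2, rel=1e-12)

    def test_stationary_matches_supplied_freqs(self, m0_nonuniform):
        np.testing.assert_allclose(
            sm.stationary(m0_nonuniform.Q), m0_nonuniform.pi, atol=1e-10
        )

    def test_reversible_and_normalized(self, m0_nonuniform):
        F = m0_nonuniform.pi[:, None] * m0_nonuniform.Q
        np.testing.assert_allclose(F, F.T, atol=1e-12)
        assert m0_nonuniform.flux == pytest.approx(1.0, abs=1e-10)

    def test_single_nucleotide_rates_proportional_to_target_freq(self, m0_nonuniform):
        sp = sm.codon_space()
        # two synonymous transversions into different targets from the same source
        i, j1, j2 = sp.index("GTC"), sp.index("GTA"), sp.index("GTT")
        assert is_transition("C", "A") is False and is_transition("C", "T") is True
        r = m0_nonuniform.Q[i, j1] / m0_nonuniform.pi[j1]
        r2 = m0_nonuniform.Q[i, j2] / (m0_nonuniform.pi[j2] * 2.5)
        assert r == pytest.approx(r2, rel=1e-12)

    def test_bad_frequency_vector_rejected(self):
        with pytest.raises(sm.ModelError):
            sm.M0Params(kappa=2.5, omega=0.2, codon_freqs=np.full(60, 1 / 60))
        with pytest.raises(sm.ModelError):
            sm.M0Params(kappa=2.5, omega=0.2, codon_freqs=np.full(61, 1.0))
        with pytest.raises(sm.ModelError):
            sm.M0Params(kappa=-1.0, omega=0.2, codon_freqs=sm.uniform_codon_freqs())


class TestEmpiricalIO:
    def test_wag_loads_normalized_and_reversible(self, wag):
        assert wag.space.N == 20
        assert wag.flux == pytest.approx(1.0, abs=1e-10)
        F = wag.pi[:, None] * wag.Q
        np.testing.assert_allclose(F, F.T, atol=1e-10)

    def test_dense_round_trip(self, wag, tmp_path):
        p = tmp_path / "wag.tsv"
        sm.write_dense(wag, p)
        back = sm.load_dense(p)
        np.testing.assert_allclose(back.Q, wag.Q, atol=1e-12)
        assert back.space.labels == wag.space.labels
        assert back.normalized

    def test_freq_override(self, tmp_path):
        f = np.full(20, 1 / 20)
        rm = sm.load_empirical(sm.wag_path(), freq_override=f)
        np.testing.assert_allclose(rm.pi, f)
        assert rm.flux == pytest.approx(1.0, abs=1e-10)

    def test_unnormalized_frequencies_warn(self, tmp_path):
        text = sm.wag_path().read_text().splitlines()
        text[-1] = " ".join(str(2 * float(x)) for x in text[-1].split())
        p = tmp_path / "bad.dat"
        p.write_text("\n".join(text) + "\n")
        with pytest.warns(UserWarning, match="renormaliz"):
            rm = sm.load_empirical(p)
        assert rm.pi.sum() == pytest.approx(1.0)

    def test_truncated_file_rejected(self, tmp_path):
        p = tmp_path / "short.dat"
        p.write_text("0.5\n0.5 0.5\n")
        with pytest.raises(sm.ModelError, match="expected at least"):
            sm.load_empirical(p)

    def test_freq_file_round_trip(self, tmp_path):
        from sitemix.models import write_freqs

        f = np.random.default_rng(1).dirichlet(np.ones(61))
        p = tmp_path / "freqs.txt"
        write_freqs(f, p)
        np.testing.assert_allclose(sm.load_freqs(p, 61), f, atol=1e-12)
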
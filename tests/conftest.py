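import numpy as np
import pytest

import sitemix as sm


@pytest.fixture(scope="session")
def toy():
    """The symmetric 3-state toy generator (un-normalized, flux 0.8)."""
    return sm.toy_three_state()


@pytest.fixture(scope="session")
def toy_norm(toy):
    return sm.normalize(toy)


@pytest.fixture(scope="session")
def m0_uniform():
    """M0 codon generator with kappa=2.5, omega=0.2, uniform sense-codon frequencies."""
    return sm.build_m0(sm.M0Params(kappa=2.5, omega=0.2, codon_freqs=sm.uniform_codon_freqs()))


@pytest.fixture(scope="session")
def m0_nonuniform():
    """M0 with a fixed non-uniform frequency vector (exercises the general case)."""
    rng = np.random.default_rng(20160624)
    f = rng.dirichlet(np.full(61, 5.0))
    return sm.build_m0(sm.M0Params(kappa=2.5, omega=0.2, codon_freqs=f))


@pytest.fixture(scope="session")
def wag():
    """The bundled published WAG amino-acid matrix, normalized."""
    return sm.load_empirical(sm.wag_path())


@pytest.fixture(scope="session")
def gamma():
    return sm.GammaRates(alpha=0.286)


@pytest.fixture(scope="session")
def two_class():
    return sm.DiscreteRateMixture.two_class()


@pytest.fixture(scope="session")
def codon_partition():
    return sm.DiffClassPartition.for_space(sm.codon_space())


@pytest.fixture(scope="session")
def aa_partition():
    return sm.DiffClassPartition.for_space(sm.amino_acid_space())
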
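import numpy as np
import pytest

from bcrpqsar.synthetic import SyntheticSpec, gen_feature_table


@pytest.fixture(scope="session")
def separable_table():
    """Strongly separated synthetic features (Cohen's d = 3, 400 + 400)."""
    return gen_feature_table(SyntheticSpec(
        n_inhibitors=400, n_noninhibitors=400,
        n_informative_continuous=5, n_noise_continuous=15,
        n_fingerprint_bits=10, effect_size=3.0,
        bit_rate_inhibitor=0.7, bit_rate_noninhibitor=0.3, seed=11))


@pytest.fixture(scope="session")
def scaffold_library():
    """Small labeled library built from six distinct ring-system families."""
    from bcrpqsar.synthetic import gen_compound_library
    spec = SyntheticSpec(
        n_inhibitors=15, n_noninhibitors=15,
        planted_fragments=(("c1ccc2ncncc2c1", 0.4, 0.05),
                           ("C1COCCN1", 0.05, 0.4),
                           ("c1ccsc1", 0.1, 0.3)),
        seed=5)
    library, membership = gen_compound_library(spec)
    return library, membership


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
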
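import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def admixed_panel():
    """Small Balding-Nichols three-population panel shared across tests."""
    from hyborigin import AdmixtureSpec, generate_admixed_panel

    spec = AdmixtureSpec(
        n_parental_a=12,
        n_parental_b=12,
        n_hybrid=8,
        n_loci=120,
        fst_parents=0.2,
        ancestry=0.68,
        missing_rate=0.05,
        seed=42,
    )
    g, anc = generate_admixed_panel(spec)
    return g


@pytest.fixture(scope="session")
def scenario1():
    from hyborigin import hybrid_origin_scenarios

    return hybrid_origin_scenarios()[0]
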
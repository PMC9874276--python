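import pytest

from trophic import synthio
from trophic.datasets import load_synthetic_isolate_traits


@pytest.fixture(scope="session")
def isolate_traits():
    """The bundled synthetic 11-strain trait panel."""
    return load_synthetic_isolate_traits()


@pytest.fixture(scope="session")
def community():
    """One seeded community dataset shared across read-table tests."""
    config = synthio.CommunitySimConfig(
        n_otus=13, n_samples=40, creff_true=0.5, env_kind="depth_binary", seed=3
    )
    table, meta, traits, truth = synthio.gen_community_dataset(config)
    return table, meta, traits, truth
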
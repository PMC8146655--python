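import pytest

from sncatlas.simulate import BundleConfig, generate_reference_bundle, default_region_profiles


@pytest.fixture(scope="session")
def bundle():
    """Small reference bundle shared across tests."""
    cfg = BundleConfig(n_mirna=30, n_pirna=240, n_trna=12, mt_len=8000)
    return generate_reference_bundle(cfg, seed=11)


@pytest.fixture(scope="session")
def profiles():
    return default_region_profiles()
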
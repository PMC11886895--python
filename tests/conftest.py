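import pytest

from cernarisk import synthetic


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """Noisy small bundle shared across tests (read-only)."""
    params = synthetic.BundleParams.small()
    out = tmp_path_factory.mktemp("bundle_small")
    paths, truth = synthetic.generate_bundle(params, seed=11, out_dir=out)
    return params, paths, truth


@pytest.fixture(scope="session")
def zero_noise_bundle(tmp_path_factory):
    """Small bundle with no background interaction edges: exact recovery."""
    params = synthetic.BundleParams.small()
    params.background_edge_prob = 0.0
    out = tmp_path_factory.mktemp("bundle_zero")
    paths, truth = synthetic.generate_bundle(params, seed=11, out_dir=out)
    return params, paths, truth
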
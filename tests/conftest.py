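import pytest

from mircross.pipeline import run_all
from mircross.synthetic import SimParams, simulate_bundle, write_bundle


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """Default-conditions synthetic study, written to disk."""
    params = SimParams(seed=7)
    bundle = simulate_bundle(params)
    d = tmp_path_factory.mktemp("bundle_default")
    write_bundle(bundle, d)
    return bundle, d


@pytest.fixture(scope="session")
def default_result(default_bundle, tmp_path_factory):
    bundle, d = default_bundle
    out = tmp_path_factory.mktemp("out_default")
    return bundle, run_all(d, out), out


@pytest.fixture(scope="session")
def high_signal_bundle(tmp_path_factory):
    """High-signal conditions: strong effects, low noise, sharp tools."""
    params = SimParams(
        effect_log2=2.0, noise_sd=0.2, tool_sensitivity=0.95, tool_fpr=0.01, seed=5
    )
    bundle = simulate_bundle(params)
    d = tmp_path_factory.mktemp("bundle_high")
    write_bundle(bundle, d)
    return bundle, d


@pytest.fixture(scope="session")
def high_signal_result(high_signal_bundle, tmp_path_factory):
    bundle, d = high_signal_bundle
    out = tmp_path_factory.mktemp("out_high")
    return bundle, run_all(d, out), out
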
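import numpy as np
import pytest

from rastriage import rascycle, synth


@pytest.fixture(scope="session")
def small_config():
    return synth.SynthConfig(
        seed=7,
        n_germline=30,
        n_somatic=40,
        n_both=10,
        msa_depth=60,
        n_gold_per_origin=10,
    )


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory, small_config):
    """A complete synthetic dataset written once per session."""
    outdir = tmp_path_factory.mktemp("synthdata")
    return synth.write_dataset(small_config, outdir)


@pytest.fixture(scope="session")
def wt_params():
    params, _variants = rascycle.load_params()
    return params


@pytest.fixture(scope="session")
def default_variants():
    _params, variants = rascycle.load_params()
    return variants


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
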
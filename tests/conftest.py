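import numpy as np
import pytest

import imbef


@pytest.fixture(scope="session")
def small_epochs() -> imbef.EpochMatrix:
    """5 stages x 12 short (4 s, 128 Hz) epochs — fast shared fixture."""
    return imbef.generate_stage_epochs(
        imbef.default_profiles(), n_per_stage=12, te=4.0, fs=128.0, seed=11
    )


@pytest.fixture(scope="session")
def default_params() -> imbef.FeatureParams:
    return imbef.FeatureParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def fixture_edf(tmp_path_factory):
    """A synthetic EDF recording with a dreams-style hypnogram sidecar."""
    em = imbef.generate_stage_epochs(
        imbef.default_profiles(), n_per_stage=3, te=4.0, fs=128.0, seed=5
    )
    out = tmp_path_factory.mktemp("edf") / "synthetic.edf"
    edf_path, hyp_path = imbef.write_fixture_edf(em, out)
    return em, edf_path, hyp_path
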
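import numpy as np
import pytest

from capnonet import gaf, preprocess, synthetic


@pytest.fixture(scope="session")
def normal_breath_noisefree():
    """One noise-free normal breath at the default 80 Hz device rate."""
    import dataclasses

    params = dataclasses.replace(synthetic.grade_morphology("normal"), noise_sd=0.0)
    return params, synthetic.simulate_breath(params, seed=11)


@pytest.fixture(scope="session")
def paa_series(normal_breath_noisefree):
    """A preprocessed 224-sample breath series."""
    _, raw = normal_breath_noisefree
    series = preprocess.preprocess_record(raw)
    assert series, "fixture breath must yield at least one valid series"
    return series[0]


@pytest.fixture(scope="session")
def gasf_image(paa_series):
    return gaf.encode_image(paa_series, kind="gasf")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
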
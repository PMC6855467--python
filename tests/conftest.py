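import numpy as np
import pytest

from flamqspr import (
    GroundTruth,
    SyntheticConfig,
    generate_dataset,
    make_fixture_suite,
    read_dataset,
)


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    """Canonical generated fixtures: {name: csv_path} plus truth sidecars."""
    out = tmp_path_factory.mktemp("fixtures")
    return make_fixture_suite(out, seed=0)


def load_fixture(paths, name):
    ds = read_dataset(paths[name], property_column="LFL")
    p = paths[name]
    truth = GroundTruth.from_json((p.parent / f"{p.stem}.truth.json").read_text())
    return ds, truth


@pytest.fixture(scope="session")
def noiseless_pair():
    """A 200x6 noise-free hybrid dataset with its generating model."""
    cfg = SyntheticConfig(N=200, n=6, noise_sd=0.0, seed=11)
    return generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
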
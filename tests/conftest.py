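import numpy as np
import pytest

import stillindex as si


@pytest.fixture(scope="session")
def cpv_spec():
    """CPV17-like cubic I23 study conditions."""
    return si.cpv17_toy_spec(jitter_px=0.3, noise_fraction=0.1)


@pytest.fixture(scope="session")
def clean_spec():
    """Same geometry, noise-free (exact forward model)."""
    return si.cpv17_toy_spec(jitter_px=0.0, noise_fraction=0.0)


@pytest.fixture(scope="session")
def cpv_priors():
    spec = si.cpv17_toy_spec()
    return si.CrystalPriors.build(spec.cell, spec.spacegroup, d_max=0.10)


@pytest.fixture(scope="session")
def i23_cell():
    return si.UnitCell(106.1, 106.1, 106.1)


@pytest.fixture(scope="session")
def i23_sg():
    return si.SpaceGroupInfo.from_symbol("I23")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
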
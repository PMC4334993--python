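import numpy as np
import pytest

from kirdock.dockengine import DockConfig, dock_rigid
from kirdock.fixtures import ToyChannelParams, make_toy_channel, make_toy_peptide

#: 21-residue bee-venom peptide sequence used as a realistic test input.
TPN_SEQUENCE = "ALCNCNRIIIPHMCWKKCGKK"


@pytest.fixture(scope="session")
def toy_channel():
    return make_toy_channel()


@pytest.fixture(scope="session")
def toy_channel_neutral():
    return make_toy_channel(ToyChannelParams(pocket_charge_pattern="neutral"))


@pytest.fixture(scope="session")
def toy_peptide():
    return make_toy_peptide(8, 3)


@pytest.fixture(scope="session")
def coarse_config():
    """Cheap deterministic docking settings for unit tests."""
    return DockConfig(rotation_step=90.0, top_n=100, contact_pool=200)


@pytest.fixture(scope="session")
def coarse_poselist(toy_channel, toy_peptide, coarse_config):
    return dock_rigid(toy_channel.structure, toy_peptide, coarse_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
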
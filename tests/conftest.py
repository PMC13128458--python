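import pytest
from hypothesis import settings

from ridgehab import mosaic_config

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def mosaic_cfg():
    """The packaged MOSAiC July run configuration."""
    return mosaic_config()


@pytest.fixture(scope="session")
def mosaic_vols(mosaic_cfg):
    """Compartment unit volumes for the packaged configuration."""
    return mosaic_cfg.unit_volumes()
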
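import pytest

from lenspk.parameters import rabbit_dexamethasone, rabbit_diffusion_demo


@pytest.fixture
def release_params():
    """Rabbit/dexamethasone release-mode parameter set."""
    return rabbit_dexamethasone()


@pytest.fixture
def diffusion_params():
    """Rabbit anatomy with the demonstration diffusion-mode lens."""
    return rabbit_diffusion_demo()


@pytest.fixture(scope="session")
def release_result():
    """One shared 7-day release-mode simulation of the fixture set."""
    from lenspk.model import EyeModel
    return EyeModel(rabbit_dexamethasone()).simulate()


@pytest.fixture(scope="session")
def diffusion_result():
    """One shared 7-day diffusion-mode simulation of the demo set."""
    from lenspk.model import EyeModel
    return EyeModel(rabbit_diffusion_demo()).simulate()
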
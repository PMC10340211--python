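import numpy as np
import pytest

from pdrscreen.config import PipelineConfig, load_config
from pdrscreen.phantom import NVLesion, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def cfg():
    """Packaged default configuration (with calibrated bands)."""
    return load_config()


@pytest.fixture(scope="session")
def plain_cfg():
    """Configuration defaults without packaged bands."""
    return PipelineConfig()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def healthy_phantom():
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def nvd_phantom():
    spec = PhantomSpec(seed=3, nv_lesions=(NVLesion(distance=0.5),),
                       n_exudates=2)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def dual_phantom():
    """Phantom with one NVD and one NVE lesion plus exudates."""
    spec = PhantomSpec(seed=3, nv_lesions=(NVLesion(distance=0.5),
                                           NVLesion(distance=1.7)),
                       n_exudates=2)
    return generate_phantom(spec)
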
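import numpy as np
import pytest

from radstab.synthdata import PhantomSpec, Protocol, generate_phantom_volume

PHILIPS_THIN = Protocol("P1", 100, 2.0, 0.86)


@pytest.fixture(scope="session")
def noise_free_phantom():
    """Noise-free 4:1 sphere phantom at the finest Philips protocol."""
    spec = PhantomSpec(noise_reference=0.0)
    return generate_phantom_volume(spec, PHILIPS_THIN, timepoint=1, seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)
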
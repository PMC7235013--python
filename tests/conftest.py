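import numpy as np
import pytest

from punctapipe.phantom import (ConversionModel, NoiseSpec, PhantomSpec,
                                WarpSpec, generate_phantom)


@pytest.fixture(scope="session")
def small_spec():
    """Compact two-timepoint phantom with clutter, moderate conversion."""
    return PhantomSpec(
        volume_shape=(20, 72, 72),
        n_synapses=60,
        conversion_model=ConversionModel(kind="constant", median=0.5,
                                         dispersion=0.4),
        autofluorescence_volume_fraction=0.01,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def warp_phantom():
    """Phantom with tissue warp and a chromatic offset, for registration."""
    spec = PhantomSpec(
        volume_shape=(24, 96, 96),
        n_synapses=220,
        conversion_model=ConversionModel(kind="constant", median=0.6,
                                         dispersion=0.4),
        autofluorescence_volume_fraction=0.015,
        warp=WarpSpec(max_displacement_um=2.0, smoothness_um=25.0),
        chromatic_offset=(0.5, -1.0, 1.0),
        seed=11,
    )
    return spec, generate_phantom(spec)


@pytest.fixture(scope="session")
def noiseless_spec():
    return PhantomSpec(
        volume_shape=(20, 72, 72),
        n_synapses=50,
        conversion_model=ConversionModel(kind="constant", median=0.7,
                                         dispersion=0.3),
        noise=NoiseSpec(photon_scale=0.0, read_sigma=0.0),
        background=0.0,
        seed=13,
    )


@pytest.fixture(scope="session")
def noiseless_phantom(noiseless_spec):
    return generate_phantom(noiseless_spec)
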
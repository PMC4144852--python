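import numpy as np
import pytest

from tjmetrics.simulate import MonolayerSpec, generate_monolayer


@pytest.fixture(scope="session")
def small_spec():
    """Small, fast mosaic used across image tests."""
    return MonolayerSpec(
        field_width_um=60.0,
        field_height_um=60.0,
        n_cells=25,
        pixel_size_um=0.1,
        tortuosity_amplitude_um=0.0,
        junction_width_um=0.2,
        psf_sigma_um=0.1,
        noise_sd=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_image(small_spec):
    return generate_monolayer(small_spec)


@pytest.fixture(scope="session")
def zigzag_spec(small_spec):
    from dataclasses import replace

    return replace(small_spec, tortuosity_amplitude_um=0.8, tortuosity_wavelength_um=5.0)


@pytest.fixture(scope="session")
def zigzag_image(zigzag_spec):
    return generate_monolayer(zigzag_spec)


@pytest.fixture(scope="session")
def dense_spec():
    """Mosaic at the analysis scale used for oracle-equivalence checks."""
    return MonolayerSpec(
        field_width_um=150.0,
        field_height_um=150.0,
        n_cells=100,
        pixel_size_um=0.1,
        tortuosity_amplitude_um=1.0,
        tortuosity_wavelength_um=5.0,
        junction_width_um=0.2,
        psf_sigma_um=0.1,
        seed=5,
    )
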
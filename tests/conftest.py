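import numpy as np
import pytest

import smcoloc as smc


@pytest.fixture()
def noiseless_field():
    """50 well-separated spots rendered without noise, with ground truth."""
    spec = smc.FieldSpec(
        n_spots=50,
        shot_noise=False,
        read_noise_sd=0.0,
        seed=7,
        min_separation_px=4 * 1.5,  # 4 sigma
        margin_px=12,
    )
    pop = smc.population_with_dual_fraction(200, 0.5, seed=5)
    images, records = smc.render_field(pop, spec)
    return spec, images, records


def gaussian_spot(shape, x0, y0, amplitude, sigma, background):
    """Direct noiseless rendering of one isotropic Gaussian spot."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return background + amplitude * np.exp(
        -((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma**2)
    )
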
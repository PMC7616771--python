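import numpy as np
import pytest

from marrowquant import stain_deconv as sdv
from marrowquant import synthetic_data as sd


@pytest.fixture(scope="session")
def hdab():
    return sdv.StainModel.hdab()


@pytest.fixture(scope="session")
def small_slide(hdab):
    """One 128x128 noise-free synthetic slide with its ground truth."""
    spec = sd.IhcSimSpec(width_px=128, height_px=128, seed=11, noise_sd=0.0)
    slide, truth = sd.gen_ihc_slide(spec, hdab)
    return spec, slide, truth


@pytest.fixture(scope="session")
def clean_field():
    """Noise-free 20-cell fluorescence field with ground truth."""
    spec = sd.FluorSimSpec(n_cells=20, noise_sd=0.0, seed=7)
    nuclei, collagen, truth = sd.gen_fluor_pair(spec)
    return spec, nuclei, collagen, truth
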
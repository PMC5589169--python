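import numpy as np
import pytest

from rbcfluidity.synthetic_cohort import CohortConfig, MembraneFieldParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_field_params():
    """Cell footprint that fits a 64-px frame at 200 nm/pixel."""
    return MembraneFieldParams(
        cell_outer_radius_um=1.4, cell_inner_radius_um=0.9
    )


@pytest.fixture
def tiny_cohort_config():
    """Smallest cohort that still exercises every pipeline stage."""
    return CohortConfig(
        n_per_group=(2, 2, 2), images_per_patient=2, image_size_px=96, seed=7
    )
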
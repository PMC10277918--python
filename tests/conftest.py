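import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from imcrecur import synthetic_cohort as sc
from imcrecur.preprocess import arcsinh_transform, range_batch_correct

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale cohort: 12 patients, a few hundred cells each."""
    return sc.CohortConfig(
        n_patients=12, n_recurrent=6, cells_per_image=(250, 350), seed=11
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """(cells, truth) from the fast statistical path."""
    return sc.simulate_cell_table(small_config)


@pytest.fixture(scope="session")
def small_cells_proc(small_config, small_cohort):
    """Batch-corrected, arcsinh-transformed cell table."""
    cells, _ = small_cohort
    corrected = range_batch_correct(cells, small_config.panel)
    return arcsinh_transform(corrected, small_config.panel)


@pytest.fixture(scope="session")
def tiny_image_config():
    """Three-patient cohort with rasterized 256x256 images."""
    return sc.CohortConfig(
        n_patients=3,
        n_recurrent=1,
        cells_per_image=(40, 60),
        image_size_px=(256, 256),
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_image_cohort(tiny_image_config):
    return sc.simulate_cohort(tiny_image_config)
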
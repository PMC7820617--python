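import numpy as np
import pytest

from nodalmap.simulate import GenParams, sample_cohort
from nodalmap.template import build_template, default_template_config


def coarse_config():
    """Default geometry on a 4 mm grid (same world extent, 8x fewer voxels)."""
    cfg = default_template_config()
    cfg["shape"] = [64, 64, 80]
    cfg["spacing"] = [4.0, 4.0, 4.0]
    return cfg


@pytest.fixture(scope="session")
def atlas2mm():
    _, atlas = build_template()
    return atlas


@pytest.fixture(scope="session")
def grid2mm(atlas2mm):
    return atlas2mm.grid


@pytest.fixture(scope="session")
def atlas4mm():
    _, atlas = build_template(coarse_config())
    return atlas


@pytest.fixture(scope="session")
def cohort75(atlas2mm):
    """Default-parameter cohort with per-patient displacement fields."""
    return sample_cohort(GenParams(n_patients=75, seed=11), atlas2mm)


@pytest.fixture(scope="session")
def cohort_rigid(atlas2mm):
    """Cohort with zero deformation (native == template); fast to draw."""
    return sample_cohort(GenParams(n_patients=75, seed=23, dvf_sd_mm=0.0), atlas2mm)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
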
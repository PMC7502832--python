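import numpy as np
import pytest

from mpmtools.phantom import SiteEffect, StudyDesign, make_ground_truth


@pytest.fixture(scope="session")
def ground_truth():
    """Small deterministic phantom shared by read-only tests."""
    return make_ground_truth((32, 32, 32), seed=7)


@pytest.fixture
def clean_site():
    """Reference-vendor site with no noise and flat fields."""
    return SiteEffect("ZH", "siemens", noise_sigma=0.0,
                      ft_amplitude=0.0, s_amplitude=0.0)


@pytest.fixture
def tiny_design():
    """Two subjects, one site per vendor, small grid: fast end-to-end runs."""
    return StudyDesign(
        n_subjects=2,
        sites=[
            SiteEffect("ZH", "siemens"),
            SiteEffect("NOT", "philips", mt_a=0.7895, mt_b=-0.0807),
        ],
        shape=(32, 32, 32),
        seed=11,
    )
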
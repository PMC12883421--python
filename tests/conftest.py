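from __future__ import annotations

import numpy as np
import pytest

from mpnmorph.imaging import ROIImage
from mpnmorph.profiles import make_default_profiles
from mpnmorph.synthgen import generate_patient_rois


@pytest.fixture(scope="session")
def default_profiles():
    return make_default_profiles()


@pytest.fixture(scope="session")
def pv_roi(default_profiles):
    """One default-sized PV ROI with ground truth (shared, read-only)."""
    _, pv, _ = default_profiles
    return generate_patient_rois(pv, 1, seed=7)[0]


@pytest.fixture(scope="session")
def pv_roi_image(pv_roi):
    return ROIImage.from_synthetic(pv_roi)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
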
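import numpy as np
import pytest

from wristqct import (PhantomSpec, extract_roi_stats, fit_calibration,
                      grey_to_hu, make_wrist_phantom)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free default wrist phantom (plates lattice, 96^3)."""
    spec = PhantomSpec(noise_sd=0.0, capping_amplitude=0.0,
                       grey_slope=0.7, grey_intercept=800.0, seed=11)
    grey, gt = make_wrist_phantom(spec)
    return spec, grey, gt


@pytest.fixture(scope="session")
def clean_hu(clean_phantom):
    """The same phantom calibrated to HU through its own insert ROIs."""
    _, grey, gt = clean_phantom
    means = {m: extract_roi_stats(grey, r)[0] for m, r in gt.insert_rois.items()}
    return grey_to_hu(grey, fit_calibration(means))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
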
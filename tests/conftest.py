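from dataclasses import replace

import numpy as np
import pytest

from fibroscreen.scores import load_coefficients
from fibroscreen.synthetic import generate_cohort, preset


@pytest.fixture(scope="session")
def coeffs():
    return load_coefficients()


@pytest.fixture(scope="session")
def obese_cohort():
    """A moderately sized overweight/obese synthetic cohort, fixed seed."""
    return generate_cohort(replace(preset("overweight_obese"), n=1500, seed=42))


@pytest.fixture(scope="session")
def mixed_cohort():
    """Pooled cohort spanning all three BMI bands (for band-level analyses)."""
    recs = []
    for name, seed in (("overweight_obese", 1), ("hepatology_lean", 2),
                       ("elevated_risk", 3)):
        recs += generate_cohort(replace(preset(name), n=800, seed=seed))
    return recs


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
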
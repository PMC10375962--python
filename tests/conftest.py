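"""Shared fixtures: a mid-size phantom study built once per session.

The study conditions: 128x128 frames (a scaled-down version of the 256x256
clinical rasters so the whole suite stays fast), 20-frame series with
contrast arrival at frame 4 and peak at frame 10, noise variance 0.01, a
12-subject training cohort for the shape prior, and held-out test subjects
drawn with the same jitter distribution.
"""

import numpy as np
import pytest

from unls import PhantomConfig, make_cohort
from unls.levelset import InitSpec
from unls.pipeline import pick_frame
from unls.prior import build_prior_from_cohort


@pytest.fixture(scope="session")
def base_cfg():
    return PhantomConfig(image_size=(128, 128), n_frames=20,
                         semi_axes=(30, 17), t0=4, alpha=3.0, beta_t=0.5,
                         sigma2=0.01)


@pytest.fixture(scope="session")
def training_cohort(base_cfg):
    return make_cohort(12, base_cfg, seed=42)


@pytest.fixture(scope="session")
def prior_and_reference(training_cohort):
    images = [pick_frame(s.frames) for s in training_cohort]
    masks = [s.truth for s in training_cohort]
    return build_prior_from_cohort(images, masks, beta=1.0)


@pytest.fixture(scope="session")
def test_subjects(base_cfg):
    return make_cohort(5, base_cfg, seed=999)


@pytest.fixture(scope="session")
def far_init():
    """A seed circle deliberately far from the kidney (which sits centrally)."""
    return InitSpec("circle", center=(15, 15), radius=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
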
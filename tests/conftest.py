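import numpy as np
import pytest

from radstrat import CohortSpec, ROIImage, generate_cohort


def random_masked_image(rng: np.random.Generator, max_side: int = 12, levels: int = 6):
    """Small random quantized image with a random mask (>= 60% coverage),
    as (quantized array with -1 outside, mask). Used by the pair-count oracles."""
    h = rng.integers(5, max_side + 1)
    w = rng.integers(5, max_side + 1)
    mask = rng.random((h, w)) < 0.8
    q = np.where(mask, rng.integers(0, levels, (h, w)), -1)
    return q, mask


def constant_roi(value: float = 5.0, side: int = 8) -> ROIImage:
    return ROIImage(np.full((side, side), value), np.ones((side, side), bool))


@pytest.fixture(scope="session")
def small_cohort():
    """Five synthetic patients, shared across I/O and extraction tests."""
    return generate_cohort(CohortSpec(n_high=2, n_lower=3, image_size=32, seed=11))
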
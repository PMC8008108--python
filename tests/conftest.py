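import numpy as np  # noqa: F401 (used by fixtures' callers)
import pytest

from mviradiomics import CohortSpec, generate_phantom


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale phantom spec used across the geometry/extraction tests."""
    return CohortSpec(
        n_patients=6,
        prevalence=0.5,
        volume_shape=(32, 32, 32),
        spacing_mm=(2.0, 2.0, 2.0),
        tumor_radius_mm=(7.0, 9.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def phantom_pair(small_spec):
    """A matched positive/negative case pair sharing anatomy and noise."""
    pos = generate_phantom(small_spec, case_seed=5, label=1)
    neg = generate_phantom(small_spec, case_seed=5, label=0)
    return pos, neg


def random_masked_crop(rng, max_side=10, n_levels=5):
    """Random small levels/mask pair for oracle-equivalence trials."""
    shape = tuple(int(rng.integers(4, max_side + 1)) for _ in range(3))
    levels = rng.integers(1, n_levels + 1, size=shape)
    mask = rng.random(shape) < rng.uniform(0.4, 0.9)
    if mask.sum() < 2:  # keep the region non-degenerate
        mask.flat[:2] = True
    return levels, mask
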
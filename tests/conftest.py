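import numpy as np
import pytest

from agekernel import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """Tiny noise-free cohort used across modules."""
    return SyntheticConfig(
        n_participants=40,
        grid_shape=(6, 6, 6),
        noise_sd=0.0,
        behavior_noise_sd=0.0,
        missing_rate=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


def linear_truth_config(
    slope, cohort_effect=0.0, n=150, grid=(6, 6, 6), noise_sd=0.0, seed=7, age_sampling="random"
):
    """Config whose every voxel follows f(age) = slope * age exactly.

    The stored basis is quadratic in u = (age-50)/30, so a linear-in-age
    trajectory is p0 = 50*slope, p1 = 30*slope, p2 = 0.
    """
    v = int(np.prod(grid))
    poly = np.zeros((4, v, 3))
    poly[:, :, 0] = 50.0 * slope
    poly[:, :, 1] = 30.0 * slope
    return SyntheticConfig(
        n_participants=n,
        grid_shape=grid,
        trajectory_basis=poly,
        cohort_effect=cohort_effect,
        noise_sd=noise_sd,
        behavior_noise_sd=0.0,
        missing_rate=0.0,
        age_sampling=age_sampling,
        seed=seed,
    )
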
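"""Shared fixtures: seeded images and the two matched-seed organoid stacks.

The full-size well/poorly cleared stacks and their profiles are session-scoped
because several behavioral tests (center dip, protocol ranking, intensity
inversion) read the same profiles.
"""

import numpy as np
import pytest

import frcqe

MATCHED_SEED = 7


def seeded_image(shape=(16, 16), seed=0, loc=100.0, scale=20.0):
    rng = np.random.default_rng(seed)
    return rng.normal(loc, scale, size=shape)


@pytest.fixture(scope="session")
def default_params():
    return frcqe.QEParams()


@pytest.fixture(scope="session")
def poor_stack():
    return frcqe.generate_organoid_stack(
        frcqe.SyntheticSpec(degradation_mode="poorly_cleared", seed=MATCHED_SEED))


@pytest.fixture(scope="session")
def well_stack():
    return frcqe.generate_organoid_stack(
        frcqe.SyntheticSpec(degradation_mode="well_cleared", seed=MATCHED_SEED))


@pytest.fixture(scope="session")
def poor_profile(poor_stack, default_params):
    return frcqe.frc_qe_profile(poor_stack, default_params)


@pytest.fixture(scope="session")
def well_profile(well_stack, default_params):
    return frcqe.frc_qe_profile(well_stack, default_params)


@pytest.fixture(scope="session")
def small_structured_stack():
    """Compact noisy structured stack for metric unit tests (12 slices, 48x48)."""
    spec = frcqe.SyntheticSpec(shape=(12, 48, 48), organoid_radius=20, n_nuclei=60,
                               degradation_mode="well_cleared", noise_sigma=2.0, seed=3)
    return frcqe.generate_organoid_stack(spec)
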
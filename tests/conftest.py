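"""Shared fixtures: small synthetic cells for fast unit tests."""

import pytest

from vacuoquant import SyntheticParams, generate_cell


@pytest.fixture(scope="session")
def small_params() -> SyntheticParams:
    """Generator parameters for quick 32 px crops."""
    return SyntheticParams.for_image_size(32)


@pytest.fixture(scope="session")
def vacuolated_cell(small_params):
    return generate_cell(small_params, vacuolated=True, seed=3)


@pytest.fixture(scope="session")
def healthy_cell(small_params):
    return generate_cell(small_params, vacuolated=False, seed=7)


@pytest.fixture(scope="session")
def small_cell_pool(small_params):
    """30 alternating vacuolated/healthy 32 px cells with ground truth."""
    return [generate_cell(small_params, vacuolated=i % 2 == 0, seed=100 + i) for i in range(30)]
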
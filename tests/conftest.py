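import numpy as np
import pytest

from lvstrain.phantom import PhantomConfig


def circle_points(radius_mm: float, n: int, center=(0.0, 0.0)) -> np.ndarray:
    theta = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack(
        (center[0] + radius_mm * np.cos(theta), center[1] + radius_mm * np.sin(theta))
    )


@pytest.fixture
def default_config() -> PhantomConfig:
    return PhantomConfig(seed=11)


@pytest.fixture
def small_config() -> PhantomConfig:
    """Reduced study for fast structural / statistical tests."""
    return PhantomConfig(
        n_slices=3,
        n_frames=5,
        n_readers=3,
        n_markers=16,
        grid_size=64,
        base_radius=25.0,
        seed=5,
    )


@pytest.fixture
def zero_noise_config() -> PhantomConfig:
    """Single noise-free reader on one unbiased package."""
    return PhantomConfig(
        reader_noise_sd=0.0,
        reader_bias_sd=0.0,
        n_readers=1,
        n_repetitions=1,
        software_length_bias={"ref": 0.0},
        seed=3,
    )
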
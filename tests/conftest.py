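import numpy as np
import pytest

from centrofish.detection import DetectionConfig
from centrofish.simulate import FishSimConfig, TrackSimConfig, _render_gaussians


@pytest.fixture
def det2d() -> DetectionConfig:
    return DetectionConfig(psf_sigma_px=(1.3, 1.3), min_distance_px=3)


@pytest.fixture
def small_fish_config() -> FishSimConfig:
    return FishSimConfig(
        image_shape=(1, 300, 300),
        n_cells=2,
        cell_diameter_px=90,
        nucleus_diameter_px=50,
        centrosomes_per_cell=1,
        spots_per_cell=25,
        enrichment_fraction=0.5,
        seed=7,
    )


def render_spots_2d(
    points_yx: np.ndarray,
    shape: tuple[int, int],
    amplitude: float = 120.0,
    sigma: float = 1.3,
) -> np.ndarray:
    """Noiseless 2D field with Gaussian spots at the given (y, x) positions."""
    pts = np.column_stack([np.zeros(len(points_yx)), np.asarray(points_yx)])
    return _render_gaussians((1, *shape), pts, (1.0, sigma, sigma), amplitude)[0]


def noisy_spot_image(
    rng: np.random.Generator,
    points_yx: np.ndarray,
    shape: tuple[int, int] = (256, 256),
    amplitude: float = 120.0,
    background: float = 100.0,
    read_sigma: float = 2.0,
) -> np.ndarray:
    img = render_spots_2d(points_yx, shape, amplitude) + background
    return rng.poisson(img).astype(float) + rng.normal(0, read_sigma, shape)


@pytest.fixture
def brownian_config() -> TrackSimConfig:
    return TrackSimConfig(
        n_tracks=200,
        n_frames=60,
        dt=1.0,
        preset_mix={"free_cytosol": 1.0},
        loc_noise_nm=0.0,
        seed=3,
    )
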
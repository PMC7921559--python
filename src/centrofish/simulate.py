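"""Ground-truthed synthetic smFISH fields and particle tracks.

Two generators feed the test-beds of the analysis:

* ``generate_fish_image`` builds HeLa-like fields — deformed elliptical cells
  with a nested nucleus, 1-2 centrosome blobs per cell, and diffraction-limited
  mRNA spots of which a tunable fraction is placed within a set radius of a
  centrosome — rendered as 3D Gaussians over a Poisson + Gaussian-read-noise
  camera model, with the noiseless ground truth returned alongside.
* ``generate_tracks`` builds 2D trajectories that are Brownian (per-axis step
  variance 2*D*dt), anchored (Brownian with a small D), or directed at a
  constant speed along a fixed direction, plus independent localization noise.

The shipped motion presets carry the diffusion coefficients and directed-speed
range measured for ASPM polysomes: anchored on microtubules (0.011 um^2/s), at
the nuclear envelope (0.004 um^2/s), free in the cytosol (0.041 um^2/s), after
nocodazole microtubule depolymerization (0.035 um^2/s), and motor-driven
transport at 0.5-1 um/s.

Determinism: each output object draws from its own ``numpy`` Generator derived
from the master seed by a fixed offset, so identical (config, seed) pairs
reproduce outputs bit-for-bit and single objects can be regenerated alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Union

import numpy as np
import scipy.ndimage as ndi
from skimage.draw import ellipse

from .detection import ImageStack
from .motion import Track, TrackSet

__all__ = [
    "FishSimConfig",
    "FishGroundTruth",
    "MotionPreset",
    "TrackSimConfig",
    "PRESETS",
    "generate_cell_geometry",
    "generate_fish_image",
    "generate_tracks",
]

# An integer sampler is a constant, a {value: probability} table, or a
# callable rng -> int.
IntSampler = Union[int, Mapping[int, float], Callable[[np.random.Generator], int]]


def draw_int(sampler: IntSampler, rng: np.random.Generator) -> int:
    if isinstance(sampler, int):
        return sampler
    if isinstance(sampler, Mapping):
        vals = np.array(list(sampler.keys()))
        probs = np.array(list(sampler.values()), dtype=float)
        return int(rng.choice(vals, p=probs / probs.sum()))
    return int(sampler(rng))


def _sampler_can_yield_zero(sampler: IntSampler) -> bool:
    if isinstance(sampler, int):
        return sampler == 0
    if isinstance(sampler, Mapping):
        return any(v == 0 and p > 0 for v, p in sampler.items())
    return False  # callables cannot be introspected; checked at draw time


@dataclass
class FishSimConfig:
    """Study conditions of a synthetic smFISH field.

    Defaults mirror the acquisition geometry of the screen the analysis was
    built for: 100 nm lateral pixels, 600 nm z-step, 220 px cells with 140 px
    nuclei, and a 2000 nm (2 um) centrosome-proximity radius.
    """

    image_shape: tuple[int, int, int] = (9, 512, 512)
    voxel_size: tuple[float, float, float] = (600.0, 100.0, 100.0)
    n_cells: int = 2
    nucleus_diameter_px: float = 140.0
    cell_diameter_px: float = 220.0
    centrosomes_per_cell: IntSampler = field(default_factory=lambda: {1: 0.7, 2: 0.3})
    spots_per_cell: IntSampler = field(
        default_factory=lambda: (lambda rng: int(rng.poisson(40)))
    )
    enrichment_fraction: float = 0.3
    proximity_radius_nm: float = 2000.0
    psf_sigma_px: tuple[float, float, float] = (0.8, 1.3, 1.3)
    spot_amplitude: float = 150.0
    centrosome_amplitude: float = 800.0
    background_level: float = 100.0
    read_noise_sigma: float = 2.0
    poisson_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nucleus_diameter_px <= 0 or self.cell_diameter_px <= 0:
            raise ValueError("diameters must be positive")
        if self.nucleus_diameter_px >= self.cell_diameter_px:
            raise ValueError("nucleus diameter must be smaller than cell diameter")
        if not 0.0 <= self.enrichment_fraction <= 1.0:
            raise ValueError("enrichment_fraction must lie in [0, 1]")
        if self.spot_amplitude < 0 or self.centrosome_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.enrichment_fraction > 0 and _sampler_can_yield_zero(
            self.centrosomes_per_cell
        ):
            raise ValueError(
                "enrichment requested but centrosomes_per_cell can draw 0"
            )


@dataclass
class FishGroundTruth:
    """True object coordinates of a synthetic field, recorded before noise.

    Coordinates are nm (z, y, x); ``spot_coords`` and ``centrosome_coords``
    map cell label -> (n, 3) arrays. ``true_enriched_fraction`` is the
    realized per-cell fraction of spots whose 2D distance to the nearest
    centrosome is strictly below the proximity radius.
    """

    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    spot_coords: dict[int, np.ndarray]
    centrosome_coords: dict[int, np.ndarray]
    true_enriched_fraction: dict[int, float]
    proximity_radius_nm: float


@dataclass(frozen=True)
class MotionPreset:
    name: str
    model: str  # brownian | anchored | directed
    D: float = 0.0  # um^2/s
    speed: float | tuple[float, float] = 0.0  # um/s; tuple = uniform range
    notes: str = ""

    def __post_init__(self) -> None:
        if self.model not in ("brownian", "anchored", "directed"):
            raise ValueError(f"unknown motion model {self.model!r}")
        if self.D < 0:
            raise ValueError("D must be >= 0")
        if self.model == "directed":
            lo = self.speed[0] if isinstance(self.speed, tuple) else self.speed
            if lo <= 0:
                raise ValueError("directed preset needs speed > 0")


PRESETS: dict[str, MotionPreset] = {
    p.name: p
    for p in [
        MotionPreset("on_microtubule", "anchored", D=0.011,
                     notes="polysomes anchored on microtubules"),
        MotionPreset("nuclear_envelope", "anchored", D=0.004,
                     notes="polysomes at the nuclear envelope"),
        MotionPreset("free_cytosol", "brownian", D=0.041,
                     notes="freely diffusing polysomes"),
        MotionPreset("nocodazole", "brownian", D=0.035,
                     notes="single population after microtubule depolymerization"),
        MotionPreset("aspm_mrna_directed", "directed", speed=(0.5, 1.0),
                     notes="motor-driven transport toward the centrosome"),
    ]
}


@dataclass
class TrackSimConfig:
    n_tracks: int = 200
    n_frames: int = 60
    dt: float = 1.0  # s, frame interval
    preset_mix: Mapping[str, float] = field(
        default_factory=lambda: {"free_cytosol": 1.0}
    )
    loc_noise_nm: float = 30.0
    field_size_um: float = 40.0
    custom_presets: Mapping[str, MotionPreset] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if abs(sum(self.preset_mix.values()) - 1.0) > 1e-9:
            raise ValueError("preset_mix proportions must sum to 1")
        for name in self.preset_mix:
            if name not in PRESETS and name not in self.custom_presets:
                raise ValueError(f"unknown preset {name!r}")

    def preset(self, name: str) -> MotionPreset:
        return self.custom_presets.get(name) or PRESETS[name]


def _rng(seed: int, offset: int) -> np.random.Generator:
    # fixed offsets give one independent stream per output object
    return np.random.default_rng(np.random.SeedSequence([int(seed), offset]))


def generate_cell_geometry(
    config: FishSimConfig, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray, dict[int, np.ndarray]]:
    """Place non-overlapping deformed-ellipse cells with nested nuclei and
    sample centrosome positions inside each cell.

    Returns ``(cell_mask, nucleus_mask, centrosome_coords)``; masks are 2D
    int32 labels (0 = background, cell k = label k), centrosome coordinates
    are nm (z, y, x) with z at the mid-plane.
    """
    if config.n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    seed = config.seed if seed is None else seed
    rng = _rng(seed, 1)
    nz, ny, nx = config.image_shape
    cell_mask = np.zeros((ny, nx), dtype=np.int32)
    nucleus_mask = np.zeros((ny, nx), dtype=np.int32)
    centrosomes: dict[int, np.ndarray] = {}
    vz, vy, vx = config.voxel_size
    r_cell = config.cell_diameter_px / 2.0

    for label in range(1, config.n_cells + 1):
        placed = False
        for _ in range(300):
            ratio = rng.uniform(0.7, 1.0)
            angle = rng.uniform(0, np.pi)
            cy = rng.uniform(r_cell, ny - r_cell)
            cx = rng.uniform(r_cell, nx - r_cell)
            rr, cc = ellipse(
                cy, cx, r_cell, r_cell * ratio, shape=(ny, nx), rotation=angle
            )
            if np.any(cell_mask[rr, cc] != 0):
                continue
            cell_mask[rr, cc] = label
            r_nuc = config.nucleus_diameter_px / 2.0
            nrr, ncc = ellipse(
                cy, cx, r_nuc, r_nuc * ratio, shape=(ny, nx), rotation=angle
            )
            nucleus_mask[nrr, ncc] = label
            # centrosomes sampled in the cytoplasm (inside cell, outside nucleus)
            n_centro = draw_int(config.centrosomes_per_cell, rng)
            cyto = (cell_mask == label) & (nucleus_mask != label)
            pix = np.argwhere(cyto)
            coords = []
            for _ in range(n_centro):
                py, px = pix[rng.integers(len(pix))]
                jy, jx = rng.uniform(-0.5, 0.5, size=2)
                z = (nz - 1) / 2.0
                coords.append([z * vz, (py + jy) * vy, (px + jx) * vx])
            centrosomes[label] = np.asarray(coords, dtype=float).reshape(-1, 3)
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place cell {label} after 300 attempts; "
                "enlarge the field or shrink the cells"
            )
    return cell_mask, nucleus_mask, centrosomes


def _render_gaussians(
    shape: tuple[int, int, int],
    coords_px: np.ndarray,
    sigma: tuple[float, float, float],
    amplitude: float,
) -> np.ndarray:
    """Sum 3D Gaussians of peak height ``amplitude`` at continuous positions."""
    img = np.zeros(shape, dtype=np.float64)
    if len(coords_px) == 0 or amplitude == 0:
        return img
    radii = [max(int(np.ceil(4 * s)), 1) for s in sigma]
    for z, y, x in coords_px:
        zi, yi, xi = int(round(z)), int(round(y)), int(round(x))
        axes = []
        slices = []
        for c, ci, r, s, n in zip(
            (z, y, x), (zi, yi, xi), radii, sigma, shape
        ):
            lo, hi = max(ci - r, 0), min(ci + r + 1, n)
            grid = np.arange(lo, hi, dtype=float)
            axes.append(np.exp(-((grid - c) ** 2) / (2 * s**2)))
            slices.append(slice(lo, hi))
        if any(a.size == 0 for a in axes):
            continue
        img[tuple(slices)] += amplitude * (
            axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
        )
    return img


def _sample_in_mask(
    rng: np.random.Generator, mask_pixels: np.ndarray
) -> tuple[float, float]:
    y, x = mask_pixels[rng.integers(len(mask_pixels))]
    jy, jx = rng.uniform(-0.5, 0.5, size=2)
    return y + jy, x + jx


def generate_fish_image(
    config: FishSimConfig, seed: int | None = None
) -> tuple[ImageStack, FishGroundTruth]:
    """Render a 3-channel (dapi / centrosome / smfish) synthetic field.

    A fraction ``enrichment_fraction`` of each cell's spots (binomial draw) is
    placed uniformly within ``proximity_radius_nm`` (2D) of one of the cell's
    centrosomes; the rest are uniform over the cell mask.  Noise (Poisson on
    signal + background, additive Gaussian read noise) is applied last; the
    ground truth records noiseless coordinates and the realized per-cell
    enriched fraction.
    """
    seed = config.seed if seed is None else seed
    cell_mask, nucleus_mask, centrosomes = generate_cell_geometry(config, seed)
    rng = _rng(seed, 2)
    nz, ny, nx = config.image_shape
    vz, vy, vx = config.voxel_size
    r_px = config.proximity_radius_nm / vx  # lateral pixels are isotropic

    spot_coords: dict[int, np.ndarray] = {}
    frac: dict[int, float] = {}
    all_spots_px: list[list[float]] = []
    for label in sorted(centrosomes):
        cell_pix = np.argwhere(cell_mask == label)
        n_spots = draw_int(config.spots_per_cell, rng)
        centro = centrosomes[label]
        n_enriched = rng.binomial(n_spots, config.enrichment_fraction)
        if n_enriched > 0 and len(centro) == 0:
            raise ValueError(
                f"cell {label}: enrichment requested but no centrosome placed"
            )
        coords = []
        for i in range(n_spots):
            z = rng.uniform(0, nz - 1) if nz > 1 else 0.0
            if i < n_enriched:
                cz, cy, cx = centro[rng.integers(len(centro))]
                for _ in range(200):
                    r = r_px * np.sqrt(rng.uniform())
                    theta = rng.uniform(0, 2 * np.pi)
                    y = cy / vy + r * np.sin(theta)
                    x = cx / vx + r * np.cos(theta)
                    yi, xi = int(round(y)), int(round(x))
                    if (
                        0 <= yi < ny and 0 <= xi < nx
                        and cell_mask[yi, xi] == label
                    ):
                        break
                else:  # dense field fallback: sit on the centrosome
                    y, x = cy / vy, cx / vx
            else:
                y, x = _sample_in_mask(rng, cell_pix)
            coords.append([z, y, x])
        arr_px = np.asarray(coords, dtype=float).reshape(-1, 3)
        arr_nm = arr_px * np.array([vz, vy, vx])
        spot_coords[label] = arr_nm
        all_spots_px.extend(arr_px.tolist())
        if n_spots > 0 and len(centro) > 0:
            d = np.hypot(
                arr_nm[:, 1][:, None] - centro[:, 1][None, :],
                arr_nm[:, 2][:, None] - centro[:, 2][None, :],
            ).min(axis=1)
            frac[label] = float(np.mean(d < config.proximity_radius_nm))
        else:
            frac[label] = 0.0

    # render channels
    sigma = config.psf_sigma_px
    smfish = _render_gaussians(
        (nz, ny, nx), np.asarray(all_spots_px).reshape(-1, 3), sigma,
        config.spot_amplitude,
    )
    centro_px = [
        c / np.array([vz, vy, vx])
        for cs in centrosomes.values()
        for c in cs
    ]
    blob_sigma = tuple(2.0 * s for s in sigma)
    gfp = _render_gaussians(
        (nz, ny, nx), np.asarray(centro_px).reshape(-1, 3), blob_sigma,
        config.centrosome_amplitude,
    )
    zprofile = np.exp(
        -((np.arange(nz) - (nz - 1) / 2.0) ** 2) / (2 * max(nz / 3.0, 0.5) ** 2)
    )
    dapi_2d = ndi.gaussian_filter((nucleus_mask > 0).astype(float), 3.0)
    dapi = 400.0 * zprofile[:, None, None] * dapi_2d[None, :, :]

    noise_rng = _rng(seed, 3)
    channels = {}
    for name, signal in (("dapi", dapi), ("centrosome", gfp), ("smfish", smfish)):
        img = signal + config.background_level
        if config.poisson_noise:
            img = noise_rng.poisson(np.clip(img, 0, None)).astype(np.float64)
        if config.read_noise_sigma > 0:
            img = img + noise_rng.normal(0, config.read_noise_sigma, img.shape)
        channels[name] = np.clip(img, 0, None)
    if nz == 1:
        channels = {k: v[0] for k, v in channels.items()}
        voxel = (vy, vx)
    else:
        voxel = (vz, vy, vx)
    stack = ImageStack(channels=channels, voxel_size=voxel, meta={"seed": seed})
    truth = FishGroundTruth(
        cell_mask=cell_mask,
        nucleus_mask=nucleus_mask,
        spot_coords=spot_coords,
        centrosome_coords=centrosomes,
        true_enriched_fraction=frac,
        proximity_radius_nm=config.proximity_radius_nm,
    )
    return stack, truth


def _preset_counts(mix: Mapping[str, float], n: int) -> dict[str, int]:
    """Deterministic largest-remainder apportionment of n tracks."""
    names = sorted(mix)
    raw = {k: mix[k] * n for k in names}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(names, key=lambda k: (-(raw[k] - counts[k]), k))[:short]:
        counts[k] += 1
    return counts


def generate_tracks(
    config: TrackSimConfig, seed: int | None = None
) -> tuple[TrackSet, list[str]]:
    """Simulate 2D tracks from the configured preset mixture.

    Brownian/anchored steps are drawn per axis with variance 2*D*dt; directed
    tracks advance speed*dt per frame along a fixed random unit direction with
    per-track speed drawn from the preset; localization noise of std
    ``loc_noise_nm`` is added independently to every coordinate.  Returns the
    TrackSet and the per-track preset names (ground-truth labels).
    """
    seed = config.seed if seed is None else seed
    counts = _preset_counts(config.preset_mix, config.n_tracks)
    times = np.arange(config.n_frames) * config.dt
    frames = np.arange(config.n_frames)
    tracks: list[Track] = []
    labels: list[str] = []
    track_id = 0
    for name in sorted(counts):
        preset = config.preset(name)
        for _ in range(counts[name]):
            rng = _rng(seed, 100 + track_id)
            start = rng.uniform(0, config.field_size_um, size=2)
            if preset.model in ("brownian", "anchored"):
                step_sd = np.sqrt(2.0 * preset.D * config.dt)
                steps = rng.normal(0, step_sd, size=(config.n_frames - 1, 2))
                pos = start + np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
            else:
                theta = rng.uniform(0, 2 * np.pi)
                if isinstance(preset.speed, tuple):
                    v = rng.uniform(*preset.speed)
                else:
                    v = float(preset.speed)
                direction = np.array([np.cos(theta), np.sin(theta)])
                pos = start + v * times[:, None] * direction[None, :]
            if config.loc_noise_nm > 0:
                pos = pos + rng.normal(
                    0, config.loc_noise_nm / 1000.0, size=pos.shape
                )
            tracks.append(
                Track(
                    track_id=track_id,
                    frames=frames.copy(),
                    times=times.copy(),
                    positions=pos,
                )
            )
            labels.append(name)
            track_id += 1
    return TrackSet(tracks=tracks, dt=config.dt, meta={"seed": seed}), labels
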
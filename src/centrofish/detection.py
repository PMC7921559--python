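"""Single-molecule spot detection, dense-region decomposition and focus calling.

The detection pipeline mirrors the standard scale-space approach used for
smFISH quantification: a Laplacian-of-Gaussian (LoG) band-pass filter tuned to
the PSF width enhances diffraction-limited spots, a local-maximum scan lists
candidate peaks, and an automatic elbow heuristic on the candidate-intensity
survival curve separates true spots from background peaks.  Dense regions where
individual molecules overlap are decomposed by dividing their integrated
intensity by that of a reference single molecule, and mRNA foci / centrosomes
are called by DBSCAN clustering of detected spots.

All operators accept 2D ``(y, x)`` or 3D ``(z, y, x)`` arrays.  Pixel
coordinates are 0-based with a pixel-center convention; physical coordinates
are nanometres, ``nm = px * voxel_size``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from sklearn.cluster import DBSCAN

__all__ = [
    "ImageStack",
    "DetectionConfig",
    "log_filter",
    "local_maxima",
    "auto_threshold",
    "detect_spots",
    "decompose_dense_regions",
    "cluster_foci",
    "detect_centrosomes",
]

SPOT_COLUMNS = ["z_px", "y_px", "x_px", "z_nm", "y_nm", "x_nm", "intensity", "source"]
FOCUS_COLUMNS = ["focus_id", "z_nm", "y_nm", "x_nm", "n_spots", "spot_indices"]


@dataclass
class ImageStack:
    """A multichannel image with physical voxel sizes.

    ``channels`` maps a channel name (e.g. ``"dapi"``, ``"centrosome"``,
    ``"smfish"``) to a 2D or 3D intensity array; all channels share one shape.
    ``voxel_size`` is (z, y, x) in nm for 3D data, (y, x) for 2D.
    """

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels do not share one shape: {shapes}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        return self.channels[name]

    def max_projection(self) -> "ImageStack":
        """Maximum-intensity projection along z (no-op for 2D stacks)."""
        if len(self.shape) == 2:
            return self
        return ImageStack(
            channels={k: v.max(axis=0) for k, v in self.channels.items()},
            voxel_size=self.voxel_size[-2:],
            meta=dict(self.meta),
        )


@dataclass
class DetectionConfig:
    """Parameters of the spot-detection pipeline.

    psf_sigma_px
        Per-axis Gaussian width of the expected spot, in pixels. Length must
        match the image dimensionality.
    min_distance_px
        Chebyshev radius of the local-maximum neighbourhood; two returned
        peaks are never closer than this (ties broken by value, then by
        lexicographic coordinate).
    threshold_mode
        ``"auto"`` (elbow heuristic) or ``"manual"`` (use ``threshold_value``).
    dense_region_factor
        Multiple of the reference single-molecule integrated intensity above
        which a connected region is decomposed into several spots.
    n_grid
        Number of points of the linear threshold grid of the elbow heuristic.
    """

    psf_sigma_px: tuple[float, ...] = (1.3, 1.3)
    min_distance_px: int = 3
    threshold_mode: str = "auto"
    threshold_value: float | None = None
    dense_region_factor: float = 1.5
    n_grid: int = 256
    min_knee_distance: float = 0.2

    def __post_init__(self) -> None:
        if any(s <= 0 for s in np.atleast_1d(self.psf_sigma_px)):
            raise ValueError("psf_sigma_px must be positive")
        if self.min_distance_px < 1:
            raise ValueError("min_distance_px must be >= 1")
        if self.threshold_mode not in ("auto", "manual"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.threshold_mode == "manual" and self.threshold_value is None:
            raise ValueError("manual threshold_mode requires threshold_value")


def log_filter(pixels: np.ndarray, sigma: float | Sequence[float]) -> np.ndarray:
    """Sign-flipped Laplacian-of-Gaussian filter.

    The LoG is a zero-mean derivative operator (constant input maps to zero);
    the output is negated so that bright blobs of width ~sigma produce
    positive local maxima, which simplifies thresholding.
    """
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    if sigma.size == 1:
        sigma = np.repeat(sigma, pixels.ndim)
    if sigma.size != pixels.ndim:
        raise ValueError(f"sigma has {sigma.size} axes for a {pixels.ndim}D image")
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    if np.any(sigma >= np.asarray(pixels.shape)):
        raise ValueError("sigma exceeds image extent")
    out = -ndi.gaussian_laplace(pixels.astype(np.float64), sigma)
    # the truncated kernel does not sum exactly to zero; subtract its DC
    # response so a constant input maps to (numerically) zero everywhere
    probe = np.ones([min(int(8 * s) * 2 + 1, n) for s, n in zip(sigma, pixels.shape)])
    k0 = -ndi.gaussian_laplace(probe, sigma)[tuple(s // 2 for s in probe.shape)]
    return out - k0 * pixels


def local_maxima(
    filtered: np.ndarray, min_distance_px: int
) -> tuple[np.ndarray, np.ndarray]:
    """All peaks of an image with non-maximum suppression.

    A candidate pixel must be >= every neighbour within a Chebyshev radius of
    ``min_distance_px``; among candidates closer than ``min_distance_px`` to a
    stronger (or lexicographically earlier, on ties) accepted peak, only the
    winner is kept.

    Returns ``(coords, values)`` with coords of shape (n, ndim), sorted by
    decreasing value then lexicographic coordinate.
    """
    if min_distance_px < 1:
        raise ValueError("min_distance_px must be >= 1")
    d = int(min_distance_px)
    size = 2 * d + 1
    maxf = ndi.maximum_filter(filtered, size=size, mode="constant", cval=-np.inf)
    cand = np.argwhere(filtered >= maxf)
    if cand.size == 0:
        return np.empty((0, filtered.ndim), dtype=int), np.empty(0)
    values = filtered[tuple(cand.T)]
    # sort by value desc, then lexicographic coordinate
    order = np.lexsort(tuple(cand[:, ax] for ax in range(cand.shape[1] - 1, -1, -1)))
    cand, values = cand[order], values[order]
    order = np.argsort(-values, kind="stable")
    cand, values = cand[order], values[order]

    suppressed = np.zeros(filtered.shape, dtype=bool)
    keep = np.zeros(len(cand), dtype=bool)
    for i, c in enumerate(cand):
        if suppressed[tuple(c)]:
            continue
        keep[i] = True
        # suppress strictly-closer candidates (Chebyshev distance < d)
        sl = tuple(
            slice(max(ci - d + 1, 0), min(ci + d, filtered.shape[ax]))
            for ax, ci in enumerate(c)
        )
        suppressed[sl] = True
    return cand[keep], values[keep]


def threshold_curve(
    values: np.ndarray, n_grid: int = 256
) -> tuple[np.ndarray, np.ndarray]:
    """Survival curve count(t) = #values >= t over a linear grid of t."""
    values = np.sort(np.asarray(values, dtype=float))
    grid = np.linspace(values[0], values[-1], n_grid)
    counts = values.size - np.searchsorted(values, grid, side="left")
    return grid, counts


def auto_threshold(
    candidate_values: Sequence[float],
    n_grid: int = 256,
    min_knee_distance: float = 0.2,
) -> float:
    """Elbow threshold on the candidate-intensity survival curve.

    Builds count(t) = #candidates >= t over a linear grid of ``n_grid``
    points, normalizes (t, log count) to the unit square and returns the grid
    point with the largest perpendicular distance to the chord joining the
    curve's endpoints, counting only points on the convex (below-chord) side
    where an elbow lives.  Ties (an exactly linear curve) return the smallest
    grid point.

    A knee is only called when the maximum chord distance reaches
    ``min_knee_distance`` (in units of the normalized chord): survival curves
    of pure background peaks are close to log-linear and only graze below the
    chord at their top order statistics (measured distances < ~0.18 across
    field sizes), while curves with a real spot population drop well below it
    (> ~0.22 even for dense fields where spots are a few percent of the
    candidates).  Without a knee the maximum value is returned so that strict
    thresholding retains nothing.
    """
    values = np.asarray(candidate_values, dtype=float)
    if values.size < 2:
        raise ValueError("auto_threshold needs at least 2 candidate values")
    if np.all(values == values[0]):
        warnings.warn("all candidate values identical; threshold is degenerate")
        return float(values[0])
    grid, counts = threshold_curve(values, n_grid=n_grid)
    x = (grid - grid[0]) / (grid[-1] - grid[0])
    logc = np.log(counts.astype(float))
    y = (logc - logc[-1]) / (logc[0] - logc[-1])
    # signed distance to the chord y = 1 - x; positive below the chord
    dist = (1.0 - x - y) / np.sqrt(2.0)
    tol = 1e-12
    if np.all(np.abs(dist) <= tol):
        return float(grid[0])
    dmax = dist.max()
    if dmax < min_knee_distance:
        warnings.warn("no elbow in the threshold curve; returning max value")
        return float(grid[-1])
    ties = np.flatnonzero(dist >= dmax - tol)
    return float(grid[ties[0]])


def _spot_table(
    coords: np.ndarray, values: np.ndarray, voxel_size: tuple[float, ...], source: str
) -> pd.DataFrame:
    ndim = coords.shape[1] if coords.size else len(voxel_size)
    vs = np.asarray(voxel_size, dtype=float)
    rows: dict[str, np.ndarray] = {}
    if ndim == 3:
        rows["z_px"] = coords[:, 0].astype(float)
        rows["y_px"] = coords[:, 1].astype(float)
        rows["x_px"] = coords[:, 2].astype(float)
        rows["z_nm"] = rows["z_px"] * vs[0]
        rows["y_nm"] = rows["y_px"] * vs[1]
        rows["x_nm"] = rows["x_px"] * vs[2]
    else:
        n = len(coords)
        rows["z_px"] = np.zeros(n)
        rows["y_px"] = coords[:, 0].astype(float) if n else np.empty(0)
        rows["x_px"] = coords[:, 1].astype(float) if n else np.empty(0)
        rows["z_nm"] = np.zeros(n)
        rows["y_nm"] = rows["y_px"] * vs[-2]
        rows["x_nm"] = rows["x_px"] * vs[-1]
    rows["intensity"] = np.asarray(values, dtype=float)
    rows["source"] = np.repeat(source, len(coords))
    return pd.DataFrame(rows, columns=SPOT_COLUMNS)


def detect_spots(
    pixels: np.ndarray,
    voxel_size: tuple[float, ...],
    config: DetectionConfig,
) -> pd.DataFrame:
    """LoG filter -> local maxima -> threshold; returns a spot table.

    The returned DataFrame has columns ``z_px, y_px, x_px, z_nm, y_nm, x_nm,
    intensity, source``; ``intensity`` is the (sign-flipped) LoG response at
    the peak and ``source`` is ``"direct"``.  Selection is strict: a peak is a
    spot iff its response exceeds the threshold.
    """
    filtered = log_filter(pixels, config.psf_sigma_px)
    coords, values = local_maxima(filtered, config.min_distance_px)
    if len(coords) == 0:
        return _spot_table(coords, values, voxel_size, "direct")
    if config.threshold_mode == "manual":
        thr = float(config.threshold_value)  # type: ignore[arg-type]
    elif len(coords) < 2:
        thr = float(values[0]) - 1.0
    else:
        thr = auto_threshold(
            values, n_grid=config.n_grid,
            min_knee_distance=config.min_knee_distance,
        )
    keep = values > thr
    return _spot_table(coords[keep], values[keep], voxel_size, "direct")


def _integrate_regions(
    pixels: np.ndarray, labels: np.ndarray, n_regions: int, background: float
) -> np.ndarray:
    sums = ndi.sum_labels(
        pixels.astype(np.float64) - background, labels, index=np.arange(1, n_regions + 1)
    )
    return np.asarray(sums, dtype=float)


def _gaussian_stamp(sigma: np.ndarray) -> np.ndarray:
    """Unit-sum Gaussian kernel with per-axis sigma, radius 4 sigma."""
    radii = np.maximum(np.ceil(4 * sigma).astype(int), 1)
    grids = np.meshgrid(
        *[np.arange(-r, r + 1) for r in radii], indexing="ij", sparse=True
    )
    expo = sum((g.astype(float) ** 2) / (2 * s**2) for g, s in zip(grids, sigma))
    out = np.exp(-expo)
    return out / out.sum()


def decompose_dense_regions(
    pixels: np.ndarray,
    voxel_size: tuple[float, ...],
    spots: pd.DataFrame,
    config: DetectionConfig,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Split dense above-threshold regions into their constituent spots.

    The reference spot is the median integrated (background-subtracted)
    intensity of regions containing exactly one detected spot.  Any connected
    above-threshold region containing detections and whose integral is at
    least ``dense_region_factor`` times the reference is reassigned
    ``round(integral / reference)`` spots, placed by iteratively subtracting a
    PSF-shaped template from the residual and taking its peak.  Spots in
    regions below the factor are passed through unchanged (``source`` stays
    ``"direct"``).
    """
    if len(spots) == 0:
        return spots.copy()
    sigma = np.atleast_1d(np.asarray(config.psf_sigma_px, dtype=float))
    if sigma.size == 1:
        sigma = np.repeat(sigma, pixels.ndim)
    filtered = log_filter(pixels, sigma)
    if threshold is None:
        coords, values = local_maxima(filtered, config.min_distance_px)
        if config.threshold_mode == "manual":
            threshold = float(config.threshold_value)  # type: ignore[arg-type]
        else:
            threshold = auto_threshold(
                values, n_grid=config.n_grid,
                min_knee_distance=config.min_knee_distance,
            )
    mask = filtered > threshold
    labels, n_regions = ndi.label(mask)
    if n_regions == 0:
        return spots.copy()

    px_cols = ["y_px", "x_px"] if pixels.ndim == 2 else ["z_px", "y_px", "x_px"]
    spot_px = spots[px_cols].to_numpy().round().astype(int)
    spot_region = labels[tuple(spot_px.T)]
    background = float(np.median(pixels))
    integrals = _integrate_regions(pixels, labels, n_regions, background)

    region_ids, spot_counts = np.unique(spot_region[spot_region > 0], return_counts=True)
    singles = region_ids[spot_counts == 1]
    if singles.size == 0:
        raise ValueError("no isolated spots available to build a reference spot")
    reference = float(np.median(integrals[singles - 1]))
    if reference <= 0:
        raise ValueError("reference spot integral is non-positive")

    stamp = _gaussian_stamp(sigma) * reference
    radii = np.array([(s - 1) // 2 for s in stamp.shape])

    out_frames: list[pd.DataFrame] = []
    residual = pixels.astype(np.float64) - background
    for rid, n_spots_in in zip(region_ids, spot_counts):
        integral = integrals[rid - 1]
        members = spot_region == rid
        if integral < config.dense_region_factor * reference:
            out_frames.append(spots.loc[members])
            continue
        n_assign = max(int(round(integral / reference)), 1)
        region_mask = labels == rid
        sub = np.where(region_mask, residual, -np.inf)
        placed = []
        for _ in range(n_assign):
            peak = np.unravel_index(np.argmax(sub), sub.shape)
            placed.append((peak, float(pixels[peak])))
            # subtract one reference spot worth of signal around the peak
            sl_img, sl_st = [], []
            for ax, (p, r) in enumerate(zip(peak, radii)):
                lo, hi = p - r, p + r + 1
                lo_c, hi_c = max(lo, 0), min(hi, sub.shape[ax])
                sl_img.append(slice(lo_c, hi_c))
                sl_st.append(slice(lo_c - lo, stamp.shape[ax] - (hi - hi_c)))
            patch = sub[tuple(sl_img)]
            finite = np.isfinite(patch)
            patch[finite] -= stamp[tuple(sl_st)][finite]
        coords = np.array([p for p, _ in placed])
        vals = np.array([v for _, v in placed])
        out_frames.append(_spot_table(coords, vals, voxel_size, "decomposed"))
    # spots outside any region pass through untouched
    outside = spot_region == 0
    if outside.any():
        out_frames.append(spots.loc[outside])
    return pd.concat(out_frames, ignore_index=True)


def cluster_foci(
    spots: pd.DataFrame, radius_nm: float = 350.0, min_spots: int = 4
) -> pd.DataFrame:
    """DBSCAN foci from spot coordinates (eps = radius_nm, min cluster size
    = min_spots, on 2D nm coordinates); noise points are not foci and focus
    centroids are the mean of member coordinates."""
    if len(spots) == 0:
        return pd.DataFrame(columns=FOCUS_COLUMNS)
    xy = spots[["y_nm", "x_nm"]].to_numpy()
    labels = DBSCAN(eps=radius_nm, min_samples=min_spots).fit_predict(xy)
    rows = []
    for focus_id, lab in enumerate(sorted(set(labels) - {-1})):
        idx = np.flatnonzero(labels == lab)
        if idx.size < min_spots:
            continue
        members = spots.iloc[idx]
        rows.append(
            {
                "focus_id": focus_id,
                "z_nm": float(members["z_nm"].mean()),
                "y_nm": float(members["y_nm"].mean()),
                "x_nm": float(members["x_nm"].mean()),
                "n_spots": int(idx.size),
                "spot_indices": list(spots.index[idx]),
            }
        )
    return pd.DataFrame(rows, columns=FOCUS_COLUMNS)


def detect_centrosomes(
    pixels: np.ndarray,
    voxel_size: tuple[float, ...],
    config: DetectionConfig,
    radius_nm: float = 350.0,
    min_spots: int = 1,
) -> pd.DataFrame:
    """Centrosome candidates: spot detection on the centrosome-marker channel
    followed by DBSCAN focus calling.

    The marker gives one bright blob per centrosome rather than countable
    single molecules, so the cluster-size floor defaults to 1; the 350 nm
    radius still merges multi-peak blobs into one focus.
    """
    spots = detect_spots(pixels, voxel_size, config)
    return cluster_foci(spots, radius_nm=radius_nm, min_spots=min_spots)
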
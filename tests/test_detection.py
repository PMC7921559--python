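"""Detection-stage tests: LoG filter, local maxima, elbow threshold,
spot detection, dense-region decomposition and DBSCAN focus calling."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import fftconvolve

from centrofish.detection import (
    DetectionConfig,
    auto_threshold,
    cluster_foci,
    decompose_dense_regions,
    detect_centrosomes,
    detect_spots,
    local_maxima,
    log_filter,
    threshold_curve,
)
from conftest import noisy_spot_image, render_spots_2d

VOX = (100.0, 100.0)


# ---------------------------------------------------------------- log_filter


class TestLogFilter:
    def test_constant_input_maps_to_zero(self):
        img = np.full((40, 40), 500.0)
        out = log_filter(img, 1.3)
        assert np.all(np.abs(out) < 1e-6 * 500.0)

    def test_impulse_gives_global_max_at_impulse(self):
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        out = log_filter(img, 1.5)
        assert np.unravel_index(np.argmax(out), out.shape) == (20, 20)
        assert out.shape == img.shape

    def test_matches_direct_convolution_with_log_kernel(self):
        """Brute-force oracle: response to a Gaussian blob equals direct
        convolution with the (sign-flipped) LoG impulse response."""
        sigma = 1.5
        delta = np.zeros((31, 31))
        delta[15, 15] = 1.0
        kernel = log_filter(delta, sigma)
        rng = np.random.default_rng(0)
        y, x = np.mgrid[0:61, 0:61]
        blob = np.exp(-((y - 30.0) ** 2 + (x - 30.0) ** 2) / (2 * sigma**2))
        blob += 0.05 * rng.normal(size=blob.shape)
        direct = fftconvolve(blob, kernel, mode="same")
        out = log_filter(blob, sigma)
        # compare away from the border where the kernel support is truncated
        assert np.allclose(out[20:41, 20:41], direct[20:41, 20:41], atol=1e-6)
        peak = np.unravel_index(np.argmax(out[20:41, 20:41]), (21, 21))
        assert peak == (10, 10)

    def test_sigma_errors(self):
        with pytest.raises(ValueError):
            log_filter(np.zeros((10, 10)), 0.0)
        with pytest.raises(ValueError):
            log_filter(np.zeros((10, 10)), 20.0)


# -------------------------------------------------------------- local_maxima


def brute_force_local_maxima(img: np.ndarray, d: int):
    """Exhaustive neighbourhood scan + explicit pairwise suppression."""
    ny, nx = img.shape
    cands = []
    for y in range(ny):
        for x in range(nx):
            v = img[y, x]
            ok = True
            for yy in range(max(y - d, 0), min(y + d + 1, ny)):
                for xx in range(max(x - d, 0), min(x + d + 1, nx)):
                    if img[yy, xx] > v:
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                cands.append(((y, x), v))
    cands.sort(key=lambda cv: (-cv[1], cv[0]))
    accepted = []
    for (y, x), v in cands:
        if all(max(abs(y - ay), abs(x - ax)) >= d for (ay, ax), _ in accepted):
            accepted.append(((y, x), v))
    return {c for c, _ in accepted}


class TestLocalMaxima:
    def test_two_separated_impulses_both_returned(self):
        img = np.zeros((30, 30))
        img[5, 5] = 2.0
        img[5, 11] = 1.0
        coords, values = local_maxima(img, 3)
        got = {tuple(c) for c, v in zip(coords, values) if v > 0}
        assert {(5, 5), (5, 11)} <= got

    def test_equal_impulses_one_px_apart_lexicographic_winner(self):
        img = np.full((20, 20), -1.0)
        img[10, 10] = 5.0
        img[10, 11] = 5.0
        coords, values = local_maxima(img, 3)
        got = [tuple(c) for c, v in zip(coords, values) if v == 5.0]
        assert got == [(10, 10)]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("d", [1, 2, 3])
    def test_equals_exhaustive_scan_oracle(self, seed, d):
        rng = np.random.default_rng(seed)
        img = rng.normal(size=(24, 24))
        coords, _ = local_maxima(img, d)
        assert {tuple(c) for c in coords} == brute_force_local_maxima(img, d)


# ------------------------------------------------------------ auto_threshold


def brute_force_elbow(values, n_grid=256, min_knee=0.2):
    """Independent chord-distance computation via explicit point-line
    geometry over the same grid."""
    values = np.sort(np.asarray(values, dtype=float))
    grid = np.linspace(values[0], values[-1], n_grid)
    counts = np.array([(values >= t).sum() for t in grid], dtype=float)
    x = (grid - grid[0]) / (grid[-1] - grid[0])
    lc = np.log(counts)
    y = (lc - lc[-1]) / (lc[0] - lc[-1])
    # distance of (x, y) to the segment (0,1)-(1,0), signed below the line
    a, b = np.array([0.0, 1.0]), np.array([1.0, 0.0])
    ab = b - a
    dists = np.array(
        [(ab[0] * (yi - a[1]) - ab[1] * (xi - a[0])) / np.linalg.norm(ab)
         for xi, yi in zip(x, y)]
    )
    dists = -dists  # below the descending chord = elbow side
    if np.all(np.abs(dists) <= 1e-12):
        return float(grid[0])
    if dists.max() < min_knee:
        return float(grid[-1])
    best = np.flatnonzero(dists >= dists.max() - 1e-12)
    return float(grid[best[0]])


class TestAutoThreshold:
    def test_two_level_population_threshold_between_levels(self):
        values = np.array([1.0] * 100 + [10.0] * 10)
        thr = auto_threshold(values)
        assert 1.0 < thr < 10.0
        assert thr == pytest.approx(brute_force_elbow(values))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_chord_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = np.concatenate(
            [rng.normal(5, 1, 400), rng.uniform(20, 60, 25)]
        )
        assert auto_threshold(values) == pytest.approx(brute_force_elbow(values))

    def test_linear_log_count_curve_returns_smallest_grid_point(self):
        # counts 8,4,2,1 at equally spaced values: exactly linear in log-count
        values = np.repeat([0.0, 1.0, 2.0, 3.0], [4, 2, 1, 1])
        thr = auto_threshold(values, n_grid=4)
        assert thr == 0.0

    def test_count_at_threshold_not_above_count_at_min(self):
        rng = np.random.default_rng(1)
        values = np.concatenate([rng.normal(5, 1, 200), rng.uniform(30, 60, 20)])
        thr = auto_threshold(values)
        assert (values >= thr).sum() <= (values >= values.min()).sum()

    def test_identical_values_return_value_with_warning(self):
        with pytest.warns(UserWarning):
            assert auto_threshold([3.0, 3.0, 3.0]) == 3.0

    def test_threshold_curve_is_survival_curve(self):
        grid, counts = threshold_curve(np.array([1.0, 2.0, 2.0, 5.0]), n_grid=5)
        assert counts[0] == 4 and counts[-1] == 1
        assert np.all(np.diff(counts) <= 0)


# -------------------------------------------------------------- detect_spots


def greedy_match(true_yx, found_yx, tol=2.0):
    """Greedy nearest matching; returns number of true positives."""
    true = [tuple(t) for t in true_yx]
    tp = 0
    for f in found_yx:
        if not true:
            break
        dists = [np.hypot(f[0] - t[0], f[1] - t[1]) for t in true]
        i = int(np.argmin(dists))
        if dists[i] <= tol:
            tp += 1
            true.pop(i)
    return tp


class TestDetectSpots:
    def test_recall_precision_on_separated_spots(self, det2d):
        rng = np.random.default_rng(42)
        pts = np.array(
            [[30 + gy * 50, 25 + gx * 45] for gy in range(4) for gx in range(5)],
            dtype=float,
        ) + rng.uniform(-5, 5, (20, 2))
        img = noisy_spot_image(rng, pts)
        spots = detect_spots(img, VOX, det2d)
        found = spots[["y_px", "x_px"]].to_numpy()
        tp = greedy_match(pts, found)
        recall = tp / len(pts)
        precision = tp / max(len(found), 1)
        assert recall >= 0.95 and precision >= 0.95

    def test_background_only_yields_zero_spots(self, det2d):
        zero_runs = 0
        for seed in range(20):
            rng = np.random.default_rng(900 + seed)
            bg = rng.poisson(100.0, (128, 128)).astype(float)
            bg += rng.normal(0, 2, (128, 128))
            with pytest.warns(UserWarning):
                n = len(detect_spots(bg, VOX, det2d))
            zero_runs += n == 0
        assert zero_runs >= 19  # >= 95% of seeds

    def test_spot_count_non_increasing_in_manual_threshold(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(20, 230, (30, 2))
        img = noisy_spot_image(rng, pts)
        counts = []
        for thr in [0.5, 2.0, 8.0, 20.0, 50.0]:
            cfg = DetectionConfig(
                psf_sigma_px=(1.3, 1.3),
                threshold_mode="manual",
                threshold_value=thr,
            )
            counts.append(len(detect_spots(img, VOX, cfg)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_scale_equivariance_of_auto_selection(self, det2d):
        rng = np.random.default_rng(8)
        pts = rng.uniform(20, 230, (25, 2))
        img = noisy_spot_image(rng, pts)
        s1 = detect_spots(img, VOX, det2d)
        s2 = detect_spots(img * 3.7, VOX, det2d)
        assert set(map(tuple, s1[["y_px", "x_px"]].to_numpy())) == set(
            map(tuple, s2[["y_px", "x_px"]].to_numpy())
        )
        assert np.allclose(s2["intensity"], s1["intensity"] * 3.7)

    def test_nm_coordinates_scale_with_voxel_size(self, det2d):
        rng = np.random.default_rng(9)
        img = noisy_spot_image(rng, np.array([[50.0, 60.0]]), shape=(128, 128))
        spots = detect_spots(img, (150.0, 150.0), det2d)
        assert np.allclose(spots["y_nm"], spots["y_px"] * 150.0)


# ------------------------------------------------- decompose_dense_regions


class TestDecompose:
    def build_field(self):
        """Six isolated reference spots plus one clump of 3 summed copies."""
        shape = (160, 160)
        refs = np.array(
            [[25, 25], [25, 80], [25, 135], [80, 25], [135, 25], [135, 135]],
            dtype=float,
        )
        img = render_spots_2d(refs, shape, amplitude=120.0)
        clump = np.array([[84.0, 84.0], [84.0, 86.0], [86.0, 85.0]])
        img += render_spots_2d(clump, shape, amplitude=120.0)
        return img + 10.0, refs, clump

    def test_triple_clump_assigned_three_spots(self, det2d):
        img, refs, clump = self.build_field()
        spots = detect_spots(img, VOX, det2d)
        out = decompose_dense_regions(img, VOX, spots, det2d)
        dec = out[out["source"] == "decomposed"]
        near_clump = (
            np.hypot(dec["y_px"] - 85.0, dec["x_px"] - 85.0) < 6
        ).sum()
        assert near_clump == 3

    def test_isolated_spots_pass_through_as_direct(self, det2d):
        img, refs, _ = self.build_field()
        spots = detect_spots(img, VOX, det2d)
        out = decompose_dense_regions(img, VOX, spots, det2d)
        direct = out[out["source"] == "direct"][["y_px", "x_px"]].to_numpy()
        assert greedy_match(refs, direct) == len(refs)

    def test_region_below_factor_keeps_single_spot(self, det2d):
        # a 1.2x-bright single spot stays one spot under factor 1.5
        shape = (160, 160)
        refs = np.array(
            [[25, 25], [25, 80], [25, 135], [80, 25], [135, 25]], dtype=float
        )
        img = render_spots_2d(refs, shape, amplitude=120.0)
        img += render_spots_2d(np.array([[100.0, 100.0]]), shape, amplitude=144.0)
        img += 10.0
        spots = detect_spots(img, VOX, det2d)
        out = decompose_dense_regions(img, VOX, spots, det2d)
        near = np.hypot(out["y_px"] - 100, out["x_px"] - 100) < 5
        assert near.sum() == 1
        assert (out.loc[near, "source"] == "direct").all()

    def test_no_isolated_reference_raises(self):
        # every above-threshold region holds two resolved spots -> no
        # single-spot region from which to take the reference integral
        shape = (128, 128)
        pairs = np.array(
            [[30.0, 30.0], [30.0, 35.0],
             [30.0, 90.0], [30.0, 95.0],
             [90.0, 30.0], [90.0, 35.0]]
        )
        img = render_spots_2d(pairs, shape, amplitude=120.0) + 10.0
        cfg = DetectionConfig(
            psf_sigma_px=(1.3, 1.3), threshold_mode="manual", threshold_value=1.0
        )
        spots = detect_spots(img, VOX, cfg)
        assert len(spots) == 6
        with pytest.raises(ValueError, match="reference"):
            decompose_dense_regions(img, VOX, spots, cfg)


# ------------------------------------------------------------- cluster_foci


def make_spots(points_nm):
    pts = np.asarray(points_nm, dtype=float)
    return pd.DataFrame(
        {
            "z_px": 0.0,
            "y_px": pts[:, 0] / 100.0,
            "x_px": pts[:, 1] / 100.0,
            "z_nm": 0.0,
            "y_nm": pts[:, 0],
            "x_nm": pts[:, 1],
            "intensity": 1.0,
            "source": "direct",
        }
    )


class TestClusterFoci:
    def test_five_spots_in_small_ball_form_one_focus(self):
        # hand-run DBSCAN: all 5 points within 100 nm -> all core, one cluster
        pts = [[0, 0], [50, 0], [0, 50], [40, 40], [20, 10]]
        foci = cluster_foci(make_spots(pts), radius_nm=350, min_spots=4)
        assert len(foci) == 1
        assert foci.iloc[0]["n_spots"] == 5
        assert foci.iloc[0]["y_nm"] == pytest.approx(np.mean([p[0] for p in pts]))

    def test_fewer_than_min_spots_no_focus(self):
        foci = cluster_foci(make_spots([[0, 0], [10, 0], [0, 10]]), min_spots=4)
        assert len(foci) == 0

    def test_two_distant_clumps_two_foci(self):
        clump = np.array([[0, 0], [50, 0], [0, 50], [40, 40], [20, 10]], float)
        far = clump + [3500.0, 0.0]
        foci = cluster_foci(
            make_spots(np.vstack([clump, far])), radius_nm=350, min_spots=4
        )
        assert len(foci) == 2

    def test_empty_input_empty_output(self):
        assert len(cluster_foci(make_spots(np.empty((0, 2))))) == 0


class TestDetectCentrosomes:
    def test_two_blobs_two_foci_near_truth(self, det2d):
        rng = np.random.default_rng(3)
        truth = np.array([[60.0, 60.0], [150.0, 170.0]])
        img = render_spots_2d(truth, (220, 220), amplitude=800.0, sigma=2.6)
        img = rng.poisson(img + 100.0).astype(float)
        foci = detect_centrosomes(img, VOX, det2d)
        assert len(foci) == 2
        found = foci[["y_nm", "x_nm"]].to_numpy() / 100.0
        assert greedy_match(truth, found, tol=2.0) == 2

    def test_blank_channel_no_foci(self, det2d):
        rng = np.random.default_rng(4)
        img = rng.poisson(100.0, (128, 128)).astype(float)
        with pytest.warns(UserWarning):
            foci = detect_centrosomes(img, VOX, det2d)
        assert len(foci) == 0

    def test_single_blob_single_focus(self, det2d):
        rng = np.random.default_rng(5)
        img = render_spots_2d(
            np.array([[64.0, 64.0]]), (128, 128), amplitude=800.0, sigma=2.6
        )
        img = rng.poisson(img + 100.0).astype(float)
        foci = detect_centrosomes(img, VOX, det2d)
        assert len(foci) == 1
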
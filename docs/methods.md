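# Methods

`centrofish` quantifies two things: (i) how strongly smFISH-detected mRNAs
concentrate around centrosomes in segmented cells, and (ii) the mobility of
single particles (mRNAs, polysomes) from 2D trajectories. Both analyses are
exercised end to end on ground-truthed synthetic data, so this note also
states exactly what the generators emulate and what passing tests do and do
not show about real microscope data.

## Spot detection

Detection follows the standard scale-space recipe for single-molecule FISH.

**LoG filter.** The image is convolved with a sign-flipped
Laplacian-of-Gaussian tuned to the PSF width (`psf_sigma_px`, default 1.3 px
laterally for ~130 nm spots on 100 nm pixels). Bright blobs become positive
maxima. Because the truncated discrete kernel does not sum exactly to zero,
the operator's DC response is measured once and subtracted (`out - k0 * img`),
making the response to a constant image zero to machine precision.

**Local maxima.** A pixel is a candidate peak when it is >= every neighbour
within a Chebyshev radius of `min_distance_px` (default 3). Candidates closer
than that radius to a stronger peak are suppressed; exact ties go to the
lexicographically smaller coordinate. The implementation (maximum filter +
greedy suppression) is tested against an exhaustive O(N·k) neighbourhood scan.

**Automatic threshold.** Candidate peak intensities are summarized by the
survival curve count(t) = #candidates >= t over a 256-point linear grid
between the extreme values. In (t, log count) coordinates, normalized to the
unit square, the threshold is the grid point farthest below the chord joining
the curve's endpoints (the classic elbow/kneedle construction; normalizing
both axes makes the chosen index invariant to multiplying the image by a
positive constant). Two guards matter in practice:

* A knee is only *called* when that distance reaches `min_knee_distance`
  (default 0.2). Measured on simulated camera noise (Poisson + Gaussian read
  noise, 128-460 px fields) the survival curve of pure background peaks is
  close to log-linear and never dips more than ~0.18 below the chord, while
  any real spot population — from 3 dim spots to dense fields where spots are
  a few percent of candidates — dips >= 0.22. Below the cutoff no elbow
  exists, the threshold falls back to the maximum candidate value, and since
  spot selection is *strictly greater than* the threshold, background-only
  images yield zero spots.
* An exactly linear log-count curve (zero chord distance everywhere) returns
  the smallest grid value, a stated tie-break rather than a meaningful elbow.

**Dense-region decomposition.** Connected above-threshold regions are
integrated after subtracting the image median as background. Regions holding
exactly one detected spot define the reference single-molecule integral
(median over such regions); any region whose integral is at least
`dense_region_factor` (default 1.5, below which splitting is ill-posed) times
the reference is reassigned `round(integral / reference)` spots, placed by
iteratively subtracting a PSF-shaped template of one reference's worth of
intensity from the residual and taking its peak. Other spots pass through
untouched and keep the `direct` flag.

**Foci and centrosomes.** mRNA foci are DBSCAN clusters of detected spots
(eps 350 nm, minimum 4 spots, on 2D physical coordinates); cluster centroids
are member means and DBSCAN noise points are not foci. Centrosomes are called
the same way on the centrosome-marker channel, but that channel shows one
bright blob per centrosome rather than countable single molecules, so a blob
contributes a single LoG peak and the cluster-size floor defaults to 1 there
(the 350 nm radius still merges multi-peak blobs). Both parameters are
exposed.

The screen pipeline runs all detection on 2D maximum-intensity projections;
every operator nevertheless accepts 3D stacks. Pixel coordinates are 0-based
with a pixel-center convention, axis order (z, y, x), physical units nm with
`nm = px * voxel_size`.

## Cell assignment and retention

Nuclei and cells arrive as integer label masks from an external segmenter.
Each nucleus is matched to the cell with the largest pixel overlap; nuclei
with no overlap are dropped with a warning, a cell takes at most one nucleus
(conflicts resolved by larger overlap, then smaller cell id), and unmatched
cells are ignored. Points (spots, centrosome foci) map to the label of the
pixel containing them; background and out-of-bounds points stay unassigned so
the partition conserves counts exactly. A cell is retained iff it has 1 or 2
detected centrosomes and strictly more than 10 detected mRNAs ("more than 10"
is read literally: 11 keeps, 10 drops). Cells touching the image border are
kept; per-cell mRNA counts use decomposed spots by default (raw detections
are available by skipping the decomposition stage).

## Proximity statistic and group statistics

For each retained cell, f = (# spots whose 2D distance to the nearest
centrosome centroid is strictly less than r) / (# spots), with r = 2000 nm by
default. The radius is configurable; 2 um is the scale of the pericentriolar
mRNA accumulation being quantified, and distances are measured in the
projection plane to focus centroids, not region edges. f is invariant under
rigid motions of the coordinates.

Group comparisons between conditions use a one-sided Welch t test (unequal
variances, Welch-Satterthwaite degrees of freedom; the default direction
tests control mean > treated mean, since translation inhibitors abolish
localization). Both-variances-zero input returns p = 0.5 with a degenerate
flag. Proportions get Wilson score intervals; 2x2 contingency tables get the
two-sided Fisher exact test, defined as the sum of hypergeometric
probabilities (fixed margins) not exceeding the observed table's probability
within a 1 + 1e-7 relative tolerance, with p = 1 for a zero margin — this
definition is implemented directly by enumeration, with scipy's
implementation serving as an independent oracle in the tests. Distribution
summaries use linear-interpolation quartiles and whiskers at the most extreme
data within 1.5 x IQR of the quartiles; the convention is pinned because the
tests assert it exactly.

## Single-particle motion

**Linking.** Per-frame detections are linked frame-forward by minimum-cost
assignment (Hungarian algorithm on Euclidean distances). Pairs farther than
`max_link_um` (default 1.5 um) never link; track ends may bridge up to
`max_gap_frames` (default 3) missing frames at the same distance cap. This is
a deliberately simple greedy-in-time linker mirroring those stated
parameters, not a full two-pass LAP tracker; externally produced track CSVs
(with a configurable column map) are accepted as an alternative input.
Tracks shorter than 15 s (last time minus first time; exactly 15 s keeps) are
filtered out before motion statistics.

**Diffusion from displacements.** Instant 1D displacements between
consecutive frames (frame gap of exactly 1; gap-closed jumps excluded) are
pooled over x and y and fitted by a zero-mean Gaussian. The fit is the
maximum-likelihood variance — the mean squared displacement — which is
binning-free and unbiased; a least-squares fit to the binned histogram is
available for fidelity to the graphical procedure and agrees within a few
percent. The 1D relation is pinned as D = sigma^2 / (2 dt). With
localization noise of std sigma_loc per axis, the fitted variance inflates to
2 D dt + 2 sigma_loc^2; tests against ground truth use this corrected
expectation, and callers estimating D from noisy data should subtract the
noise floor if it is known.

**MSD.** The ensemble MSD aligns all tracks at their first frame:
MSD(k dt) averages |r(first + k) - r(first)|^2 over the tracks possessing
that frame, so MSD(0) = 0 by construction and each track contributes once per
lag. A through-origin least-squares fit of MSD(tau) = 4 D tau over the first
`n_fit_lags` (default 5) lags gives the cross-checking estimate D = slope/4;
restricting to early lags keeps the fit in the linear regime when directed
motion adds curvature. A time-averaged MSD is deliberately not the default.
Note the exact identity: MSD(dt) equals the mean squared 2D instant
displacement when every frame pair enters the ensemble once, hence the
histogram and MSD estimators agree on pure Brownian data up to sampling
error (|D_hist - D_msd| <= 15% of D at 200-500 tracks x 60 frames).

**Directed segments and speed.** Sliding windows of `window_frames` (default
5) consecutive positions are flagged when net displacement / path length >=
`straightness_min` (default 0.8) and net displacement / elapsed time >=
`v_min_um_s` (default 0.3 um/s); overlapping flagged windows merge into
maximal segments. Speed is net displacement over elapsed time between
segment endpoints — not path length — over at least `min_frames` frames
(5 for polysome-style movies, 3 for sparse mRNA movies). The default
thresholds are calibrated so that slow Brownian populations
(D <= ~0.015 um^2/s, the anchored polysome regime) are flagged < 5% of the
time; fast free diffusion (D ~ 0.04 um^2/s at 1 s frame intervals) exceeds
them by chance, so analyses mixing fast diffusers raise the gates (e.g.
v_min 0.6 um/s, straightness 0.9, which keeps the Brownian false-positive
rate < 1% while detecting 0.5-1 um/s runs at ~100% sensitivity). When a
target point is supplied, a segment is "toward" it when its net displacement
points within 45 degrees of the start-to-target direction.

**Classification.** Tracks are sorted into four categories with directed
precedence: directed (any directed segment) > on microtubules (>= 80% of
positions within 200 nm of the MT mask) > nuclear envelope (same rule against
the envelope ring) > free in the cytosol. Percentages are reported per cell
and sum to 100 over classified tracks; with missing masks only
directed/unclassified are reported and the summary is flagged incomplete.

## Synthetic data

The FISH generator places non-overlapping deformed-ellipse cells (random
axis ratio 0.7-1.0, random orientation — ellipses rather than circles so
mask handling sees no degenerate symmetric ties) with concentric nuclei,
samples 0-3 centrosomes per cell in the cytoplasm, and scatters each cell's
spots so that a binomially drawn fraction (`enrichment_fraction`) falls
uniformly within the proximity radius of a centrosome and the rest uniformly
over the cell. Channels (DAPI / centrosome / smFISH) are rendered as 3D
Gaussians; noise is Poisson on signal + background plus additive Gaussian
read noise (the standard camera model), applied last, with ground truth
recorded before it. Defaults mirror the target acquisition: 100 nm lateral
pixels, 600 nm z-steps, 220 px cells, 140 px nuclei, 2000 nm radius. The
realized per-cell enriched fraction is recorded from the final geometry, so
the proximity statistic on noiseless ground-truth coordinates reproduces it
exactly. Spot density and SNR are free parameters, not calibrated to any
particular instrument.

The track generator draws Brownian/anchored steps per axis with variance
2 D dt, moves directed tracks at constant per-track speed along a fixed
random direction, and adds independent localization noise to every
coordinate. Shipped presets carry the published polysome statistics: on
microtubules D = 0.011 um^2/s, nuclear envelope 0.004, free cytosol 0.041,
nocodazole 0.035, and directed transport at 0.5-1 um/s. Every output object
draws from its own generator derived from the master seed by a fixed offset,
so runs are bit-reproducible and single objects can be regenerated alone.

**What the generators do not emulate:** photophysics (blinking, bleaching),
mitotic geometry, chromatic aberration, anisotropic or spatially varying
backgrounds, segmentation errors (masks are exact by construction), motion
switching within a track, and out-of-focus loss in projections. Passing
tests therefore demonstrate correctness of the estimators under the stated
statistical model, not robustness to every artifact of real microscopy.

## Problem sizes

The shipped analyses use sizes chosen to make their statistics stable:
diffusion recovery uses 200 tracks x 60 frames (23,600 pooled displacements;
sampling error of the variance ~1.3%, comfortably inside the 10% recovery
tolerance); directed-speed estimation uses 100 tracks x 40 frames at 0.5 s;
the synthetic screen uses 100 cells per condition (20 fields of 5 cells,
single-plane 460 px fields, 80 px cells, Poisson(25) spots per cell) at
enrichment 0.6 vs 0.1, which separates the conditions at p ~ 1e-50 while the
per-cell fractions retain the large cell-to-cell spread seen in real
screens.

## Known limitations

* The linker is greedy in time; it is exact for well-separated particles
  (the tested regime) but can mis-link dense crossing trajectories that a
  global two-pass LAP would resolve.
* The decomposition model assumes additive, PSF-shaped, equal-brightness
  molecules; transcription sites or bright aggregates violate it and are
  counted as round(integral/reference) molecules.
* The elbow threshold assumes a unimodal background peak population plus a
  brighter spot population; exotic bimodal backgrounds can defeat the knee
  guard in either direction. `min_knee_distance` and a manual threshold are
  the escape hatches.
* Diffusion estimates are 2D; for 3D motion observed in projection they
  estimate the in-plane mobility.
* Anchored particles are modelled as slow Brownian motion, which is only
  locally valid: over long windows a true tether bounds the excursion while
  a slow walker does not.
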
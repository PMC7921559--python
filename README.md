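# centrofish

Quantitative analysis of centrosomal mRNA localization and single-particle
motion, for smFISH screens of transcripts that concentrate around
centrosomes (and for the live-imaging follow-up those screens motivate).

Some mRNAs encoding centrosomal proteins are physically enriched around the
centrosome, and that enrichment can be perturbed (e.g. by translation
inhibitors) or followed in live cells where single mRNAs and polysomes
diffuse, anchor, or undergo motor-driven transport. This package implements
the two quantification pipelines such experiments need:

1. **smFISH proximity screen** — detect single-molecule spots with a
   Laplacian-of-Gaussian filter and an automatic elbow threshold, decompose
   dense regions into molecule counts, call centrosomes by DBSCAN focus
   clustering of the marker channel, match nuclei to cells and assign
   detections, retain cells with 1-2 centrosomes and more than 10 mRNAs,
   and compute per cell the fraction

       f = #{spots with 2D distance to nearest centrosome < r} / #spots,

   with r = 2 um, compared across conditions by a one-sided Welch t test
   (plus Wilson score intervals, two-sided Fisher exact tests and
   1.5 x IQR boxplot summaries for the counting assays).

2. **Single-particle motion** — link detections into tracks (1.5 um cap,
   3-frame gap closing), drop tracks shorter than 15 s, pool instant 1D
   frame displacements and fit a zero-mean Gaussian whose variance gives the
   diffusion coefficient, D = sigma^2 / (2 dt); cross-check with the
   start-aligned ensemble MSD (MSD(tau) = 4 D tau for 2D Brownian motion);
   call directed segments from straightness and speed over sliding windows
   and measure transport speed as net displacement over elapsed time; and
   classify tracks into directed / on-microtubule / nuclear-envelope /
   free-cytosol categories.

Both pipelines come with ground-truthed synthetic generators (HeLa-like
fields with tunable centrosomal enrichment over a Poisson + read-noise
camera model; Brownian / anchored / directed tracks with localization
noise), so every stage is tested without microscope data. Shipped motion
presets carry measured polysome mobilities: D = 0.011 um^2/s on
microtubules, 0.004 at the nuclear envelope, 0.041 free in the cytosol,
0.035 after nocodazole, and directed transport at 0.5-1 um/s.

## Worked example

Recover the four preset diffusion coefficients from simulated tracks:

```bash
$ python analysis/03_diffusion_presets.py --seed 1
           group  D_true   D_hist    D_msd  rel_err_hist
    free_cytosol   0.041 0.040672 0.042989      0.008002
      nocodazole   0.035 0.035171 0.033331      0.004898
nuclear_envelope   0.004 0.004037 0.004213      0.009375
  on_microtubule   0.011 0.011091 0.009858      0.008254

worst histogram-estimator relative error: 0.9%
```

`D_hist` is the displacement-histogram estimate and `D_msd` the
through-origin MSD slope / 4; on 200 tracks x 60 frames both sit within ~1%
(histogram) and a few percent (MSD) of the simulated truth.

Run the synthetic proximity screen (100 cells per condition, centrosomal
enrichment 0.6 vs 0.1):

```bash
$ python analysis/02_proximity_screen.py --seed 11
condition  n_cells     mean   median       q1       q3  whisker_low  whisker_high
 enriched      100 0.683094 0.681818 0.605357 0.758966     0.480000      0.941176
  control      100 0.304585 0.290995 0.213346 0.370066     0.055556      0.600000

one-sided Welch t test (enriched > control): t = 22.60, nu = 191.3, p = 3.19e-56
```

Each row summarizes the distribution of per-cell proximity fractions f: the
enriched condition recovers a mean f of ~0.68 against ~0.30 for the control
(a uniform spot distribution still puts some spots near a centrosome by
area), and the one-sided Welch test separates the conditions decisively.

The other numbered drivers simulate a screen's image files
(`01_simulate_fish_screen.py`), measure directed-transport speeds
(`04_directed_transport.py`: median 0.751 um/s for tracks simulated at
0.75 um/s) and classify a mixed track population
(`05_track_classification.py`). A `centrofish` CLI wraps the same library
functions (`centrofish simulate-tracks`, `centrofish proximity`,
`centrofish motion`, `centrofish run --config run.yaml`).

## Library layout

| module                 | contents                                                  |
|------------------------|-----------------------------------------------------------|
| `centrofish.simulate`  | synthetic fields, tracks, motion presets                  |
| `centrofish.detection` | LoG filter, local maxima, elbow threshold, decomposition, DBSCAN foci |
| `centrofish.cells`     | nucleus-cell matching, point assignment, retention filter |
| `centrofish.proximity` | proximity fraction, Welch / Wilson / Fisher / boxplot     |
| `centrofish.motion`    | linking, displacement fits, MSD, directed segments, classification |
| `centrofish.pipeline`  | end-to-end orchestration from config files                |
| `centrofish.io`        | TIFF stacks, label masks, track CSVs                      |

See `docs/methods.md` for the statistical model behind each stage, the
numerical conventions, and what the synthetic generators do and do not
emulate.

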
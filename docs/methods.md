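# Methods

## The problem

Single-molecule localization microscopy (SMLM — PALM, STORM, PAINT) builds
a super-resolved image from the fitted positions of sparse, stochastically
activated emitters accumulated over many thousands of camera frames.  Over
the minutes an acquisition takes, thermal and mechanical drift moves the
sample by more than the localization precision σ (typically 5–20 nm), so
the pooled localization map is smeared unless the drift trajectory is
estimated and subtracted.  `msdrift` estimates that trajectory from the
localizations themselves, without fiducial markers, in 2D or 3D.

## Shift estimation by mean shift

Given two point sets A and B sampling the same emitters with a relative
translation **r**, the set of pairwise displacements {b − a} has a sharp
peak at **r** (pairs from the same molecule, per-axis width √2·σ) on a
broad background (pairs from different molecules).  The estimator is a
plain mean-shift iteration on that displacement cloud:

1. centre an observation window of radius `r_initial` on the current guess
   (zero by default);
2. collect all displacements inside the window (closed ball; KD-tree query,
   exact, with a brute-force oracle used in tests);
3. move the guess to the unweighted centroid of the collected
   displacements;
4. repeat with radius `r_window` until the centroid moves ≤ `tol`
   (default 0.1 nm) or `max_iter` (50) is reached.

The window is flat — no kernel weighting — matching the geometric picture
of redrawing a region of interest around the running mean.  Any true shift
smaller than `r_initial` is capturable from a zero start; `r_initial` is
150 nm for the simulated benchmarks (10σ shifts) and 100 nm is the
suggested value for typical experimental tables.

**Two radii.**  By default `r_window = r_initial` (fixed-radius
iteration).  For temporally binned, blinking data we recommend and use
`r_window = 50 nm` after a 150 nm capture iteration.  The reason is that
blinking makes the pairwise background *clumpy*: a molecule pair
contributes `l_i·l_j` displacements at essentially one location, so a
clump sitting 100–150 nm from the peak can drag the window centroid by
several nanometres.  A 50 nm refinement window still covers the ~21 nm
peak many times over but excludes most clumps; in our drift-series
simulations it reduces per-pair errors from ~5–9 nm to below 1 nm.

**Error estimate.**  The per-axis error attached to each shift estimate is
the standard error of the mean of the final window's displacements,
`err_k = SD(v_k)/√N`.  It shrinks when same-molecule pairs dominate and
grows when background dilutes the window, and it is the basis of both the
trajectory weights and the σ/4 robustness guide below.  It is implemented
as a swappable function (`meanshift.estimate_error`).  Known limitation:
displacement pairs sharing a localization or a molecule are correlated, so
the SEM *underestimates* the true sampling error of the window centroid on
densely sampled or strongly blinking data — by roughly the same factor for
every bin pair of a given data set.  Relative weights in the trajectory
fit are therefore still sensible, but absolute confidence intervals built
from raw SEMs undercover; see "Confidence intervals" below.

**Degenerate inputs.**  A window with fewer than `min_pairs` (10) pairs,
or fewer than 2 pairs for the error estimate, yields an estimate flagged
invalid (never an exception), which downstream fitting drops.

## Drift trajectories

Frames 1..F are divided into K non-overlapping bins of `bin_width` frames
(trailing remainder folded into the last bin so no localization is
discarded).  Mean shift is run between every bin pair i < j, giving
estimates Δ_ij with errors ε_ij.  Per axis, the control-point drifts d_k
(d_1 ≡ 0, the gauge anchor) minimize

    Σ_{i<j}  (Δ_ij − (d_j − d_i))² / ε_ij²

solved by least squares on the whitened design matrix.  The K(K−1)/2-fold
redundancy is what makes the control points much more precise than a chain
of consecutive-bin estimates.  Drift at an arbitrary frame is interpolated
linearly between control points and clamped (held constant) before the
first and after the last control time; correction subtracts the
interpolated drift from every localization.  The clamped edges leave a
small uncorrected ramp of order (drift rate × bin_width/4) at either end
of the series.

Options, all off by default:

* `exclude_adjacent` — drop pairs with j = i + 1, a diagnostic for
  blinking-induced temporal correlation.  On simulated data without long
  blink correlations it changes the fit by less than the CIs.
* `error_gate` — drop estimates whose RMS estimated error exceeds a
  threshold (σ/4 is the natural choice); the guide is ordinarily used to
  pick the bin width, not to censor pairs.
* `two_pass` — when accrued drift may exceed `r_initial`: a first pass
  chains consecutive bins only (whose relative drift is small), and the
  fitted coarse trajectory seeds the start point of every pair in the full
  redundant second pass.

**Confidence intervals.**  `ci68` is the square root of the diagonal of
the inverse weighted normal matrix, treating ε as absolute standard
deviations (no a-posteriori rescaling) — appropriate when the ε come from
a calibrated error model, and exactly 68%-calibrated in that case (tested
by Monte Carlo).  Because the SEM-based ε of real binned data
underestimates the truth by a common factor, a `chi2_rescale` switch
multiplies the covariance by the reduced chi-square of the fit, estimating
that factor from the redundancy residuals themselves.  The simulation
tests that compare recovered drift against its CI use the rescaled form.
Even rescaled CIs cannot see error components that are consistent with the
model Δ_ij = d_j − d_i across all pairs (per-bin sampling offsets); the
trajectory tests therefore validate coverage at the level the redundancy
can support (total accrued drift, median over replicates).

**Overlapping bins.**  `bin_frames_overlapping` builds 50%-overlapping
bins (stride = width/2) purely as a diagnostic.  Shared frames place
identical localizations in both members of adjacent bin pairs, producing
exact zero displacements (plus near-zero same-blink pairs) that pull those
Δ toward 0; since overlapping adjacent pairs also carry large weights,
the fitted trajectory systematically underestimates the accrued drift.
The regression test reproduces this: under linear drift with blinking
(mean run 5 frames), non-overlapping bins recover the total drift within
the rescaled CI while 50%-overlapping bins fall short by more than it.

## The simulation benchmark

`simulate_shifted_pair` draws molecules uniformly over a circular test
cell (2D) or a cylinder (3D), gives each molecule an independent
Poisson(`mean_locs`) number of localizations in each data set, adds
Gaussian localization noise (σ_xy lateral, σ_z axial), and translates the
second data set by a shift whose magnitude is uniform on (0, `shift_max`)
with isotropic direction.  Defaults are the published benchmark
conditions: σ_xy = 15 nm, shifts up to 150 nm (10σ), the easy cell at
5 molecules/µm² with 2 localizations/molecule and the hard cell at
20 molecules/µm² with 0.05.  The cell radius (5 µm) and cylinder height
(1 µm, with σ_z = 2σ_xy) are package defaults chosen to give realistic
localization counts; only scale bars, not cell sizes, are fixed by the
benchmark.

Scoring follows the benchmark conventions: **precision** is the SD of a
Gaussian (plus constant pedestal) fitted to the central peak of the
per-axis signed-error histogram, binned at σ/5 over ±4σ — robust to the
pedestal of gross failures that would dominate a raw SD; **failure rate**
is the fraction of replicates with any-axis |error| > 2σ.

`simulate_drift_series` emulates a drifting acquisition with blinking:
each molecule emits Poisson(`mean_locs`/`blink_corr`) blink runs starting
at uniform random frames, with geometric run lengths of mean `blink_corr`
frames (1 = independent single-frame blinks), one localization per frame
of a run, displaced by the supplied drift curve plus noise.  What this
does **not** model: photon-count variation (per-localization precision is
constant), clustered or structured emitter layouts (generally favourable
cases for peak finding), emitters entering/leaving the field of view,
z-dependent lateral precision, and multi-emitter fitting artifacts.
Passing tests therefore demonstrate correctness of the algorithm under
idealized photophysics, not performance on every real sample.

Drift-series study conditions used by the tests (chosen once, as
representative dSTORM-like numbers): 15,000 frames, 20 molecules/µm² over
a 2.5 µm-radius cell, 8 localizations per molecule over the series with
mean blink run 2 frames (≈ 3,200–25,000 localizations), 60 nm total drift
along a smooth ramp-plus-sine curve.  The overlap-bias diagnostic uses
10,000 frames, 5/µm² over 10 µm, 10 locs/molecule, blink run 5 frames,
and a purely linear 60/30 nm drift with 2,000-frame bins.

## Fourier ring correlation

`frc_resolution` splits the table into halves by randomly dealing
50-frame blocks (coin-flipping individual localizations would let blink
runs straddle the halves and spuriously inflate the correlation), renders
each half as a 2D position histogram at 5 nm pixels on the common bounding
box zero-padded to a square power-of-two side, and correlates the Fourier
transforms ring by ring (one frequency sample per ring, 3-ring moving
average).  The resolution is the inverse of the first frequency at which
the smoothed curve crosses 1/7 (linearly interpolated between rings); the
mean ± SD over 20 replicate splits is reported.  3D tables are evaluated
in-plane (x–y).  A curve that never crosses below Nyquist is flagged
rather than extrapolated.  The split block size, pixel size, smoothing
width and threshold are all explicit knobs, since reasonable
implementations differ in each.

Plotting FRC resolution against temporal bin width reproduces the
expected U-shape: very small bins give too few same-molecule pairs per
window (noisy or failed shift estimates jitter the trajectory), very
large bins leave intra-bin drift uncorrected, and the optimum lies
between (750–1,875 frames under the study conditions above).

## Numerical choices

* Window inclusion is a closed ball (≤ radius); the measure-zero boundary
  convention is fixed so the KD-tree path and the brute-force oracle agree
  exactly.
* The 3D window is an isotropic sphere by default; the `scale` parameter
  rescales axes before the query (an axis-aligned ellipsoid), used with
  scale (1, 1, σ_z/σ_xy) so axial pairs are collected commensurately with
  lateral ones.
* All randomness flows through `numpy` Generators seeded from explicit
  seeds or spawned `SeedSequence` children; a fixed seed reproduces tables
  bit for bit.
* The all-pairs displacement path is used below 10⁶ candidate pairs;
  beyond that a KD-tree ball query on the shifted set keeps memory and
  time near-linear in the local pair count.
* Weighted LS uses `numpy.linalg.lstsq` on the whitened system; the
  normal-matrix inverse is only formed (K−1 × K−1) for the CIs.
* Gaussian peak fits use `scipy.optimize.curve_fit` with the sample SD as
  the starting width; a degenerate histogram falls back to the sample SD
  with a warning.
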
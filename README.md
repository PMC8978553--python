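# msdrift

Drift correction for single-molecule localization microscopy (SMLM —
PALM/STORM/PAINT), in 2D and 3D, from the localizations themselves: no
fiducial markers, no image cross-correlation, no FFTs.

Over the minutes an SMLM acquisition takes, the sample drifts by more than
the localization precision σ, smearing the reconstructed image.  `msdrift`
estimates the drift trajectory directly from the localization table:

1. **Mean-shift shift estimation.**  For two point sets sampling the same
   emitters, the pairwise displacements b − a cluster sharply around the
   true relative shift (same-molecule pairs) on a broad background
   (different-molecule pairs).  An observation window (radius
   `r_initial`, 100–150 nm) is centred on the current guess and repeatedly
   recentred on the centroid of the in-window displacements until it stops
   moving — a plain mean-shift mode search, exact pair extraction by
   KD-tree.  Each estimate Δ carries a data-driven per-axis error ε (the
   standard error of the window mean).
2. **Redundant weighted trajectory fitting.**  Frames are divided into K
   non-overlapping temporal bins; Δ_ij, ε_ij are measured for *all*
   K(K−1)/2 bin pairs, and the control-point drifts d_k (d_1 ≡ 0) solve
   the weighted least-squares system Δ_ij ≈ d_j − d_i with weights
   1/ε_ij², with 68% confidence intervals from the inverse normal matrix.
   Drift at any frame is linearly interpolated and subtracted.
3. **Validation.**  A built-in simulator reproduces the standard benchmark
   (circular test cell in 2D, cylindrical volume in 3D, known shifts and
   drift curves, blinking emitters), and a Fourier ring correlation (FRC)
   module scores corrections via the 1/7-threshold resolution of random
   half-splits.

The data-driven error doubles as a robustness guide: shift estimates are
reliable while ε stays below σ/4, which is how one picks the temporal bin
width.

## Worked example

`examples/01_estimate_a_shift.py` simulates the "easy" benchmark cell
(5 molecules/µm², two localizations per molecule per data set, σ = 15 nm),
translates the second data set by a random shift, and recovers it:

```
true shift      : [-105.81   60.59] nm
mean-shift      : [-106.07   61.12] nm (6 iterations, 2021 in-window pairs)
error           : [-0.26  0.54] nm
estimated error : [0.94 0.95] nm (standard error of the window mean)
centre of mass  : [-74.47 133.08] nm  <- the baseline, typically tens of nm off
```

A >100 nm shift is recovered to sub-nanometre accuracy — an order of
magnitude below the 15 nm localization precision — while the
centre-of-mass baseline is tens of nanometres off.  The estimated error
matches the scale of the true error.

`examples/02_correct_a_drifting_series.py` runs the full pipeline on a
15,000-frame blinking acquisition with 60 nm of smooth drift:

```
simulated 3232 localizations over 15000 frames
fitted 19 control points; accrued drift [44.5 32. ] nm (truth [48.5 29.1] nm)
68% CI on the last control point: [0.63 0.65] nm
residual accrued drift after correction: [2.51 3.26] nm
```

and `examples/03_frc_resolution.py` shows what that buys in resolution:

```
FRC resolution, uncorrected: 65.5 +- 2.5 nm
FRC resolution, corrected  : 55.3 +- 1.7 nm
```

The remaining examples cover 3D estimation with an anisotropic
(z-stretched) window and the precision/failure-rate benchmark grid.

## Command line

A thin CLI wraps the same functions:

```bash
msdrift simulate --preset drift-series-2d --seed 1 --out-dir run/
msdrift drift --input run/localizations.csv --bin-frames 750 \
        --r-initial 150 --r-window 50 \
        --output-trajectory run/traj.csv --output-corrected run/corrected.csv
msdrift frc --input run/corrected.csv --replicates 20 --seed 1
```

Input tables are ThunderSTORM-style CSV (`frame, x [nm], y [nm][, z [nm]]
[, uncertainty [nm]]`); arbitrary headers can be bound with a YAML config
(`--config`), which also sets defaults for every parameter.  Each run
writes a JSON manifest sufficient to reproduce it.

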
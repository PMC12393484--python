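# Methods

This note documents the models behind each analysis, the estimators and
their numerical choices, what the simulators emulate (and do not), and the
design decisions taken where the underlying procedures are conventionally
under-specified.

## Number & Brightness

**Model.** Each pixel of a frame-scan time series holds counts F(t) from
molecules moving through the focal volume. For mobile particles on a
photon-counting detector the apparent brightness

    B = var(F) / mean(F) = 1 + ε·s,

where ε is the molecular brightness of a monomer (detected counts per
molecule per pixel dwell) and s the oligomeric stoichiometry. The "+1" is
the shot-noise contribution of photon counting. The package computes
per-pixel temporal moments (unbiased n−1 variance; the difference from the
population variance is far below recovery tolerance at 100 frames), flags
zero-mean pixels as undefined, and reports B and the apparent number
N = mean²/var.

**Detrending.** Cell movement and photobleaching add slow drifts that
inflate the temporal variance. A centered boxcar moving average (default
window 10 frames, i.e. 10% of a standard 100-frame acquisition; truncated
at the stack edges) is subtracted per pixel and the temporal mean restored,
preserving the first moment exactly. Because the subtracted window contains
the current frame, white-noise variance would be deflated by exactly
(1 − 1/w); the residuals are rescaled by √(w/(w−1)) per frame (with the
truncated per-frame window length at the edges) so the second moment of the
genuine fluctuations is unbiased. Without this correction a window of 10
depresses recovered ε by ~10 percentage points of B, which would consume
the entire recovery budget.

**Monomer calibration.** The default calibration statistic is the pooled
moment ratio over the control mask, ε = Σvar/Σmean − 1 (means over pixels).
The per-pixel ratio's sampling distribution at 100 frames is right-skewed
and its median sits ~2% low in B — negligible for bright species but an
11–17% error on ε = 0.2, where the recovery contract is 10%. A
`method="median"` option retains the median-of-B statistic for controls
contaminated by bright aggregates.

**Cursors.** Expected levels are B_s = s·ε + 1 for s ∈ {1, 2, 4}; the
"oligomer" reference is the tetramer, the standard extrapolation example.
The published procedure states levels but not interval widths; the package
uses the maximum-margin partition: monomer spans [B₁ − ε/2, mid(B₁,B₂)),
dimer [mid(B₁,B₂), mid(B₂,B₄)), oligomer [mid(B₂,B₄), ∞), and everything
below the monomer lower bound is background. Fractions are reported both
over all classified pixels (four classes summing to 1) and renormalized
over non-background pixels.

## Single-molecule tracking

**Linking.** Localizations are linked frame to frame by deterministic
minimum-cost assignment (total squared displacement, solved exactly per
frame), with three controls mirroring the standard multiple-target-tracing
parameterisation: a gap allowance of `blink_frames` (default 1) skipped
frames; truncation of each localization's candidate list to the
`max_competitors` (default 3) nearest open tracks; and a hard gate on the
displacement over a gap of g frames,

    r(g) = gate_factor · √(4·d_max·dt·(g+1)).

`d_max` is the maximum expected diffusion coefficient (3 µm²/s fast preset,
0.33 µm²/s slow preset). The gate_factor (default 2) keeps the gate a
generous quantile of the fastest expected molecule's step distribution: the
squared 2-D Brownian displacement is exponential with mean 4·D·dt·(g+1), so
a 1× radius would truncate 1 − e⁻¹ = 63% of links for a molecule at d_max
itself, and e⁻³ ≈ 5% even for one three-fold slower. Probabilistic MTT
scoring is deliberately not reproduced; at the molecule densities used
(≲5 visible molecules per frame) cost-minimizing assignment is equivalent
and exactly reproducible. Every input localization ends up in exactly one
trajectory.

**Diffusion.** The time-averaged MSD is computed at frame lags
1..min(4, span) using all position pairs at each lag, and fitted with
MSD(τ) = 4·D·τ·dt + b. The free intercept absorbs the localization-error
offset 4σ_loc² (a through-origin option exists). Non-positive slopes are
floored at D = 10⁻⁴ µm²/s so log₁₀D is defined; floored trajectories always
classify as confined. Trajectories need ≥3 positions. Per-trajectory D̂
from a handful of short lags is strongly right-skewed: the estimator is
mean-unbiased (within 5% at 10⁴ tracks, zero localization error) while its
median sits ~10% low at 20-frame tracks — both properties are asserted in
the test suite at their own tolerances.

**Confined/non-confined split.** The log₁₀D profile pooled from a control
condition is density-estimated (Gaussian KDE, Silverman bandwidth); the
threshold is the density minimum between the two highest modes. Spurious
tail bumps are ignored (a mode must reach 5% of the peak density and the
valley must dip below 90% of the lower mode), and a unimodal profile falls
back to the decision boundary of a two-component Gaussian mixture. The
threshold is estimated once and applied to all conditions; cells with fewer
than 500 trajectories are excluded and reported, and per-cell confined /
non-confined fractions and their ratio are returned.

**Residence times.** Slow-acquisition dwell durations are frame counts ×
dt (0.5 s), right-censored at the observation limit. The two-exponential
mixture survival S(t) = f·e^(−t/τ_long) + (1−f)·e^(−t/τ_short) is fitted by
maximum likelihood with the *grouped* (interval-censored) likelihood: an
uncensored dwell observed as k frames contributes S((k−1)dt) − S(k·dt),
a censored one S(t_cens). Fitting a continuous density to frame-discretized
data would bias τ_short upward by ~25% at τ_short ≈ 2·dt, which is why the
grouped form is the default whenever dt is known. Parameters are optimized
on an unconstrained scale (log τ_short, log(τ_long − τ_short), logit f) by
Nelder–Mead from 5 seeded starts; near-degenerate fits (τ ratio < 2) raise
a warning, non-convergence flags the result. The Kaplan–Meier survival
curve accompanies every fit, and an opt-in photobleaching correction
applies 1/τ_corr = 1/τ − k_bleach for a user-supplied bleach rate.

## MIEL

**Features.** Per nucleus and channel: the 13 classic co-occurrence
statistics (angular second moment, contrast, correlation, variance,
inverse difference moment, sum average/variance/entropy, entropy,
difference variance/entropy, and both information measures of correlation)
of the 64-level gray-level co-occurrence matrix, averaged over the four
directions, at pixel distances {1, 2, 4, 8}, plus mean/SD/skewness/kurtosis
of the masked intensity — 56 features per channel. Quantization spans the
masked intensity range; pixels outside the mask receive a sentinel 65th
level whose GLCM row/column is dropped before normalization, so only
intra-mask pairs count. Constant crops yield defined degenerate values
(ASM 1, entropies 0, correlation 0). The original texture-profiling
publications do not list their exact feature set; this family is the
standard Haralick lineage and is deliberately swappable.

**Pipeline.** Features are z-scored across all cells (zero-variance
features dropped with a warning; parameters stored for held-out data).
Within each condition, cells are shuffled (seeded) and partitioned into
disjoint pools of exactly n (default 60); the remainder is discarded and
counted; each center is the unweighted pool mean. Centers are reduced with
PCA (4 components, fitted on training centers only) and classified with a
linear SVM (C = 1) on the PC scores; a stratified 80/20 split gives the
confusion matrix (rows normalized to 100%) and accuracy. Because a 20%
test set of centers is small, the default averages 20 seeded splits;
`repeats=1` reproduces the literal single-split procedure. Euclidean
distances between centers give the pairwise matrix, the condition-level
matrix of mean cross-condition distances, and within-condition dispersion
(mean intra-condition pair distance; undefined and flagged for singleton
conditions). For 2-D scatter plots a regularized linear discriminant
projection is used (shrunk within-class covariance; with two conditions the
single discriminant is complemented by the leading within-class residual
PC; axis signs fixed by making the largest-magnitude loading positive).
The figure-style "discriminant" scatter and the SVM accuracy pipeline are
deliberately separate views of the same centers.

**Bootstrap pool-size rule.** Per candidate n and iteration: 80% of each
condition's cells are resampled *with replacement*, the resample is
partitioned into pools of n (condensation never resamples twice), and
PCA + SVM with a single stratified 80/20 split records an accuracy. The
optimal n is the smallest candidate reaching ≥95% accuracy in ≥95% of
iterations; if none qualifies the result is None. Infeasible candidates
(n exceeding the 80% sample of the smallest condition) are rejected up
front. Inside the bootstrap the per-condition test floor is 1 center
(an 80% resample of 500 cells at n = 60 leaves only 6 centers per
condition); outside it the classifier requires ≥2 test centers per
condition and names the offending condition otherwise.

## Simulators: what they emulate, and what they do not

* **Fluctuation stacks** — Poisson occupancy (mean N_s per species) ×
  Poisson emission (mean s·ε per molecule), giving var/mean = 1 + s·ε
  exactly; photobleaching as a deterministic ramp (linear by default,
  exponential option) applied to the *occupancy mean*, i.e. fluorophores
  going dark — a slow drift of the kind the moving average removes.
  Frames are independent samples: no raster-scan temporal correlation
  within a frame, no detector excess noise, no PSF spatial correlation.
  Default geometry mirrors a standard acquisition (100 frames, ~41 nm
  pixels, 12.5 µs dwell).
* **Trajectories** — 2-D Brownian mixtures (per-axis step SD √(2D·dt)),
  i.i.d. Gaussian localization error, blinking with at most one
  consecutive missed frame (matching the 1-frame linking gap), geometric
  track lengths with mean 20 frames and minimum 2. Twenty frames reflects
  photobleaching-limited JF-dye track survival in long fast-rate
  acquisitions and keeps trajectories comfortably longer than the largest
  MSD lag; per-track D estimation needs that margin — at a mean of 10
  frames the median D̂ skew bias alone exceeds the recovery contract.
  Track starts are spread over enough frames to keep ~5 molecules visible
  per frame unless `n_frames` is given. No within-track state switching
  (the underlying biology question — whether molecules interconvert
  between confined and free within one track — is out of scope), no
  hidden-Markov mobility.
* **Dwell times** — mixture f·Exp(τ_long) + (1−f)·Exp(τ_short),
  discretized up to whole frames (a binding event spanning any part of k
  frames is observed as k·dt, minimum one frame), right-censored at t_max
  with a flag. Defaults: τ_short = 1 s, τ_long = 12 s, f = 0.3, dt =
  0.5 s, t_max = 250 s (the slow acquisition's 500 frames × 0.5 s).
* **Feature tables** — multivariate Gaussian cells; each condition's mean
  shifted by effect_size·SD along its own fixed random unit direction
  (near-orthogonal directions in high dimension, so two conditions sit
  ≈ effect_size·√2 apart). Optional equicorrelation or per-feature
  variances. No outliers, batch effects or heavy tails.
* **Nuclei** — elliptical masks filled with a Gaussian random field
  smoothed to the condition's correlation length and rescaled to a fixed
  0–255 range. This produces textures the GLCM features separate cleanly;
  it does not emulate chromocenters, nucleoli or staining artifacts.

Passing recovery tests on these inputs demonstrates that the estimators
are correct for the models they assume; it does not certify performance on
real microscopy data, where detector noise, drift, segmentation errors and
model misspecification all enter.

**Study conditions used by tests and the acceptance script** (all seeded):
128×128×100-frame stacks for brightness recovery (ε ∈ {0.2, 0.5, 1.0}),
500-frame mixed monomer/dimer fields for cursor classification, 400-track
movies with 10% blinking for linking recall, 5000 tracks at D = 2 µm²/s
with 30 nm localization error for diffusion recovery, 3000-track mixtures
for the confined fraction, 2000 censored dwells for the residence fit,
600–1200 cells per condition for MIEL calibration, and 200 bootstrap
iterations over candidates {5, 10, 20, 40, 60} (a 5× scale-down of the
canonical 1000 that leaves the 95/95 decision rule unchanged).

## Determinism

Every stochastic step takes an explicit integer seed; there is no global
random state. Identical seeds reproduce simulator outputs bit for bit and
analysis payloads byte for byte; run manifests carry the config hash and
seed (the manifest timestamp is the only run-varying output).

## Known limitations

* The N&B "+1" detector offset assumes true photon counting; analog
  detectors need a separate calibration that is out of scope.
* The linking stage is not a full probabilistic MTT: at high molecule
  densities (≫5 per frame) assignment ambiguity will degrade gracefully
  rather than being resolved by intensity/history scoring. The spot
  detector accepts an intensity threshold rather than a localization
  p-value, and is a simplified stand-in.
* Residence-time fitting assumes exactly two exponential components;
  model selection (1 vs 2 vs 3 components) is not performed, though
  near-degenerate two-component fits are flagged.
* MIEL reproduction is at the level of the stated pipeline (z-score →
  condense → PCA(4) → linear SVM), not a bit-level match of any specific
  feature implementation.
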
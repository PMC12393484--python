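# tfscope

Quantitative live-cell imaging analyses of transcription-factor dynamics,
built around three complementary measurements of how a factor such as SOX18
engages chromatin:

* **Number & Brightness (N&B)** — moment-based fluctuation analysis of
  frame-scan image stacks. Each pixel's intensity trace F(t) gives an
  apparent brightness B = σ²/⟨F⟩; on a photon-counting detector
  B = ε + 1, where ε is the molecular brightness (counts/molecule/dwell).
  Because ε scales with stoichiometry, a monomer calibration defines
  brightness cursors (B₁ = ε+1, B₂ = 2ε+1, B₄ = 4ε+1) that map each pixel
  to monomer, dimer or oligomer, after moving-average detrending removes
  photobleaching and cell-movement drift.
* **Single-molecule tracking (SMT)** — localization linking with gap
  closing (MTT-style parameters: max expected D, 1-frame blinking, 3
  competitors), per-trajectory diffusion coefficients from a linear fit to
  the first four MSD lags (MSD = 4Dτ·dt + b), a confined/non-confined split
  at the minimum between the two modes of the log₁₀ D profile, and
  residence times from a right-censored two-exponential maximum-likelihood
  fit S(t) = f·e^(−t/τ_long) + (1−f)·e^(−t/τ_short) of slow-acquisition
  dwell durations.
* **MIEL** (microscopic imaging of epigenetic landscapes) — per-nucleus
  texture profiling: Haralick co-occurrence features + intensity moments,
  z-scored, condensed into pooled "centers" of n cells, reduced with PCA
  (4 components), classified with a linear SVM (confusion matrix, pairwise
  Euclidean distance matrices), with the pool size n chosen by bootstrap as
  the smallest n reaching ≥95% accuracy in ≥95% of iterations.

A fourth module simulates inputs with the exact statistical structure each
analysis assumes (compound-Poisson photon counts, Brownian mixtures with
localization error and blinking, censored exponential mixtures, Gaussian
feature tables and textured nuclei), so every stage is verifiable by
parameter recovery against known ground truth.

The package is aimed at microscopists and image analysts who want a tested,
scriptable reimplementation of these three pipelines rather than the
GUI/commercial tools they usually live in (SimFCS, SLIMfast, Harmony).

## Worked example

```python
import numpy as np
from tfscope import (FfsSimParams, simulate_ffs_stack, detrend_stack,
                     brightness_map, calibrate_monomer, classify_pixels)

# a 100-frame monomer acquisition with 30% photobleaching, true eps = 0.5
params = FfsSimParams(epsilon_monomer=0.5, species_mix=[(1, 50.0)],
                      n_frames=100, shape=(128, 128),
                      bleach_fraction=0.3, seed=2)
stack, truth = simulate_ffs_stack(params)

eps_raw = calibrate_monomer(brightness_map(stack)).epsilon_monomer
eps_det = calibrate_monomer(
    brightness_map(detrend_stack(stack, window=10))).epsilon_monomer
print(f"raw eps {eps_raw:.3f}  detrended eps {eps_det:.3f}")
```

prints

```
raw eps 0.727  detrended eps 0.515
```

The uncorrected calibration overestimates the molecular brightness by 45%
because the slow bleach drift inflates each pixel's temporal variance; the
10-frame moving-average detrend removes the drift and recovers the true
ε = 0.5 to within 3%.

The same analyses are available from the shell:

```bash
tfscope simulate ffs --out sim/ --seed 11
tfscope nandb --stack sim/stack.tif --out nb/
tfscope smt residence --dwells dwells.csv --out res/
tfscope miel fit --features cells.csv --pool-size 60 --out miel/
```

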
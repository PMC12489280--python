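# Methods

## Measurement model

A pollen load is measured in two modalities.

**Spectroscopy.** Six excitation wavelengths (365, 390, 395, 460, 530,
625 nm). For excitation `E` the emission grid is the consecutive integers
from `E + 50` to 740 nm (1 nm steps), i.e. `691 − E` samples; the six block
lengths are 326, 301, 296, 231, 161, 66 and sum to 1381. The 50 nm offset
keeps the excitation line and its first-order scatter out of the recorded
window; the common 740 nm endpoint makes the six grids concatenate to a
fixed-length signature. Intensities are arbitrary instrument units,
non-negative; the 10 nm monochromator bandwidth is carried as metadata only.
Feature names are `L{k}_{emission}` with `L1..L6` the excitations in
ascending order. Emission beyond 740 nm (chlorophyll-type bands) is visible
only as a rising shoulder at the grid edge — a deliberate property of the
fixed endpoint.

**Analyser.** Six RGB images, one per LED flash, same geometry. The
region of interest is found on the red channel of the 625 nm image: Otsu's
threshold splits the plane; the class whose mean differs most from the
image-border mean is foreground (this sidesteps any assumption about the
load being darker or brighter than the white paper disc); the largest
connected component is kept if it has ≥ 50 px, holes are filled, and the
contour is eroded by one pixel against background bleed. If the two Otsu
classes differ by under 8 grey levels the image is treated as contrast-free
and no load is reported — without this guard a threshold on pure camera
noise yields a percolating speckle component. The 18 features are the
per-channel arithmetic means inside the ROI, named `{excitation}{r|g|b}`.

## Camera forward model

The expected camera value for channel `c` under excitation `E` is

```
value_c(E) = clip( gain · Σ_λ S_E(λ) · R_c(λ)  +  1[E visible] · I_led · a_c · R_c(E)  +  b_c , 0, 255)
```

with `S_E` the load's emission spectrum on its grid, `R_c` the channel
sensitivity sampled at 1 nm over 400–900 nm, `a_c` the load's diffuse
reflectance, `I_led` the LED strength and `b_c` the dark level. The UV LEDs
(365/390/395 nm) lie outside the sensitivity curves, so those images are
fluorescence-only; the visible LEDs (460/530/625 nm) add a direct
reflectance term. The default response emulates an IMX219-class sensor with
the IR-cut filter removed: Gaussian curves (blue 460/σ50, green 530/σ50,
red 600/σ60) with a flat near-infrared floor of 0.2 above 700 nm on every
channel. The curves are a qualitative stand-in, configurable and never
fitted. The model is linear in spectral intensity before clipping, which the
tests exploit.

Defaults (`gain` 0.006, `I_led` 230, baseline 2) were chosen once so that
(a) typical fluorescence features land mid-range in [0, 255] and
(b) the load remains separable from the white paper under the red LED for
every colour tone, including the brightest: with the tone reflectances used
(red albedo ≤ 0.55 vs paper 1.0) the red-plane contrast stays above ~20 grey
levels even when far-red fluorescence adds to the disc.

## Synthetic species and campaigns

Each species is a mixture of 2–6 Gaussian emission bands ("fluorophores"),
each with a centre in 400–850 nm, a width of 8–45 nm and an excitation
efficiency per LED. Every species gets a strong blue band (centre
425–495 nm, efficient under UV) so its 365 nm spectrum peaks inside
415–512 nm — the blue prominence typical of pollen; 70% get a far-red
chlorophyll-like band (centre 690–820 nm) and half an extra mid-band at
least 40 nm from its neighbours. Amplitudes are uniform in 800–2500 units.
Species 1 and 2 are "congeneric": identical bands, amplitude and tone,
different mixture weights — the hardest pair by construction. Tones cycle
white/yellow/orange/green/dark; dark tones carry a ×3 analyser noise
multiplier, reproducing the observation that dark loads measure noisier.
Candidate models are redrawn (fresh substream, ≤ 100 attempts) until all
pairwise L2 distances between noise-free mean signatures exceed a floor
(default 200 units).

A sampled load is `scale · mixture(w̃) + ε`, with `scale ~ LogNormal(0,
σ=0.35)` (loads vary ~2× in brightness), `w̃ ~ Dirichlet(60·w)` (mild shape
jitter; concentration 0 disables it), `ε ~ N(0, 4)` per sample, clipped at
zero. Peak positions are species-constant. The default campaign is 14
species × 24 loads; the analyser table keeps all 336 rows while 3 random
loads are dropped from the spectroscopy table only, emulating the small
shortfall between the two instruments in a real campaign (the drop mechanism
is a stand-in; the cause of such shortfalls is not modelled).

Randomness is counter-based: every draw comes from
`SeedSequence([seed, stream, species_index, load_index])`, so adding a
species never perturbs existing loads and all artifacts are byte-identical
under a fixed seed.

**What the generator does not emulate:** real fluorophore chemistry
(band centres are not terpenoid/flavonoid/chlorophyll parameters),
instrument gain structure across plates, polyfloral loads, sample ageing,
and load-geometry effects (the rendered load is a flat disc). Passing tests
therefore demonstrate that the pipeline recovers species-specific spectral
structure under realistic noise — not that any particular accuracy carries
over to field data.

## Statistical pipeline

* **Split**: per class, `round(0.7·n)` loads (half-up) to train, rest to
  test; seeded permutation.
* **Standardization**: per-feature (mean, sd) from the training set only;
  zero-sd features map to 0. Max-normalization (peak = 1) exists separately
  for visual/averaging exports; classifier inputs always use raw intensities
  standardized this way, and per-species means default to raw intensities
  with a `normalized` option, since the plotted averages could be either.
* **PCA**: on standardized features, 10 components; rank-deficient inputs
  are padded with zero-variance components (warning) to keep shapes stable.
  The four-component variance share on default campaigns runs ~80–89%
  depending on the generator seed.
* **Grid search**: exhaustive, scored by mean stratified 10-fold CV
  accuracy, folds seeded; `k` drops to the smallest class count when needed;
  ties break first-in-grid. Default grids: SVM `C ∈ {0.01,0.1,1,10,100} ×
  kernel {linear, rbf}`, LR `C ∈ {0.01..100}`, kNN `k ∈ {3,5,7,9}`
  (Euclidean), Gaussian NB, RF `trees ∈ {100,300,500}`. The grids span the
  linear `C = 0.1, gamma='scale'` optimum reported for the original
  campaign. Accuracy is the selection metric; the bench reports both CV and
  held-out accuracy because a single printed accuracy can refer to either.
* **Metrics**: recall, precision, F1 from the confusion matrix (zero when
  undefined); ROC-AUC-OVR is the unweighted macro mean over classes of the
  one-vs-rest AUC on per-class scores (probabilities where available,
  decision values for the SVM). A single-class test set makes AUC undefined
  and is rejected.
* **Shapley attribution**: for per-class linear decision functions
  (logistic regression, or the tuned linear SVM refit one-vs-rest) the
  interventional value is closed-form, `φ_ij^c = W_cj (x_ij − mean(bg_j))`,
  with the background summarised by its mean — this makes local accuracy
  `Σ_j φ = f(x) − f(mean)` exact on every sample and testable. Non-linear
  models use a permutation Monte-Carlo estimate whose marginal contributions
  are averaged over the *entire* background set each permutation; for a
  linear scorer this reproduces the closed form to machine precision, and
  ≥ 128 permutations (512 in the tests) are used in general. Rankings use
  the global mean |φ| over samples and classes.
* **Regions**: emission wavelengths of the top-ranked features are sorted;
  a gap above 40 nm opens a new region, reported as `[min, max]` nm.
  Analyser names have no emission axis and are rejected.

## Problem sizes and determinism

The test suite and the acceptance script run everything at the default
campaign scale (333 × 1381 and 336 × 18 matrices), with imaging checks on
48–200 px rasters and 100 rendered image sets; the five-family bench runs in
well under a minute on one core and the whole acceptance script in a few
seconds. Every stochastic step — generation, splitting, fold shuffling,
label permutation, Monte-Carlo Shapley — takes its stream from the single
user seed, so identical invocations produce byte-identical tables and JSON.

## Known limitations

* The 1381-feature grid assumes the fixed 740 nm endpoint; instruments
  recording further into the infrared need a different `GridSpec`.
* Segmentation expects a single roughly convex load on a brighter-or-darker
  uniform background; touching loads or textured backgrounds are out of
  scope.
* The Monte-Carlo Shapley estimator scales as
  `permutations × features × background × samples` model evaluations and is
  meant for the 18-feature analyser space or small feature subsets, not the
  full signature space (where the linear closed form applies anyway).
* Tone labels are descriptive metadata only and are never used as
  classifier input.
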
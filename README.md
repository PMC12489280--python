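# pollensig

Species identification of honeybee pollen loads from multi-excitation
autofluorescence.

Forager honeybees pack the pollen of (usually) a single plant species into a
corbicular pellet — the *pollen load*. Because each species carries its own
cocktail of natural fluorophores, a load's autofluorescence is a taxonomic
fingerprint that can be read without destroying the sample. `pollensig`
implements the complete measurement-to-identification pipeline for the two
instruments used in the field:

* **spectroscopy** — six excitation wavelengths (365, 390, 395, 460, 530,
  625 nm, labelled L1–L6); each emission spectrum is recorded at 1 nm
  resolution from 50 nm above the excitation up to 740 nm, so a load's
  *spectral signature* is the concatenation of six blocks of
  326 + 301 + 296 + 231 + 161 + 66 = **1381 features** named `L1_415` …
  `L6_740`;
* **the pollen analyser** — a portable chamber that flashes the load with the
  same six LEDs and photographs it with an RGB camera (no IR-cut filter).
  The red channel of the red-LED image is Otsu-segmented into a region of
  interest and the three channels are averaged inside it per image, giving
  **18 features** named `{excitation}{channel}` (e.g. `365r`, `530g`).

On top of the feature extraction the package provides the chemometric and
machine-learning pipeline: `StandardScaler`-style standardization (train
statistics only), 10-component PCA, a five-family classifier bench (logistic
regression, k-NN, Gaussian naive Bayes, random forest, SVM) tuned by
exhaustive grid search under stratified 10-fold cross-validation, multiclass
metrics (per-class recall `TP/(TP+FN)`, precision `TP/(TP+FP)`,
`F1 = 2PR/(P+R)`, macro one-vs-rest ROC-AUC), Shapley feature attribution
(exact for linear one-vs-rest decision functions, permutation Monte-Carlo
otherwise), and clustering of the most influential features into contiguous
emission-wavelength regions.

Because the real measurement campaign cannot be redistributed, the package
ships a first-class synthetic generator: each species is a mixture of
Gaussian emission bands with per-LED excitation efficiencies, load-to-load
log-normal brightness variation, Dirichlet weight jitter, colour tones that
drive the imaging path's reflectance, and a camera forward model
(`value = clip(gain · Σ S(λ)R_c(λ) + reflectance + baseline, 0, 255)`) that
renders the six LED images per load.

## Worked example

```sh
python examples/04_classification_and_attribution.py
```

```
dataset: 333 loads x 1381 features, 14 species
PCA: first 4 of 10 components explain 86.8% of the variance
SVM grid search winner: {'C': 0.1, 'gamma': 'scale', 'kernel': 'linear'} (CV accuracy 1.000)
held-out: accuracy 1.000, ROC-AUC-OVR 1.000, min per-class recall 1.00 over 98 test loads

attribution method: linear-exact
top 5 features by global mean |phi|: L1_415, L1_417, L1_416, L1_418, L1_419
influential emission regions: 415-425 nm, 726-740 nm
```

Reading the output: 14 synthetic species × ~24 loads are split 70/30 per
class; the linear-kernel SVM (C = 0.1) separates all species on the held-out
30%, and the exact Shapley decomposition of its one-vs-rest decision
functions says the classifier leans on blue (415–425 nm) and far-red
(726–740 nm) emission — the two bands the generator makes most
species-specific. The other examples cover simulation (`01`), signature
arithmetic (`02`) and the imaging path (`03`).

There is also a thin CLI:

```sh
pollensig simulate --out-dir fixtures/ --seed 1 --images 1
pollensig signatures --in fixtures/spectra.csv --out signatures.csv
pollensig featurize-images --dir fixtures/images --out imgfeat.csv --truth fixtures/truth.csv
pollensig train --features fixtures/features.csv --modality analyser --family all --seed 7 --report report.json
pollensig report report.json
```

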
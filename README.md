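# hsicad

Per-pixel recognition of cancer versus healthy mucosa in hyperspectral
images (HSI) of resected colon and esophagogastric tissue, built for the
surgical computer-assisted-diagnosis setting: a camera records a 640×480
image with 100 reflectance bands over 500–1000 nm (a *hypercube*), a
pathologist annotates regions of interest, and a classifier must flag
cancer tissue on images of patients it has never seen.

The package implements the full analysis pipeline as a reusable library:

- **hsio** — hypercube (ENVI `.hdr`/`.raw`), annotation-mask (indexed PNG)
  and patient-manifest (CSV) I/O, RGB synthesis from the visible bands, and
  cohort composition statistics.
- **preprocess** — standard-normal-variate (SNV) spectral normalization
  `x ↦ (x − mean(x))/sd(x)` per pixel, which removes the additive and
  multiplicative scatter effects of tissue surface orientation; labeled
  sample extraction (spectra and 5×5×L patches, zero-padded at borders);
  random class balancing; train/validation splitting.
- **models** — classical per-pixel classifiers on SNV spectra (RBF/linear
  SVM, two-hidden-layer tanh MLP with an L-BFGS solver, random forest,
  logistic regression) and a light 3-D patch CNN with **32,232 trainable
  weights** (5×5×100 input, 2 classes), trained with SGD (lr 0.01, weight
  decay 5·10⁻⁴), Kaiming initialization, class-weighted cross-entropy,
  one 3000-patch batch per epoch and best-validation-epoch selection.
  The CNN (forward and backward passes) is implemented in numpy.
- **evaluation** — leave-one-patient-out cross-validation (LOPOCV) over
  three settings (colon, esophagogastric, combined) plus cross-dataset
  transfer; ROC-AUC (rank statistic), MCC and DICE; decision-threshold
  tuning on a 201-point grid under a *patient-generic* policy (one
  threshold maximizing the mean metric over all test images) and a
  *patient-specific* policy (per-image optimum); paired two-tailed t-tests
  and mean ± sd aggregation.
- **synthetic** — a two-organ synthetic cohort generator (12 colon
  patients of whom 2 are cancer-free, 10 esophagogastric) with
  class-dependent smooth spectral curves, patient-level scatter removable
  by SNV, contiguous elliptical tumors occupying a small minority of
  annotated pixels, and a single separation parameter Δ (Δ = 0 gives a
  null cohort where no classifier should beat chance).
- **reporting** — spectral mean ± sd curve figures, four-panel
  RGB/truth/prediction/error maps, and per-patient + aggregate results
  tables.
- **reference** — published per-patient LOPOCV ROC-AUC values and cohort
  composition tables of the clinical colon/esophagogastric cohorts,
  packaged as CSV so the aggregation and statistical machinery can be
  checked against published numbers.

The clinical hypercubes themselves are not publicly available, so the
synthetic generator stands in for them: it reproduces the *statistical
structure* the pipeline relies on, not real tissue optics.

## Worked example

Simulate a small cohort and evaluate an RBF-SVM with LOPOCV on the colon
group:

```sh
hsicad simulate --out demo --seed 7 --size 48 --n-colon 4 --n-eg 4
hsicad evaluate --manifest demo/manifest.csv --setting colon \
                --model rbf_svm --seed 7 --out demo_results
```

which prints

```
                    roc_auc mcc_patient_generic mcc_patient_specific dice_patient_generic dice_patient_specific
setting
colon:rbf_svm  0.99 ± 0.005         0.44 ± 0.51          0.45 ± 0.52          0.81 ± 0.22           0.96 ± 0.05
```

and writes `per_patient.csv`:

```
,colon:rbf_svm
colon_01,/
colon_02,/
colon_03,0.99
colon_04,0.99
```

Reading the output: the two cancer-free patients (`colon_01`, `colon_02`)
have no ROC-AUC — the metric is undefined without positive pixels — and
are shown as `/`; they still enter MCC/DICE as all-negative images, where
the MCC convention maps a degenerate confusion table to 0 (hence the large
MCC spread). On the two cancer-bearing patients the model ranks cancer
pixels above healthy ones essentially perfectly (AUC 0.99), and the
patient-specific threshold lifts DICE from 0.81 to 0.96 — the gap that
motivates interactive per-patient threshold tuning.

The same flow with `--model cnn3d --epochs 20` trains the 3-D patch CNN;
`hsicad report --manifest demo/manifest.csv --out figures` renders the
spectral-curve figures, and `--checkpoint` adds prediction/error maps.

## Caveats

- The train/validation split used for CNN epoch selection is over pixels,
  not patients; pixels of one patient can appear on both sides. This
  mirrors the evaluated training recipe and is optimistically biased for
  the validation loss (not for the held-out-patient test metrics, which
  are always patient-disjoint).
- The patient-generic threshold is tuned on the test images, an oracle
  upper bound for any fixed-threshold deployment; a train-derived variant
  would be strictly harder.
- Synthetic spectra are phenomenological Gaussian-feature mixtures; see
  `docs/methods.md` for what passing tests do and do not imply about real
  tissue data.
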
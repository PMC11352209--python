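# sersdx

Label-free SERS liquid-biopsy classification for thyroid fine-needle-aspiration
(FNA) washout fluids: a tested, reusable implementation of the full analysis
workflow — synthetic spectral cohort generation, spectral preprocessing, four
classification models, patient-level evaluation, and CNN interpretability.

## The problem

Thyroid nodules are screened by FNA cytology; the washout fluid left over
after cytology is a cheap liquid-biopsy specimen. Mixed with silver
nanoparticle colloids it yields surface-enhanced Raman spectra (SERS) whose
vibrational bands — e.g. 747 cm⁻¹ (adenine/cytochrome c), 1038 cm⁻¹
(collagen/phospholipids/phenylalanine), 1163, 1396 and 1616 cm⁻¹ — shift in
relative intensity between malignant and benign samples. A classifier over
these spectra can support rapid malignant-vs-benign triage.

Clinical spectra of this kind are not publicly deposited, so `sersdx` ships a
first-class synthetic cohort generator that reproduces the study design (18
patients, one malignant and one benign sample each, 100 spectra per sample,
300–2000 cm⁻¹) and the statistical structure the analysis must cope with:
class-dependent band amplitudes, a constant preservation-buffer band near
1036 cm⁻¹, a smooth fluorescence-like background, and hierarchical
patient → sample → spectrum noise. Every downstream stage is testable against
this generator's known ground truth.

## Methods at the core

**Preprocessing** (per spectrum): Savitzky–Golay smoothing (window 5, order
3) → airPLS baseline removal → crop to the 300–1800 cm⁻¹ fingerprint region →
min–max normalization to (0, 1). airPLS estimates the baseline z as the
minimizer of the weighted Whittaker objective

    Σᵢ wᵢ (yᵢ − zᵢ)² + λ Σ (Δᵈ z)²,      λ = 150, d = 3,

iteratively zeroing the weights on channels above the baseline (peaks) and
exponentially up-weighting channels below it until the negative-residual mass
falls under 0.1 % of the total signal. The solve is a symmetric banded linear
system (`scipy.linalg.solveh_banded`), verified in the tests against an
independent dense solve.

**Classifiers**, all behind one contract (`score_dataset` → per-spectrum
malignancy score, malignant = 1):

| model | definition | score |
|---|---|---|
| PCA-LDA | PCA to 95 % explained variance, ≤ 12 components; two-class Fisher LDA | signed discriminant |
| RF | 200 trees on raw channel intensities | fraction of tree votes |
| SVM | soft-margin SVC, RBF kernel, C = 1 | signed decision value |
| CNN | 3 × (conv–ReLU–maxpool), dense head, sigmoid; Adam on BCE, lr 10⁻³ halved on validation plateau, batch 64, ≤ 50 epochs, minimum-validation-loss snapshot | sigmoid output |

The CNN is implemented directly on NumPy (im2col convolutions, manual
backpropagation), which also yields exact input gradients for attribution.

**Evaluation**: patients are shuffled and assigned 10:3:5 to
train/validation/test (the classical models merge train+validation, 13:5;
the test patients are identical across modes). All spectra of one sample
stay in one partition — the hierarchical noise makes spectrum-level splitting
leak sample fingerprints, which the tests demonstrate the split prevents.
Spectrum-level sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy
(TP+TN)/total, and ROC/AUC (trapezoidal; equals the Mann–Whitney pairwise
statistic).

**Interpretability**: gradient × input on the CNN's pre-sigmoid logit,
averaged over the test set, smoothed, and reduced to ranked local extrema —
positive contributions push toward malignant.

## Worked example

`python examples/03_train_and_compare_models.py` (reduced cohort, 5 cm⁻¹
grid, ~1 min) prints:

```
model     accuracy  sensitivity  specificity     AUC
pca_lda     0.8920       0.9120       0.8720   0.969
rf          0.9160       0.9280       0.9040   0.964
svm         0.9160       0.9600       0.8720   0.990
cnn         0.9400       0.9360       0.9440   0.982
(spectrum-level metrics on the 5 held-out test patients)
```

Each row is one model evaluated on the spectra of the five held-out test
patients: e.g. the CNN labels 94.0 % of test spectra correctly, catches
93.6 % of malignant spectra (sensitivity), 94.4 % of benign ones
(specificity), and ranks a random malignant spectrum above a random benign
one with probability 0.982 (AUC). Numbers are properties of the synthetic
cohort and its seed, not clinical performance.

The other examples cover cohort generation (`01`), preprocessing and the
malignant-minus-benign difference spectrum (`02`), and CNN band attribution
(`04`). The same stages are available from the shell:

```bash
sersdx run-all --out-dir runs/demo --seed 1
```

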
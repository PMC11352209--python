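# Methods

This note records the models, numerical choices and open design decisions
behind `sersdx`, and what the synthetic cohort does and does not establish
about real FNA-washout SERS data.

## Synthetic cohort generator

One spectrum of sample *s* (patient *q*, class indicator *c*, malignant = 1)
on the wavenumber grid *x* is

    y(x) = Σₖ aₖ Lₖ(x) + buffer(x) + baseline(x) + ε(x),   clipped at 0
    aₖ   = baseₖ + c·effect_scale·δₖ + u_qk + v_sk
    u_qk ~ N(0, σ_patient²),   v_sk ~ N(0, σ_sample²)      (per band)
    ε(x) ~ N(0, σ_noise²)                                  (per channel)

with Lₖ a unit-apex Lorentzian `1/(1+((x−cₖ)/wₖ)²)` (HWHM wₖ; Lorentzians
are the canonical Raman line shape; a Gaussian option sits behind
`line_shape="gaussian"`). Defaults:

* Grid 300–2000 cm⁻¹ at 1 cm⁻¹ (1701 channels). The source measurement
  design states the range but not the channel count; the spacing is an
  assumption recorded in `GridSpec` and freely configurable.
* Band library: 747, 1038, 1163, 1396, 1616 cm⁻¹ (widths 9–12 cm⁻¹, base
  amplitudes 0.45–0.80 a.u.) carrying malignant-minus-benign deltas
  0.20/0.40/0.10/0.24/0.30; a class-neutral residual-ethanol band at
  1459 cm⁻¹; the preservation-buffer band at 1036 cm⁻¹ (class-neutral by
  construction and enforced by config validation).
* Baseline: cubic polynomial in the normalized coordinate plus a broad
  Lorentzian wing centred at 150 cm⁻¹ (below the measured range), total
  magnitude on the order of the band amplitudes, so baseline removal has
  realistic work to do.
* Noise scales σ_patient = σ_sample = 0.10, σ_noise = 0.02 (a.u.).

No quantitative effect sizes exist for the real assay (the published
difference spectrum is graphical), so the deltas are free parameters. They
were fixed once by the design rule that a plain linear classifier on
preprocessed spectra should reach roughly 0.85–0.95 spectrum-level AUC —
the "tumor heterogeneity" regime in which the model comparison is
interesting — measured at 0.84–0.90 (mean 0.875) over four seeds with a
linear SVM. Notably, per-spectrum min–max normalization removes much of the
raw apex-amplitude signal (a band that sets the spectrum maximum is scaled
to 1 regardless of class), so class information survives mainly through
band ratios; this is why the deltas are larger than a naive
signal-to-noise argument would suggest.

Patient and sample effects are shared by all replicate spectra of a sample,
so spectra are exchangeable only within samples. This is the structure that
makes spectrum-level splitting leak (a model can memorize sample
fingerprints) and patient-level splitting necessary; the permutation-null
tests rely on it.

Clipping at zero keeps intensities physical; with the default baseline
(≥ 0.36 a.u. everywhere) and σ_noise = 0.02 it essentially never triggers,
but at very low amplitudes it would bias means upward — documented, not
corrected.

What the generator does **not** emulate: instrument response and wavenumber
calibration drift, cosmic rays, heteroscedastic shot noise, band-position
shifts between classes (only intensities move), correlated multi-band
biochemistry, and non-Gaussian patient heterogeneity. Passing tests
demonstrate algorithmic correctness and the soundness of the evaluation
protocol, not clinical performance.

## Preprocessing

Stage order: Savitzky–Golay → airPLS → crop → normalize. The source
protocol lists smoothing, baseline correction and normalization in that
order and mentions the 300–1800 cm⁻¹ fingerprint crop separately; cropping
before normalization guarantees the analyzed window itself spans [0, 1].
Normalization is per spectrum (standard chemometrics practice; a
dataset-level alternative would couple test spectra to training statistics).

* **Savitzky–Golay** (window 5, order 3) via `scipy.signal.savgol_filter`
  with `mode="interp"`: edge values come from evaluating the polynomial
  fitted to the nearest full window — no data are invented by padding.
  Verified against an explicit per-window normal-equations fit (≤ 1e−10).
* **airPLS** (λ = 150, difference order d = 3, ≤ 15 iterations, tolerance
  1e−3 of total signal magnitude): weights start at 1; after each banded
  Whittaker solve, wᵢ ← 0 where yᵢ ≥ zᵢ and wᵢ ← exp(t·|dᵢ|/‖d‖₁) where
  yᵢ < zᵢ (d the negative residuals, t the iteration). Non-convergence
  returns the last baseline and logs a warning. The banded path equals an
  independent dense solve to 1e−8.
  A numerical observation worth recording: the Whittaker smoothing length
  is ≈ λ^(1/2d) channels, i.e. ~2–3 channels at λ = 150, d = 3 on a
  1 cm⁻¹ grid. The fitted baseline is therefore locally flexible and
  follows part of each band's height; correction removes background *and*
  attenuates absolute band amplitude, leaving class information largely in
  band ratios. With a stiffer λ (say 1e6) bands survive almost fully; the
  parameter values here are the published ones and are kept as defaults.
* **Normalization** maps min → 0, max → 1 per spectrum; a constant
  spectrum is a degenerate-input error.
* **Group aggregation** is two-stage: per-sample mean spectra first, then
  the unweighted mean (and n−1 SD) across sample means, so unbalanced
  replicate counts cannot skew a group mean. The difference spectrum is
  malignant minus benign group mean.

## Classifiers

All four expose `score_dataset` (higher = more malignant) plus a default
threshold: 0.5 for probability-like scores (RF vote fraction, CNN sigmoid),
0 for margin scores (PCA-LDA, SVM). Class encoding malignant = 1 is used
by every model and metric.

* **PCA-LDA**: deterministic full-SVD PCA on centred spectra; keep the
  smallest k whose cumulative explained variance reaches 95 %, capped at 12
  (the cap binds on data that need more; k = min(cap, components-to-95 %)
  resolves the ambiguity of "12 vectors explaining 95 %"). Two-class
  Fisher LDA on the scores with a ridge of 1e−6·trace/k on the
  within-class scatter diagonal (k up to 12 with few patients can be
  ill-conditioned). Cross-checked against scikit-learn's LDA on the same
  scores (identical AUC).
* **RF**: scikit-learn forest, 200 trees, seeded, trees grown to purity so
  per-tree probabilities are 0/1 votes and the score is the vote fraction.
* **SVM**: scikit-learn SVC. Kernel and C are nowhere stated for the
  original assay; defaults RBF, C = 1, `gamma="scale"` are a documented
  assumption, configurable.
* **CNN**: input is the cropped, normalized spectrum as a single-channel
  1-D signal, no augmentation. Default stack: three conv blocks (16/32/64
  filters, kernel 7, stride 1, ReLU, max-pool 2), flatten, dense 64, ReLU,
  dense 1, sigmoid. The original assay never disclosed its exact layer
  shapes, so the architecture is a documented default, fully configurable
  via `CnnConfig`. Training: Adam (β = 0.9/0.999) on
  binary cross-entropy computed on logits (softplus form, numerically
  safe), batch 64, initial lr 1e−3. The decay schedule is stated only as
  "factor 0.5"; implemented as halving after 5 epochs without validation
  improvement (standard plateau rule). The returned model is the
  minimum-validation-loss snapshot; training additionally stops after 15
  improvement-free epochs, which cannot change the selected snapshot
  materially and keeps CPU training in minutes. Everything (He-uniform
  init, batch order) derives from `config.seed`; float32 throughout.
  The network is hand-implemented on NumPy with im2col convolutions
  lowered to BLAS GEMM and manual backpropagation, gradient-checked
  against central finite differences in the tests.

## Splitting and evaluation

`split_patients` shuffles patient ids with a seeded generator and assigns
them contiguously by the requested ratio with largest-remainder rounding
(18 patients at 10:3:5 → exactly 10/3/5). Two-way mode folds validation
into train *after* the same three-way assignment, so the test partition is
identical across modes at a given seed — all four models are compared on
the same held-out patients. A ratio part that is positive but receives no
patients is an error.

Metrics are spectrum-level (each spectrum one unit); four-decimal
accuracies on a 5-patient test set, as the original workflow reports, are
only arithmetically possible at spectrum level. A per-sample majority-vote summary
(`patient_level_votes`) is provided as a clearly-labelled supplement.
ROC is a full threshold sweep (`drop_intermediate=False`) with trapezoidal
AUC, which equals the Mann–Whitney pairwise statistic with ties counted
half — asserted against an O(n²) enumeration.

## Saliency

The attribution method behind the original peak-contribution figure is not
described; gradient × input on the pre-sigmoid logit, averaged over the
evaluation set, was chosen because it is deterministic and has a
closed-form oracle (for a linear model the profile is exactly
w ⊙ mean(x)). The averaged profile is SG-smoothed (window 5, order 3) and
reduced to local extrema with ≥ 10 cm⁻¹ separation, ranked by |value|;
positive = toward malignant. A sliding-window occlusion profile is
available as a model-agnostic robustness check. Quantitative agreement
with the original figure is not claimed.

## Pipeline and provenance

`run_all` derives each stage's seed as CRC32(global_seed, stage name)
(< 2³¹), so adding or removing a stage never shifts another stage's
randomness. Artifacts are CSV/JSON with a run manifest recording versions,
config echo, stage seeds and SHA-256 checksums; re-running a config
reproduces the checksums bit-for-bit. Dataset text I/O uses 9 significant
digits, which round-trips the float64 values used in analysis to ~1e−8
relative — exact enough that a written-and-reread dataset re-serializes
byte-identically.

## Problem sizes in the test suite

Model-level tests run on reduced cohorts (typically 8 patients × 2 samples
× 12–16 spectra on a 5 cm⁻¹ grid) — the statistical structure is identical
and every algorithmic path is exercised; the full-size cohort (18 patients,
3600 spectra × 1701 channels, CNN at full resolution and ≤ 50 epochs) runs
in the end-to-end suite and in `scripts/acceptance.py`. Null-recovery
assertions average over 5–10 seeds because a single 2-patient test
partition is individually noisy.

## Known limitations

* Synthetic data only; no claim transfers to clinical spectra.
* airPLS at the published λ attenuates band amplitudes (see above); users
  analyzing real spectra on finer grids may want λ scaled with sampling
  density.
* The CNN is CPU-oriented; very large architectures will be slow compared
  to GPU frameworks.
* No cross-validation or AUC confidence intervals (out of scope of the
  reproduced protocol); single-split results on 5 test patients carry
  substantial seed-to-seed variance, which the examples make visible.
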
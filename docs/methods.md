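# Methods

`oralftir` implements a complete chemometric analysis of transmission-mode
FTIR hyperspectral images of oral biopsy sections, from raw 16×16-pixel
imaging areas to a per-sample risk grade for epithelial dysplasia. Because
clinical FTIR biopsy datasets of this kind are not publicly deposited, the
package ships a first-class synthetic-data module that emulates the study
design the analysis targets; every downstream stage is developed and tested
against that generator's known ground truth.

## The synthetic cohort

The default cohort comprises 34 biopsy samples: 12 hyperkeratosis (H,
benign), 11 oral epithelial dysplasia (D, precancerous) and 11 oral
squamous cell carcinoma (C, malignant). Each sample is imaged over 3 areas
of 16×16 pixels; each pixel carries a transmission spectrum on a
1800→950 cm⁻¹ grid at 2 cm⁻¹ spacing (426 points, descending). The
instrument's 4 cm⁻¹ spectral resolution is represented by band widths
(FWHM ≥ 8 cm⁻¹), not by the grid.

Clean absorbance spectra are sums of Gaussian bands. The per-class band
amplitudes encode the biochemistry of malignant progression in oral
epithelium:

* protein bands — amide I (1650), amide II (1548) and amide III
  (1310 cm⁻¹) — descend HK > OED > OSCC;
* nucleic-acid and carbohydrate bands — PO₂⁻ asymmetric/symmetric
  stretches (1240, 1080), C–O carbohydrate (1154), glycogen (1030) and the
  DNA backbone band (966 cm⁻¹) — descend OSCC > OED > HK;
* the amide II right shoulder red-shifts for dysplastic and malignant
  tissue, realized as a shoulder sub-band at 1548 − 8 cm⁻¹ (OED) and
  1548 − 14 cm⁻¹ (OSCC); the shift magnitudes are package choices, as only
  the direction and ordering (more shift for OSCC) are constrained;
* no band sits in 1750–1700 cm⁻¹: samples are modeled post-
  deparaffinization, which strips free lipids;
* stroma pixels follow a collagen-like profile with a distinctive
  1338/1280/1204 cm⁻¹ triplet, making connective tissue separable from
  epithelium by clustering.

Absolute absorbance magnitudes are unconstrained by any published table;
they were fixed once for ordering fidelity (amide I of HK ≈ 1.0 AU) and a
realistic dynamic range, and are not tuned thereafter.

Dysplasia samples carry a latent grade — 6 HK-like, 4 OSCC-like and 1
borderline by default — drawn as per-sample band-amplitude profiles
intermediate between HK and OSCC. The borderline sample draws half its
imaging areas (rounding up) from each sub-profile, so its two
representative spectra genuinely straddle the decision boundary.

Distortions applied in absorbance space, then converted to transmission
(T = 10^−A, clipped to [10⁻⁶, 1] so the log stays defined — clipping is
documented, test-visible behaviour):

| parameter | default | meaning |
| --- | --- | --- |
| scatter scale | U(0.85, 1.15) per pixel | multiplicative scatter / thickness |
| baseline | order-2 Legendre, coeff SD (0.04, 0.03, 0.02) | smooth background drift |
| baseline offset | 0.25 AU | substrate absorbance |
| noise SD | 0.01 AU | detector noise (per-pixel SNR ≈ 100) |
| outlier fraction | 0.02 | pixels with baseline and noise ×10 |
| band jitter | 5% per pixel, 5% per area | biological heterogeneity |

The noise level is chosen so that ×10-boosted outlier pixels remain
detectable after preprocessing: the correction chain itself removes an
outlier's boosted polynomial baseline (AWLS fits the same polynomial
order), so the residual noise is the signature the T²/Q step must see.
At 0.01 AU base noise the reduced-T²/Q rule recovers ≥ 90% of injected
outliers at ≤ 5% false positives; at substantially lower noise the boosted
outliers become genuinely indistinguishable after correction.

What the generator does *not* emulate: resonant-Mie scattering physics
(the distortion is plain multiplicative + polynomial), paraffin residue,
atmospheric water-vapor/CO₂ lines, spatial correlation between neighboring
pixels, and instrument drift between areas. Passing tests therefore
demonstrate that the pipeline recovers the designed class structure under
these idealized artifacts, not that it would survive every failure mode of
real micro-spectroscopy data.

## Preprocessing

The general chain runs in a fixed order (configs permuting it are
rejected): transmission→absorbance (A = log₁₀(1/T); base 10, the standard
absorbance convention), fingerprint selection (1800–950 cm⁻¹),
Savitzky–Golay smoothing (order 2, 9-point window — wide enough to
suppress the generator's noise, narrower than its narrowest band), EMSC,
AWLS baseline subtraction, and L2 vector normalization. For model building
a 7-point second-derivative Savitzky–Golay step (polyorder 3) follows,
with re-normalization because differentiation destroys the unit norm.

* **EMSC** is the basic variant: each spectrum is regressed on an offset,
  the cohort-mean reference and order-2 Legendre polynomials, then divided
  by the multiplicative coefficient. Full physics-based resonant-Mie EMSC
  is out of scope; the basic form corrects the multiplicative and smooth
  additive artifacts the generator produces. Rows whose fitted scale falls
  below 10⁻⁸ are returned uncorrected and flagged.
* **AWLS** is an asymmetric 0/1-reweighted polynomial fit (order 2): points
  above the current fit are treated as peaks and dropped from the next
  iteration, points at or below keep weight one, iterated until the weight
  sets stop changing (max 50 iterations; non-convergence — possible because
  0/1 weight sets can cycle — keeps the last iterate and logs a warning).
  Rows left with fewer support points than coefficients keep their last
  baseline. The exact algorithm behind the name in commercial chemometrics
  software is unpublished; this is a faithful, deterministic reading of it.
* **Savitzky–Golay edges** use scipy's polynomial-extrapolation mode
  (`interp`), so interior points match a brute-force sliding windowed
  polynomial fit exactly — the oracle the tests check against at 1e−10.
* Saturated outlier pixels can emerge from the chain as all-zero rows;
  the chain's normalization leaves them unscaled (a logged warning) so the
  T²/Q step can remove them, while direct calls to `vector_normalize`
  raise on zero rows.

The chain is deliberately *not* idempotent: smoothing has a polynomial-fit
bias, EMSC against a heterogeneous cohort mean reshapes class-distinct
rows, and the AWLS lower envelope is re-estimated on each pass. Step
correctness is guaranteed by per-step oracles, chain-level behaviour by
determinism and ordering tests.

Two open conventions were resolved as: vector normalization is L2 (not
area), and the EMSC reference is the whole-cohort mean (not per-class
means) so that no class information leaks into preprocessing.

## Pixel QC and representative spectra

Per imaging area, on the preprocessed (non-derivative) pixel spectra:

1. **Outlier removal.** PCA (SVD of the centered matrix; smallest
   component count explaining ≥ 95% variance, capped at 10) supplies
   Hotelling T² (score distance, normalized per-component by its
   eigenvalue) and Q residuals (off-model sum of squares). Both are
   divided by their 95% confidence limits — T² via the F-distribution
   relation, Q via the Jackson–Mudholkar approximation — giving "reduced"
   statistics; a pixel is removed when either exceeds 3 (three times the
   95% limit). The fixed ×3 rule replaces the visual inspection a human
   analyst would apply, making the step reproducible.
2. **Epithelium selection.** Ward-linkage hierarchical clustering on
   Euclidean distance, cut at k = 2 (the common chemometrics default; the
   synthetic tissue profiles separate at the top of the dendrogram). The
   area counts as two tissues only if the minority cluster holds ≥ 10% of
   pixels *and* the clusters separate by ≥ 2 pooled within-cluster SDs
   along the between-centroid axis — a Gaussian single-tissue cloud split
   in half scores ≈ 1.1–1.3 on that statistic, genuinely distinct tissues
   score ≳ 6. Single-tissue areas are returned whole; otherwise the
   majority cluster is taken as epithelium (areas are placed primarily in
   epithelial regions), overridable by configuration.
3. **Representatives.** Surviving epithelial pixels are averaged into one
   representative spectrum per area; per sample, the pair of
   representatives at maximal Euclidean distance is retained
   (ties break to the lexicographically first area pair). Maximal
   pairwise distance is the most literal deterministic operationalization
   of "the two spectra best reflecting intra-sample heterogeneity". The
   default cohort yields exactly 68 representatives from 34 samples.

## PLSDA

The discriminant model is PLS1 fitted by NIPALS with X-block deflation:
y is the 0/1 class code (H → 0, C → 1), each latent variable's weight
vector is the covariance direction X_kᵀy_res (normalized), and the
regression vector is assembled as b = W(PᵀW)⁻¹q. The 0/1 coding keeps the
0.5 decision threshold meaningful; ties at exactly 0.5 classify as C
(documented, test-pinned). If the response residual is exhausted early
(perfectly separable data), the model keeps the latent variables it could
extract rather than failing. Per-LV explained X-variance is
‖t_k p_kᵀ‖²/‖X_c‖², which the tests pin to a reconstruction-norm oracle;
the fitted regression vector is cross-checked against an independent PLS1
recursion and against scikit-learn's `PLSRegression` at 1e−8.

The LV count is chosen as the smallest count minimizing the grouped-CV
classification error (ties → fewer LVs), scanning up to `max_lv` = 10.
Feature bands are the local extrema of the chosen LV loadings with
absolute loading ≥ 0.5 of that LV's maximum. The 0.5 floor is deliberate
for second-derivative inputs: each Gaussian band's second derivative has
side lobes at ≈ 0.45 of its central lobe, which the floor excludes. Bands
closer than ~σ√3 can still produce a genuine overlap lobe between them
(the synthetic 1080/1030 pair yields one near 1054 cm⁻¹); extraction is
therefore validated as *recovery* — every differential band center has an
extracted band within ±6 cm⁻¹ — rather than as an exclusive list.

SVM (RBF kernel) and gradient-boosted-tree comparators sit behind the same
fit/predict contract (scores on the 0..1 scale, 0.5 threshold, identical
fold assignments); their hyperparameters — nowhere externally specified —
are tuned by a small logged grid search under the same grouped folds.

## Evaluation

Cross-validation is grouped venetian blinds: samples sorted
lexicographically by id, sample j assigned to fold j mod k (k = 10), both
of a sample's spectra riding in one fold. The grouping invariant is
asserted on every run. Metrics use OSCC as the positive class:
sensitivity TP/(TP+FN), specificity TN/(TN+FP), computed from the pooled
held-out confusion matrix (per-fold metrics are also derivable from the
persisted predictions); ROC/AUC are computed on the pooled held-out scores
(trapezoidal, ties stepping jointly), pinned to a pairwise-concordance
oracle at 1e−12. Calibration (resubstitution) metrics are reported
alongside. No external test set exists at this cohort size; CV is the
evaluation, as in the study design this mirrors.

## Dysplasia stratification

The trained HK-vs-OSCC model scores each dysplasia sample's two
representative spectra. With threshold 0.5 and borderline half-width δ
(default 0): both scores ≤ 0.5 − δ → HK-grade; both ≥ 0.5 + δ →
OSCC-grade; otherwise (pair straddles the line, or a score falls inside
the δ band) → borderline. δ = 0 makes the rule purely side-based, the most
literal reading of "which side of the discrimination line"; a pair sitting
exactly on the line resolves to OSCC-grade, consistent with the
classifier's tie rule. Grades are per-sample, never per-spectrum. The rule
is monotone: raising both scores can never move a sample from OSCC-grade
to HK-grade.

This grading asserts spectral similarity to the benign or malignant class,
not a prediction of actual malignant transformation — validating the
latter needs archived dysplasia cases with known outcomes.

## Orchestration, determinism, problem sizes

`RunConfig` bundles scenario, distortion, preprocessing, model, CV and
stratification parameters and serializes to YAML; a run's resolved config
is written next to its outputs. One global seed drives everything, forked
per stage by a counter scheme (`seed × 1000003 + stage`, mod 2³¹−1), so a
config reproduces its artifacts byte for byte and individual stages can be
re-run in isolation. The `analysis/` scripts are thin numbered drivers
over the same stage functions; stagewise execution is tested to equal the
monolithic run exactly.

Problem sizes are the default study design throughout: 34 samples × 3
areas × 256 pixels (26 112 spectra × 426 wavenumbers) for a full run, 20
seeded replicates for the stratification-recovery and outlier-power
checks. These sizes keep a full pipeline run in the tens of seconds on a
single core while exercising every stage at realistic dimensionality.

## Known limitations

* The basic-EMSC substitution means physically realistic resonant-Mie
  distortions would not be corrected; none are generated.
* The single-tissue/two-tissue decision rule is calibrated to the
  generator's contrast regime; real H&E-registered annotation would
  replace it in a clinical application.
* PLSDA is strictly two-class by design; dysplasia enters only at
  prediction time. No multiclass variant is provided.
* Reported perfect separation (100%/100%, AUC 1) is a property of the
  designed class separations and low distortion levels, recovered by the
  pipeline — not a claim about new clinical data.
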
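# Methods

## Pixel classification model

Each specimen frame is a stack of nine co-registered intensity planes
acquired under narrow-band LEDs with peak wavelengths 405, 430, 465, 505,
545, 600, 630, 660 and 700 nm. After flat-field division (`raw /
flatfield`, clipped to [0, 1], clip count logged) each pixel is a spectral
transmittance vector `A ∈ [0,1]⁹`. Classification is nearest-reference
under cosine similarity (the spectral angle mapper of remote sensing):
`class(A) = argmax_X (A·X)/(‖A‖‖X‖)` over a reference library containing at
least `whitish_core` (B) and `red_component` (C), optionally `background`.

Assumptions: (i) references and pixels share one band set; (ii) blood
contamination acts approximately multiplicatively on the spectrum
(Beer–Lambert), so it perturbs a pixel's direction much less than its
magnitude, and a brightness-invariant metric suppresses it; (iii) the two
target materials differ in spectral *shape* — whitish tissue is nearly
flat, blood-rich material is steeply sloped.

Numerical conventions, all in double precision:

* **Ties** resolve to the earliest class in library declaration order
  (`argmax` first-maximum). The fitted classifier therefore keeps
  `classes_` in first-appearance order rather than sorted.
* **Zero-norm pixels** (fully opaque) have undefined direction; they are
  routed to a configurable fallback class, default `red_component`, so an
  opaque artifact can never inflate the whitish-core area.
* With multiple training spectra per class, the reference direction is the
  unit-normalised mean of unit-normalised examples; a one-spectrum-per-class
  library reproduces plain nearest-reference matching.

## Segmentation and measurement

`segment_image` applies the classifier pixelwise, then reassigns
whitish-core connected components (8-connectivity) smaller than
`min_component_px` (default 16 px — suppresses single-pixel noise speckle
at the default 0.05 mm pitch, i.e. anything under 0.04 mm²) to each
pixel's runner-up class. Reassignment rather than deletion keeps the
per-class counts summing to the pixel total, which is tested as an
invariant. Area is exactly `count × pitch²`.

`estimate_core_length_mm` emulates the manual ruler measurement: the core
mask is reduced to its morphological skeleton and path length is summed
with 8-connected step weights (1 for axial, √2 for diagonal; a diagonal
step is not counted when the path already runs through a shared axial
neighbour). This is an approximation — it overshoots slightly on wide
strokes whose skeleton extends into the rounded ends (≈ 6% on the default
phantom) — adequate for rank-correlation analyses, not for calibrated
length metrology.

## Phantom generator

The generator emulates what the real frames look like: an earthworm-like
curvilinear core (polyline centreline, resampled to uniform arc length;
a pixel belongs to the core when its centre lies within half the stroke
width) on a bright dish, with a blood film of spatially varying optical
depth covering a configurable fraction of the frame. Optics:

* **Blood**: `T(λ) = exp(−t·μ(λ))` with a shipped attenuation table μ(λ)
  shaped on hemoglobin (Soret absorption near 405–430 nm, Q-band near
  545 nm, weak red absorption); magnitudes are config-overridable since
  they are qualitative, not measured constants. Film optical depth varies
  smoothly as `t = blood_thickness × (0.6 + 0.8·u)` with `u` a smooth
  random field; the covered region is a smooth field thresholded at the
  requested coverage quantile.
* **Core**: transmittance `0.85 × exp(−0.15·μ(λ))` — bright and nearly
  flat with a mild short-wavelength dip from residual blood staining. A
  perfectly flat core would be direction-identical to the flat dish
  (`0.98` everywhere) and no brightness-invariant classifier could
  separate them; real whitish cores retain some hemoglobin, so the tinted
  default is both physically reasonable and non-degenerate. The margin
  analysis behind the constants: clean core vs dish differ by 0.0105 in
  similarity units (≈ 2.6 σ at transmittance noise 0.02; residual flips
  are absorbed by the component filter).
* **Core under film**: the dense core displaces most of the overlying
  blood, modelled as an effective depth `core_blood_fraction × t` with
  default 0.15; this keeps the worst-case contaminated core pixel on the
  whitish side of the decision boundary (crossover at combined depth
  ≈ 0.45) so segmentation through blood is accurate by the same mechanism
  as in the real instrument.
* **Noise**: additive Gaussian on transmittance, clipped to [0, 1]; one
  root seed per specimen drives all randomness, so identical configs are
  bit-identical.

Ground truth: core pixels are `whitish_core` even where the film crosses
them; film-only pixels are `red_component`; the rest `background`. Truth
area is the rasterised pixel count times pitch²; truth length is the
centreline arc length.

What the phantom does **not** model: tissue texture and scattering,
specular highlights, dish edges, sample overlap, chromatic misregistration
and sensor nonlinearity. Passing the phantom suite therefore demonstrates
the correctness of the algorithmic chain (spectral model → classifier →
measurement), not field performance on real frames.

Default frame: 240 × 320 px at 0.05 mm pitch (12 × 16 mm dish region),
core ≈ 14 mm long and 1 mm wide (≈ 14.8 mm² — the scale of a typical
specimen), 50% blood coverage at unit optical-depth scale. Tests use a
120 × 160 px frame with a proportionally smaller core to keep the suite
fast; the geometry is otherwise identical.

## Synthetic cohorts

`generate_cohort` draws per-pass measurement rows: whitish-core areas are
log-normal with median 13 mm² and log-sd 0.93 (placing the IQR near
6–21 mm², the scale seen in practice); manual core length is a noisy
power-law transform of area, `14·(area/13)^0.75 · exp(ε)`, with log-noise
0.45 chosen so the length–area Spearman ρ is ≈ 0.83–0.84 (signal sd 0.70
vs noise 0.45 on logs); diagnostic success is Bernoulli with a logistic
link in area. The default link (slope 0.2 /mm², intercept −1.0) yields
the discriminative structure such validation cohorts show in practice —
≈ 77% overall success, area-vs-diagnosis AUC ≈ 0.85, success rate ≈ 0.9
among samples ≥ 8 mm². A steep link (slope 6, intercept −48) encodes a
near-deterministic threshold at 8 mm² and is used for cutoff-recovery
experiments, where the Youden analysis recovers the threshold to within a
few tenths of a mm² at n = 500. Pathology scores come from area-linked
latent traits read independently by two simulated evaluators (exact-read
probabilities 0.7–0.85), giving mid-range kappas (≈ 0.5–0.7); the
isolation group receives stochastically less blood contamination (higher
blood score).

## Evaluation statistics

* **ROC / Youden**: thresholds sweep the unique observed values with the
  convention *score ≥ cutoff ⇒ test-positive*; AUC is the trapezoidal area
  under (FPR, TPR) with the (0,0) and (1,1) endpoints appended, which
  equals the tie-adjusted Mann–Whitney statistic divided by `n₁n₀` (tested
  as an identity on every dataset). The Youden cutoff maximises
  J = sensitivity + specificity − 1, ties resolving to the smallest
  threshold.
* **Mann–Whitney U**: exact permutation distribution when the pooled
  sample is ≤ 12 with no ties, otherwise normal approximation with tie
  and continuity corrections; two-sided throughout.
* **Fisher's exact test**: two-sided hypergeometric rule (sum of all
  same-margin tables no more probable than the observed one).
* **Cohen's kappa**: unweighted, with the Fleiss–Cohen–Everitt
  large-sample standard error and a 95% Wald interval clipped to [−1, 1].
  The SE method is stated explicitly because published reports typically
  print only the CI.
* **Printed percentages**: half-up (commercial) rounding at the printed
  precision — required for fractions like 93/120 to print as 78.
* **Sensitivity at a cutoff**: among samples with measurement ≥ cutoff,
  the fraction achieving histological diagnosis, reported with its
  numerator and denominator.

Degenerate inputs raise typed errors rather than returning NaN:
single-class labels (ROC), constant vectors (Spearman), empty margins
(Fisher), identical constant raters (kappa), zero-norm spectra.

## Known limitations and open points

* Reference spectra provenance (calibration target vs manual ROI) is not
  modelled; the library JSON accepts either.
* The instrument's geometry (true transmission vs reflectance), dynamic
  range and bit depth are not public; phantoms work in normalised
  transmittance.
* Published AUC confidence intervals for this kind of study use an
  unstated method (and the figure captions and text disagree on one
  subgroup's AUC, 0.80 vs 0.85); this package deliberately reports the
  AUC point estimate without a CI rather than guess the method.
* Clinical headline values (ρ = 0.83, AUC 0.84, cutoff ≥ 8 mm²,
  sensitivity 92.5%, medians 14 mm / 13 mm²) depend on the patient
  dataset, which is unavailable; the synthetic cohort reproduces their
  *structure* (and its generator is parameterised at those scales), not
  the values themselves.
* Problem sizes used by the test suite and the acceptance script
  (120 × 160 px phantoms, 20 seeds, cohorts of 117–2000) are the
  package's chosen defaults for routine verification; all scale linearly
  if larger runs are wanted.
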
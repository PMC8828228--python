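# amus

Quantifying the amount of usable tissue in a fine-needle biopsy specimen,
directly on the procedure table, from a nine-band multiband image.

When a pancreatic mass is sampled by endoscopic ultrasound-guided
fine-needle aspiration biopsy (EUS-FNAB), the diagnostically useful part of
the specimen is the *whitish core* — strands of solid tissue — while the
rest is *red component* (blood and fibrin). Manually measuring the visible
white core under a stereomicroscope predicts whether histological diagnosis
will succeed, but is operator-dependent and slow. This package implements
an automated alternative: the specimen is imaged under nine narrow-band
LEDs (405–700 nm), each pixel's spectral transmittance is treated as a
vector **A**, and the pixel is assigned to whichever reference spectrum —
whitish core **B** or red component **C** — it resembles most by cosine
similarity:

```
sim(A, X) = (A · X) / (‖A‖ ‖X‖),    class(A) = argmax_X sim(A, X)
```

Cosine similarity is invariant to overall brightness, so a variable-density
blood film (which multiplies the spectrum by a hemoglobin-shaped
Beer–Lambert factor, strong at 405–545 nm and weak at 600–700 nm) changes
a pixel's magnitude far more than its direction — this is what lets the
classifier see the core through blood contamination. The whitish-core area
is then `pixel count × pitch²` (mm²).

The package is aimed at researchers evaluating specimen-adequacy imaging:
it contains the classifier, the area/length measurement, a synthetic
optical phantom generator with ground truth (no public image data exist
for this instrument), and the full evaluation statistics used to validate
such a measurement against manual assessment: ROC/AUC with the
Youden-index operating cutoff, Spearman correlation, Mann–Whitney U,
Fisher's exact test, Cohen's kappa with a large-sample CI, and the
pathology scoring data model (adequacy 0–5, tumor-cell content 0–5, blood
contamination 1–3, two-rater lower-score consolidation).

## Worked example

Generate a phantom specimen (a curved ~14 mm core, half the dish smeared
with blood) and a 117-sample synthetic cohort, segment, measure, evaluate:

```bash
amus simulate --out-dir demo --n-specimens 1 --cohort-size 117 --seed 1
amus segment  --stack demo/phantom_000.tif --library demo/references.json \
              --out demo/mask.png --table demo/areas.csv
amus measure  --mask demo/mask.png
amus evaluate --table demo/cohort.csv --out demo/report.json
```

which prints (exact output from the commands above):

```
amus: phantom 0: true core area 14.81 mm2, centreline 14.07 mm
...
amus:   whitish_core: 5925 px, 14.813 mm2
whitish core area: 14.813 mm2
estimated core length: 14.95 mm
...
Cohort report (n = 117)
  isolation    n= 59  length 13.6 mm (IQR 9.2-21.8)  area 13.3 mm2 (IQR 7.5-21.1)
  no_isolation n= 58  length 11.1 mm (IQR 7.0-21.7)  area 13.3 mm2 (IQR 8.2-21.2)
  all          n=117  length 11.9 mm (IQR 7.6-22.0)  area 13.3 mm2 (IQR 8.1-21.6)
  Spearman length_vs_area: rho = 0.84
  ROC (area vs diagnosis): AUC = 0.87, Youden cutoff >= 10.9 mm2 (J = 0.69)
  success rate at svwc_length_mm>=11: 64/67 (95.5%)
  success rate at whitish_area_mm2>=8: 79/88 (89.8%)
```

The segmented area (14.813 mm²) recovers the phantom's true core area
exactly despite the 50% blood film, because the cosine classifier ignores
the film's multiplicative attenuation. The skeleton-length estimate
(14.95 mm) approximates the 14.07 mm centreline. In the cohort report, the
strong length–area rank correlation (ρ = 0.84), the area-vs-diagnosis AUC
and the Youden cutoff near the generative 8 mm² threshold are the
quantities such a validation study reads off.

As a library, the classifier is a scikit-learn style estimator:

```python
from amus import ReferenceLibrary, SpectralAngleClassifier
lib = ReferenceLibrary.from_json("demo/references.json")
clf = SpectralAngleClassifier.from_library(lib)   # fit on the references
labels = clf.predict(image.pixels())              # one label per pixel
```

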
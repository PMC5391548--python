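# masscontour

Shape analysis of mammographic mass boundaries: is a lesion contour smooth
and regular (typically benign) or irregular and spiculated (typically
malignant)?

`masscontour` is for researchers working on computer-aided diagnosis from
screening mammography who have lesion **boundaries** (e.g. Freeman
chain-code overlay files or plain vertex lists) and want a reproducible
pipeline from contour to classification:

1. **2D contour → 1D signature.** A closed anticlockwise contour
   `C = {p_i}` is reduced to one value per boundary point. Besides the
   classical radial signature `h_p(i) = |p_i − p_c|` (distance to the vertex
   centroid `p_c`), the package implements an ellipse-residual signature: a
   reference ellipse is anchored at the centroid with diameters
   `D_x = max|x_i − x_j|`, `D_y = max|y_i − y_j|`, and
   `h(i) = |h_p(i) − h_q(i)|` where `q_i` is the intersection of the ray
   `p_c → p_i` with that ellipse. A regular oval mass hugs its reference
   ellipse (`h ≈ 0` everywhere); spiculation shows up as large rough
   residuals, so `h` captures both roughness and departure from oval shape.
2. **Local features on ranked subsections.** The signature is split into
   `C ∈ {1, 2, 4, …, 20}` contiguous blocks; on each block one of four
   scalar descriptors is computed and the `C` values are sorted into a
   rank-ordered feature vector:
   * RMS roughness `w = √(⟨h²⟩ − ⟨h⟩²)`
   * circularity ratio `μ_R/σ_R`
   * fractal exponent `α` from the small-lag power law of the
     height–height correlation `H(ρ) = ⟨[h(n) − h(n+ρ)]²⟩ ∝ ρ^{2α}`
     (fractal dimension `D = 2 − α`)
   * RMS slope `s = √⟨(dh/dρ)²⟩`
3. **Classification.** 1-nearest-neighbor, linear SVM and a 10-node
   single-hidden-layer neural network, evaluated with seeded repeated
   stratified splits; accuracy / sensitivity / specificity are averaged over
   repetitions and over the 11-value `C` sweep.

Because public mammography archives cannot ship with the package, a
first-class synthetic generator produces labeled cohorts — near-elliptical
low-frequency contours for the benign class, high-frequency high-amplitude
contours with spicule spikes for the malignant class — plus 1D
fractional-Brownian-motion profiles of known roughness exponent for
calibrating the fractal estimator.

## Worked example

```python
import masscontour as mc

spec = mc.CohortSpec(seed=42)
benign = mc.make_benign_contour(spec, seed=1)
malignant = mc.make_malignant_contour(spec, seed=2)

for name, contour in [("benign", benign), ("malignant", malignant)]:
    sig = mc.ellipse_signature(mc.align_start(contour))
    print(f"{name}: N={len(sig)}  w={mc.rms_roughness(sig):.2f} px  "
          f"s={mc.rms_slope(sig):.3f}  mu/sigma={mc.mu_sigma_ratio(sig):.2f}")

contours, labels, _ = mc.make_cohort(
    mc.CohortSpec(n_benign=30, n_malignant=30, seed=42))
table = mc.build_feature_table(
    contours, labels, features=("s",), kinds=("ellipse_residual",))
res = mc.evaluate(table, "s", "ellipse_residual", "linear_svm",
                  mc.Protocol(n_train=50, repetitions=25, seed=42))
print(f"accuracy={res.summary['accuracy']:.3f}")
```

prints

```
benign: N=256  w=1.25 px  s=0.381  mu/sigma=1.36
malignant: N=255  w=2.64 px  s=1.401  mu/sigma=1.77
accuracy=1.000
```

The benign contour's ellipse residual fluctuates by ~1 px (pure
digitization plus gentle low-order waviness) while the spiculated contour is
both rougher (`w`) and, above all, *faster*-varying (`s`, the per-step RMS
change of the residual — here 3.7× the benign value). On this cohort the
rank-ordered RMS-slope vectors are linearly separable, so the C-sweep
averaged SVM accuracy is 1.000.

## Command line

```bash
masscontour simulate --n-benign 50 --n-malignant 50 --seed 7 --out cohort/
masscontour signature cohort/*.overlay --kind ellipse_residual --out sigs/
masscontour extract cohort/*.overlay --manifest cohort/manifest.json --out table.csv
masscontour bench --seed 7 --out report/
```

`simulate` writes overlay-dialect chain-code boundary files plus a JSON
manifest of labels and per-contour seeds; `signature` exports per-contour
CSVs (`index,h,h_p,h_q,theta`); `extract` builds the labeled
(contour × feature × C) table; `bench` generates a cohort and writes the
feature × signature-kind × classifier comparison matrices (CSV + JSON).

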
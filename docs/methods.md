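# Methods

## Pipeline model and assumptions

The package treats a hyperspectral scene as a cube `R(x, y, λ)` of diffuse
reflectance over a uniform wavelength grid (874–1734 nm in 5 nm steps, 173
bands). Raw camera intensity is converted to reflectance with white/dark
reference frames, `R = (I_raw − I_dark)/(I_white − I_dark)`, which assumes
a linear sensor and stable illumination between reference and sample
acquisition; the correction is exact for any common positive rescaling of
the three intensities (affine invariance, tested).

Objects (beans) are assumed bright against a near-zero background, so a
single gray-scale band thresholded at Otsu's level separates foreground
from background. Bean instances are 8-connected components with a minimum
area of 20 px; touching objects are deliberately *not* split (the emulated
acquisition places beans separably), and this behaviour is documented and
tested rather than hidden behind a watershed.

The statistical model of a pixel spectrum within a bean is

```
x(px, λ) = gain(px) · E_k(λ) + ε(px, λ)
```

where `E_k` is the variety's endmember, `gain(px) ∈ [1, shape_gain]` is a
multiplicative path-length/illumination factor rising from bean edge to
bean center, and `ε` is additive zero-mean noise, i.i.d. per pixel and
band. Bean-average spectra are the within-bean means, which shrinks the
noise sd by ≈1/√n and collapses the gain spread to a per-bean mean gain.
These two facts — noise suppression and gain collapse — are exactly why
models calibrated on averages and applied to pixels extrapolate, while the
reverse direction interpolates.

## Synthetic scene generator

The generator's defaults define the study conditions: 4 classes, 6 scenes
per class, 50 non-overlapping axis-aligned elliptical beans per 256×320
scene (semi-axes uniform in 6–10 px), `shape_gain = 1.6`, additive
Gaussian noise with sd 0.02 reflectance units (a Student-t df=3 toggle
with matched sd exists for robustness work), background level 0.02.

Endmembers are a shared smooth baseline (a broad parabola plus a gentle
sinusoid, C∞, strictly inside (0, 1)) minus class-specific negative
Gaussian absorption features, scaled by a per-class overall reflectance
level (defaults 1.00, 0.94, 1.06, 0.97). The level component is essential
to the science the pipeline probes: real varieties differ in overall
brightness as well as in band positions, and it is precisely this
intensity information that the within-bean gain confounds. With purely
feature-coded classes every margin classifier is gain-invariant (the
between-class direction is orthogonal to the common intensity direction)
and the cross-prediction asymmetry cannot arise; with a modest level
spread the asymmetry appears at `shape_gain = 1.6` and collapses when the
gain is switched off, isolating sample shape as the causal factor.

What the generator does **not** emulate: surface texture, specular
highlights, band-correlated (pink) noise, wavelength-dependent gain,
touching/overlapping objects, and dead pixels. Passing tests therefore
demonstrate the pipeline's internal correctness and the shape-effect
mechanism, not performance on any real seed-sorting dataset.

## Preprocessing

* **MA** — centered boxcar over an odd number of bands (7–23); edges use a
  symmetrically shrinking window so the length is preserved without
  extrapolation. Linear, hence commutes with bean averaging (tested).
* **MF** — per-band spatial median over 3×3…15×15 with reflect padding;
  windows {3, 5, 7, 9, 11, 15} are all accepted. The mask is re-applied
  after filtering, since the median window straddles the bean boundary and
  would otherwise leave nonzero background.
* **WT** — db4, level 4, soft threshold on all detail levels. Default rule
  is the universal threshold `σ̂√(2 ln n)` with `σ̂ = MAD/0.6745` from the
  finest detail level; a per-level SURE minimiser is available. These are
  the standard chemometric shrinkage defaults; nothing was tuned per
  dataset.
* **EMD** — classical sifting with cubic-spline envelopes through local
  extrema (end extrema mirrored about the signal boundaries), SD stopping
  criterion 0.2, at most 50 siftings per IMF and 12 IMFs; decomposition
  stops when the residual has fewer than 4 extrema, and such signals pass
  through unchanged. By construction `Σ IMF + residual` equals the input
  to rounding error. Denoising soft-thresholds the first IMF (exposed as
  `emd_n_noise_imfs`) with the universal rule; hard thresholding is
  available since the choice between the two is genuinely open.

Spectral methods operate on foreground pixels only, so the background
stays exactly zero.

## Wavelength selection

Second derivatives are Savitzky–Golay (window 11, polyorder 3) on the
class-mean spectra, in reflectance/nm². SG is used instead of bare second
differences because the derivative is taken on already-denoised means and
SG is the spectroscopic standard; window and order are logged in the
result object. Selection replaces manual peak picking with a deterministic
rule: candidates are local extrema of any class's d² curve, the score is
the across-class range of d² at the band, and candidates are kept greedily
(ties toward the lower wavelength) subject to a 10 nm minimum separation,
up to `max_k` (15 by default, matching the scale of a manual selection on
this kind of data). A score floor of 0 means identical class means select
nothing. The rule recovers ≥90% of randomly planted feature centers within
±10 nm over 100 replicate endmember sets (tested at exactly that scale).

## Classification

libsvm (via scikit-learn's `SVC`) solves the binary soft-margin duals; the
package re-expresses the fitted model as explicit per-pair coefficients
`αᵢyᵢ`, support vectors and biases, and performs prediction itself by
kernel evaluation and one-vs-one sign voting, ties toward the smaller
class label. This makes the dual-feasibility conditions (`Σ αᵢyᵢ = 0`
within 1e−6, `0 ≤ αᵢ ≤ C`) and the decision rule directly testable, with
libsvm's own `predict` as an independent cross-check. A sign convention
detail: for exactly two classes the sklearn-exposed decision function is
positive for the *second* class; the bundle normalises this at training
time so "positive favours the pair's first class" holds uniformly.

The kernel is Gaussian RBF `exp(−g‖x − x′‖²)`; a `laplacian` kernel
(unsquared norm) is provided because the two readings of an RBF definition
with an unsquared printed norm differ, and the Gaussian reading is the
default. Grid search covers `C ∈ 2^{−4..12}`, `g ∈ 2^{−10..4}` with
stratified 5-fold CV; ties break toward smaller C, then smaller g, by
sweeping the grid in ascending order and accepting only strict
improvements. Reflectance features are not standardised by default (they
already live on a common [0, ~1.7] scale).

## Experiment design and problem sizes

The default study splits each class's 6 scenes 4/2 into calibration and
prediction (200/100 beans per class). The pixel calibration set samples
2000 pixels per class uniformly without replacement (seeded). The pixel
view of the prediction set is evaluated on a seeded subsample of 2000
pixels per class — an unbiased accuracy estimator whose binomial sd at
8000 total pixels is under 0.6 points, chosen to keep repeated-seed
experiments cheap; `eval_pixels_per_class=None` scores every pixel.
Cross-prediction experiments use fixed `C = 256` and the variance-scale
heuristic for `g` unless a tuned pair is passed.

Repeated-seed properties are measured as medians: 10 seeds at the default
configuration, 5 at `shape_gain = 1`. The denoiser benchmark uses 100
noise realisations on a clean endmember; the recovery benchmark 100
endmember sets.

## Numerical choices and degenerate inputs

* Wavelength lookups resolve to the nearest band; ties break toward the
  lower wavelength.
* Cubes are float32 by default (memory: a full study is ~1.4 GB); the
  correction and all spectra-level math promote to float64.
* An empty mask is a warning, not an error; a non-positive `white − dark`
  element is an error with the offending index; even or oversized filter
  windows, out-of-range features, single-class training sets and
  band-count mismatches are errors.
* Scene placement retries each bean up to 4000 times before failing with
  advice to shrink the beans.
* Serialization of models is plain JSON (arrays as lists), so identical
  runs produce byte-identical files; maps are PNGs with a fixed palette
  (class 1 red, 2 green, 3 blue, 4 yellow, background black).

## Known limitations

* EMD sifting is O(bands × siftings) pure Python per spectrum; denoising
  whole scenes with EMD is substantially slower than WT and is exercised
  at reduced scale in the tests.
* The per-bean majority vote is an addition beyond per-pixel maps — it
  quantifies map readability but has no external reference value.
* The mask threshold and object individuation method are package choices
  (Otsu + connected components); no claim is made that they match any
  particular acquisition software.
* Endmember "levels" summarise intensity differences between varieties
  with a single scalar; real inter-variety differences are smoother
  functions of wavelength.
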
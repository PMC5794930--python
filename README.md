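# pixelspec

Pixel-wise vs. object-average classification of NIR hyperspectral images,
built around a question that matters whenever hyperspectral prediction maps
are drawn: **a calibration model is usually trained on object-average
spectra, but a prediction map applies it to single pixels — does that
transfer?**

Seed-sorting applications (the motivating case is identifying coffee-bean
varieties on a conveyor belt) image ~50 beans per scene with an NIR line
camera (874–1734 nm, 5 nm resolution). Each bean yields hundreds of pixel
spectra that are noisy and brightness-shifted by the bean's curved surface
(center pixels are uniformly brighter than edge pixels — a multiplicative
path-length effect), while the bean's *average* spectrum is clean and
narrow. `pixelspec` implements the full analysis pipeline around that
contrast, plus a synthetic scene generator with the same statistical
structure, so every stage is testable end to end without proprietary data.

## What the pipeline computes

1. **Reflectance correction** of raw intensity cubes with white/dark
   reference frames: `R = (I_raw − I_dark) / (I_white − I_dark)`.
2. **Masking** on a single gray-scale band (1200 nm, Otsu threshold) and
   8-connected component labelling of bean instances; background set to 0.
3. **Preprocessing**, four families: per-pixel moving average (MA, 7–23
   points), per-band spatial median filter (MF, 3×3–15×15), per-pixel
   wavelet shrinkage (WT: db4, level 4, soft universal threshold), and
   per-pixel empirical mode decomposition denoising (EMD: sift into IMFs,
   soft-threshold the first, reconstruct).
4. **Spectra extraction**: one spectrum per foreground pixel, and one
   average spectrum per bean.
5. **Wavelength selection** from Savitzky–Golay second derivatives of the
   class-mean spectra: candidate bands are local extrema of any class's
   d² curve, scored by the across-class range of d² at that band, kept
   greedily under a minimum-separation constraint.
6. **Classification** with one-vs-one soft-margin SVMs using the Gaussian
   RBF kernel `K(x, x′) = exp(−g‖x − x′‖²)`, `g = 1/(2σ²)`; grid search
   over `C ∈ 2^{−4..12}`, `g ∈ 2^{−10..4}` with stratified k-fold CV. The
   fitted model is exposed as an explicit bundle (per-pair α·y, support
   vectors, bias) so the dual constraints `Σ αᵢyᵢ = 0`, `0 ≤ αᵢ ≤ C` are
   directly checkable.
7. **Cross-prediction and maps**: train one model on 2000 sampled pixels
   per class and one on bean averages; evaluate both on both prediction-set
   views; colour prediction maps per pixel and condense them to per-bean
   majority votes.

## Worked example

```python
import pixelspec as ps

cfg = ps.SceneConfig(rows=128, cols=160, beans_per_scene=15, seed=7)
study = ps.make_study(cfg)                       # 4 varieties x 6 scenes
plan = ps.make_splits(study, cal_per_class=4, pixels_per_class_cal=800)
mat = ps.run_experiment(study, ps.PreprocessConfig(method="WT"), plan, seed=7)
for (train_on, test_on), rep in sorted(mat.cells.items()):
    print(f"train on {train_on:7s} -> predict {test_on:7s}: "
          f"{rep.pred_acc:6.2f}% (n={rep.n_pred})")

cal_avg = ps.concat_datasets([
    ps.scene_spectra(c, r, k, ps.PreprocessConfig(method="WT"))[1]
    for c, r, _, k in study if int(c.meta["scene_id"]) in plan.cal_scenes[k]])
ws = ps.select_wavelengths(ps.second_derivative(cal_avg), max_k=15)
print("selected wavelengths (nm):", ", ".join(f"{w:.0f}" for w in ws.selected))
```

prints

```
train on average -> predict average: 100.00% (n=120)
train on average -> predict pixel  :  52.50% (n=8000)
train on pixel   -> predict average: 100.00% (n=120)
train on pixel   -> predict pixel  : 100.00% (n=8000)
selected wavelengths (nm): 954, 989, 1059, 1079, 1154, 1234, 1314, 1354, 1379, 1394, 1474, 1554, 1639, 1649, 1709
```

The four cells are the heart of the matter: both models are near-perfect on
their own view, and the pixel-trained model also transfers to bean
averages, but the average-trained model collapses on pixel spectra
(52.5%) because the bean-shape brightness gradient pushes pixel spectra
outside the narrow calibration range of the averages. Setting
`shape_gain=1.0` in `SceneConfig` removes the gradient and the asymmetry
vanishes — the shape effect, not the noise, is the causal factor. Practical
consequence: if you intend to draw per-pixel prediction maps, calibrate on
pixels.

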
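"""Cross-prediction experiments and per-pixel prediction maps.

The central experiment trains two models on the same calibration scenes —
one on subsampled pixel-wise spectra, one on bean-average spectra — and
evaluates each on both prediction-set views.  Averaging removes both the
per-pixel noise and the center-to-edge brightness spread, so bean-average
spectra occupy a much narrower region of feature space than pixel spectra:
a pixel-trained model sees the averages as interior points and predicts
them well, while an average-trained model is asked to extrapolate to pixel
spectra far outside its calibration range and degrades sharply.  That
asymmetry, and its collapse when the shape gain is switched off, is what
:func:`run_experiment` measures.

Prediction maps colour every foreground pixel of a scene by its predicted
class (background black), and :func:`per_bean_vote` condenses a map to one
majority-vote label per bean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

from .classify import (EvalReport, SplitPlan, SVMModelBundle, sample_pixels,
                       svm_predict, svm_train)
from .cube_io import (BeanLabelMap, HyperCube, ReferenceFrames, SpectraDataset,
                      apply_mask, average_by_bean, build_mask, concat_datasets,
                      extract_pixel_spectra, reflectance_correct)
from .preprocess import PreprocessConfig, preprocess_cube
from .wavesel import WavelengthSet, subset_bands

#: Fixed class palette: 1 red, 2 green, 3 blue, 4 yellow; background black.
DEFAULT_PALETTE: dict[int, tuple[int, int, int]] = {
    0: (0, 0, 0),
    1: (255, 0, 0),
    2: (0, 255, 0),
    3: (0, 0, 255),
    4: (255, 255, 0),
    5: (255, 0, 255),
    6: (0, 255, 255),
    7: (255, 128, 0),
    8: (128, 128, 128),
}


@dataclass
class PredictionMap:
    """Per-pixel predicted class image; 0 marks background."""

    labels: np.ndarray
    scene_id: int
    legend: dict[int, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_PALETTE))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)

    @property
    def foreground_count(self) -> int:
        return int(np.count_nonzero(self.labels))


@dataclass
class ExperimentMatrix:
    """The four cross-prediction cells of one configuration.

    Keys are ``(train_on, test_on)`` with values in {"pixel", "average"}.
    """

    cells: dict[tuple[str, str], EvalReport]
    feature_set: str = "full"
    method: str = "none"
    pixel_model: SVMModelBundle | None = None
    average_model: SVMModelBundle | None = None

    def __post_init__(self) -> None:
        want = {(a, b) for a in ("pixel", "average") for b in ("pixel", "average")}
        if set(self.cells) != want:
            raise ValueError(f"matrix must hold exactly the four cells {want}")

    def accuracy(self, train_on: str, test_on: str) -> float:
        return self.cells[(train_on, test_on)].pred_acc

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"train_on": tr, "test_on": te, "features": self.feature_set,
             "method": self.method, "cal_acc": rep.cal_acc,
             "cv_acc": rep.cv_acc, "pred_acc": rep.pred_acc,
             "n_pred": rep.n_pred}
            for (tr, te), rep in sorted(self.cells.items())
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Scene -> spectra pipeline
# ---------------------------------------------------------------------------

def scene_spectra(cube: HyperCube, refs: ReferenceFrames, class_label: int,
                  pre_cfg: PreprocessConfig,
                  scene_id: int | None = None,
                  ) -> tuple[SpectraDataset, SpectraDataset, BeanLabelMap, HyperCube]:
    """Correct, mask, preprocess and extract one scene.

    Returns (pixel spectra, bean-average spectra, the label map, and the
    preprocessed masked reflectance cube).
    """
    corrected = reflectance_correct(cube, refs)
    lmap = build_mask(corrected)
    masked = apply_mask(corrected, lmap)
    processed = preprocess_cube(masked, lmap, pre_cfg)
    pixels = extract_pixel_spectra(processed, lmap, class_label,
                                   scene_id=scene_id)
    averages = average_by_bean(pixels)
    return pixels, averages, lmap, processed


def run_experiment(study: list, pre_cfg: PreprocessConfig, plan: SplitPlan,
                   ws: WavelengthSet | None = None,
                   svm_params: tuple[float, float] = (256.0, None),
                   seed: int = 0, kernel: str = "rbf",
                   eval_pixels_per_class: int | None = 2000,
                   ) -> ExperimentMatrix:
    """Train pixel-wise and bean-average models once each; evaluate both on
    both prediction-set views.

    ``svm_params`` is the (C, g) pair; ``g=None`` uses the variance-scale
    heuristic on the pixel calibration matrix.  The pixel view of the
    prediction set is subsampled to ``eval_pixels_per_class`` pixels per
    class (seeded) to keep the accuracy estimate cheap; pass ``None`` to
    score every prediction pixel.
    """
    cal_pix_parts, pred_pix_parts = [], []
    cal_avg_parts, pred_avg_parts = [], []
    for cube, refs, _truth, k in study:
        sid = int(cube.meta["scene_id"])
        in_cal = sid in plan.cal_scenes.get(k, ())
        in_pred = sid in plan.pred_scenes.get(k, ())
        if not (in_cal or in_pred):
            continue
        pixels, averages, _lmap, _ = scene_spectra(cube, refs, k, pre_cfg,
                                                   scene_id=sid)
        if in_cal:
            cal_pix_parts.append(pixels)
            cal_avg_parts.append(averages)
        else:
            pred_pix_parts.append(pixels)
            pred_avg_parts.append(averages)
    if not pred_pix_parts:
        raise ValueError("prediction set is empty under this plan")
    cal_pix = sample_pixels(concat_datasets(cal_pix_parts), plan, seed=seed)
    cal_avg = concat_datasets(cal_avg_parts)
    pred_pix = concat_datasets(pred_pix_parts)
    pred_avg = concat_datasets(pred_avg_parts)
    if eval_pixels_per_class is not None:
        rng = np.random.default_rng(seed + 1)
        take = []
        for k in np.unique(pred_pix.y):
            idx = np.flatnonzero(pred_pix.y == k)
            m = min(eval_pixels_per_class, idx.size)
            take.append(np.sort(rng.choice(idx, size=m, replace=False)))
        pred_pix = pred_pix.subset_rows(np.concatenate(take))

    feature_set = "full"
    if ws is not None:
        cal_pix = subset_bands(cal_pix, ws)
        cal_avg = subset_bands(cal_avg, ws)
        pred_pix = subset_bands(pred_pix, ws)
        pred_avg = subset_bands(pred_avg, ws)
        feature_set = f"optimal-{len(ws)}"

    C, g = svm_params
    if g is None:
        from .classify import gamma_scale
        g = gamma_scale(cal_pix.X)
    pixel_model = svm_train(cal_pix, C=C, g=g, kernel=kernel)
    average_model = svm_train(cal_avg, C=C, g=g, kernel=kernel)
    cells = {
        ("pixel", "pixel"): svm_predict(pixel_model, pred_pix)[1],
        ("pixel", "average"): svm_predict(pixel_model, pred_avg)[1],
        ("average", "pixel"): svm_predict(average_model, pred_pix)[1],
        ("average", "average"): svm_predict(average_model, pred_avg)[1],
    }
    return ExperimentMatrix(cells=cells, feature_set=feature_set,
                            method=pre_cfg.method,
                            pixel_model=pixel_model,
                            average_model=average_model)


# ---------------------------------------------------------------------------
# Prediction maps
# ---------------------------------------------------------------------------

def predict_scene(m: SVMModelBundle, cube: HyperCube, lmap: BeanLabelMap,
                  pre_cfg: PreprocessConfig,
                  ws: WavelengthSet | None = None) -> PredictionMap:
    """Classify every foreground pixel of a corrected, masked scene.

    The cube is preprocessed here with the same configuration used for
    training; band subsetting (if the model was trained on selected
    wavelengths) is applied after preprocessing.
    """
    processed = preprocess_cube(cube, lmap, pre_cfg)
    pixels = extract_pixel_spectra(processed, lmap, class_label=0)
    if ws is not None:
        pixels = subset_bands(pixels, ws)
    if pixels.X.shape[1] != m.n_features:
        raise ValueError(
            f"scene spectra have {pixels.X.shape[1]} bands, model expects "
            f"{m.n_features}; preprocess/subset to match training"
        )
    out = np.zeros(lmap.labels.shape, dtype=np.int32)
    if len(pixels):
        pred = m.predict(pixels.X)
        out[pixels.pixel_rc[:, 0], pixels.pixel_rc[:, 1]] = pred
    return PredictionMap(labels=out,
                         scene_id=int(cube.meta.get("scene_id", 0)))


def per_bean_vote(pmap: PredictionMap, lmap: BeanLabelMap,
                  true_class: int | None = None,
                  ) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Majority vote of pixel predictions within each bean instance.

    Returns (bean ids, voted labels, accuracy%) — the accuracy is against
    ``true_class`` (one scene holds one variety) or ``None`` if no truth is
    given.  Ties break toward the smaller class label; beans with no
    predicted pixels are skipped with a warning.
    """
    if pmap.labels.shape != lmap.labels.shape:
        raise ValueError("prediction map and label map geometries differ")
    bean_ids, votes = [], []
    for bid in range(1, lmap.n_beans + 1):
        preds = pmap.labels[(lmap.labels == bid) & (pmap.labels > 0)]
        if preds.size == 0:
            warnings.warn(f"bean {bid} has no predicted pixels; skipped",
                          stacklevel=2)
            continue
        counts = np.bincount(preds)
        bean_ids.append(bid)
        votes.append(int(np.argmax(counts)))   # first max = smallest label
    bean_ids = np.array(bean_ids, dtype=np.int64)
    votes = np.array(votes, dtype=np.int64)
    acc = None
    if true_class is not None and votes.size:
        acc = float(100.0 * np.mean(votes == true_class))
    return bean_ids, votes, acc


def render_map(pmap: PredictionMap, path) -> None:
    """Write the map as a lossless PNG with the fixed class palette.

    Identical maps produce byte-identical files.
    """
    missing = set(np.unique(pmap.labels)) - set(pmap.legend)
    if missing:
        raise ValueError(f"legend lacks colors for classes {sorted(missing)}")
    h, w = pmap.labels.shape
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    for k, color in pmap.legend.items():
        rgb[pmap.labels == k] = color
    Image.fromarray(rgb, mode="RGB").save(path, format="PNG")
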
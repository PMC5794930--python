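"""Calibration/prediction splits and multiclass soft-margin RBF-SVM models.

The study design keeps whole scenes together: for each variety the first
``cal_per_class`` scenes form the calibration set and the remaining scenes
the prediction set, so no bean contributes spectra to both sides.  Pixel
calibration sets are subsampled to a fixed number of pixels per class
(2000 by default in the study design), since whole scenes contain orders of
magnitude more pixels than are needed to fit the model.

Training is delegated to libsvm via scikit-learn's ``SVC`` (one-vs-one),
but the fitted model is re-expressed as an explicit
:class:`SVMModelBundle`: for every binary problem (i, j) the support-vector
coefficients alpha_i * y_i, the bias b and the support vectors themselves
are materialised, prediction is computed from them by kernel evaluation and
sign voting (ties toward the smaller class label), and the dual-feasibility
conditions (sum alpha_i y_i = 0 and the 0 <= alpha_i <= C box) can be
checked directly.

Kernels: Gaussian RBF exp(-g ||x - x'||^2) (default, g = 1/(2 sigma^2)),
``laplacian`` exp(-g ||x - x'||) and ``linear``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .cube_io import SpectraDataset

DEFAULT_C_GRID = tuple(float(2.0 ** p) for p in range(-4, 13))
DEFAULT_G_GRID = tuple(float(2.0 ** p) for p in range(-10, 5))


def gamma_scale(X: np.ndarray) -> float:
    """sklearn's 'scale' heuristic: 1 / (n_features * var(X))."""
    X = np.asarray(X, dtype=np.float64)
    v = X.var()
    return 1.0 / (X.shape[1] * v) if v > 0 else 1.0


# ---------------------------------------------------------------------------
# Split design
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Scene-level calibration/prediction assignment per class."""

    cal_scenes: dict[int, list[int]]
    pred_scenes: dict[int, list[int]]
    pixels_per_class_cal: int = 2000

    def __post_init__(self) -> None:
        for k in self.cal_scenes:
            overlap = set(self.cal_scenes[k]) & set(self.pred_scenes.get(k, []))
            if overlap:
                raise ValueError(f"class {k}: scenes {overlap} in both splits")
            if not self.cal_scenes[k] or not self.pred_scenes.get(k):
                raise ValueError(f"class {k} needs scenes in both splits")

    @property
    def all_cal(self) -> set[int]:
        return {s for ids in self.cal_scenes.values() for s in ids}

    @property
    def all_pred(self) -> set[int]:
        return {s for ids in self.pred_scenes.values() for s in ids}


def make_splits(study: list, cal_per_class: int = 4, seed: int = 0,
                pixels_per_class_cal: int = 2000) -> SplitPlan:
    """First ``cal_per_class`` scenes of each class to calibration, rest to
    prediction.  Deterministic given the study's scene ordering (``seed`` is
    accepted for interface symmetry but the assignment is order-based)."""
    by_class: dict[int, list[int]] = {}
    for cube, _refs, _truth, k in study:
        by_class.setdefault(k, []).append(int(cube.meta["scene_id"]))
    cal, pred = {}, {}
    for k, ids in by_class.items():
        if len(ids) < cal_per_class + 1:
            raise ValueError(
                f"class {k} has {len(ids)} scenes; need >= {cal_per_class + 1} "
                "for a non-empty prediction set"
            )
        cal[k] = ids[:cal_per_class]
        pred[k] = ids[cal_per_class:]
    return SplitPlan(cal_scenes=cal, pred_scenes=pred,
                     pixels_per_class_cal=pixels_per_class_cal)


def sample_pixels(pixels: SpectraDataset, plan: SplitPlan,
                  seed: int = 0) -> SpectraDataset:
    """Uniform, seeded, per-class subsample of calibration-scene pixels.

    Exactly ``plan.pixels_per_class_cal`` rows per class, drawn without
    replacement.  Rows must come from calibration scenes only.
    """
    cal_scenes = plan.all_cal
    if not set(np.unique(pixels.scene_id)).issubset(cal_scenes):
        raise ValueError("dataset contains pixels from non-calibration scenes")
    rng = np.random.default_rng(seed)
    take: list[np.ndarray] = []
    want = plan.pixels_per_class_cal
    for k in np.unique(pixels.y):
        idx = np.flatnonzero(pixels.y == k)
        if idx.size < want:
            raise ValueError(
                f"class {k}: requested {want} pixels but only {idx.size} available"
            )
        chosen = rng.choice(idx, size=want, replace=False)
        take.append(np.sort(chosen))
    return pixels.subset_rows(np.concatenate(take))


# ---------------------------------------------------------------------------
# Model bundle
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Accuracy summary; percentages of correctly classified samples."""

    pred_acc: float
    confusion: np.ndarray          # K x K counts, rows = truth, cols = predicted
    classes: np.ndarray
    n_pred: int
    cal_acc: float | None = None
    cv_acc: float | None = None
    n_cal: int = 0


@dataclass
class SVMModelBundle:
    """Explicit one-vs-one soft-margin SVM: kernel params + dual solution.

    ``dual_coef`` follows the libsvm layout: support vectors are grouped by
    class (ascending label) and row r holds the coefficients alpha*y of each
    SV in its r-th binary problem; :meth:`binary_problems` unpacks this into
    one (coefficients, support vectors, bias) record per class pair.
    """

    classes: np.ndarray
    C: float
    g: float
    kernel: str
    support_X: np.ndarray          # n_SV x n_features
    dual_coef: np.ndarray          # (K-1) x n_SV
    intercepts: np.ndarray         # K(K-1)/2 biases, pair order (0,1),(0,2),...
    n_support: np.ndarray          # SVs per class
    train_pred: np.ndarray         # stored predictions on the training set
    cal_acc: float
    cv_accuracy: float | None = None
    grid_trace: list = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.support_X.shape[1]

    def _kernel(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        A = np.asarray(A, dtype=np.float64)
        B = np.asarray(B, dtype=np.float64)
        if self.kernel == "linear":
            return A @ B.T
        sq = (np.sum(A * A, axis=1)[:, None] + np.sum(B * B, axis=1)[None, :]
              - 2.0 * (A @ B.T))
        np.maximum(sq, 0.0, out=sq)
        if self.kernel == "rbf":
            return np.exp(-self.g * sq)
        if self.kernel == "laplacian":
            return np.exp(-self.g * np.sqrt(sq))
        raise ValueError(f"unknown kernel '{self.kernel}'")

    def binary_problems(self):
        """Yield one record per class pair (i, j), i < j (by class position).

        Each record holds the pair labels, the alpha*y coefficients of the
        pair's support vectors (class-i SVs first, positive sign = class i),
        the support vectors themselves and the bias.
        """
        K = len(self.classes)
        starts = np.concatenate([[0], np.cumsum(self.n_support)])
        for p, (i, j) in enumerate(combinations(range(K), 2)):
            sl_i = slice(starts[i], starts[i + 1])
            sl_j = slice(starts[j], starts[j + 1])
            coef = np.concatenate([self.dual_coef[j - 1, sl_i],
                                   self.dual_coef[i, sl_j]])
            sv = np.vstack([self.support_X[sl_i], self.support_X[sl_j]])
            yield {
                "pair": (int(self.classes[i]), int(self.classes[j])),
                "alpha_y": coef,
                "support_X": sv,
                "bias": float(self.intercepts[p]),
            }

    def decision_ovo(self, X: np.ndarray, chunk: int = 4096) -> np.ndarray:
        """Per-pair decision values f(x) = sum alpha_y K(x, sv) + b."""
        X = np.asarray(X, dtype=np.float64)
        pairs = list(self.binary_problems())
        out = np.empty((X.shape[0], len(pairs)))
        for start in range(0, X.shape[0], chunk):
            block = X[start:start + chunk]
            for p, rec in enumerate(pairs):
                Km = self._kernel(block, rec["support_X"])
                out[start:start + chunk, p] = Km @ rec["alpha_y"] + rec["bias"]
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        """One-vs-one sign voting; ties break toward the smaller class label."""
        dec = self.decision_ovo(X)
        K = len(self.classes)
        votes = np.zeros((X.shape[0], K), dtype=np.int32)
        for p, (i, j) in enumerate(combinations(range(K), 2)):
            pos = dec[:, p] > 0
            votes[pos, i] += 1
            votes[~pos, j] += 1
        # argmax returns the first (= smallest label, classes sorted) maximum
        return self.classes[np.argmax(votes, axis=1)]

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "classes": self.classes.tolist(),
            "C": self.C, "g": self.g, "kernel": self.kernel,
            "support_X": self.support_X.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercepts": self.intercepts.tolist(),
            "n_support": self.n_support.tolist(),
            "train_pred": self.train_pred.tolist(),
            "cal_acc": self.cal_acc,
            "cv_accuracy": self.cv_accuracy,
            "grid_trace": self.grid_trace,
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SVMModelBundle":
        d = json.loads(Path(path).read_text())
        return cls(
            classes=np.array(d["classes"], dtype=np.int64),
            C=d["C"], g=d["g"], kernel=d["kernel"],
            support_X=np.array(d["support_X"], dtype=np.float64),
            dual_coef=np.array(d["dual_coef"], dtype=np.float64),
            intercepts=np.array(d["intercepts"], dtype=np.float64),
            n_support=np.array(d["n_support"], dtype=np.int64),
            train_pred=np.array(d["train_pred"], dtype=np.int64),
            cal_acc=d["cal_acc"], cv_accuracy=d["cv_accuracy"],
            grid_trace=[tuple(t) for t in d["grid_trace"]],
        )


# ---------------------------------------------------------------------------
# Training / prediction / grid search
# ---------------------------------------------------------------------------

def svm_train(ds: SpectraDataset, C: float, g: float,
              kernel: str = "rbf") -> SVMModelBundle:
    """Fit K(K-1)/2 binary soft-margin SVMs (one-vs-one) and bundle them.

    ``g`` is the kernel width parameter: K = exp(-g ||x - x'||^2) for the
    Gaussian RBF (so g = 1/(2 sigma^2)); ``laplacian`` uses the unsquared
    norm, ``linear`` the plain inner product.
    """
    X = np.asarray(ds.X, dtype=np.float64)
    y = np.asarray(ds.y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training requires at least 2 classes")
    counts = np.array([(y == k).sum() for k in classes])
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 training samples")
    if kernel in ("rbf", "linear"):
        clf = SVC(C=C, kernel=kernel, gamma=g, decision_function_shape="ovo")
        clf.fit(X, y)
        support_X = X[clf.support_]
    elif kernel == "laplacian":
        sq = (np.sum(X * X, axis=1)[:, None] + np.sum(X * X, axis=1)[None, :]
              - 2.0 * (X @ X.T))
        np.maximum(sq, 0.0, out=sq)
        clf = SVC(C=C, kernel="precomputed", decision_function_shape="ovo")
        clf.fit(np.exp(-g * np.sqrt(sq)), y)
        support_X = X[clf.support_]
    else:
        raise ValueError(f"unknown kernel '{kernel}'")
    dual_coef = np.asarray(clf.dual_coef_, dtype=np.float64)
    intercepts = np.atleast_1d(np.asarray(clf.intercept_, dtype=np.float64))
    if classes.size == 2:
        # libsvm's two-class decision as exposed by sklearn is positive for
        # the second class; flip so "positive favours the pair's first
        # class" holds uniformly (matching the K > 2 ovo columns)
        dual_coef = -dual_coef
        intercepts = -intercepts
    bundle = SVMModelBundle(
        classes=classes.astype(np.int64),
        C=float(C), g=float(g), kernel=kernel,
        support_X=support_X,
        dual_coef=dual_coef,
        intercepts=intercepts,
        n_support=np.asarray(clf.n_support_, dtype=np.int64),
        train_pred=np.zeros(len(y), dtype=np.int64),
        cal_acc=0.0,
    )
    bundle.train_pred = bundle.predict(X)
    bundle.cal_acc = float(100.0 * np.mean(bundle.train_pred == y))
    return bundle


def svm_predict(m: SVMModelBundle, ds: SpectraDataset,
                ) -> tuple[np.ndarray, EvalReport]:
    """Predict class labels and, truth being present in ``ds``, score them."""
    if ds.X.shape[1] != m.n_features:
        raise ValueError(
            f"dataset has {ds.X.shape[1]} bands, model expects {m.n_features}"
        )
    labels = m.predict(ds.X)
    K = len(m.classes)
    pos = {int(k): i for i, k in enumerate(m.classes)}
    confusion = np.zeros((K, K), dtype=np.int64)
    for t, p in zip(ds.y, labels):
        confusion[pos.get(int(t), 0), pos[int(p)]] += 1
    acc = float(100.0 * np.mean(labels == ds.y))
    report = EvalReport(pred_acc=acc, confusion=confusion, classes=m.classes,
                        n_pred=len(ds), cal_acc=m.cal_acc, cv_acc=m.cv_accuracy)
    return labels, report


def grid_search(ds: SpectraDataset, C_grid=DEFAULT_C_GRID,
                g_grid=DEFAULT_G_GRID, folds: int = 5, seed: int = 0,
                kernel: str = "rbf") -> tuple[float, float, list]:
    """Stratified k-fold CV accuracy over the (C, g) grid; argmax returned.

    Ties break toward the smaller C, then the smaller g (the grid is swept
    in ascending order and only strict improvements replace the incumbent).
    Returns ``(C, g, trace)`` with one ``(C, g, cv_percent)`` triple per
    grid point.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = np.asarray(ds.y)
    min_class = min((y == k).sum() for k in np.unique(y))
    if folds > min_class:
        raise ValueError(
            f"{folds}-fold CV impossible: smallest class has {min_class} samples"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_idx = list(skf.split(ds.X, y))
    trace: list[tuple[float, float, float]] = []
    best = (None, None, -1.0)
    for C in sorted(C_grid):
        for g in sorted(g_grid):
            correct = 0
            for tr, te in fold_idx:
                m = svm_train(ds.subset_rows(tr), C=C, g=g, kernel=kernel)
                pred = m.predict(ds.X[te])
                correct += int(np.sum(pred == y[te]))
            acc = 100.0 * correct / len(y)
            trace.append((float(C), float(g), acc))
            if acc > best[2]:
                best = (float(C), float(g), acc)
    return best[0], best[1], trace


def cross_validate(ds: SpectraDataset, C: float, g: float, folds: int = 5,
                   seed: int = 0, kernel: str = "rbf") -> float:
    """Stratified k-fold CV accuracy (%) at one (C, g) point."""
    _, _, trace = grid_search(ds, C_grid=[C], g_grid=[g], folds=folds,
                              seed=seed, kernel=kernel)
    return trace[0][2]
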
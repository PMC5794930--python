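"""Optimal-wavelength selection from second-derivative class-mean spectra.

Second-derivative spectra sharpen absorption features, suppress the smooth
baseline and make small class-to-class differences visible as peaks and
valleys.  Bands where the second derivatives of the class means differ most
are the most discriminative, so selection proceeds by (1) computing a
Savitzky-Golay second derivative of each class-mean spectrum, (2) collecting
every local extremum of any class's derivative curve as a candidate, (3)
scoring each candidate by the across-class range (max - min) of the second
derivative at that band, and (4) greedily keeping the highest-scoring
candidates subject to a minimum wavelength separation, up to ``max_k``.

This replaces the manual peak picking a spectroscopist would do on the
derivative plot with a deterministic, reproducible rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .cube_io import SpectraDataset


@dataclass
class SecondDerivativeSet:
    """Second-derivative curves of the K class-mean spectra (per nm^2)."""

    d2: np.ndarray               # K x bands
    wavelengths: np.ndarray
    class_labels: np.ndarray
    source_preprocess: str = "none"

    def __post_init__(self) -> None:
        self.d2 = np.asarray(self.d2, dtype=np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        self.class_labels = np.asarray(self.class_labels, dtype=np.int64)
        if self.d2.shape != (self.class_labels.size, self.wavelengths.size):
            raise ValueError("d2 must be (n_classes, n_bands)")


@dataclass
class WavelengthSet:
    """Selected band subset, ascending in nm, with per-band scores."""

    selected: np.ndarray         # nm values
    indices: np.ndarray          # band indices into the source grid
    scores: np.ndarray           # across-class d2 range at each band
    wavelengths: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=np.float64)
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if not (self.selected.size == self.indices.size == self.scores.size):
            raise ValueError("selected, indices and scores must align")
        if self.selected.size and np.any(np.diff(self.selected) <= 0):
            raise ValueError("selected wavelengths must be strictly ascending")

    def __len__(self) -> int:
        return self.selected.size

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({
            "wavelength_nm": self.selected,
            "band_index": self.indices,
            "score": self.scores,
        }).to_csv(path, index=False)


def class_mean_spectra(ds: SpectraDataset) -> tuple[np.ndarray, np.ndarray]:
    """Mean spectrum per class label, sorted ascending by label."""
    labels = np.unique(ds.y)
    means = np.stack([np.asarray(ds.X[ds.y == k], dtype=np.float64).mean(axis=0)
                      for k in labels])
    return means, labels


def second_derivative(class_means: SpectraDataset | np.ndarray,
                      wavelengths: np.ndarray | None = None,
                      class_labels: np.ndarray | None = None,
                      window: int = 11, polyorder: int = 3,
                      source_preprocess: str = "none") -> SecondDerivativeSet:
    """Savitzky-Golay second derivative of each class-mean spectrum.

    Accepts either a :class:`SpectraDataset` (class means are computed from
    it) or an already-averaged ``K x bands`` matrix plus its wavelength grid.
    The derivative is in reflectance per nm^2, using the grid spacing as the
    sample interval; the grid must be uniform.
    """
    if isinstance(class_means, SpectraDataset):
        means, labels = class_mean_spectra(class_means)
        wavelengths = class_means.wavelengths
    else:
        means = np.atleast_2d(np.asarray(class_means, dtype=np.float64))
        if wavelengths is None:
            raise ValueError("wavelengths required for a bare matrix")
        labels = (np.arange(1, means.shape[0] + 1)
                  if class_labels is None else np.asarray(class_labels))
    wavelengths = np.asarray(wavelengths, dtype=np.float64)
    if means.shape[1] < window:
        raise ValueError(f"need >= {window} bands for the derivative window")
    steps = np.diff(wavelengths)
    if not np.allclose(steps, steps[0]):
        raise ValueError("wavelength grid must be uniform")
    d2 = savgol_filter(means, window_length=window, polyorder=polyorder,
                       deriv=2, delta=float(steps[0]), axis=-1)
    return SecondDerivativeSet(d2=d2, wavelengths=wavelengths,
                               class_labels=labels,
                               source_preprocess=source_preprocess)


def _local_extrema_1d(v: np.ndarray) -> np.ndarray:
    """Indices of interior local maxima and minima of one curve."""
    left = v[1:-1] - v[:-2]
    right = v[1:-1] - v[2:]
    is_max = (left > 0) & (right >= 0)
    is_min = (left < 0) & (right <= 0)
    return np.where(is_max | is_min)[0] + 1


def select_wavelengths(d2set: SecondDerivativeSet, max_k: int = 15,
                       min_separation_nm: float = 10.0,
                       score_floor: float = 0.0) -> WavelengthSet:
    """Greedy scored-extrema selection of discriminative bands.

    Candidates are local extrema of any class's second-derivative curve;
    the score of a candidate band is the across-class range of the second
    derivative there.  Candidates are taken highest score first (ties break
    toward the lower wavelength), skipping any within ``min_separation_nm``
    of an already-kept band, until ``max_k`` bands are kept.  Bands whose
    score does not exceed ``score_floor`` are never selected, so identical
    class means yield an empty set.
    """
    if d2set.d2.shape[0] < 2:
        raise ValueError("need at least 2 classes to score differences")
    candidates: set[int] = set()
    for row in d2set.d2:
        candidates.update(_local_extrema_1d(row).tolist())
    if not candidates:
        warnings.warn("no local extrema in second-derivative curves",
                      stacklevel=2)
        return WavelengthSet(selected=[], indices=[], scores=[])
    cand = np.array(sorted(candidates))
    scores = d2set.d2[:, cand].max(axis=0) - d2set.d2[:, cand].min(axis=0)
    keep_mask = scores > score_floor
    cand, scores = cand[keep_mask], scores[keep_mask]
    # highest score first; ties toward the lower wavelength (stable sort on
    # ascending band index, then stable sort on descending score)
    order = np.argsort(-scores, kind="stable")
    kept: list[int] = []
    kept_scores: list[float] = []
    wl = d2set.wavelengths
    for j in order:
        b = int(cand[j])
        if any(abs(wl[b] - wl[k]) < min_separation_nm for k in kept):
            continue
        kept.append(b)
        kept_scores.append(float(scores[j]))
        if len(kept) >= max_k:
            break
    idx = np.argsort(kept)
    kept_arr = np.array(kept, dtype=np.int64)[idx]
    return WavelengthSet(selected=wl[kept_arr], indices=kept_arr,
                         scores=np.array(kept_scores)[idx])


def subset_bands(ds: SpectraDataset, ws: WavelengthSet) -> SpectraDataset:
    """Restrict a dataset to the selected bands, order preserved."""
    if len(ws) == 0:
        raise ValueError("wavelength set is empty")
    if ws.indices.max() >= ds.wavelengths.size or ws.indices.min() < 0:
        raise IndexError("wavelength-set indices out of range for this dataset")
    return SpectraDataset(
        X=ds.X[:, ws.indices],
        y=ds.y,
        scene_id=ds.scene_id,
        bean_id=ds.bean_id,
        wavelengths=ds.wavelengths[ws.indices],
        pixel_rc=ds.pixel_rc,
    )


def plot_second_derivative(d2set: SecondDerivativeSet,
                           ws: WavelengthSet | None = None, path=None):
    """Plot the per-class d2 curves with the selected bands marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    for k, row in zip(d2set.class_labels, d2set.d2):
        ax.plot(d2set.wavelengths, row, label=f"class {k}", lw=1)
    if ws is not None and len(ws):
        for nm in ws.selected:
            ax.axvline(nm, color="0.6", ls=":", lw=0.8)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("2nd derivative (refl / nm$^2$)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
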
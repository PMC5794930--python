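"""Hyperspectral cube I/O, reflectance correction, masking and spectra extraction.

The central object is the :class:`HyperCube`: a ``rows x cols x bands``
reflectance (or raw-intensity) array paired with its wavelength vector in
nanometres.  Scenes are read from / written to the ENVI layout (an ASCII
``.hdr`` next to a raw binary cube, BSQ or BIL interleave).  Raw intensity
cubes are converted to reflectance with white/dark reference frames,

    R = (I_raw - I_dark) / (I_white - I_dark),

beans are separated from the near-zero background by thresholding a single
gray-scale band (1200 nm by default) and labelling connected components, and
spectra are extracted either per pixel or as per-bean averages.

Conventions used throughout the package: pixel coordinates are 0-based
``(row, col)`` in row-major scan order; band indices are 0-based; requests
for a wavelength in nm resolve to the nearest band, ties breaking toward the
lower wavelength.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label


class EnviFormatError(ValueError):
    """Malformed ENVI header or size-mismatched binary cube."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class HyperCube:
    """Reflectance cube ``data[row, col, band]`` with wavelengths in nm."""

    data: np.ndarray
    wavelengths: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D, got shape {self.data.shape}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise ValueError(
                f"wavelength count {self.wavelengths.size} != band count {self.data.shape[2]}"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_index(self, nm: float) -> int:
        """Nearest band to ``nm``; ties break toward the lower wavelength."""
        d = np.abs(self.wavelengths - nm)
        # argmin returns the first (= lower-wavelength) index on ties
        return int(np.argmin(d))


@dataclass
class ReferenceFrames:
    """White and dark reference frames, broadcastable to the cube shape.

    Either full ``rows x cols x bands`` frames or per-band vectors of length
    ``bands`` (a flat-field line reduced over the spatial axes).
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white)
        self.dark = np.asarray(self.dark)
        if self.white.shape != self.dark.shape:
            raise ValueError("white and dark frames must have the same shape")


@dataclass
class BeanLabelMap:
    """Binary foreground mask plus integer bean-instance labels.

    ``mask`` is 1 on sample pixels, 0 on background; ``labels`` is 0 on
    background and ``1..n_beans`` on the pixels of each connected bean.
    """

    mask: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.mask.shape != self.labels.shape:
            raise ValueError("mask and labels must have the same shape")
        if np.any((self.labels > 0) != (self.mask == 1)):
            raise ValueError("labels must be positive exactly where mask == 1")

    @property
    def n_beans(self) -> int:
        return int(self.labels.max())


@dataclass
class SpectraDataset:
    """Spectra matrix with class labels and per-row provenance.

    ``X`` is ``n_spectra x n_bands``; ``y`` holds integer class labels in
    ``1..K``.  ``pixel_rc`` is ``n x 2`` (row, col) for pixel-wise spectra and
    ``None`` for sample-average spectra.
    """

    X: np.ndarray
    y: np.ndarray
    scene_id: np.ndarray
    bean_id: np.ndarray
    wavelengths: np.ndarray
    pixel_rc: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.scene_id = np.asarray(self.scene_id, dtype=np.int64)
        self.bean_id = np.asarray(self.bean_id, dtype=np.int64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        n = self.X.shape[0]
        if not (len(self.y) == len(self.scene_id) == len(self.bean_id) == n):
            raise ValueError("X, y and provenance arrays must be row-aligned")
        if self.X.shape[1] != self.wavelengths.size:
            raise ValueError("X column count must match wavelength count")
        if self.pixel_rc is not None:
            self.pixel_rc = np.asarray(self.pixel_rc, dtype=np.int64)
            if self.pixel_rc.shape != (n, 2):
                raise ValueError("pixel_rc must be n x 2")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.y)

    def subset_rows(self, idx: np.ndarray) -> "SpectraDataset":
        return SpectraDataset(
            X=self.X[idx],
            y=self.y[idx],
            scene_id=self.scene_id[idx],
            bean_id=self.bean_id[idx],
            wavelengths=self.wavelengths,
            pixel_rc=None if self.pixel_rc is None else self.pixel_rc[idx],
        )

    def to_csv(self, path: str | Path) -> None:
        """Write as CSV: scene_id, bean_id, row, col, y, then one column per nm."""
        n = len(self)
        cols: dict[str, np.ndarray] = {
            "scene_id": self.scene_id,
            "bean_id": self.bean_id,
        }
        if self.pixel_rc is not None:
            cols["row"] = self.pixel_rc[:, 0]
            cols["col"] = self.pixel_rc[:, 1]
        else:
            cols["row"] = np.full(n, np.nan)
            cols["col"] = np.full(n, np.nan)
        cols["y"] = self.y
        df = pd.DataFrame(cols)
        spec = pd.DataFrame(
            np.asarray(self.X, dtype=np.float64),
            columns=[f"{w:g}" for w in self.wavelengths],
        )
        pd.concat([df, spec], axis=1).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectraDataset":
        df = pd.read_csv(path)
        wl_cols = df.columns[5:]
        wavelengths = np.array([float(c) for c in wl_cols])
        has_rc = df["row"].notna().all()
        return cls(
            X=df[wl_cols].to_numpy(),
            y=df["y"].to_numpy(),
            scene_id=df["scene_id"].to_numpy(),
            bean_id=df["bean_id"].to_numpy(),
            wavelengths=wavelengths,
            pixel_rc=df[["row", "col"]].to_numpy(dtype=np.int64) if has_rc else None,
        )


def concat_datasets(parts: list[SpectraDataset]) -> SpectraDataset:
    """Row-wise concatenation; wavelength grids must match."""
    if not parts:
        raise ValueError("nothing to concatenate")
    wl = parts[0].wavelengths
    for p in parts[1:]:
        if not np.array_equal(p.wavelengths, wl):
            raise ValueError("wavelength grids differ between datasets")
    has_rc = all(p.pixel_rc is not None for p in parts)
    return SpectraDataset(
        X=np.concatenate([p.X for p in parts]),
        y=np.concatenate([p.y for p in parts]),
        scene_id=np.concatenate([p.scene_id for p in parts]),
        bean_id=np.concatenate([p.bean_id for p in parts]),
        wavelengths=wl,
        pixel_rc=np.concatenate([p.pixel_rc for p in parts]) if has_rc else None,
    )


# ---------------------------------------------------------------------------
# ENVI I/O
# ---------------------------------------------------------------------------

_DTYPE_TO_ENVI = {np.dtype("float32"): 4, np.dtype("float64"): 5,
                  np.dtype("int16"): 2, np.dtype("uint16"): 12,
                  np.dtype("int32"): 3, np.dtype("uint8"): 1}
_ENVI_TO_DTYPE = {v: k for k, v in _DTYPE_TO_ENVI.items()}


def _data_path_for(header_path: Path) -> Path:
    base = header_path.with_suffix("") if header_path.suffix == ".hdr" else header_path
    for cand in (base, base.with_suffix(".raw"), base.with_suffix(".img"),
                 base.with_suffix(".dat")):
        if cand.exists() and cand != header_path:
            return cand
    raise EnviFormatError(f"no binary cube found next to {header_path}")


def _parse_envi_header(text: str) -> dict:
    """Parse the ASCII key = value header; {...} values may span lines."""
    fields: dict[str, str] = {}
    body = text
    if body.lstrip().upper().startswith("ENVI"):
        body = body.lstrip()[4:]
    i = 0
    while i < len(body):
        eq = body.find("=", i)
        if eq < 0:
            break
        key = body[i:eq].strip().lower()
        rest = body[eq + 1:].lstrip()
        offset = eq + 1 + (len(body[eq + 1:]) - len(rest))
        if rest.startswith("{"):
            close = body.find("}", offset)
            if close < 0:
                raise EnviFormatError(f"unterminated {{...}} for key '{key}'")
            val = body[offset + 1:close]
            i = close + 1
        else:
            nl = body.find("\n", offset)
            nl = len(body) if nl < 0 else nl
            val = body[offset:nl]
            i = nl + 1
        if key:
            fields[key] = val.strip()
    return fields


def read_envi(header_path: str | Path) -> HyperCube:
    """Read an ENVI-format cube (BSQ or BIL) given its header path."""
    header_path = Path(header_path)
    if not header_path.exists():
        raise EnviFormatError(f"header not found: {header_path}")
    fields = _parse_envi_header(header_path.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise EnviFormatError(f"header missing required field: {exc}") from exc
    if "wavelength" not in fields:
        raise EnviFormatError("header has no wavelength list")
    wavelengths = np.array(
        [float(tok) for tok in fields["wavelength"].replace("\n", " ").split(",")]
    )
    if wavelengths.size != bands:
        raise EnviFormatError(
            f"wavelength list length {wavelengths.size} != bands {bands}"
        )
    if dtype_code not in _ENVI_TO_DTYPE:
        raise EnviFormatError(f"unsupported ENVI data type {dtype_code}")
    dtype = _ENVI_TO_DTYPE[dtype_code]
    if interleave not in ("bsq", "bil"):
        raise EnviFormatError(f"unsupported interleave '{interleave}' (use bsq or bil)")

    data_path = _data_path_for(header_path)
    flat = np.fromfile(data_path, dtype=dtype)
    expected = samples * lines * bands
    if flat.size != expected:
        raise EnviFormatError(
            f"binary cube has {flat.size} elements, header implies {expected}"
        )
    if interleave == "bsq":          # (bands, lines, samples)
        data = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    else:                            # bil: (lines, bands, samples)
        data = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    meta = {k: v for k, v in fields.items()
            if k not in ("samples", "lines", "bands", "data type",
                         "interleave", "wavelength", "byte order",
                         "header offset")}
    meta["interleave"] = interleave
    return HyperCube(data=np.ascontiguousarray(data), wavelengths=wavelengths,
                     meta=meta)


def write_envi(cube: HyperCube, header_path: str | Path,
               interleave: str = "bsq") -> Path:
    """Write ``cube`` as ENVI header + raw binary; returns the binary path."""
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil"):
        raise ValueError(f"unsupported interleave '{interleave}'")
    header_path = Path(header_path)
    if header_path.suffix != ".hdr":
        header_path = header_path.with_suffix(".hdr")
    data_path = header_path.with_suffix(".raw")
    rows, cols, bands = cube.shape
    dtype = cube.data.dtype
    if dtype not in _DTYPE_TO_ENVI:
        raise ValueError(f"unsupported dtype {dtype} for ENVI export")
    wl = ", ".join(f"{w:g}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        f"data type = {_DTYPE_TO_ENVI[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength = {{ {wl} }}\n"
    )
    header_path.write_text(header)
    if interleave == "bsq":
        out = cube.data.transpose(2, 0, 1)
    else:
        out = cube.data.transpose(0, 2, 1)
    np.ascontiguousarray(out).tofile(data_path)
    return data_path


# ---------------------------------------------------------------------------
# Reflectance correction
# ---------------------------------------------------------------------------

def reflectance_correct(raw: HyperCube, refs: ReferenceFrames) -> HyperCube:
    """Convert raw intensity to reflectance: (raw - dark) / (white - dark).

    The white/dark frames are broadcast against the cube, so per-band
    reference vectors and full reference frames are both accepted.  Any
    non-positive ``white - dark`` element used in the division is an error
    (it would divide by zero or flip the sign of the reflectance).
    """
    denom = refs.white - refs.dark
    try:
        np.broadcast_shapes(raw.data.shape, denom.shape)
    except ValueError as exc:
        raise ValueError(
            f"reference frames of shape {denom.shape} are not broadcastable "
            f"to cube shape {raw.data.shape}"
        ) from exc
    bad = denom <= 0
    if np.any(bad):
        loc = tuple(int(i) for i in
                    np.unravel_index(int(np.flatnonzero(bad)[0]), denom.shape))
        raise ZeroDivisionError(
            f"white - dark is non-positive at index {loc} "
            f"(value {denom[loc]}); correction undefined"
        )
    corrected = (raw.data - refs.dark) / denom
    meta = dict(raw.meta)
    meta["reflectance_corrected"] = True
    return HyperCube(data=corrected.astype(raw.data.dtype, copy=False),
                     wavelengths=raw.wavelengths, meta=meta)


# ---------------------------------------------------------------------------
# Masking and bean instance labelling
# ---------------------------------------------------------------------------

def build_mask(cube: HyperCube, band_nm: float = 1200.0,
               threshold: float | None = None,
               min_area: int = 20) -> BeanLabelMap:
    """Threshold one gray-scale band into a foreground mask and label beans.

    The band nearest ``band_nm`` is used.  With ``threshold=None`` the cut is
    Otsu's threshold on that band (reproducible and parameter-free); pass a
    fixed reflectance value to override.  Foreground is ``gray > threshold``.
    Bean instances are 8-connected components of the mask; components smaller
    than ``min_area`` pixels are dropped as specks.
    """
    gray = np.asarray(cube.data[:, :, cube.band_index(band_nm)], dtype=np.float64)
    if threshold is None:
        if np.ptp(gray) == 0:
            # constant band: nothing to separate
            threshold = np.inf
        else:
            threshold = float(threshold_otsu(gray))
    mask = gray > threshold
    labels = cc_label(mask, connectivity=2).astype(np.int32)
    if min_area > 0 and labels.max() > 0:
        ids, counts = np.unique(labels[labels > 0], return_counts=True)
        small = ids[counts < min_area]
        if small.size:
            labels[np.isin(labels, small)] = 0
        # relabel consecutively, preserving scan order of first appearance
        kept = np.unique(labels[labels > 0])
        lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
        lut[kept] = np.arange(1, kept.size + 1, dtype=np.int32)
        labels = lut[labels]
    mask = labels > 0
    if not mask.any():
        warnings.warn("mask is empty: no foreground pixels above threshold",
                      stacklevel=2)
    return BeanLabelMap(mask=mask.astype(np.uint8), labels=labels)


def apply_mask(cube: HyperCube, lmap: BeanLabelMap) -> HyperCube:
    """Zero the background at every band; foreground is untouched."""
    if lmap.mask.shape != cube.shape[:2]:
        raise ValueError(
            f"mask shape {lmap.mask.shape} != cube spatial shape {cube.shape[:2]}"
        )
    data = cube.data.copy()
    data[lmap.mask == 0] = 0
    return HyperCube(data=data, wavelengths=cube.wavelengths, meta=dict(cube.meta))


# ---------------------------------------------------------------------------
# Spectra extraction
# ---------------------------------------------------------------------------

def extract_pixel_spectra(cube: HyperCube, lmap: BeanLabelMap, class_label: int,
                          scene_id: int | None = None) -> SpectraDataset:
    """One spectrum per foreground pixel, in row-major scan order.

    Bean id and (row, col) coordinates are recorded per spectrum; the class
    label is attached to every row (one scene holds one variety).
    """
    if lmap.mask.shape != cube.shape[:2]:
        raise ValueError("label map does not match cube geometry")
    if scene_id is None:
        scene_id = int(cube.meta.get("scene_id", 0))
    rr, cc = np.nonzero(lmap.labels)        # row-major order
    if rr.size == 0:
        warnings.warn("extracting from an empty mask", stacklevel=2)
    X = cube.data[rr, cc, :]
    return SpectraDataset(
        X=X,
        y=np.full(rr.size, class_label),
        scene_id=np.full(rr.size, scene_id),
        bean_id=lmap.labels[rr, cc],
        wavelengths=cube.wavelengths,
        pixel_rc=np.stack([rr, cc], axis=1),
    )


def average_by_bean(pixels: SpectraDataset) -> SpectraDataset:
    """Collapse pixel spectra to one mean spectrum per (scene, bean).

    The class label is inherited (it is constant within a bean); pixel
    coordinates are dropped.  Averaging n i.i.d.-noise pixel spectra reduces
    the additive-noise standard deviation by about 1/sqrt(n), which is why
    sample-average spectra are so much cleaner than pixel-wise ones.
    """
    key = np.stack([pixels.scene_id, pixels.bean_id], axis=1)
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    n_beans = uniq.shape[0]
    counts = np.bincount(inv, minlength=n_beans).astype(np.float64)
    Xm = np.zeros((n_beans, pixels.X.shape[1]), dtype=np.float64)
    np.add.at(Xm, inv, np.asarray(pixels.X, dtype=np.float64))
    Xm /= counts[:, None]
    y = np.zeros(n_beans, dtype=np.int64)
    y[inv] = pixels.y
    return SpectraDataset(
        X=Xm.astype(pixels.X.dtype, copy=False),
        y=y,
        scene_id=uniq[:, 0],
        bean_id=uniq[:, 1],
        wavelengths=pixels.wavelengths,
        pixel_rc=None,
    )
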
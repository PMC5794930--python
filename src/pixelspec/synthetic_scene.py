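"""Synthetic hyperspectral bean scenes with controlled statistical structure.

The generator emulates NIR pushbroom scenes of loose seeds on a dark
conveyor plate: ~50 elliptical bean objects per 256 x 320 frame, a
874-1734 nm wavelength axis on a 5 nm grid, per-class smooth reflectance
endmembers distinguished by Gaussian absorption features, a multiplicative
center-to-edge brightness gradient per bean (the path-length / surface-shape
effect that makes center pixels uniformly brighter across all bands), and
additive per-pixel per-band random noise.  White and dark reference frames
are emitted alongside the raw-intensity cube so that the standard
white/dark reflectance correction recovers the designed reflectance in
expectation.

Everything is deterministic given the configuration seed, so a full study
(several scenes per class) can be regenerated bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cube_io import BeanLabelMap, HyperCube, ReferenceFrames

#: (center nm, depth, Gaussian sigma nm) triples per class — the default
#: four varieties differ pairwise in at least one absorption feature.
DEFAULT_FEATURES: dict[int, list[tuple[float, float, float]]] = {
    1: [(950.0, 0.10, 18.0), (1400.0, 0.12, 22.0)],
    2: [(1050.0, 0.10, 18.0), (1400.0, 0.12, 22.0)],
    3: [(950.0, 0.10, 18.0), (1550.0, 0.10, 20.0)],
    4: [(1150.0, 0.10, 18.0), (1650.0, 0.10, 20.0)],
}

#: Overall reflectance level per variety.  Real varieties differ in overall
#: brightness as well as in absorption features, and it is this intensity
#: component that the per-bean shape gain confounds: a darker variety's
#: center pixels look like a brighter variety's edge pixels.
DEFAULT_CLASS_LEVELS: tuple[float, ...] = (1.00, 0.94, 1.06, 0.97)


def default_wavelengths() -> np.ndarray:
    """874-1734 nm at the instrument's 5 nm resolution (173 bands)."""
    return np.arange(874.0, 1734.0 + 1e-9, 5.0)


def default_endmember_features(n_classes: int) -> dict[int, list[tuple[float, float, float]]]:
    """Per-class absorption features; classes 1-4 use the fixed default table."""
    if n_classes <= 4:
        return {k: DEFAULT_FEATURES[k] for k in range(1, n_classes + 1)}
    centers = np.linspace(950.0, 1650.0, n_classes)
    return {k + 1: [(float(c), 0.10, 18.0), (1400.0, 0.12, 22.0)]
            for k, c in enumerate(centers)}


@dataclass
class SceneConfig:
    """Study-design parameters for the synthetic scenes.

    Defaults reproduce the emulated acquisition design: 4 varieties,
    6 scenes per variety, 50 beans per scene on 256 x 320 frames, additive
    noise sd 0.02 reflectance units and a 1.6x center-to-edge gain.
    """

    n_classes: int = 4
    beans_per_scene: int = 50
    scenes_per_class: int = 6
    rows: int = 256
    cols: int = 320
    wavelengths: np.ndarray = field(default_factory=default_wavelengths)
    endmember_features: dict[int, list[tuple[float, float, float]]] | None = None
    class_levels: tuple[float, ...] | None = None
    shape_gain: float = 1.6
    noise_sd: float = 0.02
    noise_dist: str = "gaussian"          # or "student_t" (df=3, matched sd)
    background_level: float = 0.02
    bean_radius_range: tuple[float, float] = (6.0, 10.0)
    dtype: str = "float32"
    seed: int = 0

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.endmember_features is None:
            self.endmember_features = default_endmember_features(self.n_classes)
        if self.class_levels is None:
            if self.n_classes <= len(DEFAULT_CLASS_LEVELS):
                self.class_levels = DEFAULT_CLASS_LEVELS[:self.n_classes]
            else:
                self.class_levels = tuple(
                    np.linspace(0.92, 1.08, self.n_classes).tolist())
        if len(self.class_levels) != self.n_classes:
            raise ValueError("class_levels length must equal n_classes")
        if any(lv <= 0 for lv in self.class_levels):
            raise ValueError("class_levels must be positive")
        if self.shape_gain < 1:
            raise ValueError("shape_gain must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_dist not in ("gaussian", "student_t"):
            raise ValueError(f"unknown noise_dist '{self.noise_dist}'")
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        for k, feats in self.endmember_features.items():
            for center, _depth, _width in feats:
                if not (lo <= center <= hi):
                    raise ValueError(
                        f"class {k} feature at {center} nm outside "
                        f"wavelength range [{lo}, {hi}]"
                    )


def _base_curve(wl: np.ndarray) -> np.ndarray:
    """Smooth (C-infinity) reflectance baseline shared by all classes."""
    u = (wl - 1300.0) / 430.0
    return 0.55 - 0.12 * u * u + 0.05 * np.sin(2 * np.pi * (wl - 874.0) / 600.0)


def make_endmembers(cfg: SceneConfig) -> np.ndarray:
    """Per-class clean reflectance spectra, shape (n_classes, n_bands).

    Each spectrum is the shared smooth baseline minus the class's Gaussian
    absorption features, scaled by the class's overall reflectance level.
    Raises if any curve leaves (0, 1).
    """
    wl = cfg.wavelengths
    E = np.empty((cfg.n_classes, wl.size), dtype=np.float64)
    for k in range(1, cfg.n_classes + 1):
        curve = _base_curve(wl).copy()
        for center, depth, width in cfg.endmember_features[k]:
            curve -= depth * np.exp(-0.5 * ((wl - center) / width) ** 2)
        E[k - 1] = cfg.class_levels[k - 1] * curve
    if np.any(E <= 0) or np.any(E >= 1):
        raise ValueError("endmember curves must lie strictly inside (0, 1)")
    return E


def random_endmember_features(n_classes: int, rng: np.random.Generator,
                              wl_lo: float = 920.0, wl_hi: float = 1680.0,
                              depth: float = 0.10, width: float = 18.0,
                              min_separation_nm: float = 60.0,
                              ) -> dict[int, list[tuple[float, float, float]]]:
    """Draw one distinct absorption-feature center per class.

    Centers are rejected until pairwise separated by ``min_separation_nm``,
    so each planted feature is unambiguously attributable to one class.
    """
    centers: list[float] = []
    tries = 0
    while len(centers) < n_classes:
        c = float(rng.uniform(wl_lo, wl_hi))
        if all(abs(c - c0) >= min_separation_nm for c0 in centers):
            centers.append(c)
        tries += 1
        if tries > 10000:
            raise RuntimeError("could not place separated feature centers")
    return {k + 1: [(centers[k], depth, width)] for k in range(n_classes)}


# ---------------------------------------------------------------------------
# Scene rendering
# ---------------------------------------------------------------------------

def _place_beans(cfg: SceneConfig, rng: np.random.Generator,
                 max_tries: int = 4000) -> list[tuple[float, float, float, float]]:
    """Non-overlapping axis-aligned ellipses (r0, c0, a, b); bounded retries."""
    lo, hi = cfg.bean_radius_range
    placed: list[tuple[float, float, float, float]] = []
    gap = 2.0
    for _ in range(cfg.beans_per_scene):
        ok = False
        for _try in range(max_tries):
            a = float(rng.uniform(lo, hi))       # row semi-axis
            b = float(rng.uniform(lo, hi))       # col semi-axis
            r0 = float(rng.uniform(hi + gap, cfg.rows - hi - gap))
            c0 = float(rng.uniform(hi + gap, cfg.cols - hi - gap))
            rad = max(a, b)
            if all((r0 - p[0]) ** 2 + (c0 - p[1]) ** 2
                   >= (rad + max(p[2], p[3]) + gap) ** 2 for p in placed):
                placed.append((r0, c0, a, b))
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place {cfg.beans_per_scene} non-overlapping beans "
                f"in a {cfg.rows}x{cfg.cols} frame; reduce bean_radius_range "
                "or beans_per_scene"
            )
    return placed


@dataclass
class SceneFields:
    """Noise-free designed fields of one scene (before the raw transform)."""

    reflectance: np.ndarray      # rows x cols x bands, clean design
    gain: np.ndarray             # rows x cols multiplicative shape factor
    truth: BeanLabelMap


def render_scene_fields(cfg: SceneConfig, class_label: int,
                        rng: np.random.Generator) -> SceneFields:
    """Designed (noise-free) reflectance cube, gain field and truth labels."""
    if not (1 <= class_label <= cfg.n_classes):
        raise ValueError(f"class_label {class_label} outside 1..{cfg.n_classes}")
    E = make_endmembers(cfg)[class_label - 1]
    beans = _place_beans(cfg, rng)
    labels = np.zeros((cfg.rows, cfg.cols), dtype=np.int32)
    gain = np.ones((cfg.rows, cfg.cols), dtype=np.float64)
    refl = np.full((cfg.rows, cfg.cols, E.size), cfg.background_level,
                   dtype=np.float64)
    for bid, (r0, c0, a, b) in enumerate(beans, start=1):
        rlo, rhi = int(np.floor(r0 - a)), int(np.ceil(r0 + a)) + 1
        clo, chi = int(np.floor(c0 - b)), int(np.ceil(c0 + b)) + 1
        rr, cc = np.mgrid[rlo:rhi, clo:chi]
        t = np.sqrt(((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2)
        inside = t <= 1.0
        rr, cc, t = rr[inside], cc[inside], t[inside]
        labels[rr, cc] = bid
        g = cfg.shape_gain - (cfg.shape_gain - 1.0) * t   # 1 at edge -> gain at center
        gain[rr, cc] = g
        refl[rr, cc, :] = g[:, None] * E[None, :]
    truth = BeanLabelMap(mask=(labels > 0).astype(np.uint8), labels=labels)
    return SceneFields(reflectance=refl, gain=gain, truth=truth)


def _reference_frames(wl: np.ndarray, dtype: np.dtype) -> ReferenceFrames:
    # lamp-shaped white line and a flat dark current, per band
    white = 1200.0 + 2600.0 * np.exp(-(((wl - 1400.0) / 500.0) ** 2))
    dark = np.full(wl.size, 100.0)
    return ReferenceFrames(white=white.astype(dtype), dark=dark.astype(dtype))


def render_scene(cfg: SceneConfig, class_label: int, scene_seed: int,
                 ) -> tuple[HyperCube, ReferenceFrames, BeanLabelMap]:
    """Render one raw-intensity scene of a single variety.

    The raw cube is ``designed_reflectance + noise`` pushed through the
    inverse of the white/dark correction, so correcting it recovers the
    designed reflectance plus the additive reflectance-domain noise.
    """
    rng = np.random.default_rng(scene_seed)
    fields = render_scene_fields(cfg, class_label, rng)
    dtype = np.dtype(cfg.dtype)
    refl = fields.reflectance.astype(dtype)
    if cfg.noise_sd > 0:
        shape = refl.shape
        if cfg.noise_dist == "gaussian":
            if dtype == np.float32:
                noise = rng.standard_normal(shape, dtype=np.float32)
            else:
                noise = rng.standard_normal(shape)
            noise *= cfg.noise_sd
        else:
            # Student-t df=3, rescaled to match the Gaussian sd
            noise = rng.standard_t(3.0, size=shape) * (cfg.noise_sd / np.sqrt(3.0))
            noise = noise.astype(dtype)
        refl += noise
    refs = _reference_frames(cfg.wavelengths, dtype)
    raw = refl * (refs.white - refs.dark) + refs.dark
    cube = HyperCube(data=raw.astype(dtype), wavelengths=cfg.wavelengths,
                     meta={"class_label": class_label, "scene_seed": scene_seed})
    return cube, refs, fields.truth


def scene_seed_for(cfg_seed: int, class_label: int, scene_idx: int) -> int:
    """Deterministic per-scene seed derived from the study seed."""
    ss = np.random.SeedSequence([int(cfg_seed), int(class_label), int(scene_idx)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def make_study(cfg: SceneConfig,
               ) -> list[tuple[HyperCube, ReferenceFrames, BeanLabelMap, int]]:
    """Render the full study: ``scenes_per_class`` scenes for every class.

    Scene ids are assigned globally (0-based) in class-major order and stored
    in each cube's ``meta["scene_id"]``.
    """
    study = []
    scene_id = 0
    for k in range(1, cfg.n_classes + 1):
        for s in range(cfg.scenes_per_class):
            cube, refs, truth = render_scene(cfg, k, scene_seed_for(cfg.seed, k, s))
            cube.meta["scene_id"] = scene_id
            study.append((cube, refs, truth, k))
            scene_id += 1
    return study
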
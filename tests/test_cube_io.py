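"""Cube I/O, reflectance correction, masking and extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pixelspec as ps
from pixelspec.cube_io import EnviFormatError


def _toy_cube(rows=10, cols=10, bands=5, seed=0, dtype=np.float32):
    rng = np.random.default_rng(seed)
    data = rng.uniform(0, 1, (rows, cols, bands)).astype(dtype)
    wl = 874.0 + 5.0 * np.arange(bands)
    return ps.HyperCube(data=data, wavelengths=wl)


class TestEnviIO:
    @pytest.mark.parametrize("interleave", ["bsq", "bil"])
    @pytest.mark.parametrize("dtype", [np.float32, np.float64])
    def test_round_trip_bit_exact(self, tmp_path, interleave, dtype):
        cube = _toy_cube(dtype=dtype)
        ps.write_envi(cube, tmp_path / "scene.hdr", interleave=interleave)
        back = ps.read_envi(tmp_path / "scene.hdr")
        assert back.data.dtype == cube.data.dtype
        np.testing.assert_array_equal(back.data, cube.data)
        np.testing.assert_array_equal(back.wavelengths, cube.wavelengths)

    def test_double_round_trip_identity(self, tmp_path):
        cube = _toy_cube()
        ps.write_envi(cube, tmp_path / "a.hdr")
        once = ps.read_envi(tmp_path / "a.hdr")
        ps.write_envi(once, tmp_path / "b.hdr")
        twice = ps.read_envi(tmp_path / "b.hdr")
        np.testing.assert_array_equal(once.data, twice.data)

    def test_size_mismatch_is_format_error(self, tmp_path):
        cube = _toy_cube()
        data_path = ps.write_envi(cube, tmp_path / "scene.hdr")
        blob = data_path.read_bytes()
        data_path.write_bytes(blob[:-16])      # truncate the binary cube
        with pytest.raises(EnviFormatError):
            ps.read_envi(tmp_path / "scene.hdr")

    def test_missing_wavelengths_is_error(self, tmp_path):
        cube = _toy_cube()
        hdr = tmp_path / "scene.hdr"
        ps.write_envi(cube, hdr)
        lines = [ln for ln in hdr.read_text().splitlines()
                 if not ln.startswith("wavelength")]
        hdr.write_text("\n".join(lines) + "\n")
        with pytest.raises(EnviFormatError):
            ps.read_envi(hdr)


class TestReflectanceCorrect:
    def setup_method(self):
        bands = 5
        self.wl = 874.0 + 5.0 * np.arange(bands)
        self.white = np.full(bands, 4000.0)
        self.dark = np.full(bands, 100.0)
        self.refs = ps.ReferenceFrames(white=self.white, dark=self.dark)

    def _cube(self, value_per_band):
        data = np.broadcast_to(value_per_band, (4, 4, len(self.wl))).copy()
        return ps.HyperCube(data=data, wavelengths=self.wl)

    def test_raw_equal_white_gives_one(self):
        out = ps.reflectance_correct(self._cube(self.white), self.refs)
        np.testing.assert_allclose(out.data, 1.0, atol=1e-12)

    def test_raw_equal_dark_gives_zero(self):
        out = ps.reflectance_correct(self._cube(self.dark), self.refs)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_midpoint_gives_half(self):
        out = ps.reflectance_correct(
            self._cube((self.white + self.dark) / 2), self.refs)
        np.testing.assert_allclose(out.data, 0.5, atol=1e-12)

    def test_white_equals_dark_raises_with_location(self):
        white = self.white.copy()
        white[2] = self.dark[2]
        refs = ps.ReferenceFrames(white=white, dark=self.dark)
        with pytest.raises(ZeroDivisionError, match=r"\(2,\)"):
            ps.reflectance_correct(self._cube(self.white), refs)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(min_value=0.01, max_value=100.0))
    def test_affine_invariance(self, scale):
        """Scaling raw, white, dark by a common factor leaves R unchanged."""
        raw = self._cube(np.linspace(500, 3500, len(self.wl)))
        base = ps.reflectance_correct(raw, self.refs)
        scaled = ps.reflectance_correct(
            ps.HyperCube(data=raw.data * scale, wavelengths=self.wl),
            ps.ReferenceFrames(white=self.white * scale, dark=self.dark * scale))
        np.testing.assert_allclose(scaled.data, base.data, rtol=1e-10)


class TestMasking:
    def test_synthetic_scene_recovers_bean_count(self, small_cfg):
        cube, refs, truth = ps.render_scene(small_cfg, 1, 77)
        corrected = ps.reflectance_correct(cube, refs)
        lmap = ps.build_mask(corrected)
        assert lmap.n_beans == small_cfg.beans_per_scene

    def test_background_only_cube_masks_empty(self):
        wl = 874.0 + 5.0 * np.arange(6)
        rng = np.random.default_rng(3)
        data = rng.normal(0.02, 0.005, (20, 20, 6))
        cube = ps.HyperCube(data=data, wavelengths=wl)
        with pytest.warns(UserWarning, match="empty"):
            lmap = ps.build_mask(cube, band_nm=880, threshold=0.5)
        assert lmap.mask.sum() == 0

    def test_touching_beans_form_one_component(self):
        """Two overlapping bright disks merge into a single labelled instance."""
        wl = 874.0 + 5.0 * np.arange(3)
        data = np.zeros((40, 60, 3))
        rr, cc = np.mgrid[0:40, 0:60]
        for c0 in (20.0, 35.0):     # disks 15 px apart, radius 10 -> touching
            data[(rr - 20.0) ** 2 + (cc - c0) ** 2 <= 100.0] = 0.8
        cube = ps.HyperCube(data=data, wavelengths=wl)
        lmap = ps.build_mask(cube, band_nm=874, threshold=0.4)
        # oracle: scikit-image connected components on the same mask
        from skimage.measure import label as cc_label
        assert lmap.n_beans == cc_label(data[:, :, 0] > 0.4, connectivity=2).max() == 1

    @pytest.mark.parametrize("mask_kind", ["all_fg", "all_bg", "checker"])
    def test_apply_mask(self, mask_kind):
        cube = _toy_cube(rows=6, cols=6, dtype=np.float64)
        if mask_kind == "all_fg":
            mask = np.ones((6, 6), dtype=np.uint8)
        elif mask_kind == "all_bg":
            mask = np.zeros((6, 6), dtype=np.uint8)
        else:
            mask = (np.indices((6, 6)).sum(axis=0) % 2).astype(np.uint8)
        lmap = ps.BeanLabelMap(mask=mask, labels=mask.astype(np.int32))
        out = ps.apply_mask(cube, lmap)
        assert np.all(out.data[mask == 0] == 0)
        np.testing.assert_array_equal(out.data[mask == 1], cube.data[mask == 1])

    def test_apply_mask_shape_mismatch(self):
        cube = _toy_cube()
        mask = np.ones((3, 3), dtype=np.uint8)
        lmap = ps.BeanLabelMap(mask=mask, labels=mask.astype(np.int32))
        with pytest.raises(ValueError):
            ps.apply_mask(cube, lmap)


class TestExtraction:
    def _three_pixel_bean(self):
        wl = 874.0 + 5.0 * np.arange(4)
        data = np.zeros((5, 5, 4))
        labels = np.zeros((5, 5), dtype=np.int32)
        coords = [(1, 1), (1, 2), (3, 4)]
        for i, (r, c) in enumerate(coords):
            data[r, c] = 0.1 * (i + 1)
            labels[r, c] = 1
        cube = ps.HyperCube(data=data, wavelengths=wl)
        lmap = ps.BeanLabelMap(mask=(labels > 0).astype(np.uint8), labels=labels)
        return cube, lmap, coords

    def test_three_pixel_bean_gives_three_rows(self):
        cube, lmap, _ = self._three_pixel_bean()
        dsy = ps.extract_pixel_spectra(cube, lmap, class_label=2)
        assert len(dsy) == 3
        assert np.all(dsy.y == 2)
        assert np.all(np.isfinite(dsy.X))
        assert dsy.X.shape[1] == cube.n_bands

    def test_row_major_scan_order(self):
        """Row order matches an explicit row-major enumeration of fg pixels."""
        cube, lmap, coords = self._three_pixel_bean()
        dsy = ps.extract_pixel_spectra(cube, lmap, class_label=1)
        oracle = [(r, c) for r in range(5) for c in range(5)
                  if lmap.labels[r, c] > 0]
        assert [tuple(rc) for rc in dsy.pixel_rc] == oracle

    def test_average_of_identical_pixels_is_that_spectrum(self):
        cube, lmap, _ = self._three_pixel_bean()
        cube.data[lmap.mask == 1] = 0.25
        pix = ps.extract_pixel_spectra(cube, lmap, class_label=1)
        avg = ps.average_by_bean(pix)
        assert len(avg) == 1
        np.testing.assert_allclose(avg.X[0], 0.25)
        assert avg.pixel_rc is None

    def test_two_pixel_mean(self):
        wl = 874.0 + 5.0 * np.arange(3)
        pix = ps.SpectraDataset(
            X=np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]]),
            y=[3, 3], scene_id=[0, 0], bean_id=[1, 1], wavelengths=wl,
            pixel_rc=[[0, 0], [0, 1]])
        avg = ps.average_by_bean(pix)
        np.testing.assert_allclose(avg.X[0], 0.5)
        assert avg.y[0] == 3

    def test_noise_variance_shrinks_as_one_over_n(self, rng):
        """Mean of n=400 i.i.d.-noise spectra has variance ~ sigma^2/n."""
        n, bands, sigma = 400, 1200, 0.05
        wl = 874.0 + np.arange(bands)
        pix = ps.SpectraDataset(
            X=rng.normal(0, sigma, (n, bands)),
            y=np.ones(n), scene_id=np.zeros(n), bean_id=np.ones(n),
            wavelengths=wl, pixel_rc=np.zeros((n, 2)))
        avg = ps.average_by_bean(pix)
        observed = avg.X[0].var()
        assert observed == pytest.approx(sigma ** 2 / n, rel=0.20)

    def test_average_commutes_with_band_subsetting(self, small_cfg):
        cube, refs, _ = ps.render_scene(small_cfg, 2, 5)
        corrected = ps.reflectance_correct(cube, refs)
        lmap = ps.build_mask(corrected)
        pix = ps.extract_pixel_spectra(ps.apply_mask(corrected, lmap), lmap, 2)
        idx = np.array([3, 10, 50])
        ws = ps.WavelengthSet(selected=pix.wavelengths[idx], indices=idx,
                              scores=np.ones(3))
        a = ps.subset_bands(ps.average_by_bean(pix), ws)
        b = ps.average_by_bean(ps.subset_bands(pix, ws))
        np.testing.assert_allclose(a.X, b.X, atol=1e-6)

    def test_csv_round_trip(self, tmp_path):
        cube, lmap, _ = self._three_pixel_bean()
        dsy = ps.extract_pixel_spectra(cube, lmap, class_label=1)
        dsy.to_csv(tmp_path / "spectra.csv")
        back = ps.SpectraDataset.from_csv(tmp_path / "spectra.csv")
        np.testing.assert_allclose(back.X, dsy.X)
        np.testing.assert_array_equal(back.y, dsy.y)
        np.testing.assert_array_equal(back.pixel_rc, dsy.pixel_rc)
        np.testing.assert_allclose(back.wavelengths, dsy.wavelengths)
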
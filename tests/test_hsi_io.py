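import numpy as np
import pytest

from spectransfer.errors import (
    CalibrationError,
    DimensionError,
    FormatError,
    ParameterError,
    ROIError,
)
from spectransfer.hsi_io import (
    CalibrationFrames,
    HSICube,
    ROIMask,
    ReflectanceCube,
    average_replicates,
    build_roi_mask,
    calibrate_reflectance,
    read_cube,
    read_spectra_table,
    roi_mean_spectrum,
    write_cube,
    write_spectra_table,
)
from spectransfer.core import SpectraSet


def _cube(rng, rows=4, cols=5, bands=6):
    data = rng.uniform(100, 900, size=(rows, cols, bands))
    wl = np.linspace(885.0, 1735.0, bands)
    return HSICube(data=data, wavelengths=wl)


class TestCubeIO:
    @pytest.mark.parametrize("interleave", ["bip", "bil", "bsq"])
    def test_envi_round_trip_bit_identical(self, rng, tmp_path, interleave):
        cube = _cube(rng)
        path = str(tmp_path / "cube.hdr")
        write_cube(cube, path, interleave=interleave)
        back = read_cube(path)
        np.testing.assert_array_equal(back.data, cube.data)
        np.testing.assert_array_equal(back.wavelengths, cube.wavelengths)

    def test_conformant_256_band_file(self, rng, tmp_path):
        wl = np.linspace(885.0, 1735.0, 256)
        cube = HSICube(data=rng.uniform(0, 1000, size=(3, 3, 256)), wavelengths=wl)
        write_cube(cube, str(tmp_path / "c.hdr"))
        back = read_cube(str(tmp_path / "c.hdr"))
        assert back.wavelengths.size == 256
        assert back.wavelengths[0] == pytest.approx(885.0)
        assert back.wavelengths[-1] == pytest.approx(1735.0)

    def test_flat_table_minimal(self, tmp_path):
        path = tmp_path / "flat.csv"
        path.write_text("row,col,1,2,3\n0,0,10.0,20.0,30.0\n")
        cube = read_cube(str(path), dialect="flat_table")
        assert cube.shape == (1, 1, 3)
        np.testing.assert_array_equal(cube.wavelengths, [1.0, 2.0, 3.0])
        np.testing.assert_array_equal(cube.data[0, 0], [10.0, 20.0, 30.0])

    def test_flat_table_round_trip(self, rng, tmp_path):
        cube = _cube(rng, rows=2, cols=3, bands=4)
        path = str(tmp_path / "flat.csv")
        write_cube(cube, path, dialect="flat_table")
        back = read_cube(path, dialect="flat_table")
        np.testing.assert_array_equal(back.data, cube.data)

    def test_missing_header_field_names_it(self, rng, tmp_path):
        cube = _cube(rng)
        write_cube(cube, str(tmp_path / "c.hdr"))
        hdr = (tmp_path / "c.hdr").read_text()
        (tmp_path / "c.hdr").write_text(
            "\n".join(l for l in hdr.splitlines() if not l.startswith("bands"))
        )
        with pytest.raises(FormatError, match="bands"):
            read_cube(str(tmp_path / "c.hdr"))

    def test_wavelength_count_mismatch(self, rng, tmp_path):
        cube = _cube(rng)
        write_cube(cube, str(tmp_path / "c.hdr"))
        hdr = (tmp_path / "c.hdr").read_text().replace("bands = 6", "bands = 5")
        (tmp_path / "c.hdr").write_text(hdr)
        with pytest.raises(DimensionError):
            read_cube(str(tmp_path / "c.hdr"))

    def test_cube_invariants(self, rng):
        with pytest.raises(DimensionError):
            HSICube(data=rng.uniform(size=(2, 2, 3)), wavelengths=np.arange(4.0))
        with pytest.raises(ParameterError):
            HSICube(data=rng.uniform(size=(2, 2, 3)), wavelengths=np.array([3.0, 2.0, 1.0]))


class TestCalibration:
    def _frames(self, shape, white=90.0, dark=10.0):
        return CalibrationFrames(
            white=np.full(shape, white), dark=np.full(shape, dark)
        )

    @pytest.mark.parametrize("raw,expected", [(90.0, 100.0), (10.0, 0.0), (50.0, 50.0)])
    def test_hand_arithmetic(self, raw, expected):
        cube = HSICube(data=np.full((2, 2, 3), raw), wavelengths=np.arange(3.0))
        refl = calibrate_reflectance(cube, self._frames((2, 2)))
        np.testing.assert_allclose(refl.data, expected)
        assert not refl.invalid_mask.any()

    def test_invalid_pixels_flagged_nan(self):
        white = np.array([[90.0, 5.0]])
        dark = np.full((1, 2), 10.0)
        cube = HSICube(data=np.full((1, 2, 2), 50.0), wavelengths=np.array([1.0, 2.0]))
        refl = calibrate_reflectance(cube, CalibrationFrames(white=white, dark=dark))
        assert refl.invalid_mask[0, 1].all() and not refl.invalid_mask[0, 0].any()
        assert np.isnan(refl.data[0, 1]).all()

    def test_all_invalid_raises(self):
        cube = HSICube(data=np.ones((2, 2, 2)), wavelengths=np.array([1.0, 2.0]))
        with pytest.raises(CalibrationError):
            calibrate_reflectance(cube, self._frames((2, 2), white=5.0, dark=10.0))

    def test_affine_invariance(self, rng):
        cube = _cube(rng)
        white = rng.uniform(800, 1000, size=cube.shape)
        dark = rng.uniform(0, 100, size=cube.shape)
        a, b = 3.7, 42.0
        r1 = calibrate_reflectance(cube, CalibrationFrames(white=white, dark=dark))
        shifted = HSICube(data=a * cube.data + b, wavelengths=cube.wavelengths)
        r2 = calibrate_reflectance(
            shifted, CalibrationFrames(white=a * white + b, dark=a * dark + b)
        )
        np.testing.assert_allclose(r1.data, r2.data, rtol=1e-12)

    def test_3d_frames_take_precedence_shape(self, rng):
        cube = _cube(rng)
        frames = CalibrationFrames(
            white=rng.uniform(900, 1000, size=cube.shape),
            dark=rng.uniform(0, 50, size=cube.shape),
        )
        refl = calibrate_reflectance(cube, frames)
        assert refl.data.shape == cube.shape


def brute_force_erode(mask, margin):
    """Oracle: keep a pixel iff every pixel within Chebyshev distance `margin` is true."""
    rows, cols = mask.shape
    out = np.zeros_like(mask)
    for i in range(rows):
        for j in range(cols):
            lo_i, hi_i = i - margin, i + margin
            lo_j, hi_j = j - margin, j + margin
            if lo_i < 0 or lo_j < 0 or hi_i >= rows or hi_j >= cols:
                continue
            out[i, j] = mask[lo_i : hi_i + 1, lo_j : hi_j + 1].all()
    return out


class TestROI:
    def test_zero_margin_identity(self, rng):
        fg = rng.uniform(size=(8, 8)) > 0.3
        fg[4, 4] = True
        roi = build_roi_mask(fg, margin_mm=0.0, px_per_mm=3.0)
        np.testing.assert_array_equal(roi.mask, fg)

    def test_square_block_erosion(self):
        fg = np.ones((10, 10), dtype=bool)
        roi = build_roi_mask(fg, margin_mm=2.0, px_per_mm=1.0)
        expected = np.zeros((10, 10), dtype=bool)
        expected[2:8, 2:8] = True
        np.testing.assert_array_equal(roi.mask, expected)
        assert roi.mask.sum() == 36

    def test_degenerate_erosion_raises(self):
        with pytest.raises(ROIError, match="smaller margin"):
            build_roi_mask(np.ones((3, 3), dtype=bool), margin_mm=2.0, px_per_mm=1.0)

    @pytest.mark.parametrize("margin", [1, 2, 3])
    def test_matches_brute_force_oracle(self, rng, margin):
        fg = rng.uniform(size=(15, 12)) > 0.2
        try:
            roi = build_roi_mask(fg, margin_mm=float(margin), px_per_mm=1.0)
        except ROIError:
            assert not brute_force_erode(fg, margin).any()
            return
        np.testing.assert_array_equal(roi.mask, brute_force_erode(fg, margin))

    def test_erosion_monotone_in_margin(self, rng):
        fg = rng.uniform(size=(20, 20)) > 0.1
        sizes = []
        for margin in (0.0, 1.0, 2.0, 3.0):
            try:
                sizes.append(build_roi_mask(fg, margin, px_per_mm=1.0).mask.sum())
            except ROIError:
                sizes.append(0)
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestROIMean:
    def _refl(self, data):
        data = np.asarray(data, dtype=float)
        return ReflectanceCube(
            data=data,
            wavelengths=np.arange(data.shape[2], dtype=float),
            invalid_mask=np.isnan(data),
        )

    def test_uniform_cube(self):
        refl = self._refl(np.full((4, 4, 3), 17.5))
        roi = ROIMask(mask=np.ones((4, 4), dtype=bool))
        np.testing.assert_allclose(roi_mean_spectrum(refl, roi), 17.5)

    def test_matches_pixel_loop_oracle(self, rng):
        data = rng.uniform(0, 100, size=(8, 8, 5))
        mask = rng.uniform(size=(8, 8)) > 0.4
        mask[0, 0] = True
        refl = self._refl(data)
        result = roi_mean_spectrum(refl, ROIMask(mask=mask))
        for band in range(5):
            vals = [data[i, j, band] for i in range(8) for j in range(8) if mask[i, j]]
            assert result[band] == pytest.approx(np.mean(vals), rel=1e-12)

    def test_single_pixel_roi(self, rng):
        data = rng.uniform(0, 100, size=(3, 3, 4))
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 2] = True
        np.testing.assert_allclose(
            roi_mean_spectrum(self._refl(data), ROIMask(mask=mask)), data[1, 2]
        )

    def test_invalid_pixels_excluded(self):
        data = np.full((2, 2, 2), 10.0)
        data[0, 0] = np.nan
        refl = self._refl(data)
        roi = ROIMask(mask=np.ones((2, 2), dtype=bool))
        np.testing.assert_allclose(roi_mean_spectrum(refl, roi), 10.0)

    def test_entirely_invalid_roi_raises(self):
        data = np.full((2, 2, 2), np.nan)
        with pytest.raises(ROIError):
            roi_mean_spectrum(self._refl(data), ROIMask(mask=np.ones((2, 2), dtype=bool)))


class TestReplicates:
    def test_identical_vectors(self):
        v = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(average_replicates([v, v, v]), v)

    def test_hand_arithmetic(self):
        out = average_replicates([np.array([0.0, 0.0]), np.array([2.0, 4.0]), np.array([4.0, 2.0])])
        np.testing.assert_array_equal(out, [2.0, 2.0])

    def test_single_vector(self):
        v = np.array([5.0, 6.0])
        np.testing.assert_array_equal(average_replicates([v]), v)

    def test_length_mismatch(self):
        with pytest.raises(DimensionError):
            average_replicates([np.zeros(3), np.zeros(4)])


class TestSpectraTable:
    def test_round_trip(self, tmp_path):
        s = SpectraSet(
            X=np.array([[1.5, 2.5, 3.5], [4.0, 5.0, 6.0]]),
            wavelengths=np.array([900.0, 1000.0, 1100.0]),
            sample_ids=["a", "b"],
        )
        path = str(tmp_path / "s.csv")
        write_spectra_table(s, path)
        back = read_spectra_table(path)
        np.testing.assert_array_equal(back.X, s.X)
        np.testing.assert_array_equal(back.wavelengths, s.wavelengths)
        assert back.sample_ids == s.sample_ids

    def test_unsorted_columns_sorted(self, tmp_path):
        path = tmp_path / "u.csv"
        path.write_text("sample_id,1100,900,1000\na,3.0,1.0,2.0\n")
        back = read_spectra_table(str(path))
        np.testing.assert_array_equal(back.wavelengths, [900.0, 1000.0, 1100.0])
        np.testing.assert_array_equal(back.X[0], [1.0, 2.0, 3.0])

    def test_duplicate_sample_id(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("sample_id,900,1000\na,1,2\na,3,4\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_spectra_table(str(path))

    def test_non_numeric_wavelength_header(self, tmp_path):
        path = tmp_path / "n.csv"
        path.write_text("sample_id,900,notawavelength\na,1,2\n")
        with pytest.raises(FormatError):
            read_spectra_table(str(path))
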
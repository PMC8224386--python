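"""Tests for ENVI I/O, reflectance calibration, and ROI extraction."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hsifresh.hypercube_io import (
    Hypercube,
    ReferencePair,
    RoiSpectrum,
    assemble_dataset,
    calibrate_reflectance,
    extract_roi,
    read_envi,
    read_mask_png,
    write_envi,
    write_mask_png,
)
from hsifresh.synthetic_data import default_wavelength_grid


def random_cube(rng, rows=5, cols=7, bands=11, units="raw"):
    values = rng.uniform(0.0, 100.0, (rows, cols, bands)).astype(np.float32)
    wl = np.linspace(400.0, 1000.0, bands)
    return Hypercube(values.astype(float), wl, units_flag=units)


class TestHypercubeType:
    def test_wavelength_length_mismatch(self, rng):
        with pytest.raises(ValueError, match="band count"):
            Hypercube(rng.normal(size=(2, 2, 3)), np.array([1.0, 2.0]))

    def test_decreasing_wavelengths_rejected(self, rng):
        with pytest.raises(ValueError, match="increasing"):
            Hypercube(rng.normal(size=(2, 2, 2)), np.array([2.0, 1.0]))


class TestEnviRoundTrip:
    @pytest.mark.parametrize("interleave", ["bsq", "bil", "bip"])
    def test_round_trip_bit_exact(self, tmp_path, rng, interleave):
        cube = random_cube(rng)
        path = write_envi(cube, tmp_path / f"cube_{interleave}.hdr", interleave=interleave)
        back = read_envi(path)
        assert np.array_equal(back.values, cube.values.astype(np.float32))
        assert np.allclose(back.wavelengths, cube.wavelengths)

    def test_interleave_invariance(self, tmp_path, rng):
        cube = random_cube(rng)
        a = read_envi(write_envi(cube, tmp_path / "a.hdr", interleave="bil"))
        b = read_envi(write_envi(cube, tmp_path / "b.hdr", interleave="bsq"))
        assert np.array_equal(a.values, b.values)

    def test_472_band_header(self, tmp_path, rng):
        wl = default_wavelength_grid()
        cube = Hypercube(rng.uniform(size=(2, 3, 472)), wl)
        back = read_envi(write_envi(cube, tmp_path / "c.hdr"))
        assert back.wavelengths.size == 472

    def test_missing_wavelength_field(self, tmp_path, rng):
        cube = random_cube(rng)
        path = write_envi(cube, tmp_path / "d.hdr")
        text = path.read_text()
        path.write_text("\n".join(l for l in text.splitlines() if not l.startswith("wavelength")))
        with pytest.raises(ValueError, match="wavelength"):
            read_envi(path)

    def test_size_mismatch_names_both(self, tmp_path, rng):
        cube = random_cube(rng)
        path = write_envi(cube, tmp_path / "e.hdr")
        raw = path.with_suffix(".raw")
        raw.write_bytes(raw.read_bytes()[:-8])
        with pytest.raises(ValueError, match="383.*385|header declares"):
            read_envi(path)


class TestCalibration:
    @pytest.fixture
    def refs(self, rng):
        shape = (4, 5, 6)
        wl = np.linspace(400, 1000, 6)
        white = Hypercube(3000.0 + rng.uniform(0, 50, shape), wl)
        black = Hypercube(50.0 + rng.uniform(0, 5, shape), wl)
        return ReferencePair(white=white, black=black)

    def test_white_gives_ones(self, refs):
        out = calibrate_reflectance(refs.white, refs)
        assert np.allclose(out.values, 1.0)
        assert out.units_flag == "reflectance"

    def test_black_gives_zeros(self, refs):
        out = calibrate_reflectance(refs.black, refs)
        assert np.allclose(out.values, 0.0)

    def test_midpoint_gives_half(self, refs):
        mid = Hypercube(
            (refs.white.values + refs.black.values) / 2.0, refs.white.wavelengths
        )
        assert np.allclose(calibrate_reflectance(mid, refs).values, 0.5)

    @given(alpha=st.floats(0.0, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_affine_combination_linearity(self, alpha):
        gen = np.random.default_rng(1)
        shape = (3, 4, 5)
        wl = np.linspace(400, 1000, 5)
        refs = ReferencePair(
            white=Hypercube(2000.0 + gen.uniform(0, 10, shape), wl),
            black=Hypercube(10.0 + gen.uniform(0, 2, shape), wl),
        )
        blend = Hypercube(
            alpha * refs.white.values + (1 - alpha) * refs.black.values, wl
        )
        assert np.allclose(calibrate_reflectance(blend, refs).values, alpha, atol=1e-12)

    def test_white_not_above_black_reports_count(self, refs):
        bad_white = Hypercube(refs.black.values.copy(), refs.white.wavelengths)
        bad = ReferencePair.__new__(ReferencePair)
        bad.white = bad_white
        bad.black = refs.black
        with pytest.raises(ValueError, match=r"\d+ elements"):
            calibrate_reflectance(refs.black, bad)

    def test_single_row_reference_broadcast(self, rng):
        wl = np.linspace(400, 1000, 6)
        white = Hypercube(3000.0 * np.ones((1, 5, 6)), wl)
        black = Hypercube(np.zeros((1, 5, 6)), wl)
        raw = Hypercube(1500.0 * np.ones((4, 5, 6)), wl)
        out = calibrate_reflectance(raw, ReferencePair(white=white, black=black))
        assert np.allclose(out.values, 0.5)

    def test_already_calibrated_rejected(self, refs):
        cube = Hypercube(np.full((4, 5, 6), 0.5), refs.white.wavelengths, "reflectance")
        with pytest.raises(ValueError, match="already"):
            calibrate_reflectance(cube, refs)


class TestExtractRoi:
    def test_constant_field_returns_that_spectrum(self):
        wl = np.linspace(400, 1000, 4)
        spectrum = np.array([0.1, 0.2, 0.3, 0.4])
        cube = Hypercube(np.tile(spectrum, (3, 3, 1)), wl, "reflectance")
        mask = np.ones((3, 3), dtype=bool)
        roi = extract_roi(cube, mask, "s1")
        assert np.allclose(roi.mean_reflectance, spectrum)
        assert roi.pixel_count == 9

    def test_two_pixel_midpoint(self):
        wl = np.linspace(400, 1000, 3)
        values = np.zeros((1, 2, 3))
        values[0, 1] = 1.0
        cube = Hypercube(values, wl, "reflectance")
        roi = extract_roi(cube, np.ones((1, 2), dtype=bool))
        assert np.allclose(roi.mean_reflectance, 0.5)

    def test_against_per_band_loop_oracle(self, rng):
        cube = Hypercube(
            rng.uniform(size=(6, 7, 5)), np.linspace(400, 1000, 5), "reflectance"
        )
        mask = rng.uniform(size=(6, 7)) > 0.5
        mask[0, 0] = True
        roi = extract_roi(cube, mask)
        for band in range(5):
            total, count = 0.0, 0
            for r in range(6):
                for c in range(7):
                    if mask[r, c]:
                        total += cube.values[r, c, band]
                        count += 1
            assert roi.mean_reflectance[band] == pytest.approx(total / count, abs=1e-12)

    def test_mean_within_pixel_bounds(self, rng):
        cube = Hypercube(
            rng.uniform(size=(5, 5, 4)), np.linspace(400, 1000, 4), "reflectance"
        )
        mask = np.ones((5, 5), dtype=bool)
        roi = extract_roi(cube, mask)
        pixels = cube.values[mask]
        assert np.all(roi.mean_reflectance >= pixels.min(axis=0) - 1e-12)
        assert np.all(roi.mean_reflectance <= pixels.max(axis=0) + 1e-12)

    def test_empty_mask_rejected(self, rng):
        cube = Hypercube(
            rng.uniform(size=(3, 3, 2)), np.array([400.0, 500.0]), "reflectance"
        )
        with pytest.raises(ValueError, match="empty"):
            extract_roi(cube, np.zeros((3, 3), dtype=bool))


def _chemistry(ids, values, indicator="tvbn"):
    return pd.DataFrame({"sample_id": ids, "indicator": indicator, "value": values})


class TestAssembleDataset:
    def _spectra(self, rng, n, k=4):
        return [
            RoiSpectrum(f"s{i:03d}", rng.uniform(size=k), 10) for i in range(n)
        ]

    def test_397_rows(self, rng):
        spectra = self._spectra(rng, 397)
        chem = _chemistry([s.sample_id for s in spectra], rng.uniform(8, 35, 397))
        ds = assemble_dataset(spectra, chem, "tvbn", np.linspace(400, 1000, 4))
        assert ds.X.shape == (397, 4)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="no spectra"):
            assemble_dataset([], _chemistry([], []), "tvbn", np.array([400.0]))

    def test_order_canonicalized(self, rng):
        spectra = self._spectra(rng, 6)
        chem = _chemistry([s.sample_id for s in spectra], np.arange(6.0))
        wl = np.linspace(400, 1000, 4)
        forward = assemble_dataset(spectra, chem, "tvbn", wl)
        shuffled = assemble_dataset(spectra[::-1], chem, "tvbn", wl)
        assert forward.sample_ids == shuffled.sample_ids
        assert np.array_equal(forward.X, shuffled.X)
        assert np.array_equal(forward.Y, shuffled.Y)

    def test_missing_chemistry_names_sample(self, rng):
        spectra = self._spectra(rng, 3)
        chem = _chemistry(["s000", "s001"], [1.0, 2.0])
        with pytest.raises(ValueError, match="s002"):
            assemble_dataset(spectra, chem, "tvbn", np.linspace(400, 1000, 4))

    def test_duplicate_sample_id_rejected(self, rng):
        spectra = self._spectra(rng, 2)
        spectra[1].sample_id = spectra[0].sample_id
        chem = _chemistry(["s000"], [1.0])
        with pytest.raises(ValueError, match="duplicat"):
            assemble_dataset(spectra, chem, "tvbn", np.linspace(400, 1000, 4))


class TestMaskIo:
    def test_png_round_trip(self, tmp_path, rng):
        mask = rng.uniform(size=(9, 11)) > 0.4
        path = write_mask_png(mask, tmp_path / "mask.png")
        assert np.array_equal(read_mask_png(path), mask)
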
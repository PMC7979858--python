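"""Flattening, denoising, autocorrelation and unit-cell measurement."""

import numpy as np
import pytest

from phasekin.afm import (
    PHASE_REFERENCES_NM,
    Topograph,
    UnitCellMeasurement,
    autocorrelate,
    caxis_timeseries,
    denoise,
    flatten_lines,
    load_topograph,
    measure_regions,
    measure_unit_cell,
)
from phasekin.synthetic import RegionSpec, SyntheticLatticeParams, generate_mixed_topograph, generate_topograph


def square_lattice(period_px=10, size=96, nm_per_px=1.0, **kw):
    lat = SyntheticLatticeParams(
        a_length=period_px * nm_per_px,
        c_length=period_px * nm_per_px,
        cell_angle=90.0,
        nm_per_px=nm_per_px,
        image_size=size,
        **kw,
    )
    return generate_topograph(lat)


class TestFlattenLines:
    def test_pure_tilt_plane_flattens_to_zero(self):
        h = 0.03 * np.arange(64)[None, :] + 0.05 * np.arange(64)[:, None]
        flat = flatten_lines(Topograph(h, 1.0))
        assert np.allclose(flat.heights, 0.0, atol=1e-9)

    def test_matches_brute_force_row_regression(self, rng):
        h = rng.normal(size=(20, 50))
        flat = flatten_lines(Topograph(h, 1.0))
        x = np.arange(50.0)
        for i in range(20):
            coef = np.polyfit(x, h[i], 1)
            assert np.allclose(flat.heights[i], h[i] - np.polyval(coef, x), atol=1e-9)

    def test_idempotent(self, rng):
        topo = Topograph(rng.normal(size=(16, 40)), 1.0)
        once = flatten_lines(topo)
        twice = flatten_lines(once)
        assert np.allclose(once.heights, twice.heights, atol=1e-9)


class TestDenoise:
    def test_generous_lowpass_keeps_periodic_image(self):
        topo, _ = square_lattice()
        out = denoise(topo, "fft_lowpass", cutoff_per_nm=0.5)  # Nyquist at 1 nm/px
        assert np.allclose(out.heights, topo.heights, atol=1e-6)

    def test_lowpass_reduces_rms_error_to_truth(self):
        clean, _ = square_lattice()
        noisy, _ = square_lattice(roughness_sd=0.3, seed=7)
        out = denoise(noisy, "fft_lowpass")
        rms_before = np.sqrt(np.mean((noisy.heights - clean.heights) ** 2))
        rms_after = np.sqrt(np.mean((out.heights - clean.heights) ** 2))
        assert rms_after < rms_before

    def test_correlation_average_of_identical_patches(self):
        """Averaging identical registered patches reproduces each patch."""
        tile = np.add.outer(np.sin(np.arange(12)), np.cos(np.arange(12)))
        topo = Topograph(np.tile(tile, (4, 4)), 1.0)
        out = denoise(topo, "correlation_average", patch_px=12)
        assert np.allclose(out.heights[:12, :12], tile, atol=1e-9)

    def test_bad_cutoff_rejected(self):
        topo, _ = square_lattice()
        with pytest.raises(ValueError):
            denoise(topo, "fft_lowpass", cutoff_per_nm=2.0)

    def test_unknown_mode_rejected(self):
        topo, _ = square_lattice()
        with pytest.raises(ValueError):
            denoise(topo, "nope")


class TestAutocorrelate:
    def test_matches_brute_force_shift_multiply_sum(self, rng):
        """16x16 oracle: ACF equals the direct zero-padded
        shift-multiply-sum at every lag, within 1e-9."""
        h = rng.normal(size=(16, 16))
        acf = autocorrelate(Topograph(h, 1.0))
        x = h - h.mean()
        norm = np.sum(x * x)
        for dy, dx in [(0, 0), (3, 2), (-5, 4), (7, -7), (15, 15)]:
            total = 0.0
            for i in range(16):
                for j in range(16):
                    ii, jj = i + dy, j + dx
                    if 0 <= ii < 16 and 0 <= jj < 16:
                        total += x[i, j] * x[ii, jj]
            assert acf.values[15 + dy, 15 + dx] == pytest.approx(total / norm, abs=1e-9)

    def test_origin_is_one_and_symmetric(self, rng):
        acf = autocorrelate(Topograph(rng.normal(size=(20, 24)), 1.0))
        assert acf.values[acf.center] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(acf.values, acf.values[::-1, ::-1], atol=1e-9)

    def test_white_noise_has_no_structure(self, rng):
        n = 64
        acf = autocorrelate(Topograph(rng.normal(size=(n, n)), 1.0))
        center = acf.values[n - 1 - 10 : n + 10, n - 1 - 10 : n + 10].copy()
        center[10, 10] = 0.0
        assert np.max(np.abs(center)) < 5.0 / n

    def test_cosine_grating_peak_at_period(self):
        t = np.cos(2 * np.pi * np.arange(100) / 10.0)
        h = np.tile(t, (100, 1))
        acf = autocorrelate(Topograph(h, 1.0))
        row = acf.values[acf.center[0], acf.center[1] + 5 : acf.center[1] + 16]
        assert np.argmax(row) + 5 == 10

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            autocorrelate(Topograph(np.full((16, 16), 3.0), 1.0))


class TestMeasureUnitCell:
    def test_square_lattice_recovered(self):
        topo, _ = square_lattice()
        m = measure_unit_cell(autocorrelate(topo), 5.0, 15.0)
        assert m.ok
        assert m.a_len_nm == pytest.approx(10.0, abs=0.2)
        assert m.c_len_nm == pytest.approx(10.0, abs=0.2)
        assert m.angle_deg == pytest.approx(90.0, abs=2.0)

    def test_oblique_lattice_with_noise_within_half_pixel(self):
        """a=4.83 nm, c=9.3 nm at 0.39 nm/px with 10%-of-corrugation noise:
        both lengths recovered within half a pixel."""
        lat = SyntheticLatticeParams(roughness_sd=0.1, seed=12)
        topo, truth = generate_topograph(lat)
        m = measure_unit_cell(autocorrelate(flatten_lines(topo)))
        tol = 0.5 * lat.nm_per_px
        assert abs(m.a_len_nm - truth["a_nm"]) < tol
        assert abs(m.c_len_nm - truth["c_nm"]) < tol

    @pytest.mark.parametrize("c_nm", [9.3, 7.9, 12.4])
    def test_printed_cell_constants_recovered(self, c_nm):
        """Topographs built with the printed c-axis constants measure back
        within +-0.3 nm through the full flatten->ACF->peak pipeline."""
        lat = SyntheticLatticeParams(
            c_length=c_nm, roughness_sd=0.1, tilt_plane=(0.002, 0.004), seed=3
        )
        topo, _ = generate_topograph(lat)
        m = measure_unit_cell(autocorrelate(flatten_lines(topo)))
        assert m.ok
        assert m.c_len_nm == pytest.approx(c_nm, abs=0.3)

    def test_noise_free_spacing_sweep_within_half_pixel(self):
        """Parameter-recovery sweep: spacings from 5 to 40 px recovered
        within half a pixel on noise-free lattices."""
        for period in (5, 9, 16, 25, 40):
            size = max(96, 5 * period)
            topo, _ = square_lattice(period_px=period, size=size)
            m = measure_unit_cell(
                autocorrelate(topo), period * 0.5, period * 1.6
            )
            assert m.ok
            assert abs(m.c_len_nm - period) <= 0.5
            assert abs(m.a_len_nm - period) <= 0.5

    def test_invariant_to_height_scaling(self):
        topo, _ = square_lattice(roughness_sd=0.05, seed=2)
        m1 = measure_unit_cell(autocorrelate(topo), 5.0, 15.0)
        scaled = Topograph(topo.heights * 7.5, topo.nm_per_px)
        m2 = measure_unit_cell(autocorrelate(scaled), 5.0, 15.0)
        assert m1.a_len_nm == pytest.approx(m2.a_len_nm, abs=1e-9)
        assert m1.c_len_nm == pytest.approx(m2.c_len_nm, abs=1e-9)

    def test_transposition_swaps_axes_consistently(self):
        lat = SyntheticLatticeParams(c_length=9.3, roughness_sd=0.0)
        topo, _ = generate_topograph(lat)
        m1 = measure_unit_cell(autocorrelate(topo))
        m2 = measure_unit_cell(autocorrelate(Topograph(topo.heights.T, topo.nm_per_px)))
        assert m2.a_len_nm == pytest.approx(m1.a_len_nm, abs=0.05)
        assert m2.c_len_nm == pytest.approx(m1.c_len_nm, abs=0.05)

    def test_denoise_does_not_shift_measured_cell(self):
        lat = SyntheticLatticeParams(roughness_sd=0.1, seed=5)
        topo, _ = generate_topograph(lat)
        m1 = measure_unit_cell(autocorrelate(topo))
        m2 = measure_unit_cell(autocorrelate(denoise(topo, "fft_lowpass")))
        assert m2.c_len_nm == pytest.approx(m1.c_len_nm, abs=0.15)

    def test_featureless_map_returns_failure_not_exception(self, rng):
        acf = autocorrelate(Topograph(rng.normal(size=(128, 128)), 1.0))
        m = measure_unit_cell(acf, 3.0, 20.0)
        assert not m.ok and np.isnan(m.c_len_nm)


class TestMeasureRegions:
    def test_homogeneous_image_split_agrees(self):
        lat = SyntheticLatticeParams(roughness_sd=0.05, seed=8)
        topo, _ = generate_topograph(lat)
        ms = measure_regions(topo, [(0, 128, 0, 256), (128, 256, 0, 256)])
        assert all(m.ok for m in ms)
        assert ms[0].c_len_nm == pytest.approx(ms[1].c_len_nm, abs=0.2)

    def test_three_region_mixed_image_recovers_each_truth(self):
        """The mixed-phase composition (c = 7.9 / 12.5 / 9.3 nm bands) is
        recovered region by region within +-0.3 nm."""
        mk = lambda c: SyntheticLatticeParams(c_length=c, image_size=384)
        regs = [
            RegionSpec(0, 128, 0, 384, mk(7.9)),
            RegionSpec(128, 256, 0, 384, mk(12.5)),
            RegionSpec(256, 384, 0, 384, mk(9.3)),
        ]
        topo, truths = generate_mixed_topograph(regs, noise_sd=0.05, seed=1)
        ms = measure_regions(topo, [r.bounds for r in regs])
        for m, truth in zip(ms, truths):
            assert m.ok
            assert m.c_len_nm == pytest.approx(truth["c_nm"], abs=0.3)

    def test_too_small_region_fails_alone(self):
        lat = SyntheticLatticeParams(roughness_sd=0.0)
        topo, _ = generate_topograph(lat)
        ms = measure_regions(topo, [(0, 6, 0, 6), (0, 256, 0, 256)])
        assert not ms[0].ok and ms[1].ok


class TestCaxisTimeseries:
    def _m(self, c, idx):
        return UnitCellMeasurement(4.8, c, 90.0, index=idx)

    def test_reference_labels_follow_nearest_phase(self):
        series = caxis_timeseries(
            [self._m(9.3, 0), self._m(9.3, 1), self._m(7.9, 2), self._m(7.9, 3)]
        )
        assert list(series.table["phase"]) == ["AUC", "AUC", "TUC1", "TUC1"]
        assert series.phase_changes() == 1

    def test_tuc2_reference(self):
        series = caxis_timeseries([self._m(12.4, 0)])
        assert series.table["phase"].item() == "TUC2"

    def test_intermediate_and_gap_labels(self):
        ms = [self._m(10.6, 0), UnitCellMeasurement.failure(index=1)]
        series = caxis_timeseries(ms)
        assert list(series.table["phase"]) == ["intermediate", "gap"]

    def test_no_references_means_unassigned(self):
        series = caxis_timeseries([self._m(9.3, 0)], references_nm=None)
        assert series.table["phase"].item() == "unassigned"

    def test_empty_measurements_rejected(self):
        with pytest.raises(ValueError):
            caxis_timeseries([])


class TestTopographIO:
    def test_text_matrix_roundtrip(self, tmp_path):
        h = np.round(np.random.default_rng(0).normal(size=(16, 16)), 5)
        np.savetxt(tmp_path / "t.txt", h, fmt="%.5f")
        topo = load_topograph(tmp_path / "t.txt", nm_per_px=0.39)
        assert np.allclose(topo.heights, h, atol=1e-9)

    def test_tiff_roundtrip(self, tmp_path):
        import tifffile

        h = np.random.default_rng(1).normal(size=(16, 16)).astype(np.float32)
        tifffile.imwrite(tmp_path / "t.tif", h)
        topo = load_topograph(tmp_path / "t.tif", nm_per_px=0.39)
        assert np.allclose(topo.heights, h, atol=1e-7)
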
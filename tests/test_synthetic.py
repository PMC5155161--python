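import numpy as np
import pandas as pd
import pytest

import spaint
from spaint.calibration import extract_profile, fit_peak
from spaint.instrument import predict_first_order_displacement
from spaint.synthetic import (
    GROUND_TRUTH_COLUMNS,
    EmitterSpecies,
    _add_integrated_gaussian,
    read_stack,
    write_stack,
)


class TestEmitterSpecies:
    def test_passband_enforced(self):
        with pytest.raises(ValueError, match="passband"):
            EmitterSpecies(peak_wavelength_nm=450.0)

    def test_negative_photons_rejected(self):
        with pytest.raises(ValueError):
            EmitterSpecies(peak_wavelength_nm=600.0, mean_photons_per_frame=-1.0)


class TestCalibrationStack:
    def test_empty_stack_is_pure_noise(self):
        stack = spaint.simulate_calibration_stack(0, n_frames=2, seed=1)
        assert stack.ground_truth.empty
        # only baseline + background: no pixel far above the noise band
        assert stack.frames.mean() < 250

    def test_seeded_runs_bit_identical(self):
        a = spaint.simulate_calibration_stack(5, n_frames=3, seed=9)
        b = spaint.simulate_calibration_stack(5, n_frames=3, seed=9)
        np.testing.assert_array_equal(a.frames, b.frames)
        pd.testing.assert_frame_equal(a.ground_truth, b.ground_truth)

    def test_photon_budget_split_across_orders(self):
        """Background-subtracted ADU / GainTotal recovers emitted x order split."""
        sp = EmitterSpecies(612.0, spectral_sigma_nm=8.0, mean_photons_per_frame=2e4)
        stack = spaint.simulate_calibration_stack(
            1, species_triplet=(sp,), n_frames=60, spatial_size_px=(64, 64),
            background_photons=0.0, seed=2,
        )
        cam, geo = stack.camera, stack.geometry
        mean_frame = stack.frames.mean(axis=0).astype(float) - cam.baseline_offset
        sh = stack.spatial_height_px
        zeroth = mean_frame[:sh].sum() / cam.gain_total
        first = mean_frame[sh:].sum() / cam.gain_total
        emitted = sp.mean_photons_per_frame
        assert zeroth == pytest.approx(emitted * geo.zeroth_order_fraction, rel=0.05)
        assert first == pytest.approx(emitted * geo.first_order_fraction, rel=0.05)

    def test_blob_lands_at_predicted_displacement(self):
        """Measured Z0Z1 distance matches the optics formula at zero aberration."""
        sp = EmitterSpecies(581.5, spectral_sigma_nm=8.0, mean_photons_per_frame=5e4)
        stack = spaint.simulate_calibration_stack(
            1, species_triplet=(sp,), n_frames=40, spatial_size_px=(64, 64),
            aberration=(0.0, 0.0), seed=3,
        )
        x, y = stack.ground_truth.x_px[0], stack.ground_truth.y_px[0]
        truth_dist = float(stack.dispersion_truth.distance(581.5, x, y))
        mean_frame = stack.frames.mean(axis=0)
        prof = extract_profile(mean_frame, x, y, truth_dist)
        pk = fit_peak(prof)
        assert pk.qc_pass
        assert pk.center_px == pytest.approx(truth_dist, abs=0.2)
        # the linearized dispersion itself tracks the grating equation closely
        exact = predict_first_order_displacement(581.5, stack.geometry)
        assert pk.center_px == pytest.approx(exact, abs=0.5)

    def test_overlapping_regions_rejected(self):
        # a detector too small to separate the orders is a configuration error
        disp = spaint.DispersionModel(beta0=-500.0, beta1=0.4)
        with pytest.raises(ValueError, match="overlap"):
            spaint.simulate_calibration_stack(
                1, dispersion_truth=disp, n_frames=1, spatial_size_px=(64, 64)
            )


class TestSpaintKinetics:
    def test_zero_rate_gives_no_events(self):
        sample = spaint.SampleGeometry(
            kind="bead_field",
            binding_site_map=np.array([[10.0, 10.0, 600.0]]),
            binding_rate_per_site=0.0,
        )
        stack = spaint.simulate_spaint_stack(sample, n_frames=20, seed=1)
        assert len(stack.ground_truth) == 0

    def test_empty_site_map_warns_noise_only(self):
        sample = spaint.SampleGeometry(kind="bead_field", binding_site_map=np.empty((0, 3)))
        with pytest.warns(UserWarning, match="noise-only"):
            stack = spaint.simulate_spaint_stack(sample, n_frames=3, seed=1)
        assert len(stack.ground_truth) == 0

    def test_event_count_follows_poisson_rate(self):
        """n_sites * rate * T events expected, within 4 sqrt(rT) (Poisson)."""
        n_sites, rate, n_frames = 25, 0.4, 200
        sites = np.column_stack(
            [
                np.tile(np.arange(5) * 10.0 + 8, 5),
                np.repeat(np.arange(5) * 10.0 + 8, 5),
                np.full(25, 620.0),
            ]
        )
        sample = spaint.SampleGeometry(
            kind="bead_field", binding_site_map=sites, binding_rate_per_site=rate
        )
        stack = spaint.simulate_spaint_stack(sample, n_frames=n_frames, seed=5)
        duration = n_frames / stack.camera.frame_rate_hz
        expected = n_sites * rate * duration
        n_events = stack.ground_truth["event_id"].nunique()
        assert abs(n_events - expected) < 4.0 * np.sqrt(expected)

    def test_short_on_times_span_single_frames(self):
        """tau_on = 25 ms at 50 ms frames: ceil(tau/dt) = 1 with prob 1-e^-2."""
        sites = np.array([[20.0, 20.0, 620.0]])
        sample = spaint.SampleGeometry(
            kind="bead_field", binding_site_map=sites,
            binding_rate_per_site=5.0, on_time_mean_s=0.025,
        )
        stack = spaint.simulate_spaint_stack(sample, n_frames=400, seed=8)
        spans = stack.ground_truth.groupby("event_id").size()
        frac_single = (spans == 1).mean()
        assert spans.mode()[0] == 1
        assert frac_single == pytest.approx(1.0 - np.exp(-2.0), abs=0.08)


class TestStackIO:
    def test_round_trip_lossless(self, tmp_path, luv_stack):
        path = tmp_path / "stack.tif"
        write_stack(luv_stack, path)
        back = read_stack(path)
        np.testing.assert_array_equal(back.frames, luv_stack.frames)
        assert back.spatial_height_px == luv_stack.spatial_height_px
        assert list(back.ground_truth.columns[:5]) == GROUND_TRUTH_COLUMNS
        np.testing.assert_allclose(
            back.ground_truth[GROUND_TRUTH_COLUMNS].to_numpy(),
            luv_stack.ground_truth[GROUND_TRUTH_COLUMNS].to_numpy(),
        )
        assert back.camera.gain_total == pytest.approx(luv_stack.camera.gain_total)
        assert back.dispersion_truth.beta1 == pytest.approx(
            luv_stack.dispersion_truth.beta1
        )

    def test_empty_stack_refused(self, tmp_path):
        stack = spaint.FrameStack(
            frames=np.empty((0, 4, 4), dtype=np.uint16),
            camera=spaint.CameraModel(),
            geometry=spaint.GratingGeometry(),
            spatial_height_px=4,
        )
        with pytest.raises(ValueError, match="empty"):
            write_stack(stack, tmp_path / "empty.tif")

    def test_malformed_tiff_raises_format_error(self, tmp_path):
        bad = tmp_path / "bad.tif"
        bad.write_bytes(b"not a tiff at all")
        with pytest.raises(ValueError, match="malformed TIFF"):
            read_stack(bad)


class TestIntegratedGaussian:
    def test_mass_conserved(self):
        img = np.zeros((41, 41))
        _add_integrated_gaussian(img, 20.3, 19.6, 1.2, 2.5, 1000.0)
        assert img.sum() == pytest.approx(1000.0, rel=1e-4)

    def test_centroid_matches_subpixel_position(self):
        img = np.zeros((41, 41))
        _add_integrated_gaussian(img, 20.35, 18.75, 1.2, 1.2, 1.0)
        yy, xx = np.mgrid[0:41, 0:41]
        assert (img * xx).sum() == pytest.approx(20.35, abs=1e-3)
        assert (img * yy).sum() == pytest.approx(18.75, abs=1e-3)


class TestFiducialTable:
    def test_scatter_follows_stability_curve(self):
        inst = spaint.InstabilityModel()
        tbl = spaint.simulate_fiducial_localizations(
            1, 4000, photon_range=(800.0, 800.0), seed=3
        )
        px = tbl.attrs["pixel_size_nm"]
        sd_nm = tbl.x_px.std(ddof=1) * px
        expected = float(inst.spatial_sigma_nm(tbl.photons.mean()))
        assert sd_nm == pytest.approx(expected, rel=0.08)
        sd_lam = tbl.wavelength_nm.std(ddof=1)
        assert sd_lam == pytest.approx(
            float(inst.spectral_sigma_nm(tbl.photons.mean())), rel=0.08
        )

    def test_floors_anchor_the_curve(self):
        inst = spaint.InstabilityModel()
        assert float(inst.spatial_sigma_nm(1e9)) == pytest.approx(6.6)
        assert float(inst.spectral_sigma_nm(1e9)) == pytest.approx(1.3)
        assert float(inst.spatial_sigma_nm(800.0)) == pytest.approx(18.0)
        assert float(inst.spectral_sigma_nm(800.0)) == pytest.approx(3.8)
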
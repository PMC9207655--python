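"""Detection-limit model: SNR arithmetic, calibration, sweeps, safety."""

import math

import numpy as np
import pytest

import difcsim as d
from difcsim import contrast as C
from difcsim import jacobian as J
from difcsim.errors import CalibrationError, SingularInputError, UndefinedRatioError

from conftest import FIXTURE_SEED
from test_jacobian import _synthetic_map


@pytest.fixture()
def model():
    return C.DetectionModel()


class TestSnrArithmetic:
    def test_five_times_noise_is_snr_floor(self, model):
        background = 10.0
        peak = model.threshold_multiple * model.noise_fraction * background
        assert C.snr_db(peak, model, background) == pytest.approx(13.9, abs=0.1)
        assert model.snr_floor_db == pytest.approx(20 * math.log10(5), rel=1e-12)

    def test_peak_equal_noise_is_zero_db(self, model):
        assert C.snr_db(0.002 * 3.0, model, 3.0) == pytest.approx(0.0, abs=1e-9)

    def test_ten_times_noise_is_twenty_db(self, model):
        assert C.snr_db(10 * 0.002 * 3.0, model, 3.0) == pytest.approx(20.0, abs=1e-9)

    def test_zero_background_rejected(self, model):
        with pytest.raises(UndefinedRatioError):
            C.snr_db(1.0, model, 0.0)

    def test_born_linearity_exact_6db_per_doubling(self, model):
        a = C.snr_db(1.0, model, 5.0)
        b = C.snr_db(2.0, model, 5.0)
        assert b - a == pytest.approx(20 * math.log10(2), abs=1e-12)

    def test_gain_cancellation(self, model):
        assert C.snr_db(1.0, model, 5.0) == pytest.approx(
            C.snr_db(1000.0, model, 5000.0), abs=1e-12
        )


class TestPeakAndBackground:
    def test_zero_yields(self, maps_780, model):
        zero = model.replace(eta_cell=0.0, eta_af=0.0)
        assert C.peak_signal(maps_780[0.3], 1.0, zero) == 0.0
        assert C.background_signal(maps_780[0.3], zero) == 0.0

    def test_peak_linearity_in_eta_cell(self, maps_780, model):
        one = C.peak_signal(maps_780[0.3], 2.0, model.replace(eta_cell=1.0))
        two = C.peak_signal(maps_780[0.3], 2.0, model.replace(eta_cell=2.0))
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_nir_beats_blue_at_depth(self, maps_780, maps_488, model):
        p_nir = C.peak_signal(maps_780[0.3], 3.0, model)
        p_blue = C.peak_signal(maps_488[0.3], 3.0, model)
        assert p_nir > p_blue

    def test_background_decreases_with_sds(self, maps_780, model):
        totals = [C.background_signal(maps_780[s], model) for s in sorted(maps_780)]
        assert all(a > b for a, b in zip(totals, totals[1:]))

    def test_out_of_volume_depth_rejected(self, maps_780, model):
        with pytest.raises(Exception):
            C.peak_signal(maps_780[0.3], 100.0, model)


class TestMaxDetectionDepth:
    def test_threshold_scan(self, model):
        curve = C.ContrastCurve(
            depths=np.array([1.0, 2.0, 3.0, 4.0]),
            snr_db=np.array([20.0, 15.0, 13.8, 10.0]),
        )
        assert C.max_detection_depth(curve, model) == 2.0

    def test_all_below_floor_is_none(self, model):
        curve = C.ContrastCurve(depths=np.array([1.0]), snr_db=np.array([5.0]))
        assert C.max_detection_depth(curve, model) is None

    def test_brighter_never_shallower(self, maps_780, model_nir):
        base = C.max_detection_depth(C.contrast_curve(maps_780[0.3], model_nir), model_nir)
        bright = model_nir.replace(eta_cell=10 * model_nir.eta_cell)
        deep = C.max_detection_depth(C.contrast_curve(maps_780[0.3], bright), bright)
        assert deep >= base


class TestCalibration:
    def test_round_trip_hits_anchor(self, maps_780, model_nir, model):
        curve = C.contrast_curve(maps_780[0.3], model_nir)
        # 3.5 mm maps to the nearest voxel center, shallow on the tie: 3.375
        assert C.max_detection_depth(curve, model_nir) == pytest.approx(3.375)

    def test_overall_map_scale_cancels(self, maps_780, model):
        """Rescaling W rescales peak and noise together, so the calibrated
        yield is invariant to the arbitrary overall normalization of W."""
        m = maps_780[0.3]
        scaled = J.SensitivityMap(
            W=m.W * 10.0, volume=m.volume, props=m.props,
            source_position=m.source_position, detector_position=m.detector_position,
        )
        a = C.calibrate_eta_cell(m, model, 3.5).eta_cell
        b = C.calibrate_eta_cell(scaled, model, 3.5).eta_cell
        assert b == pytest.approx(a, rel=5e-3)

    def test_fixed_noise_scale_inverts_eta(self, maps_780, model):
        """Holding the absolute noise fixed (eta_af scaled down tenfold while
        W scales up tenfold), the calibrated cell yield drops tenfold."""
        m = maps_780[0.3]
        scaled = J.SensitivityMap(
            W=m.W * 10.0, volume=m.volume, props=m.props,
            source_position=m.source_position, detector_position=m.detector_position,
        )
        a = C.calibrate_eta_cell(m, model, 3.5).eta_cell
        b = C.calibrate_eta_cell(scaled, model.replace(eta_af=0.1), 3.5).eta_cell
        assert b == pytest.approx(a / 10.0, rel=5e-3)

    def test_unreachably_shallow_target_rejected(self, model):
        smap = _synthetic_map(np.array([1.0, 2.0, 4.0, 8.0]), sds=0.0)
        # profile increases with depth: the deepest voxel always dominates,
        # so no eta can make a shallow voxel the detection limit
        with pytest.raises(CalibrationError):
            C.calibrate_eta_cell(smap, model, 0.1, max_depth_mm=1.0)


class TestSdsSelection:
    def test_tie_breaks_toward_smaller_sds(self, model):
        depths = np.array([2.125, 3.125])
        c = C.ContrastCurve(depths=depths, snr_db=np.array([20.0, 15.0]))
        curves = {3.0: c, 1.0: C.ContrastCurve(depths=depths, snr_db=c.snr_db.copy())}
        assert C.sds_argmax_at_depth(curves, 3.0) == 1.0

    def test_single_depth_median_reduces_to_argmax(self, curves_780):
        med = C.sds_best_median(curves_780, (3.0, 3.0))
        arg = C.sds_argmax_at_depth(curves_780, 3.0)
        assert med == arg

    def test_argmax_invariant_to_eta_cell(self, maps_780, model_nir):
        curves_a = {s: C.contrast_curve(m, model_nir) for s, m in maps_780.items()}
        dim = model_nir.replace(eta_cell=model_nir.eta_cell / 7.0)
        curves_b = {s: C.contrast_curve(m, dim) for s, m in maps_780.items()}
        assert C.sds_argmax_at_depth(curves_a, 3.0) == C.sds_argmax_at_depth(curves_b, 3.0)


class TestExtendedSource:
    def test_hex_grid_covers_disk(self):
        pts = C.hex_disk_points((0.0, 0.0), 3.0)
        assert len(pts) >= 37
        assert (np.linalg.norm(pts, axis=1) <= 1.5 + 1e-9).all()

    def test_small_spot_approaches_pencil(self, volume, model_nir):
        """A spot much smaller than a voxel reproduces the pencil-beam curve."""
        cfg = d.MCConfig(n_photons=120_000, seed=FIXTURE_SEED)
        spot = C.extended_source_curve(volume, "780", 3.0, 0.05, cfg, model_nir)
        pencil = C.contrast_curve(
            J.sensitivity_map("780", 3.0, volume, cfg, mirror=False), model_nir
        )
        sel = slice(4, 16)  # 1-4 mm: depths where both are well sampled
        assert np.allclose(spot.snr_db[sel], pencil.snr_db[sel], atol=2.0)

    def test_iec_spot_retains_sensitivity_at_depth(self, volume, model_nir, curves_780):
        """3-mm spot stays within ~3 dB of the pencil beam over 2-4 mm."""
        cfg = d.MCConfig(n_photons=150_000, seed=FIXTURE_SEED)
        spot = C.extended_source_curve(volume, "780", 3.0, 3.0, cfg, model_nir)
        pencil = curves_780[3.0]
        sel = (spot.depths >= 2.0) & (spot.depths <= 4.0)
        assert np.all(np.abs(spot.snr_db[sel] - pencil.snr_db[sel]) < 3.0)

    def test_spot_beyond_face_rejected(self, model_nir):
        vol = d.VoxelVolume((4.0, 4.0, 4.0), 0.25)
        with pytest.raises(Exception):
            C.extended_source_curve(vol, "780", 3.0, 6.0, d.MCConfig(n_photons=100, seed=0), model_nir)


class TestIrradiance:
    def test_zero_power_compliant(self):
        irr, ok = C.irradiance_check(0.0, 3.0)
        assert irr == 0.0 and ok

    def test_current_design_20mw_3mm_spot(self):
        irr, ok = C.irradiance_check(20.0, 3.0)
        assert irr == pytest.approx(20.0 / (math.pi * 0.15**2), rel=1e-12)
        assert irr == pytest.approx(283.0, abs=1.0)
        assert ok

    def test_1mm_spot_overexposes(self):
        irr, ok = C.irradiance_check(20.0, 1.0)
        assert irr == pytest.approx(2546.0, abs=2.0)
        assert not ok

    def test_zero_diameter_singular(self):
        with pytest.raises(SingularInputError):
            C.irradiance_check(20.0, 0.0)


class TestPerturbations:
    def test_identity_factors_change_nothing(self, maps_780, model_nir, volume):
        df = C.property_perturbation_sweep(
            "780", model_nir, sds_list=(0.3,), combinations=[(1.0, 1.0)],
            volume=volume, config=d.MCConfig(n_photons=1000, seed=1),
            baseline_maps={0.3: maps_780[0.3]},
        )
        assert (df.delta_mm == 0).all()

    def test_brightness_identity_and_monotonicity(self, model_nir, curves_780):
        df = C.brightness_perturbation_sweep(model_nir, curves_780, factors=(0.5, 1.0, 1.5))
        ident = df[df.factor_eta_cell == 1.0]
        assert (ident.delta_mm == 0).all()
        # a NaN delta means the dimmed cell fell below the floor everywhere,
        # the strongest form of "dimmer never deepens"
        dim = df[df.factor_eta_cell == 0.5]
        assert (dim.delta_mm.dropna() <= 0).all()
        assert dim[dim.delta_mm.isna()].max_depth_mm.isna().all()
        bright = df[df.factor_eta_cell == 1.5]
        assert (bright.delta_mm.dropna() >= 0).all()

    def test_more_absorption_never_deepens(self, maps_780, model_nir, volume):
        df = C.property_perturbation_sweep(
            "780", model_nir, sds_list=(0.3,), combinations=[(1.5, 1.0)],
            volume=volume, config=d.MCConfig(n_photons=150_000, seed=FIXTURE_SEED),
            baseline_maps={0.3: maps_780[0.3]},
        )
        assert (df.delta_mm <= 0).all()


class TestWavelengthFloor:
    def test_all_wavelengths_detectable_at_1mm(self, maps_780, maps_488, map_640_3, model_nir):
        """Shallow (mouse-like ~1 mm) targets clear the floor at every line."""
        for smap in (maps_780[0.3], maps_488[0.3]):
            c = C.contrast_curve(smap, model_nir)
            assert c.snr_db[4] >= model_nir.snr_floor_db

    def test_reported_depths_quantized_to_voxels(self, curves_780, model_nir):
        for c in curves_780.values():
            dd = C.max_detection_depth(c, model_nir)
            assert dd is None or (dd / 0.25) % 1 == pytest.approx(0.5)
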
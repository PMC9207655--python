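"""Sensitivity-map assembly, reciprocity, and depth-profile extraction."""

import numpy as np
import pytest

import difcsim as d
from difcsim import jacobian as J
from difcsim.errors import GeometryError, IncompatibleGridError, UndefinedMaximumError
from difcsim.tissue_optics import FluenceField



def _stub_field(values, volume, props, source):
    return FluenceField(
        values=values,
        volume=volume,
        props=props,
        source_position=np.asarray(source, dtype=float),
        escaped_weight=0.0,
        absorbed_weight=float(values.sum()),
        inflight_weight=0.0,
        n_photons=1,
        n_scatter_events=0,
        seed=0,
    )


def _synthetic_map(column, volume=None, sds=0.0):
    """SensitivityMap whose midline column equals ``column`` (uniform in x, y)."""
    volume = volume or d.VoxelVolume((2.0, 2.0, max(2.0, len(column) * 0.25)), 0.25)
    W = np.broadcast_to(
        np.asarray(column, dtype=float), volume.shape[:2] + (len(column),)
    ).copy()
    if W.shape[2] != volume.shape[2]:
        full = np.zeros(volume.shape)
        full[:, :, : W.shape[2]] = W
        W = full
    rs, rd = J.probe_positions(volume, sds)
    return J.SensitivityMap(W=W, volume=volume, props=d.get_preset("780"),
                            source_position=rs, detector_position=rd)


class TestBornSensitivity:
    def test_zero_excitation_annihilates(self):
        vol = d.VoxelVolume((2.0, 2.0, 2.0), 0.5)
        props = d.get_preset("780")
        zero = _stub_field(np.zeros(vol.shape), vol, props, [1.0, 1.0, 0.0])
        ones = _stub_field(np.ones(vol.shape), vol, props, [1.0, 1.0, 0.0])
        smap = J.born_sensitivity(zero, ones)
        assert not smap.W.any()

    def test_grid_mismatch_rejected(self):
        props = d.get_preset("780")
        a = _stub_field(np.ones((4, 4, 4)), d.VoxelVolume((2.0, 2.0, 2.0), 0.5), props, [1, 1, 0])
        b = _stub_field(np.ones((8, 8, 8)), d.VoxelVolume((2.0, 2.0, 2.0), 0.25), props, [1, 1, 0])
        with pytest.raises(IncompatibleGridError):
            J.born_sensitivity(a, b)

    def test_property_mismatch_rejected(self):
        vol = d.VoxelVolume((2.0, 2.0, 2.0), 0.5)
        a = _stub_field(np.ones(vol.shape), vol, d.get_preset("780"), [1, 1, 0])
        b = _stub_field(np.ones(vol.shape), vol, d.get_preset("488"), [1, 1, 0])
        with pytest.raises(IncompatibleGridError):
            J.born_sensitivity(a, b)

    def test_reciprocity_under_probe_swap(self):
        """Swapping source and detector roles leaves W unchanged within MC error.

        Both orientations are computed from fully independent photon sets;
        agreement is checked on 2-mm pooled cells against 3x the combined
        standard error estimated from replicates.
        """
        vol = d.VoxelVolume((20.0, 20.0, 20.0), 0.25)
        rs, rd = J.probe_positions(vol, 3.0)
        reps_ab, reps_ba = [], []
        for k in range(3):
            cfg = lambda s: d.MCConfig(n_photons=60_000, seed=s)
            g_s = d.simulate_fluence(vol, "640", rs, cfg(10 + k))
            g_d = d.simulate_fluence(vol, "640", rd, cfg(110 + k))
            reps_ab.append(J.born_sensitivity(g_s, g_d).W)
            g_d2 = d.simulate_fluence(vol, "640", rd, cfg(210 + k))
            g_s2 = d.simulate_fluence(vol, "640", rs, cfg(310 + k))
            reps_ba.append(J.born_sensitivity(g_d2, g_s2).W)

        def pool(W):  # 2-mm (8-voxel) block sums
            n = W.shape[0] // 8
            return W[: n * 8, : n * 8, : n * 8].reshape(n, 8, n, 8, n, 8).sum(axis=(1, 3, 5))

        A = np.stack([pool(w) for w in reps_ab])
        B = np.stack([pool(w) for w in reps_ba])
        mA, mB = A.mean(axis=0), B.mean(axis=0)
        seA = A.std(axis=0, ddof=1) / np.sqrt(A.shape[0])
        seB = B.std(axis=0, ddof=1) / np.sqrt(B.shape[0])
        floor = mA.max() * 1e-4
        sel = (mA > floor) & (mB > floor) & (seA > 0) & (seB > 0)
        ok = np.abs(mA - mB)[sel] <= 3.0 * np.sqrt(seA**2 + seB**2)[sel]
        assert ok.mean() > 0.9


class TestMidlineProfile:
    def test_degenerate_colocated_pair(self):
        col = np.array([5.0, 3.0, 1.0, 0.5])
        smap = _synthetic_map(col, sds=0.0)
        prof = J.midline_depth_profile(smap, max_depth_mm=1.0)
        np.testing.assert_allclose(prof.values, col)

    def test_off_surface_probe_rejected(self):
        smap = _synthetic_map(np.ones(4))
        smap.source_position = np.array([1.0, 1.0, 0.5])
        with pytest.raises(GeometryError):
            J.midline_depth_profile(smap)

    def test_own_max_normalization_is_one(self, maps_780):
        prof = J.midline_depth_profile(maps_780[0.3]).normalized_to_own_max()
        assert prof.values.max() == 1.0

    def test_blue_depth_of_max_shallower_at_short_sds(self, maps_488):
        p03 = J.midline_depth_profile(maps_488[0.3])
        p6 = J.midline_depth_profile(maps_488[6.0])
        assert J.depth_of_max_sensitivity(p03) < J.depth_of_max_sensitivity(p6)


class TestDepthOfMax:
    def test_monotone_profile_peaks_at_first_voxel(self):
        prof = J.DepthProfile(depths=(np.arange(8) + 0.5) * 0.25,
                              values=np.exp(-np.arange(8.0)))
        assert J.depth_of_max_sensitivity(prof) == 0.125

    def test_plateau_tie_breaks_shallow(self):
        vals = np.array([0.1, 0.2, 0.3, 0.3, 0.2, 0.1])
        prof = J.DepthProfile(depths=(np.arange(6) + 0.5) * 0.25, values=vals)
        # plateau at depths 0.625 and 0.875 -> shallower one wins
        assert J.depth_of_max_sensitivity(prof) == pytest.approx(0.625)

    def test_all_zero_profile_rejected(self):
        prof = J.DepthProfile(depths=np.array([0.125]), values=np.array([0.0]))
        with pytest.raises(UndefinedMaximumError):
            J.depth_of_max_sensitivity(prof)

    def test_depth_of_max_nondecreasing_in_sds(self, maps_780):
        depths = [
            J.depth_of_max_sensitivity(J.midline_depth_profile(maps_780[s]))
            for s in sorted(maps_780)
        ]
        assert all(a <= b for a, b in zip(depths, depths[1:]))


class TestNormalizeProfiles:
    def test_single_profile_equals_own_normalization(self):
        prof = J.DepthProfile(depths=np.array([0.125, 0.375]), values=np.array([2.0, 1.0]))
        out = J.normalize_profiles([prof])[0]
        np.testing.assert_allclose(out.values, [1.0, 0.5])

    def test_global_max_is_exactly_one(self, maps_780, maps_488, map_640_3):
        profs = [J.midline_depth_profile(m) for m in maps_780.values()]
        profs += [J.midline_depth_profile(m) for m in maps_488.values()]
        profs.append(J.midline_depth_profile(map_640_3))
        normed = J.normalize_profiles(profs)
        assert max(p.values.max() for p in normed) == 1.0

    def test_global_max_attained_at_blue_short_sds(self, maps_780, maps_488, map_640_3):
        """The 0.3-mm SDS, 488-nm combination dominates every other profile."""
        blue = J.midline_depth_profile(maps_488[0.3]).values.max()
        others = [J.midline_depth_profile(m).values.max() for m in maps_780.values()]
        others += [J.midline_depth_profile(maps_488[s]).values.max() for s in (3.0, 6.0, 12.0)]
        others.append(J.midline_depth_profile(map_640_3).values.max())
        assert blue > max(others)

    def test_all_zero_collection_rejected(self):
        prof = J.DepthProfile(depths=np.array([0.125]), values=np.array([0.0]))
        with pytest.raises(UndefinedMaximumError):
            J.normalize_profiles([prof])


class TestSdsSweep:
    def test_singleton_equals_direct_call(self):
        vol = d.VoxelVolume((10.0, 10.0, 10.0), 0.25)
        cfg = d.MCConfig(n_photons=20_000, seed=5)
        sweep = J.sds_sweep("780", (1.0,), vol, cfg)
        direct = J.sensitivity_map("780", 1.0, vol, cfg)
        np.testing.assert_array_equal(sweep[1.0].W, direct.W)

    def test_sweep_deterministic(self):
        vol = d.VoxelVolume((10.0, 10.0, 10.0), 0.25)
        cfg = d.MCConfig(n_photons=20_000, seed=5)
        a = J.sds_sweep("780", (0.3, 2.0), vol, cfg)
        b = J.sds_sweep("780", (0.3, 2.0), vol, cfg)
        for s in a:
            np.testing.assert_array_equal(a[s].W, b[s].W)

    def test_midline_max_decreases_with_sds(self, maps_780, maps_488):
        for maps in (maps_780, maps_488):
            peaks = [
                J.midline_depth_profile(maps[s]).values.max() for s in sorted(maps)
            ]
            assert all(a > b for a, b in zip(peaks, peaks[1:]))

    def test_empty_sds_list_rejected(self):
        with pytest.raises(GeometryError):
            J.sds_sweep("780", ())

    def test_oversized_sds_rejected(self):
        vol = d.VoxelVolume((10.0, 10.0, 10.0), 0.25)
        with pytest.raises(GeometryError):
            J.probe_positions(vol, 12.0)
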
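import numpy as np
import pytest

from mesotof.io import Volume
from mesotof.partial_volume import blood_fraction
from mesotof.phantom import (
    LABEL_ARTERY,
    LABEL_VEIN,
    PhantomConfig,
    VesselSegment,
    VesselTree,
    add_bias_field,
    add_rician_noise,
    generate_phantom,
    generate_tree,
    merge_trees,
    rasterize_fraction_map,
    simulate_tof,
)
from mesotof.segmentation import measure_fre
from mesotof.signal_model import AcquisitionParams, TissueParams, steady_state_mz

from conftest import straight_cylinder_phantom


class TestGenerateTree:
    def test_depth_zero_single_segment(self):
        cfg = PhantomConfig(depth=0)
        tree = generate_tree(cfg, rng_seed=1)
        assert len(tree.segments) == 1
        assert tree.segments[0].delivery_offset_ms == cfg.root_delivery_ms

    def test_deterministic_under_seed(self):
        cfg = PhantomConfig(depth=3)
        a = generate_tree(cfg, rng_seed=7)
        b = generate_tree(cfg, rng_seed=7)
        assert len(a.segments) == len(b.segments)
        for sa, sb in zip(a.segments, b.segments):
            np.testing.assert_array_equal(sa.start_mm, sb.start_mm)
            np.testing.assert_array_equal(sa.end_mm, sb.end_mm)
            assert sa.diameter_mm == sb.diameter_mm

    def test_branch_angles_near_right_angle(self):
        cfg = PhantomConfig(depth=4)
        angles = []
        seed = 0
        while len(angles) < 1000:
            tree = generate_tree(cfg, rng_seed=seed)
            angles += [s.branch_angle_deg for s in tree.segments
                       if s.branch_angle_deg is not None]
            seed += 1
        angles = np.array(angles[:1000])
        assert abs(angles.mean() - 90.0) < 5.0
        assert np.all((angles >= 75.0) & (angles <= 105.0))

    def test_child_diameter_and_delivery_invariants(self):
        tree = generate_tree(PhantomConfig(depth=4), rng_seed=3)
        for seg in tree.segments:
            if seg.parent_index is not None:
                parent = tree.segments[seg.parent_index]
                assert seg.diameter_mm <= parent.diameter_mm + 1e-12
                assert seg.delivery_offset_ms >= parent.delivery_offset_ms

    def test_velocity_monotone_in_diameter(self):
        tree = generate_tree(PhantomConfig(depth=4), rng_seed=5)
        segs = sorted(tree.segments, key=lambda s: s.diameter_mm)
        vels = [s.velocity_mm_s for s in segs]
        assert all(a <= b + 1e-12 for a, b in zip(vels, vels[1:]))
        assert all(10.0 <= v <= 50.0 for v in vels)

    def test_degenerate_fov_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(fov_mm=(0.0, 10.0, 10.0))


class TestRasterize:
    @pytest.mark.parametrize("d_over_l", [0.5, 0.7, 1.0, 1.5])
    def test_agrees_with_analytic_fraction(self, d_over_l):
        voxel = 0.3
        ph = straight_cylinder_phantom(voxel * d_over_l, voxel)
        n = ph["cfg"].grid_shape[1] // 2
        got = ph["raster"].fraction.data[n, n, n]
        expected = blood_fraction(voxel * d_over_l, voxel)
        assert abs(got - expected) <= 0.02
        assert abs(got - expected) <= 0.01  # tighter: centred case

    def test_empty_tree_all_zero(self):
        cfg = PhantomConfig(fov_mm=(3.0, 3.0, 3.0))
        out = rasterize_fraction_map(VesselTree([]), cfg)
        assert not np.any(out.fraction.data)
        assert not np.any(out.mask.data)

    def test_volume_conservation(self):
        ph = straight_cylinder_phantom(0.3, 0.3)
        seg = ph["tree"].segments[0]
        total = ph["raster"].fraction.data.sum() * 0.3**3
        analytic = np.pi * (seg.diameter_mm / 2) ** 2 * seg.length_mm
        assert total == pytest.approx(analytic, rel=0.02)

    def test_delivery_increases_downstream(self):
        ph = straight_cylinder_phantom(0.3, 0.3, delivery_ms=200.0)
        d = ph["raster"].delivery.data
        f = ph["raster"].fraction.data
        n = ph["cfg"].grid_shape[1] // 2
        along = d[:, n, n][f[:, n, n] > 0.5]
        assert np.all(np.diff(along) > 0)
        # entry voxel is excluded by end-cap coverage; first full voxel is
        # one voxel (10 ms at 30 mm/s) downstream
        assert along[0] == pytest.approx(200.0, abs=15.0)

    def test_labels_follow_kind(self):
        ph = straight_cylinder_phantom(0.3, 0.3, kind="vein")
        labels = ph["raster"].labels.data
        assert np.all(labels[ph["raster"].mask.data > 0] == LABEL_VEIN)


class TestSimulateTof:
    def test_vessel_free_voxel(self, acq, tis):
        ph = straight_cylinder_phantom(0.3, 0.3, acq=acq, tis=tis)
        img = ph["echoes"][0].data
        expected = (steady_state_mz(acq, tis, tis.t1_tissue_ms)
                    * np.exp(-acq.te_ms[0] / tis.t2s_tissue_ms))
        corner = img[0, 0, 0]
        assert corner == pytest.approx(expected, rel=1e-9)

    def test_fully_blood_unsaturated_voxel(self, acq, tis):
        # wide vessel, short delivery: a voxel near the entry face is pure
        # fresh blood that has seen a single RF pulse (delivery < TR)
        ph = straight_cylinder_phantom(1.2, 0.3, delivery_ms=5.0,
                                       acq=acq, tis=tis)
        n = ph["cfg"].grid_shape[1] // 2
        entry = ph["echoes"][0].data[1, n, n]
        assert ph["raster"].fraction.data[1, n, n] == 1.0
        expected = tis.m0 * np.exp(-acq.te_ms[0] / tis.t2s_artery_ms)
        assert entry == pytest.approx(expected, rel=1e-6)

    def test_measured_fre_matches_partial_volume_prediction(self, acq, tis):
        from mesotof.partial_volume import VesselVoxelGeometry, partial_volume_fre
        from mesotof.signal_model import FlowParams

        ph = straight_cylinder_phantom(0.3, 0.3, delivery_ms=300.0,
                                       acq=acq, tis=tis)
        measured = measure_fre(ph["echoes"][0], ph["raster"].mask)
        mid_delivery = float(np.median(
            ph["raster"].delivery.data[ph["raster"].mask.data > 0]))
        predicted = partial_volume_fre(
            acq, tis, FlowParams(delivery_ms=mid_delivery),
            VesselVoxelGeometry(0.3, 0.3))
        assert measured == pytest.approx(predicted, rel=0.05)

    def test_grid_mismatch_rejected(self, acq, tis):
        ph = straight_cylinder_phantom(0.3, 0.3)
        other = Volume(np.zeros((2, 2, 2)), 0.3)
        with pytest.raises(ValueError):
            simulate_tof(ph["raster"].fraction, other, acq, tis)


class TestRicianNoise:
    def test_sigma_zero_identity(self):
        vol = Volume(np.random.default_rng(0).random((8, 8, 8)), 0.3)
        out = add_rician_noise(vol, 0.0, seed=1)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_rayleigh_mean_on_zero_signal(self):
        vol = Volume(np.zeros((100, 100, 100)), 0.3)
        out = add_rician_noise(vol, 1.0, seed=2)
        assert out.data.mean() == pytest.approx(np.sqrt(np.pi / 2), rel=0.01)

    def test_seed_reproducible(self):
        vol = Volume(np.ones((16, 16, 16)), 0.3)
        a = add_rician_noise(vol, 0.5, seed=3)
        b = add_rician_noise(vol, 0.5, seed=3)
        np.testing.assert_array_equal(a.data, b.data)

    def test_negative_sigma_rejected(self):
        vol = Volume(np.ones((4, 4, 4)), 0.3)
        with pytest.raises(ValueError):
            add_rician_noise(vol, -0.1, seed=0)


class TestBiasField:
    def test_amplitude_zero_identity(self):
        vol = Volume(np.ones((16, 16, 16)), 0.3)
        out = add_bias_field(vol, 0.0, 8.0, seed=1)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_field_range_bound(self):
        amplitude = 0.3
        vol = Volume(np.ones((32, 32, 32)), 0.3)
        out = add_bias_field(vol, amplitude, 4.0, seed=4)
        assert out.data.min() >= 1 - amplitude - 1e-12
        assert out.data.max() <= 1 + amplitude + 1e-12

    def test_seed_reproducible(self):
        vol = Volume(np.ones((16, 16, 16)), 0.3)
        a = add_bias_field(vol, 0.2, 4.0, seed=5)
        b = add_bias_field(vol, 0.2, 4.0, seed=5)
        np.testing.assert_array_equal(a.data, b.data)


class TestGeneratePhantom:
    def test_emits_all_ground_truth(self, default_phantom):
        for key in ("fraction", "delivery", "labels", "mask", "echoes"):
            assert key in default_phantom
        assert len(default_phantom["echoes"]) == 2
        assert default_phantom["mask"].data.any()

    def test_contains_arteries_and_veins(self, default_phantom):
        labels = default_phantom["labels"].data
        assert np.any(labels == LABEL_ARTERY)
        assert np.any(labels == LABEL_VEIN)

    def test_deterministic(self, acq, tis, default_phantom):
        again = generate_phantom(PhantomConfig(), seed=42, acq=acq, tis=tis)
        np.testing.assert_array_equal(again["echoes"][0].data,
                                      default_phantom["echoes"][0].data)

    def test_merge_trees_rebases_parents(self):
        cfg = PhantomConfig(depth=2)
        t1 = generate_tree(cfg, rng_seed=1)
        t2 = generate_tree(cfg, rng_seed=2)
        merged = merge_trees([t1, t2])
        assert len(merged.segments) == len(t1.segments) + len(t2.segments)
        second_root = merged.segments[len(t1.segments)]
        assert second_root.parent_index is None
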
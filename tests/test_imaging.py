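"""Imaging stage: IO round-trips, projection, segmentation, spots, pairing."""

import math

import numpy as np
import pytest

from ccsplit import imaging
from ccsplit.errors import CalibrationError, InputError
from ccsplit.imaging import (CentrosomalStructure, ImageStack, NucleusRegion,
                             Spot, assemble_cells, detect_spots, load_stack,
                             max_project, pair_markers, pcnt_structures,
                             segment_nuclei, write_stack)
from ccsplit.synth import ImageSimConfig, simulate_image_set


def _stack(dapi, pcnt, px=0.1, **extra):
    channels = {"DAPI": dapi, "PCNT": pcnt, **extra}
    return ImageStack(channels=channels, pixel_size_um=px)


def _spot(x, y, channel="PCNT", quality=1.0):
    return Spot(channel=channel, x_um=x, y_um=y, peak_intensity=1.0,
                quality=quality)


class TestLoadStack:
    def test_ome_roundtrip(self, noiseless_set, tmp_path):
        stacks, _ = noiseless_set
        path = tmp_path / "field.ome.tif"
        write_stack(stacks[0], path)
        back = load_stack(path)
        assert set(back.channels) == set(stacks[0].channels)
        assert back.pixel_size_um == pytest.approx(0.1)
        assert back.z_step_um == pytest.approx(0.5)
        for name, ch in stacks[0].channels.items():
            np.testing.assert_allclose(back.channels[name], ch)

    def test_missing_channel_is_input_error(self, tmp_path):
        import tifffile
        path = tmp_path / "dapi_only.ome.tif"
        tifffile.imwrite(path, np.zeros((2, 16, 16), dtype=np.float32),
                         ome=True,
                         metadata={"axes": "ZYX", "PhysicalSizeX": 0.1})
        with pytest.raises(InputError, match="PCNT"):
            load_stack(path, channel_map={"DAPI": 0})

    def test_pixel_size_override_wins(self, noiseless_set, tmp_path):
        stacks, _ = noiseless_set
        path = tmp_path / "field.ome.tif"
        write_stack(stacks[0], path)
        back = load_stack(path, pixel_size_um=0.2)
        assert back.pixel_size_um == 0.2

    def test_missing_pixel_size_is_calibration_error(self, tmp_path):
        import tifffile
        path = tmp_path / "plain.tif"
        tifffile.imwrite(path, np.zeros((2, 2, 16, 16), dtype=np.float32))
        with pytest.raises(CalibrationError):
            load_stack(path, channel_map={"DAPI": 0, "PCNT": 1})


class TestMaxProject:
    def test_single_plane_identity(self, rng):
        img = rng.random((1, 8, 8))
        proj = max_project(_stack(img, img.copy()))
        np.testing.assert_array_equal(proj["DAPI"], img[0])

    def test_single_hot_pixel(self):
        stack = np.zeros((4, 8, 8))
        stack[2, 3, 5] = 7.0
        proj = max_project(_stack(stack, np.zeros((4, 8, 8))))
        assert proj["DAPI"][3, 5] == 7.0
        assert proj["DAPI"].sum() == 7.0

    def test_matches_brute_force_elementwise_max(self, rng):
        stack = rng.random((3, 12, 10))
        proj = max_project(_stack(stack, stack.copy()))["DAPI"]
        brute = np.empty((12, 10))
        for i in range(12):
            for j in range(10):
                brute[i, j] = max(stack[k, i, j] for k in range(3))
        np.testing.assert_array_equal(proj, brute)


class TestSegmentNuclei:
    def test_counts_and_centroids_match_ground_truth(self, noiseless_set,
                                                     noiseless_config):
        stacks, gt = noiseless_set
        px = noiseless_config.pixel_size_um
        for f, stack in enumerate(stacks):
            true = gt.cells[gt.cells["field"] == f]
            nuclei = segment_nuclei(max_project(stack)["DAPI"], px)
            assert len(nuclei) == len(true)
            for n in nuclei:
                d = np.hypot(true["x_um"] - n.centroid_um[0],
                             true["y_um"] - n.centroid_um[1])
                assert d.min() < 1 * px  # within one pixel

    def test_equivalent_diameter_recovered(self, noiseless_set,
                                           noiseless_config):
        stacks, gt = noiseless_set
        px = noiseless_config.pixel_size_um
        nuclei = segment_nuclei(max_project(stacks[0])["DAPI"], px)
        true = gt.cells[gt.cells["field"] == 0]
        for n in nuclei:
            d = np.hypot(true["x_um"] - n.centroid_um[0],
                         true["y_um"] - n.centroid_um[1])
            truth = true.loc[d.idxmin(), "diameter_um"]
            assert n.equivalent_diameter_um == pytest.approx(truth, abs=0.3)

    def test_blank_image_yields_empty(self):
        assert segment_nuclei(np.zeros((64, 64)), 0.1) == []

    def test_mitotic_cells_flagged(self):
        cfg = ImageSimConfig(n_cells=30, mitotic_fraction=0.2, noise_sd=0.0,
                             shot_noise=False, seed=13)
        stacks, gt = simulate_image_set(cfg)
        flagged, truth = 0, int(gt.cells["mitotic"].sum())
        for stack in stacks:
            nuclei = segment_nuclei(max_project(stack)["DAPI"],
                                    cfg.pixel_size_um)
            flagged += sum(n.mitotic for n in nuclei)
        assert flagged == truth
        assert truth > 0


class TestDetectSpots:
    def test_single_dot_subpixel_accuracy(self):
        px, sigma_um = 0.1, 0.15
        img = np.zeros((64, 64))
        x_true, y_true = 31.37 * px, 28.81 * px
        ys, xs = np.mgrid[0:64, 0:64].astype(float)
        img += 100 * np.exp(-(((xs * px - x_true) ** 2 + (ys * px - y_true) ** 2)
                              / (2 * sigma_um ** 2)))
        spots = detect_spots(img, px)
        assert len(spots) == 1
        assert abs(spots[0].x_um - x_true) < 0.25 * px
        assert abs(spots[0].y_um - y_true) < 0.25 * px

    def test_pair_separation_measured(self):
        px, sigma_um = 0.1, 0.15
        img = np.zeros((128, 128))
        ys, xs = np.mgrid[0:128, 0:128].astype(float)
        for cx, cy in ((5.0, 6.0), (7.0, 6.0)):  # 2 μm apart
            img += 100 * np.exp(-(((xs * px - cx) ** 2 + (ys * px - cy) ** 2)
                                  / (2 * sigma_um ** 2)))
        spots = detect_spots(img, px)
        assert len(spots) == 2
        sep = math.hypot(spots[0].x_um - spots[1].x_um,
                         spots[0].y_um - spots[1].y_um)
        assert sep == pytest.approx(2.0, abs=0.05)

    def test_blank_and_noisy_blank_images(self, rng):
        assert detect_spots(np.zeros((64, 64)), 0.1) == []
        noisy = rng.normal(100, 5, size=(128, 128))
        assert detect_spots(noisy, 0.1) == []

    def test_recall_precision_one_on_noiseless_fields(self, noiseless_set,
                                                      noiseless_config):
        stacks, gt = noiseless_set
        px = noiseless_config.pixel_size_um
        for f, stack in enumerate(stacks):
            true = gt.cells[gt.cells["field"] == f]
            tx = np.concatenate([true["d1x_um"], true["d2x_um"].dropna()])
            ty = np.concatenate([true["d1y_um"], true["d2y_um"].dropna()])
            spots = detect_spots(max_project(stack)["PCNT"], px)
            assert len(spots) == len(tx)  # recall and precision both 1
            for s in spots:
                assert np.hypot(tx - s.x_um, ty - s.y_um).min() < 0.05


class TestPairMarkers:
    def test_unmatched_pcnt_is_not_dual_positive(self):
        structures = pair_markers([_spot(1.0, 1.0)], [], radius_um=0.5)
        assert len(structures) == 1
        assert not structures[0].dual_positive

    def test_coincident_spots_merge_at_midpoint(self):
        structures = pair_markers([_spot(1.0, 2.0)],
                                  [_spot(1.1, 2.0, "GTUB")], radius_um=0.5)
        assert len(structures) == 1
        s = structures[0]
        assert s.dual_positive
        assert s.x_um == pytest.approx(1.05)
        assert s.y_um == pytest.approx(2.0)

    def test_matches_brute_force_mutual_nn(self, rng):
        """Crossing geometries agree with an exhaustive mutual-NN oracle."""
        for _ in range(25):
            p = [_spot(x, y) for x, y in rng.uniform(0, 4, size=(3, 2))]
            g = [_spot(x, y, "GTUB") for x, y in rng.uniform(0, 4, size=(3, 2))]
            got = {(s.pcnt_index, s.gtub_index)
                   for s in pair_markers(p, g, radius_um=1.0)
                   if s.dual_positive}
            # oracle: all-pairs scan for mutual nearest neighbors
            d = np.array([[math.hypot(a.x_um - b.x_um, a.y_um - b.y_um)
                           for b in g] for a in p])
            expected = set()
            for i in range(3):
                for j in range(3):
                    if (d[i, j] <= 1.0 and d[i, j] == d[i, :].min()
                            and d[i, j] == d[:, j].min()):
                        expected.add((i, j))
            assert got == expected

    def test_symmetric_in_channel_order(self, rng):
        p = [_spot(x, y) for x, y in rng.uniform(0, 3, size=(4, 2))]
        g = [_spot(x, y, "GTUB") for x, y in rng.uniform(0, 3, size=(4, 2))]
        fwd = {(s.pcnt_index, s.gtub_index)
               for s in pair_markers(p, g, 0.8) if s.dual_positive}
        rev = {(s.gtub_index, s.pcnt_index)
               for s in pair_markers(g, p, 0.8) if s.dual_positive}
        assert fwd == rev

    def test_single_marker_mode_counts_every_spot(self):
        spots = [_spot(0, 0), _spot(1, 1)]
        structures = pcnt_structures(spots)
        assert len(structures) == 2
        assert all(not s.dual_positive for s in structures)


def _disk_nucleus(label, cx_px, cy_px, r_px, shape, px):
    mask_full = np.zeros(shape, dtype=bool)
    ys, xs = np.mgrid[0:shape[0], 0:shape[1]]
    mask_full[(xs - cx_px) ** 2 + (ys - cy_px) ** 2 <= r_px ** 2] = True
    rows, cols = np.nonzero(mask_full)
    sl = (slice(rows.min(), rows.max() + 1), slice(cols.min(), cols.max() + 1))
    return NucleusRegion(
        label=label, slice_yx=sl, mask=mask_full[sl],
        centroid_um=(cx_px * px, cy_px * px),
        equivalent_diameter_um=2 * r_px * px,
        area_um2=math.pi * (r_px * px) ** 2, solidity=1.0, mean_dapi=1.0,
        touches_border=False, mitotic=False)


def _structure(x, y):
    return CentrosomalStructure(x_um=x, y_um=y, pcnt_index=0, gtub_index=None,
                                dual_positive=False)


class TestAssembleCells:
    px = 0.1

    def test_structure_inside_nucleus(self):
        n = _disk_nucleus(1, 50, 50, 20, (100, 100), self.px)
        asm, dropped = assemble_cells([n], [_structure(5.0, 5.0)], self.px)
        assert dropped == 0
        assert len(asm[0].structures) == 1

    def test_equidistant_tie_goes_to_lower_label(self):
        a = _disk_nucleus(1, 30, 50, 10, (100, 200), self.px)
        b = _disk_nucleus(2, 130, 50, 10, (100, 200), self.px)
        # exactly midway between the two identical disks
        asm, dropped = assemble_cells([a, b], [_structure(8.0, 5.0)], self.px)
        assert len(asm[0].structures) == 1
        assert len(asm[1].structures) == 0

    def test_distant_structure_dropped(self):
        n = _disk_nucleus(1, 20, 20, 10, (256, 256), self.px)
        asm, dropped = assemble_cells([n], [_structure(20.0, 20.0)], self.px,
                                      max_distance_um=5.0)
        assert dropped == 1
        assert asm[0].structures == []

    def test_ground_truth_membership_recovered(self, noiseless_set,
                                               noiseless_config):
        stacks, gt = noiseless_set
        px = noiseless_config.pixel_size_um
        for f, stack in enumerate(stacks):
            proj = max_project(stack)
            nuclei = segment_nuclei(proj["DAPI"], px)
            structures = pcnt_structures(detect_spots(proj["PCNT"], px))
            asm, dropped = assemble_cells(nuclei, structures, px)
            assert dropped == 0
            true = gt.cells[gt.cells["field"] == f]
            for a in asm:
                d = np.hypot(true["x_um"] - a.nucleus.centroid_um[0],
                             true["y_um"] - a.nucleus.centroid_um[1])
                row = true.loc[d.idxmin()]
                assert len(a.structures) == row["n_dots"]
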
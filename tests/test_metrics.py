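"""Segmentation metrics, skeletonization and vascular descriptors."""
import dataclasses

import networkx as nx
import numpy as np
import pytest
from scipy import ndimage

from vangan.metrics import (ConfusionCounts, betti_numbers, confusion,
                            descriptors, seg_metrics, skeletonize)
from vangan.vessel_synth import BinaryMask3D, VesselGraph, voxelize


def brute_metrics(pred, truth):
    p, t = pred.astype(bool).ravel(), truth.astype(bool).ravel()
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    tn = int(np.sum(~p & ~t))
    fn = int(np.sum(~p & t))
    return tp, fp, tn, fn


def make_torus(outer=14, tube=4, size=48, depth=16):
    ax = np.arange(size)
    X, Y, Z = np.meshgrid(ax, ax, np.arange(depth), indexing="ij")
    d = (np.sqrt((X - size / 2) ** 2 + (Y - size / 2) ** 2) - outer) ** 2 \
        + (Z - depth / 2) ** 2
    return (d <= tube ** 2).astype(np.uint8)


class TestSegMetrics:
    def test_perfect_prediction(self, rng):
        truth = (rng.random((8, 8, 8)) > 0.7).astype(np.uint8)
        m = seg_metrics(confusion(truth, truth))
        assert m["f1"] == m["iou"] == m["sensitivity"] == 1.0

    def test_all_negative_prediction(self, rng):
        truth = (rng.random((8, 8, 8)) > 0.7).astype(np.uint8)
        m = seg_metrics(confusion(np.zeros_like(truth), truth))
        assert m["sensitivity"] == 0.0
        assert m["specificity"] == 1.0
        assert m["f1"] == 0.0

    def test_worked_confusion_example(self):
        # TP=2, FP=1, FN=1, TN=12: precision 2/3, sensitivity 2/3,
        # F1 = 2*(2/3*2/3)/(4/3) = 2/3, IoU = 2/4 = 1/2
        m = seg_metrics(ConfusionCounts(tp=2, fp=1, tn=12, fn=1))
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["iou"] == pytest.approx(0.5)
        assert m["f1"] == pytest.approx(2 / 3)
        # F1 and IoU are functionally linked: F1 = 2*IoU/(1+IoU)
        assert m["f1"] == pytest.approx(2 * m["iou"] / (1 + m["iou"]))

    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(100):
            pred = (rng.random((8, 8, 8)) > rng.uniform(0.3, 0.9))
            truth = (rng.random((8, 8, 8)) > rng.uniform(0.3, 0.9))
            tp, fp, tn, fn = brute_metrics(pred, truth)
            c = confusion(pred.astype(np.uint8), truth.astype(np.uint8))
            assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)
            m = seg_metrics(c)
            if tp + fp + fn:
                prec = tp / (tp + fp) if tp + fp else 1.0
                sens = tp / (tp + fn) if tp + fn else 1.0
                f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
                assert m["f1"] == pytest.approx(f1)
                assert m["iou"] == pytest.approx(tp / (tp + fp + fn))

    def test_both_empty_conventions(self):
        z = np.zeros((4, 4, 4), np.uint8)
        m = seg_metrics(confusion(z, z))
        assert m["f1"] == 1.0 and m["iou"] == 1.0 and m["sensitivity"] == 1.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion(np.zeros((4, 4, 4)), np.zeros((4, 4, 5)))


class TestSkeleton:
    def test_solid_cylinder_reduces_to_a_path(self):
        cyl = np.zeros((40, 20, 20), np.uint8)
        cyl[4:36, 7:13, 7:13] = 1
        sk = skeletonize(BinaryMask3D(cyl))
        b0, b1 = betti_numbers(sk)
        assert (b0, b1) == (1, 0)
        degrees = np.zeros(sk.n_nodes, int)
        for i, j in sk.edges:
            degrees[i] += 1
            degrees[j] += 1
        assert np.sum(degrees == 1) == 2  # exactly two endpoints
        assert np.all(degrees <= 2)       # a simple path

    def test_torus_has_one_loop(self):
        sk = skeletonize(BinaryMask3D(make_torus()))
        assert betti_numbers(sk) == (1, 1)

    def test_empty_mask_gives_empty_graph(self):
        sk = skeletonize(BinaryMask3D(np.zeros((8, 8, 8), np.uint8)))
        assert sk.n_nodes == 0 and sk.n_edges == 0
        assert betti_numbers(sk) == (0, 0)

    def test_betti_matches_networkx_oracle_on_random_masks(self, rng):
        for _ in range(100):
            m = ndimage.binary_dilation(rng.random((12, 12, 12)) > 0.94)
            sk = skeletonize(BinaryMask3D(m.astype(np.uint8)))
            g = nx.Graph()
            g.add_nodes_from(range(sk.n_nodes))
            g.add_edges_from(sk.edges)
            expected = (nx.number_connected_components(g) if sk.n_nodes
                        else 0, len(nx.cycle_basis(g)))
            assert betti_numbers(sk) == expected

    def test_skeleton_components_match_mask_components(self, rng):
        for _ in range(20):
            m = ndimage.binary_dilation(rng.random((14, 14, 14)) > 0.93)
            sk = skeletonize(BinaryMask3D(m.astype(np.uint8)))
            n_mask = ndimage.label(m, np.ones((3, 3, 3)))[1]
            assert betti_numbers(sk)[0] == n_mask

    def test_radii_reflect_tube_thickness(self):
        cyl = np.zeros((30, 21, 21), np.uint8)
        cyl[3:27, 7:14, 7:14] = 1  # half-width ~3.5 voxels
        sk = skeletonize(BinaryMask3D(cyl, voxel_size_um=20.0))
        mid = sk.radii_um[(sk.coords[:, 0] > 8) & (sk.coords[:, 0] < 22)]
        assert 40.0 <= np.median(mid) <= 90.0


class TestDescriptors:
    def test_two_disjoint_vessels_with_two_to_one_volume(self):
        # square-section vessels of identical cross-section, lengths 2:1
        m = np.zeros((50, 50, 50), np.uint8)
        m[10:42, 10:14, 20:24] = 1   # 32 voxels long
        m[10:26, 36:40, 20:24] = 1   # 16 voxels long
        both = BinaryMask3D(m)
        sk = skeletonize(both)
        d = descriptors(sk, both, tissue_volume_mm3=1.0)
        assert d.cc_density_per_mm3 == pytest.approx(2.0)
        assert d.loop_density_per_mm3 == 0.0
        assert d.connectivity_pct == pytest.approx(100 * 2 / 3)

    def test_single_loop_counts_once(self):
        mask = BinaryMask3D(make_torus())
        d = descriptors(skeletonize(mask), mask, tissue_volume_mm3=2.0)
        assert d.loop_density_per_mm3 == pytest.approx(0.5)

    def test_uniform_tube_has_small_diameter_spread(self):
        cyl = np.zeros((40, 15, 15), np.uint8)
        cyl[4:36, 5:10, 5:10] = 1
        mask = BinaryMask3D(cyl)
        d = descriptors(skeletonize(mask), mask, tissue_volume_mm3=1.0)
        mean_diam = 2 * np.mean(skeletonize(mask).radii_um)
        assert d.diameter_sd_um < 0.35 * mean_diam

    def test_network_volume_and_surface_density_units(self):
        cube = np.zeros((10, 10, 10), np.uint8)
        cube[2:7, 2:7, 2:7] = 1  # 5^3 voxels at 20 um
        mask = BinaryMask3D(cube)
        d = descriptors(skeletonize(mask), mask, tissue_volume_mm3=8.0)
        assert d.network_volume_mm3 == pytest.approx(125 * (0.02 ** 3))
        # cube surface: 6 faces of 25 voxels at (0.02 mm)^2
        assert d.surface_density_per_mm == pytest.approx(
            6 * 25 * 0.02 ** 2 / 8.0)

    def test_empty_skeleton_gives_zero_descriptors(self):
        empty = BinaryMask3D(np.zeros((6, 6, 6), np.uint8))
        d = descriptors(skeletonize(empty), empty, 1.0)
        assert all(v == 0.0 for v in dataclasses.asdict(d).values())

    def test_descriptors_invariant_under_rotation_and_flip(self):
        mask = make_torus(outer=10, tube=3, size=32, depth=32)
        base = BinaryMask3D(mask)
        d0 = descriptors(skeletonize(base), base, 1.0)
        for transform in (lambda m: np.rot90(m, axes=(0, 1)).copy(),
                          lambda m: m[::-1].copy()):
            m2 = BinaryMask3D(transform(mask))
            d2 = descriptors(skeletonize(m2), m2, 1.0)
            assert d2.cc_density_per_mm3 == d0.cc_density_per_mm3
            assert d2.loop_density_per_mm3 == d0.loop_density_per_mm3
            assert d2.network_volume_mm3 == pytest.approx(
                d0.network_volume_mm3)
            assert d2.surface_density_per_mm == pytest.approx(
                d0.surface_density_per_mm)
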
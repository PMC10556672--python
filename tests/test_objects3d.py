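"""3D object modelling: preprocessing, segmentation, measurement, LD-plastid distance."""

import math

import numpy as np
import pytest

from conftest import make_sphere_stack
from ldscope import objects3d
from ldscope.objects3d import (
    ChannelParams,
    Object3D,
    exclude_outside_cell,
    ld_plastid_distance,
    measure_objects,
    model_cell,
    preprocess_channel,
    segment_objects,
)

VOXEL = (0.072, 0.072, 0.1)


class TestPreprocess:
    def test_constant_stack_becomes_zero(self):
        stack = np.full((20, 20, 20), 7.0)
        out = preprocess_channel(stack, ChannelParams(0.3, 0.2), VOXEL)
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_sphere_integral_roughly_preserved(self):
        stack = make_sphere_stack([0.8], [(3.0, 3.0, 3.0)])
        out = preprocess_channel(stack, ChannelParams(0.1, 0.4), VOXEL)
        assert out.sum() == pytest.approx(stack.sum(), rel=0.1)

    def test_point_source_spreads_with_requested_sigma(self):
        stack = np.zeros((40, 40, 40))
        stack[20, 20, 20] = 1.0
        smooth = 0.3
        out = preprocess_channel(stack, ChannelParams(smooth, 10.0), VOXEL,
                                 baseline_sigma_um=50.0)
        profile = out[20, 20, :]
        sigma_px = smooth / VOXEL[0]
        x = np.arange(40) - 20
        measured_sigma = math.sqrt((profile * x * x).sum() / profile.sum())
        assert measured_sigma == pytest.approx(sigma_px, rel=0.15)

    def test_default_params_match_study_values(self):
        assert ChannelParams.for_channel("thylakoid").smooth_um == 0.3
        assert ChannelParams.for_channel("thylakoid").background_um == 0.2
        assert ChannelParams.for_channel("LD", "Pt1").background_um == 0.2
        assert ChannelParams.for_channel("LD", "Pt4").background_um == 0.4


class TestSegmentation:
    def test_two_separated_spheres_two_labels(self):
        stack = make_sphere_stack([0.5, 0.5], [(1.5, 1.5, 1.5), (4.5, 4.5, 4.5)])
        labels = segment_objects(stack, threshold=10.0, voxel_size_um=VOXEL)
        assert labels.max() == 2

    def test_touching_spheres_split_flag(self):
        # ~10 % volume overlap: centers 1.75 r apart
        r = 0.5
        centers = [(2.3, 3.0, 3.0), (2.3 + 1.75 * r, 3.0, 3.0)]
        stack = make_sphere_stack([r, r], centers)
        split = segment_objects(stack, threshold=10.0, split_touching=True,
                                voxel_size_um=VOXEL)
        merged = segment_objects(stack, threshold=10.0, split_touching=False,
                                 voxel_size_um=VOXEL)
        assert split.max() == 2
        assert merged.max() == 1

    def test_k_planted_spheres_recovered_exactly(self):
        """Watershed splitting returns k objects for k touching spheres."""
        r = 0.45
        d = 1.8 * r
        centers = [(2.0 + i * d, 3.0, 3.0) for i in range(5)]
        stack = make_sphere_stack([r] * 5, centers, shape_um=(8, 6, 6))
        labels = segment_objects(stack, threshold=10.0, split_touching=True,
                                 voxel_size_um=VOXEL)
        assert labels.max() == 5

    def test_empty_foreground(self):
        labels = segment_objects(np.zeros((10, 10, 10)), threshold=1.0)
        assert labels.max() == 0

    def test_planted_sphere_volume_within_15pct(self):
        r = 0.62  # ~1.0 um^3
        stack = make_sphere_stack([r], [(3.0, 3.0, 3.0)])
        pre = preprocess_channel(stack, ChannelParams(0.1, 0.4), VOXEL)
        labels = segment_objects(pre, voxel_size_um=VOXEL)
        objs = measure_objects(labels, VOXEL)
        true_vol = 4.0 / 3.0 * math.pi * r ** 3
        assert len(objs) == 1
        assert objs[0].volume_um3 == pytest.approx(true_vol, rel=0.15)


class TestExclusion:
    def _labels(self):
        labels = np.zeros((10, 10, 10), dtype=np.int32)
        labels[2:4, 2:4, 2:4] = 1
        labels[7:9, 7:9, 7:9] = 2
        return labels

    def test_all_inside_is_identity(self):
        labels = self._labels()
        mask = np.ones_like(labels, bool)
        assert np.array_equal(exclude_outside_cell(labels, mask), labels)

    def test_outside_object_removed_and_relabelled(self):
        labels = self._labels()
        mask = np.zeros_like(labels, bool)
        mask[:5] = True  # only object 1's region
        out = exclude_outside_cell(labels, mask)
        assert out.max() == 1
        assert (out[2:4, 2:4, 2:4] == 1).all()

    def test_straddling_object_kept_if_barycenter_inside(self):
        labels = np.zeros((10, 10, 10), dtype=np.int32)
        labels[3:8, 4:6, 4:6] = 1  # spans the z=5 boundary
        mask = np.zeros_like(labels, bool)
        mask[:6] = True  # barycenter at z=5 -> inside
        out = exclude_outside_cell(labels, mask)
        assert out.max() == 1


class TestMeasurement:
    def test_single_voxel_volume_and_center_convention(self):
        labels = np.zeros((5, 5, 5), dtype=np.int32)
        labels[0, 0, 0] = 1
        obj = measure_objects(labels, (0.1, 0.1, 0.1))[0]
        assert obj.volume_um3 == pytest.approx(0.001)
        assert obj.barycenter_um == pytest.approx((0.05, 0.05, 0.05))

    def test_sphere_barycenter_at_center(self):
        stack = make_sphere_stack([0.5], [(3.0, 3.0, 3.0)])
        labels = segment_objects(stack, threshold=10.0, voxel_size_um=VOXEL)
        obj = measure_objects(labels, VOXEL)[0]
        assert np.allclose(obj.barycenter_um, (3.0, 3.0, 3.0),
                           atol=0.5 * max(VOXEL))

    def test_two_voxel_object_barycenter_midway(self):
        labels = np.zeros((4, 4, 4), dtype=np.int32)
        labels[1, 1, 1:3] = 1
        obj = measure_objects(labels, (0.1, 0.1, 0.1))[0]
        assert obj.barycenter_um[0] == pytest.approx(0.2)


class TestDistance:
    def _obj(self, x, y, z):
        return Object3D(1, "LD", 1, 1.0, (x, y, z))

    def test_identity_and_symmetry(self):
        a, b = self._obj(1, 2, 3), self._obj(4, 6, 3)
        assert ld_plastid_distance(a, a) == 0.0
        assert ld_plastid_distance(a, b) == ld_plastid_distance(b, a)

    def test_3_4_5_triangle(self):
        a, b = self._obj(0, 0, 0), self._obj(3, 4, 0)
        assert ld_plastid_distance(a, b) == 5.0

    def test_machine_precision_against_direct_formula(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            p, q = rng.uniform(-30, 30, (2, 3))
            a, b = self._obj(*p), self._obj(*q)
            brute = math.sqrt(sum((x - y) ** 2 for x, y in zip(p, q)))
            assert ld_plastid_distance(a, b) == brute


class TestModelCell:
    def test_single_thylakoid_and_lds_recovered(self, small_stack):
        cfg, stack, mask, truth = small_stack
        rec = model_cell(stack, mask, ecotype="Pt4", voxel_size_um=VOXEL)
        assert rec.thylakoid is not None
        assert rec.thylakoid.channel == "thylakoid"
        # per-cell total LD volume close to planted truth
        meas = sum(o.volume_um3 for o in rec.lds)
        true = truth.lds.volume_um3.sum()
        assert meas == pytest.approx(true, rel=0.15)

    def test_volume_conservation_bound(self, small_stack):
        cfg, stack, mask, truth = small_stack
        rec = model_cell(stack, mask, ecotype="Pt4", voxel_size_um=VOXEL)
        stack_vol = np.prod(stack.shape[1:]) * VOXEL[0] * VOXEL[1] * VOXEL[2]
        total = sum(o.volume_um3 for o in rec.lds) + rec.thylakoid.volume_um3
        assert total <= stack_vol
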
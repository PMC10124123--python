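import math
import warnings

import numpy as np
import pytest

from mixcount.detect import (
    Component,
    ConfigurationError,
    ImageFrame,
    decluster,
    detect_frame,
    estimate_background,
    filter_objects,
    label_components,
    measure,
    threshold_mask,
)
from mixcount.profiles import CountingProfile, builtin_profile

from conftest import make_disk, make_rod, uniform_frame


class TestEstimateBackground:
    def test_uniform(self):
        assert estimate_background(uniform_frame(123)) == 123

    def test_sparse_objects(self, make_frame):
        # objects cover <5% of the field; the median sees background
        frame = make_frame(
            [make_disk(20 + 15 * i, 30) for i in range(4)],
            background=0.1, noise_sd=0.01,
        )
        bg = estimate_background(frame)
        assert bg == pytest.approx(0.1 * 65535, rel=0.02)

    def test_saturated_warns(self):
        with pytest.warns(UserWarning, match="saturated"):
            bg = estimate_background(uniform_frame(65535))
        assert bg == 65535


class TestThresholdMask:
    def test_flat_frame_empty_mask(self, bacteria_profile):
        assert not threshold_mask(uniform_frame(500), bacteria_profile).any()

    def test_noise_only_frame_empty_mask(self, bacteria_profile):
        rng = np.random.default_rng(0)
        pixels = np.clip(rng.normal(3000, 300, (200, 200)), 0, 65535).astype(np.uint16)
        frame = ImageFrame(pixels=pixels, pixel_area=0.5)
        assert not threshold_mask(frame, bacteria_profile).any()

    def test_disk_mask_area_matches_rasterization_oracle(self, make_frame, optics):
        # independent oracle: recompute per-pixel coverage of the disk at
        # 32x subsampling and count pixels whose rendered value clears the
        # threshold cut
        d, peak, bg, thr = 6.0, 0.8, 0.1, 10.0
        frame = make_frame([make_disk(50, 50, diameter=d, peak=peak)],
                           background=bg, noise_sd=0.0)
        mask = threshold_mask(frame, builtin_profile("mixed_bacteria"))

        side = optics.pixel_side_um
        n = frame.pixels.shape[0]
        sub = 32
        coords = (np.arange(n * sub) + 0.5) / sub * side
        rr = coords[:, None]
        cc = coords[None, :]
        inside = (rr - 50) ** 2 + (cc - 50) ** 2 <= (d / 2) ** 2
        coverage = inside.reshape(n, sub, n, sub).mean(axis=(1, 3))
        value = bg + peak * coverage
        fmax = value.max()
        cut = bg + (thr / 100.0) * (fmax - bg)
        oracle_area = (value > cut).sum()
        assert mask.sum() == pytest.approx(oracle_area, rel=0.10)

    def test_threshold_100_keeps_only_maximum(self):
        pixels = np.zeros((20, 20), dtype=np.uint16)
        pixels[5, 5] = 60000
        pixels[10, 10] = 60000
        pixels[15, 15] = 30000
        frame = ImageFrame(pixels=pixels, pixel_area=0.5)
        profile = CountingProfile(0.5, 5.0, 0.0, 100.0, 0.9)
        mask = threshold_mask(frame, profile)
        assert mask.sum() == 2
        assert mask[5, 5] and mask[10, 10] and not mask[15, 15]


def _flood_fill_oracle(mask):
    """Brute-force BFS flood fill, 8-connectivity. Independent oracle."""
    h, w = mask.shape
    lab = np.zeros((h, w), dtype=int)
    nxt = 0
    for r in range(h):
        for c in range(w):
            if mask[r, c] and lab[r, c] == 0:
                nxt += 1
                stack = [(r, c)]
                lab[r, c] = nxt
                while stack:
                    rr, cc = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            r2, c2 = rr + dr, cc + dc
                            if (
                                0 <= r2 < h and 0 <= c2 < w
                                and mask[r2, c2] and lab[r2, c2] == 0
                            ):
                                lab[r2, c2] = nxt
                                stack.append((r2, c2))
    return lab


class TestLabelComponents:
    def test_two_separated_disks(self, make_frame, bacteria_profile):
        frame = make_frame([make_disk(30, 30), make_disk(70, 70)],
                           background=0.05, noise_sd=0.0)
        mask = threshold_mask(frame, bacteria_profile)
        assert len(label_components(mask)) == 2

    def test_diagonal_touching_is_one_object(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[2, 2] = mask[3, 3] = mask[4, 4] = True
        assert len(label_components(mask)) == 1

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = np.zeros((64, 64), dtype=bool)
        # interior-only masks so the border policy is a no-op
        mask[1:-1, 1:-1] = rng.uniform(size=(62, 62)) < 0.3
        comps = label_components(mask)
        oracle = _flood_fill_oracle(mask)
        assert len(comps) == oracle.max()
        for comp in comps:
            labels = set(oracle[comp.rows, comp.cols])
            assert len(labels) == 1  # each component is one oracle region
        covered = np.zeros_like(mask)
        for comp in comps:
            covered[comp.rows, comp.cols] = True
        assert np.array_equal(covered, mask)

    def test_border_policy(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[0:2, 5:8] = True  # centroid on border ring -> dropped
        mask[8:14, 0:5] = True  # touches border, centroid interior -> kept
        comps = label_components(mask)
        assert len(comps) == 1
        assert comps[0].centroid_px[0] == pytest.approx(10.5)


class TestDecluster:
    def _component_from_mask(self, frame, profile):
        mask = threshold_mask(frame, profile)
        return label_components(mask)

    def test_single_disk_idempotent(self, make_frame, yeast_profile):
        frame = make_frame([make_disk(50, 50)], noise_sd=0.0)
        (comp,) = self._component_from_mask(frame, yeast_profile)
        children = decluster(comp, frame, yeast_profile)
        assert len(children) == 1
        child = children[0]
        assert set(zip(child.rows, child.cols)) == set(zip(comp.rows, comp.cols))

    def test_overlapping_disks_split(self, make_frame, yeast_profile, optics):
        # two d=7.5 disks overlapping by 20% of diameter
        frame = make_frame([make_disk(46, 50), make_disk(52, 50)], noise_sd=0.0)
        comps = self._component_from_mask(frame, yeast_profile)
        assert len(comps) == 1
        children = decluster(comps[0], frame, yeast_profile)
        assert len(children) == 2
        # children partition the parent
        parent_px = set(zip(comps[0].rows, comps[0].cols))
        child_px = [set(zip(c.rows, c.cols)) for c in children]
        assert child_px[0].isdisjoint(child_px[1])
        assert child_px[0] | child_px[1] == parent_px
        # ground-truth centers within 1 pixel of the child centroids
        side = optics.pixel_side_um
        centers = sorted(
            ((c.centroid_px[1] + 0.5) * side, (c.centroid_px[0] + 0.5) * side)
            for c in children
        )
        for (cx, cy), (tx, ty) in zip(centers, [(46, 50), (52, 50)]):
            assert math.hypot(cx - tx, cy - ty) < side

    def test_factor_near_zero_never_splits(self, make_frame):
        profile = CountingProfile(6.0, 50.0, 0.0, 8.0, 0.01)
        frame = make_frame([make_disk(46, 50), make_disk(52, 50)], noise_sd=0.0)
        (comp,) = self._component_from_mask(frame, profile)
        assert len(decluster(comp, frame, profile)) == 1

    def test_empty_component_rejected(self, make_frame, yeast_profile):
        frame = make_frame([make_disk(50, 50)], noise_sd=0.0)
        empty = Component(np.array([], dtype=int), np.array([], dtype=int))
        with pytest.raises(ValueError):
            decluster(empty, frame, yeast_profile)

    @pytest.mark.parametrize("seed", range(5))
    def test_children_partition_parent_property(self, seed, sd025_small, mixed_plan,
                                                optics, yeast_profile):
        from mixcount.simulate import render_field, sample_field_truth

        truth = sample_field_truth(
            4e7, 0, sd025_small, mixed_plan, seed=seed, cluster_fraction=0.5
        )
        frame = render_field(truth, optics, "total", noise_sd=0.005, seed=seed + 100)
        mask = threshold_mask(frame, yeast_profile)
        for comp in label_components(mask):
            children = decluster(comp, frame, yeast_profile)
            parent_px = set(zip(comp.rows, comp.cols))
            seen = set()
            for child in children:
                px = set(zip(child.rows, child.cols))
                assert px and px.isdisjoint(seen)
                seen |= px
            assert seen == parent_px


class TestMeasure:
    def test_disk_diameter_and_roundness(self, make_frame, yeast_profile):
        frame = make_frame([make_disk(50, 50, diameter=6.0)], noise_sd=0.0)
        mask = threshold_mask(frame, yeast_profile)
        objs = measure(label_components(mask), frame)
        assert len(objs) == 1
        assert objs[0].equivalent_diameter_um == pytest.approx(6.0, rel=0.10)
        assert objs[0].roundness >= 0.85

    def test_single_pixel_object(self):
        pixels = np.zeros((9, 9), dtype=np.uint16)
        pixels[4, 4] = 1000
        frame = ImageFrame(pixels=pixels, pixel_area=0.5)
        comp = Component(np.array([4]), np.array([4]))
        (obj,) = measure([comp], frame)
        assert obj.area_um2 == pytest.approx(0.5)
        # 2*sqrt(0.5/pi) = 0.7978845608
        assert obj.equivalent_diameter_um == pytest.approx(0.7978845608, abs=1e-9)
        assert 0 <= obj.roundness <= 1

    def test_invariant_area_diameter_relation(self, make_frame, yeast_profile):
        frame = make_frame(
            [make_disk(30, 30), make_disk(70, 60, diameter=9.0)], noise_sd=0.0
        )
        mask = threshold_mask(frame, yeast_profile)
        for obj in measure(label_components(mask), frame):
            assert obj.area_um2 == pytest.approx(obj.pixel_count * 0.5)
            assert obj.equivalent_diameter_um == pytest.approx(
                2 * math.sqrt(obj.area_um2 / math.pi)
            )
            assert 0 <= obj.roundness <= 1

    def test_overlapping_objects_rejected(self, make_frame):
        frame = make_frame([make_disk(50, 50)], noise_sd=0.0)
        comp = Component(np.array([3, 4]), np.array([3, 4]))
        dup = Component(np.array([4, 5]), np.array([4, 5]))
        with pytest.raises(ValueError, match="disjoint"):
            measure([comp, dup], frame)


class TestFilterObjects:
    def _obj(self, eqd, roundness=0.9):
        from mixcount.detect import DetectedObject

        area = math.pi * (eqd / 2) ** 2
        return DetectedObject(
            object_id=1, pixel_count=1, area_um2=area,
            equivalent_diameter_um=eqd, roundness=roundness,
            perimeter_um=1.0, centroid_x_um=0, centroid_y_um=0,
            mean_intensity=0, peak_intensity=0,
        )

    def test_boundary_exclusion(self, yeast_profile):
        assert filter_objects([self._obj(5.9)], yeast_profile) == []
        kept = filter_objects([self._obj(6.0)], yeast_profile)
        assert len(kept) == 1  # inclusive bound

    def test_bacteria_gate_keeps_small(self, bacteria_profile):
        assert len(filter_objects([self._obj(3.0)], bacteria_profile)) == 1

    def test_roundness_zero_never_excludes(self, yeast_profile):
        objs = [self._obj(10.0, roundness=0.0)]
        assert len(filter_objects(objs, yeast_profile)) == 1

    @pytest.mark.parametrize("seed", range(3))
    def test_widening_gate_is_monotone(self, seed):
        rng = np.random.default_rng(seed)
        objs = [self._obj(float(d)) for d in rng.uniform(0.5, 12, 50)]
        narrow = CountingProfile(2.0, 6.0, 0.0, 10.0, 0.9)
        wide = CountingProfile(1.0, 8.0, 0.0, 10.0, 0.9)
        assert len(filter_objects(objs, wide)) >= len(filter_objects(objs, narrow))

    def test_order_preserved(self, bacteria_profile):
        objs = [self._obj(1.0), self._obj(9.0), self._obj(2.0)]
        kept = filter_objects(objs, bacteria_profile)
        assert [o.equivalent_diameter_um for o in kept] == [1.0, 2.0]


class TestImageFrameValidation:
    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            ImageFrame(pixels=np.full((4, 4), -1.0), pixel_area=0.5)

    def test_excess_bit_depth_rejected(self):
        with pytest.raises(ValueError):
            ImageFrame(pixels=np.full((4, 4), 70000, dtype=np.uint32),
                       pixel_area=0.5, bit_depth=16)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ImageFrame(pixels=np.empty((0, 0)), pixel_area=0.5)


def test_detect_frame_recovers_rod_and_disk(make_frame, yeast_profile, bacteria_profile):
    frame = make_frame(
        [make_disk(30, 30), make_rod(70, 70, theta=0.7)], noise_sd=0.005
    )
    yeast = detect_frame(frame, yeast_profile)
    bacteria = detect_frame(frame, bacteria_profile)
    assert len(yeast) == 1 and len(bacteria) == 1
    assert yeast[0].equivalent_diameter_um > 6
    assert bacteria[0].equivalent_diameter_um < 5
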
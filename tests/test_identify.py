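"""Component labeling, stitching, descriptors, classification, gating."""

import numpy as np
import pytest

from ndnt.identify import (
    ComponentRecord,
    FilterRule,
    classify_components,
    extract_records,
    keep_largest_components,
    label_components,
    morphological_cleanup,
    overlap_filter,
    stitch_2d_components,
)
from ndnt.synthetic import SphereSpec, PhantomSpec, generate_phantom

from conftest import flood_fill_components, partitions_equal, random_mask


def _blob(shape, sl, value=True):
    m = np.zeros(shape, bool)
    m[sl] = value
    return m


class TestCleanup:
    def test_undersized_blob_removed(self):
        m = _blob((5, 5, 5), (slice(0, 2), slice(0, 5), slice(0, 1)))  # 10 voxels
        assert not morphological_cleanup(m, min_size=11).any()

    def test_identity_with_no_ops(self, rng):
        m = random_mask(rng, (6, 6), 0.3)
        assert np.array_equal(morphological_cleanup(m, 0, []), m)

    def test_size_filter_keeps_large_blob_only(self):
        m = np.zeros((4, 10, 10), bool)
        m[0, 0:1, 0:5] = True  # 5 voxels
        m[2:4, 3:8, 3:8] = True  # 50 voxels
        out = morphological_cleanup(m, min_size=10)
        labels, k = label_components(out)
        assert k == 1 and out.sum() == 50

    def test_dilate_then_erode_closes_gap(self):
        m = np.zeros((3, 9), bool)
        m[:, 2] = m[:, 4] = True
        out = morphological_cleanup(m, 0, [("dilate", 1), ("erode", 1)])
        assert out[1, 3]  # the one-pixel gap between the bars is closed

    def test_min_size_monotone_in_component_count(self, rng):
        m = random_mask(rng, (12, 12), 0.35)
        counts = [label_components(morphological_cleanup(m, s))[1] for s in (0, 2, 4, 8)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestLabeling:
    def test_corner_touching_voxels_by_connectivity(self):
        m = np.zeros((2, 2), bool)
        m[0, 0] = m[1, 1] = True
        assert label_components(m, "face")[1] == 2
        assert label_components(m, "full")[1] == 1

    def test_empty_mask(self):
        assert label_components(np.zeros((3, 3, 3), bool))[1] == 0

    @pytest.mark.parametrize("connectivity", ["face", "face+edge", "full"])
    def test_matches_flood_fill_oracle(self, rng, connectivity):
        m = random_mask(rng, (10, 10, 10), 0.15)
        labels, k = label_components(m, connectivity)
        oracle_labels, oracle_k = flood_fill_components(m, connectivity)
        assert k == oracle_k
        assert partitions_equal(labels, oracle_labels)


class TestStitching:
    def test_identical_disk_in_every_slice_is_one_object(self):
        disk = np.zeros((9, 9), int)
        disk[3:6, 3:6] = 1
        labels, k = stitch_2d_components([disk] * 5)
        assert k == 1 and (labels[labels > 0] == 1).all()

    def test_disjoint_columns_stay_separate(self):
        sl = np.zeros((6, 12), int)
        sl[2:4, 1:4] = 1
        sl[2:4, 8:11] = 2
        labels, k = stitch_2d_components([sl] * 4)
        assert k == 2

    def test_min_overlap_gate(self):
        a = np.zeros((4, 4), int)
        b = np.zeros((4, 4), int)
        a[0, 0:2] = 1
        b[0, 1:3] = 1  # overlap of exactly one pixel
        assert stitch_2d_components([a, b], min_overlap_voxels=1)[1] == 1
        assert stitch_2d_components([a, b], min_overlap_voxels=2)[1] == 2

    def test_transitive_merging_across_slices(self):
        # objects A-B overlap in slices 0-1, B-C in 1-2: one 3D object
        s0 = np.zeros((5, 5), int)
        s1 = np.zeros((5, 5), int)
        s2 = np.zeros((5, 5), int)
        s0[0, 0:2] = 1
        s1[0, 1:4] = 1
        s2[0, 3:5] = 1
        assert stitch_2d_components([s0, s1, s2])[1] == 1

    def test_matches_3d_labeling_on_random_masks(self, rng):
        for _ in range(5):
            m = random_mask(rng, (6, 12, 12), 0.25)
            per_slice = [label_components(m[z], "face")[0] for z in range(m.shape[0])]
            stitched, _ = stitch_2d_components(per_slice, 1)
            direct, _ = label_components(m, "face")
            assert partitions_equal(stitched, direct)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            stitch_2d_components([np.zeros((3, 3), int), np.zeros((4, 4), int)])


class TestRecords:
    def test_single_voxel_record(self):
        labels = np.zeros((5, 6, 7), int)
        labels[2, 3, 4] = 1
        src = np.arange(5 * 6 * 7).reshape(5, 6, 7)
        (rec,) = extract_records(labels, src)
        assert rec.centroid == (2.0, 3.0, 4.0)
        assert rec.voxel_count == 1 and rec.elongation == 1.0
        assert rec.mean_intensity == src[2, 3, 4]
        assert rec.bbox_min == (2, 3, 4) and rec.bbox_max == (3, 4, 5)

    def test_axis_aligned_segment_orientation(self):
        labels = np.zeros((3, 3, 11), int)
        labels[1, 1, 1:10] = 1
        (rec,) = extract_records(labels, np.ones((3, 3, 11)))
        assert abs(rec.orientation[2]) == pytest.approx(1.0)
        assert rec.elongation == float("inf")

    def test_planted_ellipsoid_orientation_and_centroid(self):
        zz, yy, xx = np.mgrid[0:21, 0:21, 0:41]
        # major axis along x, centered at (10, 10, 20)
        ell = ((zz - 10) / 4) ** 2 + ((yy - 10) / 4) ** 2 + ((xx - 20) / 15) ** 2 <= 1
        labels = ell.astype(int)
        (rec,) = extract_records(labels, np.ones(labels.shape))
        angle = np.degrees(np.arccos(abs(rec.orientation[2])))
        assert angle < 5.0
        assert np.allclose(rec.centroid, (10, 10, 20), atol=0.5)
        assert rec.elongation > 5

    def test_histogram_normalized_and_conserved(self, rng):
        mask = random_mask(rng, (8, 8, 8), 0.3)
        labels, k = label_components(mask)
        src = rng.integers(0, 256, size=mask.shape).astype(np.uint8)
        records = extract_records(labels, src)
        assert len(records) == k
        assert sum(r.voxel_count for r in records) == np.count_nonzero(labels)
        for r in records:
            assert sum(r.intensity_histogram) == pytest.approx(1.0)
            assert all(a <= c < b for a, c, b in zip(r.bbox_min, r.centroid, r.bbox_max))


class TestClassification:
    RULES = [
        FilterRule("cell", {"voxel_count": (50, 5000), "elongation": (1, 3)}, priority=1),
        FilterRule("vasculature", {"elongation": (5, float("inf"))}, priority=0),
    ]

    def _rec(self, **kw):
        base = dict(id=1, voxel_count=100, elongation=1.2, mean_intensity=80.0)
        base.update(kw)
        return ComponentRecord(**base)

    def test_sphere_classified_as_cell(self):
        (rec,) = classify_components([self._rec()], self.RULES)
        assert rec.class_label == "cell"

    def test_elongated_tube_classified_as_vasculature(self):
        (rec,) = classify_components([self._rec(voxel_count=100000, elongation=40)], self.RULES)
        assert rec.class_label == "vasculature"

    def test_priority_orders_rule_evaluation(self):
        # matches both rules: the lower priority number wins
        rules = [
            FilterRule("a", {"voxel_count": (0, 1e9)}, priority=5),
            FilterRule("b", {"voxel_count": (0, 1e9)}, priority=2),
        ]
        (rec,) = classify_components([self._rec()], rules)
        assert rec.class_label == "b"

    def test_default_policies(self):
        rec = self._rec(voxel_count=10, elongation=1.0)
        assert classify_components([rec], self.RULES, "keep_unassigned")[0].class_label == "unassigned"
        assert classify_components([rec], self.RULES, "discard")[0].class_label == "discarded"

    def test_duplicate_priorities_rejected(self):
        rules = [
            FilterRule("a", {"voxel_count": (0, 1)}, priority=0),
            FilterRule("b", {"voxel_count": (0, 1)}, priority=0),
        ]
        with pytest.raises(ValueError):
            classify_components([self._rec()], rules)

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            FilterRule("a", {"voxel_count": (5, 1)})

    def test_planted_classes_recovered_without_confusion(self):
        spec = PhantomSpec(
            shape=(24, 48, 48),
            background=140.0,
            noise_sigma=0.0,
            cells=SphereSpec(count=5, radius=(3, 4), offset=-60.0),
            bright_cells=SphereSpec(count=4, radius=(3, 4), offset=60.0),
            seed=7,
        )
        ph = generate_phantom(spec)
        records = extract_records(ph.truth_labels, ph.volume)
        rules = [
            FilterRule("cell", {"mean_intensity": (0, 110)}, priority=0),
            FilterRule("bright_cell", {"mean_intensity": (170, 255)}, priority=1),
        ]
        classify_components(records, rules)
        for rec in records:
            assert rec.class_label == ph.truth_classes[rec.id]


class TestGatingAndSelection:
    def test_full_gate_is_identity_up_to_relabeling(self, rng):
        labels, k = label_components(random_mask(rng, (8, 8), 0.3))
        out, k2 = overlap_filter(labels, np.ones_like(labels, bool), 1)
        assert k2 == k and partitions_equal(out, labels)

    def test_empty_gate_removes_everything(self, rng):
        labels, _ = label_components(random_mask(rng, (8, 8), 0.3))
        out, k = overlap_filter(labels, np.zeros_like(labels, bool), 1)
        assert k == 0 and not out.any()

    def test_gate_selects_overlapping_tube_only(self):
        labels = np.zeros((4, 10, 10), int)
        labels[:, 2, :] = 1  # tube A
        labels[:, 7, :] = 2  # tube B
        gate = np.zeros_like(labels, bool)
        gate[:, 6:9, :] = True  # tube B dilated by 1
        out, k = overlap_filter(labels, gate, 1)
        assert k == 1
        assert set(np.unique(out[labels == 2])) == {1}
        assert not out[labels == 1].any()

    def test_keep_all_largest_is_identity(self, rng):
        labels, k = label_components(random_mask(rng, (8, 8), 0.3))
        out, k2 = keep_largest_components(labels, max(k, 1))
        assert k2 == k and partitions_equal(out, labels)

    def test_keep_single_largest(self):
        labels = np.zeros((3, 40, 40), int)
        labels[0, 0, 0:5] = 1
        labels[1, 5:10, 0:10] = 2
        labels[2, 15:35, 15:35] = 3
        out, k = keep_largest_components(labels, 1)
        assert k == 1 and (out[labels == 3] == 1).all() and out.sum() == (labels == 3).sum()

    def test_keep_largest_matches_size_sort(self, rng):
        mask = random_mask(rng, (12, 12, 12), 0.1)
        labels, k = label_components(mask)
        if k < 4:
            pytest.skip("fixture produced too few components")
        sizes = np.bincount(labels.ravel())[1:]
        expected = set(np.argsort(-sizes, kind="stable")[:3] + 1)
        out, k3 = keep_largest_components(labels, 3)
        kept = {int(labels[out == i][0]) for i in range(1, k3 + 1)}
        assert kept == expected
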
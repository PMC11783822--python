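"""Two-stage detection fusion and the frequency confidence score."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tilegrade.fusion import (
    Thresholds,
    detect_sets,
    frequency_score,
    fuse_2d_to_3d,
    fuse_across_scans,
    fuse_patient,
    type_confidence,
)
from tilegrade.records import FRACTURE_TYPES, Detection2D, Fracture3D, FractureType

from oracles_util import detections_linked, transitive_closure_components

PSD = FractureType.PSD
RING = FractureType.RING_FX


def _det(slice_index, box=(0.0, 0.0, 10.0, 10.0), ftype=PSD, score=0.9, aug=0, pid="p"):
    return Detection2D(pid, aug, slice_index, box, ftype, score)


def _f3d(cuboid, ftype=PSD, aug=0, score=0.9):
    x0, y0, z0, x1, y1, z1 = cuboid
    dets = [
        Detection2D("p", aug, s, (x0, y0, x1, y1), ftype, score)
        for s in range(int(z0), int(z1))
    ]
    return Fracture3D.from_detections(dets)


class TestFuse2Dto3D:
    def test_adjacent_overlapping_same_type_merge(self):
        out = fuse_2d_to_3d([_det(3), _det(4)])
        assert len(out) == 1
        assert out[0].cuboid[2] == 3.0 and out[0].cuboid[5] == 5.0  # z in [3, 5)

    def test_identical_boxes_different_types_stay_apart(self):
        out = fuse_2d_to_3d([_det(3, ftype=PSD), _det(3, ftype=RING)])
        assert len(out) == 2

    def test_gap_of_two_slices_splits(self):
        out = fuse_2d_to_3d([_det(3), _det(5)])
        assert len(out) == 2

    def test_chain_merges_transitively(self):
        # a-b and b-c overlap in-plane, a-c do not
        a = _det(3, box=(0.0, 0.0, 10.0, 10.0))
        b = _det(3, box=(8.0, 0.0, 20.0, 10.0))
        c = _det(3, box=(18.0, 0.0, 30.0, 10.0))
        out = fuse_2d_to_3d([a, b, c])
        assert len(out) == 1

    def test_keep_threshold_is_strict(self):
        out = fuse_2d_to_3d([_det(3, score=0.5), _det(4, score=0.51)], keep_2d=0.5)
        assert len(out) == 1
        assert out[0].score == 0.51

    def test_mixed_augmentation_ids_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            fuse_2d_to_3d([_det(3, aug=0), _det(3, aug=1)])

    def test_score_is_max_of_constituents(self):
        out = fuse_2d_to_3d([_det(3, score=0.6), _det(4, score=0.8)])
        assert out[0].score == 0.8

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_matches_transitive_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        dets = []
        for _ in range(int(rng.integers(1, 50))):
            x0, y0 = rng.uniform(0, 40, 2)
            w, h = rng.uniform(1, 25, 2)
            dets.append(
                _det(
                    int(rng.integers(0, 8)),
                    box=(float(x0), float(y0), float(x0 + w), float(y0 + h)),
                    ftype=FRACTURE_TYPES[int(rng.integers(0, 3))],
                    score=float(rng.uniform(0.51, 1.0)),
                )
            )
        got = fuse_2d_to_3d(dets, keep_2d=0.5)
        expected = transitive_closure_components(dets, detections_linked)
        got_partition = {
            frozenset(dets.index(d) for d in f.constituents) for f in got
        }
        assert got_partition == expected

    @settings(deadline=None, derandomize=True, max_examples=15)
    @given(seed=st.integers(0, 1000), perm_seed=st.integers(0, 1000))
    def test_permutation_invariant(self, seed, perm_seed):
        rng = np.random.default_rng(seed)
        dets = []
        for _ in range(20):
            x0, y0 = rng.uniform(0, 30, 2)
            dets.append(
                _det(int(rng.integers(0, 6)),
                     box=(float(x0), float(y0), float(x0 + 10), float(y0 + 10)),
                     ftype=FRACTURE_TYPES[int(rng.integers(0, 2))])
            )
        shuffled = list(dets)
        np.random.default_rng(perm_seed).shuffle(shuffled)
        a = fuse_2d_to_3d(dets)
        b = fuse_2d_to_3d(shuffled)
        assert [(f.cuboid, f.fracture_type) for f in a] == [
            (f.cuboid, f.fracture_type) for f in b
        ]


class TestFuseAcrossScans:
    def test_split_fracture_bridged_across_scans(self):
        # scan 0: two pieces with a one-slice gap; scan 1: one bridging box;
        # scan 2: nothing -> one finding seen in 2 of 3 scans
        split_a = _f3d((0, 0, 2, 10, 10, 4), aug=0)
        split_b = _f3d((0, 0, 5, 10, 10, 7), aug=0)
        bridge = _f3d((0, 0, 2, 10, 10, 7), aug=1)
        fused = fuse_across_scans({0: [split_a, split_b], 1: [bridge], 2: []}, K=3)
        assert len(fused) == 1
        assert round(fused[0].frequency, 3) == 0.667

    def test_disjoint_same_type_cuboids_stay_apart(self):
        a = _f3d((0, 0, 0, 5, 5, 2), aug=0)
        b = _f3d((20, 20, 10, 30, 30, 12), aug=0)
        fused = fuse_across_scans({0: [a, b]}, K=25)
        assert len(fused) == 2
        assert all(f.frequency == 1 / 25 for f in fused)

    def test_component_cuboid_is_elementwise_min_max(self):
        a = _f3d((0, 0, 2, 10, 10, 4), aug=0)
        b = _f3d((5, 5, 3, 20, 15, 6), aug=1)
        fused = fuse_across_scans({0: [a], 1: [b]}, K=2)
        assert fused[0].cuboid == (0, 0, 2, 20, 15, 6)

    def test_nonpositive_K_rejected(self):
        with pytest.raises(ValueError):
            fuse_across_scans({}, K=0)

    def test_augmentation_id_outside_range_rejected(self):
        with pytest.raises(ValueError, match="augmentation_id"):
            fuse_across_scans({5: [_f3d((0, 0, 0, 1, 1, 1), aug=5)]}, K=3)


class TestFrequencyScore:
    def test_two_of_three_scans(self):
        fused = fuse_across_scans(
            {0: [_f3d((0, 0, 0, 5, 5, 3), aug=0)], 1: [_f3d((0, 0, 0, 5, 5, 3), aug=1)]},
            K=3,
        )
        assert round(frequency_score(fused[0], 3), 3) == 0.667

    def test_all_scans_give_one(self):
        fused = fuse_across_scans(
            {k: [_f3d((0, 0, 0, 5, 5, 3), aug=k)] for k in range(5)}, K=5
        )
        assert frequency_score(fused[0], 5) == 1.0

    def test_duplicates_within_scan_counted_once(self):
        # 2 pieces in scan 0 + 1 in scan 1, K=3 -> still 2/3
        fused = fuse_across_scans(
            {
                0: [_f3d((0, 0, 0, 5, 5, 2), aug=0), _f3d((0, 0, 3, 5, 5, 5), aug=0)],
                1: [_f3d((0, 0, 0, 5, 5, 5), aug=1)],
            },
            K=3,
        )
        assert len(fused) == 1
        assert round(fused[0].frequency, 3) == 0.667

    def test_frequency_on_k_grid(self):
        for K in (3, 25):
            fused = fuse_across_scans({0: [_f3d((0, 0, 0, 5, 5, 3), aug=0)]}, K=K)
            assert fused[0].frequency in {n / K for n in range(K + 1)}


class TestTypeConfidence:
    def test_max_over_findings_of_a_type(self):
        f_low = fuse_across_scans({0: [_f3d((0, 0, 0, 5, 5, 2), aug=0)]}, K=5)[0]
        f_high = fuse_across_scans(
            {k: [_f3d((20, 20, 20, 25, 25, 22), aug=k)] for k in range(4)}, K=5
        )[0]
        conf = type_confidence([f_low, f_high])
        assert conf[PSD] == 0.8

    def test_no_findings_all_zero(self):
        conf = type_confidence([])
        assert set(conf) == set(FRACTURE_TYPES)
        assert all(v == 0.0 for v in conf.values())

    def test_single_finding_maps_to_its_frequency(self):
        f = fuse_across_scans({0: [_f3d((0, 0, 0, 5, 5, 2), aug=0)]}, K=4)[0]
        assert type_confidence([f])[PSD] == 0.25


class TestDetectSets:
    def test_thresholding(self):
        conf = {t: 0.0 for t in FRACTURE_TYPES}
        conf[PSD] = 1.0
        conf[RING] = 0.6
        fx_high, fx_low = detect_sets(conf, Thresholds(z_high=0.8, z_low=0.5))
        assert fx_high == {PSD}
        assert fx_low == {PSD, RING}

    def test_all_zero_confidences_empty_sets(self):
        fx_high, fx_low = detect_sets({t: 0.0 for t in FRACTURE_TYPES}, Thresholds())
        assert fx_high == fx_low == frozenset()

    def test_equal_thresholds_equal_sets(self):
        conf = {t: 0.7 for t in FRACTURE_TYPES}
        fx_high, fx_low = detect_sets(conf, Thresholds(z_high=0.6, z_low=0.6))
        assert fx_high == fx_low == frozenset(FRACTURE_TYPES)

    def test_high_subset_of_low_always(self, rng):
        for _ in range(20):
            conf = {t: float(rng.random()) for t in FRACTURE_TYPES}
            fx_high, fx_low = detect_sets(conf, Thresholds())
            assert fx_high <= fx_low

    def test_threshold_uses_greater_or_equal(self):
        conf = {t: 0.0 for t in FRACTURE_TYPES}
        conf[PSD] = 1.0
        fx_high, _ = detect_sets(conf, Thresholds(z_high=1.0, z_low=0.5))
        assert PSD in fx_high  # the z=max operating point is attainable

    def test_invalid_threshold_order_rejected(self):
        with pytest.raises(ValueError):
            Thresholds(z_high=0.4, z_low=0.6)


def test_fuse_patient_end_to_end():
    dets = [
        _det(2, aug=0), _det(3, aug=0),          # piece 1 in scan 0
        _det(5, aug=0), _det(6, aug=0),          # piece 2 in scan 0 (gap at 4)
        *[_det(s, aug=1) for s in range(2, 7)],  # bridge in scan 1
    ]
    fused = fuse_patient(dets, K=3)
    assert len(fused) == 1
    assert round(fused[0].frequency, 3) == 0.667
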
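"""IOU and sucker counting against brute-force oracles."""
import numpy as np
import pytest
from scipy import ndimage

from tomseg.metrics import (EvalConfig, class_iou, count_correct_suckers,
                            evaluate_dataset, filter_noise_regions,
                            measure_throughput, sucker_binary)
from tomseg.synth import generate_counting_fixture

rng = np.random.default_rng(99)


def oracle_iou(pred, truth, n_classes=4):
    """Explicit pixel-set intersection/union counting."""
    out = []
    for c in range(n_classes):
        p = {(i, j) for i, j in zip(*np.nonzero(pred == c))}
        t = {(i, j) for i, j in zip(*np.nonzero(truth == c))}
        u = p | t
        out.append(len(p & t) / len(u) if u else np.nan)
    return np.array(out)


def oracle_count(pred, truth, threshold=160):
    """All-pairs pixel-overlap oracle for the sucker count."""
    eight = np.ones((3, 3), int)
    pc, pn = ndimage.label(pred == 3, structure=eight)
    keep = {i for i in range(1, pn + 1) if (pc == i).sum() >= threshold}
    tc, tn = ndimage.label(truth == 3, structure=eight)
    n_correct = 0
    for g in range(1, tn + 1):
        gpix = set(zip(*np.nonzero(tc == g)))
        if any((i, j) in gpix for i, j in zip(*np.nonzero(np.isin(pc, list(keep))))):
            n_correct += 1
    return tn, n_correct


class TestClassIOU:
    def test_perfect_prediction(self):
        m = rng.integers(0, 4, size=(10, 10))
        per_class, mean = class_iou(m, m)
        assert np.allclose(per_class[~np.isnan(per_class)], 1.0)
        assert mean == 1.0

    def test_disjoint_masks_score_zero(self):
        pred = np.zeros((6, 6), int)
        truth = np.zeros((6, 6), int)
        pred[:3] = 1
        truth[3:] = 1
        per_class, _ = class_iou(pred, truth)
        assert per_class[1] == 0.0

    def test_matches_brute_force_oracle_on_random_maps(self):
        for _ in range(100):
            pred = rng.integers(0, 4, size=(16, 16))
            truth = rng.integers(0, 4, size=(16, 16))
            per_class, mean = class_iou(pred, truth)
            ref = oracle_iou(pred, truth)
            assert np.allclose(np.nan_to_num(per_class, nan=-1),
                               np.nan_to_num(ref, nan=-1))
            assert np.isclose(mean, np.nanmean(ref))

    def test_absent_class_excluded_from_mean(self):
        pred = np.zeros((4, 4), int)
        truth = np.zeros((4, 4), int)
        per_class, mean = class_iou(pred, truth)
        assert np.isnan(per_class[1:]).all()
        assert mean == 1.0  # only class 0 occurs, IOU 1

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            class_iou(np.zeros((3, 3), int), np.zeros((4, 4), int))


class TestSuckerBinary:
    def test_mask_semantics(self):
        label = rng.integers(0, 4, size=(12, 12))
        mask = sucker_binary(label)
        assert set(np.unique(mask)) <= {0, 1}
        assert mask.sum() == (label == 3).sum()
        assert not sucker_binary(np.zeros((3, 3), int)).any()
        assert sucker_binary(np.full((3, 3), 3)).all()


class TestNoiseFilter:
    def test_area_boundary_at_threshold(self):
        mask = np.zeros((30, 30), np.uint8)
        mask[:159 // 30 + 1].flat[:159] = 1  # single region of 159 px
        mask = np.zeros((30, 30), np.uint8)
        mask[0:10, 0:16] = 1  # 160 px exactly
        kept = filter_noise_regions(mask, EvalConfig(noise_area_threshold=160))
        assert np.array_equal(kept, mask)  # area == t survives
        mask2 = np.zeros((30, 30), np.uint8)
        mask2[0:10, 0:16] = 1
        mask2[0, 15] = 0  # 159 px
        assert not filter_noise_regions(
            mask2, EvalConfig(noise_area_threshold=160)).any()

    def test_mixed_regions(self):
        mask = np.zeros((40, 40), np.uint8)
        mask[0:10, 0:20] = 1    # 200 px, survives
        mask[30:35, 30:40] = 1  # 50 px, removed
        kept = filter_noise_regions(mask, EvalConfig(noise_area_threshold=160))
        assert kept[0:10, 0:20].all()
        assert not kept[30:35, 30:40].any()

    def test_idempotent(self):
        for _ in range(10):
            mask = (rng.random((32, 32)) < 0.35).astype(np.uint8)
            cfg = EvalConfig(noise_area_threshold=12)
            once = filter_noise_regions(mask, cfg)
            assert np.array_equal(once, filter_noise_regions(once, cfg))

    def test_connectivity_choice_matters_for_diagonals(self):
        mask = np.zeros((4, 4), np.uint8)
        mask[0, 0] = mask[1, 1] = 1  # diagonal pair
        cfg8 = EvalConfig(noise_area_threshold=2, connectivity=8)
        cfg4 = EvalConfig(noise_area_threshold=2, connectivity=4)
        assert filter_noise_regions(mask, cfg8).sum() == 2
        assert filter_noise_regions(mask, cfg4).sum() == 0


class TestCountCorrectSuckers:
    def test_counting_fixture_worked_example(self):
        pred, truth = generate_counting_fixture()
        res = count_correct_suckers(pred, truth)
        assert res.n_ground_truth_suckers == 2
        assert res.n_prediction_regions_after_filter == 2  # small one removed
        assert res.n_correct == 1
        assert res.overlap_flags == [True, False]

    def test_empty_prediction(self):
        _, truth = generate_counting_fixture()
        res = count_correct_suckers(np.zeros_like(truth), truth)
        assert res.n_correct == 0
        assert res.n_ground_truth_suckers == 2

    def test_matches_brute_force_oracle_on_random_maps(self):
        cfg = EvalConfig(noise_area_threshold=6)
        for _ in range(100):
            pred = np.where(rng.random((16, 16)) < 0.2, 3, 0)
            truth = np.where(rng.random((16, 16)) < 0.2, 3, 0)
            res = count_correct_suckers(pred, truth, cfg)
            tn, n_correct = oracle_count(pred, truth, threshold=6)
            assert (res.n_ground_truth_suckers, res.n_correct) == (tn, n_correct)
            assert 0 <= res.n_correct <= res.n_ground_truth_suckers

    def test_invariant_to_subthreshold_noise_regions(self):
        pred, truth = generate_counting_fixture()
        noisy = pred.copy()
        noisy[0:5, 0:5] = 3  # 25 px < 160
        assert count_correct_suckers(noisy, truth).n_correct == \
            count_correct_suckers(pred, truth).n_correct


class _OracleNet:
    """Stub predictor used to test aggregation independently of any model."""

    def __init__(self, mapper):
        self.mapper = mapper
        self.calls = 0

    def predict(self, sample, t1=None):
        self.calls += 1
        return self.mapper(sample), {}


class TestEvaluateDataset:
    def test_perfect_predictor(self, tiny_dataset):
        # no area filter: every true component must then be recovered exactly
        cfg = EvalConfig(noise_area_threshold=0)
        report = evaluate_dataset(_OracleNet(lambda s: s.label), tiny_dataset,
                                  cfg)
        assert report["mean_iou"] == 1.0
        if report["n_ground_truth_suckers"]:
            assert report["sucker_detection_pct"] == 100.0

    def test_all_background_predictor(self, tiny_dataset):
        net = _OracleNet(lambda s: np.zeros_like(s.label))
        report = evaluate_dataset(net, tiny_dataset)
        if report["n_ground_truth_suckers"]:
            assert report["sucker_detection_pct"] == 0.0
        assert report["mean_iou"] < 1.0

    def test_detection_undefined_without_suckers(self, tiny_dataset):
        import dataclasses
        no_suckers = [dataclasses.replace(
            s, label=np.where(s.label == 3, 0, s.label))
            for s in tiny_dataset]
        report = evaluate_dataset(_OracleNet(lambda s: s.label), no_suckers)
        assert report["sucker_detection_pct"] is None

    def test_aggregation_consistent_with_per_image_breakdown(self, tiny_dataset):
        report = evaluate_dataset(_OracleNet(lambda s: s.label), tiny_dataset)
        assert report["n_correct"] == sum(r["n_correct"]
                                          for r in report["per_image"])
        assert report["n_ground_truth_suckers"] == sum(
            r["n_ground_truth_suckers"] for r in report["per_image"])


class TestThroughput:
    def test_positive_and_counts_frames(self):
        net = _OracleNet(lambda s: np.zeros(s.depth.shape, int))
        fps = measure_throughput(net, n_frames=4, shape=(16, 16), warmup=2)
        assert np.isfinite(fps) and fps > 0
        assert net.calls == 6  # warmup excluded from timing but still run
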
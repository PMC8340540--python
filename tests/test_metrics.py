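import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thinedges import ensure_nonempty, evaluate_pairs, iou_box, sde


def random_map(rng, shape=(12, 12), p=0.1):
    m = rng.random(shape) < p
    if not m.any():
        m[tuple(rng.integers(0, s) for s in shape)] = True
    return m


class TestEnsureNonempty:
    def test_nonempty_unchanged(self, rng):
        m = random_map(rng)
        assert ensure_nonempty(m) is m or (ensure_nonempty(m) == m).all()

    def test_empty_gets_center_pixel(self):
        out = ensure_nonempty(np.zeros((11, 11), dtype=bool))
        assert out.sum() == 1 and out[5, 5]

    def test_even_dimensions_floor(self):
        out = ensure_nonempty(np.zeros((4, 6), dtype=bool))
        assert out[2, 3] and out.sum() == 1

    def test_one_by_one(self):
        out = ensure_nonempty(np.zeros((1, 1), dtype=bool))
        assert out[0, 0]

    def test_idempotent(self):
        once = ensure_nonempty(np.zeros((5, 5), dtype=bool))
        assert (ensure_nonempty(once) == once).all()


class TestSde:
    def test_identity_is_zero(self, rng):
        m = random_map(rng)
        assert sde(m, m) == 0.0

    def test_hand_example_distance_three(self):
        pred = np.zeros((1, 4), dtype=bool)
        gt = np.zeros((1, 4), dtype=bool)
        pred[0, 0] = True
        gt[0, 3] = True
        assert sde(pred, gt) == pytest.approx(3.0)

    def test_empty_prediction_center_correction(self):
        pred = np.zeros((11, 11), dtype=bool)
        gt = np.zeros((11, 11), dtype=bool)
        gt[5, 5] = True
        assert sde(pred, gt) == 0.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            sde(np.zeros((2, 2), dtype=bool), np.zeros((3, 3), dtype=bool))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_and_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_map(rng), random_map(rng)
        assert sde(a, b) == pytest.approx(sde(b, a))
        assert sde(a, b) >= 0.0

    def test_moving_pixel_farther_never_decreases(self):
        gt = np.zeros((1, 9), dtype=bool)
        gt[0, 0] = True
        vals = []
        for c in range(1, 9):
            pred = np.zeros((1, 9), dtype=bool)
            pred[0, c] = True
            vals.append(sde(pred, gt))
        assert vals == sorted(vals)


class TestIouBox:
    def test_identity_is_one(self, rng):
        m = random_map(rng)
        assert iou_box(m, m) == pytest.approx(1.0)

    def test_disjoint_boxes_zero(self):
        pred = np.zeros((10, 10), dtype=bool)
        gt = np.zeros((10, 10), dtype=bool)
        pred[0, 0] = True
        gt[9, 9] = True
        assert iou_box(pred, gt) == 0.0

    def test_half_overlap_box(self):
        # gt box rows 0-3 x cols 0-3 (area 16), pred rows 0-1 x cols 0-3
        # (area 8, fully inside): IoU = 8 / 16
        gt = np.zeros((6, 6), dtype=bool)
        gt[0:4, 0] = gt[0:4, 3] = gt[0, 0:4] = gt[3, 0:4] = True
        pred = np.zeros((6, 6), dtype=bool)
        pred[0:2, 0:4] = True
        assert iou_box(pred, gt) == pytest.approx(0.5)

    def test_one_to_one_matching(self):
        # one sprawling prediction cannot score against two gt components
        gt = np.zeros((5, 11), dtype=bool)
        gt[2, 1:4] = True
        gt[2, 7:10] = True
        pred = np.zeros((5, 11), dtype=bool)
        pred[2, 1:10] = True
        score = iou_box(pred, gt)
        assert score < 0.5  # second gt component unmatched, scores 0

    def test_in_unit_interval(self, rng):
        for _ in range(20):
            v = iou_box(random_map(rng), random_map(rng))
            assert 0.0 <= v <= 1.0


class TestEvaluatePairs:
    def test_perfect_single_pair(self, rng):
        m = random_map(rng)
        rep = evaluate_pairs([m], [m])
        assert rep.mean_sde == 0.0
        assert rep.mean_iou_box == pytest.approx(1.0)

    def test_population_statistics(self):
        # two pairs engineered to give SDE values {0, 6}
        a = np.zeros((1, 13), dtype=bool)
        a[0, 0] = True
        b = np.zeros((1, 13), dtype=bool)
        b[0, 6] = True
        rep = evaluate_pairs([a, a], [a, b])
        agg = rep.aggregate("sde")
        assert agg["mean"] == pytest.approx(3.0)
        assert agg["median"] == pytest.approx(3.0)
        assert agg["std"] == pytest.approx(3.0)  # population sigma

    def test_median_within_range(self, rng):
        preds = [random_map(rng) for _ in range(7)]
        gts = [random_map(rng) for _ in range(7)]
        rep = evaluate_pairs(preds, gts)
        vals = [s.sde for s in rep.scores]
        assert min(vals) <= rep.aggregate("sde")["median"] <= max(vals)

    def test_error_cases(self):
        m = np.zeros((2, 2), dtype=bool)
        with pytest.raises(ValueError):
            evaluate_pairs([m], [m, m])
        with pytest.raises(ValueError):
            evaluate_pairs([], [])

    def test_report_files(self, tmp_path, rng):
        import json

        m = random_map(rng)
        rep = evaluate_pairs([m], [m], names=["a.png"])
        rep.write_csv(tmp_path / "r.csv")
        rep.write_json(tmp_path / "r.json")
        data = json.loads((tmp_path / "r.json").read_text())
        assert data["aggregates"]["iou_box"]["mean"] == pytest.approx(1.0)
        assert (tmp_path / "r.csv").read_text().startswith("name,sde,iou_box")
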
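"""Distance metrics against brute-force oracles, Dice arithmetic, aggregation."""

import numpy as np
import pandas as pd
import pytest

from carotid_xsec.annotation import LabelMask
from carotid_xsec.metrics import (
    acd,
    aggregate,
    densify,
    dice,
    evaluate_mask,
    hausdorff,
    region_contours_for_metrics,
)


def _oracle_point_to_polyline(point, polyline):
    """Exhaustive point-to-segment distance, plain double loop."""
    p = np.asarray(polyline, float)
    if not np.allclose(p[0], p[-1]):
        p = np.vstack([p, p[0]])
    best = np.inf
    for a, b in zip(p[:-1], p[1:]):
        d = b - a
        t = np.clip(np.dot(point - a, d) / max(np.dot(d, d), 1e-300), 0.0, 1.0)
        best = min(best, float(np.linalg.norm(point - (a + t * d))))
    return best


def _oracle_hd_acd(a, b, step=0.05):
    da = [_oracle_point_to_polyline(p, b) for p in densify(a, step)]
    db = [_oracle_point_to_polyline(p, a) for p in densify(b, step)]
    return max(max(da), max(db)), 0.5 * (np.mean(da) + np.mean(db))


def _random_polyline(rng, n_max=12):
    n = rng.integers(4, n_max)
    th = np.sort(rng.uniform(0, 2 * np.pi, n))
    r = rng.uniform(0.5, 3.0, n)
    return np.column_stack([r * np.cos(th), r * np.sin(th)]) + rng.uniform(-1, 1, 2)


class TestDistanceOracles:
    def test_identical_contours_zero(self, circle_contours):
        inner, _ = circle_contours
        assert hausdorff(inner, inner) == pytest.approx(0.0, abs=1e-12)
        assert acd(inner, inner) == pytest.approx(0.0, abs=1e-12)

    def test_concentric_circles_unit_gap(self, circle_contours):
        inner, outer = circle_contours
        assert hausdorff(inner, outer) == pytest.approx(1.0, abs=2e-3)
        assert acd(inner, outer) == pytest.approx(1.0, abs=2e-3)

    def test_translated_unit_square(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        assert hausdorff(sq, sq + [1.0, 0.0]) == pytest.approx(1.0, abs=1e-9)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            a, b = _random_polyline(rng), _random_polyline(rng)
            hd_o, acd_o = _oracle_hd_acd(a, b)
            assert hausdorff(a, b) == pytest.approx(hd_o, abs=1e-9)
            assert acd(a, b) == pytest.approx(acd_o, abs=1e-9)

    def test_symmetry_and_mean_le_max(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a, b = _random_polyline(rng), _random_polyline(rng)
            assert hausdorff(a, b) == pytest.approx(hausdorff(b, a), abs=1e-12)
            assert acd(a, b) == pytest.approx(acd(b, a), abs=1e-12)
            assert acd(a, b) <= hausdorff(a, b) + 1e-12

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        a, b = _random_polyline(rng), _random_polyline(rng)
        base_hd, base_acd = hausdorff(a, b), acd(a, b)
        for _ in range(5):
            th = rng.uniform(0, 2 * np.pi)
            rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            shift = rng.uniform(-10, 10, 2)
            ar, br = a @ rot.T + shift, b @ rot.T + shift
            assert hausdorff(ar, br) == pytest.approx(base_hd, abs=1e-6)
            assert acd(ar, br) == pytest.approx(base_acd, abs=1e-6)

    def test_open_polyline_rejected(self):
        with pytest.raises(ValueError):
            hausdorff(np.array([[0.0, 0.0], [1.0, 0.0]]), np.array([[0.0, 1.0], [1.0, 1.0]]))


class TestDice:
    def _mask(self, labels):
        return LabelMask(labels.astype(np.uint8), 0.195)

    def test_identical_masks(self):
        labels = np.zeros((32, 32))
        labels[5:15, 5:15] = 2
        labels[2:5, 2:20] = 1
        m = self._mask(labels)
        assert dice(m, m, "lumen") == 1.0
        assert dice(m, m, "wall") == 1.0

    def test_disjoint_regions(self):
        a = np.zeros((32, 32))
        b = np.zeros((32, 32))
        a[0:10, 0:10] = 2
        b[20:30, 20:30] = 2
        a[15, 15] = 1
        b[15, 15] = 1
        assert dice(self._mask(a), self._mask(b), "lumen") == 0.0

    def test_half_overlap_squares(self):
        a = np.zeros((32, 32))
        b = np.zeros((32, 32))
        a[0:10, 0:10] = 2  # 10 x 10
        b[0:10, 5:15] = 2  # overlap 10 x 5
        assert dice(self._mask(a), self._mask(b), "lumen") == pytest.approx(0.5)

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        a = self._mask(rng.integers(0, 3, (32, 32)))
        b = self._mask(rng.integers(0, 3, (32, 32)))
        for region in ("lumen", "wall"):
            assert dice(a, b, region) == dice(b, a, region)

    def test_both_empty_is_one(self):
        z = self._mask(np.zeros((8, 8)))
        assert dice(z, z, "lumen") == 1.0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            dice(self._mask(np.zeros((8, 8))), self._mask(np.zeros((16, 16))), "lumen")


class TestRegionContours:
    def test_annulus_wall_has_two_curves(self):
        n = 64
        yy, xx = np.mgrid[:n, :n] - (n - 1) / 2
        d = np.hypot(xx, yy)
        labels = np.where(d < 8, 2, np.where(d < 14, 1, 0)).astype(np.uint8)
        curves = region_contours_for_metrics(LabelMask(labels, 0.195), "wall")
        assert len(curves) == 2

    def test_missing_region_flagged_with_sentinel(self):
        labels = np.zeros((64, 64), dtype=np.uint8)
        labels[20:40, 20:40] = 1
        labels[25:35, 25:35] = 2
        pred = np.zeros((64, 64), dtype=np.uint8)
        pred[20:40, 20:40] = 1  # prediction misses the lumen entirely
        pred[25:35, 25:35] = 1
        rows = evaluate_mask(LabelMask(pred, 0.195), LabelMask(labels, 0.195))
        lumen_row = next(r for r in rows if r.region == "lumen")
        diag = np.hypot(64, 64) * 0.195
        assert lumen_row.dc == 0.0
        assert lumen_row.hd_mm == pytest.approx(diag)

    def test_rasterized_disk_contour_radius(self):
        n = 64
        yy, xx = np.mgrid[:n, :n] - (n - 1) / 2
        labels = np.where(np.hypot(xx, yy) < 15.4, 2, 0).astype(np.uint8)
        labels[0, 0] = 1  # wall present so the mask is well-formed
        curves = region_contours_for_metrics(LabelMask(labels, 1.0), "lumen")
        radii = np.linalg.norm(curves[0], axis=1)
        assert np.all(np.abs(radii - 15.4) <= 1.0)


class TestAggregate:
    def _table(self):
        return pd.DataFrame(
            {
                "subject": ["a", "a", "b"],
                "region": ["lumen"] * 3,
                "dc": [1.0, 2.0, 3.0],
                "hd_mm": [1.0, 2.0, 3.0],
                "acd_mm": [0.1, 0.2, 0.3],
            }
        )

    def test_single_row_summary_equals_row(self):
        t = self._table().iloc[:1]
        out = aggregate(t, ["region"], "mean")
        assert out.dc.iloc[0] == 1.0

    def test_mean_and_median(self):
        t = self._table()
        assert aggregate(t, ["region"], "mean").dc.iloc[0] == pytest.approx(2.0)
        assert aggregate(t, ["region"], "median").dc.iloc[0] == pytest.approx(2.0)

    def test_permutation_invariance(self):
        t = self._table()
        shuffled = t.sample(frac=1.0, random_state=1)
        a = aggregate(t, ["subject", "region"], "mean")
        b = aggregate(shuffled, ["subject", "region"], "mean")
        pd.testing.assert_frame_equal(
            a.sort_values("subject").reset_index(drop=True),
            b.sort_values("subject").reset_index(drop=True),
        )

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            aggregate(self._table().iloc[:0], ["region"])

    def test_subject_then_cohort_median(self):
        t = self._table()
        per_subject = aggregate(t, ["subject", "region"], "mean")
        cohort = aggregate(per_subject, ["region"], "median")
        assert cohort.dc.iloc[0] == pytest.approx(np.median([1.5, 3.0]))
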
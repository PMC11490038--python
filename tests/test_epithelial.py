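import numpy as np
import pytest
from scipy.spatial import ConvexHull

from bvquant.classify import NONVIABLE, VIABLE, ClassMap, classify_stack
from bvquant.epithelial import (
    Component,
    EpithelialCriteria,
    exclude_epithelial,
    find_red_components,
    find_red_components_stack,
    flag_epithelial,
    pixel_convex_area,
)

# ---------------------------------------------------------------------------
# independent convex-area oracle: hull via scipy, pixel clipping via
# Sutherland-Hodgman implemented here
# ---------------------------------------------------------------------------


def _clip_area(square, hull_poly):
    """Area of square ∩ convex polygon (Sutherland-Hodgman + shoelace)."""
    poly = list(square)
    n = len(hull_poly)
    for i in range(n):
        a, b = hull_poly[i], hull_poly[(i + 1) % n]
        out = []
        for j, p in enumerate(poly):
            q = poly[(j + 1) % len(poly)]
            side_p = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
            side_q = (b[0] - a[0]) * (q[1] - a[1]) - (b[1] - a[1]) * (q[0] - a[0])
            if side_p >= 0:
                out.append(p)
            if side_p * side_q < 0:
                t = side_p / (side_p - side_q)
                out.append((p[0] + t * (q[0] - p[0]), p[1] + t * (q[1] - p[1])))
        poly = out
        if not poly:
            return 0.0
    area = 0.0
    for j, p in enumerate(poly):
        q = poly[(j + 1) % len(poly)]
        area += p[0] * q[1] - q[0] * p[1]
    return abs(area) / 2


def oracle_convex_area(coords):
    coords = np.asarray(coords)
    if len(coords) == 1:
        return 1
    corners = []
    for r, c in coords:
        corners += [(r, c), (r + 1, c), (r, c + 1), (r + 1, c + 1)]
    corners = np.unique(np.array(corners, float), axis=0)
    hull = ConvexHull(corners)
    hull_poly = [tuple(corners[i]) for i in hull.vertices]
    count = 0
    for r in range(coords[:, 0].min(), coords[:, 0].max() + 1):
        for c in range(coords[:, 1].min(), coords[:, 1].max() + 1):
            sq = [(r, c), (r + 1, c), (r + 1, c + 1), (r, c + 1)]
            if _clip_area(sq, hull_poly) > 1e-9:
                count += 1
    return count


class TestComponents:
    def test_solid_block(self):
        lab = np.zeros((6, 6), dtype=np.uint8)
        lab[1:4, 1:4] = NONVIABLE
        red = np.where(lab == NONVIABLE, 200.0, 0.0)
        comps = find_red_components(lab, red)
        assert len(comps) == 1
        assert comps[0].area_px == 9
        assert comps[0].solidity == pytest.approx(1.0)
        assert comps[0].mean_red == pytest.approx(200.0)

    def test_diagonal_connectivity(self):
        lab = np.zeros((4, 4), dtype=np.uint8)
        lab[1, 1] = lab[2, 2] = NONVIABLE
        red = np.full((4, 4), 150.0)
        assert len(find_red_components(lab, red, connectivity=8)) == 1
        assert len(find_red_components(lab, red, connectivity=4)) == 2

    def test_l_shape_solidity(self):
        # 2x3 block minus one corner pixel: area 5, hull 6 pixels
        lab = np.zeros((4, 5), dtype=np.uint8)
        lab[1:3, 1:4] = NONVIABLE
        lab[2, 3] = 0
        red = np.where(lab == NONVIABLE, 150.0, 0.0)
        (comp,) = find_red_components(lab, red)
        assert comp.area_px == 5
        assert comp.solidity == pytest.approx(5 / 6)

    def test_convex_area_matches_polygon_clipping_oracle(self, rng):
        for _ in range(20):
            mask = rng.random((9, 9)) < 0.35
            if not mask.any():
                continue
            coords = np.argwhere(mask)
            assert pixel_convex_area(coords) == oracle_convex_area(coords)

    def test_components_cover_all_nonviable_pixels(self, synthetic_field):
        stack, _, cm = synthetic_field
        comps = find_red_components_stack(cm, stack.red)
        for idx in range(cm.n_slices):
            nv = int((cm.labels[idx] == NONVIABLE).sum())
            covered = sum(c.area_px for c in comps if c.slice_index == idx)
            assert covered == nv

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            find_red_components(np.zeros((3, 3), np.uint8), np.zeros((3, 4)))


def _component(area, solidity, mean_red):
    return Component(
        slice_index=0,
        coords=np.zeros((area, 2), dtype=int),
        area_px=area,
        mean_red=mean_red,
        _solidity=solidity,
    )


class TestFlagging:
    @pytest.mark.parametrize(
        "area,solidity,mean_red,expected",
        [
            (500, 0.85, 200, True),  # all three criteria satisfied
            (150, 0.90, 220, False),  # too small
            (200, 0.90, 220, False),  # boundary: 'bigger than 200' is strict
            (500, 0.60, 220, False),  # not compact enough
            (500, 0.70, 220, False),  # boundary: 'more than 0.70' is strict
            (500, 0.85, 170, False),  # too dim
            (500, 0.85, 180, True),  # boundary: 'minimum ... 180' is inclusive
        ],
    )
    def test_criteria_conjunction(self, area, solidity, mean_red, expected):
        [(_, flag)] = flag_epithelial([_component(area, solidity, mean_red)])
        assert flag is expected

    def test_tightening_any_criterion_never_flags_more(self, rng):
        comps = [
            _component(
                int(rng.integers(1, 1000)),
                float(rng.uniform(0.1, 1.0)),
                float(rng.uniform(0, 255)),
            )
            for _ in range(200)
        ]
        base = EpithelialCriteria()
        n_base = sum(f for _, f in flag_epithelial(comps, base))
        for tighter in (
            EpithelialCriteria(min_area_px=400),
            EpithelialCriteria(min_solidity=0.9),
            EpithelialCriteria(min_mean_intensity=220),
        ):
            assert sum(f for _, f in flag_epithelial(comps, tighter)) <= n_base


class TestExclusion:
    def test_bv_arithmetic_before_and_after(self):
        # 100 viable px, 700 non-viable px of which one flagged 500-px
        # component: BV 12.5% before, 100/300 = 33.3% after
        lab = np.zeros((1, 64, 64), dtype=np.uint8)
        lab[0, 0:10, 0:10] = VIABLE
        lab[0, 20:40, 20:45] = NONVIABLE  # 500 px compact bright nucleus
        lab[0, 50:54, 0:50] = NONVIABLE  # 200 px dim strip, kept
        red = np.zeros((1, 64, 64))
        red[0, 20:40, 20:45] = 220.0
        red[0, 50:54, 0:50] = 150.0
        cm = ClassMap(lab)
        comps = find_red_components_stack(cm, red)
        flagged = flag_epithelial(comps)
        assert sum(f for _, f in flagged) == 1
        after, report = exclude_epithelial(cm, flagged)
        row = report.per_slice.iloc[0]
        assert row["bv_before"] == pytest.approx(100 * 100 / 800)
        assert row["bv_after"] == pytest.approx(100 * 100 / 300)
        assert row["excluded_px"] == 500

    def test_no_flags_is_identity(self, small_fixture):
        _, cm = small_fixture
        after, report = exclude_epithelial(cm, [])
        np.testing.assert_array_equal(after.labels, cm.labels)
        ps = report.per_slice.dropna()
        np.testing.assert_allclose(ps["bv_before"], ps["bv_after"])

    def test_all_nonviable_flagged_gives_100pct(self):
        lab = np.zeros((1, 30, 30), dtype=np.uint8)
        lab[0, 0:5, 0:5] = VIABLE
        lab[0, 8:25, 8:25] = NONVIABLE  # 289-px nucleus
        red = np.where(lab[0] == NONVIABLE, 220.0, 0.0)[None][0]
        cm = ClassMap(lab)
        flagged = flag_epithelial(find_red_components_stack(cm, red[None]))
        after, report = exclude_epithelial(cm, flagged)
        assert report.per_slice.iloc[0]["bv_after"] == pytest.approx(100.0)

    def test_exclusion_monotonic_and_viable_preserving(self, synthetic_field):
        stack, _, cm = synthetic_field
        flagged = flag_epithelial(find_red_components_stack(cm, stack.red))
        after, report = exclude_epithelial(cm, flagged)
        assert ((cm.labels == VIABLE) == (after.labels == VIABLE)).all()
        ps = report.per_slice.dropna()
        assert (ps["bv_after"] >= ps["bv_before"] - 1e-12).all()

    def test_planted_nuclei_recovered_exactly(self, synthetic_field):
        stack, truth, cm = synthetic_field
        flagged = flag_epithelial(find_red_components_stack(cm, stack.red))
        hits = [c for c, f in flagged if f]
        assert len(hits) == len(truth.nucleus_masks)
        for s, coords in truth.nucleus_masks:
            planted = set(map(tuple, coords))
            jaccards = [
                len(planted & set(map(tuple, c.coords)))
                / len(planted | set(map(tuple, c.coords)))
                for c in hits
                if c.slice_index == s
            ]
            assert max(jaccards) >= 0.95
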
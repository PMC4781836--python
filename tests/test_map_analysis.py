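import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Polygon, box

from placeschema.map_analysis import (
    PlaceFieldMap,
    construct_place_fields,
    entropy_bits,
    mutual_information,
    nerve,
    overlap_orders,
    polygon_rcc5,
    schema_map_information,
)
from placeschema.simplicial_schema import betti_numbers
from tests.conftest import make_trains


def fmap_from_boxes(boxes: dict) -> PlaceFieldMap:
    return PlaceFieldMap(regions={cid: box(*b) for cid, b in boxes.items()})


class TestConstructPlaceFields:
    def test_square_hull_from_corner_spikes(self):
        xy = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5]] * 3, float)
        trains = make_trains({0: np.arange(15) * 0.1}, duration=2.0)
        trains.positions[0][:] = xy
        fmap = construct_place_fields(trains, min_spikes=10)
        assert fmap.regions[0].area == pytest.approx(1.0)

    def test_cells_below_min_spikes_omitted(self):
        trains = make_trains({0: [0.1, 0.2]}, duration=1.0)
        fmap = construct_place_fields(trains, min_spikes=10)
        assert 0 not in fmap.regions

    def test_collinear_spikes_flagged_degenerate(self):
        trains = make_trains({0: np.arange(12) * 0.1}, duration=2.0)
        trains.positions[0][:, 0] = np.linspace(0, 1, 12)  # y stays 0
        fmap = construct_place_fields(trains, min_spikes=10)
        assert 0 in fmap.degenerate and 0 not in fmap.regions

    def test_outliers_do_not_inflate_hull(self):
        rng = np.random.default_rng(0)
        pts = rng.normal([0.5, 0.5], 0.05, size=(60, 2))
        pts[0] = [5.0, 5.0]  # a stray spike far away
        trains = make_trains({0: np.arange(60) * 0.1}, duration=10.0)
        trains.positions[0][:] = pts
        fmap = construct_place_fields(trains, min_spikes=10)
        assert fmap.regions[0].area < 0.2

    def test_simulated_field_contains_center(self, small_session):
        from shapely.geometry import Point

        from placeschema import build_environment

        env = build_environment()
        ens, _, trains = small_session
        fmap = construct_place_fields(trains, min_spikes=10)
        checked = 0
        for cell in ens.cells:
            if cell.id not in fmap.regions:
                continue
            # wall-adjacent fields are clipped by the boundary; only
            # interior cells are well-sampled all around their center
            if env.navigable.exterior.distance(Point(cell.center)) < cell.width:
                continue
            if any(h.exterior.distance(Point(cell.center)) < cell.width
                   for h in env.holes):
                continue
            assert fmap.regions[cell.id].buffer(1e-6).contains(Point(cell.center))
            checked += 1
        assert checked >= 5


class TestOverlapOrders:
    def test_disjoint_squares(self):
        fmap = fmap_from_boxes({1: (0, 0, 1, 1), 2: (2, 0, 3, 1)})
        orders, combos = overlap_orders(fmap, grid_step=0.05)
        assert dict(orders) == {1: 2}

    def test_triple_overlap(self):
        fmap = fmap_from_boxes(
            {1: (0, 0, 1, 1), 2: (0.4, 0, 1.4, 1), 3: (0.8, 0, 1.8, 1)}
        )
        orders, combos = overlap_orders(fmap, grid_step=0.05)
        assert frozenset({1, 2, 3}) in combos

    @given(st.data())
    @settings(max_examples=25, deadline=None)
    def test_matches_exact_subset_intersections(self, data):
        # lattice-aligned rectangles: every non-empty intersection has
        # positive area and contains interior grid points
        n = data.draw(st.integers(2, 6))
        boxes = {}
        for cid in range(n):
            x = data.draw(st.integers(0, 8))
            y = data.draw(st.integers(0, 8))
            w = data.draw(st.integers(2, 6))
            h = data.draw(st.integers(2, 6))
            boxes[cid] = (x * 0.1, y * 0.1, (x + w) * 0.1, (y + h) * 0.1)
        fmap = fmap_from_boxes(boxes)
        _, combos = overlap_orders(fmap, grid_step=0.01)
        exact = set()
        for k in range(1, n + 1):
            for sub in itertools.combinations(range(n), k):
                inter = fmap.regions[sub[0]]
                for cid in sub[1:]:
                    inter = inter.intersection(fmap.regions[cid])
                if inter.area > 1e-9:
                    exact.add(frozenset(sub))
        exact_maximal = {s for s in exact if not any(s < t for t in exact)}
        assert set(combos) == exact_maximal

    @given(st.data())
    @settings(max_examples=15, deadline=None)
    def test_monotone_under_region_enlargement(self, data):
        n = data.draw(st.integers(2, 5))
        boxes = {}
        for cid in range(n):
            x, y = data.draw(st.integers(0, 6)), data.draw(st.integers(0, 6))
            boxes[cid] = (x * 0.1, y * 0.1, x * 0.1 + 0.3, y * 0.1 + 0.3)
        fmap = fmap_from_boxes(boxes)
        _, combos = overlap_orders(fmap, grid_step=0.01)
        grow = data.draw(st.integers(0, n - 1))
        big = dict(boxes)
        x0, y0, x1, y1 = big[grow]
        big[grow] = (x0 - 0.1, y0 - 0.1, x1 + 0.1, y1 + 0.1)
        _, combos_big = overlap_orders(fmap_from_boxes(big), grid_step=0.01)
        for c in combos:
            assert any(c <= cb for cb in combos_big)


class TestNerve:
    # seven regions arranged as a chain of triple overlaps plus a tail,
    # reproducing the reference seven-field map
    SEVEN = {
        6: (0.0, 0.0, 1.0, 1.0),
        1: (0.6, 0.0, 1.6, 1.0),
        7: (0.3, 0.0, 1.3, 1.0),
        2: (1.2, 0.0, 2.2, 1.0),
        4: (1.5, 0.0, 2.5, 1.5),
        3: (2.1, 0.0, 3.1, 1.0),
        5: (1.6, 1.2, 2.4, 2.0),
    }

    def test_seven_region_map_nerve(self):
        cx = nerve(fmap_from_boxes(self.SEVEN), grid_step=0.02)
        maximal = set(cx.maximal)
        assert maximal == {
            frozenset({6, 1, 7}),
            frozenset({7, 1, 2}),
            frozenset({1, 2, 4}),
            frozenset({2, 3, 4}),
            frozenset({4, 5}),
        }

    def test_disjoint_regions_give_isolated_vertices(self):
        fmap = fmap_from_boxes({1: (0, 0, 1, 1), 2: (2, 0, 3, 1)})
        cx = nerve(fmap, grid_step=0.05)
        assert set(cx.maximal) == {frozenset({1}), frozenset({2})}

    def test_annulus_of_patches_has_one_loop(self):
        # overlapping squares around a ring: nerve is a cycle, b1 = 1
        centers = [
            (np.cos(a), np.sin(a)) for a in np.linspace(0, 2 * np.pi, 9)[:-1]
        ]
        fmap = fmap_from_boxes(
            {
                k: (cx - 0.45, cy - 0.45, cx + 0.45, cy + 0.45)
                for k, (cx, cy) in enumerate(centers)
            }
        )
        cx = nerve(fmap, grid_step=0.02)
        assert betti_numbers(cx) == (1, 1)


class TestInformationMeasures:
    def test_identical_streams_mi_equals_entropy(self):
        labels = ["a", "b", "a", "c", "b", "a"] * 50
        h = entropy_bits(labels)
        assert mutual_information(labels, labels) == pytest.approx(h, abs=1e-9)

    def test_independent_streams_low_mi(self):
        rng = np.random.default_rng(0)
        xs = rng.integers(0, 2, 10_000)
        ys = rng.integers(0, 2, 10_000)
        assert mutual_information(xs.tolist(), ys.tolist()) < 0.01

    def test_known_joint_table(self):
        # joint {(a,a): .4, (a,b): .1, (b,a): .1, (b,b): .4} -> MI ~ 0.278
        xs, ys = [], []
        for pair, cnt in [(("a", "a"), 40), (("a", "b"), 10), (("b", "a"), 10), (("b", "b"), 40)]:
            xs += [pair[0]] * cnt
            ys += [pair[1]] * cnt
        assert mutual_information(xs, ys) == pytest.approx(0.278, abs=1e-3)

    @given(
        st.lists(
            st.tuples(st.integers(0, 3), st.integers(0, 3)), min_size=1, max_size=60
        )
    )
    @settings(max_examples=80, deadline=None)
    def test_mi_bounds(self, pairs):
        xs = [p[0] for p in pairs]
        ys = [p[1] for p in pairs]
        mi = mutual_information(xs, ys)
        assert 0.0 <= mi <= min(entropy_bits(xs), entropy_bits(ys)) + 1e-9

    def test_timeline_shapes_and_bounds(self):
        rng = np.random.default_rng(1)
        n = 400
        xs = rng.integers(0, 3, n).tolist()
        ys = [(x + rng.integers(0, 2)) % 3 for x in xs]
        tl = schema_map_information(np.arange(n) * 0.25, xs, ys, n_probes=20)
        assert len(tl.times) == len(tl.mi) == len(tl.h_schema)
        assert np.all(tl.mi >= 0)
        assert np.all(tl.mi <= np.minimum(tl.h_schema, tl.h_map) + 1e-9)


class TestPolygonRCC5:
    def test_relations(self):
        a = box(0, 0, 1, 1)
        b = box(2, 2, 3, 3)
        c = box(0.2, 0.2, 0.8, 0.8)
        d = box(0.5, 0, 1.5, 1)
        assert polygon_rcc5(a, b) == "DR"
        assert polygon_rcc5(c, a) == "PP"
        assert polygon_rcc5(a, c) == "PPi"
        assert polygon_rcc5(a, d) == "PO"
        assert polygon_rcc5(a, box(0, 0, 1, 1)) == "EQ"
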
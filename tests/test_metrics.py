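"""Overlap metrics against hand-computed values and independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from spinetrack import (
    Box2D,
    Detection2D,
    SpineTrack3D,
    box_area,
    evaluate_2d,
    f1_score,
    f_beta,
    intersection_area,
    iom_3d,
    iom_xy_2d,
    iom_z,
    iou_2d,
    match_3d,
    mean_box,
)

# ---------------------------------------------------------------------------
# rasterization oracle: boxes drawn on the 0.01-px lattice, cell centers
# counted per axis; independent of the closed-form overlap arithmetic

CELL = 0.01


def _cells_in(lo: float, hi: float) -> int:
    centers_below_hi = int(np.floor(hi / CELL + 0.5))
    centers_below_lo = int(np.floor(lo / CELL + 0.5))
    return max(0, centers_below_hi - centers_below_lo)


def _raster_area(b: Box2D) -> float:
    return _cells_in(b.x_min, b.x_max) * _cells_in(b.y_min, b.y_max) * CELL * CELL


def _raster_intersection(b1: Box2D, b2: Box2D) -> float:
    nx = _cells_in(max(b1.x_min, b2.x_min), min(b1.x_max, b2.x_max))
    ny = _cells_in(max(b1.y_min, b2.y_min), min(b1.y_max, b2.y_max))
    return nx * ny * CELL * CELL


def random_lattice_box(rng: np.random.Generator, span: float = 30.0) -> Box2D:
    """A random box whose coordinates are multiples of 0.01 px."""
    n = int(span / CELL)
    x = np.sort(rng.choice(n, size=2, replace=False)) * CELL
    y = np.sort(rng.choice(n, size=2, replace=False)) * CELL
    return Box2D(x[0], y[0], x[1], y[1])


# ---------------------------------------------------------------------------
# elementary areas and overlaps


@pytest.mark.parametrize(
    "box, expected",
    [
        (Box2D(0, 0, 10, 10), 100.0),
        (Box2D(0, 0, 1, 1), 1.0),
        (Box2D(2, 3, 7, 5), 10.0),
    ],
)
def test_box_area(box, expected):
    assert box_area(box) == expected


@pytest.mark.parametrize(
    "b1, b2, expected",
    [
        (Box2D(0, 0, 10, 10), Box2D(0, 0, 10, 10), 100.0),
        (Box2D(0, 0, 10, 10), Box2D(20, 20, 30, 30), 0.0),
        (Box2D(0, 0, 10, 10), Box2D(5, 5, 15, 15), 25.0),
    ],
)
def test_intersection_area(b1, b2, expected):
    assert intersection_area(b1, b2) == expected
    assert intersection_area(b2, b1) == expected


def test_iou_and_iom_contrast():
    """A box nested in a 4x-larger one: IoU 0.25 but IoM 1."""
    small, big = Box2D(0, 0, 10, 10), Box2D(0, 0, 20, 20)
    assert iou_2d(small, big) == 0.25
    assert iom_xy_2d(small, big) == 1.0


@pytest.mark.parametrize("fn", [iou_2d, iom_xy_2d])
def test_overlap_identity_and_disjoint(fn):
    b = Box2D(3, 4, 9, 11)
    assert fn(b, b) == 1.0
    assert fn(b, Box2D(100, 100, 110, 110)) == 0.0


def test_overlap_metrics_match_rasterization_oracle(rng):
    worst = 0.0
    for _ in range(1000):
        b1, b2 = random_lattice_box(rng), random_lattice_box(rng)
        inter = _raster_intersection(b1, b2)
        a1, a2 = _raster_area(b1), _raster_area(b2)
        oracle_iou = inter / (a1 + a2 - inter)
        oracle_iom = inter / min(a1, a2)
        worst = max(
            worst,
            abs(iou_2d(b1, b2) - oracle_iou),
            abs(iom_xy_2d(b1, b2) - oracle_iom),
        )
    assert worst < 1e-3


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    coords=hst.lists(
        hst.tuples(
            hst.floats(0, 100), hst.floats(0, 100), hst.floats(0.5, 50), hst.floats(0.5, 50)
        ),
        min_size=2,
        max_size=2,
    )
)
def test_iou_bounded_by_iom(coords):
    boxes = [Box2D(x, y, x + w, y + h) for x, y, w, h in coords]
    u, m = iou_2d(*boxes), iom_xy_2d(*boxes)
    assert 0.0 <= u <= m <= 1.0
    assert m == iom_xy_2d(boxes[1], boxes[0])  # symmetry


# ---------------------------------------------------------------------------
# z-overlap


@pytest.mark.parametrize(
    "d, g, expected",
    [
        ((3, 7), (5, 10), 3 / 5),  # shared slices {5,6,7}, shorter length 5
        ((4, 4), (4, 4), 1.0),
        ((0, 2), (5, 9), 0.0),
    ],
)
def test_iom_z_slice_count(d, g, expected):
    assert iom_z(d, g) == pytest.approx(expected)
    assert iom_z(g, d) == pytest.approx(expected)


def test_iom_z_literal_convention():
    # raw endpoint arithmetic: overlap 2, shorter raw length 4
    assert iom_z((3, 7), (5, 10), convention="literal") == pytest.approx(2 / 4)
    # degenerate single-slice intervals under the literal formula
    assert iom_z((4, 4), (4, 4), convention="literal") == 1.0
    assert iom_z((4, 4), (5, 5), convention="literal") == 0.0


def test_iom_z_matches_slice_set_oracle(rng):
    """slice_count mode equals a brute-force count over explicit index sets."""
    for _ in range(300):
        z = rng.integers(0, 30, size=4)
        d = (min(z[0], z[1]), max(z[0], z[1]))
        g = (min(z[2], z[3]), max(z[2], z[3]))
        sd, sg = set(range(d[0], d[1] + 1)), set(range(g[0], g[1] + 1))
        oracle = len(sd & sg) / min(len(sd), len(sg))
        assert iom_z(d, g) == pytest.approx(oracle)


def test_iom_z_rejects_malformed_interval():
    with pytest.raises(ValueError):
        iom_z((5, 3), (0, 1))


# ---------------------------------------------------------------------------
# 3D combination


def _track(sid, boxes_by_slice):
    return SpineTrack3D.from_boxes(spine_id=sid, boxes_by_slice=boxes_by_slice)


def test_mean_box():
    single = _track(0, {4: Box2D(1, 2, 5, 9)})
    assert mean_box(single) == Box2D(1, 2, 5, 9)
    two = _track(1, {0: Box2D(0, 0, 10, 10), 1: Box2D(2, 2, 12, 12)})
    assert mean_box(two) == Box2D(1, 1, 11, 11)
    const = _track(2, {z: Box2D(3, 3, 8, 8) for z in range(3)})
    assert mean_box(const) == Box2D(3, 3, 8, 8)


def test_f_beta_values():
    assert f_beta(1.0, 1.0) == 1.0
    assert f_beta(0.8, 0.5) == pytest.approx(2 / 2.8)
    assert f_beta(0.7, 0.0) == 0.0
    assert f_beta(0.0, 0.0) == 0.0


def test_iom_3d_equals_fbeta_of_components(rng):
    """The combined score is exactly 5xy/(x+4y) of its components, and is
    symmetric; it is 1 iff both components are 1."""
    for _ in range(1000):
        c = rng.uniform(0, 60, size=8)
        z = rng.integers(0, 12, size=4)
        d = _track(0, {s: Box2D(c[0], c[1], c[0] + 1 + c[2], c[1] + 1 + c[3])
                       for s in range(min(z[0], z[1]), max(z[0], z[1]) + 1)})
        g = _track(1, {s: Box2D(c[4], c[5], c[4] + 1 + c[6], c[5] + 1 + c[7])
                       for s in range(min(z[2], z[3]), max(z[2], z[3]) + 1)})
        x = iom_xy_2d(mean_box(d), mean_box(g))
        y = iom_z(d.z_interval, g.z_interval)
        expected = 0.0 if (x == 0 and y == 0) else 5 * x * y / (x + 4 * y)
        score = iom_3d(d, g)
        assert score == pytest.approx(expected, abs=1e-12)
        assert iom_3d(g, d) == pytest.approx(score, abs=1e-12)
        assert (score == 1.0) == (x == 1.0 and y == 1.0)


# ---------------------------------------------------------------------------
# matching and F1


@pytest.mark.parametrize(
    "tp, fp, fn, expected",
    [(2, 0, 0, 1.0), (8, 2, 2, 0.8), (0, 1, 1, 0.0)],
)
def test_f1_score(tp, fp, fn, expected):
    assert f1_score(tp, fp, fn) == pytest.approx(expected)
    assert f1_score(tp, fn, fp) == pytest.approx(expected)  # fp/fn symmetry


def test_f1_score_empty_is_zero_with_warning(caplog):
    with caplog.at_level("WARNING"):
        assert f1_score(0, 0, 0) == 0.0
    assert any("empty" in r.message for r in caplog.records)


def test_match_3d_single_pair_and_boundary():
    g = _track(0, {z: Box2D(0, 0, 10, 10) for z in range(5)})
    d = _track(1, {z: Box2D(0, 0, 10, 10) for z in range(5)})
    rep = match_3d([d], [g], threshold=0.5)
    assert (rep.tp, rep.fp, rep.fn) == (1, 0, 0) and rep.f1 == 1.0
    # a score exactly at the threshold counts as a TP
    rep = match_3d([d], [g], threshold=1.0)
    assert rep.tp == 1


def test_match_3d_empty_detections():
    gts = [_track(i, {0: Box2D(20 * i + 1, 1, 20 * i + 10, 10)}) for i in range(3)]
    rep = match_3d([], gts)
    assert (rep.tp, rep.fp, rep.fn) == (0, 0, 3) and rep.f1 == 0.0


def test_match_3d_existential_vs_one_to_one():
    """Two detections of one spine: two TPs existentially, one TP one-to-one."""
    g = _track(0, {z: Box2D(0, 0, 10, 10) for z in range(4)})
    d1 = _track(1, {z: Box2D(0, 0, 10, 10) for z in range(4)})
    d2 = _track(2, {z: Box2D(1, 1, 11, 11) for z in range(4)})
    ex = match_3d([d1, d2], [g], mode="existential")
    assert (ex.tp, ex.fp, ex.fn) == (2, 0, 0)
    oo = match_3d([d1, d2], [g], mode="one_to_one")
    assert (oo.tp, oo.fp, oo.fn) == (1, 1, 0)
    assert oo.tp <= min(2, 1)


def test_match_counts_invariants(rng):
    """existential: tp + fp = #detections; one_to_one: tp <= min(#d, #g)."""
    for _ in range(50):
        def rand_tracks(n, offset):
            out = []
            for i in range(n):
                c = rng.uniform(0, 80, size=2)
                z1 = int(rng.integers(0, 6))
                z2 = z1 + int(rng.integers(0, 4))
                out.append(_track(offset + i, {
                    z: Box2D(c[0], c[1], c[0] + rng.uniform(4, 15), c[1] + rng.uniform(4, 15))
                    for z in range(z1, z2 + 1)
                }))
            return out

        dets = rand_tracks(int(rng.integers(0, 6)), 0)
        gts = rand_tracks(int(rng.integers(1, 6)), 100)
        ex = match_3d(dets, gts, mode="existential")
        assert ex.tp + ex.fp == len(dets)
        oo = match_3d(dets, gts, mode="one_to_one")
        assert oo.tp <= min(len(dets), len(gts))
        assert oo.tp + oo.fp == len(dets) and oo.tp + oo.fn == len(gts)


def test_evaluate_2d():
    g_box = Box2D(10, 10, 20, 20)
    gts = [(3, g_box)]
    same = [Detection2D(box=g_box, slice_index=3, confidence=0.9)]
    assert evaluate_2d(same, gts).f1 == 1.0
    wrong_slice = [Detection2D(box=g_box, slice_index=4, confidence=0.9)]
    assert evaluate_2d(wrong_slice, gts).f1 == 0.0


def test_evaluate_2d_aggregates_over_slices():
    """10 gts, 8 matched + 2 spurious detections -> F1 = 16/20 = 0.8."""
    gts = [(s, Box2D(30 * i + 1, 1, 30 * i + 12, 12)) for s in range(2) for i in range(5)]
    dets = [
        Detection2D(box=b, slice_index=s, confidence=0.9) for s, b in gts[:8]
    ] + [
        Detection2D(box=Box2D(400, 400 + 20 * j, 412, 412 + 20 * j), slice_index=0, confidence=0.9)
        for j in range(2)
    ]
    rep = evaluate_2d(dets, gts)
    assert (rep.tp, rep.fp, rep.fn) == (8, 2, 2)
    assert rep.f1 == pytest.approx(0.8)
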
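import itertools

import numpy as np
import pytest

import neuroherd as nh
from neuroherd.designs import FractalDesign
from neuroherd.maxrect import largest_empty_rectangle
from neuroherd.metrics import (
    UndefinedProximityError,
    _amax_closed,
    area_raster,
    closed_form_metrics,
    connected_gap_area,
    connected_gap_area_closed,
    edge_length_raster,
    gap_rectangles,
    max_gap_width,
    mean_proximity,
    min_clearance,
    min_gap_width,
    proximity_map,
    tortuosity,
)
from neuroherd.raster import RasterMask, rasterize


def _mask(cnt, res=1.0):
    return RasterMask(cnt=np.asarray(cnt, dtype=bool), resolution=res, origin=(0.0, 0.0))


# ---------------------------------------------------------------------------
# tortuosity
# ---------------------------------------------------------------------------

def test_tortuosity_single_h_analytic():
    d = FractalDesign(D=2.0, m=1, W_CNT=20.0, W=2020.0)
    expected = (1 + 2 ** -0.5) / np.sqrt(1.5)
    assert tortuosity(d) == pytest.approx(expected, rel=1e-12)


def test_tortuosity_matches_endpoint_enumeration():
    """Brute-force mean over all 2^(N+1) finest endpoints."""
    d = nh.FRACTAL_DESIGNS["1.1-4"]
    L = d.segment_lengths()
    path = L.sum()
    ratios = []
    for signs in itertools.product((1, -1), repeat=len(L)):
        x = sum(s * l for s, l in zip(signs[0::2], L[0::2]))
        y = sum(s * l for s, l in zip(signs[1::2], L[1::2]))
        ratios.append(path / np.hypot(x, y))
    assert tortuosity(d) == pytest.approx(np.mean(ratios), rel=1e-12)


def test_tortuosity_straight_rows_is_one():
    assert tortuosity(nh.EUCLIDEAN_DESIGNS["S50C50"]) == 1.0


# ---------------------------------------------------------------------------
# proximity
# ---------------------------------------------------------------------------

def test_proximity_strip_brute_force():
    """Gap strip of width 4 px between two faces: P = mean(1, 1/2, 1/2, 1)."""
    cnt = np.zeros((3, 6), dtype=bool)
    cnt[:, 0] = cnt[:, 5] = True
    pm = proximity_map(_mask(cnt))
    assert mean_proximity(pm) == pytest.approx(0.75)
    # a gap pixel adjacent to a branch carries exactly 1/resolution
    assert pm.values[1, 1] == pytest.approx(1.0)
    assert np.isnan(pm.values[0, 0])


def test_proximity_units_scale_with_resolution():
    cnt = np.zeros((3, 6), dtype=bool)
    cnt[:, 0] = cnt[:, 5] = True
    p2 = mean_proximity(proximity_map(_mask(cnt, res=2.0)))
    assert p2 == pytest.approx(0.375)


def test_proximity_undefined_without_both_labels():
    with pytest.raises(UndefinedProximityError):
        proximity_map(_mask(np.ones((4, 4))))
    with pytest.raises(UndefinedProximityError):
        proximity_map(_mask(np.zeros((4, 4))))


# ---------------------------------------------------------------------------
# gap areas
# ---------------------------------------------------------------------------

def test_connected_gap_area_rows(small_rows):
    design, tree = small_rows
    mask = rasterize(tree, 1.0)
    assert connected_gap_area(mask) == pytest.approx(design.W * design.W_Si)
    assert connected_gap_area_closed(design) == design.W * design.W_Si


def test_connected_gap_area_checkerboard():
    cnt = np.ones((9, 9), dtype=bool)
    cnt[1::2, 1::2] = False  # isolated one-pixel gaps
    assert connected_gap_area(_mask(cnt)) == pytest.approx(1.0)


def test_largest_empty_rectangle_against_brute_force():
    rng = np.random.default_rng(3)
    free = rng.random((12, 9)) > 0.35
    area, (r, c, h, w) = largest_empty_rectangle(free)
    best = 0
    ny, nx = free.shape
    for r0 in range(ny):
        for c0 in range(nx):
            for r1 in range(r0, ny):
                for c1 in range(c0, nx):
                    if free[r0:r1 + 1, c0:c1 + 1].all():
                        best = max(best, (r1 - r0 + 1) * (c1 - c0 + 1))
    assert area == best
    assert free[r:r + h, c:c + w].all() and h * w == area


def test_gap_rectangles_rows(small_rows):
    design, tree = small_rows
    mask = rasterize(tree, 1.0)
    a_min, a_max, a_r = gap_rectangles(mask, design)
    assert a_min == a_max == pytest.approx(design.W * design.W_Si)
    assert a_r == pytest.approx(1.0)


def test_fractal_amax_raster_matches_closed_form():
    design = nh.FRACTAL_DESIGNS["1.5-4"]
    mask = rasterize(nh.build_htree(design, check_overlap=False), 1.0)
    _, a_max, _ = gap_rectangles(mask, design)
    closed = _amax_closed(design)
    assert abs(a_max - closed) / closed < 0.02


# ---------------------------------------------------------------------------
# gap widths and edge length
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "label,expected", [("1.1-4", 56.4), ("1.5-4", 101.0), ("2-6", 25.0)]
)
def test_characteristic_min_gap_widths(label, expected):
    assert min_gap_width(nh.FRACTAL_DESIGNS[label]) == pytest.approx(expected, abs=0.05)


def test_max_gap_width():
    d = nh.FRACTAL_DESIGNS["2-6"]
    assert max_gap_width(d) == pytest.approx(2 * d.base_length - d.W_CNT)
    assert max_gap_width(d) == pytest.approx(3150.5, abs=0.5)


def test_min_clearance_bounded_by_characteristic_gap():
    """The global clearance can be at most the labeled smallest gap."""
    design = nh.FRACTAL_DESIGNS["1.5-4"]
    tree = nh.build_htree(design, check_overlap=False)
    clearance = min_clearance(tree)
    assert 0.0 < clearance <= min_gap_width(design) + 1e-6


def test_edge_length_solid_block():
    cnt = np.zeros((30, 50), dtype=bool)
    cnt[5:15, 10:40] = True  # 10 x 30 block
    assert edge_length_raster(_mask(cnt)) == pytest.approx(2 * (10 + 30))


def test_raster_oracles_match_closed_forms():
    design = nh.EUCLIDEAN_DESIGNS["S25C25"]
    gm = closed_form_metrics(design)
    mask = rasterize(nh.build_euclidean(design), 1.0)
    a_cnt, a_si, _ = area_raster(mask)
    assert a_cnt == pytest.approx(gm.A_CNT)
    assert a_si == pytest.approx(gm.A_Si)
    assert edge_length_raster(mask) == pytest.approx(gm.E)


# ---------------------------------------------------------------------------
# closed-form metric properties
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("label", list(nh.FRACTAL_DESIGNS) + list(nh.EUCLIDEAN_DESIGNS))
def test_metric_invariants(label):
    design = nh.FRACTAL_DESIGNS.get(label) or nh.EUCLIDEAN_DESIGNS[label]
    gm = closed_form_metrics(design)
    assert gm.A_CNT + gm.A_Si == pytest.approx(gm.A_bounding)
    assert gm.E_n == pytest.approx(gm.E / design.W)
    assert gm.T >= 1.0
    assert gm.A_r >= 1.0
    assert 0 < gm.A_c <= gm.A_Si + 1e-9


def test_zero_width_limit():
    """As the branch width vanishes, the area vanishes with it."""
    d = FractalDesign(D=2.0, m=1, W_CNT=1e-6, W=2000.0)
    gm = closed_form_metrics(d)
    L = d.segment_lengths()
    assert gm.L_b == pytest.approx(2 * L[0] + 4 * L[1])
    assert gm.A_CNT == pytest.approx(0.0, abs=1e-2)


def test_edge_and_tortuosity_increase_with_dimension():
    metrics = [closed_form_metrics(d) for d in nh.htree_sim_series(m=4)]
    e_n = [m.E_n for m in metrics]
    t = [m.T for m in metrics]
    assert all(b >= a for a, b in zip(e_n, e_n[1:]))
    assert all(b >= a for a, b in zip(t, t[1:]))


def test_connected_area_sanity_wide_rows_vs_open_fractal():
    """The widest simulated row gap was chosen to roughly match the most
    open fractal's central connected gap area."""
    widest = nh.euclidean_sim_series()[-1]
    open_fractal = FractalDesign(D=1.1, m=4, W_CNT=20.0, W=6262.0)
    a_rows = connected_gap_area_closed(widest)
    a_tree = connected_gap_area_closed(open_fractal)
    assert abs(a_rows - a_tree) / a_tree < 0.20


def test_metrics_table(small_rows):
    design, _ = small_rows
    table = nh.metrics_table([design, nh.FRACTAL_DESIGNS["1.5-4"]])
    assert len(table) == 2
    assert {"label", "E", "E_n", "A_CNT", "A_r", "A_c"} <= set(table.columns)
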
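import numpy as np
import pytest
from shapely.geometry import Point

import neuroherd as nh
from neuroherd.imaging import render_scene
from neuroherd.quantify import (
    ThresholdError,
    UndefinedIndexWarning,
    align_mask,
    herding_indices,
    measure_glial_area,
    measure_process_length,
    profile_sums,
    regime_split,
)
from neuroherd.raster import RasterMask
from tests.conftest import make_line_scene


def _noise(shape, seed=0, mean=100.0, sigma=8.0):
    return np.random.default_rng(seed).normal(mean, sigma, shape)


# ---------------------------------------------------------------------------
# indices and regimes
# ---------------------------------------------------------------------------

def test_herding_indices_symmetry_and_limits():
    r = herding_indices((100.0, 100.0), (0.0, 50.0), 1000.0, 1000.0)
    assert r.N == pytest.approx(0.5)
    assert r.G == pytest.approx(1.0)
    r = herding_indices((200.0, 100.0), (10.0, 90.0), 1000.0, 1000.0)
    assert r.N == pytest.approx(2 / 3)
    assert r.G == pytest.approx(0.9)
    assert r.GN == pytest.approx(0.6)


def test_herding_indices_direct_formula():
    # 100 um of process entirely on a 1e6 um^2 electrode
    r = herding_indices((100.0, 0.0), (0.0, 1.0), 1e6, 1e6)
    assert r.N_CNT == pytest.approx(1e-4)
    assert r.N == pytest.approx(1.0)


def test_undefined_indices_are_flagged_not_nan():
    with pytest.warns(UndefinedIndexWarning):
        r = herding_indices((0.0, 0.0), (1.0, 1.0), 10.0, 10.0)
    assert r.N is None and r.GN is None and r.G is not None
    with pytest.raises(ValueError):
        herding_indices((1.0, 1.0), (1.0, 1.0), 0.0, 10.0)


def test_regime_split_boundary_inclusive_low():
    assert regime_split(0.95).value == "low"
    assert regime_split(0.96).value == "high"
    assert regime_split(0.0).value == "low"
    labels = regime_split([0.9, 0.99])
    assert [l.value for l in labels] == ["low", "high"]
    assert regime_split(0.95, g_threshold=0.9).value == "high"


# ---------------------------------------------------------------------------
# thresholds and blank images
# ---------------------------------------------------------------------------

def test_blank_channels_measure_zero(small_rows):
    _, tree = small_rows
    mask = nh.rasterize(tree, 1.0)
    noise = _noise(mask.shape)
    assert measure_process_length(noise, mask) == (0.0, 0.0)
    assert measure_glial_area(noise, mask) == (0.0, 0.0)
    flat = np.zeros(mask.shape)
    assert measure_process_length(flat, mask) == (0.0, 0.0)


def test_constant_glia_channel_requires_manual_threshold(small_rows):
    _, tree = small_rows
    mask = nh.rasterize(tree, 1.0)
    with pytest.raises(ThresholdError):
        measure_glial_area(np.full(mask.shape, 500.0), mask)
    on, off = measure_glial_area(np.full(mask.shape, 500.0), mask,
                                 threshold_mode=400.0)
    assert on == pytest.approx(mask.area_cnt())
    assert off == pytest.approx(mask.area_gap())


# ---------------------------------------------------------------------------
# process length measurement
# ---------------------------------------------------------------------------

def _gap_mask(small_rows, half=100.0, ps=0.32):
    _, tree = small_rows
    return tree, nh.rasterize(tree, ps, bounds=(-half, -half, half, half))


def test_straight_line_in_gap_recovered(small_rows):
    tree, mask = _gap_mask(small_rows, half=300.0)
    y_gap = 0.0  # the central gap is centered on the pattern axis
    scene = make_line_scene(mask, [[(-250.0, y_gap), (250.0, y_gap)]])
    channels = render_scene(scene, pixel_size=0.32)
    on, off = measure_process_length(channels["neuron"], mask)
    assert off == pytest.approx(500.0, rel=0.02)
    assert on < 5.0


def test_coincident_processes_count_once(small_rows):
    tree, mask = _gap_mask(small_rows, half=200.0)
    line = [(-150.0, 10.0), (150.0, 10.0)]  # inside the central gap
    scene = make_line_scene(mask, [line, line])  # two identical polylines
    channels = render_scene(scene, pixel_size=0.32)
    total = sum(measure_process_length(channels["neuron"], mask))
    assert total == pytest.approx(300.0, rel=0.02)


def test_length_partition_is_exact(culture_setup):
    """CNT + GAP lengths equal the measurement with an all-GAP mask."""
    _, mask, _, scene = culture_setup
    channels = render_scene(scene, pixel_size=0.32)
    on, off = measure_process_length(channels["neuron"], mask)
    blank = RasterMask(cnt=np.zeros_like(mask.cnt), resolution=mask.resolution,
                       origin=mask.origin)
    on0, off0 = measure_process_length(channels["neuron"], blank)
    assert on0 == 0.0
    assert on + off == pytest.approx(off0, rel=1e-9)


def test_resolution_invariance(small_rows):
    _, tree = small_rows
    lengths = []
    for ps in (0.32, 0.16):
        mask = nh.rasterize(tree, ps, bounds=(-150.0, -150.0, 150.0, 150.0))
        scene = make_line_scene(mask, [[(-100.0, 0.0), (80.0, 40.0)]])
        channels = render_scene(scene, pixel_size=ps)
        lengths.append(sum(measure_process_length(channels["neuron"], mask)))
    assert abs(lengths[0] - lengths[1]) / lengths[1] < 0.02


# ---------------------------------------------------------------------------
# glial area measurement
# ---------------------------------------------------------------------------

def test_glial_polygon_area_recovered(small_rows):
    from shapely.geometry import box as sbox

    tree, mask = _gap_mask(small_rows, half=200.0)
    # a 10^4 um^2 patch fitting inside the central 50 um gap
    patch = sbox(-104.1667, -24.0, 104.1667, 24.0)
    scene = make_line_scene(mask, [])
    scene.glial_regions = [patch]
    channels = render_scene(scene, pixel_size=0.32)
    on, off = measure_glial_area(channels["glia"], mask)
    assert off == pytest.approx(1e4, rel=0.03)
    assert on < 0.03 * 1e4


def test_full_gap_coverage_normalizes_to_one(small_rows):
    tree, mask = _gap_mask(small_rows, half=100.0)
    img = np.where(mask.cnt, 100.0, 6000.0) + _noise(mask.shape, sigma=5.0)
    on, off = measure_glial_area(img, mask)
    r = herding_indices((0.0, 1.0), (on, off), mask.area_cnt(), mask.area_gap())
    assert r.G_Si == pytest.approx(1.0, abs=0.01)
    assert r.G == pytest.approx(1.0, abs=0.01)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def test_profile_peaks_at_edges_and_gaps(culture_setup):
    """Edge-following processes put the length peaks at the electrode edges;
    gap-confined glia put coverage peaks inside the gaps."""
    _, mask, _, scene = culture_setup
    channels = render_scene(scene, pixel_size=0.32)
    curve = profile_sums(channels["neuron"], channels["glia"], mask, axis="Y")
    assert len(curve.edge_positions) > 0
    # every strong process-length peak sits within 2 px of an electrode edge
    strong = curve.N_l > 0.8 * curve.N_l.max()
    for pos in curve.positions[strong]:
        assert np.min(np.abs(curve.edge_positions - pos)) <= 2.0
    # glial coverage maxima fall in the gaps
    frac = mask.cnt.mean(axis=1)
    top_glia = np.argsort(curve.G_a)[-20:]
    assert np.mean(frac[top_glia] < 0.5) > 0.9


def test_profile_blank_images(small_rows):
    _, tree = small_rows
    mask = nh.rasterize(tree, 1.0)
    curve = profile_sums(np.zeros(mask.shape), np.zeros(mask.shape), mask)
    assert not curve.N_l.any() and not curve.G_a.any()


# ---------------------------------------------------------------------------
# mask alignment
# ---------------------------------------------------------------------------

def test_align_mask_identity_preserves_labels(small_rows):
    _, tree = small_rows
    mask = nh.rasterize(tree, 1.0)
    aligned = align_mask(mask, mask.bounds(), 1.0)
    assert np.array_equal(aligned.cnt, mask.cnt)


def test_align_mask_edge_adjust_dilates():
    cnt = np.zeros((300, 40), dtype=bool)
    cnt[100:200, :] = True  # a straight 100 px wide row
    mask = RasterMask(cnt=cnt, resolution=1.0, origin=(0.0, 0.0))
    adj = align_mask(mask, mask.bounds(), 1.0, edge_adjust_px=1)
    widths = adj.cnt.sum(axis=0)
    assert np.all(widths == 102)
    ero = align_mask(mask, mask.bounds(), 1.0, edge_adjust_px=-1)
    assert np.all(ero.cnt.sum(axis=0) == 98)


def test_align_mask_resamples_from_vector(small_rows):
    """Mask rasterized at the image grid agrees with the vector area."""
    design, tree = small_rows
    bounds = (-200.0, -200.0, 200.0, 200.0)
    aligned = align_mask(tree, bounds, 0.32)
    coarse = nh.rasterize(tree, 1.0, bounds=bounds)
    assert abs(aligned.area_cnt() - coarse.area_cnt()) / coarse.area_cnt() < 0.005
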
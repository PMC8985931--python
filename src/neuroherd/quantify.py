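"""Herding quantification: from label images to the N, G, GN indices.

The measurement chain mirrors the experimental analysis: a binary electrode
mask is aligned to the (stitched) two-channel image; the neuron channel is
binarized, soma blobs are removed, the remaining processes are skeletonized
and their length is summed with sqrt(2) weighting for diagonal steps, split
by surface label; the glia channel is thresholded (Otsu by default, with a
manual override for difficult images) and coverage areas are summed by
label.  Normalizing by the analyzed surface areas gives

    N_CNT = length on CNT / A_CNT        N_Si = length on gap / A_Si
    G_CNT = glial area on CNT / A_CNT    G_Si = glial area on gap / A_Si

and the herding indices

    N = N_CNT / (N_CNT + N_Si),  G = G_Si / (G_CNT + G_Si),  GN = G * N,

all in [0, 1] with 0.5 the neutral point.  Because skeletonization collapses
bundled or coincident processes onto one centerline, overlapping processes
are counted once — the same overlap-insensitivity the reference tracing
algorithm exhibits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import measure as _skmeasure
from skimage import morphology as _skmorph
from skimage.filters import threshold_otsu

from .designs import SegmentTree
from .raster import RasterMask, rasterize

__all__ = [
    "HerdingResult",
    "ProfileCurve",
    "RegimeLabel",
    "ThresholdError",
    "UndefinedIndexWarning",
    "align_mask",
    "measure_process_length",
    "measure_glial_area",
    "herding_indices",
    "profile_sums",
    "regime_split",
    "quantify_scene",
    "grid_shape",
]

SQRT2 = float(np.sqrt(2.0))


class ThresholdError(ValueError):
    """Automatic thresholding failed (constant/saturated image)."""


class UndefinedIndexWarning(UserWarning):
    """A herding index is undefined (both normalized terms are zero)."""


@dataclass
class HerdingResult:
    """Per-electrode herding measurements.

    Normalized process lengths are in um per um^2; glial coverages are
    dimensionless area fractions; N, G, GN are dimensionless indices in
    [0, 1] (None when undefined)."""

    label: str
    div: int | None
    N_CNT: float
    N_Si: float
    G_CNT: float
    G_Si: float
    N: float | None
    G: float | None
    GN: float | None
    area_cnt: float
    area_si: float
    n_fov_accepted: int = 1

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class ProfileCurve:
    """Per-position sums of glial coverage (G_a, pixel counts) and process
    skeleton length (N_l, pixel counts) along one image axis."""

    axis: str
    positions: np.ndarray
    G_a: np.ndarray
    N_l: np.ndarray
    edge_positions: np.ndarray


@dataclass(frozen=True)
class RegimeLabel:
    """Glial-herding regime: 'low' iff G <= threshold (default 0.95)."""

    value: str
    threshold: float = 0.95


def grid_shape(bounds: tuple[float, float, float, float], pixel_size: float) -> tuple[int, int]:
    """(ny, nx) of the pixel grid covering ``bounds`` at ``pixel_size``."""
    xmin, ymin, xmax, ymax = bounds
    nx = max(int(np.ceil((xmax - xmin) / pixel_size - 1e-9)), 1)
    ny = max(int(np.ceil((ymax - ymin) / pixel_size - 1e-9)), 1)
    return ny, nx


# ---------------------------------------------------------------------------
# mask alignment
# ---------------------------------------------------------------------------

def align_mask(
    source: RasterMask | SegmentTree,
    bounds: tuple[float, float, float, float],
    pixel_size: float,
    edge_adjust_px: int = 0,
) -> RasterMask:
    """Produce the CNT/GAP mask on the image grid.

    ``source`` may be the vector tree (rasterized directly at the image
    resolution — the preferred, exact route) or an existing RasterMask,
    which is resampled by nearest label.  ``edge_adjust_px`` dilates
    (positive) or erodes (negative) the CNT regions to absorb fabrication
    or registration slack.
    """
    if isinstance(source, SegmentTree):
        out = rasterize(source, pixel_size, bounds=bounds)
    else:
        ny, nx = grid_shape(bounds, pixel_size)
        xs = bounds[0] + (np.arange(nx) + 0.5) * pixel_size
        ys = bounds[1] + (np.arange(ny) + 0.5) * pixel_size
        xy = np.stack(np.meshgrid(xs, ys), axis=-1).reshape(-1, 2)
        cnt = source.label_at(xy).reshape(ny, nx)
        out = RasterMask(cnt=cnt, resolution=pixel_size, origin=(bounds[0], bounds[1]),
                         tree=source.tree)
    if edge_adjust_px:
        selem = _skmorph.disk(abs(int(edge_adjust_px)))
        if edge_adjust_px > 0:
            out.cnt = _skmorph.dilation(out.cnt, selem)
        else:
            out.cnt = _skmorph.erosion(out.cnt, selem)
    return out


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

def _auto_threshold(img: np.ndarray) -> float | None:
    """Otsu threshold with a separation guard.

    Returns None when the image carries no real signal (the two Otsu
    classes are closer than five background sigmas — a noise-only field),
    and raises ThresholdError for a constant image."""
    if img.max() == img.min():
        raise ThresholdError("constant image: automatic threshold undefined")
    thr = float(threshold_otsu(img))
    fg = img > thr
    if not fg.any():
        return None
    bg = img[~fg]
    if float(img[fg].mean() - bg.mean()) < 5.0 * max(float(bg.std()), 1e-9):
        return None
    return thr


# ---------------------------------------------------------------------------
# neuronal process length
# ---------------------------------------------------------------------------

def _skeleton_length_split(skel: np.ndarray, cnt: np.ndarray, resolution: float
                           ) -> tuple[float, float]:
    """Sum skeleton step lengths (1 for face steps, sqrt(2) for diagonal
    steps that are not shortcuts of an L-corner), splitting each step half
    to the label of each endpoint pixel."""
    s = skel
    len_cnt = 0.0
    len_gap = 0.0

    def _acc(pair_a: np.ndarray, pair_b: np.ndarray, sel: np.ndarray, w: float) -> None:
        nonlocal len_cnt, len_gap
        a_cnt = float(np.count_nonzero(pair_a & sel))
        b_cnt = float(np.count_nonzero(pair_b & sel))
        n = float(np.count_nonzero(sel))
        cnt_part = 0.5 * w * (a_cnt + b_cnt)
        len_cnt += cnt_part
        len_gap += w * n - cnt_part

    sel = s[:, 1:] & s[:, :-1]
    _acc(cnt[:, 1:], cnt[:, :-1], sel, 1.0)
    sel = s[1:, :] & s[:-1, :]
    _acc(cnt[1:, :], cnt[:-1, :], sel, 1.0)
    sel = s[1:, 1:] & s[:-1, :-1] & ~(s[1:, :-1] | s[:-1, 1:])
    _acc(cnt[1:, 1:], cnt[:-1, :-1], sel, SQRT2)
    sel = s[1:, :-1] & s[:-1, 1:] & ~(s[1:, 1:] | s[:-1, :-1])
    _acc(cnt[1:, :-1], cnt[:-1, 1:], sel, SQRT2)
    return len_cnt * resolution, len_gap * resolution


def _remove_somas(binary: np.ndarray, resolution: float,
                  min_area_um2: float = 80.0, min_solidity: float = 0.8) -> np.ndarray:
    """Mask out soma blobs: open away thin processes, keep compact blobs
    above the area/solidity cut, subtract them (dilated) from the binary."""
    r_open = max(2, int(round(0.8 / resolution)))
    blobs = _skmorph.opening(binary, _skmorph.disk(r_open))
    if not blobs.any():
        return binary
    labels = _skmeasure.label(blobs, connectivity=2)
    keep = np.zeros(int(labels.max()) + 1, dtype=bool)
    for p in _skmeasure.regionprops(labels):
        if p.area * resolution ** 2 > min_area_um2 and p.solidity > min_solidity:
            keep[p.label] = True
    soma = keep[labels]
    if not soma.any():
        return binary
    # dilate past the opening erosion plus the rendering halo, so no ring
    # of blob boundary survives the subtraction
    soma = _skmorph.dilation(soma, _skmorph.disk(r_open + 2))
    return binary & ~soma


def measure_process_length(
    neuron_channel: np.ndarray,
    mask: RasterMask,
    threshold: float | None = None,
    remove_somas: bool = True,
) -> tuple[float, float]:
    """(total process length on CNT, on GAP) in um.

    Binarize, remove soma blobs, skeletonize, sum skeleton length with
    sqrt(2) diagonal weighting, split by mask label per skeleton pixel.
    Bundled or coincident processes contribute once.
    """
    img = np.asarray(neuron_channel, dtype=float)
    if img.max() == img.min():
        return 0.0, 0.0
    thr = float(threshold) if threshold is not None else _auto_threshold(img)
    if thr is None:
        return 0.0, 0.0
    binary = img > thr
    if not binary.any():
        return 0.0, 0.0
    if remove_somas:
        binary = _remove_somas(binary, mask.resolution)
    skel = _skmorph.skeletonize(binary)
    return _skeleton_length_split(skel, mask.cnt, mask.resolution)


def measure_glial_area(
    glia_channel: np.ndarray,
    mask: RasterMask,
    threshold_mode: str | float = "auto",
) -> tuple[float, float]:
    """(glial coverage area on CNT, on GAP) in um^2.

    Global automatic threshold (default) or a user-supplied value; speckle
    is removed by a one-pixel morphological opening.
    """
    img = np.asarray(glia_channel, dtype=float)
    if isinstance(threshold_mode, str):
        if threshold_mode != "auto":
            raise ValueError("threshold_mode must be 'auto' or a number")
        thr = _auto_threshold(img)  # raises ThresholdError on constant input
        if thr is None:  # noise-only field
            return 0.0, 0.0
    else:
        thr = float(threshold_mode)
    binary = img > thr
    binary = _skmorph.opening(binary, _skmorph.disk(1))
    pa = mask.pixel_area
    on_cnt = float(np.count_nonzero(binary & mask.cnt)) * pa
    on_gap = float(np.count_nonzero(binary & ~mask.cnt)) * pa
    return on_cnt, on_gap


# ---------------------------------------------------------------------------
# indices, profiles, regimes
# ---------------------------------------------------------------------------

def herding_indices(
    lengths: tuple[float, float],
    glial_areas: tuple[float, float],
    area_cnt: float,
    area_si: float,
    label: str = "",
    div: int | None = None,
    n_fov_accepted: int = 1,
) -> HerdingResult:
    """Combine per-surface measurements into a HerdingResult.

    ``lengths`` is (process length on CNT, on gap) in um; ``glial_areas`` is
    (glial area on CNT, on gap) in um^2.  Undefined indices (both normalized
    terms zero) are flagged with a warning and set to None rather than NaN.
    """
    if area_cnt <= 0 or area_si <= 0:
        raise ValueError("analyzed areas must be positive")
    n_cnt = lengths[0] / area_cnt
    n_si = lengths[1] / area_si
    g_cnt = glial_areas[0] / area_cnt
    g_si = glial_areas[1] / area_si
    if n_cnt + n_si > 0:
        N = n_cnt / (n_cnt + n_si)
    else:
        warnings.warn("N undefined: no processes on either surface",
                      UndefinedIndexWarning, stacklevel=2)
        N = None
    if g_cnt + g_si > 0:
        G = g_si / (g_cnt + g_si)
    else:
        warnings.warn("G undefined: no glial coverage on either surface",
                      UndefinedIndexWarning, stacklevel=2)
        G = None
    GN = G * N if (G is not None and N is not None) else None
    return HerdingResult(label=label, div=div, N_CNT=n_cnt, N_Si=n_si, G_CNT=g_cnt,
                         G_Si=g_si, N=N, G=G, GN=GN, area_cnt=area_cnt, area_si=area_si,
                         n_fov_accepted=n_fov_accepted)


def profile_sums(
    neuron_channel: np.ndarray,
    glia_channel: np.ndarray,
    mask: RasterMask,
    axis: str = "Y",
    threshold: float | None = None,
) -> ProfileCurve:
    """Summed glial coverage (G_a) and skeletonized process length (N_l)
    per position along the chosen axis, with electrode edge positions.

    For row electrodes the Y profile (sums taken along the rows) locates
    the glia peaks in the gaps and the process peaks at the electrode
    edges."""
    axis = axis.upper()
    if axis not in ("X", "Y"):
        raise ValueError("axis must be 'X' or 'Y'")
    sum_axis = 1 if axis == "Y" else 0
    img = np.asarray(neuron_channel, dtype=float)
    thr = float(threshold) if threshold is not None else (
        _auto_threshold(img) if img.max() > img.min() else None)
    if thr is not None:
        binary = _remove_somas(img > thr, mask.resolution)
        skel = _skmorph.skeletonize(binary)
        n_l = skel.sum(axis=sum_axis).astype(float)
    else:
        n_l = np.zeros(img.shape[1 - sum_axis])
    gimg = np.asarray(glia_channel, dtype=float)
    gthr = _auto_threshold(gimg) if gimg.max() > gimg.min() else None
    if gthr is not None:
        gbin = _skmorph.opening(gimg > gthr, _skmorph.disk(1))
        g_a = gbin.sum(axis=sum_axis).astype(float)
    else:
        g_a = np.zeros(gimg.shape[1 - sum_axis])
    frac = mask.cnt.mean(axis=sum_axis)
    on = frac > 0.5
    edges = np.nonzero(on[1:] != on[:-1])[0] + 0.5
    return ProfileCurve(axis=axis, positions=np.arange(len(n_l), dtype=float),
                        G_a=g_a, N_l=n_l, edge_positions=edges)


def regime_split(results, g_threshold: float = 0.95):
    """Label HerdingResults (or raw G values) 'low' (G <= threshold) or 'high'."""
    single = isinstance(results, (HerdingResult, float, int))
    items = [results] if single else list(results)
    labels = []
    for r in items:
        g = r.G if isinstance(r, HerdingResult) else float(r)
        if g is None:
            raise ValueError("regime undefined: G is undefined")
        labels.append(RegimeLabel("low" if g <= g_threshold else "high", g_threshold))
    return labels[0] if single else labels


def quantify_scene(
    channels: dict[str, np.ndarray],
    mask: RasterMask,
    label: str = "",
    div: int | None = None,
    glia_threshold: str | float = "auto",
    neuron_threshold: float | None = None,
) -> HerdingResult:
    """Run the full measurement chain on stitched channels with an aligned mask."""
    lengths = measure_process_length(channels["neuron"], mask, threshold=neuron_threshold)
    areas = measure_glial_area(channels["glia"], mask, threshold_mode=glia_threshold)
    return herding_indices(lengths, areas, mask.area_cnt(), mask.area_gap(),
                           label=label, div=div)
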
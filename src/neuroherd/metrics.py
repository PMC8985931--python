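"""Geometric quantification of electrode patterns.

Two independent routes are provided for most quantities:

* closed forms evaluated on the vector tree (branch lengths follow the
  exact scaling law ``L_n = L_0 * 2**(-n/D)``), and
* raster oracles evaluated on a pixel mask (face-adjacency edge length,
  label counting for areas, Euclidean distance transform for proximity,
  maximal-empty-rectangle search for the largest gap rectangle).

The closed forms are fast and exact; the raster route makes no use of the
scaling law and serves as a cross-check, exactly as the pattern masks used
for the culture imaging do.

Quantities (um, um^2 unless noted):

``E``            total branch edge length; ``E_n = E / W`` (dimensionless)
``L_b``          total centerline branch length
``T``            mean tortuosity over all finest-branch endpoints (>= 1)
``P``            mean proximity: mean over gap pixels of 1/distance (um^-1)
``A_CNT/A_Si``   branch / gap areas; ``A_bounding`` their sum
``A_min/A_max``  smallest / largest branch-bounded gap rectangles
``A_r``          A_max / A_min (dimensionless, 1 for single-scaled rows)
``A_c``          largest uninterrupted central gap area
``W_Si_min/max`` characteristic smallest / largest gap widths
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .designs import (
    EuclideanDesign,
    FractalDesign,
    InvalidDesignError,
    SegmentTree,
    build_euclidean,
    build_htree,
)
from .maxrect import largest_empty_rectangle
from .raster import RasterMask, rasterize

__all__ = [
    "GeometryMetrics",
    "ProximityMap",
    "UndefinedProximityError",
    "closed_form_metrics",
    "tortuosity",
    "proximity_map",
    "mean_proximity",
    "connected_gap_area",
    "connected_gap_area_closed",
    "gap_rectangles",
    "min_gap_width",
    "max_gap_width",
    "min_clearance",
    "edge_length_raster",
    "area_raster",
    "metrics_table",
]


class UndefinedProximityError(ValueError):
    """Proximity is undefined on an all-CNT or all-GAP mask."""


@dataclass
class GeometryMetrics:
    E: float
    E_n: float
    L_b: float
    T: float
    A_CNT: float
    A_Si: float
    A_bounding: float
    A_min: float
    A_max: float
    A_r: float
    A_c: float
    W_Si_min: float | None
    W_Si_max: float
    P: float | None = None
    P_resolution: float | None = None


@dataclass
class ProximityMap:
    """Reciprocal distance-to-nearest-CNT field over gap pixels (um^-1).

    CNT pixels carry NaN; every gap value is positive."""

    values: np.ndarray
    resolution: float


# ---------------------------------------------------------------------------
# closed forms (fractal)
# ---------------------------------------------------------------------------

def _branch_length_total(design: FractalDesign) -> float:
    L = design.segment_lengths()
    return float(np.sum(2.0 ** (np.arange(design.N + 1) + 1) * L))


def _area_cnt_closed(design: FractalDesign) -> float:
    """Branch area: width times total centerline length, minus the overlap
    double-counted at every junction (each junction re-covers W_CNT^2/2)."""
    n = np.arange(1, design.N + 1)
    junction = float(np.sum(2.0 ** n)) * design.W_CNT ** 2 / 2.0
    return design.W_CNT * _branch_length_total(design) - junction


def _edge_length_closed(design: FractalDesign) -> float:
    # perimeter of the branch union for the axis-aligned tree
    return 2.0 * _area_cnt_closed(design) / design.W_CNT + 2.0 * design.W_CNT


def _bounding_height(design: FractalDesign) -> float:
    L = design.segment_lengths()
    return 2.0 * float(L[1::2].sum()) + design.W_CNT


def _amin_closed(design: FractalDesign) -> float:
    """Smallest branch-bounded gap rectangle: the cell framed by the two
    finest branch orders, (L_{N-2} - W_CNT) x (L_{N-1} - W_CNT)."""
    L = design.segment_lengths()
    a = (L[design.N - 2] - design.W_CNT) * (L[design.N - 1] - design.W_CNT)
    if a <= 0:
        raise InvalidDesignError("finest-level gap rectangle has collapsed")
    return float(a)


def _amax_closed(design: FractalDesign) -> float:
    """Largest branch-bounded gap rectangle: the central clear column between
    the innermost even-order branch columns, above (or below) the crossbar."""
    r = design.scale_ratio
    K = (design.N - 1) // 2
    L0 = design.base_length
    A = 1.0 - float(np.sum(r ** (2 * np.arange(1, K + 1))))
    B = float(np.sum(r ** (2 * np.arange(K + 1) + 1)))
    Wc = design.W_CNT
    return 2.0 * L0 ** 2 * A * B - L0 * Wc * (A + B) + (Wc / 2.0) ** 2


def connected_gap_area_closed(design: FractalDesign | EuclideanDesign) -> float:
    """Largest uninterrupted gap area.

    For rows this is a single gap, W * W_Si.  For the H-tree it is the
    central multi-scaled gap region enclosed by the branch skeleton
    (excluding the outer lobes beyond the first-level bars), evaluated in
    closed form from the scaling law.
    """
    if isinstance(design, EuclideanDesign):
        return design.W * design.W_Si
    r = design.scale_ratio
    N, K = design.N, (design.N - 1) // 2
    L0 = design.base_length
    Wc = design.W_CNT
    B = float(np.sum(r ** (2 * np.arange(K + 1) + 1)))
    C = 0.0
    for n in range(1, K + 1):
        for mm in range(n, K + 1):
            C += r ** (2 * mm + 2 * n + 1)
    S1 = 0.0
    for n in range(1, K + 1):
        for mm in range(2 * n + 1, N + 1):
            S1 += 2.0 ** mm * r ** (2 * n + mm)
    S2 = float(np.sum(r ** np.arange(N + 1)))
    return 2.0 * L0 ** 2 * (B - C) - L0 * Wc * (S1 + S2)


def min_gap_width(design: FractalDesign) -> float:
    """Characteristic smallest gap: face-to-face distance between the end of
    a finest-order branch and the facing side of its grandparent crossbar,
    ``L_{N-2} - L_N - W_CNT/2``."""
    if design.m < 2:
        raise InvalidDesignError("W_Si_min requires at least two repeating levels")
    L = design.segment_lengths()
    w = float(L[design.N - 2] - L[design.N] - design.W_CNT / 2.0)
    if w <= 0:
        raise InvalidDesignError("branches collide: smallest gap is non-positive")
    return w


def max_gap_width(design: FractalDesign) -> float:
    """Characteristic largest gap: the clear span between the two first-level
    branch pairs, ``2 L_0 - W_CNT``."""
    return 2.0 * design.base_length - design.W_CNT


def tortuosity(tree_or_design: SegmentTree | FractalDesign | EuclideanDesign) -> float:
    """Mean over all finest-branch endpoints of (along-branch path length)
    / (straight-line distance from the pattern center).

    The path length sum_{n} L_n is identical for every endpoint; the
    endpoint positions are all sign combinations of the even-order (x) and
    odd-order (y) branch lengths.  Straight rows have T = 1 by definition.
    """
    design = tree_or_design.design if isinstance(tree_or_design, SegmentTree) else tree_or_design
    if isinstance(design, EuclideanDesign):
        return 1.0
    L = design.segment_lengths()
    path = float(L.sum())
    xs = np.array([0.0])
    for l in L[0::2]:
        xs = np.concatenate([xs + l, xs - l])
    ys = np.array([0.0])
    for l in L[1::2]:
        ys = np.concatenate([ys + l, ys - l])
    d = np.sqrt(xs[:, None] ** 2 + ys[None, :] ** 2)
    return float(np.mean(path / d))


def closed_form_metrics(
    design: FractalDesign | EuclideanDesign,
    proximity_resolution: float | None = None,
) -> GeometryMetrics:
    """All closed-form geometry metrics for a design.

    Proximity has no closed form; pass ``proximity_resolution`` (um/px) to
    also rasterize the pattern and attach the distance-transform mean P.
    """
    if isinstance(design, EuclideanDesign):
        n = design.n_rows
        a_cnt = n * design.W * design.W_CNT
        a_si = (n - 1) * design.W * design.W_Si
        gm = GeometryMetrics(
            E=n * 2.0 * (design.W + design.W_CNT),
            E_n=n * 2.0 * (design.W + design.W_CNT) / design.W,
            L_b=n * design.W,
            T=1.0,
            A_CNT=a_cnt,
            A_Si=a_si,
            A_bounding=a_cnt + a_si,
            A_min=design.W * design.W_Si,
            A_max=design.W * design.W_Si,
            A_r=1.0,
            A_c=design.W * design.W_Si,
            W_Si_min=design.W_Si,
            W_Si_max=design.W_Si,
        )
    else:
        a_cnt = _area_cnt_closed(design)
        e = _edge_length_closed(design)
        a_bounding = design.W * _bounding_height(design)
        a_min = _amin_closed(design)
        a_max = _amax_closed(design)
        gm = GeometryMetrics(
            E=e,
            E_n=e / design.W,
            L_b=_branch_length_total(design),
            T=tortuosity(design),
            A_CNT=a_cnt,
            A_Si=a_bounding - a_cnt,
            A_bounding=a_bounding,
            A_min=a_min,
            A_max=a_max,
            A_r=a_max / a_min,
            A_c=connected_gap_area_closed(design),
            W_Si_min=min_gap_width(design) if design.m >= 2 else None,
            W_Si_max=max_gap_width(design),
        )
    if proximity_resolution is not None:
        tree = build_htree(design, check_overlap=False) if isinstance(design, FractalDesign) \
            else build_euclidean(design)
        mask = rasterize(tree, proximity_resolution)
        gm.P = mean_proximity(proximity_map(mask))
        gm.P_resolution = proximity_resolution
    return gm


# ---------------------------------------------------------------------------
# raster oracles
# ---------------------------------------------------------------------------

def proximity_map(mask: RasterMask) -> ProximityMap:
    """Reciprocal Euclidean distance from every gap pixel to the nearest CNT
    pixel (pixel-center metric), in um^-1 at the mask resolution."""
    if not mask.cnt.any() or mask.cnt.all():
        raise UndefinedProximityError("mask must contain both CNT and GAP pixels")
    dist = ndimage.distance_transform_edt(~mask.cnt) * mask.resolution
    values = np.full(mask.shape, np.nan)
    gap = ~mask.cnt
    values[gap] = 1.0 / dist[gap]
    return ProximityMap(values=values, resolution=mask.resolution)


def mean_proximity(pm: ProximityMap) -> float:
    """P: mean of the reciprocal-distance field over gap pixels."""
    return float(np.nanmean(pm.values))


def connected_gap_area(mask: RasterMask) -> float:
    """Area of the largest 4-connected GAP component within the bounding
    rectangle (um^2).  Diagonal-touching gaps are treated as disconnected."""
    labels, n = ndimage.label(~mask.cnt)
    if n == 0:
        return 0.0
    counts = np.bincount(labels.ravel())[1:]
    return float(counts.max()) * mask.pixel_area


def gap_rectangles(
    mask: RasterMask,
    design: FractalDesign | EuclideanDesign | None = None,
) -> tuple[float, float, float]:
    """(A_min, A_max, A_r).

    A_max is found by maximal-empty-rectangle search over the raster.
    A_min comes from the design's family of branch-bounded gap rectangles
    (closed form) when a design is given; otherwise the raster A_max of the
    inverted problem is not meaningful and a design is required.
    """
    if design is None:
        design = mask.tree.design if mask.tree is not None else None
    if design is None:
        raise ValueError("gap_rectangles needs the design to define A_min")
    if not (~mask.cnt).any():
        raise InvalidDesignError("mask has no gap pixels")
    area_px, _ = largest_empty_rectangle(~mask.cnt)
    a_max = area_px * mask.pixel_area
    if isinstance(design, EuclideanDesign):
        a_min = design.W * design.W_Si
    else:
        a_min = _amin_closed(design)
    return a_min, a_max, a_max / a_min


def edge_length_raster(mask: RasterMask) -> float:
    """Edge length by counting CNT<->GAP (and CNT<->outside) pixel face
    adjacencies; exact for axis-aligned geometry up to pixel alignment."""
    padded = np.pad(mask.cnt, 1, constant_values=False)
    horiz = padded[:, 1:] != padded[:, :-1]
    vert = padded[1:, :] != padded[:-1, :]
    return float(horiz.sum() + vert.sum()) * mask.resolution


def area_raster(mask: RasterMask) -> tuple[float, float, float]:
    """(A_CNT, A_Si, A_bounding) from label counts."""
    return mask.area_cnt(), mask.area_gap(), mask.area_bounding()


def min_clearance(tree: SegmentTree) -> float:
    """Global minimum face-to-face distance between non-touching branches.

    Exposed for transparency alongside the characteristic W_Si_min gap;
    the global clearance can be smaller when other branch pairs approach
    more closely than the labeled gap."""
    from shapely.geometry import box as _box
    from shapely.strtree import STRtree

    boxes = [_box(*s.bounds()) for s in tree.segments]
    strtree = STRtree(boxes)
    best = np.inf
    for i, (seg, geom) in enumerate(zip(tree.segments, boxes)):
        # search radius: grow until a non-touching neighbour is found
        radius = max(seg.width * 4, seg.length)
        idx = strtree.query(geom.buffer(radius))
        for j in idx:
            if j == i:
                continue
            d = geom.distance(boxes[j])
            if d > 1e-9:
                best = min(best, d)
    return float(best)


def metrics_table(designs, resolution: float | None = None):
    """One row of closed-form metrics per design, as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for d in designs:
        gm = closed_form_metrics(d, proximity_resolution=resolution)
        row = {"label": d.label, **gm.__dict__}
        if isinstance(d, FractalDesign):
            row.update(D=d.D, m=d.m, W_CNT=d.W_CNT, W=d.W)
        else:
            row.update(W_CNT=d.W_CNT, W_Si=d.W_Si, W=d.W)
        rows.append(row)
    return pd.DataFrame(rows)
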
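"""Parametric electrode designs: H-tree fractals and Euclidean row patterns.

An H-tree electrode is described by its fractal dimension ``D`` (shrinkage
rate between repeating levels), the number of repeating H levels ``m``
(branch orders run 0..N with N = 2m - 1), the branch width ``W_CNT`` and the
overall pattern width ``W``.  The base branch length ``L_0`` is not free: it
is solved from the width constraint so that every design, regardless of D,
spans the same overall width.  A Euclidean electrode is a stack of textured
rows of width ``W_CNT`` separated by smooth gaps of width ``W_Si``.

Coordinates are pattern-centered, in micrometres, with y increasing upward.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import box as _shapely_box
from shapely.strtree import STRtree

__all__ = [
    "InvalidDesignError",
    "OverlappingDesignError",
    "DegenerateDesignWarning",
    "FractalDesign",
    "EuclideanDesign",
    "Segment",
    "SegmentTree",
    "solve_base_length",
    "build_htree",
    "build_euclidean",
    "EUCLIDEAN_DESIGNS",
    "FRACTAL_DESIGNS",
    "euclidean_sim_series",
    "htree_sim_series",
    "load_design",
    "save_design",
]


class InvalidDesignError(ValueError):
    """The requested design parameters do not describe a buildable pattern."""


class OverlappingDesignError(InvalidDesignError):
    """The requested (D, m) produce branches that overlap beyond junctions."""


class DegenerateDesignWarning(UserWarning):
    """The design is buildable but degenerate (e.g. fewer than two rows)."""


@dataclass(frozen=True)
class FractalDesign:
    """H-tree design parameters.

    Parameters
    ----------
    D : float
        Fractal dimension, 1 < D <= 2.  Sets the per-order shrinkage
        ratio ``L_{n+1}/L_n = 2**(-1/D)``.
    m : int
        Number of repeating H levels (>= 1); branch orders are 0..N with
        ``N = 2m - 1``.
    W_CNT : float
        Branch width in um.
    W : float
        Overall pattern width in um (fixes the base length L_0).
    label : str
        Free-text tag, e.g. ``"1.1-4"``.
    """

    D: float
    m: int
    W_CNT: float
    W: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (1.0 < self.D <= 2.0):
            raise InvalidDesignError(f"fractal dimension must satisfy 1 < D <= 2, got {self.D}")
        if self.m < 1 or int(self.m) != self.m:
            raise InvalidDesignError(f"repeating levels m must be a positive integer, got {self.m}")
        if self.W_CNT <= 0:
            raise InvalidDesignError("branch width W_CNT must be positive")
        if self.W <= self.W_CNT:
            raise InvalidDesignError("overall width W must exceed the branch width W_CNT")

    @property
    def N(self) -> int:
        """Finest branch order, N = 2m - 1."""
        return 2 * self.m - 1

    @property
    def scale_ratio(self) -> float:
        """Per-order length ratio r = 2**(-1/D)."""
        return 2.0 ** (-1.0 / self.D)

    @property
    def base_length(self) -> float:
        return solve_base_length(self)

    def segment_lengths(self) -> np.ndarray:
        """Branch lengths L_n = L_0 * 2**(-n/D) for n = 0..N."""
        return self.base_length * self.scale_ratio ** np.arange(self.N + 1)


@dataclass(frozen=True)
class EuclideanDesign:
    """Row-electrode design: horizontal textured rows separated by gaps."""

    W_CNT: float
    W_Si: float
    W: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.W_CNT <= 0:
            raise InvalidDesignError("row width W_CNT must be positive")
        if self.W_Si <= 0:
            raise InvalidDesignError("gap width W_Si must be positive")
        if self.W_CNT > self.W:
            raise InvalidDesignError("row width cannot exceed overall width")

    @property
    def n_rows(self) -> int:
        """Largest row count with n*W_CNT + (n-1)*W_Si <= W."""
        return int(math.floor((self.W + self.W_Si) / (self.W_CNT + self.W_Si) + 1e-9))

    @property
    def height(self) -> float:
        n = self.n_rows
        return n * self.W_CNT + (n - 1) * self.W_Si


@dataclass(frozen=True)
class Segment:
    """One axis-aligned branch: a rectangle of width ``width`` centered on the
    centerline from ``p0`` (junction end) to ``p1`` (free end)."""

    order: int
    orientation: str  # "horizontal" | "vertical"
    p0: tuple[float, float]
    p1: tuple[float, float]
    length: float
    width: float

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the branch rectangle."""
        half = self.width / 2.0
        x0, y0 = self.p0
        x1, y1 = self.p1
        if self.orientation == "horizontal":
            return (min(x0, x1), y0 - half, max(x0, x1), y0 + half)
        return (x0 - half, min(y0, y1), x0 + half, max(y0, y1))


@dataclass
class SegmentTree:
    """Ordered collection of branch segments; the vector form of a pattern."""

    segments: list[Segment]
    design: FractalDesign | EuclideanDesign

    def __len__(self) -> int:
        return len(self.segments)

    def bounds(self) -> tuple[float, float, float, float]:
        if not self.segments:
            return (0.0, 0.0, 0.0, 0.0)
        arr = np.array([s.bounds() for s in self.segments])
        return (arr[:, 0].min(), arr[:, 1].min(), arr[:, 2].max(), arr[:, 3].max())

    def boxes(self) -> np.ndarray:
        """(n, 4) array of branch rectangles as (xmin, ymin, xmax, ymax)."""
        return np.array([s.bounds() for s in self.segments], dtype=float)

    def orders(self) -> np.ndarray:
        return np.array([s.order for s in self.segments], dtype=int)


def solve_base_length(design: FractalDesign) -> float:
    """Solve L_0 from the overall-width constraint.

    The half-width of the tree is the sum of the even-order branch lengths
    (orders 0, 2, ..., N-1) plus half the tip branch width, so

        W = 2 * sum_{k=0}^{m-1} L_0 * r**(2k) + W_CNT,   r = 2**(-1/D).
    """
    r = design.scale_ratio
    s_even = float(np.sum(r ** (2 * np.arange(design.m))))
    L0 = (design.W - design.W_CNT) / (2.0 * s_even)
    if L0 <= 0:
        raise InvalidDesignError(
            f"overall width W={design.W} is too small for W_CNT={design.W_CNT}"
        )
    return L0


def _check_overlap(segments: list[Segment]) -> None:
    """Raise OverlappingDesignError if two unrelated branches overlap.

    Branches that meet at a junction (parent/child, siblings, the two order-0
    bars at the pattern center) legitimately overlap there; any other pair
    with positive intersection area means the (D, m) combination closes its
    gaps and was excluded in the experimental design space.
    """
    geoms = [_shapely_box(*s.bounds()) for s in segments]
    tree = STRtree(geoms)
    pairs = tree.query(geoms, predicate="intersects")
    eps = 1e-9
    for i, j in zip(*pairs):
        if j <= i:
            continue
        si, sj = segments[i], segments[j]
        # related through a shared junction point?
        if si.p0 == sj.p0 or si.p1 == sj.p0 or sj.p1 == si.p0:
            continue
        inter = geoms[i].intersection(geoms[j])
        if inter.area > eps:
            raise OverlappingDesignError(
                f"branches of order {si.order} and {sj.order} overlap "
                f"(area {inter.area:.3g} um^2); this (D, m) is excluded"
            )


def build_htree(design: FractalDesign, check_overlap: bool = True) -> SegmentTree:
    """Construct the H-tree segment list recursively from the pattern center.

    Two horizontal order-0 bars extend +-L_0 from the center; at each free
    endpoint of an order-n segment two perpendicular order-(n+1) segments
    extend +-L_{n+1}; this repeats through order N = 2m - 1.  Orientation
    alternates with order parity (even = horizontal, odd = vertical).
    """
    lengths = design.segment_lengths()
    W_CNT = design.W_CNT
    segments: list[Segment] = []
    origin = (0.0, 0.0)
    frontier: list[Segment] = []
    for sx in (+1.0, -1.0):
        seg = Segment(0, "horizontal", origin, (sx * lengths[0], 0.0), lengths[0], W_CNT)
        segments.append(seg)
        frontier.append(seg)
    for n in range(1, design.N + 1):
        orientation = "horizontal" if n % 2 == 0 else "vertical"
        L = float(lengths[n])
        nxt: list[Segment] = []
        for parent in frontier:
            x, y = parent.p1
            for sgn in (+1.0, -1.0):
                p1 = (x + sgn * L, y) if orientation == "horizontal" else (x, y + sgn * L)
                seg = Segment(n, orientation, parent.p1, p1, L, W_CNT)
                segments.append(seg)
                nxt.append(seg)
        frontier = nxt
    tree = SegmentTree(segments, design)
    if check_overlap:
        _check_overlap(segments)
    return tree


def build_euclidean(design: EuclideanDesign) -> SegmentTree:
    """Construct the row pattern: n_rows horizontal W x W_CNT rectangles
    separated by W_Si, vertically centered about y = 0."""
    n = design.n_rows
    if n < 2:
        warnings.warn(
            f"design {design.label or design} packs only {n} row(s)",
            DegenerateDesignWarning,
            stacklevel=2,
        )
    height = design.height
    pitch = design.W_CNT + design.W_Si
    y_bottom = -height / 2.0
    segments = []
    for i in range(n):
        yc = y_bottom + design.W_CNT / 2.0 + i * pitch
        segments.append(
            Segment(0, "horizontal", (-design.W / 2.0, yc), (design.W / 2.0, yc),
                    design.W, design.W_CNT)
        )
    return SegmentTree(segments, design)


# ---------------------------------------------------------------------------
# The experimental design catalogue.  Overall widths follow the precise
# fabrication numbers: 6000 um for all Euclidean rows, 6020 um for the m = 4
# fractals and 6262 um for the D = 2, m = 5 and 6 fractals (chosen so the
# smallest 2-6 gap is 25 um).
# ---------------------------------------------------------------------------

EUCLIDEAN_DESIGNS: dict[str, EuclideanDesign] = {
    label: EuclideanDesign(W_CNT=wc, W_Si=ws, W=6000.0, label=label)
    for label, wc, ws in [
        ("S100C100", 100.0, 100.0),
        ("S75C100", 100.0, 75.0),
        ("S50C100", 100.0, 50.0),
        ("S25C100", 100.0, 25.0),
        ("S75C75", 75.0, 75.0),
        ("S50C50", 50.0, 50.0),
        ("S25C25", 25.0, 25.0),
    ]
}

FRACTAL_DESIGNS: dict[str, FractalDesign] = {
    label: FractalDesign(D=D, m=m, W_CNT=20.0, W=W, label=label)
    for label, D, m, W in [
        ("1.1-4", 1.1, 4, 6020.0),
        ("1.5-4", 1.5, 4, 6020.0),
        ("2-4", 2.0, 4, 6020.0),
        ("2-5", 2.0, 5, 6262.0),
        ("2-6", 2.0, 6, 6262.0),
    ]
}


def euclidean_sim_series() -> list[EuclideanDesign]:
    """The simulated wide-gap row series: W_Si = 200..1100 um in 100 um steps."""
    return [
        EuclideanDesign(W_CNT=100.0, W_Si=float(ws), W=6000.0, label=f"sim-S{ws}C100")
        for ws in range(200, 1200, 100)
    ]


def htree_sim_series(m: int = 4) -> list[FractalDesign]:
    """The simulated fractal series: D = 1.1..2.0 in 0.1 steps at W = 6262 um."""
    return [
        FractalDesign(D=round(d / 10.0, 1), m=m, W_CNT=20.0, W=6262.0,
                      label=f"sim-{d / 10.0:.1f}-{m}")
        for d in range(11, 21)
    ]


def save_design(design: FractalDesign | EuclideanDesign, path: str | Path) -> None:
    if isinstance(design, FractalDesign):
        payload = {"type": "htree", "D": design.D, "m": design.m,
                   "W_CNT": design.W_CNT, "W": design.W, "label": design.label}
    else:
        payload = {"type": "rows", "W_CNT": design.W_CNT, "W_Si": design.W_Si,
                   "W": design.W, "label": design.label}
    Path(path).write_text(json.dumps(payload, indent=2))


def load_design(path: str | Path) -> FractalDesign | EuclideanDesign:
    payload = json.loads(Path(path).read_text())
    kind = payload.pop("type")
    if kind == "htree":
        return FractalDesign(**payload)
    if kind == "rows":
        return EuclideanDesign(**payload)
    raise InvalidDesignError(f"unknown design type {kind!r}")


def build(design: FractalDesign | EuclideanDesign, **kwargs) -> SegmentTree:
    """Dispatch to :func:`build_htree` or :func:`build_euclidean`."""
    if isinstance(design, FractalDesign):
        return build_htree(design, **kwargs)
    return build_euclidean(design)
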
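"""Raster form of an electrode pattern: a CNT/GAP label grid.

The grid uses pixel-center sampling: a pixel is CNT iff its center lies
inside the union of branch rectangles.  Arrays are 0-based and row-major
with the row index increasing with y (row 0 is the bottom of the pattern);
TIFF/PNG export flips to the usual image convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .designs import SegmentTree, InvalidDesignError

__all__ = ["RasterMask", "rasterize", "save_mask", "load_mask", "export_svg"]


@dataclass
class RasterMask:
    """CNT/GAP label grid over a rectangle of the pattern plane.

    Attributes
    ----------
    cnt : bool ndarray (ny, nx)
        True where the pixel is CNT (electrode), False for GAP.
    resolution : float
        Pixel size in um.
    origin : (float, float)
        Pattern coordinates of the lower-left corner of the grid.
    tree : SegmentTree or None
        The vector pattern this mask was rasterized from, when available.
    """

    cnt: np.ndarray
    resolution: float
    origin: tuple[float, float]
    tree: SegmentTree | None = field(default=None, repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.cnt.shape

    @property
    def gap(self) -> np.ndarray:
        return ~self.cnt

    @property
    def pixel_area(self) -> float:
        return self.resolution ** 2

    def bounds(self) -> tuple[float, float, float, float]:
        ny, nx = self.cnt.shape
        x0, y0 = self.origin
        return (x0, y0, x0 + nx * self.resolution, y0 + ny * self.resolution)

    def area_cnt(self) -> float:
        return float(self.cnt.sum()) * self.pixel_area

    def area_gap(self) -> float:
        return float((~self.cnt).sum()) * self.pixel_area

    def area_bounding(self) -> float:
        return self.cnt.size * self.pixel_area

    def world_to_index(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map (n, 2) pattern coordinates to (row, col) indices, clipped."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        cols = np.floor((xy[:, 0] - self.origin[0]) / self.resolution).astype(int)
        rows = np.floor((xy[:, 1] - self.origin[1]) / self.resolution).astype(int)
        ny, nx = self.cnt.shape
        return np.clip(rows, 0, ny - 1), np.clip(cols, 0, nx - 1)

    def label_at(self, xy: np.ndarray) -> np.ndarray:
        """True where the pattern-coordinate points fall on CNT."""
        rows, cols = self.world_to_index(xy)
        return self.cnt[rows, cols]


def rasterize(
    tree: SegmentTree,
    resolution: float = 1.0,
    bounds: tuple[float, float, float, float] | None = None,
) -> RasterMask:
    """Rasterize a segment tree onto a pixel grid.

    Parameters
    ----------
    tree : SegmentTree
    resolution : float
        Pixel size in um.  Must resolve the branch width (finer than W_CNT).
    bounds : optional (xmin, ymin, xmax, ymax)
        Window to rasterize; defaults to the tight bounding box of the
        branch union.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if tree.segments:
        min_width = min(s.width for s in tree.segments)
        if resolution >= min_width:
            raise InvalidDesignError(
                f"resolution {resolution} um/px cannot resolve branches of "
                f"width {min_width} um"
            )
    if bounds is None:
        if not tree.segments:
            raise InvalidDesignError("cannot infer bounds of an empty tree")
        bounds = tree.bounds()
    xmin, ymin, xmax, ymax = bounds
    nx = max(int(np.ceil((xmax - xmin) / resolution - 1e-9)), 1)
    ny = max(int(np.ceil((ymax - ymin) / resolution - 1e-9)), 1)
    cnt = np.zeros((ny, nx), dtype=bool)
    for seg in tree.segments:
        bx0, by0, bx1, by1 = seg.bounds()
        # first/last pixel whose CENTER lies inside [b0, b1]
        i0 = int(np.ceil((bx0 - xmin) / resolution - 0.5 - 1e-9))
        i1 = int(np.floor((bx1 - xmin) / resolution - 0.5 + 1e-9))
        j0 = int(np.ceil((by0 - ymin) / resolution - 0.5 - 1e-9))
        j1 = int(np.floor((by1 - ymin) / resolution - 0.5 + 1e-9))
        i0, i1 = max(i0, 0), min(i1, nx - 1)
        j0, j1 = max(j0, 0), min(j1, ny - 1)
        if i1 >= i0 and j1 >= j0:
            cnt[j0:j1 + 1, i0:i1 + 1] = True
    return RasterMask(cnt=cnt, resolution=resolution, origin=(xmin, ymin), tree=tree)


def save_mask(mask: RasterMask, path: str | Path) -> None:
    """Write an 8-bit mask image (CNT=255, GAP=0) plus a JSON sidecar."""
    from PIL import Image

    path = Path(path)
    img = (np.flipud(mask.cnt).astype(np.uint8)) * 255
    Image.fromarray(img).save(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "resolution_um_per_px": mask.resolution,
        "origin_um": list(mask.origin),
        "shape": list(mask.shape),
        "row0": "top",
    }, indent=2))


def load_mask(path: str | Path) -> RasterMask:
    from PIL import Image

    path = Path(path)
    img = np.asarray(Image.open(path))
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    cnt = np.flipud(img > 127)
    return RasterMask(cnt=cnt.copy(), resolution=float(meta["resolution_um_per_px"]),
                      origin=tuple(meta["origin_um"]))


def export_svg(tree: SegmentTree, path: str | Path) -> None:
    """Write the branch rectangles as an SVG for visual inspection."""
    xmin, ymin, xmax, ymax = tree.bounds()
    w, h = xmax - xmin, ymax - ymin
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" viewBox="0 0 {w:.2f} {h:.2f}" '
        f'width="{w:.0f}" height="{h:.0f}">',
        f'<rect x="0" y="0" width="{w:.2f}" height="{h:.2f}" fill="white"/>',
    ]
    for seg in tree.segments:
        x0, y0, x1, y1 = seg.bounds()
        # SVG y axis points down
        parts.append(
            f'<rect x="{x0 - xmin:.3f}" y="{ymax - y1:.3f}" '
            f'width="{x1 - x0:.3f}" height="{y1 - y0:.3f}" fill="black"/>'
        )
    parts.append("</svg>")
    Path(path).write_text("\n".join(parts))
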
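"""Rendering synthetic scenes to tiled two-channel images, and stitching.

Fields of view follow the microscopy geometry: 2048 x 2048 pixel tiles at
0.32 um/pixel with 10 % overlap between neighbours.  Channels are 16-bit:
``neuron`` (process label), ``glia`` (glial label) and ``nuclei``.
Processes are rendered as ~1 um wide anti-aliased curves, somas as bright
blobs, glial regions as filled areas; Poisson shot noise and a Gaussian
background are added per tile.  Stitching places tiles on the fixed grid
(stride = tile x (1 - overlap)) and averages the overlap strips.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import draw as _skdraw
from skimage import morphology as _skmorph

from .quantify import grid_shape
from .raster import RasterMask

__all__ = [
    "FOVTile",
    "tile_grid",
    "render_scene",
    "render_fov_tiles",
    "stitch_tiles",
    "write_tiles",
    "read_tiles",
]

CHANNELS = ("neuron", "glia", "nuclei")


@dataclass
class FOVTile:
    """One field of view: 16-bit channel images plus its grid position."""

    channels: dict[str, np.ndarray]
    row: int
    col: int
    pixel_size: float
    overlap: float


def tile_grid(shape_px: tuple[int, int], tile: int, overlap: float
              ) -> tuple[int, int, int]:
    """(n_rows, n_cols, stride_px) covering an image of ``shape_px``."""
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must be in [0, 1)")
    stride = int(np.floor(tile * (1.0 - overlap)))
    ny, nx = shape_px
    n_rows = max(int(np.ceil(ny / stride)), 1)
    n_cols = max(int(np.ceil(nx / stride)), 1)
    return n_rows, n_cols, stride


def _fill_polygons(polygons, mask: RasterMask) -> np.ndarray:
    """Boolean raster of shapely polygons on the mask grid."""
    out = np.zeros(mask.shape, dtype=bool)
    res = mask.resolution
    x0, y0 = mask.origin
    for poly in polygons:
        geoms = poly.geoms if hasattr(poly, "geoms") else [poly]
        for g in geoms:
            xs, ys = np.asarray(g.exterior.coords).T
            rr, cc = _skdraw.polygon((ys - y0) / res - 0.5, (xs - x0) / res - 0.5,
                                     shape=out.shape)
            out[rr, cc] = True
            for ring in g.interiors:
                xs, ys = np.asarray(ring.coords).T
                rr, cc = _skdraw.polygon((ys - y0) / res - 0.5, (xs - x0) / res - 0.5,
                                         shape=out.shape)
                out[rr, cc] = False
    return out


def render_scene(
    scene,
    pixel_size: float = 0.32,
    line_amp: float = 8000.0,
    soma_amp: float = 12000.0,
    glia_amp: float = 6000.0,
    soma_radius: float = 7.5,
    blur_sigma_px: float = 0.8,
) -> dict[str, np.ndarray]:
    """Render noise-free floating-point channels over the scene bounds."""
    ny, nx = grid_shape(scene.bounds, pixel_size)
    x0, y0 = scene.bounds[0], scene.bounds[1]

    def to_px(xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cols = (xy[:, 0] - x0) / pixel_size - 0.5
        rows = (xy[:, 1] - y0) / pixel_size - 0.5
        return rows, cols

    neuron = np.zeros((ny, nx), dtype=float)
    glia = np.zeros((ny, nx), dtype=float)
    nuclei = np.zeros((ny, nx), dtype=float)

    # processes: stamp centerline samples, widen by one-pixel dilation
    lines = np.zeros((ny, nx), dtype=bool)
    for p in scene.processes:
        v = p.vertices
        seg = np.diff(v, axis=0)
        seglen = np.hypot(seg[:, 0], seg[:, 1])
        n_samp = np.maximum((seglen / (0.5 * pixel_size)).astype(int), 1)
        pts = [v[:1]]
        for i, n in enumerate(n_samp):
            t = np.linspace(0, 1, n + 1)[1:, None]
            pts.append(v[i] * (1 - t) + v[i + 1] * t)
        pts = np.vstack(pts)
        rows, cols = to_px(pts)
        rows = np.clip(np.round(rows).astype(int), 0, ny - 1)
        cols = np.clip(np.round(cols).astype(int), 0, nx - 1)
        lines[rows, cols] = True
    if lines.any():
        lines = _skmorph.dilation(lines, _skmorph.disk(1))
        neuron[lines] = line_amp

    # somas: clustered neurons render as one compact aggregate blob (the
    # soma clusters seen in culture); unclustered cells individually
    def _disk(img, x, y, r_um, amp):
        rr, cc = _skdraw.disk(((y - y0) / pixel_size - 0.5, (x - x0) / pixel_size - 0.5),
                              max(r_um / pixel_size, 1.0), shape=(ny, nx))
        img[rr, cc] = amp

    for (x, y) in scene.soma_xy:
        _disk(nuclei, x, y, 2.5, soma_amp)
    for c in getattr(scene, "clusters", []):
        cx, cy = c["centroid"]
        _disk(neuron, cx, cy, c["radius"], soma_amp)
    cluster = np.asarray(scene.soma_cluster)
    is_neuron = scene.soma_kind == "neuron"
    for (x, y) in scene.soma_xy[(cluster < 0) & is_neuron]:
        _disk(neuron, x, y, soma_radius, soma_amp)

    # glial regions
    if scene.glial_regions:
        ref = RasterMask(cnt=np.zeros((ny, nx), dtype=bool), resolution=pixel_size,
                         origin=(x0, y0))
        filled = _fill_polygons(scene.glial_regions, ref)
        glia[filled] = glia_amp

    out = {"neuron": neuron, "glia": glia, "nuclei": nuclei}
    if blur_sigma_px > 0:
        out = {k: ndimage.gaussian_filter(v, blur_sigma_px) for k, v in out.items()}
    return out


def render_fov_tiles(
    scene,
    pixel_size: float = 0.32,
    tile: int = 2048,
    overlap: float = 0.10,
    noise: bool = True,
    background: float = 100.0,
    background_sigma: float = 8.0,
    **render_kwargs,
) -> tuple[list[FOVTile], dict]:
    """Render the scene and cut it into overlapping 16-bit tiles.

    Returns (tiles, manifest).  Tiles cover the full field on the fixed
    grid; border tiles are zero-padded.  Noise (Poisson shot noise plus a
    Gaussian background) is drawn per tile from the scene seed, so the
    render is deterministic."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    channels = render_scene(scene, pixel_size=pixel_size, **render_kwargs)
    ny, nx = channels["neuron"].shape
    n_rows, n_cols, stride = tile_grid((ny, nx), tile, overlap)
    seeds = np.random.SeedSequence([scene.rng_seed, 2]).spawn(n_rows * n_cols)
    tiles: list[FOVTile] = []
    for r in range(n_rows):
        for c in range(n_cols):
            rng = np.random.default_rng(seeds[r * n_cols + c])
            y0, x0 = r * stride, c * stride
            chans = {}
            for name in CHANNELS:
                sub = np.zeros((tile, tile), dtype=float)
                src = channels[name][y0:min(y0 + tile, ny), x0:min(x0 + tile, nx)]
                sub[:src.shape[0], :src.shape[1]] = src
                if noise:
                    signal = sub > 0
                    if signal.any():
                        sub[signal] = rng.poisson(sub[signal]).astype(float)
                    sub += rng.normal(background, background_sigma, sub.shape)
                chans[name] = np.clip(sub, 0, 65535).astype(np.uint16)
            tiles.append(FOVTile(channels=chans, row=r, col=c,
                                 pixel_size=pixel_size, overlap=overlap))
    manifest = {
        "label": scene.label,
        "div": scene.div,
        "seed": scene.rng_seed,
        "pixel_size": pixel_size,
        "tile": tile,
        "overlap": overlap,
        "stride": stride,
        "grid": [n_rows, n_cols],
        "scene_bounds": list(scene.bounds),
        "scene_shape": [ny, nx],
        "channels": list(CHANNELS),
        "excluded": [],
    }
    return tiles, manifest


def stitch_tiles(tiles: list[FOVTile], manifest: dict) -> dict[str, np.ndarray]:
    """Average-stitch tiles onto the fixed grid.

    Output size is (n-1) * stride + tile per axis (it may extend past the
    original scene by the border padding).  Tiles listed in the manifest's
    ``excluded`` list are ignored; any other missing tile is a hard error.
    """
    n_rows, n_cols = manifest["grid"]
    tile = manifest["tile"]
    stride = manifest["stride"]
    excluded = {tuple(e) for e in manifest.get("excluded", [])}
    have = {(t.row, t.col): t for t in tiles}
    missing = [(r, c) for r in range(n_rows) for c in range(n_cols)
               if (r, c) not in have and (r, c) not in excluded]
    if missing:
        raise ValueError(f"missing tiles at grid positions {missing}")
    ny = (n_rows - 1) * stride + tile
    nx = (n_cols - 1) * stride + tile
    out = {}
    for name in manifest["channels"]:
        acc = np.zeros((ny, nx), dtype=float)
        weight = np.zeros((ny, nx), dtype=float)
        for (r, c), t in have.items():
            if (r, c) in excluded:
                continue
            y0, x0 = r * stride, c * stride
            acc[y0:y0 + tile, x0:x0 + tile] += t.channels[name].astype(float)
            weight[y0:y0 + tile, x0:x0 + tile] += 1.0
        out[name] = acc / np.maximum(weight, 1.0)
    return out


def crop_to_scene(channels: dict[str, np.ndarray], manifest: dict) -> dict[str, np.ndarray]:
    """Cut a stitched field back to the original scene extent."""
    ny, nx = manifest["scene_shape"]
    return {k: v[:ny, :nx] for k, v in channels.items()}


def write_tiles(tiles: list[FOVTile], manifest: dict, out_dir: str | Path) -> None:
    """Write tiles as multi-channel 16-bit TIFFs plus a JSON manifest."""
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    label = manifest.get("label") or "scene"
    for t in tiles:
        stack = np.stack([t.channels[c] for c in manifest["channels"]])
        tifffile.imwrite(out_dir / f"{label}_r{t.row}_c{t.col}.tif", stack,
                         photometric="minisblack")
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_tiles(in_dir: str | Path) -> tuple[list[FOVTile], dict]:
    import tifffile

    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    label = manifest.get("label") or "scene"
    tiles = []
    n_rows, n_cols = manifest["grid"]
    for r in range(n_rows):
        for c in range(n_cols):
            path = in_dir / f"{label}_r{r}_c{c}.tif"
            if not path.exists():
                continue
            stack = tifffile.imread(path)
            chans = {name: stack[i] for i, name in enumerate(manifest["channels"])}
            tiles.append(FOVTile(channels=chans, row=r, col=c,
                                 pixel_size=manifest["pixel_size"],
                                 overlap=manifest["overlap"]))
    return tiles, manifest
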
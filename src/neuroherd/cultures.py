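"""Synthetic neuron/glia cultures on electrode masks, with exact ground truth.

The generator emulates the spatial structure of dissociated retinal cultures
on textured-electrode/smooth-gap substrates rather than their cell biology:

* homogeneous Poisson seeding at the experimental density
  (9.3e3 cells mm^-2 by default), neurons vs glia by a fixed fraction;
* neuron migration as an hourly biased random walk (speeds 10-20 um/h) that
  attaches preferentially to the textured electrode surface;
* neuronal processes that follow electrode edges, and that connect soma
  clusters to each other and to nearby branches in the gaps (bundles);
* total process length rising to a maximal-complexity peak at 7 days in
  vitro and declining by 17 days through pruning and bundle merging;
* glial coverage as disks in the gaps whose retention is weighted by
  proximity to the branches — producing glia-rich boundary zones near
  branches and nearly glia-free deserts in low-proximity gaps — with rare
  attachment on the electrode itself.

Every scene is reproducible bit-for-bit from (mask, params, seed), and
exact ground-truth measurements (polyline lengths and polygon areas split
by surface) are available for pipeline-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from shapely.geometry import Point, box as _shapely_box
from shapely.ops import unary_union

from .quantify import HerdingResult, herding_indices
from .raster import RasterMask

__all__ = [
    "CultureParams",
    "Process",
    "SyntheticScene",
    "seed_cells",
    "simulate_development",
    "ground_truth_measurements",
]

# Development-time factors expressing the observed 7-DIV complexity peak:
# process lengths grow until ~7 DIV; by 17 DIV pruning and bundle merging
# reduce the number of connections while glial coverage keeps increasing.
_LENGTH_FACTOR = {3: 0.55, 7: 1.0, 17: 1.0}
_EDGE_COVERAGE = {3: 0.50, 7: 0.85, 17: 0.55}   # fraction of edge length occupied
_SECOND_LINK_P = {3: 0.20, 7: 0.60, 17: 0.10}   # extra cluster-cluster links
_BOUNDARY_LINK_P = {3: 0.40, 7: 0.80, 17: 0.70}
_NEAREST_LINK_P = {3: 0.70, 7: 1.00, 17: 1.00}
_GLIA_TIME = {3: 0.45, 7: 0.75, 17: 1.0}        # glial growth factor
_BODY_MARGIN = 16.0  # um: cell bodies stay clear of the field border, so no
                     # soma is clipped into an unremovable fragment


@dataclass(frozen=True)
class CultureParams:
    """Synthetic-culture conditions.

    Defaults are the study conditions: seeding density 9.3e3 cells/mm^2,
    migration speeds uniform in 10-20 um/h, culture times 3/7/17 DIV
    (72/168/408 hourly steps).  ``neuron_fraction`` is not reported for the
    dissociated retina; 0.7 is used and only the spatial contrast depends
    on it.  Affinities are relative adhesion weights: ``cnt_neuron_affinity``
    sets the per-contact probability a migrating neuron anchors on the
    textured surface, ``gap_glia_affinity`` the gap:electrode retention
    ratio for glia."""

    seed_density: float = 9.3e3          # cells per mm^2
    neuron_fraction: float = 0.7
    div: int = 17                        # days in vitro (3, 7 or 17)
    migration_speed: tuple[float, float] = (10.0, 20.0)  # um/h
    cnt_neuron_affinity: float = 3.0
    gap_glia_affinity: float = 10.0
    cluster_scale: float = 100.0         # um
    glia_growth: float = 1.0             # scales glial disk radii; 0 = no glia
    glia_radius: float = 14.0            # um, base disk radius at 17 DIV
    edge_inset: float = 0.5              # um, follower inset inside the branch
    follower_length: float = 110.0       # um, mean edge-follower length
    min_cluster_size: int = 3
    proximity_scale: float = 60.0        # um, glial retention ~ min(1, scale/d)
    boundary_reach: float = 150.0        # um, cluster-to-branch link range
    walk_hours: int = 48                 # migration phase length (h)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.seed_density < 0:
            raise ValueError("seed_density must be non-negative")
        if not (0.0 < self.neuron_fraction < 1.0):
            raise ValueError("neuron_fraction must be in (0, 1)")
        if self.div not in _LENGTH_FACTOR:
            raise ValueError(f"div must be one of {sorted(_LENGTH_FACTOR)}")
        if self.migration_speed[0] <= 0 or self.migration_speed[1] < self.migration_speed[0]:
            raise ValueError("migration_speed must be a positive (low, high) pair")


@dataclass
class Process:
    """One neuronal process: a polyline with a per-sub-segment surface flag."""

    vertices: np.ndarray          # (k, 2) um
    on_cnt: np.ndarray            # (k-1,) bool, True where sub-segment is on CNT
    kind: str = "bundle"          # "edge" | "bundle" | "boundary"

    def length(self) -> float:
        d = np.diff(self.vertices, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def length_split(self) -> tuple[float, float]:
        d = np.diff(self.vertices, axis=0)
        seg = np.hypot(d[:, 0], d[:, 1])
        on = float(seg[self.on_cnt].sum())
        return on, float(seg.sum()) - on


@dataclass
class SyntheticScene:
    """Generated somas, processes and glial coverage on an electrode field."""

    label: str
    bounds: tuple[float, float, float, float]
    soma_xy: np.ndarray
    soma_kind: np.ndarray              # 'neuron' | 'glia'
    soma_cluster: np.ndarray           # cluster id, -1 for none
    processes: list[Process] = field(default_factory=list)
    glial_regions: list = field(default_factory=list)  # shapely polygons
    clusters: list[dict] = field(default_factory=list)  # centroid, n, radius, on_cnt
    div: int = 17
    rng_seed: int = 0
    params: CultureParams | None = None
    ground_truth: HerdingResult | None = None

    @property
    def n_cells(self) -> int:
        return len(self.soma_xy)

    def total_process_length(self) -> float:
        return float(sum(p.length() for p in self.processes))

    def glial_union(self):
        return unary_union(self.glial_regions) if self.glial_regions else None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "label": self.label,
            "bounds": list(self.bounds),
            "div": self.div,
            "rng_seed": self.rng_seed,
            "soma_xy": self.soma_xy.tolist(),
            "soma_kind": self.soma_kind.tolist(),
            "soma_cluster": self.soma_cluster.tolist(),
            "processes": [
                {"vertices": p.vertices.tolist(), "on_cnt": p.on_cnt.tolist(),
                 "kind": p.kind}
                for p in self.processes
            ],
            "glial_regions": [
                np.asarray(g.exterior.coords).tolist() for g in self.glial_regions
            ],
            "clusters": [
                {"centroid": list(map(float, c["centroid"])), "n": int(c["n"]),
                 "radius": float(c["radius"]), "on_cnt": bool(c["on_cnt"])}
                for c in self.clusters
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticScene":
        from shapely.geometry import Polygon

        payload = json.loads(Path(path).read_text())
        return cls(
            label=payload["label"],
            bounds=tuple(payload["bounds"]),
            soma_xy=np.asarray(payload["soma_xy"], dtype=float).reshape(-1, 2),
            soma_kind=np.asarray(payload["soma_kind"]),
            soma_cluster=np.asarray(payload["soma_cluster"], dtype=int),
            processes=[
                Process(np.asarray(p["vertices"], dtype=float),
                        np.asarray(p["on_cnt"], dtype=bool), p["kind"])
                for p in payload["processes"]
            ],
            glial_regions=[Polygon(c) for c in payload["glial_regions"]],
            clusters=[
                {"centroid": np.asarray(c["centroid"]), "n": c["n"],
                 "radius": c["radius"], "on_cnt": c["on_cnt"]}
                for c in payload.get("clusters", [])
            ],
            div=payload["div"],
            rng_seed=payload["rng_seed"],
        )


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

def seed_cells(mask: RasterMask, params: CultureParams,
               rng: np.random.Generator | None = None) -> SyntheticScene:
    """Homogeneous spatial Poisson seeding over the mask's bounding rectangle."""
    xmin, ymin, xmax, ymax = mask.bounds()
    area_mm2 = (xmax - xmin) * (ymax - ymin) / 1e6
    if area_mm2 <= 0:
        raise ValueError("mask has zero area")
    rng = rng if rng is not None else np.random.default_rng(params.rng_seed)
    n = int(rng.poisson(params.seed_density * area_mm2))
    m = min(_BODY_MARGIN, 0.25 * min(xmax - xmin, ymax - ymin))
    xy = np.column_stack([rng.uniform(xmin + m, xmax - m, n),
                          rng.uniform(ymin + m, ymax - m, n)])
    kind = np.where(rng.random(n) < params.neuron_fraction, "neuron", "glia")
    label = mask.tree.design.label if mask.tree is not None else ""
    return SyntheticScene(label=label, bounds=(xmin, ymin, xmax, ymax),
                          soma_xy=xy, soma_kind=kind,
                          soma_cluster=np.full(n, -1, dtype=int),
                          div=params.div, rng_seed=params.rng_seed, params=params)


# ---------------------------------------------------------------------------
# development
# ---------------------------------------------------------------------------

def _densify(p0: np.ndarray, p1: np.ndarray, step: float = 2.0) -> np.ndarray:
    d = float(np.hypot(*(p1 - p0)))
    n = max(int(np.ceil(d / step)), 1)
    t = np.linspace(0.0, 1.0, n + 1)[:, None]
    return p0[None, :] * (1 - t) + p1[None, :] * t


def _label_polyline(vertices: np.ndarray, mask: RasterMask) -> np.ndarray:
    mids = 0.5 * (vertices[1:] + vertices[:-1])
    return mask.label_at(mids)


def _make_process(points: list[np.ndarray] | np.ndarray, mask: RasterMask,
                  kind: str) -> Process:
    pts = np.vstack([_densify(a, b) for a, b in zip(points[:-1], points[1:])]) \
        if len(points) > 2 else _densify(np.asarray(points[0]), np.asarray(points[1]))
    # drop duplicated joints
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(np.diff(pts, axis=0) != 0, axis=1)
    pts = pts[keep]
    return Process(vertices=pts, on_cnt=_label_polyline(pts, mask), kind=kind)


def _edges_from_tree(tree, bounds, inset: float, margin: float = 2.0):
    """Long-side edge lines of every branch rectangle, clipped to bounds and
    inset into the branch so edge-following processes sit on CNT."""
    xmin, ymin, xmax, ymax = bounds
    edges = []
    for seg in tree.segments:
        bx0, by0, bx1, by1 = seg.bounds()
        if bx1 < xmin or bx0 > xmax or by1 < ymin or by0 > ymax:
            continue
        if seg.orientation == "horizontal":
            x0, x1 = max(bx0 + margin, xmin + margin), min(bx1 - margin, xmax - margin)
            if x1 - x0 < 10:
                continue
            for y in (by1 - inset, by0 + inset):
                if ymin < y < ymax:
                    edges.append((np.array([x0, y]), np.array([x1, y])))
        else:
            y0, y1 = max(by0 + margin, ymin + margin), min(by1 - margin, ymax - margin)
            if y1 - y0 < 10:
                continue
            for x in (bx1 - inset, bx0 + inset):
                if xmin < x < xmax:
                    edges.append((np.array([x, y0]), np.array([x, y1])))
    return edges


def _edges_from_raster(mask: RasterMask, inset: float, min_run_px: int = 30):
    """Raster fallback: extract horizontal/vertical CNT boundary runs."""
    res = mask.resolution
    x0, y0 = mask.origin
    edges = []
    cnt = mask.cnt
    for flip in (False, True):
        a = cnt.T if flip else cnt
        diff = a[1:, :] != a[:-1, :]
        for j in range(diff.shape[0]):
            row = diff[j]
            idx = np.nonzero(row)[0]
            if idx.size == 0:
                continue
            splits = np.split(idx, np.nonzero(np.diff(idx) > 1)[0] + 1)
            for run in splits:
                if run.size < min_run_px:
                    continue
                lo, hi = (run[0] + 0.5) * res, (run[-1] + 0.5) * res
                side = 1.0 if a[j + 1, run[0]] else -1.0  # CNT above/right of boundary
                pos = (j + 1) * res + side * inset
                if flip:
                    edges.append((np.array([x0 + pos, y0 + lo]),
                                  np.array([x0 + pos, y0 + hi])))
                else:
                    edges.append((np.array([x0 + lo, y0 + pos]),
                                  np.array([x0 + hi, y0 + pos])))
    return edges


def _migrate(xy: np.ndarray, mask: RasterMask, params: CultureParams,
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Hourly biased random walk; returns final positions and an attached
    flag (True where the neuron anchored on CNT).

    The adhesion weight decides up front whether a neuron is an "anchorer"
    (probability a/(a+1) with a = cnt_neuron_affinity): anchorers stop at
    their first electrode contact, the rest treat the electrode as
    pass-through and are displaced into the nearest gap at the end."""
    xmin, ymin, xmax, ymax = mask.bounds()
    n = len(xy)
    if n == 0:
        return xy.copy(), np.zeros(0, dtype=bool)
    res = mask.resolution
    dist_px, (jj, ii) = ndimage.distance_transform_edt(~mask.cnt, return_indices=True)
    nearest_x = mask.origin[0] + (ii + 0.5) * res
    nearest_y = mask.origin[1] + (jj + 0.5) * res
    pos = xy.copy()
    p_attach = params.cnt_neuron_affinity / (params.cnt_neuron_affinity + 1.0)
    will_attach = rng.random(n) < p_attach
    attached = will_attach & mask.label_at(pos)
    moving = ~attached
    for _ in range(int(params.walk_hours)):
        if not moving.any():
            break
        idx = np.nonzero(moving)[0]
        speed = rng.uniform(*params.migration_speed, idx.size)
        theta = rng.uniform(0, 2 * np.pi, idx.size)
        step = np.column_stack([np.cos(theta), np.sin(theta)])
        rows, cols = mask.world_to_index(pos[idx])
        d = dist_px[rows, cols] * res
        tx = np.column_stack([nearest_x[rows, cols], nearest_y[rows, cols]]) - pos[idx]
        norm = np.hypot(tx[:, 0], tx[:, 1])
        ok = norm > 1e-9
        tx[ok] /= norm[ok, None]
        bias = np.where(will_attach[idx] & (d < 100.0), 0.7, 0.05)[:, None]
        vec = step * (1 - bias) + tx * bias
        vnorm = np.hypot(vec[:, 0], vec[:, 1])
        vec /= np.maximum(vnorm, 1e-9)[:, None]
        pos[idx] = pos[idx] + vec * speed[:, None]
        pos[idx, 0] = np.clip(pos[idx, 0], xmin + _BODY_MARGIN, xmax - _BODY_MARGIN)
        pos[idx, 1] = np.clip(pos[idx, 1], ymin + _BODY_MARGIN, ymax - _BODY_MARGIN)
        anchor = will_attach[idx] & mask.label_at(pos[idx])
        attached[idx[anchor]] = True
        moving[idx[anchor]] = False
    # push non-anchorers that ended on the electrode back into the gap,
    # past the edge corridor used by edge-following processes
    stranded = ~attached & mask.label_at(pos)
    if stranded.any():
        gdist, (gj, gi) = ndimage.distance_transform_edt(mask.cnt, return_indices=True)
        rows, cols = mask.world_to_index(pos[stranded])
        target = np.column_stack([mask.origin[0] + (gi[rows, cols] + 0.5) * res,
                                  mask.origin[1] + (gj[rows, cols] + 0.5) * res])
        away = target - pos[stranded]
        norm = np.maximum(np.hypot(away[:, 0], away[:, 1]), 1e-9)[:, None]
        target = target + away / norm * 8.0
        target[:, 0] = np.clip(target[:, 0], xmin + _BODY_MARGIN, xmax - _BODY_MARGIN)
        target[:, 1] = np.clip(target[:, 1], ymin + _BODY_MARGIN, ymax - _BODY_MARGIN)
        pos[stranded] = target
    return pos, attached


def _cluster_blob_radius(n: int) -> float:
    """Rendered radius (um) of a soma cluster of n cells."""
    return float(min(4.0 + 1.6 * np.sqrt(n), 16.0))


def _cluster(xy: np.ndarray, scale: float, min_size: int
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Grid-bin clustering: (cluster id per point, centroids, member counts)."""
    ids = np.full(len(xy), -1, dtype=int)
    if len(xy) == 0:
        return ids, np.zeros((0, 2)), np.zeros(0, dtype=int)
    bins = np.floor(xy / scale).astype(int)
    _, inverse, counts = np.unique(bins, axis=0, return_inverse=True, return_counts=True)
    centroids, sizes = [], []
    next_id = 0
    for b in range(counts.size):
        if counts[b] < min_size:
            continue
        members = inverse == b
        ids[members] = next_id
        centroids.append(xy[members].mean(axis=0))
        sizes.append(int(counts[b]))
        next_id += 1
    return ids, np.asarray(centroids).reshape(-1, 2), np.asarray(sizes, dtype=int)


def _merge_close(centroids: np.ndarray, sizes: np.ndarray, radius: float
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Coalesce mutually-nearest centroid pairs closer than ``radius``
    (cluster absorption by 17 DIV).  Pairwise only, so chains of clusters
    do not collapse into one."""
    if len(centroids) < 2:
        return centroids, sizes
    tree = cKDTree(centroids)
    dist, nbr = tree.query(centroids, k=2)
    merged = np.zeros(len(centroids), dtype=bool)
    out, out_n = [], []
    for i in range(len(centroids)):
        if merged[i]:
            continue
        j = int(nbr[i, 1])
        if (not merged[j] and dist[i, 1] < radius and int(nbr[j, 1]) == i):
            merged[i] = merged[j] = True
            w = sizes[i] + sizes[j]
            out.append((sizes[i] * centroids[i] + sizes[j] * centroids[j]) / w)
            out_n.append(w)
        else:
            merged[i] = True
            out.append(centroids[i])
            out_n.append(sizes[i])
    return np.asarray(out).reshape(-1, 2), np.asarray(out_n, dtype=int)


def _snap_to_centerlines(tree, pts: np.ndarray,
                         bounds: tuple[float, float, float, float] | None = None
                         ) -> np.ndarray:
    """Project points onto the centerline of the nearest branch segment, so
    on-branch networks run along the branch axis rather than its edges.
    With ``bounds`` the projections are kept a body margin inside the field."""
    if tree is None or not len(pts):
        return pts
    out = pts.copy()
    boxes = [(s, s.bounds()) for s in tree.segments]
    for i, (x, y) in enumerate(pts):
        best, proj = np.inf, None
        for s, (bx0, by0, bx1, by1) in boxes:
            dx = max(bx0 - x, 0.0, x - bx1)
            dy = max(by0 - y, 0.0, y - by1)
            d = dx * dx + dy * dy
            if d < best:
                best = d
                if s.orientation == "horizontal":
                    proj = (min(max(x, bx0 + 1), bx1 - 1), s.p0[1])
                else:
                    proj = (s.p0[0], min(max(y, by0 + 1), by1 - 1))
        if proj is not None:
            out[i] = proj
    if bounds is not None:
        xmin, ymin, xmax, ymax = bounds
        out[:, 0] = np.clip(out[:, 0], xmin + _BODY_MARGIN, xmax - _BODY_MARGIN)
        out[:, 1] = np.clip(out[:, 1], ymin + _BODY_MARGIN, ymax - _BODY_MARGIN)
    return out


def simulate_development(scene: SyntheticScene, mask: RasterMask,
                         params: CultureParams | None = None) -> SyntheticScene:
    """Evolve a seeded scene to its culture time (params.div).

    Rule-based, not mechanistic: migration/attachment, edge-following
    process growth, cluster bundling with a 7-DIV complexity peak, and
    proximity-weighted glial coverage.  Deterministic given
    (scene, mask, params)."""
    params = params if params is not None else (scene.params or CultureParams())
    rng = np.random.default_rng([params.rng_seed, 1])
    div = params.div
    lf = _LENGTH_FACTOR[div]
    xmin, ymin, xmax, ymax = scene.bounds

    neurons = scene.soma_kind == "neuron"
    n_xy = scene.soma_xy[neurons]
    has_cnt = bool(mask.cnt.any())

    processes: list[Process] = []
    soma_xy = scene.soma_xy.copy()
    cluster_ids = np.full(scene.n_cells, -1, dtype=int)

    if has_cnt and len(n_xy):
        pos, attached = _migrate(n_xy, mask, params, rng)
        if attached.any():
            # anchored somas settle into the branch interior, leaving the
            # edge corridors to the edge-following processes
            pos[attached] = _snap_to_centerlines(mask.tree, pos[attached], scene.bounds)
        soma_xy[neurons] = pos
    else:
        pos = n_xy.copy()
        attached = np.zeros(len(n_xy), dtype=bool)

    # --- edge-following processes on the branches -------------------------
    # each follower is grown by an anchored neuron, so a cell-free culture
    # (or one without any attached neurons) produces no edge processes
    n_followers_left = int(attached.sum())
    if has_cnt and n_followers_left > 0:
        if mask.tree is not None:
            edges = _edges_from_tree(mask.tree, scene.bounds, params.edge_inset)
        else:
            edges = _edges_from_raster(mask, params.edge_inset)
        coverage = _EDGE_COVERAGE[div]
        mean_len = params.follower_length * lf
        gap_mean = max(mean_len * (1 - coverage) / max(coverage, 1e-6), 1.0)
        for p0, p1 in edges:
            if n_followers_left <= 0:
                break
            vec = p1 - p0
            elen = float(np.hypot(*vec))
            u = vec / elen
            t = float(rng.uniform(0, gap_mean))
            while t < elen - 5.0:
                flen = float(rng.lognormal(np.log(mean_len), 0.35))
                end = min(t + flen, elen - 1.0)
                if end - t > 4.0:
                    processes.append(
                        _make_process([p0 + u * t, p0 + u * end], mask, "edge"))
                    n_followers_left -= 1
                    if n_followers_left <= 0:
                        break
                t = end + float(rng.exponential(gap_mean)) + 2.0

    # --- cluster networks in the gaps and on the branches -----------------
    gap_xy = pos[~attached] if len(pos) else np.zeros((0, 2))
    ids, centroids, sizes = _cluster(gap_xy, params.cluster_scale,
                                     params.min_cluster_size)
    neuron_idx = np.nonzero(neurons)[0]
    if len(pos):
        cluster_ids[neuron_idx[~attached]] = ids
    if div == 17:
        centroids, sizes = _merge_close(centroids, sizes, 1.2 * params.cluster_scale)

    cnt_xy = pos[attached] if len(pos) else np.zeros((0, 2))
    cnt_ids, cnt_centroids, cnt_sizes = _cluster(cnt_xy, 0.6 * params.cluster_scale,
                                                 params.min_cluster_size)
    cnt_centroids = _snap_to_centerlines(mask.tree, cnt_centroids, scene.bounds)
    if len(pos):
        offset = (ids.max() + 1) if ids.size and ids.max() >= 0 else 0
        cnt_ids = np.where(cnt_ids >= 0, cnt_ids + offset, -1)
        cluster_ids[neuron_idx[attached]] = cnt_ids

    if has_cnt:
        dist_px, (jj, ii) = ndimage.distance_transform_edt(~mask.cnt, return_indices=True)
        res = mask.resolution
        nearest_x = mask.origin[0] + (ii + 0.5) * res
        nearest_y = mask.origin[1] + (jj + 0.5) * res

    # Soma aggregates are confined by their surface: on-branch blobs cannot
    # outgrow the branch, gap blobs settle toward the gap center and stop at
    # the electrode edges, keeping the edge corridors free for the
    # edge-following processes.
    radii = np.array([_cluster_blob_radius(n) for n in sizes])
    cnt_radii = np.array([_cluster_blob_radius(n) for n in cnt_sizes])
    if has_cnt and len(centroids):
        rows, cols = mask.world_to_index(centroids)
        d_gap = dist_px[rows, cols] * mask.resolution
        tight = d_gap < radii + 2.5
        for i in np.nonzero(tight)[0]:
            near = np.array([nearest_x[rows[i], cols[i]], nearest_y[rows[i], cols[i]]])
            away = centroids[i] - near
            norm = float(np.hypot(*away))
            if norm > 1e-9:
                c = near + away / norm * min(radii[i] + 2.5, d_gap[i] + 12.0)
                c[0] = np.clip(c[0], xmin + _BODY_MARGIN, xmax - _BODY_MARGIN)
                c[1] = np.clip(c[1], ymin + _BODY_MARGIN, ymax - _BODY_MARGIN)
                if not mask.label_at(c[None, :])[0]:
                    centroids[i] = c
        rows, cols = mask.world_to_index(centroids)
        d_gap = dist_px[rows, cols] * mask.resolution
        radii = np.clip(np.minimum(radii, d_gap - 2.5), 3.0, None)
    if has_cnt and len(cnt_centroids):
        halfw = ndimage.distance_transform_edt(mask.cnt) * mask.resolution
        rows, cols = mask.world_to_index(cnt_centroids)
        cnt_radii = np.clip(np.minimum(cnt_radii, halfw[rows, cols] - 3.5), 3.0, None)

    def _bundle(a: np.ndarray, b: np.ndarray, kind: str,
                trim_a: float = 0.0, trim_b: float = 0.0,
                require_cnt: bool = False) -> None:
        vec = b - a
        norm = float(np.hypot(*vec))
        # start/stop just outside the soma-cluster bodies (the perimeter plus
        # the blur halo), so the rendered line is never occluded by the blob
        trim_a = trim_a + 1.6 if trim_a > 0 else 0.0
        trim_b = trim_b + 1.6 if trim_b > 0 else 0.0
        if norm < trim_a + trim_b + 10.0:
            return
        u = vec / norm
        a = a + u * trim_a
        b = b - u * trim_b
        vec = b - a
        norm = float(np.hypot(*vec))
        perp = np.array([-vec[1], vec[0]]) / norm
        mid = 0.5 * (a + b) + perp * float(rng.normal(0.0, 6.0))
        dense = np.vstack([_densify(a, mid), _densify(mid, b)[1:]])
        if lf < 1.0:
            # partially grown: keep the first lf fraction of the path
            seg = np.hypot(*np.diff(dense, axis=0).T)
            cum = np.concatenate([[0.0], np.cumsum(seg)])
            cut = int(np.searchsorted(cum, lf * cum[-1]))
            dense = dense[:max(cut, 2)]
        on = _label_polyline(dense, mask)
        if require_cnt and on.mean() < 0.8 and rng.random() > 0.1:
            return  # on-branch links stay on the branch; bridging gaps is rare
        processes.append(Process(dense, on, kind))

    def _link_network(cents: np.ndarray, trims: np.ndarray, kind: str,
                      require_cnt: bool, max_rank: int) -> None:
        if len(cents) < 2:
            return
        ctree = cKDTree(cents)
        k = min(max_rank + 1, len(cents))
        _, nbrs = ctree.query(cents, k=k)
        seen = set()
        for i in range(len(cents)):
            for rank in range(1, k):
                j = int(nbrs[i, rank])
                pair = (min(i, j), max(i, j))
                if pair in seen:
                    continue
                p_link = _NEAREST_LINK_P[div] if rank == 1 else _SECOND_LINK_P[div]
                if rng.random() < p_link:
                    seen.add(pair)
                    _bundle(cents[i], cents[j], kind,
                            trim_a=trims[i], trim_b=trims[j],
                            require_cnt=require_cnt)

    _link_network(centroids, radii, "bundle", require_cnt=False, max_rank=2)
    # on-branch networks: nearest-neighbour chains along the branch axis
    _link_network(cnt_centroids, cnt_radii, "cnt-net", require_cnt=True, max_rank=1)

    if has_cnt and len(centroids):
        rows, cols = mask.world_to_index(centroids)
        d = dist_px[rows, cols] * mask.resolution
        for i, c in enumerate(centroids):
            if 1.0 < d[i] < params.boundary_reach and rng.random() < _BOUNDARY_LINK_P[div]:
                target = np.array([nearest_x[rows[i], cols[i]], nearest_y[rows[i], cols[i]]])
                _bundle(c, target, "boundary", trim_a=radii[i])

    # unclustered gap somas hugging an edge would sit on the edge-following
    # processes when rendered; keep their bodies clear of the edge corridor
    if has_cnt and len(pos):
        lone_gap = ~attached & (cluster_ids[neuron_idx] < 0)
        if lone_gap.any():
            rows, cols = mask.world_to_index(pos[lone_gap])
            d = dist_px[rows, cols] * mask.resolution
            close = d < 10.5
            if close.any():
                sel = np.nonzero(lone_gap)[0][close]
                near = np.column_stack([nearest_x[rows[close], cols[close]],
                                        nearest_y[rows[close], cols[close]]])
                away = pos[sel] - near
                norm = np.maximum(np.hypot(away[:, 0], away[:, 1]), 1e-9)[:, None]
                moved = near + away / norm * 10.5
                moved[:, 0] = np.clip(moved[:, 0], xmin + _BODY_MARGIN, xmax - _BODY_MARGIN)
                moved[:, 1] = np.clip(moved[:, 1], ymin + _BODY_MARGIN, ymax - _BODY_MARGIN)
                pos[sel] = moved
            soma_xy[neurons] = pos

    cluster_records = [
        {"centroid": c, "n": int(n), "radius": float(r), "on_cnt": False}
        for c, n, r in zip(centroids, sizes, radii)
    ] + [
        {"centroid": c, "n": int(n), "radius": float(r), "on_cnt": True}
        for c, n, r in zip(cnt_centroids, cnt_sizes, cnt_radii)
    ]

    # --- glial coverage ---------------------------------------------------
    # Gap glia are confined by the electrode edges (disks are clipped to the
    # gap); the rare electrode-attached glia stay on the branch.
    glial_regions = []
    if params.glia_growth > 0:
        glia = scene.soma_kind == "glia"
        g_xy = scene.soma_xy[glia]
        tf = _GLIA_TIME[div] * params.glia_growth
        field_box = _shapely_box(xmin, ymin, xmax, ymax)
        cnt_poly = None
        gap_poly = field_box
        if has_cnt and mask.tree is not None and mask.tree.segments:
            cnt_poly = unary_union(
                [_shapely_box(*s.bounds()) for s in mask.tree.segments]
            ).intersection(field_box)
            gap_poly = field_box.difference(cnt_poly)
        if len(g_xy):
            on_cnt = mask.label_at(g_xy) if has_cnt else np.zeros(len(g_xy), dtype=bool)
            if has_cnt:
                rows, cols = mask.world_to_index(g_xy)
                d = dist_px[rows, cols] * mask.resolution
            else:
                d = np.full(len(g_xy), np.inf)
            aff = params.gap_glia_affinity
            p_gap = np.minimum(1.0, params.proximity_scale / np.maximum(d, 1.0)) \
                * (aff / (aff + 1.0))
            p_cnt = min(1.0, 0.8 / aff)
            p_keep = np.where(on_cnt, p_cnt, p_gap)
            keep = rng.random(len(g_xy)) < p_keep
            radii = np.where(on_cnt, 8.0,
                             params.glia_radius * (0.7 + 0.6 * rng.random(len(g_xy)))) * tf
            for i in np.nonzero(keep)[0]:
                r = radii[i]
                if r < 1.0:
                    continue
                disk = Point(g_xy[i]).buffer(r, quad_segs=16)
                clip = (cnt_poly if on_cnt[i] else gap_poly) if cnt_poly is not None \
                    else field_box
                disk = disk.intersection(clip)
                if not disk.is_empty and disk.area > 1.0:
                    for part in (disk.geoms if hasattr(disk, "geoms") else [disk]):
                        glial_regions.append(part)

    out = replace(scene)
    out.soma_xy = soma_xy
    out.soma_cluster = cluster_ids
    out.processes = processes
    out.glial_regions = glial_regions
    out.clusters = cluster_records
    out.div = div
    out.params = params
    return out


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def ground_truth_measurements(scene: SyntheticScene, mask: RasterMask) -> HerdingResult:
    """Exact measurements from the scene geometry.

    Process lengths are exact polyline lengths split by the mask label of
    each sub-segment; glial areas are exact (shapely) areas of the union of
    glial polygons split against the vector branch geometry when available
    (pixel-counted otherwise).  Normalizing areas are the mask's label
    counts — the same denominators the measurement pipeline uses.
    """
    len_cnt = len_gap = 0.0
    for p in scene.processes:
        on, off = p.length_split()
        len_cnt += on
        len_gap += off
    g_cnt = g_gap = 0.0
    union = scene.glial_union()
    if union is not None:
        total = union.area
        if mask.tree is not None and mask.tree.segments:
            from shapely.geometry import box as _box

            field_box = _box(*scene.bounds)
            cnt_poly = unary_union(
                [_box(*s.bounds()) for s in mask.tree.segments]).intersection(field_box)
            g_cnt = union.intersection(cnt_poly).area
        else:
            # pixel fallback: sample polygon coverage on the mask grid
            from .imaging import _fill_polygons

            filled = _fill_polygons(scene.glial_regions, mask)
            g_cnt = float(np.count_nonzero(filled & mask.cnt)) * mask.pixel_area
            total = float(np.count_nonzero(filled)) * mask.pixel_area
        g_gap = total - g_cnt
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        result = herding_indices((len_cnt, len_gap), (g_cnt, g_gap),
                                 mask.area_cnt(), mask.area_gap(),
                                 label=scene.label, div=scene.div)
    scene.ground_truth = result
    return result
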
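import numpy as np
import pytest

import neuroherd as nh
from neuroherd.cultures import Process


@pytest.fixture(scope="session")
def small_rows():
    """A small row pattern (fast to rasterize) with the real gap scales."""
    design = nh.EuclideanDesign(W_CNT=50.0, W_Si=50.0, W=600.0, label="rows-small")
    return design, nh.build_euclidean(design)


@pytest.fixture(scope="session")
def culture_setup():
    """One developed synthetic culture on an S50C50 crop at 17 DIV."""
    tree = nh.build_euclidean(nh.EUCLIDEAN_DESIGNS["S50C50"])
    mask = nh.rasterize(tree, 0.32, bounds=(-128.0, -128.0, 128.0, 128.0))
    params = nh.CultureParams(div=17, rng_seed=7)
    scene = nh.simulate_development(nh.seed_cells(mask, params), mask, params)
    return tree, mask, params, scene


def make_line_scene(mask, polylines, label="synthetic-lines"):
    """Scene containing only the given polylines (no somas, no glia)."""
    processes = []
    for pts in polylines:
        pts = np.asarray(pts, dtype=float)
        # densify so the per-sub-segment surface split is fine-grained
        dense = [pts[0]]
        for a, b in zip(pts[:-1], pts[1:]):
            n = max(int(np.ceil(np.hypot(*(b - a)) / 2.0)), 1)
            t = np.linspace(0, 1, n + 1)[1:, None]
            dense.append(a * (1 - t) + b * t)
        dense = np.vstack(dense)
        mids = 0.5 * (dense[1:] + dense[:-1])
        processes.append(Process(dense, mask.label_at(mids), "edge"))
    return nh.SyntheticScene(
        label=label, bounds=mask.bounds(),
        soma_xy=np.zeros((0, 2)), soma_kind=np.array([]),
        soma_cluster=np.array([], dtype=int),
        processes=processes, div=17, rng_seed=0,
    )
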
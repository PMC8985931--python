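"""Maximal empty axis-aligned rectangle in a boolean grid.

Classic histogram-of-heights scan with a monotonic stack: O(rows * cols).
Ties are broken by first occurrence in row-major order.  A numba-compiled
kernel is used when available; the pure-Python fallback is identical.
"""

from __future__ import annotations

import numpy as np

__all__ = ["largest_empty_rectangle"]


def _scan(free: np.ndarray) -> tuple[int, int, int, int, int]:
    ny, nx = free.shape
    heights = np.zeros(nx, dtype=np.int64)
    stack_pos = np.empty(nx + 1, dtype=np.int64)
    stack_h = np.empty(nx + 1, dtype=np.int64)
    best = 0
    best_row = best_col = best_w = best_h = 0
    for j in range(ny):
        for i in range(nx):
            heights[i] = heights[i] + 1 if free[j, i] else 0
        top = 0
        for i in range(nx + 1):
            h = heights[i] if i < nx else 0
            start = i
            while top > 0 and stack_h[top - 1] >= h:
                top -= 1
                hh = stack_h[top]
                ww = i - stack_pos[top]
                if hh * ww > best:
                    best = hh * ww
                    best_row, best_col = j - hh + 1, stack_pos[top]
                    best_w, best_h = ww, hh
                start = stack_pos[top]
            if top == 0 or stack_h[top - 1] < h:
                stack_pos[top] = start
                stack_h[top] = h
                top += 1
    return best, best_row, best_col, best_h, best_w


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _scan_jit = njit(cache=False)(_scan)
except Exception:  # pragma: no cover
    _scan_jit = None


def largest_empty_rectangle(free: np.ndarray) -> tuple[int, tuple[int, int, int, int]]:
    """Return (area_px, (row, col, height, width)) of the largest all-True
    axis-aligned rectangle in ``free``."""
    free = np.ascontiguousarray(free, dtype=bool)
    if free.size == 0:
        return 0, (0, 0, 0, 0)
    scan = _scan_jit if _scan_jit is not None else _scan
    best, row, col, h, w = scan(free)
    return int(best), (int(row), int(col), int(h), int(w))
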
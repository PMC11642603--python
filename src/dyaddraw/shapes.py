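"""Ideal drawing shapes.

Both shapes run from a start point at the top to an end point directly
below it, bulging rightward:

- half circle: semicircle whose diameter is the start-end segment;
- half diamond: two line segments meeting at an apex at half height,
  with the same maximal lateral extent (``length / 2``) as the circle.

Coordinates are in tablet/screen pixels with y increasing downward from
the start point, so valid paths are monotone in y.
"""

from __future__ import annotations

import numpy as np

#: start-to-end distance in pixels (the midline segment of the display)
DEFAULT_LENGTH = 1200.0


def ideal_shape(shape: str, n: int = 100, length: float = DEFAULT_LENGTH) -> np.ndarray:
    """Return ``n`` points of the ideal shape, uniform in arc length.

    Parameters
    ----------
    shape : {"circle", "diamond"}
    n : number of points
    length : start-to-end distance in px

    Returns
    -------
    (n, 2) array of (x, y) points from (0, 0) to (0, length).
    """
    if shape == "circle":
        r = length / 2.0
        theta = np.linspace(-np.pi / 2.0, np.pi / 2.0, n)
        return np.column_stack([r * np.cos(theta), r + r * np.sin(theta)])
    if shape == "diamond":
        # two equal-length segments; arc-length-uniform sampling
        s = np.linspace(0.0, 1.0, n)
        apex = np.array([length / 2.0, length / 2.0])
        start = np.array([0.0, 0.0])
        end = np.array([0.0, length])
        pts = np.where(
            (s <= 0.5)[:, None],
            start + (s * 2.0)[:, None] * (apex - start),
            apex + ((s - 0.5) * 2.0)[:, None] * (end - apex),
        )
        return pts
    raise ValueError(f"unknown shape {shape!r}")


def shape_path_length(shape: str, length: float = DEFAULT_LENGTH) -> float:
    """Arc length of the ideal shape."""
    if shape == "circle":
        return np.pi * length / 2.0
    if shape == "diamond":
        return 2.0 * np.hypot(length / 2.0, length / 2.0)
    raise ValueError(f"unknown shape {shape!r}")


_TREE_CACHE: dict[tuple[str, int, float], object] = {}


def _shape_tree(shape: str, n_dense: int, length: float):
    from scipy.spatial import cKDTree

    key = (shape, n_dense, length)
    if key not in _TREE_CACHE:
        _TREE_CACHE[key] = cKDTree(ideal_shape(shape, n_dense, length))
    return _TREE_CACHE[key]


def distance_to_shape(points: np.ndarray, shape: str, length: float = DEFAULT_LENGTH,
                      n_dense: int = 2000) -> np.ndarray:
    """Pointwise Euclidean distance from ``points`` to the ideal curve.

    Nearest-vertex distance on a dense polyline of the ideal shape
    (KD-tree), accurate to ~length/n_dense.
    """
    d, _ = _shape_tree(shape, n_dense, length).query(np.asarray(points, float))
    return d
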
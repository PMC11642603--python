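"""Trajectory pipeline: resampling, error screening, templates, distortion.

The visuomotor-interference (VMI) score of a trial is the unsigned area
enclosed between the drawn trajectory and the participant's own average
("template") shape, both resampled to 100 points.  Upstream of that score
the pipeline (i) resamples raw 30 Hz pen traces with an index-parameterised
cubic spline, (ii) screens out gross errors (scribbles), (iii) detects swap
errors by comparing a one-knot linear vs quadratic univariate spline fit of
x as a function of y (a corner favours the linear fit -> diamond; a smooth
arc favours the quadratic -> circle), and (iv) Box-Cox-transforms the area
scores toward normality for mixed-model inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.interpolate as si
import scipy.stats as ss

from dyaddraw.shapes import DEFAULT_LENGTH, distance_to_shape, shape_path_length

N_RESAMPLE = 100


class DegenerateTrajectoryError(ValueError):
    """Trajectory has too few samples to fit a cubic spline."""


@dataclass
class Trajectory:
    """Raw pen samples of one trial: (n, 2) points and sample times (s)."""

    points: np.ndarray
    t: np.ndarray
    trial_id: int = -1

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2)")
        if len(self.t) != len(self.points):
            raise ValueError("t and points length mismatch")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("sample times must be strictly increasing")

    @property
    def path_length(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.points, axis=0).T)))


@dataclass
class ResampledTrajectory:
    """Exactly 100 spline-resampled (x, y) points."""

    points: np.ndarray
    trial_id: int = -1

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (N_RESAMPLE, 2):
            raise ValueError(f"resampled trajectory must be ({N_RESAMPLE}, 2)")


@dataclass
class ShapeTemplate:
    """Per-participant mean shape over all retained trajectories."""

    shape: str
    points: np.ndarray
    n_contributing: int


@dataclass
class ShapeFit:
    """Result of the linear-vs-quadratic spline shape classifier."""

    label: str  # "circle" | "diamond"
    residual_linear: float
    residual_quadratic: float
    classifiable: bool = True


def resample_trajectory(traj: Trajectory, n: int = N_RESAMPLE) -> ResampledTrajectory:
    """Resample to ``n`` points via component-wise cubic spline interpolation.

    x and y are fitted separately as cubic splines of the sample index
    (scipy default, not-a-knot boundaries) and evaluated at ``n`` equally
    spaced index values spanning the full range.
    """
    pts = traj.points
    if len(pts) < 4:
        raise DegenerateTrajectoryError(
            f"need >=4 samples to resample, got {len(pts)}"
        )
    idx = np.arange(len(pts), dtype=float)
    grid = np.linspace(0.0, idx[-1], n)
    spline = si.CubicSpline(idx, pts)  # component-wise cubic on (x, y)
    return ResampledTrajectory(points=spline(grid), trial_id=traj.trial_id)


def classify_shape(traj: ResampledTrajectory) -> ShapeFit:
    """Classify a resampled trajectory as circle or diamond.

    Fits x as a least-squares univariate spline of y with a single interior
    knot at the y of the rightmost point, once with degree 1 and once with
    degree 2.  A C1 quadratic spline cannot reproduce the diamond's corner,
    so the shape with the lower residual sum of squares wins (linear ->
    diamond, quadratic -> circle).  y is made strictly monotone by an
    infinitesimal jitter; if the rightmost point lies at either end of the
    path the trajectory is flagged unclassifiable.
    """
    pts = traj.points
    x, y = pts[:, 0].copy(), pts[:, 1].copy()
    if y[-1] < y[0]:  # path drawn bottom-up: flip so y increases
        x, y = x[::-1], y[::-1]
    # enforce strict monotonicity (infinitesimal jitter on ties/backtracks)
    y = np.maximum.accumulate(y)
    span = max(y[-1] - y[0], 1.0)
    y = y + np.arange(len(y)) * (span * 1e-9)

    knot_idx = int(np.argmax(x))  # first occurrence on ties
    if knot_idx == 0 or knot_idx == len(x) - 1:
        return ShapeFit("circle", np.nan, np.nan, classifiable=False)
    knot = y[knot_idx]

    try:
        lin = si.LSQUnivariateSpline(y, x, [knot], k=1)
        quad = si.LSQUnivariateSpline(y, x, [knot], k=2)
    except ValueError:
        return ShapeFit("circle", np.nan, np.nan, classifiable=False)
    r_lin = float(lin.get_residual())
    r_quad = float(quad.get_residual())
    if r_lin == r_quad:
        warnings.warn("equal linear/quadratic residuals; labelling circle")
        return ShapeFit("circle", r_lin, r_quad)
    label = "diamond" if r_lin < r_quad else "circle"
    return ShapeFit(label, r_lin, r_quad)


def detect_swap_errors(
    trials: Sequence[tuple[ResampledTrajectory, str]],
) -> list[bool]:
    """Flag trials whose classified shape disagrees with the cued shape.

    Unclassifiable trajectories are flagged (conservatively treated as
    errors and removed downstream).
    """
    flags = []
    for traj, cued in trials:
        fit = classify_shape(traj)
        flags.append((not fit.classifiable) or fit.label != cued)
    return flags


def screen_gross_errors(
    trials: Sequence[tuple[Trajectory, str]],
    length_ratio: float = 2.0,
    distance_ceiling: float = 300.0,
    length: float = DEFAULT_LENGTH,
) -> list[bool]:
    """Automated stand-in for visual gross-error screening.

    A trajectory is flagged if its path length exceeds ``length_ratio``
    times the cued ideal shape's arc length, or if its maximum pointwise
    distance from *both* ideal shapes exceeds ``distance_ceiling`` px
    (i.e. it resembles neither shape anywhere along the way).
    """
    if not trials:
        return []
    # batch the distance computation over all trajectories
    all_pts = np.concatenate([traj.points for traj, _ in trials], axis=0)
    bounds = np.cumsum([0] + [len(traj.points) for traj, _ in trials])
    d_circ = distance_to_shape(all_pts, "circle", length)
    d_diam = distance_to_shape(all_pts, "diamond", length)
    flags = []
    for i, (traj, cued) in enumerate(trials):
        ideal_len = shape_path_length(cued, length)
        if traj.path_length > length_ratio * ideal_len:
            flags.append(True)
            continue
        sl = slice(bounds[i], bounds[i + 1])
        flags.append(bool(d_circ[sl].max() > distance_ceiling
                          and d_diam[sl].max() > distance_ceiling))
    return flags


def compute_templates(
    trajs: Sequence[ResampledTrajectory],
    labels: Sequence[str],
    shapes: Sequence[str] | None = None,
) -> dict[str, ShapeTemplate]:
    """Pointwise mean trajectory per shape, pooled across all conditions.

    ``shapes`` lists the required template shapes (default: the shapes
    present in ``labels``); a required shape with no trajectories raises.
    """
    out: dict[str, ShapeTemplate] = {}
    labels = list(labels)
    shapes = tuple(shapes) if shapes is not None else tuple(dict.fromkeys(labels))
    for shape in shapes:
        members = [t.points for t, l in zip(trajs, labels) if l == shape]
        if not members:
            raise ValueError(f"no retained trajectories for shape {shape!r}")
        out[shape] = ShapeTemplate(
            shape=shape, points=np.mean(members, axis=0), n_contributing=len(members)
        )
    return out


def _segment_intersections(P: np.ndarray, T: np.ndarray):
    """Intersection parameters of index-matched segments P[i]P[i+1] vs T[i]T[i+1].

    Returns (idx, points): indices i of crossing quads and the (x, y)
    intersection points.
    """
    d1 = np.diff(P, axis=0)
    d2 = np.diff(T, axis=0)
    b = T[:-1] - P[:-1]
    denom = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (b[:, 0] * d2[:, 1] - b[:, 1] * d2[:, 0]) / denom
        u = (b[:, 0] * d1[:, 1] - b[:, 1] * d1[:, 0]) / denom
    hit = np.isfinite(s) & np.isfinite(u) & (s > 0) & (s < 1) & (u > 0) & (u < 1)
    idx = np.nonzero(hit)[0]
    pts = P[idx] + s[idx, None] * d1[idx]
    return idx, pts


def area_to_template(
    traj: ResampledTrajectory | np.ndarray, template: ShapeTemplate | np.ndarray
) -> float:
    """Unsigned area enclosed between a trajectory and its template.

    The closed polygon (trajectory followed by the reversed template) is
    split at the crossing points of the two curves and the absolute areas
    of the sub-loops are summed (shoelace), so distortion is nonnegative
    and never cancels across crossings.  Both curves must have the same
    point count; the result is symmetric in the two curves and invariant
    under a common rigid translation.

    Implementation: per-index quads (T_i, T_{i+1}, P_{i+1}, P_i) carry the
    local signed area; quads in which the two curves cross are split
    exactly at the intersection point, and contiguous same-sign runs form
    the sub-loops.  Assumes the two curves are index-aligned (true for
    trajectories and templates resampled on a common index grid).
    """
    P = traj.points if isinstance(traj, ResampledTrajectory) else np.asarray(traj, float)
    T = template.points if isinstance(template, ShapeTemplate) else np.asarray(template, float)
    if P.shape != T.shape:
        raise ValueError("trajectory and template must have the same point count")

    quads = np.stack([T[:-1], T[1:], P[1:], P[:-1]], axis=1)  # (n-1, 4, 2)
    x = quads[..., 0]
    y = quads[..., 1]
    # per-edge cross terms first, then the sum: keeps degenerate quads
    # (trajectory == template) at exactly zero
    edge = x * np.roll(y, -1, axis=1) - y * np.roll(x, -1, axis=1)
    areas = 0.5 * edge.sum(axis=1)

    cross_idx, cross_pts = _segment_intersections(P, T)
    if len(cross_idx) == 0:
        # no crossings: sub-loops are contiguous same-sign runs
        return _sum_runs(areas)

    # split each crossing quad into its two triangles at the intersection
    def tri_area(A, B, C):
        return 0.5 * ((B[:, 0] - A[:, 0]) * (C[:, 1] - A[:, 1])
                      - (B[:, 1] - A[:, 1]) * (C[:, 0] - A[:, 0]))

    a_first = tri_area(T[cross_idx], cross_pts, P[cross_idx])
    a_second = tri_area(cross_pts, T[cross_idx + 1], P[cross_idx + 1])
    # assemble: quads in order, crossing quads replaced by their two triangles
    pieces = np.empty(len(areas) + len(cross_idx))
    keep = np.ones(len(areas), dtype=bool)
    keep[cross_idx] = False
    # positions: each element i of `areas` shifts right by the number of
    # crossings strictly before it (each crossing adds one extra piece)
    shift = np.zeros(len(areas), dtype=int)
    shift[cross_idx] = 1
    offset = np.cumsum(shift) - shift
    pos_keep = np.nonzero(keep)[0]
    pieces[pos_keep + offset[pos_keep]] = areas[pos_keep]
    pieces[cross_idx + offset[cross_idx]] = a_first
    pieces[cross_idx + offset[cross_idx] + 1] = a_second
    return _sum_runs(pieces)


def _sum_runs(areas: np.ndarray) -> float:
    """Sum of absolute values of contiguous same-sign run totals.

    Zero-area elements join the current run.
    """
    areas = np.asarray(areas, dtype=float)
    if len(areas) == 0:
        return 0.0
    s = np.sign(areas)
    if not s.any():
        return 0.0
    # forward-fill signs so runs are delimited by true sign changes
    idx = np.where(s != 0, np.arange(len(s)), 0)
    np.maximum.accumulate(idx, out=idx)
    ff = s[idx]
    change = np.empty(len(s), dtype=bool)
    change[0] = True
    change[1:] = (ff[1:] != ff[:-1]) & (s[1:] != 0)
    starts = np.nonzero(change)[0]
    return float(np.abs(np.add.reduceat(areas, starts)).sum())


def corridor_accuracy(
    points: np.ndarray, shape: str, band: float = 100.0, length: float = DEFAULT_LENGTH
) -> float:
    """Fraction of points within ``band`` px of the ideal shape curve."""
    pts = points.points if isinstance(points, ResampledTrajectory) else np.asarray(points, float)
    d = distance_to_shape(pts, shape, length)
    return float(np.mean(d <= band))


def boxcox(values: np.ndarray) -> dict:
    """Box-Cox transform with profile-likelihood lambda.

    Returns the MLE lambda, the transformed values and the skewness and
    kurtosis (Fisher) of the transformed sample.  All inputs must be
    strictly positive.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    transformed, lam = ss.boxcox(values)
    return {
        "lambda": float(lam),
        "transformed": transformed,
        "skewness": float(ss.skew(transformed)),
        "kurtosis": float(ss.kurtosis(transformed)),
    }
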
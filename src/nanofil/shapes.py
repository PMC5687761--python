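"""Per-frame shape descriptors of a filament contour.

Three quantifiers summarize each frame:

* buckling degree ``c`` — diameter of the smallest circle enclosing the
  contour divided by the contour length; 1 for a straight filament,
  small for coiled ones;
* inclination angle ``phi`` — signed orientation of the major axis of
  the contour's second-moment (inertia-equivalent) ellipse, measured
  from the cross-channel axis toward the flow axis, in [-pi/2, +pi/2]
  (-pi/2 = aligned pointing upstream, +pi/2 = downstream,
  0 = perpendicular to the flow);
* end-to-end ratio ``r`` — end-to-end distance over contour length.

The smallest enclosing circle is exact (Welzl's randomized incremental
construction with a fixed shuffle seed); a quartic brute-force reference
implementation is kept alongside as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contours import FilamentContour

__all__ = [
    "Circle",
    "ShapeDescriptors",
    "min_enclosing_circle",
    "min_enclosing_circle_bruteforce",
    "buckling_degree",
    "inclination_angle",
    "end_to_end_ratio",
    "describe_contour",
    "descriptor_trends",
]


@dataclass(frozen=True)
class Circle:
    center: tuple[float, float]
    radius: float

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    def contains(self, p, rtol: float = 1e-9) -> bool:
        return np.hypot(p[0] - self.center[0], p[1] - self.center[1]) <= self.radius * (1 + rtol) + 1e-18


@dataclass(frozen=True)
class ShapeDescriptors:
    """Shape quantifiers for one frame."""

    buckling: float
    inclination: float | None
    end_to_end: float
    frame: int = 0
    phase_label: str = ""


def _circle_two(a, b) -> Circle:
    c = ((a[0] + b[0]) / 2.0, (a[1] + b[1]) / 2.0)
    return Circle(c, float(np.hypot(a[0] - b[0], a[1] - b[1]) / 2.0))


def _circle_three(a, b, c) -> Circle | None:
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-30:
        return None  # collinear
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay) + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx) + (cx**2 + cy**2) * (bx - ax)) / d
    return Circle((ux, uy), float(np.hypot(ax - ux, ay - uy)))


def _trivial(support: list) -> Circle:
    if not support:
        return Circle((0.0, 0.0), 0.0)
    if len(support) == 1:
        return Circle(tuple(support[0]), 0.0)
    if len(support) == 2:
        return _circle_two(support[0], support[1])
    c = _circle_three(*support)
    if c is None:
        # collinear support: the two-point circle of the farthest pair
        best = None
        for i in range(3):
            for j in range(i + 1, 3):
                cand = _circle_two(support[i], support[j])
                if best is None or cand.radius > best.radius:
                    best = cand
        return best
    return c


def min_enclosing_circle(points, shuffle_seed: int = 0) -> Circle:
    """Exact smallest enclosing circle (Welzl, iterative move-to-front).

    Duplicate points are removed first; the input order is randomized
    with a fixed seed so the expected linear-time behavior is
    deterministic.  Every input point lies inside or on the returned
    circle within 1e-9 relative tolerance, and the circle is determined
    by at most 3 support points.
    """
    pts = np.unique(np.asarray(points, dtype=float).reshape(-1, 2), axis=0)
    if len(pts) == 0:
        raise ValueError("empty point set")
    rng = np.random.default_rng(shuffle_seed)
    pts = pts[rng.permutation(len(pts))]
    pts_list = [tuple(p) for p in pts]

    circle = Circle(pts_list[0], 0.0)
    for i, p in enumerate(pts_list):
        if circle.contains(p):
            continue
        # p is on the boundary of the circle of pts[:i+1]
        circle = Circle(p, 0.0)
        for j, q in enumerate(pts_list[:i]):
            if circle.contains(q):
                continue
            circle = _circle_two(p, q)
            for r in pts_list[:j]:
                if circle.contains(r):
                    continue
                circle = _trivial([p, q, r])
    return circle


def min_enclosing_circle_bruteforce(points) -> Circle:
    """O(n^4) reference: test every pair/triple candidate circle.

    Slow but independent of the incremental construction; used as a
    cross-check oracle in the validation suite.
    """
    pts = np.unique(np.asarray(points, dtype=float).reshape(-1, 2), axis=0)
    if len(pts) == 0:
        raise ValueError("empty point set")
    if len(pts) == 1:
        return Circle(tuple(pts[0]), 0.0)
    best: Circle | None = None
    n = len(pts)

    def covers(c: Circle) -> bool:
        d = np.hypot(pts[:, 0] - c.center[0], pts[:, 1] - c.center[1])
        return bool(np.all(d <= c.radius * (1 + 1e-12) + 1e-18))

    for i in range(n):
        for j in range(i + 1, n):
            c = _circle_two(pts[i], pts[j])
            if covers(c) and (best is None or c.radius < best.radius):
                best = c
            for kk in range(j + 1, n):
                c3 = _circle_three(pts[i], pts[j], pts[kk])
                if c3 is not None and covers(c3) and (best is None or c3.radius < best.radius):
                    best = c3
    assert best is not None
    return best


def buckling_degree(contour: FilamentContour) -> float:
    """Enclosing-circle diameter over contour length; always <= 1 + O(discretization)."""
    L = contour.length
    if L <= 0:
        raise ValueError("degenerate contour")
    return min_enclosing_circle(contour.points).diameter / L


def end_to_end_ratio(contour: FilamentContour) -> float:
    """End-to-end distance over contour length, in [0, 1]."""
    L = contour.length
    if L <= 0:
        raise ValueError("degenerate contour")
    return contour.end_to_end_distance / L


def inclination_angle(
    contour: FilamentContour,
    flow_axis: str = "y",
    isotropy_eps: float = 1e-6,
) -> float | None:
    """Signed inclination of the second-moment-ellipse major axis.

    The angle is measured from the cross-channel axis toward the flow
    axis and lies in [-pi/2, +pi/2]: 0 for a filament perpendicular to
    the flow, |phi| = pi/2 for a flow-aligned one.  The undirected axis
    is folded to a positive cross-channel component; for an exactly
    flow-aligned filament (zero cross component) the sign is taken from
    the endpoint lying further downstream, ties breaking positive.
    Returns ``None`` for an isotropic point cloud (no distinct major
    axis).
    """
    pts = contour.points - contour.points.mean(axis=0)
    if flow_axis == "x":
        pts = pts[:, ::-1]  # swap so the flow is along the second component
    elif flow_axis != "y":
        raise ValueError("flow_axis must be 'x' or 'y'")
    cov = pts.T @ pts / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] <= evals[0] * (1.0 + isotropy_eps) + 1e-30:
        return None
    major = evecs[:, 1]  # (cross, flow) components
    if abs(major[0]) > 1e-12:
        if major[0] < 0:
            major = -major
        return float(np.arctan2(major[1], major[0]))
    # flow-aligned: resolve the sign from the more downstream endpoint
    ends = pts[[0, -1]]
    downstream_end = ends[np.argmax(ends[:, 1])]
    sign = 1.0 if np.dot(major, downstream_end) >= 0 else -1.0
    return float(sign * np.sign(major[1]) * np.pi / 2) if major[1] != 0 else np.pi / 2


def describe_contour(
    contour: FilamentContour,
    flow_axis: str = "y",
    phase_label: str = "",
) -> ShapeDescriptors:
    """All three descriptors for one frame."""
    return ShapeDescriptors(
        buckling=buckling_degree(contour),
        inclination=inclination_angle(contour, flow_axis=flow_axis),
        end_to_end=end_to_end_ratio(contour),
        frame=contour.frame,
        phase_label=phase_label,
    )


def descriptor_trends(
    values: np.ndarray,
    cycle_index: np.ndarray,
    cycle_parity: np.ndarray,
):
    """Per-branch trends of a descriptor sampled at flow zero-crossings.

    ``values[i]`` is the descriptor at the i-th zero-crossing,
    ``cycle_index[i]`` the crossing counter n (phase n pi) and
    ``cycle_parity[i]`` 0 for forward (even n) and 1 for reverse (odd n)
    half-cycles.  Returns a dict with, per branch, the sample arrays and
    the least-squares linear trend (slope per cycle, intercept), plus
    initial- and final-cycle values for histogramming.
    """
    values = np.asarray(values, dtype=float)
    cycle_index = np.asarray(cycle_index)
    cycle_parity = np.asarray(cycle_parity)
    if not (len(values) == len(cycle_index) == len(cycle_parity)):
        raise ValueError("inputs must align")
    if len(values) < 4 or len(np.unique(cycle_index)) < 4:
        raise ValueError("need at least two complete cycles")
    out = {}
    for parity, name in ((0, "forward"), (1, "reverse")):
        m = cycle_parity == parity
        if m.sum() < 2:
            raise ValueError(f"too few {name} samples")
        coeffs = np.polyfit(cycle_index[m], values[m], 1)
        out[name] = {
            "cycles": cycle_index[m],
            "values": values[m],
            "slope": float(coeffs[0]),
            "intercept": float(coeffs[1]),
        }
    out["initial"] = float(values[0])
    out["final"] = float(values[-1])
    return out
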
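"""Image-to-contour pipeline for single fluorescent filaments.

Stages: intensity thresholding of a fluorescence frame, morphological
skeletonization, ordering of the skeleton into an open path (longest
geodesic path between endpoints, short spurs pruned), smoothing-spline
fit against a chord-length parameter, reparametrization to arc length,
and tangent-angle extraction.  Quality control mirrors the experimental
protocol: runs whose apparent contour length varies by more than 10%
are rejected (out-of-plane deformation), and frames outside the 10 um
focal slab are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import interpolate
from skimage import measure, morphology

__all__ = [
    "FilamentContour",
    "TangentProfile",
    "RejectionRecord",
    "SegmentationConfig",
    "extract_contour",
    "fit_smooth_curve",
    "tangent_angles",
    "qc_contour_length",
    "qc_focal_plane",
]


@dataclass
class FilamentContour:
    """An ordered planar filament contour with arc-length parametrization.

    ``points`` are ordered (x, y) coordinates in meters.  If the contour
    was produced by :func:`fit_smooth_curve` the smooth parametric curve
    is retained (``_tck``) so that tangents come from the analytic spline
    derivative; a contour built with :meth:`from_polyline` uses the exact
    piecewise-linear geometry instead.
    """

    points: np.ndarray
    frame: int = 0
    in_focus: bool = True
    _tck: tuple | None = field(default=None, repr=False)
    _u_arc: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if len(self.points) < 2:
            raise ValueError("a contour needs at least two points")

    @classmethod
    def from_polyline(cls, points, frame: int = 0, in_focus: bool = True) -> "FilamentContour":
        """Wrap raw ordered points with exact polyline arc length (no fit)."""
        return cls(points=np.asarray(points, dtype=float), frame=frame, in_focus=in_focus)

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    @property
    def arc_length_stations(self) -> np.ndarray:
        """Cumulative arc length at each stored point, starting at 0."""
        return np.concatenate([[0.0], np.cumsum(self.segment_lengths)])

    @property
    def length(self) -> float:
        """Contour length L (m)."""
        if self._tck is not None and self._u_arc is not None:
            return float(self._u_arc[-1])
        return float(self.arc_length_stations[-1])

    @property
    def end_to_end_distance(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))

    def point_at(self, s) -> np.ndarray:
        """Position at arc length(s) ``s`` (m), from the spline if fitted."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if self._tck is not None:
            u = np.interp(s, self._u_arc, np.linspace(0.0, 1.0, len(self._u_arc)))
            x, y = interpolate.splev(u, self._tck)
            return np.column_stack([x, y])
        stations = self.arc_length_stations
        x = np.interp(s, stations, self.points[:, 0])
        y = np.interp(s, stations, self.points[:, 1])
        return np.column_stack([x, y])

    def tangent_angle_at(self, s) -> np.ndarray:
        """Unwrapped tangent angle at arc length(s) ``s`` (rad)."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if self._tck is not None:
            u = np.interp(s, self._u_arc, np.linspace(0.0, 1.0, len(self._u_arc)))
            dx, dy = interpolate.splev(u, self._tck, der=1)
            return np.unwrap(np.arctan2(dy, dx))
        # polyline: angle of the segment containing each station; the tiny
        # nudge keeps stations that sit exactly on a vertex (up to cumsum
        # rounding) assigned to the following segment
        stations = self.arc_length_stations
        nudge = 1e-9 * (stations[-1] / max(len(stations) - 1, 1))
        seg = np.clip(np.searchsorted(stations, s + nudge, side="right") - 1, 0, len(self.points) - 2)
        d = self.points[seg + 1] - self.points[seg]
        return np.unwrap(np.arctan2(d[:, 1], d[:, 0]))

    def translated(self, dx: float, dy: float) -> "FilamentContour":
        c = FilamentContour(self.points + np.array([dx, dy]), self.frame, self.in_focus)
        return c


@dataclass(frozen=True)
class TangentProfile:
    """Tangent angles theta(s_i) at equally spaced arc-length stations."""

    stations: np.ndarray
    angles: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "stations", np.asarray(self.stations, dtype=float))
        object.__setattr__(self, "angles", np.asarray(self.angles, dtype=float))
        if len(self.stations) != len(self.angles):
            raise ValueError("stations and angles must align")
        if len(self.stations) >= 3:
            ds = np.diff(self.stations)
            if not np.allclose(ds, ds[0], rtol=1e-6):
                raise ValueError("stations must be equally spaced")

    @property
    def spacing(self) -> float:
        return float(self.stations[1] - self.stations[0])


@dataclass(frozen=True)
class RejectionRecord:
    """Per-frame rejection with a machine-readable reason."""

    frame: int
    reason: str


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholding and skeleton-cleanup parameters.

    The threshold is ``background + k * MAD`` with the background taken
    as the image median (robust for sparse filaments); ``k`` defaults
    to 5.  Skeleton spurs shorter than ``min_branch_px`` are pruned and
    objects smaller than ``min_object_px`` are ignored.
    """

    mad_k: float = 5.0
    min_object_px: int = 20
    min_branch_px: int = 6
    pixel_size: float = 1.0  # m/px


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    rows, cols = np.nonzero(skel)
    pix = set(zip(rows.tolist(), cols.tolist()))
    for r, c in pix:
        g.add_node((r, c))
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dr, dc) == (0, 0):
                    continue
                q = (r + dr, c + dc)
                if q in pix:
                    g.add_edge((r, c), q, weight=float(np.hypot(dr, dc)))
    return g


def _prune_spurs(g: nx.Graph, min_branch_px: int) -> nx.Graph:
    changed = True
    while changed:
        changed = False
        endpoints = [n for n in g.nodes if g.degree(n) == 1]
        for e in endpoints:
            # walk from the endpoint to the nearest junction
            path = [e]
            prev, cur = None, e
            while g.degree(cur) <= 2:
                nbrs = [n for n in g.neighbors(cur) if n != prev]
                if not nbrs:
                    break
                prev, cur = cur, nbrs[0]
                path.append(cur)
                if g.degree(cur) >= 3:
                    break
            if g.degree(path[-1]) >= 3 and len(path) - 1 < min_branch_px:
                g.remove_nodes_from(path[:-1])
                changed = True
    return g


def _longest_geodesic(g: nx.Graph) -> list:
    endpoints = [n for n in g.nodes if g.degree(n) == 1]
    if len(endpoints) < 2:
        # closed loop or single pixel: fall back to double-BFS from any node
        start = next(iter(g.nodes))
        far = max(nx.single_source_dijkstra_path_length(g, start).items(), key=lambda kv: kv[1])[0]
        lengths, paths = nx.single_source_dijkstra(g, far)
        end = max(lengths.items(), key=lambda kv: kv[1])[0]
        return paths[end]
    best: list = []
    best_len = -1.0
    for i, a in enumerate(endpoints):
        lengths, paths = nx.single_source_dijkstra(g, a)
        for b in endpoints[i + 1 :]:
            if b in lengths and lengths[b] > best_len:
                best_len = lengths[b]
                best = paths[b]
    return best


def extract_contour(
    image: np.ndarray,
    cfg: SegmentationConfig | None = None,
    frame: int = 0,
):
    """Extract an ordered pixel chain for the single filament in ``image``.

    Returns an ``(n, 2)`` array of (x, y) coordinates in meters (pixel
    centers scaled by ``cfg.pixel_size``), or a :class:`RejectionRecord`
    when the frame shows no object or more than one object above the
    size floor — rejection is a per-frame data event, not an exception.
    """
    if cfg is None:
        cfg = SegmentationConfig()
    image = np.asarray(image, dtype=float)
    background = np.median(image)
    mad = np.median(np.abs(image - background))
    # floor keeps the threshold meaningful for (near-)noise-free images,
    # where the MAD collapses and bare background would pass
    floor = 0.1 * (np.percentile(image, 99.9) - background)
    thresh = background + max(cfg.mad_k * mad, floor, 1e-12)
    mask = image > thresh
    mask = morphology.remove_small_objects(mask, max_size=cfg.min_object_px - 1)
    labels = measure.label(mask, connectivity=2)
    n_objects = labels.max()
    if n_objects == 0:
        return RejectionRecord(frame, "no object")
    if n_objects > 1:
        return RejectionRecord(frame, "multiple objects")
    skel = morphology.skeletonize(mask)
    g = _skeleton_graph(skel)
    if g.number_of_nodes() < 2:
        return RejectionRecord(frame, "degenerate skeleton")
    g = _prune_spurs(g, cfg.min_branch_px)
    path = _longest_geodesic(g)
    if len(path) < 2:
        return RejectionRecord(frame, "degenerate skeleton")
    rc = np.asarray(path, dtype=float)
    if len(rc) >= 7:
        # a short moving average removes the stair-step zigzag of the pixel
        # chain, which otherwise inflates the arc length of oblique
        # filaments; the raw end pixels are kept so the tip refinement
        # starts on the ridge
        from scipy.ndimage import uniform_filter1d

        ends = rc[[0, -1]].copy()
        rc = uniform_filter1d(rc, size=5, axis=0, mode="nearest")
        rc[[0, -1]] = ends
    rc = _extend_ends(rc, image, background)
    # (row, col) -> (x, y) in meters; x = col, y = row
    return np.column_stack([rc[:, 1], rc[:, 0]]) * cfg.pixel_size


def _extend_ends(rc: np.ndarray, image: np.ndarray, background: float) -> np.ndarray:
    """Refine the filament tips to sub-pixel accuracy.

    Skeletonization misplaces the endpoints of a thresholded ridge by
    up to a line-width in either direction.  For a Gaussian line-spread
    function the ridge intensity falls to half of its interior value
    exactly at the true tip, so each end of the path is moved along the
    local tangent to the sub-pixel half-maximum crossing — extending an
    eroded end, trimming an overshot one.
    """
    from scipy.ndimage import map_coordinates

    img = image.astype(float)
    interior = map_coordinates(img, rc.T, order=1, mode="nearest")
    ridge = float(np.median(interior))
    half = background + 0.5 * (ridge - background)
    if ridge <= background:
        return rc

    def refine(chain: np.ndarray) -> np.ndarray:
        """Refine the tip at chain[-1]; returns the adjusted chain."""
        k_ref = max(-6, -len(chain))
        d = chain[-1] - chain[k_ref]
        norm = np.linalg.norm(d)
        if norm < 1e-9:
            return chain
        d = d / norm
        step = 0.25
        ts = np.arange(-8.0, 12.0 + step, step)
        pts = chain[-1][None, :] + ts[:, None] * d[None, :]
        inside = (
            (pts[:, 0] >= 0) & (pts[:, 0] <= img.shape[0] - 1)
            & (pts[:, 1] >= 0) & (pts[:, 1] <= img.shape[1] - 1)
        )
        if not inside.any():
            return chain
        pts, ts = pts[inside], ts[inside]
        vals = map_coordinates(img, pts.T, order=1, mode="nearest")
        # outermost downward crossing of the half level
        above = vals >= half
        crossings = np.nonzero(above[:-1] & ~above[1:])[0]
        if crossings.size == 0:
            return chain
        k = crossings[-1]
        frac = (vals[k] - half) / (vals[k] - vals[k + 1])
        tip = chain[-1] + (ts[k] + frac * step) * d
        # drop chain points lying beyond the tip along the outward tangent
        keep = (chain - tip) @ d < 0
        keep[: max(len(chain) - 12, 1)] = True  # only the tail is trimmed
        return np.vstack([chain[keep], tip[None, :]])

    rc = refine(rc)
    rc = refine(rc[::-1])
    return rc[::-1]


def fit_smooth_curve(
    points,
    smoothing: float | str = "auto",
    frame: int = 0,
    n_resample: int = 400,
) -> FilamentContour:
    """Fit a smoothing spline through ordered contour points.

    Both coordinates are fit against a chord-length parameter, then the
    curve is reparametrized to arc length by numerical integration; the
    reported ``L`` is the total arc length of the fitted curve.

    ``smoothing`` is the residual budget passed to the spline fit
    (``scipy.interpolate.splprep`` ``s``); ``"auto"`` selects it by
    two-fold cross-validation over a log-spaced grid (even points fit,
    odd points scored, and vice versa), and ``0`` interpolates exactly.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or len(points) < 8:
        raise ValueError("need at least 8 ordered (x, y) points")
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(points, axis=0), axis=1))])
    if chord[-1] <= 0:
        raise ValueError("degenerate point set")
    u = chord / chord[-1]
    # collapse duplicate parameter values
    keep = np.concatenate([[True], np.diff(u) > 1e-12])
    points, u = points[keep], u[keep]

    if smoothing == "auto":
        smoothing = _cv_smoothing(points, u)

    chord_total = float(chord[-1])
    s_try = float(smoothing)
    for _ in range(8):
        tck, _ = interpolate.splprep([points[:, 0], points[:, 1]], u=u, s=s_try, k=3)
        uu = np.linspace(0.0, 1.0, n_resample)
        dx, dy = interpolate.splev(uu, tck, der=1)
        speed = np.hypot(dx, dy)
        arc = np.concatenate([[0.0], np.cumsum((speed[1:] + speed[:-1]) / 2.0 * np.diff(uu))])
        # a sane fit cannot be much longer than the input polyline;
        # a wildly oscillating interpolant is refit with more smoothing
        if arc[-1] <= 1.1 * chord_total:
            break
        s_try = max(s_try * 10.0, (1e-3 * chord_total) ** 2)
    x, y = interpolate.splev(uu, tck)
    return FilamentContour(
        points=np.column_stack([x, y]), frame=frame, _tck=tck, _u_arc=arc
    )


def _cv_smoothing(points: np.ndarray, u: np.ndarray) -> float:
    """Two-fold cross-validated spline smoothing budget."""
    scale = float(np.ptp(points))
    candidates = np.concatenate([[0.0], scale**2 * np.logspace(-10, -4, 13)])
    best_s, best_err = 0.0, np.inf
    for s in candidates:
        err = 0.0
        ok = True
        for parity in (0, 1):
            train = np.arange(len(u)) % 2 == parity
            if train.sum() < 8:
                ok = False
                break
            try:
                tck, _ = interpolate.splprep(
                    [points[train, 0], points[train, 1]], u=u[train], s=float(s), k=3
                )
            except Exception:
                ok = False
                break
            test = ~train
            xs, ys = interpolate.splev(np.clip(u[test], u[train][0], u[train][-1]), tck)
            err += float(np.mean((xs - points[test, 0]) ** 2 + (ys - points[test, 1]) ** 2))
        if ok and err < best_err:
            best_err, best_s = err, float(s)
    return best_s


def tangent_angles(contour: FilamentContour, ds: float) -> TangentProfile:
    """Tangent angles at stations 0, ds, 2ds, ... along the contour.

    For spline-fitted contours the angle comes from the analytic spline
    derivative; for polyline contours from the local segment direction.
    Angles are unwrapped so the profile is continuous.
    """
    if ds <= 0:
        raise ValueError("ds must be positive")
    L = contour.length
    if ds > L / 10.0:
        raise ValueError("station spacing too coarse (ds must be <= L/10)")
    n = int(np.floor(L / ds)) + 1
    stations = np.arange(n) * ds
    return TangentProfile(stations=stations, angles=contour.tangent_angle_at(stations))


def qc_contour_length(lengths, tolerance: float = 0.10):
    """Accept a run if its contour-length spread stays within ``tolerance``.

    Relative variation is ``(max L - min L) / mean L``; a larger spread
    flags out-of-plane deformation and rejects the whole run.  Returns
    ``(keep, mean_L, relative_variation)``.
    """
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size < 2:
        raise ValueError("need at least two frames for the length QC")
    mean_L = float(lengths.mean())
    rel = float((lengths.max() - lengths.min()) / mean_L)
    return rel <= tolerance, mean_L, rel


def qc_focal_plane(z_positions, slab_half_width: float = 5e-6):
    """Flag frames whose z lies inside the focal slab (default 10 um thick).

    ``z_positions`` are distances from the focal-plane center (m);
    returns a boolean in-focus mask.
    """
    z = np.asarray(z_positions, dtype=float)
    return np.abs(z) <= slab_half_width
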
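"""Synthetic data emulating the microchannel filament experiment.

The raw recordings behind the study conditions are not deposited, so
every downstream stage is exercised on synthetic data with known ground
truth:

* planar worm-like-chain contours with prescribed persistence length
  (tangent-angle increments are i.i.d. Gaussian with variance
  ``ds / l_p``, giving the projected-contour decay
  ``<cos dtheta(s)> = exp(-s / (2 l_p))``);
* diffraction-limited fluorescence renderings of those contours (a
  Gaussian line-spread function along the contour, Poisson or Gaussian
  counting noise);
* tracer and filament trajectories advected by the oscillatory flow
  model with a prescribed lateral drift, Brownian steps and reflecting
  walls;
* per-frame contour sequences following a deformation schedule
  (static, periodic bend, periodic rotation) that emulate the observed
  coiling/uncoiling and rotation cycles.

All randomness flows from explicit integer seeds; equal configurations
reproduce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contours import FilamentContour
from .flow import FlowModel

__all__ = [
    "WlcParameters",
    "RenderConfig",
    "TrajectoryConfig",
    "DeformationSchedule",
    "sample_wlc_contour",
    "sample_wlc_angles",
    "render_filament_image",
    "simulate_particle_trajectory",
    "simulate_filament_sequence",
]


@dataclass(frozen=True)
class WlcParameters:
    """Worm-like-chain sampling parameters (SI units).

    The arc step must resolve the chain (``ds <= L/20``); the decay
    constant of the tangent-cosine correlation is ``2 l_p`` under the
    default planar convention and ``l_p`` if ``planar`` is switched off.
    """

    contour_length: float = 40e-6
    persistence_length: float = 10e-6
    arc_step: float = 0.2e-6
    seed: int = 0
    planar: bool = True

    def __post_init__(self) -> None:
        if self.persistence_length <= 0:
            raise ValueError("persistence length must be positive")
        if not 0 < self.arc_step <= self.contour_length / 20.0:
            raise ValueError("arc step must satisfy 0 < ds <= L/20")


@dataclass(frozen=True)
class RenderConfig:
    """Fluorescence rendering parameters.

    ``sigma_px`` is the Gaussian line-spread width; defaults emulate a
    diffraction-limited 20x epifluorescence image at SNR ~ 10 with
    Poisson counting noise (the experimental noise statistics are not
    reported, so these are exposed, not baked in).
    """

    pixel_size: float = 0.4e-6
    sigma_px: float = 1.2
    peak_intensity: float = 1000.0
    background: float = 100.0
    noise: str = "poisson"  # {"poisson", "gaussian", "none"}
    gaussian_sigma: float = 10.0
    shape: tuple[int, int] = (256, 256)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.sigma_px <= 0:
            raise ValueError("pixel size and sigma must be positive")
        if self.noise not in ("poisson", "gaussian", "none"):
            raise ValueError("noise must be 'poisson', 'gaussian' or 'none'")


@dataclass(frozen=True)
class TrajectoryConfig:
    """Kinematic transport parameters for a simulated particle/filament.

    Defaults match the recording conditions emulated throughout: 10 Hz
    frame rate and runs of 500-2000 frames.  ``drift`` is the imposed
    lateral migration velocity (m/s, positive toward the wall at
    x_rel > 0), ``diffusivity`` the translational Brownian coefficient
    (m^2/s), ``slip_factor`` the ratio of particle to local fluid
    longitudinal velocity, and ``initial_x_rel`` the normalized start
    position in (-1, 1).
    """

    frame_rate: float = 10.0
    n_frames: int = 500
    drift: float = 0.0
    diffusivity: float = 0.0
    slip_factor: float = 1.0
    initial_x_rel: float = 0.0
    out_of_plane_probability: float = 0.0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be positive")
        if not -1.0 < self.initial_x_rel < 1.0:
            raise ValueError("initial position must lie inside the channel")


@dataclass(frozen=True)
class DeformationSchedule:
    """Per-frame contour deformation: one of static / periodic-bend /
    periodic-rotation, driven at an angular frequency (rad/s).

    ``periodic-rotation`` rotates the base contour rigidly by
    ``amplitude * sin(omega t)`` (isometric, so the contour length never
    drifts); ``periodic-bend`` bends it along a circular arc whose total
    turning angle oscillates with the same law.
    """

    kind: str = "static"
    amplitude: float = 0.0
    omega: float = 2.0 * np.pi * 0.25

    def __post_init__(self) -> None:
        if self.kind not in ("static", "periodic-bend", "periodic-rotation"):
            raise ValueError(f"unknown schedule kind: {self.kind!r}")


def sample_wlc_angles(params: WlcParameters, rng: np.random.Generator | None = None) -> np.ndarray:
    """Tangent angles of one discrete WLC realization at each arc step."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n_seg = int(round(params.contour_length / params.arc_step))
    var = params.arc_step / params.persistence_length
    if not params.planar:
        var *= 2.0  # 3-D convention: faster decay of the projected cosine
    increments = rng.normal(0.0, np.sqrt(var), size=n_seg - 1)
    theta0 = rng.uniform(-np.pi, np.pi)
    return theta0 + np.concatenate([[0.0], np.cumsum(increments)])


def sample_wlc_contour(params: WlcParameters, rng: np.random.Generator | None = None) -> FilamentContour:
    """Sample one planar worm-like-chain contour.

    Points are spaced ``ds`` apart along the arc; successive tangent
    angles differ by independent N(0, ds/l_p) increments, so the mean
    tangent cosine decays as ``exp(-s / (2 l_p))``.  Passing the same
    parameters (same seed) returns an identical point list.
    """
    theta = sample_wlc_angles(params, rng)
    steps = params.arc_step * np.column_stack([np.cos(theta), np.sin(theta)])
    pts = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return FilamentContour.from_polyline(pts)


class ContourOutOfBounds(ValueError):
    """Raised when a contour cannot be rendered with a 3-sigma margin."""

    def __init__(self, clipped_points: int, total: int):
        self.clipped_points = clipped_points
        self.total = total
        super().__init__(
            f"contour leaves the rendering frame: {clipped_points}/{total} points "
            "closer than 3 sigma to the border"
        )


def render_filament_image(
    contour: FilamentContour,
    cfg: RenderConfig,
    rng: np.random.Generator | None = None,
    origin: tuple[float, float] | None = None,
) -> np.ndarray:
    """Render a contour as a diffraction-limited fluorescence image.

    The intensity is the line integral of a normalized 2-D Gaussian
    kernel along the contour, scaled so that the ridge of a straight
    filament reaches ``peak_intensity``, plus the background and the
    configured counting noise.  Noise-free rendering is deterministic.
    ``origin`` places the physical coordinate (m) of the image corner;
    by default the contour is centered in the frame.
    """
    h, w = cfg.shape
    px = cfg.pixel_size
    pts = contour.points
    if origin is None:
        com = pts.mean(axis=0)
        origin = (com[0] - w * px / 2.0, com[1] - h * px / 2.0)
    xy_px = (pts - np.asarray(origin)) / px

    margin = 3.0 * cfg.sigma_px
    outside = (
        (xy_px[:, 0] < margin)
        | (xy_px[:, 0] > w - 1 - margin)
        | (xy_px[:, 1] < margin)
        | (xy_px[:, 1] > h - 1 - margin)
    )
    if outside.any():
        raise ContourOutOfBounds(int(outside.sum()), len(pts))

    # resample the polyline densely relative to sigma for a smooth line integral
    seg = np.linalg.norm(np.diff(xy_px, axis=0), axis=1)
    s_cum = np.concatenate([[0.0], np.cumsum(seg)])
    step = cfg.sigma_px / 4.0
    s_dense = np.arange(0.0, s_cum[-1] + step / 2, step)
    xd = np.interp(s_dense, s_cum, xy_px[:, 0])
    yd = np.interp(s_dense, s_cum, xy_px[:, 1])

    img = np.zeros((h, w), dtype=float)
    sig2 = cfg.sigma_px**2
    half = int(np.ceil(4.0 * cfg.sigma_px)) + 1
    for xc, yc in zip(xd, yd):
        c0, r0 = int(round(xc)), int(round(yc))
        rows = slice(max(r0 - half, 0), min(r0 + half + 1, h))
        cols = slice(max(c0 - half, 0), min(c0 + half + 1, w))
        yy, xx = np.mgrid[rows, cols]
        img[rows, cols] += np.exp(-((xx - xc) ** 2 + (yy - yc) ** 2) / (2.0 * sig2))
    # the raw sum approximates (1/step) * integral of the kernel along the
    # line; a straight ridge carries sqrt(2 pi) sigma / step, so rescale
    # that to the configured peak intensity.
    img *= cfg.peak_intensity * step / (np.sqrt(2.0 * np.pi) * cfg.sigma_px)
    img += cfg.background

    if cfg.noise == "none":
        return img
    if rng is None:
        rng = np.random.default_rng(0)
    if cfg.noise == "poisson":
        return rng.poisson(np.clip(img, 0, None)).astype(float)
    return img + rng.normal(0.0, cfg.gaussian_sigma, size=img.shape)


@dataclass
class ParticleTrack:
    """Ground-truth trajectory of a simulated particle."""

    times: np.ndarray
    x: np.ndarray  # lateral (cross-channel), m, origin at centerline
    y: np.ndarray  # longitudinal, m
    in_focus: np.ndarray = field(default=None)  # type: ignore[assignment]


def _reflect(x: np.ndarray, half_width: float) -> np.ndarray:
    # reflect into [-a, a] (single reflection suffices for small steps)
    period = 4.0 * half_width
    x = np.mod(x + half_width, period)
    x = np.where(x > 2.0 * half_width, period - x, x)
    return x - half_width

def simulate_particle_trajectory(
    cfg: TrajectoryConfig,
    flow: FlowModel,
    seed: int = 0,
) -> ParticleTrack:
    """Advect a point particle kinematically through the oscillatory flow.

    Per frame: longitudinal displacement is ``slip_factor`` times the
    local observed-profile velocity times dt (midpoint rule in time);
    lateral displacement is ``drift * dt`` plus a Gaussian Brownian step
    of variance ``2 D dt``; positions reflect at the channel walls.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / cfg.frame_rate
    a = flow.geometry.half_width
    n = cfg.n_frames
    times = np.arange(n) * dt
    x = np.empty(n)
    y = np.empty(n)
    x[0] = cfg.initial_x_rel * a
    y[0] = 0.0
    lat_noise = rng.normal(0.0, np.sqrt(2.0 * cfg.diffusivity * dt), size=n - 1) if cfg.diffusivity > 0 else np.zeros(n - 1)
    lon_noise = rng.normal(0.0, np.sqrt(2.0 * cfg.diffusivity * dt), size=n - 1) if cfg.diffusivity > 0 else np.zeros(n - 1)
    drift = cfg.drift
    for i in range(n - 1):
        t_mid = times[i] + dt / 2.0
        v = flow.velocity(x[i] / a, t_mid)
        y[i + 1] = y[i] + cfg.slip_factor * v * dt + lon_noise[i]
        x_new = x[i] + drift * dt + lat_noise[i]
        if abs(x_new) > a:
            # the wall reflects both the position and the deterministic
            # drift direction (billiard bounce), so a drifting particle
            # is not pinned against the wall
            drift = -drift
        x[i + 1] = _reflect(np.asarray(x_new), a)
    if cfg.out_of_plane_probability > 0:
        in_focus = rng.random(n) >= cfg.out_of_plane_probability
    else:
        in_focus = np.ones(n, dtype=bool)
    return ParticleTrack(times=times, x=x, y=y, in_focus=in_focus)


def _bend_arc(base: FilamentContour, total_turn: float) -> np.ndarray:
    """Bend a contour isometrically along a circular arc with the given
    total turning angle added uniformly along the arc length."""
    pts = base.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    theta = np.arctan2(np.diff(pts[:, 1]), np.diff(pts[:, 0]))
    L = seg.sum()
    s_mid = np.concatenate([[0.0], np.cumsum(seg)])[:-1] + seg / 2.0
    theta_new = theta + total_turn * (s_mid / L - 0.5)
    steps = seg[:, None] * np.column_stack([np.cos(theta_new), np.sin(theta_new)])
    out = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return out - out.mean(axis=0) + pts.mean(axis=0)


def simulate_filament_sequence(
    wlc: WlcParameters,
    traj: TrajectoryConfig,
    flow: FlowModel,
    schedule: DeformationSchedule | None = None,
    seed: int = 0,
) -> tuple[list[FilamentContour], ParticleTrack]:
    """Per-frame contours of a transported, deforming filament.

    The base WLC contour is transformed frame by frame according to the
    deformation schedule (an isometry for ``static`` and
    ``periodic-rotation``, so the contour length is constant by
    construction), then translated along the simulated center-of-mass
    trajectory.  Returns the contour stack and the ground-truth track.
    """
    if schedule is None:
        schedule = DeformationSchedule()
    rng = np.random.default_rng(seed)
    base = sample_wlc_contour(wlc, rng)
    base_centered = base.points - base.points.mean(axis=0)
    track = simulate_particle_trajectory(traj, flow, seed=seed + 1)
    contours = []
    for i, t in enumerate(track.times):
        if schedule.kind == "static":
            pts = base_centered.copy()
        elif schedule.kind == "periodic-rotation":
            ang = schedule.amplitude * np.sin(schedule.omega * t)
            rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
            pts = base_centered @ rot.T
        else:  # periodic-bend
            turn = schedule.amplitude * np.sin(schedule.omega * t)
            bent = _bend_arc(FilamentContour.from_polyline(base_centered), turn)
            pts = bent - bent.mean(axis=0)
        pts = pts + np.array([track.x[i], track.y[i]])
        contours.append(FilamentContour.from_polyline(pts, frame=i, in_focus=bool(track.in_focus[i])))
    return contours, track
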
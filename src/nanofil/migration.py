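"""Trajectory building and transport statistics in the oscillatory flow.

The experimental protocol samples each tracked object phase-locked to
the flow oscillation: center-of-mass positions at every zero-crossing
of the forcing (phase n pi) give the lateral migration velocity

    U_r = mean(|dx_lateral| / dt) / V_max ,

and longitudinal velocities at every flow extremum (phase n pi/2, n
odd) give the slip velocity

    U_s = V_filament / V_fluid(x_COM, t) ,

with the fluid velocity evaluated from the blunted observation-plane
profile at the object's lateral position.  The oscillation phase itself
is recovered by least-squares fitting a sinusoid to a reference
longitudinal velocity series (in the experiment, short filament
fragments acting as tracers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .flow import FlowModel

__all__ = [
    "PhaseFit",
    "MigrationRecord",
    "link_tracks",
    "detect_phase",
    "lateral_migration_velocity",
    "slip_velocity",
    "normalized_position",
    "population_summary",
]


@dataclass(frozen=True)
class PhaseFit:
    """Fitted sinusoidal forcing and its phase-locked frame indices."""

    vmax: float
    omega: float
    phase: float
    r_squared: float
    zero_crossings: np.ndarray  # frame indices nearest phase = n pi, n >= 1
    extrema: np.ndarray  # frame indices nearest phase = n pi/2, n odd

    def phase_at(self, t):
        return self.omega * np.asarray(t) + self.phase


@dataclass
class MigrationRecord:
    """Center-of-mass time series of one tracked object plus phase labels."""

    times: np.ndarray
    x: np.ndarray  # lateral position, m, origin at the centerline
    y: np.ndarray  # longitudinal position, m
    phase_fit: PhaseFit | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.times) == len(self.x) == len(self.y)):
            raise ValueError("times, x, y must align")


def link_tracks(detections, max_displacement: float):
    """Greedy nearest-neighbor frame-to-frame linking.

    ``detections`` is a sequence of per-frame ``(n_i, 2)`` position
    arrays.  Within each frame pair, candidate links are sorted by
    displacement (ties resolved by detection order, so the result is
    deterministic) and accepted greedily under the gate; detections
    that stay unlinked start new tracks.  Returns a list of tracks,
    each a list of ``(frame, x, y)`` tuples.
    """
    tracks: list[list[tuple[int, float, float]]] = []
    active: dict[int, int] = {}  # detection index in previous frame -> track id
    prev = None
    for f, det in enumerate(detections):
        det = np.asarray(det, dtype=float).reshape(-1, 2)
        new_active: dict[int, int] = {}
        if prev is not None and len(prev) and len(det):
            cand = []
            for i in range(len(prev)):
                if i not in active:
                    continue
                d = np.linalg.norm(det - prev[i], axis=1)
                for j in range(len(det)):
                    if d[j] <= max_displacement:
                        cand.append((d[j], i, j))
            cand.sort(key=lambda c: (c[0], c[1], c[2]))
            used_i: set[int] = set()
            used_j: set[int] = set()
            for d, i, j in cand:
                if i in used_i or j in used_j:
                    continue
                used_i.add(i)
                used_j.add(j)
                tid = active[i]
                tracks[tid].append((f, det[j, 0], det[j, 1]))
                new_active[j] = tid
        for j in range(len(det)):
            if j not in new_active:
                tracks.append([(f, det[j, 0], det[j, 1])])
                new_active[j] = len(tracks) - 1
        active = new_active
        prev = det
    return tracks


def detect_phase(
    times,
    velocities,
    min_r_squared: float = 0.5,
) -> PhaseFit:
    """Fit ``V(t) = V_max sin(w t + phi)`` to a reference velocity series.

    The frequency is initialized from the periodogram and refined by
    nonlinear least squares.  Requires at least three oscillation
    periods of data and a fit R^2 above ``min_r_squared``; otherwise the
    series carries no usable phase information and a ``ValueError`` is
    raised instead of returning misleading labels.
    """
    times = np.asarray(times, dtype=float)
    v = np.asarray(velocities, dtype=float)
    if len(times) < 8:
        raise ValueError("too few samples for a phase fit")
    dt = float(np.median(np.diff(times)))
    freqs = np.fft.rfftfreq(len(v), dt)
    spectrum = np.abs(np.fft.rfft(v - v.mean()))
    f0 = freqs[np.argmax(spectrum[1:]) + 1]
    if f0 <= 0 or (times[-1] - times[0]) * f0 < 3.0:
        raise ValueError("need at least three oscillation periods")

    def model(t, a, w, p):
        return a * np.sin(w * t + p)

    a0 = float(np.sqrt(2.0) * np.std(v))
    best = None
    for p0 in (0.0, np.pi / 2, np.pi, -np.pi / 2):
        try:
            popt, _ = curve_fit(model, times, v, p0=[a0, 2 * np.pi * f0, p0], maxfev=5000)
        except RuntimeError:
            continue
        res = float(np.sum((v - model(times, *popt)) ** 2))
        if best is None or res < best[0]:
            best = (res, popt)
    if best is None:
        raise ValueError("sinusoid fit failed")
    res, (a, w, p) = best
    if a < 0:
        a, p = -a, p + np.pi
    p = np.mod(p + np.pi, 2 * np.pi) - np.pi
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - res / ss_tot if ss_tot > 0 else 0.0
    if r2 < min_r_squared:
        raise ValueError(f"phase fit unreliable (R^2 = {r2:.3f})")

    phase = w * times + p
    zero_idx = _nearest_phase_indices(phase, np.pi, start=1, step=1)
    ext_idx = _nearest_phase_indices(phase, np.pi / 2, start=1, step=2)
    return PhaseFit(float(a), float(w), float(p), r2, zero_idx, ext_idx)


def _nearest_phase_indices(phase: np.ndarray, unit: float, start: int, step: int) -> np.ndarray:
    """Frame indices nearest each target phase ``n * unit`` within range."""
    lo, hi = phase[0], phase[-1]
    n_first = max(start, int(np.ceil(lo / unit)))
    # align n to the arithmetic sequence start, start+step, ...
    if (n_first - start) % step:
        n_first += step - (n_first - start) % step
    targets = np.arange(n_first, int(np.floor(hi / unit)) + 1, step) * unit
    if targets.size == 0:
        return np.array([], dtype=int)
    right = np.searchsorted(phase, targets).clip(1, len(phase) - 1)
    left = right - 1
    pick_left = np.abs(phase[left] - targets) <= np.abs(phase[right] - targets)
    return np.where(pick_left, left, right).astype(int)


def lateral_migration_velocity(record: MigrationRecord, vmax: float):
    """Lateral migration velocity U_r from zero-crossing samples.

    The lateral center-of-mass position is read at every flow
    zero-crossing; ``U_r`` is the mean of ``|dx|/dt`` over consecutive
    crossing pairs, normalized by ``V_max``.  The migration direction
    (toward the centerline vs the wall) is reported separately as the
    sign of the mean displacement of |x|: ``-1`` toward the center,
    ``+1`` toward the wall, ``0`` for no net motion.
    Returns ``(U_r, direction)``.
    """
    if record.phase_fit is None:
        raise ValueError("record carries no phase labels")
    idx = record.phase_fit.zero_crossings
    if len(idx) < 2:
        raise ValueError("need at least two zero-crossing samples")
    x = record.x[idx]
    t = record.times[idx]
    speed = np.abs(np.diff(x)) / np.diff(t)
    u_r = float(np.mean(speed) / vmax)
    radial = np.abs(x)
    net = float(radial[-1] - radial[0])
    direction = 0 if net == 0 else int(np.sign(net))
    return u_r, direction


def slip_velocity(
    record: MigrationRecord,
    flow: FlowModel,
    window: int = 1,
):
    """Slip velocity U_s at each flow extremum, and its mean.

    At every odd n pi/2 extremum the filament's longitudinal velocity is
    a centered finite difference over ``+-window`` frames, divided by
    the local fluid velocity from the blunted profile at the object's
    lateral position and the extremum time.  A centered difference of a
    sinusoidal displacement attenuates the instantaneous velocity by
    ``sin(w h)/(w h)`` (h the half-window); the fitted angular frequency
    is known, so that attenuation is divided back out.  Extrema too
    close to the record boundary are skipped.  Returns
    ``(per-extremum U_s, mean)``.
    """
    if record.phase_fit is None:
        raise ValueError("record carries no phase labels")
    a = flow.geometry.half_width
    omega = record.phase_fit.omega
    out = []
    for i in record.phase_fit.extrema:
        if i - window < 0 or i + window >= len(record.times):
            continue
        dt = record.times[i + window] - record.times[i - window]
        wh = omega * dt / 2.0
        attenuation = np.sin(wh) / wh if wh > 1e-12 else 1.0
        v_fil = (record.y[i + window] - record.y[i - window]) / dt / attenuation
        v_fluid = flow.velocity(record.x[i] / a, record.times[i])
        if abs(v_fluid) < 1e-15:
            continue
        out.append(v_fil / v_fluid)
    series = np.asarray(out)
    if series.size == 0:
        raise ValueError("no usable extremum samples")
    return series, float(series.mean())


def normalized_position(x, geometry) -> np.ndarray:
    """Normalized lateral position ``p = |x| / (W/2)`` in [0, 1]."""
    x = np.asarray(x, dtype=float)
    a = geometry.half_width
    if np.any(np.abs(x) > a * (1 + 1e-9)):
        raise ValueError("position outside the channel")
    p = np.abs(x) / a
    return float(p) if p.ndim == 0 else p


def population_summary(
    records: dict,
    flow: FlowModel,
    mid_channel_limit: float | None = None,
    bins: int = 10,
):
    """Initial/final position distributions and transport statistics per group.

    ``records`` maps a group label (e.g. ``"bent-like"``,
    ``"U-shaped stretched"``, ``"U-shaped buckled"``) to a list of
    :class:`MigrationRecord`.  For every non-empty group the summary
    holds histograms of the normalized position p at the first and last
    zero-crossing, mean +- sd of U_r and mean U_s, and the migration
    directions.  ``mid_channel_limit`` (m) optionally retains only
    records whose initial |x| lies within that distance of the
    centerline (the protocol's mid-channel selection, 40 um) before any
    statistics.  Empty groups are omitted and listed under ``"skipped"``.
    """
    geometry = flow.geometry
    edges = np.linspace(0.0, 1.0, bins + 1)
    out: dict = {"groups": {}, "skipped": []}
    for group, recs in records.items():
        recs = list(recs)
        if mid_channel_limit is not None:
            recs = [r for r in recs if abs(r.x[r.phase_fit.zero_crossings[0]]) <= mid_channel_limit]
        if not recs:
            out["skipped"].append(group)
            continue
        p_init, p_final, urs, uss, dirs = [], [], [], [], []
        for r in recs:
            zc = r.phase_fit.zero_crossings
            p_init.append(normalized_position(r.x[zc[0]], geometry))
            p_final.append(normalized_position(r.x[zc[-1]], geometry))
            u_r, direction = lateral_migration_velocity(r, r.phase_fit.vmax)
            urs.append(u_r)
            dirs.append(direction)
            _, us_mean = slip_velocity(r, flow)
            uss.append(us_mean)
        out["groups"][group] = {
            "n": len(recs),
            "p_initial_hist": np.histogram(p_init, bins=edges)[0].tolist(),
            "p_final_hist": np.histogram(p_final, bins=edges)[0].tolist(),
            "p_edges": edges.tolist(),
            "p_initial_mean": float(np.mean(p_init)),
            "p_final_mean": float(np.mean(p_final)),
            "U_r_mean": float(np.mean(urs)),
            "U_r_sd": float(np.std(urs)),
            "U_s_mean": float(np.mean(uss)),
            "U_s_sd": float(np.std(uss)),
            "direction_mean": float(np.mean(dirs)),
        }
    return out
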
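"""Track linking, phase detection and the U_r / U_s statistics."""

import numpy as np
import pytest

from nanofil.flow import ChannelGeometry, FlowModel, FluidProperties, OscillatoryForcing
from nanofil.migration import (
    MigrationRecord,
    detect_phase,
    lateral_migration_velocity,
    link_tracks,
    normalized_position,
    population_summary,
    slip_velocity,
)
from nanofil.synthetics import TrajectoryConfig, simulate_particle_trajectory

GEOM = ChannelGeometry()


def make_flow(vmax=250e-6, freq=0.25):
    return FlowModel(
        GEOM, FluidProperties(), OscillatoryForcing(vmax=vmax, omega=2 * np.pi * freq)
    )


def tracked_record(flow, cfg, seed=0):
    tr = simulate_particle_trajectory(cfg, flow, seed=seed)
    v = np.gradient(tr.y, tr.times)
    pf = detect_phase(tr.times, v)
    return MigrationRecord(tr.times, tr.x, tr.y, phase_fit=pf), tr


class TestLinkTracks:
    def test_single_particle_full_track(self):
        det = [np.array([[f * 0.1, 0.0]]) for f in range(30)]
        tracks = link_tracks(det, max_displacement=0.5)
        assert len(tracks) == 1 and len(tracks[0]) == 30

    def test_two_separated_particles(self):
        det = [np.array([[0.0, 0.0], [100.0, 0.0]]) for _ in range(10)]
        tracks = link_tracks(det, max_displacement=1.0)
        assert sorted(len(t) for t in tracks) == [10, 10]

    def test_gate_breaks_links(self):
        det = [np.array([[0.0, 0.0]]), np.array([[10.0, 0.0]])]
        tracks = link_tracks(det, max_displacement=1.0)
        assert len(tracks) == 2

    def test_crossing_tracks_mostly_correct(self):
        """Two crossing constant-velocity tracks relink correctly when the
        gate is a few times the per-frame displacement."""
        rng = np.random.default_rng(3)
        n = 60
        t = np.arange(n, dtype=float)
        a = np.column_stack([t * 1.0, 20 - t * 0.5]) + rng.normal(0, 0.05, (n, 2))
        b = np.column_stack([t * 1.0, -20 + t * 0.5]) + rng.normal(0, 0.05, (n, 2))
        det = [np.vstack([a[f], b[f]]) for f in range(n)]
        tracks = link_tracks(det, max_displacement=3.5)
        long_tracks = [tr for tr in tracks if len(tr) > 5]
        assert len(long_tracks) == 2
        # each long track stays on one ground-truth line away from the crossing
        correct = 0
        total = 0
        for tr in long_tracks:
            pts = np.array([(f, x, y) for f, x, y in tr])
            for f, x, y in pts:
                fi = int(f)
                truth = a[fi] if np.hypot(*(np.array([x, y]) - a[fi])) < np.hypot(
                    *(np.array([x, y]) - b[fi])
                ) else b[fi]
                total += 1
                correct += np.allclose([x, y], truth)
        assert correct / total >= 0.95


class TestDetectPhase:
    def test_exact_sinusoid_recovery(self):
        t = np.arange(0, 40, 0.1)
        w, phi, a = 2 * np.pi * 0.25, 0.4, 250e-6
        pf = detect_phase(t, a * np.sin(w * t + phi))
        assert pf.vmax == pytest.approx(a, rel=1e-6)
        assert pf.omega == pytest.approx(w, rel=1e-6)
        assert pf.phase == pytest.approx(phi, abs=1e-6)
        assert pf.r_squared > 0.999

    def test_noisy_sinusoid_frequency_within_one_percent(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 40, 0.1)  # 10 periods at 0.25 Hz
        w = 2 * np.pi * 0.25
        v = 250e-6 * np.sin(w * t) + rng.normal(0, 25e-6, len(t))
        pf = detect_phase(t, v)
        assert pf.omega == pytest.approx(w, rel=0.01)

    def test_zero_crossing_count(self):
        t = np.arange(0, 40, 0.1)
        pf = detect_phase(t, np.sin(2 * np.pi * 0.25 * t))
        # phase spans ~10 periods starting at 0: crossings at n pi, n>=1
        assert len(pf.zero_crossings) == pytest.approx(2 * 10, abs=1)
        assert len(pf.extrema) == pytest.approx(2 * 10, abs=1)

    def test_crossings_and_extrema_alternate(self):
        t = np.arange(0, 40, 0.1)
        pf = detect_phase(t, np.sin(2 * np.pi * 0.25 * t))
        merged = sorted(
            [(i, "z") for i in pf.zero_crossings] + [(i, "e") for i in pf.extrema]
        )
        kinds = [k for _, k in merged]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_short_series_refused(self):
        t = np.arange(0, 4, 0.1)  # one period only
        with pytest.raises(ValueError):
            detect_phase(t, np.sin(2 * np.pi * 0.25 * t))

    def test_noise_only_refused(self):
        rng = np.random.default_rng(1)
        t = np.arange(0, 40, 0.1)
        with pytest.raises(ValueError):
            detect_phase(t, rng.normal(size=len(t)))


class TestLateralMigration:
    def test_stationary_gives_zero(self):
        flow = make_flow()
        rec, _ = tracked_record(flow, TrajectoryConfig(n_frames=800, initial_x_rel=0.2))
        u_r, direction = lateral_migration_velocity(rec, flow.forcing.vmax)
        assert u_r == pytest.approx(0.0, abs=1e-12)
        assert direction == 0

    def test_constant_drift_ratio(self):
        flow = make_flow(vmax=250e-6)
        rec, _ = tracked_record(
            flow, TrajectoryConfig(n_frames=800, drift=0.25e-6, initial_x_rel=0.1)
        )
        u_r, direction = lateral_migration_velocity(rec, flow.forcing.vmax)
        assert u_r == pytest.approx(1.0e-3, rel=0.01)
        assert direction == +1  # moving away from the centerline

    def test_centerward_drift_direction(self):
        flow = make_flow()
        rec, _ = tracked_record(
            flow, TrajectoryConfig(n_frames=800, drift=-0.5e-6, initial_x_rel=0.5)
        )
        _, direction = lateral_migration_velocity(rec, flow.forcing.vmax)
        assert direction == -1

    def test_noisy_drift_recovery_within_fifteen_percent(self):
        """drift 0.5 um/s with D = 0.05 um^2/s over 20 periods: the mean
        U_r across seeds stays within 15% of drift / V_max."""
        flow = make_flow(vmax=250e-6)
        cfg = TrajectoryConfig(
            n_frames=800, drift=0.5e-6, diffusivity=0.05e-12, initial_x_rel=0.05
        )
        urs = []
        for seed in range(10):
            rec, _ = tracked_record(flow, cfg, seed=seed)
            u_r, _ = lateral_migration_velocity(rec, flow.forcing.vmax)
            urs.append(u_r)
        assert np.mean(urs) == pytest.approx(0.5e-6 / 250e-6, rel=0.15)

    def test_longitudinal_translation_invariance(self):
        flow = make_flow()
        rec, _ = tracked_record(
            flow, TrajectoryConfig(n_frames=800, drift=0.3e-6, initial_x_rel=0.1)
        )
        shifted = MigrationRecord(rec.times, rec.x, rec.y + 1e-3, phase_fit=rec.phase_fit)
        u0, _ = lateral_migration_velocity(rec, flow.forcing.vmax)
        u1, _ = lateral_migration_velocity(shifted, flow.forcing.vmax)
        assert u1 == pytest.approx(u0, rel=1e-12)


class TestSlipVelocity:
    @pytest.mark.parametrize("slip", [1.0, 0.5])
    def test_programmed_slip_recovered(self, slip):
        flow = make_flow()
        rec, _ = tracked_record(
            flow, TrajectoryConfig(n_frames=800, slip_factor=slip, initial_x_rel=0.3)
        )
        series, mean = slip_velocity(rec, flow)
        assert mean == pytest.approx(slip, abs=0.02)
        assert np.all(np.abs(series - slip) < 0.02)

    def test_lateral_offset_invariance(self):
        """Adding a constant lateral offset changes the local fluid speed,
        but U_s still matches the slip factor because the particle was
        advected at that same local speed."""
        flow = make_flow()
        for x0 in (0.0, 0.4):
            rec, _ = tracked_record(
                flow, TrajectoryConfig(n_frames=800, slip_factor=0.9, initial_x_rel=x0)
            )
            _, mean = slip_velocity(rec, flow)
            assert mean == pytest.approx(0.9, abs=0.02)

    def test_phase_labels_required(self):
        rec = MigrationRecord(np.arange(10.0), np.zeros(10), np.zeros(10))
        with pytest.raises(ValueError):
            slip_velocity(rec, make_flow())


class TestNormalizedPosition:
    @pytest.mark.parametrize("x_um, p", [(0.0, 0.0), (100.0, 1.0), (50.0, 0.5), (-50.0, 0.5)])
    def test_mapping(self, x_um, p):
        assert normalized_position(x_um * 1e-6, GEOM) == pytest.approx(p)

    def test_outside_channel_rejected(self):
        with pytest.raises(ValueError):
            normalized_position(150e-6, GEOM)


class TestPopulationSummary:
    def _records(self, flow, drifts, x0s, seeds):
        recs = []
        for drift, x0, seed in zip(drifts, x0s, seeds):
            rec, _ = tracked_record(
                flow, TrajectoryConfig(n_frames=800, drift=drift, initial_x_rel=x0), seed=seed
            )
            recs.append(rec)
        return recs

    def test_centerward_population_shifts_histogram(self):
        flow = make_flow()
        recs = self._records(flow, [-0.8e-6] * 5, [0.5, 0.6, 0.4, 0.55, 0.45], range(5))
        out = population_summary({"bent-like": recs}, flow)
        g = out["groups"]["bent-like"]
        assert g["p_final_mean"] < g["p_initial_mean"]
        assert g["direction_mean"] < 0

    def test_empty_group_skipped(self):
        flow = make_flow()
        out = population_summary({"U-shaped": []}, flow)
        assert out["skipped"] == ["U-shaped"]
        assert out["groups"] == {}

    def test_mid_channel_filter_retains_central_records(self):
        flow = make_flow()
        recs = self._records(flow, [0.0] * 4, [0.1, 0.3, 0.6, 0.9], range(4))
        out = population_summary({"g": recs}, flow, mid_channel_limit=40e-6)
        # |x0| <= 40 um means x_rel <= 0.4: two of four records remain
        assert out["groups"]["g"]["n"] == 2
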
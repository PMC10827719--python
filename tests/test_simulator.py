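"""Agent model: drag wiring, steering controllers, variants, batch sweeps."""

import math

import numpy as np
import pytest

from dlrflight.errors import ConfigurationError
from dlrflight.frames import Trajectory
from dlrflight.metrics import classify_motif, range_change_rate
from dlrflight.simulator import (AgentParams, AgentState, initial_state,
                                 random_sweep, run, steering_errors,
                                 steering_rotation, step)

MOTIF_PARAMS = dict(k1=15.0, k2=1.0, k3=15.0, vt=3.5, a_forw=5.0,
                    a_dors=15.0, dt=0.01)


class TestDragConstant:
    @pytest.mark.parametrize("vt,c", [(3.5, 0.80), (10.5, 0.09),
                                      (0.5, 39.24)])
    def test_form_factor_from_terminal_velocity(self, vt, c):
        assert AgentParams(vt=vt).c == pytest.approx(c, abs=0.005)

    def test_free_fall_reaches_terminal_velocity(self):
        params = AgentParams(a_forw=0, a_dors=0, k1=0, k2=0, k3=0,
                             variant="light_off")
        state = initial_state(params, [0, 0, 0], 0.0, speed=0.0)
        for _ in range(2000):
            state = step(state, params)
        assert np.linalg.norm(state.v) == pytest.approx(params.vt, rel=0.01)

    def test_speed_approaches_terminal_monotonically(self):
        params = AgentParams(a_forw=0, a_dors=0, k1=0, k2=0, k3=0,
                             variant="light_off")
        # from rest and from a fast dive: no spontaneous energy gain
        for v0 in (0.0, 10.0):
            state = initial_state(params, [0, 0, 0], 0.0, speed=0.0)
            state.v = np.array([0.0, 0.0, -v0])
            speeds = []
            for _ in range(1000):
                state = step(state, params)
                speeds.append(np.linalg.norm(state.v))
            diffs = np.diff(speeds)
            assert np.all(diffs >= -1e-12) if v0 < params.vt else \
                np.all(diffs <= 1e-12)


class TestSteering:
    def test_zero_error_zero_rotation(self):
        params = AgentParams(**MOTIF_PARAMS)
        # dorsal toward the light and vertical, forward along velocity:
        # put the agent below the light so LOS == vertical == dorsal
        state = initial_state(params, [0, 0, -1.0], 0.0)
        omega = steering_rotation(state, params)
        assert np.linalg.norm(omega) == pytest.approx(0.0, abs=1e-12)

    def test_k2_only_rotation_magnitude(self):
        params = AgentParams(k1=0, k2=1.0, k3=0, dt=0.01, variant="light_off")
        state = initial_state(params, [0, 0, 0], 0.0)
        tilt = 0.1
        R = np.array([[1, 0, 0],
                      [0, math.cos(tilt), -math.sin(tilt)],
                      [0, math.sin(tilt), math.cos(tilt)]], float)
        state.R = R @ state.R
        omega = steering_rotation(state, params)
        # k * theta * dt = 1.0 * 0.1 * 0.01 = 0.001 rad this step
        assert np.linalg.norm(omega) * params.dt == pytest.approx(0.001,
                                                                  rel=1e-9)

    def test_antiparallel_target_uses_fallback_axis(self):
        params = AgentParams(k1=0, k2=5.0, k3=0, variant="light_off")
        state = initial_state(params, [0, 0, 0], 0.0, speed=0.0)
        state.R = np.diag([1.0, -1.0, -1.0])  # fully inverted
        omega = steering_rotation(state, params)
        assert np.isfinite(omega).all()
        assert np.linalg.norm(omega) == pytest.approx(5.0 * math.pi, rel=1e-9)
        for _ in range(500):
            state = step(state, params)
        assert state.R[2, 2] > 0.99  # righted itself

    def test_steering_errors_ranges(self):
        params = AgentParams(**MOTIF_PARAMS)
        state = initial_state(params, [1.0, 2.0, -0.5], 30.0)
        theta, gamma, beta = steering_errors(state, params)
        for e in (theta, gamma, beta):
            assert 0.0 <= e <= math.pi

    def test_thrust_balancing_gravity_keeps_state(self):
        params = AgentParams(k1=0, k2=0, k3=0, a_forw=0.0, a_dors=9.81,
                             variant="light_off")
        state = initial_state(params, [1, 1, 1], 0.0, speed=0.0)
        nxt = step(state, params)
        assert np.allclose(nxt.p, state.p)
        assert np.allclose(nxt.v, 0.0)

    def test_level_cruise_speed_limit(self):
        # body held level (no gains), dorsal thrust balancing gravity:
        # forward speed converges to sqrt(a_forw / c)
        params = AgentParams(k1=0, k2=0, k3=0, a_forw=5.0, a_dors=9.81,
                             variant="light_off")
        state = initial_state(params, [0, 0, 0], 0.0, speed=0.0)
        for _ in range(3000):
            state = step(state, params)
        expect = math.sqrt(params.a_forw / params.c)
        assert np.linalg.norm(state.v) == pytest.approx(expect, rel=0.01)

    def test_triad_stays_orthonormal(self):
        params = AgentParams(**MOTIF_PARAMS)
        state = initial_state(params, [1, 0, 0], 90.0)
        for _ in range(500):
            state = step(state, params)
            R = state.R
            assert np.allclose(R.T @ R, np.eye(3), atol=1e-9)


class TestMotifRuns:
    def test_orbit_entry(self):
        traj = run(AgentParams(**MOTIF_PARAMS), [1.0, 0, 0], 90.0, 5.0)
        assert classify_motif(traj) == {"orbit"}
        r = np.linalg.norm(traj.p - traj.light_position, axis=1)
        assert r.max() < 3.0  # bounded range, never escapes
        # sustained speed over the last 2 s
        assert traj.speed()[300:].min() > 1.0

    def test_stall_entry(self):
        traj = run(AgentParams(**MOTIF_PARAMS), [2.0, 0, -1.0], 0.0, 1.5,
                   initial_speed=5.0)
        motifs = classify_motif(traj)
        assert "stall" in motifs
        assert "orbit" not in motifs

    def test_invert_entry(self):
        traj = run(AgentParams(**MOTIF_PARAMS), [0.0, 0, 1.0], 0.0, 2.0)
        motifs = classify_motif(traj)
        assert motifs == {"invert"}
        # inversion is followed by an accelerating dive
        s = traj.speed()
        assert traj.p[-1, 2] < traj.p[0, 2]
        assert s[-1] > s[0]

    def test_dt_refinement_stability(self):
        base = run(AgentParams(**MOTIF_PARAMS), [1.0, 0, 0], 90.0, 5.0)
        fine_params = dict(MOTIF_PARAMS, dt=0.005)
        fine = run(AgentParams(**fine_params), [1.0, 0, 0], 90.0, 5.0)
        r0 = np.linalg.norm(base.p[-1] - base.light_position)
        r1 = np.linalg.norm(fine.p[-1] - fine.light_position)
        assert abs(r1 - r0) / max(r0, 1e-9) < 0.05


class TestVariants:
    def test_light_off_equals_dlr_with_zero_gain(self):
        a = run(AgentParams(**dict(MOTIF_PARAMS, k1=0.0)), [1, 0, 0], 90.0,
                2.0)
        b = run(AgentParams(**MOTIF_PARAMS, variant="light_off"), [1, 0, 0],
                90.0, 2.0)
        assert np.array_equal(a.p, b.p)
        assert np.array_equal(a.dorsal, b.dorsal)

    def test_compass_with_dorsal_reference_equals_dlr(self):
        params_d = AgentParams(**MOTIF_PARAMS)
        params_c = AgentParams(**MOTIF_PARAMS, variant="compass")
        sd = initial_state(params_d, [2, 1, 0.5], 30.0)
        sc = initial_state(params_c, [2, 1, 0.5], 30.0)
        sc.ref_body = np.array([0.0, 0.0, 1.0])
        for _ in range(300):
            sd = step(sd, params_d)
            sc = step(sc, params_c)
        assert np.array_equal(sd.p, sc.p)

    def test_compass_zero_correction_at_reference(self):
        params = AgentParams(**MOTIF_PARAMS, variant="compass")
        state = initial_state(params, [3.0, 0, 0], 90.0)
        # reference was just stored from the current geometry; isolate
        # controller 1 by zeroing the others
        params2 = AgentParams(**dict(MOTIF_PARAMS, k2=0.0, k3=0.0),
                              variant="compass")
        state.v = np.zeros(3)
        omega = steering_rotation(state, params2)
        assert np.linalg.norm(omega) == pytest.approx(0.0, abs=1e-12)

    def test_compass_cannot_start_at_light(self):
        params = AgentParams(**MOTIF_PARAMS, variant="compass")
        with pytest.raises(ConfigurationError):
            initial_state(params, [0, 0, 0], 0.0)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ConfigurationError):
            AgentParams(variant="strobe")


class TestRandomSweep:
    def test_reproducible_and_sized(self):
        a = random_sweep(n=20, duration=5.0, variant="dlr", seed=123)
        b = random_sweep(n=20, duration=5.0, variant="dlr", seed=123)
        assert len(a.range_rates) == 20
        assert np.array_equal(a.range_rates, b.range_rates)
        assert a.median_range_rate == b.median_range_rate

    def test_parameters_within_documented_ranges(self):
        res = random_sweep(n=20, duration=5.0, variant="dlr", seed=5)
        for p in res.params:
            assert 0.0 <= p.k1 <= 20.0
            assert 0.0 <= p.k2 <= 20.0
            assert p.k3 == 15.0
            assert 0.5 <= p.vt <= 10.5
            assert 0.0 <= p.a_forw <= 10.0
            assert 9.81 <= p.a_dors <= 24.81
            assert p.c == pytest.approx(9.81 / p.vt ** 2, abs=1e-9)
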
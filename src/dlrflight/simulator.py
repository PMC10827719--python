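"""Agent-based flight model of light entrapment via the dorsal light response.

The agent is a point body with an orthonormal triad (forward b_x, left b_y,
dorsal b_z). Three proportional steering controllers each command an angular
speed equal to a gain times an angular error:

* controller 1 (gain ``k1``, 1/s): rotates the dorsal axis toward the
  line of sight (LOS) to the light — the dorsal light response. In the
  ``compass`` variant it instead holds the LOS at a fixed egocentric
  direction recorded at t = 0 (a corrupted celestial compass); in the
  ``light_off`` variant it is disabled.
* controller 2 (gain ``k2``): rotates the dorsal axis toward true
  vertical, standing in for passive/active righting.
* controller 3 (gain ``k3``): rotates the forward axis toward the
  velocity vector (weathercocking).

Per step, the three angular-velocity vectors are summed and applied as a
single axis-angle rotation of the triad, after which the triad is
re-orthonormalised. Translational dynamics combine a body-fixed thrust
``a_forw * b_x + a_dors * b_z``, gravity, and quadratic drag with form
factor ``c = g / vt**2`` (``vt`` the terminal velocity in free fall):

    a_net(t) = g - v_hat(t-1) * c * |v(t-1)|^2 + a_b(t)
    v(t) = v(t-1) + a_net(t) * dt
    p(t) = p(t-1) + v(t) * dt        (semi-implicit Euler)

No aerodynamic realism beyond this is attempted; the model is a minimal
guidance abstraction. The light source sits at ``params.light_position``
(default the origin); there is no ground plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigurationError
from .frames import G_MAG, GRAVITY, Trajectory
from .metrics import range_change_rate
from .circstats import wilcoxon_signed_rank

VARIANTS = ("dlr", "light_off", "compass")

_Z = np.array([0.0, 0.0, 1.0])


@dataclass
class AgentParams:
    """Simulation parameters.

    Gains ``k1``..``k3`` in 1/s, terminal velocity ``vt`` in m/s, thrust
    components ``a_forw``/``a_dors`` in m/s^2, time step ``dt`` in s. The
    drag form factor ``c`` is derived, never set: c = g / vt**2 (1/m; it
    multiplies |v|^2 to give a deceleration).
    """

    k1: float = 15.0
    k2: float = 1.0
    k3: float = 15.0
    vt: float = 3.5
    a_forw: float = 5.0
    a_dors: float = 15.0
    dt: float = 0.01
    variant: str = "dlr"
    light_position: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigurationError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.vt <= 0:
            raise ConfigurationError("terminal velocity vt must be > 0")
        if self.dt <= 0:
            raise ConfigurationError("time step dt must be > 0")
        if min(self.k1, self.k2, self.k3) < 0:
            raise ConfigurationError("gains must be >= 0")
        self.light_position = np.asarray(self.light_position, dtype=float)

    @property
    def c(self) -> float:
        """Quadratic-drag form factor g / vt**2."""
        return G_MAG / self.vt ** 2


@dataclass
class AgentState:
    """Evolving simulation state: position, velocity and body triad.

    ``R`` has columns (b_x, b_y, b_z) = (forward, left, dorsal).
    ``ref_body`` is the stored egocentric LOS direction (body coordinates)
    used by the compass variant; None otherwise.
    """

    p: np.ndarray
    v: np.ndarray
    R: np.ndarray
    ref_body: Optional[np.ndarray] = None


def _orthonormalize(R: np.ndarray) -> np.ndarray:
    """Gram-Schmidt on the columns, preserving b_x then b_y."""
    bx = R[:, 0]
    bx = bx / np.linalg.norm(bx)
    by = R[:, 1] - bx * (bx @ R[:, 1])
    by = by / np.linalg.norm(by)
    bz = np.cross(bx, by)
    return np.column_stack([bx, by, bz])


def _rodrigues(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix for a unit axis and angle (Rodrigues formula)."""
    x, y, z = axis
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + math.sin(angle) * K + (1.0 - math.cos(angle)) * (K @ K)


def _controller_omega(current: np.ndarray, target: np.ndarray, gain: float,
                      fallback_axis: np.ndarray) -> np.ndarray:
    """Angular velocity k * theta * u_hat rotating ``current`` toward
    ``target`` (both unit vectors); ``fallback_axis`` disambiguates the
    antiparallel case deterministically."""
    c = float(np.clip(current @ target, -1.0, 1.0))
    theta = math.acos(c)
    if theta < 1e-12 or gain == 0.0:
        return np.zeros(3)
    axis = np.cross(current, target)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        # antiparallel: any axis perpendicular to `current` works; use the
        # supplied body axis for determinism
        axis = fallback_axis - current * (current @ fallback_axis)
        norm = np.linalg.norm(axis)
        if norm < 1e-12:
            return np.zeros(3)
    return (gain * theta / norm) * axis


def steering_errors(state: AgentState, params: AgentParams):
    """The three angular errors (theta, gamma, beta) in radians.

    theta: dorsal axis (or compass reference) vs LOS to the light;
    gamma: dorsal axis vs vertical; beta: forward axis vs velocity.
    Errors that are undefined at this state (agent at the light, zero
    velocity) are returned as nan.
    """
    bx, _, bz = state.R[:, 0], state.R[:, 1], state.R[:, 2]
    los = params.light_position - state.p
    rng = np.linalg.norm(los)
    if rng < 1e-12:
        theta = math.nan
    else:
        los = los / rng
        cur = state.R @ state.ref_body if params.variant == "compass" else bz
        theta = math.acos(float(np.clip(cur @ los, -1.0, 1.0)))
    gamma = math.acos(float(np.clip(bz @ _Z, -1.0, 1.0)))
    sp = np.linalg.norm(state.v)
    beta = math.nan if sp < 1e-12 else math.acos(
        float(np.clip(bx @ (state.v / sp), -1.0, 1.0)))
    return theta, gamma, beta


def steering_rotation(state: AgentState, params: AgentParams) -> np.ndarray:
    """Summed angular-velocity command (rad/s, world frame) for one step."""
    bx, by, bz = state.R[:, 0], state.R[:, 1], state.R[:, 2]
    omega = np.zeros(3)

    if params.variant != "light_off":
        los = params.light_position - state.p
        rng = np.linalg.norm(los)
        if rng > 1e-12:
            los = los / rng
            if params.variant == "compass":
                # hold the LOS at the stored egocentric direction: rotate the
                # world image of the reference onto the current LOS
                current = state.R @ state.ref_body
            else:
                current = bz
            omega += _controller_omega(current, los, params.k1, bx)

    omega += _controller_omega(bz, _Z, params.k2, bx)

    sp = np.linalg.norm(state.v)
    if sp > 1e-12:
        omega += _controller_omega(bx, state.v / sp, params.k3, by)
    return omega


def step(state: AgentState, params: AgentParams) -> AgentState:
    """Advance one time step: rotate the triad, then integrate dynamics."""
    omega = steering_rotation(state, params)
    w = np.linalg.norm(omega)
    R = state.R
    if w > 0.0:
        R = _orthonormalize(_rodrigues(omega / w, w * params.dt) @ R)

    a_b = params.a_forw * R[:, 0] + params.a_dors * R[:, 2]
    sp = np.linalg.norm(state.v)
    drag = (params.c * sp) * state.v if sp > 0.0 else np.zeros(3)
    a_net = GRAVITY - drag + a_b
    v = state.v + a_net * params.dt
    p = state.p + v * params.dt
    return AgentState(p=p, v=v, R=R, ref_body=state.ref_body)


def initial_state(params: AgentParams, position, bearing_deg: float,
                  speed: float = 2.0) -> AgentState:
    """Upright agent at ``position`` moving horizontally at ``bearing_deg``
    (degrees, 0 = +x, counterclockwise) with the given speed."""
    b = math.radians(bearing_deg)
    bx = np.array([math.cos(b), math.sin(b), 0.0])
    by = np.cross(_Z, bx)
    R = np.column_stack([bx, by, _Z])
    p = np.asarray(position, dtype=float)
    state = AgentState(p=p, v=speed * bx, R=R)
    if params.variant == "compass":
        los = params.light_position - p
        rng = np.linalg.norm(los)
        if rng < 1e-12:
            raise ConfigurationError("compass variant cannot start at the light")
        state.ref_body = R.T @ (los / rng)
    return state


def run(params: AgentParams, initial_position, initial_bearing_deg: float,
        duration: float, initial_speed: float = 2.0) -> Trajectory:
    """Simulate for ``duration`` seconds and return the full 6-DoF track."""
    if duration <= 0:
        raise ConfigurationError("duration must be > 0")
    n_steps = int(round(duration / params.dt))
    state = initial_state(params, initial_position, initial_bearing_deg,
                          initial_speed)
    n = n_steps + 1
    t = np.arange(n) * params.dt
    p = np.empty((n, 3))
    fwd = np.empty((n, 3))
    left = np.empty((n, 3))
    dors = np.empty((n, 3))
    p[0], fwd[0], left[0], dors[0] = state.p, state.R[:, 0], state.R[:, 1], state.R[:, 2]
    for i in range(1, n):
        state = step(state, params)
        p[i], fwd[i], left[i], dors[i] = (state.p, state.R[:, 0],
                                          state.R[:, 1], state.R[:, 2])
    return Trajectory(
        t=t, p=p, rate=1.0 / params.dt, forward=fwd, left=left, dorsal=dors,
        light_position=params.light_position.copy(),
        meta={
            "source": "dlrflight.simulator",
            "variant": params.variant,
            "initial_speed_m_s": initial_speed,
            "initial_bearing_deg": initial_bearing_deg,
        },
    )


# ---------------------------------------------------------------------------
# batch experiments

# uniform draw ranges for the randomised-parameter experiment
SWEEP_RANGES = {
    "k1": (0.0, 20.0),
    "k2": (0.0, 20.0),
    "vt": (0.5, 10.5),
    "a_forw": (0.0, 10.0),
    "a_dors": (9.81, 24.81),
}
SWEEP_K3 = 15.0
SWEEP_START_HALFWIDTH = 5.0  # start cube: +/- 5 m of the light on each axis


@dataclass
class SweepResult:
    """Outcome of a random-parameter batch.

    ``range_rates`` holds each run's mean rate of change of distance to the
    light over its final window (m/s; negative = approach). ``signed_rank``
    is the (z, p) of a Wilcoxon signed-rank test of those rates against 0.
    """

    variant: str
    params: list
    range_rates: np.ndarray
    median_range_rate: float
    signed_rank: tuple
    trajectories: Optional[list] = None


def random_sweep(n: int = 300, duration: float = 5.0, variant: str = "dlr",
                 seed: int = 0, dt: float = 0.01, window: float = 3.0,
                 keep_trajectories: bool = False) -> SweepResult:
    """Run ``n`` simulations with parameters drawn uniformly from
    :data:`SWEEP_RANGES` (k3 fixed), start positions uniform in the cube
    about the light and random horizontal initial bearings."""
    if variant not in VARIANTS:
        raise ConfigurationError(f"unknown variant {variant!r}")
    rng = np.random.default_rng(seed)
    rates = np.empty(n)
    all_params = []
    trajs = [] if keep_trajectories else None
    h = SWEEP_START_HALFWIDTH
    for i in range(n):
        draws = {k: rng.uniform(lo, hi) for k, (lo, hi) in SWEEP_RANGES.items()}
        params = AgentParams(k1=draws["k1"], k2=draws["k2"], k3=SWEEP_K3,
                             vt=draws["vt"], a_forw=draws["a_forw"],
                             a_dors=draws["a_dors"], dt=dt, variant=variant)
        start = rng.uniform(-h, h, size=3)
        if np.linalg.norm(start) < 1e-9:
            start = np.array([h / 2, 0.0, 0.0])  # compass needs a finite LOS
        bearing = rng.uniform(0.0, 360.0)
        traj = run(params, start, bearing, duration)
        rates[i] = range_change_rate(traj, window=window)
        all_params.append(params)
        if keep_trajectories:
            trajs.append(traj)
    z, pval = wilcoxon_signed_rank(rates)
    return SweepResult(variant=variant, params=all_params, range_rates=rates,
                       median_range_rate=float(np.median(rates)),
                       signed_rank=(z, pval), trajectories=trajs)
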
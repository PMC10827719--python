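"""Seeded generators for the behavioural motifs and marker observations.

Closed-form parametric trajectories emulate the motifs seen around point
lights — orbiting (circling the light, banked toward it), stalling
(a nose-up climb with exponentially decaying speed), inversion (a vertical
half-loop over the light, dorsum rolling below the horizon) — plus a level
straight cruise control. A separate stage converts any 6-DoF trajectory
into noisy L-frame marker triplets, with optional injected defects, so the
reconstruction and QC stages can be exercised without real capture data.

All randomness flows from the integer ``seed`` of the call; identical
inputs give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import List, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError
from .frames import MarkerTriplet, Trajectory

MOTIFS = ("orbit", "stall", "invert", "cruise")

DEFAULT_ARM_LENGTH = 0.004  # m; two 4 mm arms at 90 degrees


@dataclass
class SynthSpec:
    """Parameters of one synthetic trajectory.

    Geometry fields are motif-specific: ``orbit_radius``/``bank_deg`` for
    orbit, ``climb_angle_deg``/``decay_rate`` for stall, ``apex_height``
    for inversion; ``speed`` applies to all. ``noise_sd`` adds isotropic
    Gaussian position noise (0 = exact closed form). ``heading_deg`` sets
    the cruise direction / orbit entry phase; None draws it from the seed.
    """

    motif: str = "cruise"
    duration: float = 2.0
    rate: float = 100.0
    light_position: tuple = (0.0, 0.0, 0.0)
    speed: float = 2.0             # m/s
    orbit_radius: float = 0.5      # m
    bank_deg: float = 45.0         # bank toward the light, orbit only
    climb_angle_deg: float = 60.0  # stall climb above horizon
    decay_rate: float = 1.0        # 1/s, stall speed s0*exp(-lambda t)
    apex_height: float = 1.0      # m above the light, inversion loop
    start_offset: tuple | None = None  # m from the light (cruise/stall)
    heading_deg: float | None = None
    meander_amplitude_deg: float = 0.0  # cruise heading weave; 0 = straight
    noise_sd: float = 0.0          # m
    dropout_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.motif not in MOTIFS:
            raise ConfigurationError(
                f"unknown motif {self.motif!r}; expected one of {MOTIFS}")
        if self.rate <= 0 or self.duration <= 0:
            raise ConfigurationError("rate and duration must be > 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ConfigurationError("dropout_prob must be in [0, 1)")


def generate_motif(spec: SynthSpec) -> Trajectory:
    """Closed-form trajectory for one motif; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.rate)) + 1
    t = np.arange(n) / spec.rate
    light = np.asarray(spec.light_position, dtype=float)
    heading = (rng.uniform(0.0, 360.0) if spec.heading_deg is None
               else spec.heading_deg)

    if spec.motif == "orbit":
        p, fwd, left, dors = _orbit(spec, t, light, heading)
    elif spec.motif == "stall":
        p, fwd, left, dors = _stall(spec, t, light, heading, rng)
    elif spec.motif == "invert":
        p, fwd, left, dors = _invert(spec, t, light)
    else:
        p, fwd, left, dors = _cruise(spec, t, light, heading, rng)

    if spec.noise_sd > 0:
        p = p + rng.normal(0.0, spec.noise_sd, size=p.shape)

    return Trajectory(
        t=t, p=p, rate=spec.rate, forward=fwd, left=left, dorsal=dors,
        light_position=light,
        meta={"source": "dlrflight.synthetic", "motif": spec.motif,
              "spec": asdict(spec)},
    )


def _level_triad(heading_rad: np.ndarray):
    """Upright triad with forward at the given horizontal heading(s)."""
    c, s = np.cos(heading_rad), np.sin(heading_rad)
    zeros = np.zeros_like(c)
    ones = np.ones_like(c)
    fwd = np.stack([c, s, zeros], axis=-1)
    left = np.stack([-s, c, zeros], axis=-1)
    dors = np.stack([zeros, zeros, ones], axis=-1)
    return fwd, left, dors


def _orbit(spec: SynthSpec, t, light, phase_deg):
    """Counterclockwise circle about the light at the light's height,
    banked toward the centre by ``bank_deg``."""
    r = spec.orbit_radius
    if r <= 0:
        raise ConfigurationError("orbit_radius must be > 0")
    w = spec.speed / r                      # rad/s
    ang = math.radians(phase_deg) + w * t
    c, s = np.cos(ang), np.sin(ang)
    p = light[None, :] + r * np.stack([c, s, np.zeros_like(c)], axis=-1)
    fwd, left0, _ = _level_triad(ang + math.pi / 2)  # tangent, CCW
    # level 'left' already points at the centre; roll toward it by the bank
    phi = math.radians(spec.bank_deg)
    up = np.array([0.0, 0.0, 1.0])[None, :]
    left = math.cos(phi) * left0 - math.sin(phi) * up
    dors = math.cos(phi) * up + math.sin(phi) * left0
    return p, fwd, np.broadcast_to(left, fwd.shape).copy(), \
        np.broadcast_to(dors, fwd.shape).copy()


def _stall(spec: SynthSpec, t, light, heading_deg, rng):
    """Straight nose-up climb, speed s0 * exp(-lambda t), attitude fixed
    along the climb direction."""
    lam = spec.decay_rate
    if lam <= 0:
        raise ConfigurationError("decay_rate must be > 0")
    alpha = math.radians(spec.climb_angle_deg)
    h = math.radians(heading_deg)
    d = np.array([math.cos(alpha) * math.cos(h),
                  math.cos(alpha) * math.sin(h),
                  math.sin(alpha)])
    start = (np.asarray(spec.start_offset, dtype=float)
             if spec.start_offset is not None
             else np.array([0.5 * math.cos(h + math.pi),
                            0.5 * math.sin(h + math.pi), 0.0]))
    dist = spec.speed / lam * (1.0 - np.exp(-lam * t))
    p = light[None, :] + start[None, :] + dist[:, None] * d[None, :]
    fwd = np.broadcast_to(d, (len(t), 3)).copy()
    left_h = np.cross([0.0, 0.0, 1.0], d)
    left_h = left_h / np.linalg.norm(left_h)
    left = np.broadcast_to(left_h, (len(t), 3)).copy()
    dors = np.cross(fwd, left)
    return p, fwd, left, dors


def _invert(spec: SynthSpec, t, light):
    """Vertical half-loop above the light: climb, over the top (fully
    inverted at the apex), then dive. The dorsal axis points at the loop
    centre, so its z-component is negative throughout the interior."""
    if spec.apex_height <= 0:
        raise ConfigurationError("apex_height must be > 0")
    rho = spec.apex_height / 2.0
    centre = light + np.array([0.0, 0.0, rho])
    theta = math.pi - (math.pi / spec.duration) * t  # pi -> 0 over the run
    c, s = np.cos(theta), np.sin(theta)
    p = centre[None, :] + rho * np.stack([c, np.zeros_like(c), s], axis=-1)
    fwd = np.stack([s, np.zeros_like(s), -c], axis=-1)   # tangent of motion
    left = np.broadcast_to([0.0, -1.0, 0.0], fwd.shape).copy()
    dors = np.cross(fwd, left)                            # centripetal
    return p, fwd, left, dors


def _cruise(spec: SynthSpec, t, light, heading_deg, rng):
    """Level straight flight at constant speed — the no-light control.

    By default the *midpoint* of the segment is placed at a seeded random
    offset from the light with a random heading, emulating an insect
    passing through the vicinity rather than departing from the light.
    ``meander_amplitude_deg`` superimposes a smooth heading weave
    (sinusoidal, frequency and phase drawn from the seed) of that
    amplitude, the way undisturbed searching flight wanders; 0 keeps the
    path perfectly straight and level.
    """
    h0 = math.radians(heading_deg)
    amp = math.radians(spec.meander_amplitude_deg)
    if amp > 0.0:
        freq = rng.uniform(0.3, 0.8)     # Hz, slow casting-style weave
        phase = rng.uniform(0.0, 2 * math.pi)
        heading = h0 + amp * np.sin(2 * math.pi * freq * t + phase)
        step = np.stack([np.cos(heading), np.sin(heading),
                         np.zeros_like(t)], axis=-1)
        rel = np.zeros_like(step)
        dt = 1.0 / spec.rate
        # trapezoid quadrature of the exact heading law
        rel[1:] = np.cumsum(0.5 * spec.speed * dt * (step[1:] + step[:-1]),
                            axis=0)
    else:
        heading = np.full(len(t), h0)
        d = np.array([math.cos(h0), math.sin(h0), 0.0])
        rel = (spec.speed * t)[:, None] * d[None, :]
    if spec.start_offset is not None:
        start = np.asarray(spec.start_offset, dtype=float)
    else:
        ang = rng.uniform(0.0, 2 * math.pi)
        rad = rng.uniform(0.5, 2.0)
        mid = np.array([rad * math.cos(ang), rad * math.sin(ang), 0.0])
        start = mid - 0.5 * (rel[0] + rel[-1])
    p = light[None, :] + start[None, :] + rel
    fwd, left, dors = _level_triad(heading)
    return p, fwd, left, dors


def cruise_control_batch(n: int = 56, seed: int = 0, duration: float = 3.0,
                         rate: float = 100.0,
                         meander_amplitude_deg: float = 180.0,
                         light_position=(0.0, 0.0, 0.0)) -> List[Trajectory]:
    """A batch of no-light control tracks: weaving level cruises.

    Emulates undisturbed flight recorded around a switched-off light: each
    track is a level constant-speed cruise whose heading weaves smoothly
    (amplitude ``meander_amplitude_deg``), placed at a random offset from
    the light position. Per-track seeds derive from ``seed`` via a
    SeedSequence, so batches with different master seeds are independent.
    """
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(n)
    return [
        generate_motif(SynthSpec(
            motif="cruise", duration=duration, rate=rate,
            light_position=tuple(light_position),
            meander_amplitude_deg=meander_amplitude_deg, seed=int(s)))
        for s in child
    ]


# ---------------------------------------------------------------------------
# marker observation model

def markers_from_trajectory(traj: Trajectory,
                            arm_length: float = DEFAULT_ARM_LENGTH,
                            noise_sd: float = 0.0,
                            dropout_prob: float = 0.0,
                            seed: int = 0) -> List[MarkerTriplet]:
    """Simulate L-frame marker observations of a 6-DoF trajectory.

    Markers sit at the body origin and at ``arm_length`` along the forward
    and left axes; each coordinate gets iid Gaussian noise of SD
    ``noise_sd``; each sample is independently dropped (flagged invalid,
    positions nan) with probability ``dropout_prob``.
    """
    if arm_length <= 0:
        raise ConfigurationError("arm_length must be > 0")
    if not traj.has_orientation:
        raise ConfigurationError("trajectory has no orientation data")
    if not 0.0 <= dropout_prob < 1.0:
        raise ConfigurationError("dropout_prob must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = len(traj)
    origins = traj.p
    f_tips = traj.p + arm_length * traj.forward
    l_tips = traj.p + arm_length * traj.left
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=(n, 3, 3))
        origins = origins + noise[:, 0]
        f_tips = f_tips + noise[:, 1]
        l_tips = l_tips + noise[:, 2]
    dropped = rng.random(n) < dropout_prob if dropout_prob > 0 else \
        np.zeros(n, dtype=bool)
    out = []
    nan3 = np.full(3, np.nan)
    for i in range(n):
        if dropped[i]:
            out.append(MarkerTriplet(t=float(traj.t[i]), m_origin=nan3.copy(),
                                     m_forward_tip=nan3.copy(),
                                     m_left_tip=nan3.copy(), valid=False))
        else:
            out.append(MarkerTriplet(t=float(traj.t[i]),
                                     m_origin=origins[i].copy(),
                                     m_forward_tip=f_tips[i].copy(),
                                     m_left_tip=l_tips[i].copy(), valid=True))
    return out


def corrupt_markers(markers: Sequence[MarkerTriplet], fraction: float,
                    mode: str, magnitude: float,
                    seed: int = 0) -> Tuple[List[MarkerTriplet], np.ndarray]:
    """Inject exact defects into round(fraction * n) valid samples.

    ``mode='arm_length'``: lengthen the forward arm by ``magnitude``
    metres. ``mode='arm_angle'``: rotate the left arm about the dorsal
    axis by ``magnitude`` degrees, changing the inter-arm angle by exactly
    that amount. Returns (new sequence, sorted corrupted indices).
    """
    if mode not in ("arm_length", "arm_angle"):
        raise ConfigurationError(f"unknown corruption mode {mode!r}")
    if not 0.0 <= fraction <= 1.0:
        raise ConfigurationError("fraction must be in [0, 1]")
    if magnitude <= 0:
        raise ConfigurationError("magnitude must be > 0")
    rng = np.random.default_rng(seed)
    valid_idx = np.array([i for i, m in enumerate(markers) if m.valid])
    k = int(round(fraction * len(markers)))
    if k > len(valid_idx):
        raise ConfigurationError("not enough valid samples to corrupt")
    chosen = np.sort(rng.choice(valid_idx, size=k, replace=False)) if k else \
        np.array([], dtype=int)
    chosen_set = set(chosen.tolist())
    out = []
    for i, m in enumerate(markers):
        if i not in chosen_set:
            out.append(m)
            continue
        a1 = m.m_forward_tip - m.m_origin
        a2 = m.m_left_tip - m.m_origin
        if mode == "arm_length":
            u = a1 / np.linalg.norm(a1)
            new_f = m.m_origin + a1 + magnitude * u
            out.append(MarkerTriplet(t=m.t, m_origin=m.m_origin.copy(),
                                     m_forward_tip=new_f,
                                     m_left_tip=m.m_left_tip.copy(),
                                     valid=True))
        else:
            axis = np.cross(a1, a2)
            axis = axis / np.linalg.norm(axis)
            ang = math.radians(magnitude)
            a2r = (a2 * math.cos(ang) + np.cross(axis, a2) * math.sin(ang)
                   + axis * (axis @ a2) * (1 - math.cos(ang)))
            out.append(MarkerTriplet(t=m.t, m_origin=m.m_origin.copy(),
                                     m_forward_tip=m.m_forward_tip.copy(),
                                     m_left_tip=m.m_origin + a2r, valid=True))
    return out, chosen
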
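"""Body-axis reconstruction from L-frame markers, and attitude metrics.

The marker frame is a rigid L: origin marker at the corner, one arm along
the body's forward axis, the other along its left axis. Orientation is
recovered by Gram-Schmidt on the two arms — exact for a rigid L, no
least-squares fit needed.

Angle conventions (degrees at the API surface):

* bank = |arcsin(left . z_hat)| in [0, 90]. This reflects across the
  horizontal plane, so a fully inverted body scores the same as an
  upright one.
* pitch = arccos(forward . z_hat) in [0, 180], measured from global
  vertical: 0 = nose straight up, 90 = level. ``pitch_from_horizontal``
  gives the complementary convention (90 - pitch).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .errors import EmptyResultError, InsufficientDataError
from .frames import GRAVITY, MarkerTriplet, Pose, Trajectory

_COLLINEAR_TOL = 1e-8


def reconstruct_orientation(m: MarkerTriplet) -> Pose:
    """Pose from one marker triplet.

    forward = unit(forward-tip - origin); left = unit component of
    (left-tip - origin) orthogonal to forward; dorsal = forward x left.
    Collinear (degenerate) markers yield an invalid 3-DoF pose rather
    than raising.
    """
    a1 = m.m_forward_tip - m.m_origin
    a2 = m.m_left_tip - m.m_origin
    n1 = np.linalg.norm(a1)
    if not m.valid or n1 < _COLLINEAR_TOL:
        return Pose(t=m.t, p=m.m_origin.copy(), dof="3dof", valid=False)
    fwd = a1 / n1
    left = a2 - fwd * (fwd @ a2)
    n2 = np.linalg.norm(left)
    if n2 < _COLLINEAR_TOL:
        return Pose(t=m.t, p=m.m_origin.copy(), dof="3dof", valid=False)
    left = left / n2
    return Pose(t=m.t, p=m.m_origin.copy(), forward=fwd, left=left,
                dorsal=np.cross(fwd, left), dof="6dof", valid=True)


def trajectory_from_markers(markers: Sequence[MarkerTriplet], rate: float,
                            light_position=None, meta=None) -> Trajectory:
    """Reconstruct a 6-DoF trajectory from marker triplets.

    Triplets that are invalid or degenerate are dropped (their samples do
    not appear in the output).
    """
    poses = [reconstruct_orientation(m) for m in markers]
    poses = [p for p in poses if p.valid and p.dof == "6dof"]
    if not poses:
        raise EmptyResultError("no valid marker triplets to reconstruct")
    return Trajectory(
        t=np.array([p.t for p in poses]),
        p=np.array([p.p for p in poses]),
        rate=rate,
        forward=np.array([p.forward for p in poses]),
        left=np.array([p.left for p in poses]),
        dorsal=np.array([p.dorsal for p in poses]),
        light_position=light_position,
        meta=dict(meta or {}),
    )


def bank_angle(pose: Pose) -> float:
    """Unsigned bank in degrees, [0, 90]; nan for a 3-DoF pose."""
    if pose.dof != "6dof":
        return math.nan
    return abs(math.degrees(math.asin(float(np.clip(pose.left[2], -1, 1)))))


def pitch_angle(pose: Pose) -> float:
    """Pitch from global vertical in degrees, [0, 180]; nan for 3-DoF."""
    if pose.dof != "6dof":
        return math.nan
    return math.degrees(math.acos(float(np.clip(pose.forward[2], -1, 1))))


def pitch_from_horizontal(pose: Pose) -> float:
    """Complementary pitch convention: elevation of the forward axis
    above the horizon, degrees in [-90, 90]."""
    return 90.0 - pitch_angle(pose)


def bank_angles(traj: Trajectory) -> np.ndarray:
    """Vectorised :func:`bank_angle` over a 6-DoF trajectory."""
    if not traj.has_orientation:
        raise InsufficientDataError("trajectory has no orientation data")
    return np.abs(np.degrees(np.arcsin(np.clip(traj.left[:, 2], -1, 1))))


def pitch_angles(traj: Trajectory) -> np.ndarray:
    if not traj.has_orientation:
        raise InsufficientDataError("trajectory has no orientation data")
    return np.degrees(np.arccos(np.clip(traj.forward[:, 2], -1, 1)))


def dorsal_tilt_index(traj: Trajectory):
    """Per-frame dorsal tilting index and its mean.

    Each frame's dorsal axis and line of sight to the light are projected
    onto the ground plane and normalised; the index is their dot product:
    1 = dorsum tilted straight at the light, -1 = straight away. Frames
    whose projected dorsal axis is numerically zero (body exactly level
    or exactly inverted) are excluded.

    Returns (per_frame_values, mean); raises EmptyResultError if no frame
    qualifies.
    """
    if traj.light_position is None:
        raise ValueError("trajectory has no light position")
    if not traj.has_orientation:
        raise InsufficientDataError("trajectory has no orientation data")
    dh = traj.dorsal[:, :2]
    lh = (traj.light_position[None, :] - traj.p)[:, :2]
    nd = np.linalg.norm(dh, axis=1)
    nl = np.linalg.norm(lh, axis=1)
    ok = (nd > 1e-8) & (nl > 1e-8) & traj.valid
    if not np.any(ok):
        raise EmptyResultError("no frames with a usable projected dorsal axis")
    vals = np.einsum("ij,ij->i", dh[ok], lh[ok]) / (nd[ok] * nl[ok])
    return vals, float(vals.mean())


def aero_acceleration_body(traj: Trajectory) -> np.ndarray:
    """Net aerodynamic acceleration in body coordinates, (n, 3) m/s^2.

    a_aero(t) = d^2 p / dt^2 - g (central differences), expressed on the
    (forward, left, dorsal) axes. For level hover this is (0, 0, +9.81):
    the wings support the body's weight dorsally.
    """
    if len(traj) < 3:
        raise InsufficientDataError("need >= 3 samples for acceleration")
    if not traj.has_orientation:
        raise InsufficientDataError("trajectory has no orientation data")
    a_world = traj.acceleration() - GRAVITY[None, :]
    out = np.empty_like(a_world)
    out[:, 0] = np.einsum("ij,ij->i", a_world, traj.forward)
    out[:, 1] = np.einsum("ij,ij->i", a_world, traj.left)
    out[:, 2] = np.einsum("ij,ij->i", a_world, traj.dorsal)
    return out
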
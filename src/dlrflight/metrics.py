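"""Trajectory-level flight metrics relative to a point light source.

Sign conventions (viewed from above, world z up):

* heading = atan2(v_y, v_x); a *rightward* (clockwise-from-above) turn is
  a decreasing heading, and ``turn_rate`` is reported positive rightward.
* ``bearing_to_light`` is the signed ground-plane angle from the
  line-of-sight (LOS) to the light to the horizontal velocity: 0 = flying
  straight at the light, +/-90 = orthogonal. Positive bearing means the
  velocity is rotated counterclockwise from the LOS, i.e. the light lies
  on the agent's right.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (ConfigurationError, DegeneratePathError,
                     EmptyResultError, InsufficientDataError)
from .frames import Trajectory

_H_SPEED_EPS = 1e-6   # m/s; below this horizontal bearing is undefined
_DISPLACEMENT_EPS = 1e-3  # m; tortuosity undefined for closed loops


def tortuosity(traj: Trajectory) -> float:
    """Total path length divided by straight-line displacement (>= 1)."""
    if len(traj) < 2:
        raise InsufficientDataError("tortuosity needs >= 2 samples")
    seg = np.diff(traj.p, axis=0)
    path = float(np.linalg.norm(seg, axis=1).sum())
    disp = float(np.linalg.norm(traj.p[-1] - traj.p[0]))
    if disp <= _DISPLACEMENT_EPS:
        raise DegeneratePathError(
            f"net displacement {disp:.2g} m too small for tortuosity")
    return path / disp


def light_relative_series(traj: Trajectory) -> pd.DataFrame:
    """Per-sample geometry relative to the light.

    Returns a DataFrame with columns ``t``, ``bearing_deg`` (signed,
    (-180, 180]), ``light_side`` ('left'/'right'), ``turn_rate_deg_s``
    (positive rightward) and ``range_m``. Samples whose horizontal speed
    is below a small threshold (vertical-only motion) are skipped.
    """
    if traj.light_position is None:
        raise ConfigurationError("trajectory has no light position")
    if len(traj) < 2:
        raise InsufficientDataError("need >= 2 samples")
    v = traj.velocity()
    los = traj.light_position[None, :] - traj.p
    rng = np.linalg.norm(los, axis=1)

    vh = v[:, :2]
    lh = los[:, :2]
    h_speed = np.linalg.norm(vh, axis=1)
    ok = (h_speed > _H_SPEED_EPS) & (np.linalg.norm(lh, axis=1) > 1e-12)

    heading = np.unwrap(np.arctan2(v[:, 1], v[:, 0]))
    turn = -np.degrees(np.gradient(heading, traj.t))  # positive rightward

    cross = lh[:, 0] * vh[:, 1] - lh[:, 1] * vh[:, 0]
    dot = np.einsum("ij,ij->i", lh, vh)
    bearing = np.degrees(np.arctan2(cross, dot))

    return pd.DataFrame({
        "t": traj.t[ok],
        "bearing_deg": bearing[ok],
        "light_side": np.where(bearing[ok] > 0, "right", "left"),
        "turn_rate_deg_s": turn[ok],
        "range_m": rng[ok],
    })


def turn_bias_table(frames: pd.DataFrame, window: float = 30.0) -> np.ndarray:
    """2x2 counts of light side vs turning direction near orthogonality.

    Only frames whose |bearing| is within ``window`` degrees of 90 are
    counted; zero-turn-rate frames are dropped. Layout::

        rows:    light left, light right
        columns: turning left, turning right

    Raises EmptyResultError when no frame qualifies.
    """
    sel = frames[(np.abs(np.abs(frames["bearing_deg"]) - 90.0) < window)
                 & (frames["turn_rate_deg_s"] != 0.0)]
    if len(sel) == 0:
        raise EmptyResultError("no frames near orthogonality")
    table = np.zeros((2, 2), dtype=int)
    for i, side in enumerate(("left", "right")):
        on_side = sel[sel["light_side"] == side]
        table[i, 0] = int((on_side["turn_rate_deg_s"] < 0).sum())
        table[i, 1] = int((on_side["turn_rate_deg_s"] > 0).sum())
    return table


def range_change_rate(traj: Trajectory, window: float = 3.0) -> float:
    """Mean d(range-to-light)/dt over the final ``window`` seconds:
    (range at end - range at end-window) / window. Negative = approach."""
    if traj.light_position is None:
        raise ConfigurationError("trajectory has no light position")
    if traj.duration < window - 1e-9:
        raise InsufficientDataError(
            f"trajectory shorter ({traj.duration:.3g} s) than window {window} s")
    rng = np.linalg.norm(traj.p - traj.light_position[None, :], axis=1)
    t_start = traj.t[-1] - window
    i0 = int(np.argmin(np.abs(traj.t - t_start)))
    dt = traj.t[-1] - traj.t[i0]
    return float((rng[-1] - rng[i0]) / dt)


@dataclass
class MotifThresholds:
    """Heuristic decision thresholds for motif classification.

    The field classification behind these labels was qualitative; the
    defaults below operationalise it and are deliberately configurable.
    """

    orbit_min_heading_change_deg: float = 180.0
    orbit_max_range_cv: float = 0.3
    orbit_min_mean_speed: float = 0.3      # m/s
    orbit_max_step_turn_deg: float = 30.0  # larger per-sample jumps are
                                           # velocity reversals, not turning
    stall_speed_fraction: float = 0.5      # decay below this x local max
    stall_min_forward_z: float = 0.2       # mean nose-up during the decay
    stall_min_climb: float = 0.1           # net z gain over the decay, m
    invert_min_duration: float = 0.05      # s of sustained dorsal-down


def classify_motif(traj: Trajectory,
                   thresholds: MotifThresholds | None = None) -> set:
    """Label a trajectory with any subset of {'orbit', 'stall', 'invert'}.

    * orbit: cumulative unsigned heading change past half a turn while the
      range to the light stays nearly constant and flight speed is kept.
    * stall: a climbing phase (local speed maximum to the following
      trough) whose speed collapses below a fraction of the local maximum
      while pitched nose-up, with no inversion inside that phase.
    * invert: the dorsal axis points below the horizon for a sustained span.

    Motifs can co-occur — a flight may stall and then invert, as insects
    near lights are seen to do. Orbit requires a light position;
    stall/invert require orientation data for the pitch/dorsal conditions.
    """
    th = thresholds or MotifThresholds()
    if traj.duration < 1.0:
        raise InsufficientDataError("need >= 1 s of data to classify")
    motifs: set = set()
    v = traj.velocity()
    speed = np.linalg.norm(v, axis=1)

    inverted_span = 0.0
    if traj.has_orientation:
        inverted_span = _longest_true_span(traj.dorsal[:, 2] < 0.0, traj.t)
        if inverted_span >= th.invert_min_duration:
            motifs.add("invert")

    if traj.light_position is not None:
        hv = v[:, :2]
        ok = np.linalg.norm(hv, axis=1) > _H_SPEED_EPS
        if ok.sum() >= 2:
            heading = np.unwrap(np.arctan2(hv[ok, 1], hv[ok, 0]))
            dh = np.degrees(np.abs(np.diff(heading)))
            # sum only smooth turning; a near-180 jump in one sample is a
            # velocity reversal passing through zero horizontal speed
            total_turn = dh[dh < th.orbit_max_step_turn_deg].sum()
            rng = np.linalg.norm(traj.p - traj.light_position[None, :], axis=1)
            cv = rng.std() / rng.mean() if rng.mean() > 0 else np.inf
            if (total_turn >= th.orbit_min_heading_change_deg
                    and cv < th.orbit_max_range_cv
                    and speed.mean() > th.orbit_min_mean_speed):
                motifs.add("orbit")

    if traj.has_orientation and _has_stall_phase(traj, speed, th):
        motifs.add("stall")
    return motifs


def _has_stall_phase(traj: Trajectory, speed: np.ndarray,
                     th: MotifThresholds) -> bool:
    """Scan speed peak->trough windows for a stalling climb.

    Troughs are local minima of the speed series (plus the final sample
    when the series ends while decaying); the matching peak is the speed
    maximum since the previous trough. A window qualifies when the trough
    speed falls below ``stall_speed_fraction`` of the peak, altitude is
    gained, the body is pitched nose-up on average, and the dorsal axis
    stays above the horizon throughout the window.
    """
    from scipy.signal import find_peaks

    inverted = traj.dorsal[:, 2] < 0.0
    troughs = list(find_peaks(-speed)[0])
    if len(speed) >= 2 and speed[-1] < speed[-2]:
        troughs.append(len(speed) - 1)
    prev = 0
    for j in troughs:
        i = prev + int(np.argmax(speed[prev:j + 1]))
        prev = j
        if j <= i:
            continue
        if speed[j] >= th.stall_speed_fraction * speed[i]:
            continue
        if traj.p[j, 2] - traj.p[i, 2] <= th.stall_min_climb:
            continue
        if traj.forward[i:j + 1, 2].mean() <= th.stall_min_forward_z:
            continue
        if inverted[i:j + 1].any():
            continue
        return True
    return False


def _longest_true_span(mask: np.ndarray, t: np.ndarray) -> float:
    """Duration of the longest contiguous run of True in ``mask``."""
    best = 0.0
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            best = max(best, float(t[j] - t[i]))
            i = j + 1
        else:
            i += 1
    return best
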
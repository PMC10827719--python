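"""Core containers: poses, trajectories and marker triplets.

Conventions
-----------
* World frame is right-handed with z up; gravity is (0, 0, -9.81) m/s^2.
* A body triad is the orthonormal set (forward, left, dorsal) with
  ``dorsal = forward x left`` (right-handed). ``forward`` points from
  posterior to anterior along the long body axis.
* All positions are metres, times seconds, rates samples/second.

A :class:`Trajectory` stores samples as contiguous arrays (one row per
sample) rather than a list of objects; :class:`Pose` is the single-sample
view used at API boundaries that operate frame by frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np

from .errors import DataError

GRAVITY = np.array([0.0, 0.0, -9.81])
G_MAG = 9.81

ORTHONORMAL_TOL = 1e-6


def _as_vec3(x) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"expected 3-vector, got shape {v.shape}")
    return v


@dataclass
class Pose:
    """One time sample of position and (optionally) body orientation.

    ``dof`` is '6dof' when the full triad is known, '3dof' when only the
    position is (axes are then None).
    """

    t: float
    p: np.ndarray
    forward: Optional[np.ndarray] = None
    left: Optional[np.ndarray] = None
    dorsal: Optional[np.ndarray] = None
    dof: str = "6dof"
    valid: bool = True

    def triad(self) -> np.ndarray:
        """Rotation matrix with columns (forward, left, dorsal)."""
        if self.dof != "6dof":
            raise ValueError("pose has no orientation (3dof)")
        return np.column_stack([self.forward, self.left, self.dorsal])

    def is_orthonormal(self, tol: float = ORTHONORMAL_TOL) -> bool:
        if self.dof != "6dof":
            return False
        R = self.triad()
        return bool(np.allclose(R.T @ R, np.eye(3), atol=tol))


@dataclass
class MarkerTriplet:
    """The three L-frame markers at one sample.

    ``m_origin`` is the corner of the L; the two arms run to
    ``m_forward_tip`` (along the body's forward axis) and ``m_left_tip``
    (along its left axis).
    """

    t: float
    m_origin: np.ndarray
    m_forward_tip: np.ndarray
    m_left_tip: np.ndarray
    valid: bool = True


@dataclass
class Trajectory:
    """An ordered sequence of samples with a common rate and metadata.

    Arrays are aligned row-wise: ``t`` (n,), ``p`` (n, 3) and, when the
    track carries 6-DoF data, ``forward``/``left``/``dorsal`` (n, 3).
    ``light_position`` is the world position of the light source, or None
    for no-light recordings.
    """

    t: np.ndarray
    p: np.ndarray
    rate: float
    forward: Optional[np.ndarray] = None
    left: Optional[np.ndarray] = None
    dorsal: Optional[np.ndarray] = None
    valid: Optional[np.ndarray] = None
    light_position: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (len(self.t), 3):
            raise ValueError("p must be (n, 3) aligned with t")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise DataError("timestamps must be strictly increasing")
        if self.valid is None:
            self.valid = np.ones(len(self.t), dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.light_position is not None:
            self.light_position = _as_vec3(self.light_position)
        for name in ("forward", "left", "dorsal"):
            a = getattr(self, name)
            if a is not None:
                setattr(self, name, np.asarray(a, dtype=float))

    # -- basics ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.t)

    @property
    def has_orientation(self) -> bool:
        return self.forward is not None

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0

    def pose(self, i: int) -> Pose:
        if self.has_orientation:
            return Pose(
                t=float(self.t[i]), p=self.p[i],
                forward=self.forward[i], left=self.left[i],
                dorsal=self.dorsal[i], dof="6dof", valid=bool(self.valid[i]),
            )
        return Pose(t=float(self.t[i]), p=self.p[i], dof="3dof",
                    valid=bool(self.valid[i]))

    def poses(self) -> Iterator[Pose]:
        for i in range(len(self)):
            yield self.pose(i)

    def take(self, idx) -> "Trajectory":
        """Sub-trajectory at integer index array ``idx`` (order preserved)."""
        idx = np.asarray(idx)
        kw = {}
        for name in ("forward", "left", "dorsal"):
            a = getattr(self, name)
            kw[name] = a[idx] if a is not None else None
        return replace(
            self, t=self.t[idx], p=self.p[idx], valid=self.valid[idx],
            meta=dict(self.meta), **kw,
        )

    # -- derived kinematics ---------------------------------------------
    def velocity(self) -> np.ndarray:
        """Per-sample velocity (n, 3): central differences at interior
        samples, one-sided at the ends; uses actual time spacing."""
        n = len(self)
        if n < 2:
            raise DataError("need >= 2 samples for velocity")
        return np.gradient(self.p, self.t, axis=0)

    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.velocity(), axis=1)

    def acceleration(self) -> np.ndarray:
        """Second central difference of position (n, 3)."""
        n = len(self)
        if n < 3:
            raise DataError("need >= 3 samples for acceleration")
        return np.gradient(self.velocity(), self.t, axis=0)
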
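"""Quality-control filters for tracked marker data and trajectories.

The stages mirror standard motion-capture hygiene for a rigid marker
frame: (1) drop frames whose reconstructed L-frame geometry deviates from
the track's median (bad tracking or mislabelling); (2) split a long
recording into bouts wherever the frame disappears for too long; (3) drop
sub-flight-speed samples (walking/settled insects); (4) subsample to a
common low rate before statistics to avoid pseudo-replication.

Removal thresholds are strict inequalities: an arm deviating by more than
``len_tol`` (default 0.4 mm) from the median, or an inter-arm angle more
than ``ang_tol`` (default 5 degrees) from the median, removes the frame;
speeds strictly below ``min_speed`` (default 0.3 m/s) are removed.
Medians are per track, computed over its valid frames.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import List, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError, EmptyResultError
from .frames import MarkerTriplet, Trajectory

log = logging.getLogger(__name__)

LEN_TOL = 0.4e-3      # m
ANG_TOL = 5.0         # degrees
MAX_GAP = 0.5         # s
MIN_FLIGHT_SPEED = 0.3  # m/s
TARGET_RATE = 10.0    # Hz


@dataclass
class QCReport:
    """Counts and thresholds from a QC pass; serialisable to JSON."""

    n_input: int = 0
    n_removed_armlength: int = 0
    n_removed_angle: int = 0
    n_removed_invalid: int = 0
    n_removed_speed: int = 0
    n_segments: int = 0
    thresholds: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _arm_geometry(m: MarkerTriplet):
    a1 = m.m_forward_tip - m.m_origin
    a2 = m.m_left_tip - m.m_origin
    l1 = float(np.linalg.norm(a1))
    l2 = float(np.linalg.norm(a2))
    if l1 == 0.0 or l2 == 0.0:
        return l1, l2, math.nan
    cosang = float(np.clip((a1 @ a2) / (l1 * l2), -1.0, 1.0))
    return l1, l2, math.degrees(math.acos(cosang))


def filter_marker_frames(
    markers: Sequence[MarkerTriplet],
    len_tol: float = LEN_TOL,
    ang_tol: float = ANG_TOL,
) -> Tuple[List[MarkerTriplet], QCReport]:
    """Remove frames whose L-frame geometry deviates from the track median.

    Median arm lengths and median inter-arm angle are computed from the
    track's valid frames; a frame is removed when either arm's length
    deviates by more than ``len_tol`` or the angle by more than
    ``ang_tol`` from those medians. Invalid (dropped-marker) frames are
    removed and counted separately.
    """
    report = QCReport(n_input=len(markers),
                      thresholds={"len_tol_m": len_tol,
                                  "ang_tol_deg": ang_tol})
    valid = [m for m in markers if m.valid]
    if not valid:
        raise EmptyResultError("all marker frames are invalid")
    geo = np.array([_arm_geometry(m) for m in valid])
    med_l1, med_l2 = np.median(geo[:, 0]), np.median(geo[:, 1])
    med_ang = np.nanmedian(geo[:, 2])

    kept: List[MarkerTriplet] = []
    for m in markers:
        if not m.valid:
            report.n_removed_invalid += 1
            continue
        l1, l2, ang = _arm_geometry(m)
        if abs(l1 - med_l1) > len_tol or abs(l2 - med_l2) > len_tol:
            report.n_removed_armlength += 1
            continue
        if not math.isnan(ang) and abs(ang - med_ang) > ang_tol:
            report.n_removed_angle += 1
            continue
        kept.append(m)
    log.info("marker QC: kept %d/%d frames (arm-length %d, angle %d, "
             "invalid %d removed); tolerances %.4g m / %.3g deg",
             len(kept), len(markers), report.n_removed_armlength,
             report.n_removed_angle, report.n_removed_invalid,
             len_tol, ang_tol)
    return kept, report


def split_on_gaps(traj: Trajectory, max_gap: float = MAX_GAP
                  ) -> List[Trajectory]:
    """Split wherever consecutive samples are more than ``max_gap`` s
    apart. Short resulting segments are kept (with their span recorded in
    metadata); segment order follows time order."""
    if len(traj) == 0:
        return []
    gaps = np.diff(traj.t)
    cuts = np.nonzero(gaps > max_gap)[0] + 1
    pieces = np.split(np.arange(len(traj)), cuts)
    out = []
    for k, idx in enumerate(pieces):
        seg = traj.take(idx)
        seg.meta.update({"segment": k, "segment_span_s": seg.duration})
        out.append(seg)
    log.info("gap split: %d segment(s) at max gap %.3g s", len(out), max_gap)
    return out


def filter_flight_speed(traj: Trajectory,
                        min_speed: float = MIN_FLIGHT_SPEED) -> Trajectory:
    """Drop samples moving strictly slower than ``min_speed`` (m/s).

    Speed comes from time-aware central differences on the track as
    given (before any subsampling); a sample at exactly ``min_speed`` is
    retained.
    """
    if len(traj) < 2:
        return traj
    speed = traj.speed()
    keep = np.nonzero(speed >= min_speed)[0]
    log.info("speed filter: removed %d/%d samples below %.3g m/s",
             len(traj) - len(keep), len(traj), min_speed)
    return traj.take(keep)


def subsample(traj: Trajectory, target_rate: float = TARGET_RATE
              ) -> Trajectory:
    """Keep every round(rate / target_rate)-th sample, starting at the
    first; guards against pseudo-replication before statistics."""
    if traj.rate < target_rate:
        raise ConfigurationError(
            f"cannot subsample {traj.rate} Hz to {target_rate} Hz")
    step = int(round(traj.rate / target_rate))
    if step <= 1:
        return traj
    out = traj.take(np.arange(0, len(traj), step))
    out.rate = traj.rate / step
    out.meta["subsampled_from_hz"] = traj.rate
    return out
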
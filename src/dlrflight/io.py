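"""Readers and writers for the trajectory and marker CSV schemas.

Trajectory files are plain CSV with ``#``-prefixed header metadata lines::

    # schema: dlrflight-trajectory-v1
    # rate_hz: 100
    # light_position_m: 0 0 0          (or 'none')
    # source: ...
    t_s,x_m,y_m,z_m[,bx_x..bz_z],valid

Positions are metres, time seconds. The nine optional triad columns are
the world components of the forward (bx_*), left (by_*) and dorsal (bz_*)
body axes and must be present all together or not at all. Floats are
written with full precision so a write/read round trip is exact.

Marker files use the same header style with columns
``t_s,m1_x..m1_z,m2_x..m2_z,m3_x..m3_z,valid`` where m1 is the L-frame
origin, m2 the forward-arm tip and m3 the left-arm tip.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError
from .frames import MarkerTriplet, Trajectory

TRIAD_COLS = ["bx_x", "bx_y", "bx_z", "by_x", "by_y", "by_z",
              "bz_x", "bz_y", "bz_z"]
POS_COLS = ["t_s", "x_m", "y_m", "z_m"]
MARKER_COLS = [f"m{i}_{c}" for i in (1, 2, 3) for c in "xyz"]

_FLOAT_FMT = "%.17g"


def _write_header(fh, rate, light_position, source, schema) -> None:
    fh.write(f"# schema: {schema}\n")
    fh.write(f"# rate_hz: {rate!r}\n")
    if light_position is None:
        fh.write("# light_position_m: none\n")
    else:
        fh.write("# light_position_m: "
                 + " ".join(repr(float(v)) for v in light_position) + "\n")
    fh.write(f"# source: {source}\n")


def _read_header(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, val = line.lstrip("# ").partition(":")
                meta[key.strip()] = val.strip()
    return meta


def write_trajectory(traj: Trajectory, path) -> None:
    path = Path(path)
    cols = {"t_s": traj.t, "x_m": traj.p[:, 0], "y_m": traj.p[:, 1],
            "z_m": traj.p[:, 2]}
    if traj.has_orientation:
        for name, arr in (("bx", traj.forward), ("by", traj.left),
                          ("bz", traj.dorsal)):
            for j, c in enumerate("xyz"):
                cols[f"{name}_{c}"] = arr[:, j]
    cols["valid"] = traj.valid.astype(int)
    with open(path, "w") as fh:
        _write_header(fh, traj.rate, traj.light_position,
                      traj.meta.get("source", "unknown"),
                      "dlrflight-trajectory-v1")
        pd.DataFrame(cols).to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_trajectory(path, orthonormal_tol: float = 1e-6) -> Trajectory:
    """Parse a trajectory CSV.

    Triad rows that fail orthonormality beyond ``orthonormal_tol`` trigger
    a warning and the whole track is downgraded to 3-DoF (axes dropped).
    """
    path = Path(path)
    meta = _read_header(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # malformed CSV body
        raise SchemaError(f"{path}: cannot parse CSV ({exc})") from exc
    for col in POS_COLS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    present = [c for c in TRIAD_COLS if c in df.columns]
    if present and len(present) != len(TRIAD_COLS):
        missing = sorted(set(TRIAD_COLS) - set(present))
        raise SchemaError(f"{path}: incomplete triad columns, missing {missing}")

    t = df["t_s"].to_numpy(float)
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        bad = int(np.nonzero(np.diff(t) <= 0)[0][0]) + 2  # 1-based + header
        raise DataError(f"{path}: non-monotone time at data row {bad}")
    p = df[["x_m", "y_m", "z_m"]].to_numpy(float)

    rate = float(meta.get("rate_hz", "0") or 0)
    lp = meta.get("light_position_m", "none")
    light = None if lp in ("none", "") else np.array(
        [float(v) for v in lp.split()])

    fwd = left = dors = None
    if present:
        fwd = df[["bx_x", "bx_y", "bx_z"]].to_numpy(float)
        left = df[["by_x", "by_y", "by_z"]].to_numpy(float)
        dors = df[["bz_x", "bz_y", "bz_z"]].to_numpy(float)
        R = np.stack([fwd, left, dors], axis=-1)
        gram = np.einsum("nij,nik->njk", R, R)
        err = np.abs(gram - np.eye(3)).max()
        if err > orthonormal_tol:
            warnings.warn(
                f"{path}: triad orthonormality error {err:.2g} exceeds "
                f"{orthonormal_tol:.2g}; downgrading track to 3-DoF")
            fwd = left = dors = None

    valid = (df["valid"].to_numpy(int).astype(bool) if "valid" in df.columns
             else None)
    return Trajectory(t=t, p=p, rate=rate, forward=fwd, left=left,
                      dorsal=dors, valid=valid, light_position=light,
                      meta={"source": meta.get("source", str(path))})


def write_markers(markers: Sequence[MarkerTriplet], path, rate: float,
                  light_position=None, source: str = "unknown") -> None:
    path = Path(path)
    rows = {
        "t_s": [m.t for m in markers],
    }
    for key, attr in (("m1", "m_origin"), ("m2", "m_forward_tip"),
                      ("m3", "m_left_tip")):
        arr = np.array([getattr(m, attr) for m in markers])
        for j, c in enumerate("xyz"):
            rows[f"{key}_{c}"] = arr[:, j]
    rows["valid"] = [int(m.valid) for m in markers]
    with open(path, "w") as fh:
        _write_header(fh, rate, light_position, source,
                      "dlrflight-markers-v1")
        pd.DataFrame(rows).to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_markers(path) -> List[MarkerTriplet]:
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    for col in ["t_s"] + MARKER_COLS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    valid = (df["valid"].to_numpy(int).astype(bool) if "valid" in df.columns
             else np.ones(len(df), dtype=bool))
    out = []
    for i in range(len(df)):
        out.append(MarkerTriplet(
            t=float(df["t_s"].iloc[i]),
            m_origin=df[["m1_x", "m1_y", "m1_z"]].iloc[i].to_numpy(float),
            m_forward_tip=df[["m2_x", "m2_y", "m2_z"]].iloc[i].to_numpy(float),
            m_left_tip=df[["m3_x", "m3_y", "m3_z"]].iloc[i].to_numpy(float),
            valid=bool(valid[i])))
    return out


def markers_file_meta(path) -> dict:
    return _read_header(path)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
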
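"""File formats: XYZ trajectories, sidecar CSV, JSON metadata.

XYZ dialect: standard per-frame blocks (atom count, then a comment line
carrying ``t=<tau> sign=<+-1>``, then one ``<element> x y z`` row per bead).
Chain beads use element ``C``; wall beads, when co-exported for
visualization, use ``O``.  Positions round-trip to better than 1e-6 sigma.
The sidecar CSV carries per-frame (time, force sign, knot core, label) and
the JSON metadata everything needed to reproduce the run.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import Trajectory
from .topology import KnotRecord


class TrajectoryFormatError(ValueError):
    pass


def write_xyz(path, trajectory: Trajectory, wall: np.ndarray | None = None):
    """Write trajectory frames as XYZ (chain 'C', optional static wall 'O')."""
    path = Path(path)
    nw = 0 if wall is None else len(wall)
    with open(path, "w") as fh:
        for t, frame, sign in zip(trajectory.times, trajectory.positions,
                                  trajectory.force_signs):
            fh.write(f"{len(frame) + nw}\n")
            fh.write(f"t={t:.6f} sign={int(sign)}\n")
            for x, y, z in frame:
                fh.write(f"C {x:.8f} {y:.8f} {z:.8f}\n")
            if wall is not None:
                for x, y, z in wall:
                    fh.write(f"O {x:.8f} {y:.8f} {z:.8f}\n")


def read_xyz(path):
    """Read an XYZ trajectory written by :func:`write_xyz`.

    Returns (times, chain_frames, force_signs, wall or None).  Malformed
    frames raise :class:`TrajectoryFormatError` with the line number.
    """
    path = Path(path)
    times, frames, signs = [], [], []
    wall = None
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        raise TrajectoryFormatError("empty trajectory file")
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            count = int(lines[ln].strip())
        except ValueError as exc:
            raise TrajectoryFormatError(
                f"line {ln + 1}: expected atom count") from exc
        comment = lines[ln + 1].strip() if ln + 1 < len(lines) else ""
        fields = dict(kv.split("=") for kv in comment.split() if "=" in kv)
        try:
            times.append(float(fields["t"]))
            signs.append(float(fields["sign"]))
        except KeyError as exc:
            raise TrajectoryFormatError(
                f"line {ln + 2}: comment must carry t= and sign=") from exc
        chain = []
        wall_frame = []
        for k in range(count):
            idx = ln + 2 + k
            if idx >= len(lines):
                raise TrajectoryFormatError(f"line {idx + 1}: truncated frame")
            parts = lines[idx].split()
            if len(parts) != 4:
                raise TrajectoryFormatError(
                    f"line {idx + 1}: expected 'El x y z'")
            el, x, y, z = parts
            p = (float(x), float(y), float(z))
            (chain if el == "C" else wall_frame).append(p)
        frames.append(chain)
        if wall_frame and wall is None:
            wall = np.array(wall_frame)
        ln += 2 + count
    return (np.array(times), np.array(frames), np.array(signs), wall)


def write_sidecar_csv(path, trajectory: Trajectory):
    """Per-frame (time_tau, force_sign, i_start, i_end, label) CSV.

    A units header comment precedes the data.
    """
    rows = []
    for t, sign, rec in zip(trajectory.times, trajectory.force_signs,
                            trajectory.knot_records):
        if rec is None:
            rows.append((t, int(sign), -1, -1, float("nan"), ""))
        else:
            rows.append((t, int(sign), rec.i_start, rec.i_end,
                         rec.writhe, rec.prefixed_label))
    df = pd.DataFrame(rows, columns=["time", "force_sign", "i_start",
                                     "i_end", "writhe", "label"])
    with open(path, "w") as fh:
        fh.write("# units: time=tau, i_start/i_end=1-based bead index, "
                 "writhe=dimensionless\n")
        df.to_csv(fh, index=False)


def read_sidecar_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_metadata(path, trajectory: Trajectory):
    with open(path, "w") as fh:
        json.dump(trajectory.metadata, fh, indent=2, sort_keys=True,
                  default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def save_trajectory(prefix, trajectory: Trajectory,
                    wall: np.ndarray | None = None):
    """Persist a trajectory as <prefix>.xyz + <prefix>.csv + <prefix>.json."""
    prefix = Path(prefix)
    write_xyz(prefix.with_suffix(".xyz"), trajectory, wall)
    write_sidecar_csv(prefix.with_suffix(".csv"), trajectory)
    write_metadata(prefix.with_suffix(".json"), trajectory)


def load_trajectory(prefix) -> Trajectory:
    """Round-trip counterpart of :func:`save_trajectory`."""
    prefix = Path(prefix)
    times, frames, signs, _ = read_xyz(prefix.with_suffix(".xyz"))
    df = read_sidecar_csv(prefix.with_suffix(".csv"))
    with open(prefix.with_suffix(".json")) as fh:
        meta = json.load(fh)
    records = []
    for _, row in df.iterrows():
        if row["i_start"] < 0 or not isinstance(row["label"], str):
            records.append(None)
            continue
        label = str(row["label"]).replace("<+>", "").replace("<->", "")
        sign = 1 if "<+>" in str(row["label"]) else \
            (-1 if "<->" in str(row["label"]) else 0)
        records.append(KnotRecord(label, sign, int(row["i_start"]),
                                  int(row["i_end"]), float(row["writhe"]),
                                  (0, 0)))
    return Trajectory(times, frames, signs, records, meta)
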
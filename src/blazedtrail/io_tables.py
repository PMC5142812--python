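"""Delimited-text tables shared by all modules.

Comma-separated, one header row.  Units are fixed repo-wide: time in
seconds, lengths in centimetres, angles in degrees.  Reading validates
the header against a schema and points at the offending column or line
on failure; write-then-read is an identity.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .detection import MarkEvent, Trajectory

__all__ = [
    "SchemaError",
    "TRAJECTORY_SCHEMA",
    "MARK_SCHEMA",
    "BOUT_SCHEMA",
    "read_table",
    "walks_to_frame",
    "write_table",
    "trajectories_from_frame",
    "trajectory_to_frame",
    "marks_from_frame",
    "marks_to_frame",
]


class SchemaError(ValueError):
    """Header or cell contents do not match the expected table schema."""


#: column name -> dtype ("str" or "float")
TRAJECTORY_SCHEMA = {"id": "str", "t": "float", "x": "float", "y": "float"}
MARK_SCHEMA = {"id": "str", "t": "float", "x": "float", "y": "float"}
BOUT_SCHEMA = {
    "id": "str",
    "n_events": "float",
    "start_distance_cm": "float",
    "bout_length_cm": "float",
}


def read_table(path: str | Path, schema: dict[str, str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in schema:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing column '{col}'")
    for col in df.columns:
        if col not in schema:
            raise SchemaError(f"{path.name}: unexpected column '{col}'")
    out = {}
    for col, kind in schema.items():
        if kind == "str":
            out[col] = df[col]
            continue
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() & (df[col] != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            # +2: header line plus 1-based numbering
            raise SchemaError(
                f"{path.name}: non-numeric value {df[col].iloc[row]!r} in "
                f"column '{col}' at line {row + 2}"
            )
        out[col] = values.astype(float)
    return pd.DataFrame(out, columns=list(schema))


def write_table(path: str | Path, df: pd.DataFrame, schema: dict[str, str]) -> None:
    for col in schema:
        if col not in df.columns:
            raise SchemaError(f"cannot write: missing column '{col}'")
    df[list(schema)].to_csv(path, index=False)


def walks_to_frame(sources, hops, reached) -> pd.DataFrame:
    """One row per walk of a batch: source, hops, reached, censored."""
    reached = np.asarray(reached, dtype=bool)
    return pd.DataFrame(
        {
            "source": np.asarray(sources, dtype=int),
            "hops": np.asarray(hops, dtype=int),
            "reached": reached.astype(int),
            "censored": (~reached).astype(int),
        }
    )


def trajectory_to_frame(trajs: list[Trajectory]) -> pd.DataFrame:
    frames = [
        pd.DataFrame({"id": tr.id, "t": tr.t, "x": tr.x, "y": tr.y})
        for tr in trajs
    ]
    return pd.concat(frames, ignore_index=True)


def trajectories_from_frame(df: pd.DataFrame, frame_rate: float) -> list[Trajectory]:
    out = []
    for tid, block in df.groupby("id", sort=False):
        block = block.sort_values("t")
        out.append(
            Trajectory(
                id=str(tid),
                t=block["t"].to_numpy(),
                x=block["x"].to_numpy(),
                y=block["y"].to_numpy(),
                frame_rate=frame_rate,
            )
        )
    return out


def marks_to_frame(marks: list[MarkEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [m.ant_id for m in marks],
            "t": [m.t for m in marks],
            "x": [m.x for m in marks],
            "y": [m.y for m in marks],
        }
    )


def marks_from_frame(df: pd.DataFrame) -> list[MarkEvent]:
    return [
        MarkEvent(ant_id=str(r.id), t=float(r.t), x=float(r.x), y=float(r.y))
        for r in df.itertuples()
    ]
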
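"""Reading and writing the pose-estimation CSV dialect and result tables.

The pose CSV dialect has three header rows (scorer / bodyparts / coords)
and per-bodypart columns x, y, likelihood, one data row per frame — the
export format of markerless pose trackers.  Hands are mapped from
configurable bodypart names (default ``left_fingertip`` /
``right_fingertip``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import HandTrack, RawRecording

__all__ = ["read_pose_csv", "write_pose_csv", "write_observation_table",
           "read_observation_table", "DEFAULT_BODYPARTS"]

DEFAULT_BODYPARTS = {"left": "left_fingertip", "right": "right_fingertip"}


def read_pose_csv(path: str | Path, fs: float = 59.94,
                  bodyparts: dict[str, str] | None = None,
                  metadata: dict | None = None) -> RawRecording:
    """Parse a three-header-row pose CSV into a RawRecording.

    ``bodyparts`` maps hand labels {'left','right'} to bodypart names in
    the file.  The frame index (first column) must be 0-based and
    monotone increasing.
    """
    path = Path(path)
    bodyparts = bodyparts or DEFAULT_BODYPARTS
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0,
                         float_precision="round_trip")
    except (ValueError, pd.errors.ParserError) as e:
        raise ValueError(f"{path}: not a valid pose CSV: {e}") from None
    frames = df.index.to_numpy()
    if len(frames) == 0:
        raise ValueError(f"{path}: no data rows")
    if not np.all(np.diff(frames) > 0):
        raise ValueError(f"{path}: frame index is not strictly increasing")
    scorer = df.columns.get_level_values(0)[0]
    hands = {}
    for label, bp in bodyparts.items():
        cols = {}
        for coord in ("x", "y", "likelihood"):
            key = (scorer, bp, coord)
            if key not in df.columns:
                raise ValueError(
                    f"{path}: missing column {coord!r} for bodypart {bp!r}")
            cols[coord] = df[key].to_numpy(dtype=float)
        hands[label] = HandTrack(x=cols["x"], y=cols["y"],
                                 likelihood=cols["likelihood"])
    return RawRecording(fs=fs, hands=hands, metadata=dict(metadata or {}))


def write_pose_csv(rec: RawRecording, path: str | Path,
                   bodyparts: dict[str, str] | None = None,
                   scorer: str = "tapdyn") -> Path:
    """Write a RawRecording in the three-header-row pose CSV dialect."""
    path = Path(path)
    bodyparts = bodyparts or DEFAULT_BODYPARTS
    columns = []
    data = {}
    for label in ("left", "right"):
        bp = bodyparts[label]
        h = rec.hands[label]
        for coord, arr in (("x", h.x), ("y", h.y), ("likelihood", h.likelihood)):
            columns.append((scorer, bp, coord))
            data[(scorer, bp, coord)] = arr
    df = pd.DataFrame(data, columns=pd.MultiIndex.from_tuples(
        columns, names=["scorer", "bodyparts", "coords"]))
    df.index.name = None
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path)
    return path


def write_observation_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_observation_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
    return path
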
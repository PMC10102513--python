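"""Reading, validation, preprocessing and writing of gaze recordings.

A gaze recording is a delimited text file with one row per eye-tracker
sample: time since recording start (ms), horizontal and vertical gaze
position (screen pixels, origin top-left, y downward), and a validity
flag.  The canonical dialect is comma-separated with the header
``time_ms,x_px,y_px,valid``; foreign logs are accommodated through a
column mapping.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GazeSeries",
    "PreprocessPolicy",
    "DEFAULT_COLUMNS",
    "read_gaze",
    "write_gaze",
    "preprocess",
    "write_table",
    "read_table",
]

#: canonical column names of the gaze CSV dialect
DEFAULT_COLUMNS: Mapping[str, str] = {
    "t": "time_ms",
    "x": "x_px",
    "y": "y_px",
    "valid": "valid",
}

TASKS = ("N-num", "N-cha", "N-obj", "N-col")
ALPHANUMERIC_TASKS = ("N-num", "N-cha")
NON_ALPHANUMERIC_TASKS = ("N-obj", "N-col")


@dataclass
class GazeSeries:
    """Ordered, timestamped 2D gaze samples for one subject and task.

    Attributes
    ----------
    t : ndarray, shape (n,)
        Sample times in ms since recording start, strictly increasing.
    x, y : ndarray, shape (n,)
        Gaze position in screen pixels.  May be NaN on invalid samples.
    valid : ndarray of bool, shape (n,)
        Tracker validity flag per sample.
    rate : float
        Nominal sampling rate in Hz.
    screen : tuple of int
        Screen size (width, height) in pixels.
    subject_id : str
        Opaque subject label.
    task : str
        One of ``N-num``, ``N-cha``, ``N-obj``, ``N-col`` (or ``""``).
    orig_index : ndarray, shape (n,)
        Index of each sample in the raw recording, so node identity stays
        traceable through preprocessing.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    rate: float = 90.0
    screen: tuple = (1920, 1080)
    subject_id: str = ""
    task: str = ""
    orig_index: np.ndarray | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.orig_index is None:
            self.orig_index = np.arange(len(self.t))
        else:
            self.orig_index = np.asarray(self.orig_index, dtype=int)
        if len(self.t) == 0:
            raise ValueError("empty recording")
        if not (len(self.t) == len(self.x) == len(self.y) == len(self.valid)):
            raise ValueError("field lengths differ")
        if np.any(~np.isfinite(self.t)) or np.any(self.t < 0):
            raise ValueError("timestamps must be finite and non-negative")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        bad = self.valid & ~(np.isfinite(self.x) & np.isfinite(self.y))
        if np.any(bad):
            raise ValueError(
                f"sample {int(np.flatnonzero(bad)[0])} is flagged valid but has "
                "non-finite coordinates"
            )
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration_ms(self) -> float:
        """Span from first to last sample, ms."""
        return float(self.t[-1] - self.t[0])

    def coords(self) -> np.ndarray:
        """(n, 2) array of x, y positions."""
        return np.column_stack([self.x, self.y])

    def replace(self, **kw) -> "GazeSeries":
        return dataclasses.replace(self, **kw)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ms": self.t,
                "x_px": self.x,
                "y_px": self.y,
                "valid": self.valid.astype(int),
            }
        )


@dataclass
class PreprocessPolicy:
    """How raw recordings are cleaned before event detection and networks.

    Invalid (blink / tracking-loss) samples are dropped, never
    interpolated: the downstream proximity rule needs real, finite
    coordinates, and interpolation would invent gazes that were never
    made.
    """

    drop_invalid: bool = True
    offscreen: str = "keep"  # "keep" | "drop" | "clip"
    margin_px: float = 0.0

    @classmethod
    def from_json(cls, path) -> "PreprocessPolicy":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def read_gaze(
    path,
    schema: Mapping[str, str] | None = None,
    rate: float = 90.0,
    screen: tuple = (1920, 1080),
    subject_id: str = "",
    task: str = "",
) -> GazeSeries:
    """Read a gaze CSV into a :class:`GazeSeries`.

    Parameters
    ----------
    path : path-like
        Delimited text file with a header row.
    schema : mapping, optional
        Maps logical fields ``t, x, y, valid`` to column names in the
        file; defaults to the canonical dialect.

    Raises
    ------
    FileNotFoundError, ValueError
        Missing file; empty recording; unresolvable columns; unparseable
        rows (reported with line number); non-increasing timestamps.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    schema = dict(DEFAULT_COLUMNS if schema is None else schema)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty recording")
    missing = [c for c in schema.values() if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: columns not found: {missing}")
    cols = {}
    for key in ("t", "x", "y", "valid"):
        raw = df[schema[key]]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if key in ("t", "valid") and bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ValueError(f"{path}: unparseable value in line {line}")
        cols[key] = num.to_numpy()
    return GazeSeries(
        t=cols["t"],
        x=cols["x"],
        y=cols["y"],
        valid=~np.isnan(cols["valid"]) & (cols["valid"] != 0),
        rate=rate,
        screen=screen,
        subject_id=subject_id,
        task=task,
    )


def write_gaze(series: GazeSeries, path) -> Path:
    """Write a series in the canonical CSV dialect; inverse of read_gaze."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    series.to_frame().to_csv(path, index=False, float_format="%.10g")
    return path


def preprocess(series: GazeSeries, policy: PreprocessPolicy | None = None) -> GazeSeries:
    """Apply the cleaning policy; order preserved, count never increases.

    Original sample indices survive in ``orig_index`` so graph nodes stay
    traceable to raw samples.

    Raises
    ------
    ValueError
        If no valid sample survives.
    """
    policy = policy or PreprocessPolicy()
    keep = np.ones(len(series), dtype=bool)
    if policy.drop_invalid:
        keep &= series.valid
    x, y = series.x, series.y
    if policy.offscreen == "drop":
        w, h = series.screen
        m = policy.margin_px
        on = (x >= -m) & (x <= w + m) & (y >= -m) & (y <= h + m)
        keep &= np.where(np.isfinite(x) & np.isfinite(y), on, False)
    if not keep.any():
        raise ValueError("all samples removed by preprocessing")
    out = series.replace(
        t=series.t[keep],
        x=x[keep],
        y=y[keep],
        valid=series.valid[keep],
        orig_index=series.orig_index[keep],
    )
    if policy.offscreen == "clip":
        w, h = series.screen
        out = out.replace(x=np.clip(out.x, 0, w), y=np.clip(out.y, 0, h))
    return out


def write_table(rows, path) -> Path:
    """Write tabular pipeline output (cohort tables, metric records) as CSV.

    Column order is kept stable so re-runs are bit-identical.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame(list(rows))
    if df.empty:
        raise ValueError("refusing to write an empty table")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
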
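"""Reading and writing of SMLM event lists and localization sets.

All coordinates inside the package are nanometres.  Input files are
headered delimited text (CSV/TSV); a :class:`Dialect` maps file columns
onto the (x, y, z[, frame]) roles and declares the unit scale applied at
read time, so acquisition-software exports in pixel units can be
normalised on ingestion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "EventList",
    "LocalizationSet",
    "Dialect",
    "DIALECTS",
    "FormatError",
    "read_event_list",
    "write_event_list",
    "read_localization_set",
    "write_localization_set",
]


class FormatError(ValueError):
    """Raised when an input table does not match the declared dialect."""


@dataclass(frozen=True)
class Dialect:
    """Column mapping and unit scale of a tabular event-list file.

    ``xy_scale`` / ``z_scale`` convert file units to nm (1.0 if the file
    is already in nm).
    """

    x: str = "x"
    y: str = "y"
    z: str = "z"
    frame: Optional[str] = "frame"
    xy_scale: float = 1.0
    z_scale: float = 1.0
    sep: str = ","


#: Registered dialects.  The plain nm CSV is the default; the pixel-unit
#: variant applies the 20 nm XY / 25 nm Z pixel pitch of the GSD export.
DIALECTS: dict[str, Dialect] = {
    "default": Dialect(),
    "leica-gsd": Dialect(),
    "leica-gsd-px": Dialect(xy_scale=20.0, z_scale=25.0),
    "tsv": Dialect(sep="\t"),
}


@dataclass
class EventList:
    """Raw blinks: one row per localization event, pre-merge."""

    points: np.ndarray  # (n, 3) float64, nm
    frame: Optional[np.ndarray] = None  # (n,) int, optional
    source_label: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("event coordinates must be finite")
        if self.frame is not None:
            self.frame = np.asarray(self.frame)
            if self.frame.shape[0] != self.points.shape[0]:
                raise ValueError("frame column length mismatch")
            if np.any(self.frame < 0):
                raise ValueError("frame indices must be non-negative")

    def __len__(self) -> int:
        return self.points.shape[0]

    def subset(self, mask: np.ndarray) -> "EventList":
        return EventList(
            points=self.points[mask],
            frame=None if self.frame is None else self.frame[mask],
            source_label=self.source_label,
        )


@dataclass
class LocalizationSet:
    """Merged nodes: predicted molecule positions.

    ``merged_from[i]`` counts the original blinks absorbed into point i;
    it sums to the pre-merge blink count.
    """

    points: np.ndarray  # (n, 3) float64, nm
    merged_from: np.ndarray = field(default=None)  # (n,) positive int
    source_label: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("coordinates must be finite")
        if self.merged_from is None:
            self.merged_from = np.ones(len(self.points), dtype=np.int64)
        else:
            self.merged_from = np.asarray(self.merged_from, dtype=np.int64)
        if self.merged_from.shape[0] != self.points.shape[0]:
            raise ValueError("merged_from length mismatch")
        if len(self.merged_from) and self.merged_from.min() < 1:
            raise ValueError("merged_from entries must be positive")

    def __len__(self) -> int:
        return self.points.shape[0]

    def subset(self, mask: np.ndarray) -> "LocalizationSet":
        return LocalizationSet(
            points=self.points[mask],
            merged_from=self.merged_from[mask],
            source_label=self.source_label,
        )


def _resolve_dialect(dialect) -> Dialect:
    if dialect is None:
        return DIALECTS["default"]
    if isinstance(dialect, str):
        try:
            return DIALECTS[dialect]
        except KeyError:
            raise FormatError(f"unknown dialect {dialect!r}") from None
    return dialect


def _numeric_column(df: pd.DataFrame, name: str) -> np.ndarray:
    if name not in df.columns:
        raise FormatError(f"missing required column {name!r}")
    col = pd.to_numeric(df[name], errors="coerce")
    bad = col.isna() & df[name].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(
            f"non-numeric value in column {name!r} at data row {row}"
        )
    if col.isna().any():
        row = int(np.flatnonzero(col.isna().to_numpy())[0])
        raise FormatError(f"empty value in column {name!r} at data row {row}")
    return col.to_numpy(dtype=np.float64)


def read_event_list(path, dialect=None, source_label: str = "") -> EventList:
    """Read a tabular event list, converting coordinates to nm.

    Row order is preserved; no rows are dropped or reordered.
    """
    dia = _resolve_dialect(dialect)
    df = pd.read_csv(path, sep=dia.sep)
    df.columns = [str(c).strip() for c in df.columns]
    if len(df) == 0:
        for name in (dia.x, dia.y, dia.z):
            if name not in df.columns:
                raise FormatError(f"missing required column {name!r}")
        frame = None
        if dia.frame is not None and dia.frame in df.columns:
            frame = np.zeros(0, dtype=np.int64)
        return EventList(points=np.zeros((0, 3)), frame=frame,
                         source_label=source_label or str(path))
    x = _numeric_column(df, dia.x) * dia.xy_scale
    y = _numeric_column(df, dia.y) * dia.xy_scale
    z = _numeric_column(df, dia.z) * dia.z_scale
    frame = None
    if dia.frame is not None and dia.frame in df.columns:
        frame = _numeric_column(df, dia.frame).astype(np.int64)
    return EventList(points=np.column_stack([x, y, z]), frame=frame,
                     source_label=source_label or str(path))


def write_event_list(ev: EventList, path, dialect=None) -> Path:
    """Write an event list as headered CSV (nm).  Returns the path."""
    dia = _resolve_dialect(dialect)
    cols = {dia.x: ev.points[:, 0], dia.y: ev.points[:, 1],
            dia.z: ev.points[:, 2]}
    if ev.frame is not None:
        cols[dia.frame or "frame"] = ev.frame
    path = Path(path)
    pd.DataFrame(cols).to_csv(path, index=False, sep=dia.sep)
    return path


def read_localization_set(path, dialect=None,
                          source_label: str = "") -> LocalizationSet:
    """Read a localization set; a ``merged_from`` column is honoured."""
    dia = _resolve_dialect(dialect)
    df = pd.read_csv(path, sep=dia.sep)
    df.columns = [str(c).strip() for c in df.columns]
    if len(df) == 0:
        return LocalizationSet(points=np.zeros((0, 3)),
                               merged_from=np.zeros(0, dtype=np.int64),
                               source_label=source_label or str(path))
    x = _numeric_column(df, dia.x) * dia.xy_scale
    y = _numeric_column(df, dia.y) * dia.xy_scale
    z = _numeric_column(df, dia.z) * dia.z_scale
    if "merged_from" in df.columns:
        merged = _numeric_column(df, "merged_from").astype(np.int64)
    else:
        merged = np.ones(len(df), dtype=np.int64)
    return LocalizationSet(points=np.column_stack([x, y, z]),
                           merged_from=merged,
                           source_label=source_label or str(path))


def write_localization_set(locs: LocalizationSet, path, dialect=None) -> Path:
    dia = _resolve_dialect(dialect)
    path = Path(path)
    pd.DataFrame({
        dia.x: locs.points[:, 0],
        dia.y: locs.points[:, 1],
        dia.z: locs.points[:, 2],
        "merged_from": locs.merged_from,
    }).to_csv(path, index=False, sep=dia.sep)
    return path
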
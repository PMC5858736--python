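"""Tabular I/O for gaze streams, readings and case metadata.

All files are tab-separated text.  Metadata (sampling rate, display
geometry) is carried in ``#``-prefixed ``key: value`` header lines before
the column header.  Coordinates are pixels, origin top-left, y increasing
downward, 0-based and continuous.  Dual displays are laid out side by
side: the global frame offsets display 2 horizontally by the width of
display 1.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyScanpathError, ParseError, SchemaError

GAZE_COLUMNS = ("reader_id", "case_id", "t", "x", "y", "display")
READINGS_COLUMNS = ("reader_id", "case_id", "order_index", "session_segment", "decision")
CASES_COLUMNS = ("case_id", "pathology", "density", "truth_rating")
FD_COLUMNS = ("reader_id", "case_id", "fd", "r2", "n_scales")

_FLOAT_FMT = "%.6f"


@dataclass(frozen=True)
class DisplayGeometry:
    """Pixel geometry of the (possibly dual) display setup."""

    width: int = 1280
    height: int = 1024
    n_displays: int = 2

    @property
    def total_width(self) -> int:
        """Width of the side-by-side global frame."""
        return self.width * self.n_displays


DEFAULT_GEOMETRY = DisplayGeometry()


@dataclass
class GazeStream:
    """One reading's time-ordered gaze samples.

    ``x``/``y`` may be in per-display (local) or global coordinates
    depending on provenance; :func:`assemble_scanpath` produces the
    global frame.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    display: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.display = np.asarray(self.display, dtype=int)
        if not (len(self.t) == len(self.x) == len(self.y) == len(self.display)):
            raise ValueError("gaze sample arrays must share one length")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class GazeTable:
    """Long-format gaze samples for many readings plus stream metadata."""

    frame: pd.DataFrame
    rate: float
    geometry: DisplayGeometry = field(default_factory=DisplayGeometry)


def _write_meta(fh: io.TextIOBase, meta: dict) -> None:
    for key, value in meta.items():
        fh.write(f"# {key}: {value}\n")


def _read_lines(path) -> tuple[dict, list[str], int]:
    """Split a TSV file into metadata dict, data lines and header offset."""
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            body_start += 1
            stripped = line.lstrip("#").strip()
            if ":" in stripped:
                key, _, value = stripped.partition(":")
                meta[key.strip()] = value.strip()
        else:
            break
    return meta, lines[body_start:], body_start


def _parse_table(path, required: tuple[str, ...], numeric: dict[str, type]) -> tuple[dict, pd.DataFrame]:
    meta, body, offset = _read_lines(path)
    if not body:
        raise SchemaError(f"{path}: missing column header")
    header = body[0].split("\t")
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    rows = [line for line in body[1:] if line != ""]
    if rows:
        frame = pd.read_csv(
            io.StringIO("\n".join(body)), sep="\t", dtype=str, keep_default_na=False
        )
    else:
        frame = pd.DataFrame({c: pd.Series(dtype=str) for c in header})
    for col, kind in numeric.items():
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & (frame[col] != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            lineno = offset + 2 + row  # 1-based file line of the bad row
            raise ParseError(
                f"{path}: line {lineno}: non-numeric value "
                f"{frame[col].iloc[row]!r} in column {col!r}"
            )
        frame[col] = converted.astype(kind)
    return meta, frame


# ---------------------------------------------------------------------------
# gaze table

def write_gaze(path, table: GazeTable) -> None:
    geo = table.geometry
    with open(path, "w", encoding="utf-8") as fh:
        _write_meta(
            fh,
            {
                "rate": _FLOAT_FMT % table.rate,
                "display_width": geo.width,
                "display_height": geo.height,
                "n_displays": geo.n_displays,
            },
        )
        table.frame.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_gaze(path) -> GazeTable:
    meta, frame = _parse_table(
        path, GAZE_COLUMNS, {"t": float, "x": float, "y": float, "display": int}
    )
    for key in ("rate", "display_width", "display_height"):
        if key not in meta:
            raise SchemaError(f"{path}: missing metadata key {key!r}")
    geometry = DisplayGeometry(
        width=int(meta["display_width"]),
        height=int(meta["display_height"]),
        n_displays=int(meta.get("n_displays", 2)),
    )
    return GazeTable(frame=frame, rate=float(meta["rate"]), geometry=geometry)


# ---------------------------------------------------------------------------
# readings / cases / fd tables

def write_readings(path, frame: pd.DataFrame, meta: dict | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        _write_meta(fh, meta or {})
        frame.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_readings(path) -> pd.DataFrame:
    _, frame = _parse_table(
        path, READINGS_COLUMNS, {"order_index": int, "session_segment": int}
    )
    dup = frame.duplicated(subset=["reader_id", "order_index"])
    if dup.any():
        raise SchemaError(f"{path}: duplicate (reader_id, order_index) rows")
    return frame


def write_cases(path, frame: pd.DataFrame, meta: dict | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        _write_meta(fh, meta or {})
        frame.to_csv(fh, sep="\t", index=False)


def read_cases(path) -> pd.DataFrame:
    _, frame = _parse_table(path, CASES_COLUMNS, {"density": int})
    return frame


def write_fd_table(path, frame: pd.DataFrame, meta: dict | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        _write_meta(fh, meta or {})
        frame.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_fd_table(path) -> pd.DataFrame:
    _, frame = _parse_table(path, FD_COLUMNS, {"fd": float, "r2": float, "n_scales": int})
    return frame


# ---------------------------------------------------------------------------
# scanpath assembly

def assemble_scanpath(rows: pd.DataFrame, geometry: DisplayGeometry, rate: float = 60.0) -> GazeStream:
    """Merge one reading's per-display samples into the global frame.

    Display ``d`` is offset horizontally by ``(d - 1) * width``.  Samples
    are stably sorted by timestamp so that ties keep input order.
    """
    if len(rows) == 0:
        raise EmptyScanpathError("cannot assemble a scanpath from zero samples")
    display = rows["display"].to_numpy(dtype=int)
    if ((display < 1) | (display > geometry.n_displays)).any():
        raise ValueError(f"display ids must lie in 1..{geometry.n_displays}")
    t = rows["t"].to_numpy(dtype=float)
    x = rows["x"].to_numpy(dtype=float) + (display - 1) * geometry.width
    y = rows["y"].to_numpy(dtype=float)
    order = np.argsort(t, kind="stable")
    return GazeStream(t=t[order], x=x[order], y=y[order], display=display[order], rate=rate)


def gaze_table_from_streams(entries, geometry: DisplayGeometry, rate: float) -> GazeTable:
    """Build a long-format :class:`GazeTable` from ``(reader_id, case_id, stream)``.

    Streams are assumed to be in global coordinates; x is mapped back to
    per-display local coordinates for storage.
    """
    parts = []
    for reader_id, case_id, stream in entries:
        local_x = stream.x - (stream.display - 1) * geometry.width
        parts.append(
            pd.DataFrame(
                {
                    "reader_id": reader_id,
                    "case_id": case_id,
                    "t": stream.t,
                    "x": local_x,
                    "y": stream.y,
                    "display": stream.display,
                }
            )
        )
    if parts:
        frame = pd.concat(parts, ignore_index=True)
    else:
        frame = pd.DataFrame({c: [] for c in GAZE_COLUMNS})
    return GazeTable(frame=frame, rate=rate, geometry=geometry)
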
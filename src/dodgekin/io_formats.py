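"""Reading and writing marker trajectories, configurations and result tables.

Two text dialects are supported for marker data:

* ``trc`` — the OpenSim-style tab-separated marker format with the usual
  five-line header (``PathFileType`` / ``DataRate`` rows, marker-name row,
  per-axis column row).
* ``csv`` — one row per frame with columns
  ``time, <marker>_x, <marker>_y, <marker>_z``.

The canonical in-memory unit is meters; TRC files declaring ``mm`` are
converted on load.  The canonical axis convention is right-handed with
AP (anterior-posterior) = +x forward, ML (medio-lateral) = +y leftward,
vertical = +z up.  Missing samples are carried as NaN, never as silent
zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "TrajectorySet",
    "AcquisitionConfig",
    "TrajectoryFormatError",
    "TrajectoryParseError",
    "read_trajectories",
    "write_trajectories",
    "interpolate_gaps",
    "read_config",
    "write_config",
]

_UNIT_SCALE = {"m": 1.0, "mm": 0.001, "cm": 0.01}


class TrajectoryFormatError(ValueError):
    """Raised when a file does not follow the declared dialect."""


class TrajectoryParseError(ValueError):
    """Raised when a data line cannot be parsed; carries the line number."""


@dataclass
class AcquisitionConfig:
    """Acquisition metadata: sampling rate, axis roles and length unit."""

    sample_rate: float = 100.0
    axes: dict = field(default_factory=lambda: {"ap": "x", "ml": "y", "vertical": "z"})
    units: str = "m"

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        roles = list(self.axes.values())
        if len(set(roles)) != 3:
            raise ValueError("axis roles must map to three distinct axes")
        if self.units not in _UNIT_SCALE:
            raise ValueError(f"unsupported unit {self.units!r}")


@dataclass
class TrajectorySet:
    """Time-indexed 3D positions of named markers.

    Attributes
    ----------
    marker_names:
        Marker identifiers, one per tracked point.
    positions:
        Array of shape ``(frame_count, n_markers, 3)`` in meters.  Missing
        samples are NaN.
    sample_rate:
        Sampling frequency in Hz.
    """

    marker_names: list
    positions: np.ndarray
    sample_rate: float = 100.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (frames, markers, 3)")
        if self.positions.shape[1] != len(self.marker_names):
            raise ValueError("positions second axis must match marker_names")
        if len(set(self.marker_names)) != len(self.marker_names):
            raise ValueError("marker names must be unique")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def frame_count(self) -> int:
        return self.positions.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.frame_count) / self.sample_rate

    def marker(self, name: str) -> np.ndarray:
        """Positions of one marker, shape ``(frame_count, 3)``."""
        try:
            i = self.marker_names.index(name)
        except ValueError:
            raise KeyError(f"marker {name!r} not in trajectory set") from None
        return self.positions[:, i, :]

    def markers(self, names) -> np.ndarray:
        """Positions of several markers, shape ``(frame_count, len(names), 3)``."""
        idx = [self.marker_names.index(n) for n in names]
        return self.positions[:, idx, :]

    def window(self, start: int, stop: int) -> "TrajectorySet":
        """Frame slice ``[start, stop)`` as a new set (data is a view)."""
        return TrajectorySet(self.marker_names, self.positions[start:stop],
                             self.sample_rate)

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(frames, markers)`` mask of missing samples."""
        return np.isnan(self.positions).any(axis=2)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("trc", "csv"):
        return suffix
    raise TrajectoryFormatError(f"cannot infer format from {path.name!r}")


def read_trajectories(path, format: str | None = None) -> TrajectorySet:
    """Read a marker trajectory file in the ``trc`` or ``csv`` dialect.

    Coordinates are converted to meters; blank fields become NaN.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    text = path.read_text()
    if fmt == "trc":
        return _read_trc(text)
    if fmt == "csv":
        return _read_csv(text)
    raise TrajectoryFormatError(f"unknown format {fmt!r}")


def write_trajectories(ts: TrajectorySet, path, format: str | None = None) -> None:
    """Write ``ts`` so that :func:`read_trajectories` round-trips losslessly
    to better than 1e-9 m."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "trc":
        path.write_text(_format_trc(ts))
    elif fmt == "csv":
        path.write_text(_format_csv(ts))
    else:
        raise TrajectoryFormatError(f"unknown format {fmt!r}")


def _fmt_value(v: float) -> str:
    return "" if np.isnan(v) else format(v, ".12g")


def _parse_value(tok: str, lineno: int) -> float:
    tok = tok.strip()
    if tok == "":
        return np.nan
    try:
        return float(tok)
    except ValueError:
        raise TrajectoryParseError(f"line {lineno}: cannot parse {tok!r}") from None


# ---------------------------------------------------------------- CSV dialect

def _format_csv(ts: TrajectorySet) -> str:
    header = ["time"]
    for name in ts.marker_names:
        header += [f"{name}_x", f"{name}_y", f"{name}_z"]
    lines = [",".join(header)]
    # sample rate is recoverable from the time column
    times = ts.times
    for f in range(ts.frame_count):
        row = [format(times[f], ".12g")]
        row += [_fmt_value(v) for v in ts.positions[f].ravel()]
        lines.append(",".join(row))
    return "\n".join(lines) + "\n"


def _read_csv(text: str) -> TrajectorySet:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise TrajectoryFormatError("empty CSV file")
    header = [h.strip() for h in lines[0].split(",")]
    if not header or header[0] != "time":
        raise TrajectoryFormatError("CSV header must start with 'time'")
    coord_cols = header[1:]
    if len(coord_cols) % 3 != 0:
        raise TrajectoryFormatError("CSV must have three columns per marker")
    marker_names = []
    for i in range(0, len(coord_cols), 3):
        triple = coord_cols[i:i + 3]
        bases = {c.rsplit("_", 1)[0] for c in triple}
        suffixes = [c.rsplit("_", 1)[1] for c in triple]
        if len(bases) != 1 or suffixes != ["x", "y", "z"]:
            raise TrajectoryFormatError(f"bad marker columns {triple}")
        marker_names.append(triple[0].rsplit("_", 1)[0])
    n_cols = len(header)
    rows, times = [], []
    for lineno, ln in enumerate(lines[1:], start=2):
        toks = ln.split(",")
        if len(toks) != n_cols:
            raise TrajectoryParseError(
                f"line {lineno}: expected {n_cols} columns, got {len(toks)}")
        times.append(_parse_value(toks[0], lineno))
        rows.append([_parse_value(t, lineno) for t in toks[1:]])
    positions = np.asarray(rows).reshape(len(rows), len(marker_names), 3)
    times = np.asarray(times)
    if len(times) > 1:
        dt = np.median(np.diff(times))
        sample_rate = 1.0 / dt if dt > 0 else 100.0
    else:
        sample_rate = 100.0
    return TrajectorySet(marker_names, positions, sample_rate)


# ---------------------------------------------------------------- TRC dialect

def _format_trc(ts: TrajectorySet, name: str = "trajectories.trc") -> str:
    n, m = ts.frame_count, len(ts.marker_names)
    rate = format(ts.sample_rate, ".12g")
    lines = [
        f"PathFileType\t4\t(X/Y/Z)\t{name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\t"
        "OrigDataStartFrame\tOrigNumFrames",
        f"{rate}\t{rate}\t{n}\t{m}\tm\t{rate}\t1\t{n}",
        "Frame#\tTime\t" + "\t\t\t".join(ts.marker_names) + ("\t\t" if m else ""),
        "\t\t" + "\t".join(
            f"X{i}\tY{i}\tZ{i}" for i in range(1, m + 1)),
        "",
    ]
    times = ts.times
    for f in range(n):
        row = [str(f + 1), format(times[f], ".12g")]
        row += [_fmt_value(v) for v in ts.positions[f].ravel()]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def _read_trc(text: str) -> TrajectorySet:
    lines = text.splitlines()
    if len(lines) < 5 or not lines[0].startswith("PathFileType"):
        raise TrajectoryFormatError("not a TRC file (missing PathFileType header)")
    keys = lines[1].split("\t")
    vals = lines[2].split("\t")
    meta = dict(zip(keys, vals))
    try:
        sample_rate = float(meta["DataRate"])
        n_markers = int(meta["NumMarkers"])
        units = meta["Units"].strip().lower()
    except (KeyError, ValueError) as exc:
        raise TrajectoryFormatError(f"malformed TRC metadata: {exc}") from exc
    if units not in _UNIT_SCALE:
        raise TrajectoryFormatError(f"unsupported TRC units {units!r}")
    scale = _UNIT_SCALE[units]
    name_row = lines[3].split("\t")
    marker_names = [t.strip() for t in name_row[2:] if t.strip()]
    if len(marker_names) != n_markers:
        raise TrajectoryFormatError(
            f"header declares {n_markers} markers, name row has {len(marker_names)}")
    n_cols = 2 + 3 * n_markers
    rows = []
    for lineno, ln in enumerate(lines[5:], start=6):
        if not ln.strip():
            continue
        toks = ln.split("\t")
        if len(toks) != n_cols:
            raise TrajectoryParseError(
                f"line {lineno}: expected {n_cols} columns, got {len(toks)}")
        rows.append([_parse_value(t, lineno) for t in toks[2:]])
    positions = np.asarray(rows, dtype=float)
    positions = positions.reshape(len(rows), n_markers, 3) * scale
    return TrajectorySet(marker_names, positions, sample_rate)


# ------------------------------------------------------------ gap handling

def interpolate_gaps(ts: TrajectorySet, max_gap: int = 5) -> TrajectorySet:
    """Linearly interpolate missing samples with gaps of at most ``max_gap``
    frames.  Longer gaps (or missing data at the edges) are left missing so
    downstream code can reject the affected trial.
    """
    pos = ts.positions.copy()
    n = ts.frame_count
    for m in range(pos.shape[1]):
        bad = np.isnan(pos[:, m, :]).any(axis=1)
        if not bad.any() or bad.all():
            continue
        # contiguous runs of missing frames
        starts = np.flatnonzero(bad & ~np.roll(bad, 1))
        if bad[0]:
            starts = np.concatenate(([0], starts[1:] if starts.size and starts[0] == 0 else starts))
        for s in starts:
            e = s
            while e < n and bad[e]:
                e += 1
            gap = e - s
            if s == 0 or e == n or gap > max_gap:
                continue
            left, right = pos[s - 1, m], pos[e, m]
            w = (np.arange(1, gap + 1) / (gap + 1))[:, None]
            pos[s:e, m] = left * (1 - w) + right * w
    return TrajectorySet(list(ts.marker_names), pos, ts.sample_rate)


# ------------------------------------------------------------ config files

def read_config(path) -> dict:
    """Load a YAML configuration file as a dictionary."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
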
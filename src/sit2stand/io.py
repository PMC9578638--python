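"""Readers and writers for sensor streams, kinematics and episode labels.

Canonical stream format is plain CSV with a named header
(time_s, ax, ay, az, gx, gy, gz) in SI units; a spreadsheet (xlsx) adapter
reads the same columns from a sheet, since deployed sensors often export
spreadsheets.  Raw recordings in g-units (device range +/-4 g) are
converted at ingest with ``units="g_units"``.  Timestamps that jitter by
more than 10% of the median step are resampled to a uniform grid by linear
interpolation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ekf import InertialStream, SegmentKinematics
from .errors import InvalidArgumentError, SchemaError
from .forward_model import GRAVITY, SensorGeometry
from .segmentation import Episode

STREAM_COLUMNS = ("time_s", "ax", "ay", "az", "gx", "gy", "gz")
_TIME_ALIASES = ("time_s", "time", "t")


def _load_table(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"file not found: {path}")
    fmt = fmt or ("xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv")
    try:
        df = pd.read_excel(path) if fmt == "xlsx" else pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - delegated parsing
        raise SchemaError(f"could not parse {path}: {exc}") from exc
    if df.empty:
        raise SchemaError(f"empty input file: {path}")
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _time_column(df: pd.DataFrame, path: str | Path) -> str:
    for alias in _TIME_ALIASES:
        if alias in df.columns:
            return alias
    raise SchemaError(f"{path}: missing time column (expected one of {_TIME_ALIASES})")


def _resample_if_jittery(t: np.ndarray, channels: dict[str, np.ndarray]):
    steps = np.diff(t)
    dt = float(np.median(steps))
    if dt <= 0:
        raise SchemaError("timestamps are not increasing")
    if np.any(np.abs(steps - dt) > 0.1 * dt):
        t_u = t[0] + dt * np.arange(len(t))
        channels = {k: np.interp(t_u, t, v) for k, v in channels.items()}
        t = t_u
    return t, channels


def read_stream(
    path: str | Path,
    placement: str,
    L: float,
    fmt: str | None = None,
    units: str = "si",
    axis_flip: tuple[int, int, int] = (1, 1, 1),
    gravity: float = GRAVITY,
) -> InertialStream:
    """Read one sensor stream from CSV or XLSX into SI units.

    ``units="g_units"`` multiplies accelerometer channels by g;
    ``axis_flip`` applies per-axis sign flips (x, y, z) to accommodate
    mounting orientation, affecting accel and gyro alike.
    """
    if units not in ("si", "g_units"):
        raise InvalidArgumentError(f"units must be 'si' or 'g_units', got {units!r}")
    df = _load_table(path, fmt)
    tcol = _time_column(df, path)
    for col in STREAM_COLUMNS[1:]:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    t = df[tcol].to_numpy(dtype=float)
    ch = {c: df[c].to_numpy(dtype=float) for c in STREAM_COLUMNS[1:]}
    t, ch = _resample_if_jittery(t, ch)
    scale = gravity if units == "g_units" else 1.0
    fx, fy, fz = axis_flip
    return InertialStream(
        t=t,
        ax=ch["ax"] * scale * fx, ay=ch["ay"] * scale * fy, az=ch["az"] * scale * fz,
        gx=ch["gx"] * fx, gy=ch["gy"] * fy, gz=ch["gz"] * fz,
        placement=placement,  # type: ignore[arg-type]
        geometry=SensorGeometry(L=L, gravity=gravity),
    )


def write_stream(stream: InertialStream, path: str | Path) -> None:
    """Write a stream to the canonical CSV format (SI units)."""
    pd.DataFrame(
        {
            "time_s": stream.t, "ax": stream.ax, "ay": stream.ay, "az": stream.az,
            "gx": stream.gx, "gy": stream.gy, "gz": stream.gz,
        }
    ).to_csv(path, index=False, float_format="%.9g")


def _looks_like_degrees(theta: np.ndarray) -> bool | None:
    """Range heuristic: angles spanning tens of units are degrees, spans
    well under ~7 are radians; in between is ambiguous (None)."""
    span = float(np.nanmax(np.abs(theta)))
    if span > 2.5 * np.pi:
        return True
    if span <= 0.6 * np.pi:
        return False
    return None


def read_reference(
    path: str | Path,
    fmt: str | None = None,
    units: str | None = None,
) -> dict[str, SegmentKinematics]:
    """Read exported reference (motion-capture) kinematics.

    Expects columns ``theta_X``, ``omega_X``, ``alpha_X`` for each segment
    X in {S, T, B} plus a time column.  ``units`` may be "deg" or "rad";
    when omitted, a range heuristic decides, and genuinely ambiguous files
    raise rather than guess.
    """
    df = _load_table(path, fmt)
    tcol = _time_column(df, path)
    t = df[tcol].to_numpy(dtype=float)
    out: dict[str, SegmentKinematics] = {}
    for seg in ("S", "T", "B"):
        cols = [f"theta_{seg}", f"omega_{seg}", f"alpha_{seg}"]
        if not all(c in df.columns for c in cols):
            continue
        theta = df[cols[0]].to_numpy(dtype=float)
        omega = df[cols[1]].to_numpy(dtype=float)
        alpha = df[cols[2]].to_numpy(dtype=float)
        if units is None:
            guess = _looks_like_degrees(theta)
            if guess is None:
                raise SchemaError(
                    f"{path}: cannot tell degrees from radians for segment {seg}; "
                    "pass units='deg' or units='rad'"
                )
            in_degrees = guess
        else:
            if units not in ("deg", "rad"):
                raise InvalidArgumentError(f"units must be 'deg' or 'rad', got {units!r}")
            in_degrees = units == "deg"
        if in_degrees:
            theta, omega, alpha = np.radians(theta), np.radians(omega), np.radians(alpha)
        out[seg] = SegmentKinematics(segment=seg, t=t.copy(), theta=theta,  # type: ignore[arg-type]
                                     omega=omega, alpha=alpha)
    if not out:
        raise SchemaError(f"{path}: no segment kinematics columns found")
    return out


def write_kinematics(kin: dict[str, SegmentKinematics], path: str | Path) -> None:
    """Write one or more segments' kinematics to a single CSV."""
    first = next(iter(kin.values()))
    data: dict[str, np.ndarray] = {"time_s": first.t}
    for seg, k in kin.items():
        data[f"theta_{seg}"] = k.theta
        data[f"omega_{seg}"] = k.omega
        data[f"alpha_{seg}"] = k.alpha
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


def read_kinematics(path: str | Path, fmt: str | None = None) -> dict[str, SegmentKinematics]:
    """Read kinematics written by :func:`write_kinematics` (radians)."""
    return read_reference(path, fmt=fmt, units="rad")


def write_episodes(episodes: list[Episode], path: str | Path, dt: float | None = None) -> None:
    """Serialize labeled episodes to a JSON list."""
    Path(path).write_text(json.dumps([ep.to_dict(dt) for ep in episodes], indent=2))


def read_episodes(path: str | Path) -> list[Episode]:
    records = json.loads(Path(path).read_text())
    return [Episode(r["start"], r["end"], r["label"]) for r in records]


def write_labels(labels: np.ndarray, path: str | Path, dt: float) -> None:
    """Per-sample label sidecar CSV (time_s, label)."""
    pd.DataFrame({"time_s": np.arange(len(labels)) * dt, "label": labels}).to_csv(
        path, index=False, float_format="%.9g"
    )
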
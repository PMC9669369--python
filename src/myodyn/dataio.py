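"""Uniform time-series tables on disk and in memory.

Every signal in the package -- raw sEMG, envelopes, joint angles, tracking
errors -- is a :class:`TimeSeriesTable`: a set of equal-length named channels
on a uniform time grid ``t0 + k/rate``.  On disk a table is a plain CSV with
one header line, an explicit ``t`` column in seconds, and an optional leading
``# rate=<Hz>`` comment that preserves the sampling rate exactly.  Angles are
stored in degrees, times in seconds, sEMG in millivolts.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesTable",
    "read_timeseries",
    "write_timeseries",
    "DataIOError",
    "MissingFileError",
    "RaggedColumnsError",
    "NonUniformGridError",
    "NonNumericDataError",
    "InvalidTableError",
]

_GRID_RTOL = 1e-6


class DataIOError(Exception):
    """Base class for table I/O failures."""


class MissingFileError(DataIOError):
    """Input file does not exist."""


class RaggedColumnsError(DataIOError):
    """Rows do not all have the same number of cells."""


class NonUniformGridError(DataIOError):
    """Explicit time column is not a uniform grid."""


class NonNumericDataError(DataIOError):
    """A data cell could not be parsed as a real number."""


class InvalidTableError(DataIOError):
    """In-memory table violates a TimeSeriesTable invariant."""


@dataclass
class TimeSeriesTable:
    """Equal-length named channels sampled uniformly at ``rate`` Hz.

    Parameters
    ----------
    rate : float
        Sampling rate in Hz, > 0.
    data : pandas.DataFrame
        One column per channel; the implied time of row ``k`` is
        ``t0 + k / rate``.
    t0 : float, optional
        Time of the first sample in seconds.
    """

    rate: float
    data: pd.DataFrame
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.rate) or self.rate <= 0:
            raise InvalidTableError(f"rate must be positive, got {self.rate}")
        if self.data.shape[1] == 0:
            raise InvalidTableError("table must have at least one channel")
        if self.data.shape[0] < 1:
            raise InvalidTableError("channels must have length >= 1")
        names = list(self.data.columns)
        if len(set(names)) != len(names):
            raise InvalidTableError(f"duplicate channel names: {names}")
        if any((not isinstance(nm, str)) or nm == "" for nm in names):
            raise InvalidTableError(f"channel names must be nonempty strings: {names}")
        for nm in names:
            if not np.issubdtype(self.data[nm].dtype, np.number):
                raise NonNumericDataError(f"channel {nm!r} is not numeric")

    # -- views ------------------------------------------------------------

    @property
    def n(self) -> int:
        return int(self.data.shape[0])

    @property
    def channel_names(self) -> list[str]:
        return list(self.data.columns)

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate

    def channel(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)

    def values(self) -> np.ndarray:
        """All channels as an (n, n_channels) float array."""
        return self.data.to_numpy(dtype=float)

    def with_data(self, arrays: dict[str, np.ndarray], rate: float | None = None) -> "TimeSeriesTable":
        """New table with the same grid origin, replaced channels/rate."""
        return TimeSeriesTable(
            rate=self.rate if rate is None else rate,
            data=pd.DataFrame(arrays),
            t0=self.t0,
        )


def _check_uniform(t: np.ndarray, declared_rate: float | None) -> tuple[float, float]:
    """Validate a time column; return (rate, t0)."""
    t0 = float(t[0])
    if len(t) == 1:
        if declared_rate is None:
            raise NonUniformGridError(
                "single-row table needs a '# rate=' header to define its rate"
            )
        return declared_rate, t0
    dt = np.diff(t)
    dt0 = dt[0]
    if dt0 <= 0 or not np.allclose(dt, dt0, rtol=_GRID_RTOL, atol=0.0):
        raise NonUniformGridError(
            f"time column is not a uniform increasing grid (dt range "
            f"[{dt.min():g}, {dt.max():g}])"
        )
    rate = declared_rate if declared_rate is not None else 1.0 / dt0
    # declared rate must agree with the observed grid
    if declared_rate is not None and not np.isclose(1.0 / dt0, declared_rate, rtol=1e-6):
        raise NonUniformGridError(
            f"declared rate {declared_rate} Hz conflicts with time column "
            f"spacing {dt0} s"
        )
    return rate, t0


def read_timeseries(path: str | Path) -> TimeSeriesTable:
    """Read a CSV time-series table.

    The file may start with comment lines ``# rate=<Hz>`` and ``# t0=<s>``.
    If a column named ``t`` is present it must be a uniform grid (relative
    tolerance 1e-6) consistent with any declared rate.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"no such file: {path}")
    declared_rate: float | None = None
    declared_t0: float | None = None
    body_lines: list[str] = []
    with open(path, "r", newline="") as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("#"):
                meta = stripped.lstrip("#").strip()
                if meta.startswith("rate="):
                    declared_rate = float(meta.split("=", 1)[1])
                elif meta.startswith("t0="):
                    declared_t0 = float(meta.split("=", 1)[1])
                continue
            if stripped:
                body_lines.append(line)
    if not body_lines:
        raise NonNumericDataError(f"{path}: no header or data rows")
    header = body_lines[0]
    ncols = header.count(",") + 1
    for i, line in enumerate(body_lines[1:], start=2):
        if line.strip().count(",") + 1 != ncols:
            raise RaggedColumnsError(f"{path}: row {i} has a different cell count")
    try:
        df = pd.read_csv(io.StringIO("".join(body_lines)), float_precision="round_trip")
    except pd.errors.ParserError as exc:  # pragma: no cover - ragged caught above
        raise RaggedColumnsError(str(exc)) from exc
    if df.shape[0] < 1:
        raise NonNumericDataError(f"{path}: table has no data rows")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise NonNumericDataError(f"{path}: column {col!r} contains non-numeric cells")
    if "t" in df.columns:
        t = df["t"].to_numpy(dtype=float)
        rate, t0 = _check_uniform(t, declared_rate)
        df = df.drop(columns=["t"])
        if df.shape[1] == 0:
            raise NonNumericDataError(f"{path}: no data channels besides time")
    else:
        if declared_rate is None:
            raise NonUniformGridError(
                f"{path}: no 't' column and no '# rate=' header"
            )
        rate = declared_rate
        t0 = 0.0
    if declared_t0 is not None:
        t0 = declared_t0
    return TimeSeriesTable(rate=rate, data=df, t0=t0)


def write_timeseries(table: TimeSeriesTable, path: str | Path) -> Path:
    """Write a table as CSV with a ``# rate=`` header and explicit ``t`` column.

    Values are written with 17 significant digits so that re-reading
    reproduces float64 channels bit-identically.
    """
    if not isinstance(table, TimeSeriesTable):
        raise InvalidTableError("write_timeseries expects a TimeSeriesTable")
    path = Path(path)
    out = table.data.copy()
    out.insert(0, "t", table.times())
    try:
        with open(path, "w", newline="") as fh:
            fh.write(f"# rate={table.rate!r}\n")
            fh.write(f"# t0={table.t0!r}\n")
            out.to_csv(fh, index=False, float_format="%.17g")
    except OSError as exc:
        raise DataIOError(f"cannot write {path}: {exc}") from exc
    return path
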
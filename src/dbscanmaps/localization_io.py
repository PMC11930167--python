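"""Reading and writing SMLM localization tables and map products.

Single-molecule localization microscopy (SMLM) reconstructions are point
clouds: one row per localized emitter, with coordinates in nanometres and,
depending on the reconstruction software, extra columns such as the frame
index and the localization precision.  This module holds the core in-memory
point-cloud type (:class:`LocalizationTable`) and the delimited-text readers
and writers used by every analysis in the package.

All coordinates are stored internally in nanometres.  Readers convert on
input using a per-dialect unit declaration; built-in dialects cover
ThunderSTORM-style headers (``"x [nm]"``) and plain ``"x"``/``"y"`` headers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger("dbscanmaps")

__all__ = [
    "LocalizationTable",
    "Dialect",
    "BUILTIN_DIALECTS",
    "read_localizations",
    "write_localizations",
    "write_map_stack",
    "read_map_stack",
    "FormatError",
    "ParseError",
]


class FormatError(ValueError):
    """A required column could not be resolved in an input table."""


class ParseError(ValueError):
    """A cell in an input table could not be parsed as a number."""


@dataclass(frozen=True)
class LocalizationTable:
    """A 2D SMLM point cloud, coordinates in nm.

    Parameters
    ----------
    x, y
        Coordinates of the localizations in nanometres.
    frame
        Optional acquisition frame index per localization.
    precision
        Optional localization precision (nm) per localization.
    """

    x: np.ndarray
    y: np.ndarray
    frame: Optional[np.ndarray] = None
    precision: Optional[np.ndarray] = None

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("localization coordinates must be finite")
        for name in ("frame", "precision"):
            col = getattr(self, name)
            if col is not None:
                col = np.asarray(col)
                if col.shape != x.shape:
                    raise ValueError(f"{name} column length mismatch")
                object.__setattr__(self, name, col)
        if self.frame is not None and np.any(np.asarray(self.frame) < 0):
            raise ValueError("frame indices must be nonnegative")

    def __len__(self) -> int:
        return self.x.size

    @property
    def count(self) -> int:
        return self.x.size

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) coordinate array in nm."""
        return np.column_stack([self.x, self.y])

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """Axis-aligned bounding rectangle ``(xmin, xmax, ymin, ymax)`` in nm.

        Raises :class:`ValueError` for an empty table.
        """
        if self.count == 0:
            raise ValueError("empty table has no bounds")
        return (
            float(self.x.min()),
            float(self.x.max()),
            float(self.y.min()),
            float(self.y.max()),
        )

    @property
    def is_degenerate(self) -> bool:
        """True when the bounding rectangle has zero area (all points on a line
        parallel to an axis, or fewer than 2 points)."""
        if self.count < 2:
            return True
        xmin, xmax, ymin, ymax = self.bounds
        return (xmax - xmin) <= 0 or (ymax - ymin) <= 0


@dataclass(frozen=True)
class Dialect:
    """Column-mapping specification for delimited localization tables.

    ``*_names`` are candidate header names, matched case-insensitively after
    stripping whitespace.  ``unit_scale`` converts coordinates to nm (e.g.
    1000 for micron input).  ``x_index``/``y_index`` allow headerless files.
    """

    name: str = "custom"
    x_names: Sequence[str] = ("x [nm]", "x", "xc", "x_nm", "xnm")
    y_names: Sequence[str] = ("y [nm]", "y", "yc", "y_nm", "ynm")
    frame_names: Sequence[str] = ("frame", "frame number", "t")
    precision_names: Sequence[str] = (
        "uncertainty [nm]", "uncertainty_xy [nm]", "precision [nm]",
        "precision", "uncertainty",
    )
    z_names: Sequence[str] = ("z [nm]", "z", "zc")
    unit_scale: float = 1.0
    delimiter: Optional[str] = None
    x_index: Optional[int] = None
    y_index: Optional[int] = None


BUILTIN_DIALECTS: dict[str, Dialect] = {
    "thunderstorm": Dialect(
        name="thunderstorm",
        x_names=("x [nm]",),
        y_names=("y [nm]",),
        frame_names=("frame",),
        precision_names=("uncertainty [nm]", "uncertainty_xy [nm]"),
    ),
    "plain": Dialect(
        name="plain",
        x_names=("x",),
        y_names=("y",),
    ),
    "auto": Dialect(name="auto"),
}

_SNIFF_DELIMITERS = (",", "\t", ";")


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", newline="") as fh:
        first = fh.readline()
    for d in _SNIFF_DELIMITERS:
        if d in first:
            return d
    return ","


def _resolve_column(columns: Sequence[str], candidates: Sequence[str]) -> Optional[str]:
    normalized = {str(c).strip().lower(): c for c in columns}
    for cand in candidates:
        if cand.strip().lower() in normalized:
            return normalized[cand.strip().lower()]
    return None


def read_localizations(
    path: Union[str, Path],
    dialect: Union[str, Dialect] = "auto",
) -> LocalizationTable:
    """Read a delimited localization table into a :class:`LocalizationTable`.

    The delimiter is sniffed (comma, then tab, then semicolon) unless the
    dialect declares one.  Row order is preserved.  A ``z`` column, if
    present, is read but ignored by all analyses (with a logged warning):
    the map and lacunarity methods here are strictly 2D.

    Raises
    ------
    FormatError
        If the x or y column cannot be resolved.
    ParseError
        If a coordinate cell is not numeric (the error names the row).
    """
    if isinstance(dialect, str):
        try:
            dialect = BUILTIN_DIALECTS[dialect]
        except KeyError:
            raise ValueError(f"unknown dialect {dialect!r}") from None
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    delim = dialect.delimiter or _sniff_delimiter(path)

    has_indices = dialect.x_index is not None and dialect.y_index is not None
    df = pd.read_csv(
        path, sep=delim, header=None if has_indices else 0, dtype=str,
        skip_blank_lines=True,
    )
    if has_indices:
        try:
            xcol = df.columns[dialect.x_index]
            ycol = df.columns[dialect.y_index]
        except IndexError:
            raise FormatError("x/y column index out of range") from None
        fcol = pcol = zcol = None
    else:
        cols = list(df.columns)
        xcol = _resolve_column(cols, dialect.x_names)
        ycol = _resolve_column(cols, dialect.y_names)
        if xcol is None or ycol is None:
            raise FormatError(
                f"could not resolve x/y columns among {cols!r} "
                f"with dialect {dialect.name!r}"
            )
        fcol = _resolve_column(cols, dialect.frame_names)
        pcol = _resolve_column(cols, dialect.precision_names)
        zcol = _resolve_column(cols, dialect.z_names)

    def _numeric(col, what):
        vals = pd.to_numeric(df[col], errors="coerce")
        raw = df[col]
        bad = vals.isna() & raw.notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ParseError(f"non-numeric {what} value {raw.iloc[row]!r} in data row {row}")
        if vals.isna().any():
            row = int(np.nonzero(vals.isna().to_numpy())[0][0])
            raise ParseError(f"missing {what} value in data row {row}")
        return vals.to_numpy(dtype=float)

    if len(df) == 0:
        return LocalizationTable(x=np.empty(0), y=np.empty(0))

    x = _numeric(xcol, "x") * dialect.unit_scale
    y = _numeric(ycol, "y") * dialect.unit_scale
    frame = _numeric(fcol, "frame").astype(int) if fcol is not None else None
    precision = _numeric(pcol, "precision") * dialect.unit_scale if pcol is not None else None
    if zcol is not None:
        logger.warning(
            "input %s has a z column; analyses in this package are 2D and ignore it",
            path,
        )
    table = LocalizationTable(x=x, y=y, frame=frame, precision=precision)
    if table.count >= 2 and table.is_degenerate:
        logger.warning("degenerate table %s: bounding rectangle has zero area", path)
    return table


def write_localizations(table: LocalizationTable, path: Union[str, Path]) -> None:
    """Write a table as CSV with ThunderSTORM-style headers, coordinates in nm."""
    data = {"x [nm]": table.x, "y [nm]": table.y}
    if table.frame is not None:
        data["frame"] = table.frame
    if table.precision is not None:
        data["uncertainty [nm]"] = table.precision
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


def write_map_stack(stack, path: Union[str, Path]) -> None:
    """Write a map stack in long format: ``epsilon_nm, N, metric, value``.

    One row per (grid cell, metric); NaN values are written as empty cells so
    the product stays plain delimited text.
    """
    eps = np.asarray(stack.grid.epsilons, dtype=float)
    ns = np.asarray(stack.grid.Ns, dtype=int)
    rows = []
    for metric in stack.METRICS:
        m = stack.maps[metric]
        for i, e in enumerate(eps):
            for j, n in enumerate(ns):
                rows.append((e, int(n), metric, m[i, j]))
    df = pd.DataFrame(rows, columns=["epsilon_nm", "N", "metric", "value"])
    df.to_csv(path, index=False, float_format="%.12g", na_rep="")


def read_map_stack(path: Union[str, Path]):
    """Read a long-format map stack written by :func:`write_map_stack`."""
    from .clustering import GridSpec, MapStack

    df = pd.read_csv(path)
    required = {"epsilon_nm", "N", "metric", "value"}
    if not required.issubset(df.columns):
        raise FormatError(f"map stack file {path} missing columns {required - set(df.columns)}")
    eps = np.unique(df["epsilon_nm"].to_numpy(dtype=float))
    ns = np.unique(df["N"].to_numpy(dtype=int))
    grid = GridSpec(epsilons=eps, Ns=ns)
    maps = {}
    ei = {e: i for i, e in enumerate(eps)}
    ni = {n: j for j, n in enumerate(ns)}
    for metric, sub in df.groupby("metric"):
        m = np.full((eps.size, ns.size), np.nan)
        ii = [ei[e] for e in sub["epsilon_nm"]]
        jj = [ni[n] for n in sub["N"]]
        m[ii, jj] = sub["value"].to_numpy(dtype=float)
        maps[metric] = m
    missing = set(MapStack.METRICS) - set(maps)
    if missing:
        raise FormatError(f"map stack file {path} missing metrics {missing}")
    if "n_clusters" in maps:
        nc = maps["n_clusters"]
        nc[np.isnan(nc)] = 0
        maps["n_clusters"] = nc
    return MapStack(grid=grid, maps=maps, metadata={"source": str(path)})
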
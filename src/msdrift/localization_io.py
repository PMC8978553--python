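"""Reading, validating and writing SMLM localization tables.

A localization table is the universal currency of single-molecule
localization microscopy (SMLM) pipelines: one row per fitted emitter
appearance, with the acquisition frame index, the fitted position in
nanometres, and (optionally) the per-localization precision reported by the
fitting software.  The canonical on-disk dialect here is a comma-separated
file with a header row using ThunderSTORM-style column names::

    frame, x [nm], y [nm][, z [nm]][, uncertainty [nm]]

Other header conventions can be bound via a ``column_map``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["LocalizationTable", "read_localizations", "write_localizations"]

CANONICAL_COLUMNS = {
    "frame": "frame",
    "x": "x [nm]",
    "y": "y [nm]",
    "z": "z [nm]",
    "precision": "uncertainty [nm]",
}


class LocalizationFormatError(ValueError):
    """A required column is missing or unparseable."""


class LocalizationValidationError(ValueError):
    """A record violates a table invariant (non-finite coordinate, etc.)."""


@dataclass
class LocalizationTable:
    """Per-localization records for one acquisition.

    Parameters
    ----------
    frame : integer array, shape (n,)
        1-based acquisition frame index of each localization.
    xy : float array, shape (n, dim)
        Coordinates in nm; ``dim`` is 2 or 3 (column order x, y[, z]).
    precision : float array, shape (n,), optional
        Per-localization precision (sigma) in nm; all entries > 0.
    """

    frame: np.ndarray
    xy: np.ndarray
    precision: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=np.int64)
        self.xy = np.atleast_2d(np.asarray(self.xy, dtype=float))
        if self.xy.size == 0:
            self.xy = self.xy.reshape(0, self.xy.shape[-1] if self.xy.ndim == 2 and self.xy.shape[-1] in (2, 3) else 2)
        if self.xy.ndim != 2 or self.xy.shape[1] not in (2, 3):
            raise LocalizationValidationError(
                f"coordinates must be (n, 2) or (n, 3); got {self.xy.shape}"
            )
        if self.frame.shape[0] != self.xy.shape[0]:
            raise LocalizationValidationError("frame and coordinate lengths differ")
        if not np.all(np.isfinite(self.xy)):
            bad = int(np.flatnonzero(~np.all(np.isfinite(self.xy), axis=1))[0])
            raise LocalizationValidationError(f"non-finite coordinate at row {bad}")
        if self.n and self.frame.min(initial=1) < 1:
            raise LocalizationValidationError("frame indices must be >= 1")
        if self.precision is not None:
            self.precision = np.asarray(self.precision, dtype=float)
            if self.precision.shape[0] != self.n:
                raise LocalizationValidationError("precision length differs from table")
            if self.n and not np.all(self.precision > 0):
                raise LocalizationValidationError("precision must be > 0 for every record")

    @property
    def dim(self) -> int:
        return int(self.xy.shape[1])

    @property
    def n(self) -> int:
        return int(self.xy.shape[0])

    @property
    def f_max(self) -> int:
        """Largest frame index present (0 for an empty table)."""
        return int(self.frame.max()) if self.n else 0

    def median_precision(self, default: float | None = None) -> float:
        """Median per-localization precision, or ``default`` if absent."""
        if self.precision is not None and self.n:
            return float(np.median(self.precision))
        if default is None:
            raise ValueError("table has no precision column and no default given")
        return float(default)

    def select(self, mask: np.ndarray) -> "LocalizationTable":
        """Row subset preserving order."""
        return LocalizationTable(
            self.frame[mask],
            self.xy[mask],
            None if self.precision is None else self.precision[mask],
        )

    def with_coordinates(self, xy: np.ndarray) -> "LocalizationTable":
        return LocalizationTable(self.frame.copy(), np.asarray(xy, float), None if self.precision is None else self.precision.copy())

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"frame": self.frame, "x [nm]": self.xy[:, 0], "y [nm]": self.xy[:, 1]}
        if self.dim == 3:
            cols["z [nm]"] = self.xy[:, 2]
        if self.precision is not None:
            cols["uncertainty [nm]"] = self.precision
        return pd.DataFrame(cols)


def read_localizations(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    unit_scale: float = 1.0,
    default_precision: float | None = None,
) -> LocalizationTable:
    """Read a localization CSV into a validated :class:`LocalizationTable`.

    Parameters
    ----------
    path
        CSV file with a header row.
    column_map
        Maps the logical names ``frame, x, y, z, precision`` to header names
        in the file.  Defaults to the canonical ThunderSTORM-style names.
        ``z`` and ``precision`` are optional: they are read iff the mapped
        column is present.
    unit_scale
        Multiplicative factor converting file coordinates to nm (e.g. 1000
        for a file in µm).  Applied to x, y, z and precision.
    default_precision
        If the file has no precision column, fill the table-level precision
        with this value (nm, after scaling is NOT applied — given in nm).
    """
    if unit_scale <= 0:
        raise ValueError("unit_scale must be > 0")
    names = dict(CANONICAL_COLUMNS)
    if column_map:
        names.update(column_map)
    df = pd.read_csv(path)
    for key in ("frame", "x", "y"):
        if names[key] not in df.columns:
            raise LocalizationFormatError(
                f"required column {names[key]!r} (for {key}) not found in {path}"
            )

    def _num(col: str) -> np.ndarray:
        raw = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        return raw

    frame = _num(names["frame"])
    if np.any(~np.isfinite(frame)):
        bad = int(np.flatnonzero(~np.isfinite(frame))[0])
        raise LocalizationFormatError(f"unparseable frame value at row {bad}")
    coords = [_num(names["x"]) * unit_scale, _num(names["y"]) * unit_scale]
    if names["z"] in df.columns:
        coords.append(_num(names["z"]) * unit_scale)
    xy = np.column_stack(coords) if len(df) else np.empty((0, len(coords)))
    precision = None
    if names["precision"] in df.columns:
        precision = _num(names["precision"]) * unit_scale
    elif default_precision is not None:
        precision = np.full(len(df), float(default_precision))
    return LocalizationTable(frame.astype(np.int64), xy, precision)


def write_localizations(table: LocalizationTable, path: str | Path) -> None:
    """Write a table as canonical CSV, re-readable by :func:`read_localizations`.

    Full float precision (repr round-trip) so write∘read is the identity.
    """
    table.to_dataframe().to_csv(path, index=False, float_format="%.17g")
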
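"""Reading and writing growth series as delimited text files.

CSV is the native format (TSV via the delimiter field).  Reading validates
the series rigorously and reports problems with the offending file and row;
writing emits full-precision decimals so a write/read round trip is exact.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import FileFormatError
from .series import GrowthSeries

__all__ = ["SeriesFileSpec", "read_series", "write_series"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SeriesFileSpec:
    """How to interpret (or produce) one series file."""

    path: str
    time_column: str = "time"
    biomass_column: str = "biomass"
    delimiter: str = ","
    decimal: str = "."


def _as_spec(spec) -> SeriesFileSpec:
    if isinstance(spec, SeriesFileSpec):
        return spec
    return SeriesFileSpec(path=os.fspath(spec))


def _numeric_column(df: pd.DataFrame, column: str, path: str) -> np.ndarray:
    if column not in df.columns:
        raise FileFormatError(
            f"{path}: missing column {column!r} (found: {list(df.columns)})"
        )
    values = pd.to_numeric(df[column], errors="coerce")
    bad = values.isna()
    if bad.any():
        # +2: one for the header line, one for 1-based numbering
        row = int(bad.idxmax()) + 2
        raise FileFormatError(
            f"{path}: non-numeric or missing {column!r} value at line {row}"
        )
    return values.to_numpy(dtype=float)


def read_series(spec, label: str | None = None) -> GrowthSeries:
    """Read and validate a series file.

    Out-of-order rows are sorted by time with a logged warning; duplicate
    times are rejected.  ``label`` defaults to the file's base name.
    """
    spec = _as_spec(spec)
    if not os.path.exists(spec.path):
        raise FileFormatError(f"series file not found: {spec.path}")
    try:
        df = pd.read_csv(spec.path, sep=spec.delimiter, decimal=spec.decimal)
    except Exception as exc:
        raise FileFormatError(f"{spec.path}: cannot parse: {exc}") from exc
    t = _numeric_column(df, spec.time_column, spec.path)
    w = _numeric_column(df, spec.biomass_column, spec.path)
    if np.unique(t).size != t.size:
        dup = t[np.argmax(np.diff(np.sort(t)) == 0)]
        raise FileFormatError(f"{spec.path}: duplicate time value {dup}")
    if np.any(np.diff(t) < 0):
        logger.warning("%s: times out of order; sorting", spec.path)
        order = np.argsort(t)
        t, w = t[order], w[order]
    if label is None:
        label = os.path.splitext(os.path.basename(spec.path))[0]
    try:
        return GrowthSeries(t, w, label=label)
    except Exception as exc:
        raise FileFormatError(f"{spec.path}: {exc}") from exc


def write_series(series: GrowthSeries, spec, force: bool = False) -> str:
    """Write a series as delimited text with header; full float precision.

    Refuses to overwrite an existing file unless ``force`` is set.  Returns
    the path written.
    """
    spec = _as_spec(spec)
    if os.path.exists(spec.path) and not force:
        raise FileFormatError(
            f"refusing to overwrite existing file {spec.path} (use force)"
        )
    df = pd.DataFrame({
        spec.time_column: series.times,
        spec.biomass_column: series.biomass,
    })
    df.to_csv(spec.path, sep=spec.delimiter, index=False,
              float_format="%.17g")
    return spec.path
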
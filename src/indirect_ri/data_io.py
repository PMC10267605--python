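"""Read, validate and filter LIS-style result exports.

A laboratory information system (LIS) export is modelled as a flat CSV
with one result per row: analyte label, numeric result, patient age, plus
whatever other columns the LIS emits (ignored).  Reading produces a
:class:`MeasurementSeries` — one analyte's positive numeric results with
its reporting resolution — together with a drop-log counting every row
that was excluded and why.

Age filtering is inclusive on both ends.  No per-patient deduplication is
performed: every result is analysed, so repeated measurements from the
same patient enter as correlated observations (a known property of
indirect reference-interval estimation on raw LIS dumps).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, EmptyInputError

__all__ = [
    "MeasurementSeries",
    "RecordFilter",
    "DropLog",
    "read_lis_csv",
    "write_lis_csv",
]

logger = logging.getLogger(__name__)

DEFAULT_COLUMNS = {"analyte": "analyte", "value": "value", "age": "age"}

_DECIMALS_CAP = 6


@dataclass(frozen=True)
class MeasurementSeries:
    """One analyte's numeric results, positive and rounded to `decimals`.

    Attributes
    ----------
    analyte_name : analyte label as reported by the LIS (e.g. "TSH")
    unit : reporting unit (e.g. "mIU/L", "pg/mL", "ng/dL")
    values : 1-d float array, every entry > 0
    decimals : rounding resolution of reported results (values are
        integer multiples of 10**-decimals within floating tolerance)
    """

    analyte_name: str
    unit: str
    values: np.ndarray
    decimals: int

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float).ravel()
        object.__setattr__(self, "values", arr)
        if arr.size == 0:
            raise EmptyInputError("measurement series has no values")
        if np.any(arr <= 0) or np.any(~np.isfinite(arr)):
            raise DomainError("all values must be positive and finite")
        if not (isinstance(self.decimals, (int, np.integer)) and self.decimals >= 0):
            raise DomainError(f"decimals must be a non-negative int, got {self.decimals}")
        scaled = arr * 10.0 ** self.decimals
        if not np.allclose(scaled, np.round(scaled), atol=1e-6):
            raise DomainError(
                f"values are not multiples of 10^-{self.decimals} "
                f"(reported rounding resolution)"
            )

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def resolution(self) -> float:
        return 10.0 ** (-self.decimals)


@dataclass(frozen=True)
class RecordFilter:
    """Row filter: inclusive age window, optional value window."""

    age_min: float
    age_max: float
    value_min: Optional[float] = None
    value_max: Optional[float] = None

    def __post_init__(self):
        if not self.age_min <= self.age_max:
            raise ConfigurationError("age_min must be <= age_max")
        if self.value_min is not None and self.value_min <= 0:
            raise ConfigurationError("value_min must be positive")
        if (
            self.value_min is not None
            and self.value_max is not None
            and not self.value_min < self.value_max
        ):
            raise ConfigurationError("value_min must be < value_max")


#: Adult filter used throughout: the study population is 18-87 years.
ADULT_FILTER = RecordFilter(age_min=18, age_max=87)


@dataclass
class DropLog:
    """Counts of rows excluded while reading, by reason."""

    total_rows: int = 0
    wrong_analyte: int = 0
    non_numeric: int = 0
    non_positive: int = 0
    age_missing: int = 0
    age_filtered: int = 0
    value_filtered: int = 0
    kept: int = 0

    def as_dict(self) -> Dict[str, int]:
        return dict(self.__dict__)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.as_dict(), fh, indent=2)


def _infer_decimals(raw: pd.Series) -> int:
    """Max number of decimal places among the textual values, capped at 6."""
    best = 0
    for s in raw.astype(str):
        m = re.match(r"^\s*[+-]?\d*\.(\d+)\s*$", s)
        if m:
            best = max(best, len(m.group(1).rstrip("0")) or 0)
        if best >= _DECIMALS_CAP:
            return _DECIMALS_CAP
    return best


def read_lis_csv(
    path,
    analyte: str,
    record_filter: RecordFilter = ADULT_FILTER,
    columns: Optional[Dict[str, str]] = None,
    unit: str = "",
    decimals: Optional[int] = None,
) -> Tuple[MeasurementSeries, DropLog]:
    """Read one analyte's results from a LIS CSV export.

    Parameters
    ----------
    path : CSV file (comma-separated, UTF-8, header row required)
    analyte : label to select in the analyte column
    record_filter : inclusive age bounds and optional value bounds
    columns : mapping from roles {"analyte", "value", "age"} to actual
        header names; defaults to those role names themselves
    unit : unit label to attach (not present in most LIS dumps)
    decimals : reporting resolution override; inferred from the data
        (max observed decimal places, capped at 6) when None

    Returns
    -------
    (series, drop_log) where drop_log counts excluded rows by reason.
    """
    cols = dict(DEFAULT_COLUMNS)
    cols.update(columns or {})
    df = pd.read_csv(path, dtype={cols["value"]: str})
    for role in ("analyte", "value", "age"):
        if cols[role] not in df.columns:
            raise ConfigurationError(
                f"required column '{cols[role]}' (role: {role}) "
                f"missing from {path}; found {list(df.columns)}"
            )

    log = DropLog(total_rows=len(df))
    sel = df[df[cols["analyte"]].astype(str) == analyte]
    log.wrong_analyte = len(df) - len(sel)

    raw_vals = sel[cols["value"]]
    vals = pd.to_numeric(raw_vals, errors="coerce")
    numeric = vals.notna()
    log.non_numeric = int((~numeric).sum())
    sel, vals, raw_vals = sel[numeric], vals[numeric], raw_vals[numeric]

    positive = vals > 0
    log.non_positive = int((~positive).sum())
    sel, vals, raw_vals = sel[positive], vals[positive], raw_vals[positive]

    ages = pd.to_numeric(sel[cols["age"]], errors="coerce")
    has_age = ages.notna()
    log.age_missing = int((~has_age).sum())
    sel, vals, ages, raw_vals = sel[has_age], vals[has_age], ages[has_age], raw_vals[has_age]

    in_age = (ages >= record_filter.age_min) & (ages <= record_filter.age_max)
    log.age_filtered = int((~in_age).sum())
    vals, raw_vals = vals[in_age], raw_vals[in_age]

    in_val = pd.Series(True, index=vals.index)
    if record_filter.value_min is not None:
        in_val &= vals >= record_filter.value_min
    if record_filter.value_max is not None:
        in_val &= vals <= record_filter.value_max
    log.value_filtered = int((~in_val).sum())
    vals, raw_vals = vals[in_val], raw_vals[in_val]

    log.kept = len(vals)
    logger.info("read_lis_csv(%s, analyte=%s): %s", path, analyte, log.as_dict())
    if log.kept == 0:
        raise EmptyInputError(
            f"no rows for analyte '{analyte}' survived filtering: {log.as_dict()}"
        )

    if decimals is None:
        decimals = _infer_decimals(raw_vals)
    values = np.round(vals.to_numpy(dtype=float), decimals)
    series = MeasurementSeries(
        analyte_name=analyte, unit=unit, values=values, decimals=int(decimals)
    )
    return series, log


def write_lis_csv(
    path,
    series: MeasurementSeries,
    ages: Optional[np.ndarray] = None,
    columns: Optional[Dict[str, str]] = None,
) -> None:
    """Write a series back out in the same flat dialect read_lis_csv reads.

    ``ages`` defaults to a constant mid-adult age (50) so a round trip
    through the default adult filter is the identity on the values.
    """
    cols = dict(DEFAULT_COLUMNS)
    cols.update(columns or {})
    if ages is None:
        ages = np.full(series.n, 50)
    ages = np.asarray(ages)
    if ages.shape != (series.n,):
        raise ConfigurationError("ages must have one entry per value")
    fmt = f"%.{series.decimals}f"
    df = pd.DataFrame(
        {
            cols["analyte"]: series.analyte_name,
            cols["value"]: [fmt % v for v in series.values],
            cols["age"]: ages,
        }
    )
    df.to_csv(path, index=False)
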
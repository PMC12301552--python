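"""Domain types, policy configuration, and long-format study-table I/O.

The unit of analysis everywhere downstream is a :class:`MeasurandSeries`:
one measurand's numeric values for one partition ("All" or a label such as
"M"/"F").  Tables are exchanged in long format with one measurement per row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, IntegrityError, SchemaError, SeriesLookupError

__all__ = [
    "MeasurandSeries",
    "DescriptiveStats",
    "MethodPolicy",
    "StudyTable",
    "POOLED_PARTITION",
    "REQUIRED_COLUMNS",
    "read_study_table",
    "write_study_table",
    "extract_series",
]

logger = logging.getLogger("refintervals")

#: Z-score at the 0.975 normal quantile (full precision, not the rounded 1.96).
Z_975 = 1.959963984540054

#: Label selecting every record of a measurand regardless of partition.
POOLED_PARTITION = "All"

REQUIRED_COLUMNS = ("animal_id", "measurand", "unit", "value")


@dataclass(frozen=True)
class MeasurandSeries:
    """Numeric values of one measurand for one partition.

    ``values`` never contains missing entries: missingness is removed (and
    counted) at ingest, so ``len(values)`` is the analyzable ``n``.
    """

    measurand: str
    unit: str
    partition: str
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            raise ValueError("values must be a 1-D vector")
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError(
                f"{self.measurand}/{self.partition}: values contain non-finite entries"
            )
        object.__setattr__(self, "values", arr)

    @property
    def n(self) -> int:
        return int(self.values.size)

    def with_values(self, values: np.ndarray) -> "MeasurandSeries":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class DescriptiveStats:
    """Sample summary mirroring a report row: n, mean, SD (n-1), median, min, max."""

    n: int
    mean: float
    sd: float
    median: float
    min: float
    max: float

    @classmethod
    def from_values(cls, values: np.ndarray) -> "DescriptiveStats":
        arr = np.asarray(values, dtype=float)
        if arr.size < 1:
            raise ValueError("descriptive stats require at least one value")
        sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
        return cls(
            n=int(arr.size),
            mean=float(np.mean(arr)),
            sd=sd,
            median=float(np.median(arr)),
            min=float(np.min(arr)),
            max=float(np.max(arr)),
        )


def _band(value: Any) -> tuple[int, int | None]:
    lo, hi = value
    return (int(lo), None if hi is None else int(hi))


@dataclass(frozen=True)
class MethodPolicy:
    """Every tunable decision of the pipeline, with study defaults.

    Sample-size bands are inclusive ``(low, high)`` ranges on the
    post-screening ``n``; ``band_full`` is open-ended upward because no rule
    exists above the study's largest n.  ``quantile_convention`` selects the
    rank formula for nonparametric limits: ``"rank_n_plus_1"`` interpolates at
    rank ``p*(n+1)`` (CLSI style), ``"rank_n_minus_1"`` at ``1 + p*(n-1)``.
    """

    normality_alpha: float = 0.2
    partition_test_alpha: float = 0.05
    z_multiplier: float = Z_975
    lower_p: float = 0.025
    upper_p: float = 0.975
    band_full: tuple[int, int | None] = (40, None)
    band_minmax: tuple[int, int | None] = (20, 39)
    band_descriptive_only: tuple[int, int | None] = (10, 19)
    horn_min_n: int = 31
    fence_k: float = 1.5
    dixon_ratio_threshold: float = 1.0 / 3.0
    dixon_use_critical_table: bool = False
    boxcox_lambda_search: tuple[float, float] = (-3.0, 3.0)
    boxcox_lambda_fixed: float | None = None
    quantile_convention: str = "rank_n_plus_1"
    partition_test: str = "ranksum"
    bootstrap_B: int = 2000
    ci_level: float = 0.90
    ci_ratio_flag_threshold: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "band_full", _band(self.band_full))
        object.__setattr__(self, "band_minmax", _band(self.band_minmax))
        object.__setattr__(
            self, "band_descriptive_only", _band(self.band_descriptive_only)
        )
        object.__setattr__(
            self, "boxcox_lambda_search", tuple(map(float, self.boxcox_lambda_search))
        )
        if not (0.0 < self.lower_p < self.upper_p < 1.0):
            raise ConfigError("require 0 < lower_p < upper_p < 1")
        if not (0.0 < self.ci_level < 1.0):
            raise ConfigError("ci_level must lie in (0, 1)")
        if self.bootstrap_B < 200:
            raise ConfigError("bootstrap_B must be at least 200")
        if self.quantile_convention not in ("rank_n_plus_1", "rank_n_minus_1"):
            raise ConfigError(f"unknown quantile_convention {self.quantile_convention!r}")
        if self.partition_test not in ("ranksum", "welch"):
            raise ConfigError(f"unknown partition_test {self.partition_test!r}")
        bands = [self.band_descriptive_only, self.band_minmax, self.band_full]
        for (lo1, hi1), (lo2, _hi2) in zip(bands, bands[1:]):
            if hi1 is None or hi1 >= lo2 or lo1 > hi1:
                raise ConfigError("sample-size bands must be disjoint and ordered")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "MethodPolicy":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown policy fields: {sorted(unknown)}")
        return cls(**dict(mapping))

    @classmethod
    def from_file(cls, path: str | Path) -> "MethodPolicy":
        path = Path(path)
        try:
            raw = yaml.safe_load(path.read_text()) or {}
        except yaml.YAMLError as exc:  # also covers malformed JSON
            raise ConfigError(f"cannot parse policy file {path}: {exc}") from exc
        if not isinstance(raw, Mapping):
            raise ConfigError(f"policy file {path} must contain a mapping")
        return cls.from_mapping(raw)

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class StudyTable:
    """Long-format collection of measurements: one row per (animal, measurand).

    ``df`` always carries :data:`REQUIRED_COLUMNS` plus the partition
    columns; any further columns ride along as metadata.
    """

    df: pd.DataFrame
    partition_columns: tuple[str, ...] = ("sex",)
    dropped_per_measurand: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [
            c
            for c in (*REQUIRED_COLUMNS, *self.partition_columns)
            if c not in self.df.columns
        ]
        if missing:
            raise SchemaError(f"study table missing required columns: {missing}")
        dup = self.df.duplicated(subset=["animal_id", "measurand"])
        if dup.any():
            offenders = self.df.loc[dup, ["animal_id", "measurand"]].values[:5].tolist()
            raise IntegrityError(f"duplicate (animal_id, measurand) pairs: {offenders}")
        units = self.df.groupby("measurand")["unit"].nunique()
        mixed = units[units > 1]
        if len(mixed):
            raise IntegrityError(
                f"mixed units within measurand(s): {sorted(mixed.index)}"
            )

    @property
    def records(self) -> list[tuple]:
        cols = ["animal_id", *self.partition_columns, "measurand", "unit", "value"]
        return [tuple(row) for row in self.df[cols].itertuples(index=False, name=None)]

    def measurands(self) -> list[str]:
        """Measurand names in order of first appearance."""
        return list(dict.fromkeys(self.df["measurand"]))

    def partition_labels(self, column: str | None = None) -> list[str]:
        column = column or self.partition_columns[0]
        return list(dict.fromkeys(self.df[column].astype(str)))

    def unit_of(self, measurand: str) -> str:
        sel = self.df.loc[self.df["measurand"] == measurand, "unit"]
        if sel.empty:
            raise SeriesLookupError(f"unknown measurand {measurand!r}")
        return str(sel.iloc[0])


def _coerce_values(raw: pd.Series) -> pd.Series:
    """Parse the value column, tolerating thousands separators ("9,900")."""
    if raw.dtype == object:
        raw = raw.astype(str).str.replace(",", "", regex=False).str.strip()
        raw = raw.replace({"": None, "nan": None, "None": None})
    return pd.to_numeric(raw, errors="coerce")


def read_study_table(
    path: str | Path,
    partition_columns: Sequence[str] = ("sex",),
) -> StudyTable:
    """Read a delimited (CSV/TSV by extension) long-format study table.

    Non-numeric and blank value cells are dropped with a per-measurand count
    recorded in ``dropped_per_measurand`` and logged.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype={"animal_id": str}, float_precision="round_trip")
    missing = [c for c in (*REQUIRED_COLUMNS, *partition_columns) if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    df = df.copy()
    df["value"] = _coerce_values(df["value"])
    bad = df["value"].isna()
    dropped = (
        df.loc[bad].groupby("measurand").size().astype(int).to_dict() if bad.any() else {}
    )
    for name, count in dropped.items():
        logger.info("ingest: dropped %d missing/non-numeric value(s) for %s", count, name)
    df = df.loc[~bad].reset_index(drop=True)
    return StudyTable(
        df=df,
        partition_columns=tuple(partition_columns),
        dropped_per_measurand=dropped,
    )


def write_study_table(table: StudyTable, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    table.df.to_csv(path, sep=sep, index=False)


def extract_series(
    table: StudyTable,
    measurand: str,
    partition: str = POOLED_PARTITION,
    partition_column: str | None = None,
) -> MeasurandSeries:
    """Pull one measurand/partition slice out of a study table.

    ``partition="All"`` pools every record of the measurand.  A partition
    label with zero records for this measurand yields an empty series (the
    band logic downstream then reports nothing), but a label absent from the
    table altogether is a lookup error.
    """
    column = partition_column or table.partition_columns[0]
    sub = table.df[table.df["measurand"] == measurand]
    if sub.empty:
        raise SeriesLookupError(f"unknown measurand {measurand!r}")
    unit = str(sub["unit"].iloc[0])
    if partition != POOLED_PARTITION:
        known = set(table.df[column].astype(str))
        if partition not in known:
            raise SeriesLookupError(
                f"unknown partition {partition!r} in column {column!r}"
            )
        sub = sub[sub[column].astype(str) == partition]
    return MeasurandSeries(
        measurand=measurand,
        unit=unit,
        partition=partition,
        values=sub["value"].to_numpy(dtype=float),
    )


def stable_substream_seed(base_seed: int, *labels: str) -> np.random.SeedSequence:
    """Derive a reproducible RNG stream for (measurand, partition) labels.

    Independent of ``PYTHONHASHSEED`` so runs are bit-stable across processes.
    """
    import zlib

    keys = [zlib.crc32(label.encode("utf-8")) for label in labels]
    return np.random.SeedSequence([int(base_seed) & 0xFFFFFFFF, *keys])
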
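"""Data model for binned strip-transect surveys.

A survey *line* is one east-west transect surveyed on one cruise; the effort
and sightings along it are aggregated into consecutive *bins* of standardized
length (nominally 3 km, shorter where effort was interrupted).  This module
holds the bin/line containers, delimited-text I/O, and the quality-control
filters that decide which lines enter the dispersion analysis:

* lines with no sightings carry no dispersion information;
* lines with a single sighting trivially give maximal aggregation (Gx = 1)
  and are discarded;
* bins shorter than 1 km or longer than 3 km break the equal-area assumption;
* strips narrower than 100 m indicate poor viewing conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "SurveyBin",
    "SurveyLine",
    "QCRules",
    "QCReport",
    "REQUIRED_BIN_COLUMNS",
    "LINE_ENV_COLUMNS",
    "read_bins",
    "read_lines",
    "build_lines",
    "apply_qc",
    "write_results",
]

REQUIRED_BIN_COLUMNS = (
    "line_id",
    "cruise_id",
    "bin_index",
    "length_km",
    "strip_width_m",
    "count",
    "depth_m",
    "lat_deg",
    "lon_deg",
    "sst_c",
    "sss",
)

#: line-level covariates expected in the companion lines table
LINE_ENV_COLUMNS = (
    "julian_day",
    "cumulative_julian_day",
    "zonal_wind",
    "meridional_wind",
    "atm_pressure_mb",
    "atm_pressure_24h_prior_mb",
    "uw6_36",
    "uw6_39",
    "uwm_36",
    "uwm_39",
    "pdo",
    "npgo",
)


@dataclass
class SurveyBin:
    """One standardized along-track interval with count and local hydrography."""

    line_id: str
    cruise_id: str
    bin_index: int
    length_km: float
    strip_width_m: float
    count: int
    depth_m: float
    lat_deg: float
    lon_deg: float
    sst_c: float = math.nan
    sss: float = math.nan

    def __post_init__(self) -> None:
        if self.length_km <= 0:
            raise ValidationError(
                f"bin ({self.line_id}, {self.cruise_id}, {self.bin_index}): "
                f"length_km must be positive, got {self.length_km}"
            )
        if self.count < 0:
            raise ValidationError(
                f"bin ({self.line_id}, {self.cruise_id}, {self.bin_index}): "
                f"count must be nonnegative, got {self.count}"
            )

    @property
    def area_km2(self) -> float:
        return self.length_km * self.strip_width_m / 1000.0


@dataclass
class SurveyLine:
    """Ordered bin sequence for one replicate survey of one transect line."""

    line_id: str
    cruise_id: str
    bins: list[SurveyBin]
    julian_day: float = math.nan
    cumulative_julian_day: float = math.nan
    env: dict[str, float] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, str]:
        return (self.line_id, self.cruise_id)

    @property
    def line_length_km(self) -> float:
        return float(sum(b.length_km for b in self.bins))

    @property
    def counts(self) -> np.ndarray:
        return np.array([b.count for b in self.bins], dtype=float)

    @property
    def depths(self) -> np.ndarray:
        return np.array([b.depth_m for b in self.bins], dtype=float)

    @property
    def total_count(self) -> int:
        return int(sum(b.count for b in self.bins))


@dataclass(frozen=True)
class QCRules:
    """Exclusion thresholds; defaults follow the survey protocol."""

    min_bin_km: float = 1.0
    max_bin_km: float = 3.0
    min_strip_m: float = 100.0


@dataclass
class QCReport:
    """Classification of one line as retained or excluded, with every reason."""

    line_key: tuple[str, str]
    status: str  # "retained" | "excluded"
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.status == "excluded") != bool(self.reasons):
            raise ValidationError("excluded status must match nonempty reasons")


def read_bins(path, *, na_values: tuple[str, ...] = ("",)) -> list[SurveyBin]:
    """Read a bins CSV into a list of :class:`SurveyBin`, preserving row order.

    Missing SST/SSS values are encoded as empty fields (configurable via
    ``na_values``); counts may not be missing.
    """
    df = pd.read_csv(path, na_values=list(na_values), keep_default_na=False,
                     comment="#")
    missing = [c for c in REQUIRED_BIN_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"bins table missing required column(s): {missing}")

    bins: list[SurveyBin] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            b = SurveyBin(
                line_id=str(row.line_id),
                cruise_id=str(row.cruise_id),
                bin_index=int(row.bin_index),
                length_km=float(row.length_km),
                strip_width_m=float(row.strip_width_m),
                count=int(row.count),
                depth_m=float(row.depth_m),
                lat_deg=float(row.lat_deg),
                lon_deg=float(row.lon_deg),
                sst_c=_to_float(row.sst_c),
                sss=_to_float(row.sss),
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"row {row_no}: {exc}") from exc
        bins.append(b)
    return bins


def _to_float(value) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return math.nan
    if isinstance(value, str) and value.strip() == "":
        return math.nan
    return float(value)


def read_lines(path) -> pd.DataFrame:
    """Read the line-level covariate table, keyed by (line_id, cruise_id)."""
    df = pd.read_csv(path, comment="#")
    for key_col in ("line_id", "cruise_id"):
        if key_col not in df.columns:
            raise SchemaError(f"lines table missing required column: {key_col}")
    df["line_id"] = df["line_id"].astype(str)
    df["cruise_id"] = df["cruise_id"].astype(str)
    return df


def build_lines(bins: list[SurveyBin], lines_table: pd.DataFrame | None = None) -> list[SurveyLine]:
    """Group bins into :class:`SurveyLine` objects and attach line covariates.

    Bin indices must be 0-based and contiguous within each line; a gap means
    the survey was interrupted and the file should have been filtered upstream.
    """
    grouped: dict[tuple[str, str], list[SurveyBin]] = {}
    for b in bins:
        grouped.setdefault((b.line_id, b.cruise_id), []).append(b)

    env_lookup: dict[tuple[str, str], dict] = {}
    if lines_table is not None:
        for _, row in lines_table.iterrows():
            env_lookup[(row["line_id"], row["cruise_id"])] = row.to_dict()

    lines: list[SurveyLine] = []
    for key in grouped:  # insertion order = file order
        line_bins = sorted(grouped[key], key=lambda b: b.bin_index)
        indices = [b.bin_index for b in line_bins]
        if indices != list(range(len(line_bins))):
            raise ValidationError(
                f"line {key}: bin_index must be 0-based and contiguous, got {indices}"
            )
        meta = env_lookup.get(key, {})
        env = {
            k: float(v)
            for k, v in meta.items()
            if k not in ("line_id", "cruise_id", "julian_day", "cumulative_julian_day")
            and _is_number(v)
        }
        lines.append(
            SurveyLine(
                line_id=key[0],
                cruise_id=key[1],
                bins=line_bins,
                julian_day=float(meta.get("julian_day", math.nan)),
                cumulative_julian_day=float(meta.get("cumulative_julian_day", math.nan)),
                env=env,
            )
        )
    return lines


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def apply_qc(line: SurveyLine, rules: QCRules = QCRules()) -> QCReport:
    """Classify a line as retained or excluded, reporting *every* triggered rule.

    Rules (all evaluated, none short-circuits):

    - ``no_sightings``: total count 0;
    - ``single_sighting``: total count 1 (degenerate Gx = 1);
    - ``short_bin``: any bin length outside [min_bin_km, max_bin_km], inclusive;
    - ``narrow_strip``: any strip width below min_strip_m;
    - ``incomplete``: bin indices not contiguous from 0 (interrupted effort).
    """
    if not line.bins:
        raise ValidationError(f"line {line.key}: has no bins")
    reasons: list[str] = []
    total = line.total_count
    if total == 0:
        reasons.append("no_sightings")
    elif total == 1:
        reasons.append("single_sighting")
    if any(b.length_km < rules.min_bin_km or b.length_km > rules.max_bin_km
           for b in line.bins):
        reasons.append("short_bin")
    if any(b.strip_width_m < rules.min_strip_m for b in line.bins):
        reasons.append("narrow_strip")
    if sorted(b.bin_index for b in line.bins) != list(range(len(line.bins))):
        reasons.append("incomplete")
    status = "excluded" if reasons else "retained"
    return QCReport(line_key=line.key, status=status, reasons=reasons)


def write_results(records: list, path, *, fieldnames: tuple[str, ...] | None = None) -> None:
    """Write a homogeneous list of result dataclasses to CSV at full precision.

    ``read_csv(write_results(x))`` round-trips all numeric fields exactly
    (floats are written with repr precision).  For an empty record list,
    ``fieldnames`` supplies the header of the otherwise header-only file.
    """
    import dataclasses

    if records:
        if not dataclasses.is_dataclass(records[0]):
            raise ValidationError("write_results expects dataclass records")
        rows = [dataclasses.asdict(r) for r in records]
        df = pd.DataFrame(rows)
    else:
        df = pd.DataFrame(columns=list(fieldnames or ()))
    df.to_csv(path, index=False, float_format=None)
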
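"""Derivation, imputation and standardization of line-level covariates.

One row per retained survey line, combining temporal descriptors (Julian day
within the year, cumulative Julian day across the study), static features
(mean depth, mean latitude, line length), local hydrography (mean SST and SSS
after gap interpolation), regional atmosphere-ocean conditions (wind
components and modulus, atmospheric pressure and its 24-h change, 6-hr and
monthly coastal upwelling indices at 36° N and 39° N), and two basin-wide
climate indices (PDO, NPGO), together with the dispersion responses
(Gx, Moran's I, depth Moran's I, log density).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dispersion import DispersionResult
from .errors import DomainError, ValidationError
from .survey_model import SurveyLine

__all__ = [
    "COVARIATE_COLUMNS",
    "RESPONSE_COLUMNS",
    "wind_modulus",
    "delta_pressure",
    "interpolate_missing",
    "zscore",
    "standardize",
    "build_covariate_table",
    "CorrelationMatrix",
    "cross_correlation_matrix",
]

#: the 18 candidate environmental variables
COVARIATE_COLUMNS = (
    "julian_day",
    "cumulative_julian_day",
    "mean_depth_m",
    "mean_latitude_deg",
    "line_length_km",
    "mean_sst_c",
    "mean_sss",
    "zonal_wind",
    "meridional_wind",
    "wind_modulus",
    "atm_pressure_mb",
    "delta_atm_pressure_mb",
    "uw6_36",
    "uw6_39",
    "uwm_36",
    "uwm_39",
    "pdo",
    "npgo",
)

RESPONSE_COLUMNS = ("gx", "moran_i", "depth_moran_i", "log_density")


def wind_modulus(zonal: float, meridional: float) -> float:
    """Absolute wind speed (m s⁻¹) from zonal (E-W) and meridional (N-S) components."""
    if not (math.isfinite(zonal) and math.isfinite(meridional)):
        raise ValidationError("wind components must be finite")
    return math.hypot(zonal, meridional)


def delta_pressure(p_now: float, p_24h_prior: float) -> float:
    """Change in atmospheric pressure: value during survey minus 24 h before (mb)."""
    if not (math.isfinite(p_now) and math.isfinite(p_24h_prior)):
        raise ValidationError("pressure values must be finite")
    return p_now - p_24h_prior


def interpolate_missing(series) -> tuple[np.ndarray, list[int]]:
    """Fill single interior gaps in an ordered per-bin series.

    A missing value flanked by two present values becomes their mean.  Runs of
    two or more consecutive missing values, and missing endpoints, remain
    missing; their indices are returned as flags.
    """
    arr = np.asarray(series, dtype=float).copy()
    n = arr.size
    missing = np.isnan(arr)
    filled = arr.copy()
    for i in np.flatnonzero(missing):
        if 0 < i < n - 1 and not missing[i - 1] and not missing[i + 1]:
            filled[i] = 0.5 * (arr[i - 1] + arr[i + 1])
    flags = [int(i) for i in np.flatnonzero(np.isnan(filled))]
    return filled, flags


def zscore(column, name: str = "column") -> np.ndarray:
    """Standardize to mean 0, SD 1 (sample SD, n−1 denominator)."""
    arr = np.asarray(column, dtype=float)
    sd = arr.std(ddof=1)
    if not np.isfinite(sd) or sd == 0.0:
        raise DomainError(f"cannot standardize {name!r}: zero or undefined SD")
    return (arr - arr.mean()) / sd


def standardize(table: pd.DataFrame, columns=None, suffix: str = "_z") -> pd.DataFrame:
    """Return a copy of ``table`` with Z-scored columns appended (``_z`` suffix)."""
    out = table.copy()
    for col in columns if columns is not None else table.columns:
        out[col + suffix] = zscore(table[col].to_numpy(), name=col)
    return out


def build_covariate_table(
    lines: list[SurveyLine], results: list[DispersionResult]
) -> pd.DataFrame:
    """Assemble the one-row-per-line covariate/response table.

    Line-level SST/SSS and depth/latitude are means over the line's bins,
    after single-gap interpolation of the hydrographic series.  Wind modulus
    and the 24-h pressure change are derived here from their components.
    Density enters as its natural log (the base only rescales regression
    coefficients, never test statistics).
    """
    by_key = {r.line_key: r for r in results}
    rows = []
    for line in lines:
        r = by_key.get(line.key)
        if r is None:
            continue
        sst, _ = interpolate_missing([b.sst_c for b in line.bins])
        sss, _ = interpolate_missing([b.sss for b in line.bins])
        env = line.env
        row = {
            "line_id": line.line_id,
            "cruise_id": line.cruise_id,
            "julian_day": line.julian_day,
            "cumulative_julian_day": line.cumulative_julian_day,
            "mean_depth_m": float(np.mean(line.depths)),
            "mean_latitude_deg": float(np.mean([b.lat_deg for b in line.bins])),
            "line_length_km": line.line_length_km,
            "mean_sst_c": float(np.nanmean(sst)) if not np.all(np.isnan(sst)) else math.nan,
            "mean_sss": float(np.nanmean(sss)) if not np.all(np.isnan(sss)) else math.nan,
            "zonal_wind": env.get("zonal_wind", math.nan),
            "meridional_wind": env.get("meridional_wind", math.nan),
            "atm_pressure_mb": env.get("atm_pressure_mb", math.nan),
            "uw6_36": env.get("uw6_36", math.nan),
            "uw6_39": env.get("uw6_39", math.nan),
            "uwm_36": env.get("uwm_36", math.nan),
            "uwm_39": env.get("uwm_39", math.nan),
            "pdo": env.get("pdo", math.nan),
            "npgo": env.get("npgo", math.nan),
            "gx": r.gx,
            "moran_i": r.moran_i,
            "depth_moran_i": r.depth_moran_i,
            "log_density": math.log(r.density_birds_per_km2),
        }
        row["wind_modulus"] = wind_modulus(row["zonal_wind"], row["meridional_wind"]) \
            if math.isfinite(row["zonal_wind"]) and math.isfinite(row["meridional_wind"]) else math.nan
        prior = env.get("atm_pressure_24h_prior_mb", math.nan)
        row["delta_atm_pressure_mb"] = (
            delta_pressure(row["atm_pressure_mb"], prior)
            if math.isfinite(row["atm_pressure_mb"]) and math.isfinite(prior)
            else math.nan
        )
        rows.append(row)
    cols = ["line_id", "cruise_id", *COVARIATE_COLUMNS, *RESPONSE_COLUMNS]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations with two-sided p-values and pair counts."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    ns_threshold: float = 0.10

    def combined_layout(self, fmt: str = "{:.3f}") -> pd.DataFrame:
        """Correlation-table layout: r above the diagonal, p below.

        p-values above ``ns_threshold`` print as ``"ns"``; cells with fewer
        than 3 complete pairs print as ``"-"``.
        """
        cols = list(self.r.columns)
        out = pd.DataFrame("-", index=cols, columns=cols)
        for i, a in enumerate(cols):
            for j, b in enumerate(cols):
                if i < j:  # upper triangle: r
                    val = self.r.loc[a, b]
                    out.loc[a, b] = fmt.format(val) if np.isfinite(val) else "-"
                elif i > j:  # lower triangle: p
                    pv = self.p.loc[a, b]
                    if not np.isfinite(pv):
                        out.loc[a, b] = "-"
                    elif pv > self.ns_threshold:
                        out.loc[a, b] = "ns"
                    else:
                        out.loc[a, b] = fmt.format(pv)
        return out


def cross_correlation_matrix(
    table: pd.DataFrame, columns=None, ns_threshold: float = 0.10
) -> CorrelationMatrix:
    """All-pairs Pearson r with two-sided p-values (pairwise-complete rows).

    Pairs with fewer than 3 complete observations get NaN r and p rather than
    raising; the ``n`` frame records how many rows each pair used.
    """
    cols = list(columns) if columns is not None else list(table.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.zeros((k, k), dtype=int)
    data = table[cols].to_numpy(dtype=float)
    for i in range(k):
        n[i, i] = np.count_nonzero(np.isfinite(data[:, i]))
        for j in range(i + 1, k):
            mask = np.isfinite(data[:, i]) & np.isfinite(data[:, j])
            m = int(mask.sum())
            n[i, j] = n[j, i] = m
            if m < 3:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = stats.pearsonr(data[mask, i], data[mask, j])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=cols, columns=cols),
        p=pd.DataFrame(p, index=cols, columns=cols),
        n=pd.DataFrame(n, index=cols, columns=cols),
        ns_threshold=ns_threshold,
    )
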
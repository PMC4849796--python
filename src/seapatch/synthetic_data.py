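"""Synthetic strip-transect survey generator.

Emulates the statistical structure the analysis assumes so every stage is
testable without the original observations: seven parallel lines of roughly
29-45 km split into 3-km bins, counts drawn from regimes spanning the whole
dispersion spectrum (all-in-one-bin, clustered, Poisson-random, uniform), a
shelf / shelf-break / slope depth ramp with optional shallow "bank" anomalies
on the central lines, and line-level environmental variables drawn from a
multivariate normal whose default correlation targets are the empirical
cross-correlation matrix of the study region.

The clustered regime is a 1-D Thomas process: Poisson-distributed parents
placed uniformly along the line, each spawning a Poisson number of offspring
displaced by Gaussian jitter, then binned.  Its cluster SD is the patch
scale, so it produces the positive Moran's I signature that distinguishes
clustering from mere overdispersion.

All randomness flows through a single seeded generator; written fixtures
embed the seed in a ``#``-comment header line.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "PoissonRegime",
    "ThomasRegime",
    "SingleBinRegime",
    "UniformRegime",
    "NegativeBinomialRegime",
    "EffectModel",
    "SimConfig",
    "SurveyFixture",
    "DEFAULT_CORR_VARIABLES",
    "default_correlation",
    "default_moments",
    "nearest_psd",
    "simulate_counts",
    "simulate_covariates",
    "simulate_survey",
    "simulate_path_system",
]


# --------------------------------------------------------------------------
# count regimes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PoissonRegime:
    """iid Poisson(lam) counts per bin — the random-dispersion reference."""

    lam: float = 1.0

    def __post_init__(self):
        if self.lam < 0:
            raise ValidationError("lam must be nonnegative")


@dataclass(frozen=True)
class ThomasRegime:
    """1-D Thomas cluster process, binned.

    Parents ~ Poisson(parent_rate_per_km x line length), uniform along the
    line; offspring per parent ~ Poisson(mean_offspring), displaced from the
    parent by N(0, cluster_sd_km); offspring falling off the line are dropped.
    """

    parent_rate_per_km: float = 0.05
    mean_offspring: float = 8.0
    cluster_sd_km: float = 3.0

    def __post_init__(self):
        if self.parent_rate_per_km < 0 or self.mean_offspring < 0 or self.cluster_sd_km < 0:
            raise ValidationError("Thomas parameters must be nonnegative")


@dataclass(frozen=True)
class SingleBinRegime:
    """All mass in one uniformly chosen bin — maximal aggregation (Gx = 1)."""

    total: int = 5

    def __post_init__(self):
        if self.total < 0:
            raise ValidationError("total must be nonnegative")


@dataclass(frozen=True)
class UniformRegime:
    """Constant count in every bin — minimal aggregation (Gx = -1/(Σx-1))."""

    per_bin: int = 2

    def __post_init__(self):
        if self.per_bin < 0:
            raise ValidationError("per_bin must be nonnegative")


@dataclass(frozen=True)
class NegativeBinomialRegime:
    """iid negative-binomial counts: overdispersed but spatially unstructured."""

    mean: float = 3.0
    k: float = 1.0  # shape; variance = mean + mean^2 / k

    def __post_init__(self):
        if self.mean < 0 or self.k <= 0:
            raise ValidationError("mean must be >= 0 and k > 0")


def simulate_counts(regime, n_bins: int, rng=None, seed=None, bin_length_km: float = 3.0) -> np.ndarray:
    """Draw one count vector under the given dispersal regime."""
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if isinstance(regime, PoissonRegime):
        return rng.poisson(regime.lam, size=n_bins).astype(int)
    if isinstance(regime, ThomasRegime):
        length = n_bins * bin_length_km
        n_parents = rng.poisson(regime.parent_rate_per_km * length)
        counts = np.zeros(n_bins, dtype=int)
        if n_parents > 0:
            parents = rng.uniform(0.0, length, size=n_parents)
            n_off = rng.poisson(regime.mean_offspring, size=n_parents)
            for pos, k in zip(parents, n_off):
                if k == 0:
                    continue
                offspring = pos + rng.normal(0.0, regime.cluster_sd_km, size=k)
                keep = offspring[(offspring >= 0.0) & (offspring < length)]
                idx = np.floor(keep / bin_length_km).astype(int)
                np.add.at(counts, idx, 1)
        return counts
    if isinstance(regime, SingleBinRegime):
        counts = np.zeros(n_bins, dtype=int)
        counts[rng.integers(0, n_bins)] = regime.total
        return counts
    if isinstance(regime, UniformRegime):
        return np.full(n_bins, regime.per_bin, dtype=int)
    if isinstance(regime, NegativeBinomialRegime):
        if regime.mean == 0:
            return np.zeros(n_bins, dtype=int)
        p = regime.k / (regime.k + regime.mean)
        return rng.negative_binomial(regime.k, p, size=n_bins).astype(int)
    raise ValidationError(f"unknown regime {regime!r}")


# --------------------------------------------------------------------------
# covariate model
# --------------------------------------------------------------------------

#: variables of the empirical line-level cross-correlation matrix
DEFAULT_CORR_VARIABLES = (
    "mean_sst_c",
    "mean_sss",
    "mean_depth_m",
    "depth_moran_i",
    "zonal_wind",
    "meridional_wind",
    "wind_modulus",
    "uw6_39",
    "uw6_36",
    "atm_pressure_mb",
    "delta_atm_pressure_mb",
    "line_length_km",
    "mean_latitude_deg",
    "bird_density",
)

# upper-triangle Pearson r of the 14 variables above, row by row
_DEFAULT_CORR_UPPER = [
    [-0.415, 0.043, -0.205, -0.572, 0.275, -0.483, -0.240, -0.493, -0.245, 0.335, -0.001, -0.114, -0.167],
    [-0.099, 0.206, 0.136, -0.416, 0.065, 0.437, 0.132, -0.248, -0.461, 0.134, -0.088, 0.222],
    [0.261, 0.169, -0.136, 0.058, 0.123, 0.086, -0.097, -0.023, -0.799, 0.708, 0.101],
    [0.202, 0.021, -0.002, 0.030, 0.200, 0.019, -0.057, 0.162, -0.127, -0.099],
    [-0.495, 0.550, 0.333, 0.760, 0.489, -0.229, -0.154, 0.125, -0.041],
    [-0.447, -0.810, -0.520, -0.057, 0.574, 0.129, -0.095, -0.013],
    [0.415, 0.416, 0.152, -0.244, -0.138, 0.127, -0.071],
    [0.440, -0.253, -0.616, -0.134, 0.135, -0.063],
    [0.556, -0.187, -0.121, 0.103, -0.245],
    [0.310, 0.048, -0.071, -0.185],
    [0.037, -0.101, -0.001],
    [-0.681, -0.027],
    [0.082],
]


def default_correlation() -> pd.DataFrame:
    """The default 14x14 correlation target, symmetrized with unit diagonal."""
    k = len(DEFAULT_CORR_VARIABLES)
    r = np.eye(k)
    for i, row in enumerate(_DEFAULT_CORR_UPPER):
        for offset, val in enumerate(row, start=1):
            r[i, i + offset] = r[i + offset, i] = val
    return pd.DataFrame(r, index=DEFAULT_CORR_VARIABLES, columns=DEFAULT_CORR_VARIABLES)


def default_moments() -> tuple[dict[str, float], dict[str, float]]:
    """Plausible study-region means and SDs for the default covariates."""
    means = {
        "mean_sst_c": 13.0,
        "mean_sss": 33.5,
        "mean_depth_m": 450.0,
        "depth_moran_i": 0.5,
        "zonal_wind": 4.18,
        "meridional_wind": -3.0,
        "wind_modulus": 6.0,
        "uw6_39": 60.0,
        "uw6_36": 80.0,
        "atm_pressure_mb": 1016.0,
        "delta_atm_pressure_mb": 0.0,
        "line_length_km": 35.07,
        "mean_latitude_deg": 37.85,
        "bird_density": 1.48,
    }
    sds = {
        "mean_sst_c": 1.5,
        "mean_sss": 0.4,
        "mean_depth_m": 250.0,
        "depth_moran_i": 0.25,
        "zonal_wind": 2.22,
        "meridional_wind": 2.5,
        "wind_modulus": 2.0,
        "uw6_39": 80.0,
        "uw6_36": 70.0,
        "atm_pressure_mb": 4.0,
        "delta_atm_pressure_mb": 3.0,
        "line_length_km": 5.09,
        "mean_latitude_deg": 0.2,
        "bird_density": 2.2,
    }
    return means, sds


def nearest_psd(corr: np.ndarray, tol: float = 1e-8, max_shift: float = 0.5) -> np.ndarray:
    """Project a symmetric matrix onto the positive-semidefinite cone.

    Negative eigenvalues are clipped at zero and the diagonal renormalized to
    1.  Raises if the required adjustment exceeds ``max_shift`` (the target is
    then too far from any valid correlation matrix to repair silently).
    """
    c = np.asarray(corr, dtype=float)
    if not np.allclose(c, c.T):
        raise ValidationError("correlation matrix must be symmetric")
    vals, vecs = np.linalg.eigh(c)
    if vals.min() >= -tol:
        return c
    if vals.min() < -max_shift:
        raise ValidationError(
            f"correlation matrix too far from PSD (min eigenvalue {vals.min():.3f})"
        )
    warnings.warn(
        f"correlation target not PSD (min eigenvalue {vals.min():.2e}); applying nearest-PSD repair",
        stacklevel=2,
    )
    repaired = vecs @ np.diag(np.clip(vals, 0.0, None)) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def simulate_covariates(
    n_rows: int,
    rng=None,
    seed=None,
    variables=None,
    corr: pd.DataFrame | np.ndarray | None = None,
    means: dict[str, float] | None = None,
    sds: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Draw a covariate table from a multivariate normal with target correlations.

    Defaults reproduce the empirical cross-correlation structure of the
    study's line-level variables; empirical correlations converge to the
    targets as ``n_rows`` grows.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if corr is None:
        corr_df = default_correlation()
        names = list(DEFAULT_CORR_VARIABLES) if variables is None else list(variables)
        corr_arr = corr_df.loc[names, names].to_numpy()
    elif isinstance(corr, pd.DataFrame):
        names = list(corr.columns) if variables is None else list(variables)
        corr_arr = corr.loc[names, names].to_numpy()
    else:
        corr_arr = np.asarray(corr, dtype=float)
        if variables is None:
            raise ValidationError("variables must be named when corr is a bare array")
        names = list(variables)
    corr_arr = nearest_psd(corr_arr)
    default_means, default_sds = default_moments()
    mu = np.array([(means or default_means).get(v, 0.0) for v in names])
    sigma = np.array([(sds or default_sds).get(v, 1.0) for v in names])
    cov = corr_arr * np.outer(sigma, sigma)
    draws = rng.multivariate_normal(mu, cov, size=n_rows, method="eigh")
    return pd.DataFrame(draws, columns=names)


def simulate_path_system(
    hierarchy,
    weights: dict[tuple[str, str], float],
    n: int,
    rng=None,
    seed=None,
    noise_sd: float = 1.0,
) -> tuple[pd.DataFrame, dict[tuple[str, str], float]]:
    """Simulate a linear recursive system laid out on a hierarchy.

    Variables in the top level are iid standard normal (exogenous).  Every
    other variable is a weighted sum of parents from strictly higher levels
    plus independent Gaussian noise:

        child = sum_parents w(parent, child) * parent + N(0, noise_sd).

    ``weights`` is keyed by ``(parent, child)``; parents may sit any number
    of levels above the child, which lets tests plant skip-level dependencies
    the adjacent-level path model cannot represent.

    Returns the simulated table and the *population* standardized partial
    coefficients for every adjacent-level (upper, lower) pair — the exact
    values the path model estimates — computed from the implied covariance
    of the system, so recovery tests compare against the true target rather
    than the generating weight (the two coincide when all variances are 1).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    levels = list(hierarchy.levels)  # bottom first
    order = [v for _, vs in reversed(levels) for v in vs]  # top first
    level_of = {v: li for li, (_, vs) in enumerate(levels) for v in vs}
    for (parent, child) in weights:
        if parent not in level_of or child not in level_of:
            raise ValidationError(f"unknown variable in weights: {(parent, child)}")
        if level_of[parent] <= level_of[child]:
            raise ValidationError(
                f"weight {(parent, child)}: parent must sit in a higher level"
            )

    # each variable = linear combination of one independent noise per variable
    loadings: dict[str, np.ndarray] = {}
    k = len(order)
    data: dict[str, np.ndarray] = {}
    for idx, v in enumerate(order):
        load = np.zeros(k)
        parents = [(p, w) for (p, c), w in weights.items() if c == v]
        col = np.zeros(n)
        for p, w in parents:
            load += w * loadings[p]
            col += w * data[p]
        own = noise_sd if parents or level_of[v] < len(levels) - 1 else 1.0
        load[idx] = own
        col = col + own * rng.normal(size=n)
        loadings[v] = load
        data[v] = col

    cov = {
        (a, b): float(loadings[a] @ loadings[b]) for a in order for b in order
    }

    def corr(a, b):
        return cov[(a, b)] / math.sqrt(cov[(a, a)] * cov[(b, b)])

    true_partials: dict[tuple[str, str], float] = {}
    for (_, lower), (_, upper) in zip(levels, levels[1:]):
        u = list(upper)
        r_uu = np.array([[corr(a, b) for b in u] for a in u])
        for y in lower:
            r_uy = np.array([corr(a, y) for a in u])
            beta = np.linalg.solve(r_uu, r_uy)
            for a, b_val in zip(u, beta):
                true_partials[(a, y)] = float(b_val)
    return pd.DataFrame({v: data[v] for v in order}), true_partials


# --------------------------------------------------------------------------
# full survey fixtures
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectModel:
    """Linear links from standardized line-level covariates to log expected count."""

    base_lambda: float = 1.0
    betas: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.base_lambda < 0:
            raise ValidationError("base_lambda must be nonnegative")


@dataclass
class SimConfig:
    """Study-design parameters for a synthetic survey fixture.

    Defaults follow the study conditions: 7 parallel lines, ~6 replicate
    cruises each (41 retained lines in the original attrition), 3-km bins,
    line lengths drawn on 29-45 km, 200-m strips, a clustered (Thomas) count
    regime, and shallow-bank depth anomalies on the three central lines.
    """

    n_lines: int = 7
    replicates: int = 6
    line_length_range_km: tuple[float, float] = (29.0, 45.0)
    bin_length_km: float = 3.0
    strip_width_m: float = 200.0
    regime: object = ThomasRegime()
    regimes_by_line: dict[str, object] = field(default_factory=dict)
    bank_lines: tuple[str, ...] = ("2", "3", "4")
    depth_inshore_m: float = 50.0
    depth_offshore_m: float = 1084.0
    bank_summit_depth_m: float = 40.0
    effect: EffectModel | None = None
    missing_hydro_rate: float = 0.0
    ensure_min_total: int = 2
    inject_short_bin: tuple[str, ...] = ()
    inject_narrow_strip: tuple[str, ...] = ()
    inject_single_sighting: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.line_length_range_km
        if not (0 < lo <= hi):
            raise ValidationError("invalid line length range")
        if self.bin_length_km <= 0 or self.strip_width_m <= 0:
            raise ValidationError("bin length and strip width must be positive")


@dataclass
class SurveyFixture:
    bins: pd.DataFrame
    lines: pd.DataFrame
    truth: dict


_ENV_DRAW_VARS = (
    "mean_sst_c",
    "mean_sss",
    "zonal_wind",
    "meridional_wind",
    "uw6_39",
    "uw6_36",
    "atm_pressure_mb",
    "delta_atm_pressure_mb",
)


def _depth_profile(n_bins: int, config: SimConfig, bank: bool) -> np.ndarray:
    frac = (np.arange(n_bins) + 0.5) / n_bins
    depth = config.depth_inshore_m + (config.depth_offshore_m - config.depth_inshore_m) * frac ** 2.2
    if bank:
        center = 0.45 * n_bins
        width = 1.5
        bump = np.exp(-0.5 * ((np.arange(n_bins) - center) / width) ** 2)
        amplitude = max(depth[int(center)] - config.bank_summit_depth_m, 0.0)
        depth = depth - amplitude * bump
    return np.clip(depth, 20.0, None)


def simulate_survey(config: SimConfig, rng=None, out_dir=None) -> SurveyFixture:
    """Generate a bins/lines fixture pair conforming to the survey schema.

    QC-clean by default (every line retained); targeted violations (short
    bins, narrow strips, single sightings) can be injected per line id for
    filter tests.  ``truth`` records the generator parameters for recovery
    tests.  With ``out_dir`` set, writes ``bins.csv``, ``lines.csv`` and
    ``truth.json`` there.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_rows = config.n_lines * config.replicates
    env = simulate_covariates(n_rows, rng=rng, variables=list(_ENV_DRAW_VARS))

    means, sds = default_moments()
    # monthly upwelling: temporally smoothed version of the 6-hr index
    uwm = {}
    for station in ("36", "39"):
        z6 = (env[f"uw6_{station}"] - means[f"uw6_{station}"]) / sds[f"uw6_{station}"]
        uwm[station] = 80.0 + 50.0 * (0.7 * z6 + math.sqrt(1 - 0.49) * rng.normal(size=n_rows))
    # basin-wide indices: negatively correlated pair, shared per cruise below
    pdo_raw = rng.normal(size=config.replicates)
    npgo_raw = -0.4 * pdo_raw + math.sqrt(1 - 0.16) * rng.normal(size=config.replicates)

    line_ids = [str(i + 1) for i in range(config.n_lines)]
    cruise_ids = [f"c{j + 1:02d}" for j in range(config.replicates)]
    years = [2004 + (j % 5) for j in range(config.replicates)]
    julian = rng.uniform(91, 290, size=config.replicates)

    # standardized covariate values for the optional effect model
    effect_z = {}
    if config.effect is not None:
        for var in config.effect.betas:
            if var not in env.columns:
                raise ValidationError(f"effect model names unknown covariate {var!r}")
            col = env[var].to_numpy()
            effect_z[var] = (col - col.mean()) / col.std(ddof=1)

    bin_rows, line_rows = [], []
    truth_lines = {}
    row = 0
    for j, cruise in enumerate(cruise_ids):
        for i, line_id in enumerate(line_ids):
            length = rng.uniform(*config.line_length_range_km)
            n_full = int(length // config.bin_length_km)
            rem = length - n_full * config.bin_length_km
            lengths = [config.bin_length_km] * n_full + ([rem] if rem >= 1.0 else [])
            n_bins = len(lengths)
            depth = _depth_profile(n_bins, config, bank=line_id in config.bank_lines)

            regime = config.regimes_by_line.get(line_id, config.regime)
            if config.effect is not None:
                log_lam = math.log(config.effect.base_lambda) + sum(
                    b * effect_z[v][row] for v, b in config.effect.betas.items()
                )
                counts = rng.poisson(math.exp(log_lam), size=n_bins)
            else:
                counts = simulate_counts(regime, n_bins, rng=rng,
                                         bin_length_km=config.bin_length_km)
            if config.ensure_min_total and line_id not in config.inject_single_sighting:
                for _ in range(1000):
                    if counts.sum() >= config.ensure_min_total:
                        break
                    if config.effect is not None:
                        counts = rng.poisson(math.exp(log_lam), size=n_bins)
                    else:
                        counts = simulate_counts(regime, n_bins, rng=rng,
                                                 bin_length_km=config.bin_length_km)
                else:
                    counts[rng.integers(0, n_bins)] += config.ensure_min_total

            strip = np.full(n_bins, config.strip_width_m)
            if line_id in config.inject_short_bin:
                lengths[-1] = 0.5
            if line_id in config.inject_narrow_strip:
                strip[rng.integers(0, n_bins)] = 50.0
            if line_id in config.inject_single_sighting:
                counts = np.zeros(n_bins, dtype=int)
                counts[rng.integers(0, n_bins)] = 1

            lat0 = 38.133 - i * (38.133 - 37.567) / max(config.n_lines - 1, 1)
            lat = lat0 + rng.normal(0.0, 0.005)
            sst_line = env.at[row, "mean_sst_c"]
            sss_line = env.at[row, "mean_sss"]
            sst = sst_line + rng.normal(0.0, 0.3, size=n_bins)
            sss = sss_line + rng.normal(0.0, 0.1, size=n_bins)
            if config.missing_hydro_rate > 0:
                gaps = rng.random(n_bins) < config.missing_hydro_rate
                sst[gaps] = np.nan
                sss[gaps] = np.nan

            cum_km = np.concatenate([[0.0], np.cumsum(lengths)[:-1]])
            for b in range(n_bins):
                bin_rows.append({
                    "line_id": line_id,
                    "cruise_id": cruise,
                    "bin_index": b,
                    "length_km": lengths[b],
                    "strip_width_m": strip[b],
                    "count": int(counts[b]),
                    "depth_m": depth[b],
                    "lat_deg": lat,
                    "lon_deg": -123.4 + (cum_km[b] + lengths[b] / 2) * 0.0113,
                    "sst_c": sst[b],
                    "sss": sss[b],
                })
            line_rows.append({
                "line_id": line_id,
                "cruise_id": cruise,
                "julian_day": julian[j],
                "cumulative_julian_day": (years[j] - 2004) * 365 + julian[j],
                "zonal_wind": env.at[row, "zonal_wind"],
                "meridional_wind": env.at[row, "meridional_wind"],
                "atm_pressure_mb": env.at[row, "atm_pressure_mb"],
                "atm_pressure_24h_prior_mb": env.at[row, "atm_pressure_mb"]
                - env.at[row, "delta_atm_pressure_mb"],
                "uw6_36": env.at[row, "uw6_36"],
                "uw6_39": env.at[row, "uw6_39"],
                "uwm_36": uwm["36"][row],
                "uwm_39": uwm["39"][row],
                "pdo": 0.3 + 0.8 * pdo_raw[j],
                "npgo": 0.5 + 1.0 * npgo_raw[j],
            })
            truth_lines[f"{line_id}/{cruise}"] = {
                "regime": type(regime).__name__ if config.effect is None else "EffectPoisson",
                "n_bins": n_bins,
                "length_km": float(sum(lengths)),
            }
            row += 1

    bins_df = pd.DataFrame(bin_rows)
    lines_df = pd.DataFrame(line_rows)
    truth = {
        "seed": config.seed,
        "n_lines": config.n_lines,
        "replicates": config.replicates,
        "regime": repr(config.regime),
        "effect": None if config.effect is None else {
            "base_lambda": config.effect.base_lambda,
            "betas": dict(config.effect.betas),
        },
        "lines": truth_lines,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = f"# seed={config.seed}\n"
        for name, df in (("bins.csv", bins_df), ("lines.csv", lines_df)):
            with open(out / name, "w") as fh:
                fh.write(header)
                df.to_csv(fh, index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2)
    return SurveyFixture(bins=bins_df, lines=lines_df, truth=truth)
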
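"""Hypothesis-driven hierarchical path model.

Variables are arranged in ordered levels (I at the bottom holding the
dispersion responses, IX at the top holding the exogenous basin-wide climate
indices).  The model quantifies only two kinds of relationship:

* **within-level** covariation: Pearson correlation for every unordered pair
  of variables sharing a level (drawn as double-headed arrows);
* **between-level** direct effects: for each variable in a level, its partial
  regression coefficient in the joint multiple regression on *all* variables
  of the level immediately above (one-headed arrows).  No skip-level edges
  are ever fitted — a dependency the hierarchy does not anticipate shows up
  only as attenuated adjacent coefficients.

All columns are Z-scored before fitting, so between-level coefficients are
standardized path coefficients; with a single upper-level predictor the
coefficient reduces exactly to the Pearson r of the pair.

Significance tiers mirror the conventional path-diagram line weights:
``ns`` (p ≥ 0.1, dashed), ``marginal`` (0.05 < p < 0.1), ``weak``
(0.01 < p ≤ 0.05), ``mid`` (0.001 < p ≤ 0.01), ``strong`` (p ≤ 0.001).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .covariates import zscore
from .errors import SchemaError, ValidationError

__all__ = [
    "Hierarchy",
    "PathEdge",
    "PathModel",
    "DEFAULT_LEVELS",
    "assign_tier",
    "within_level_edges",
    "between_level_edges",
    "fit_path_model",
    "render_edge_list",
    "to_dot",
]

#: default nine-level hierarchy: dispersion responses at the bottom, local
#: hydrography above them, then short-term and monthly upwelling, wind
#: modulus, wind components, pressure change, pressure, and finally the
#: exogenous basin-wide indices.
DEFAULT_LEVELS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("I", ("gx", "moran_i", "log_density")),
    ("II", ("mean_sst_c", "mean_sss")),
    ("III", ("uw6_36", "uw6_39")),
    ("IV", ("uwm_36", "uwm_39")),
    ("V", ("wind_modulus",)),
    ("VI", ("zonal_wind", "meridional_wind")),
    ("VII", ("delta_atm_pressure_mb",)),
    ("VIII", ("atm_pressure_mb",)),
    ("IX", ("pdo", "npgo")),
)

#: standardized-design condition number above which a collinearity warning
#: is attached to the affected edges
CONDITION_NUMBER_THRESHOLD = 30.0


def assign_tier(p: float) -> str:
    if not np.isfinite(p):
        return "ns"
    if p <= 0.001:
        return "strong"
    if p <= 0.01:
        return "mid"
    if p <= 0.05:
        return "weak"
    if p < 0.1:
        return "marginal"
    return "ns"


@dataclass(frozen=True)
class Hierarchy:
    """Ordered levels of named variables, bottom (responses) first."""

    levels: tuple[tuple[str, tuple[str, ...]], ...] = DEFAULT_LEVELS

    def __post_init__(self) -> None:
        names = [v for _, variables in self.levels for v in variables]
        if len(names) != len(set(names)):
            raise ValidationError("variable names must be unique across levels")

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(v for _, vs in self.levels for v in vs)

    def validate_against(self, table: pd.DataFrame) -> None:
        missing = [v for v in self.variables if v not in table.columns]
        if missing:
            raise SchemaError(f"hierarchy variables absent from table: {missing}")

    @classmethod
    def from_dict(cls, spec: dict) -> "Hierarchy":
        """Build from a mapping of level label -> list of column names."""
        return cls(tuple((str(k), tuple(v)) for k, v in spec.items()))

    @classmethod
    def from_yaml(cls, path) -> "Hierarchy":
        import yaml

        with open(path) as fh:
            spec = yaml.safe_load(fh)
        return cls.from_dict(spec)


@dataclass
class PathEdge:
    kind: str  # "within_level" | "between_level"
    from_var: str
    to_var: str
    coefficient: float
    p_value: float
    se: float = float("nan")
    tier: str = ""
    sign: str = ""
    warning: str = ""

    def __post_init__(self) -> None:
        if not self.tier:
            self.tier = assign_tier(self.p_value)
        if not self.sign:
            self.sign = "negative" if self.coefficient < 0 else "positive"


@dataclass
class PathModel:
    hierarchy: Hierarchy
    edges: list[PathEdge]
    n: int

    def within_edges(self) -> list[PathEdge]:
        return [e for e in self.edges if e.kind == "within_level"]

    def between_edges(self) -> list[PathEdge]:
        return [e for e in self.edges if e.kind == "between_level"]


def within_level_edges(level_vars, table: pd.DataFrame) -> list[PathEdge]:
    """Pearson correlation for every unordered pair within one level."""
    variables = list(level_vars)
    for v in variables:
        if v not in table.columns:
            raise SchemaError(f"variable {v!r} absent from table")
    edges = []
    for a, b in itertools.combinations(variables, 2):
        res = stats.pearsonr(table[a].to_numpy(float), table[b].to_numpy(float))
        n = len(table)
        r = float(res.statistic)
        se = math.sqrt(max(1.0 - r * r, 0.0) / (n - 2)) if n > 2 else float("nan")
        edges.append(
            PathEdge(
                kind="within_level",
                from_var=a,
                to_var=b,
                coefficient=r,
                p_value=float(res.pvalue),
                se=se,
            )
        )
    return edges


def between_level_edges(lower_vars, upper_vars, table: pd.DataFrame) -> list[PathEdge]:
    """Partial-regression edges from each upper-level variable to each lower one.

    Each lower variable is regressed (OLS, with intercept) on the Z-scored
    full adjacent-upper set; every upper variable contributes one edge with
    its partial coefficient and t-test p-value.
    """
    lower = list(lower_vars)
    upper = list(upper_vars)
    for v in lower + upper:
        if v not in table.columns:
            raise SchemaError(f"variable {v!r} absent from table")
    n = len(table)
    if n <= len(upper) + 1:
        raise ValidationError(
            f"need more than {len(upper) + 1} rows to regress on {len(upper)} predictors"
        )
    zu = np.column_stack([zscore(table[v].to_numpy(float), v) for v in upper])
    warning = ""
    if len(upper) > 1:
        cond = float(np.linalg.cond(zu))
        if cond > CONDITION_NUMBER_THRESHOLD:
            warning = f"collinear upper level (condition number {cond:.1f})"
    design = sm.add_constant(zu)
    edges: list[PathEdge] = []
    for y in lower:
        zy = zscore(table[y].to_numpy(float), y)
        fit = sm.OLS(zy, design).fit()
        for k, u in enumerate(upper):
            edges.append(
                PathEdge(
                    kind="between_level",
                    from_var=u,
                    to_var=y,
                    coefficient=float(fit.params[k + 1]),
                    p_value=float(fit.pvalues[k + 1]),
                    se=float(fit.bse[k + 1]),
                    warning=warning,
                )
            )
    return edges


def fit_path_model(hierarchy: Hierarchy, table: pd.DataFrame) -> PathModel:
    """Fit every within-level correlation and adjacent-level partial regression.

    Edges are exactly: all unordered pairs inside each level, plus one edge
    per (lower variable, adjacent-upper variable) pair.  Deterministic; no
    skip-level edges.
    """
    hierarchy.validate_against(table)
    edges: list[PathEdge] = []
    for _, level_vars in hierarchy.levels:
        if len(level_vars) >= 2:
            edges.extend(within_level_edges(level_vars, table))
    for (_, lower), (_, upper) in zip(hierarchy.levels, hierarchy.levels[1:]):
        edges.extend(between_level_edges(lower, upper, table))
    return PathModel(hierarchy=hierarchy, edges=edges, n=len(table))


def render_edge_list(model: PathModel, path) -> None:
    """Write the fitted edges as a plain-text table for graph-drawing tools."""
    rows = [
        {
            "from": e.from_var,
            "to": e.to_var,
            "kind": e.kind,
            "coefficient": e.coefficient,
            "se": e.se,
            "p_value": e.p_value,
            "tier": e.tier,
            "sign": e.sign,
            "warning": e.warning,
        }
        for e in model.edges
    ]
    df = pd.DataFrame(
        rows,
        columns=["from", "to", "kind", "coefficient", "se", "p_value", "tier", "sign", "warning"],
    )
    df.to_csv(path, index=False)


_PENWIDTH = {"ns": 1.0, "marginal": 1.0, "weak": 1.5, "mid": 2.5, "strong": 4.0}


def to_dot(model: PathModel) -> str:
    """DOT description: dashed = non-significant, grey = negative coefficient."""
    lines = ["digraph path_model {", "  rankdir=BT;"]
    for label, variables in model.hierarchy.levels:
        lines.append(f"  subgraph cluster_{label} {{ label=\"{label}\"; rank=same;")
        for v in variables:
            lines.append(f"    \"{v}\";")
        lines.append("  }")
    for e in model.edges:
        style = "dashed" if e.tier == "ns" else "solid"
        color = "grey" if e.sign == "negative" else "black"
        dir_attr = "none" if e.kind == "within_level" else "forward"
        lines.append(
            f"  \"{e.from_var}\" -> \"{e.to_var}\" ["
            f"style={style}, color={color}, dir={dir_attr}, "
            f"penwidth={_PENWIDTH[e.tier]}, "
            f"label=\"{e.coefficient:+.2f}\"];"
        )
    lines.append("}")
    return "\n".join(lines) + "\n"
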
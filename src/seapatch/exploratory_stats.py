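"""Exploratory layer: forward stepwise GLM, Bonferroni flags, one-way ANOVA
with Tukey post-hoc, and residual-normality diagnostics.

The stepwise selector is pure forward: at each step every remaining candidate
is added to the current model in turn, and the one with the smallest
partial-F p-value (equivalently, the t-test of its coefficient) enters if
that p is at or below the entry threshold (default 0.1).  There is no
removal step.  Standardized coefficients of the final joint model are
reported together with the adjusted r² and a Kolmogorov-Smirnov check of
residual normality.  Because a forward search over many candidates at a
permissive threshold invites false entries, coefficients are additionally
flagged against a Bonferroni-corrected level 0.05/m, with m the size of the
candidate family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import DomainError, ValidationError

__all__ = [
    "StepwiseStep",
    "StepwiseFit",
    "AnovaResult",
    "forward_stepwise",
    "bonferroni_flag",
    "anova_by_line",
    "ks_normality",
]


@dataclass
class StepwiseStep:
    variable: str
    coefficient: float  # standardized, in the final joint model
    p_at_entry: float
    p_final: float
    bonferroni_significant: bool = False


@dataclass
class StepwiseFit:
    response: str
    steps: list[StepwiseStep]
    adjusted_r2: float
    r2: float
    ks_stat: float
    ks_p: float
    n: int
    entry_p: float
    bonferroni_m: int
    warnings: list[str] = field(default_factory=list)

    @property
    def selected(self) -> list[str]:
        return [s.variable for s in self.steps]


@dataclass
class AnovaResult:
    response: str
    df_between: int
    df_within: int
    F: float
    p: float
    r2: float
    tukey: list[tuple[tuple[str, str], float]]
    ks_stat: float
    ks_p: float
    warnings: list[str] = field(default_factory=list)


def _zscore(x: np.ndarray, name: str) -> np.ndarray:
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise DomainError(f"zero-variance column {name!r}")
    return (x - x.mean()) / sd


def forward_stepwise(
    response,
    candidates: pd.DataFrame,
    entry_p: float = 0.1,
    response_name: str = "response",
    bonferroni_m: int | None = None,
) -> StepwiseFit:
    """Forward stepwise selection among standardized candidate columns.

    Ties on the entry p-value are broken by larger absolute standardized
    coefficient, then by column order.  A candidate whose addition makes the
    design rank-deficient is skipped with a warning.  ``bonferroni_m``
    defaults to the number of candidates offered.
    """
    y = _zscore(np.asarray(response, dtype=float), response_name)
    n = y.size
    if len(candidates) != n:
        raise ValidationError("response and candidates have different lengths")
    cols = list(candidates.columns)
    z = {c: _zscore(candidates[c].to_numpy(float), c) for c in cols}
    m = bonferroni_m if bonferroni_m is not None else max(len(cols), 1)

    selected: list[str] = []
    entry_ps: dict[str, float] = {}
    notes: list[str] = []
    collinear_seen: set[str] = set()
    remaining = list(cols)
    while remaining:
        if n <= len(selected) + 2:  # need residual df for the next t-test
            notes.append("stopped: insufficient residual degrees of freedom")
            break
        best = None  # (p, -|coef|, order, name)
        for order, c in enumerate(remaining):
            design = sm.add_constant(np.column_stack([z[v] for v in selected + [c]]))
            if np.linalg.matrix_rank(design) < design.shape[1]:
                collinear_seen.add(c)
                continue
            fit = sm.OLS(y, design).fit()
            p_c = float(fit.pvalues[-1])
            coef_c = float(fit.params[-1])
            key = (p_c, -abs(coef_c), order)
            if best is None or key < best[0]:
                best = (key, c, p_c)
        if best is None:
            notes.append("stopped: all remaining candidates collinear with model")
            break
        _, name, p_c = best
        if p_c > entry_p:
            break
        selected.append(name)
        entry_ps[name] = p_c
        remaining.remove(name)

    for c in sorted(collinear_seen - set(selected)):
        notes.append(f"candidate {c!r} skipped (collinear with current model)")

    if selected:
        design = sm.add_constant(np.column_stack([z[v] for v in selected]))
        final = sm.OLS(y, design).fit()
        coefs = final.params[1:]
        pvals = final.pvalues[1:]
        resid = np.asarray(final.resid)
        adj_r2 = float(final.rsquared_adj)
        r2 = float(final.rsquared)
    else:
        final = sm.OLS(y, np.ones((n, 1))).fit()
        coefs, pvals = np.array([]), np.array([])
        resid = np.asarray(final.resid)
        adj_r2, r2 = 0.0, 0.0

    try:
        ks_stat, ks_p = ks_normality(resid)
    except DomainError:
        ks_stat, ks_p = float("nan"), float("nan")

    steps = [
        StepwiseStep(
            variable=v,
            coefficient=float(coefs[i]),
            p_at_entry=entry_ps[v],
            p_final=float(pvals[i]),
            bonferroni_significant=bool(pvals[i] <= 0.05 / m),
        )
        for i, v in enumerate(selected)
    ]
    return StepwiseFit(
        response=response_name,
        steps=steps,
        adjusted_r2=adj_r2,
        r2=r2,
        ks_stat=ks_stat,
        ks_p=ks_p,
        n=n,
        entry_p=entry_p,
        bonferroni_m=m,
        warnings=notes,
    )


def bonferroni_flag(fit: StepwiseFit, m: int) -> list[bool]:
    """Flag each retained coefficient significant iff its p ≤ 0.05/m.

    Updates the fit's per-step flags in place and returns them.
    """
    if m < 1:
        raise ValidationError("family size m must be >= 1")
    flags = []
    for step in fit.steps:
        flag = bool(step.p_final <= 0.05 / m)
        step.bonferroni_significant = flag
        flags.append(flag)
    fit.bonferroni_m = m
    return flags


def anova_by_line(response, line_ids, response_name: str = "response") -> AnovaResult:
    """One-way fixed-effects ANOVA of a per-line metric across transect lines.

    r² = SS_between / SS_total.  Tukey HSD runs on all pairs of lines with at
    least 2 observations; lines with a single observation stay in the ANOVA
    but are dropped from the post-hoc with a warning.  Residuals (deviations
    from group means) are tested against a normal with matched mean/SD.
    """
    y = np.asarray(response, dtype=float)
    groups = np.asarray(line_ids).astype(str)
    if y.size != groups.size:
        raise ValidationError("response and line_ids have different lengths")
    labels, counts = np.unique(groups, return_counts=True)
    usable = labels[counts >= 2]
    if len(labels) < 2 or len(usable) < 2:
        raise ValidationError("need >= 2 lines with >= 2 observations each")

    grand = y.mean()
    group_means = {g: y[groups == g].mean() for g in labels}
    ss_between = sum(
        (groups == g).sum() * (group_means[g] - grand) ** 2 for g in labels
    )
    ss_total = float(((y - grand) ** 2).sum())
    ss_within = ss_total - ss_between
    df_between = len(labels) - 1
    df_within = y.size - len(labels)
    if ss_within <= 0 or df_within <= 0:
        f_val = 0.0 if ss_between == 0 else float("inf")
        p_val = 1.0 if ss_between == 0 else 0.0
    else:
        f_val = (ss_between / df_between) / (ss_within / df_within)
        p_val = float(stats.f.sf(f_val, df_between, df_within))
    r2 = ss_between / ss_total if ss_total > 0 else float("nan")

    notes: list[str] = []
    singletons = [g for g, c in zip(labels, counts) if c < 2]
    if singletons:
        notes.append(f"lines excluded from Tukey (single observation): {singletons}")
    mask = np.isin(groups, usable)
    tukey_pairs: list[tuple[tuple[str, str], float]] = []
    if len(usable) >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hsd = pairwise_tukeyhsd(y[mask], groups[mask])
        uniq = [str(g) for g in hsd.groupsunique]
        import itertools

        for (a, b), pv in zip(itertools.combinations(uniq, 2), hsd.pvalues):
            tukey_pairs.append(((a, b), float(pv)))

    resid = y - np.array([group_means[g] for g in groups])
    try:
        ks_stat, ks_p = ks_normality(resid)
    except DomainError:
        ks_stat, ks_p = float("nan"), float("nan")
    return AnovaResult(
        response=response_name,
        df_between=df_between,
        df_within=df_within,
        F=float(f_val),
        p=p_val,
        r2=float(r2),
        tukey=tukey_pairs,
        ks_stat=ks_stat,
        ks_p=ks_p,
        warnings=notes,
    )


def ks_normality(residuals) -> tuple[float, float]:
    """Kolmogorov-Smirnov residual-normality check against a fitted normal.

    The reference normal uses the residuals' own mean and sample SD, so the
    statistic is location/scale adjusted; the classical KS p-value is
    reported (conservative when parameters are estimated).
    """
    r = np.asarray(residuals, dtype=float)
    if r.size < 5:
        raise DomainError("ks_normality requires at least 5 residuals")
    sd = r.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise DomainError("ks_normality undefined for zero-variance residuals")
    res = stats.kstest(r, "norm", args=(r.mean(), sd))
    return float(res.statistic), float(res.pvalue)
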
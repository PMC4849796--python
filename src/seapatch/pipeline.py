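"""End-to-end orchestration: validate -> QC filter -> dispersion -> covariates
-> path model -> exploratory layer -> report bundle.

Every analysis constant surfaces as a named config key with the study's value
as default (1-3 km bin bounds, 100 m strip minimum, 1,000 permutations,
p <= 0.1 stepwise entry, Bonferroni family of 18, alpha = 0.05).  Identical
config and seed give byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .covariates import (
    COVARIATE_COLUMNS,
    build_covariate_table,
    cross_correlation_matrix,
)
from .dispersion import DispersionResult, analyze_line
from .errors import PipelineError
from .exploratory_stats import anova_by_line, bonferroni_flag, forward_stepwise
from .hierarchy_path import Hierarchy, fit_path_model, render_edge_list, to_dot
from .survey_model import QCRules, apply_qc, build_lines, read_bins, read_lines, write_results

log = logging.getLogger("seapatch")

__all__ = ["RunConfig", "RunResult", "run_pipeline"]

#: the pairwise cross-correlation table covers the 6-hr / daily variables
CORR_COLUMNS = (
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
    "log_density",
)


@dataclass
class RunConfig:
    bins_path: str
    lines_path: str
    out_dir: str
    qc: QCRules = field(default_factory=QCRules)
    x_kind: str = "counts"
    n_perm: int = 1000
    seed: int = 0
    hierarchy_path: str | None = None
    entry_p: float = 0.1
    bonferroni_m: int = 18
    responses: tuple[str, ...] = ("gx", "moran_i", "log_density")
    ns_threshold: float = 0.10
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "qc" in raw and isinstance(raw["qc"], dict):
            raw["qc"] = QCRules(**raw["qc"])
        if "responses" in raw:
            raw["responses"] = tuple(raw["responses"])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["qc"] = dataclasses.asdict(self.qc)
        d["responses"] = list(self.responses)
        return d


@dataclass
class RunResult:
    qc_report: pd.DataFrame
    dispersion: list[DispersionResult]
    covariates: pd.DataFrame
    path_model: object
    stepwise: dict
    anova: dict
    manifest: dict


def _stage(name: str):
    log.info("stage: %s", name)


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all stages on retained lines only and write the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    # --- validate / load -------------------------------------------------
    _stage("read")
    try:
        bins = read_bins(config.bins_path)
        lines_table = read_lines(config.lines_path)
        lines = build_lines(bins, lines_table)
    except Exception as exc:
        raise PipelineError(f"stage read: {exc}") from exc
    log.info("read %d bins on %d lines", len(bins), len(lines))

    # --- QC ---------------------------------------------------------------
    _stage("qc")
    reports = [apply_qc(line, config.qc) for line in lines]
    qc_df = pd.DataFrame(
        {
            "line_id": [r.line_key[0] for r in reports],
            "cruise_id": [r.line_key[1] for r in reports],
            "status": [r.status for r in reports],
            "reasons": [";".join(r.reasons) for r in reports],
        }
    )
    qc_df.to_csv(out / "qc_report.csv", index=False)
    retained = [l for l, r in zip(lines, reports) if r.status == "retained"]
    log.info("QC: %d of %d lines retained", len(retained), len(lines))
    if not retained:
        raise PipelineError(
            "stage qc: every line excluded; see qc_report.csv for per-line reasons"
        )

    # --- dispersion --------------------------------------------------------
    _stage("dispersion")
    results = []
    for line in retained:
        try:
            results.append(
                analyze_line(line, n_perm=config.n_perm, rng=rng, x_kind=config.x_kind)
            )
        except Exception as exc:
            raise PipelineError(f"stage dispersion: line {line.key}: {exc}") from exc
    write_results(results, out / "dispersion.csv")

    # --- covariates --------------------------------------------------------
    _stage("covariates")
    try:
        table = build_covariate_table(retained, results)
        cov_out = table.copy()
        for col in COVARIATE_COLUMNS:
            sd = table[col].std(ddof=1)
            if np.isfinite(sd) and sd > 0:
                cov_out[col + "_z"] = (table[col] - table[col].mean()) / sd
        cov_out.to_csv(out / "covariates.csv", index=False)
        corr = cross_correlation_matrix(
            table, columns=[c for c in CORR_COLUMNS if c in table.columns],
            ns_threshold=config.ns_threshold,
        )
        corr.combined_layout().to_csv(out / "corr_matrix.csv")
    except Exception as exc:
        raise PipelineError(f"stage covariates: {exc}") from exc

    # --- hierarchical path model -------------------------------------------
    _stage("path")
    try:
        hierarchy = (
            Hierarchy.from_yaml(config.hierarchy_path)
            if config.hierarchy_path
            else Hierarchy()
        )
        model = fit_path_model(hierarchy, table)
        render_edge_list(model, out / "path_edges.csv")
        (out / "path_model.dot").write_text(to_dot(model))
    except Exception as exc:
        raise PipelineError(f"stage path: {exc}") from exc

    # --- exploratory layer ---------------------------------------------------
    _stage("explore")
    stepwise, anova = {}, {}
    for response in config.responses:
        try:
            pool = [c for c in COVARIATE_COLUMNS if c in table.columns]
            # the dispersion metrics may also respond to density and to the
            # spatial structure of the bathymetry
            if response in ("gx", "moran_i"):
                pool += ["depth_moran_i", "log_density"]
            pool = [c for c in pool if c != response]
            candidates = table[pool].dropna(axis=1, how="any")
            fit = forward_stepwise(
                table[response].to_numpy(float),
                candidates,
                entry_p=config.entry_p,
                response_name=response,
                bonferroni_m=config.bonferroni_m,
            )
            bonferroni_flag(fit, config.bonferroni_m)
            stepwise[response] = fit
            pd.DataFrame(
                [
                    {
                        "step": i + 1,
                        "variable": s.variable,
                        "standardized_coefficient": s.coefficient,
                        "p_at_entry": s.p_at_entry,
                        "p_final": s.p_final,
                        "bonferroni_significant": s.bonferroni_significant,
                        "adjusted_r2": fit.adjusted_r2,
                    }
                    for i, s in enumerate(fit.steps)
                ]
            ).to_csv(out / f"stepwise_{response}.csv", index=False)

            res = anova_by_line(
                table[response].to_numpy(float),
                table["line_id"].to_numpy(),
                response_name=response,
            )
            anova[response] = res
            pd.DataFrame(
                [
                    {
                        "response": response,
                        "df_between": res.df_between,
                        "df_within": res.df_within,
                        "F": res.F,
                        "p": res.p,
                        "r2": res.r2,
                        "ks_stat": res.ks_stat,
                        "ks_p": res.ks_p,
                    }
                ]
            ).to_csv(out / f"anova_{response}.csv", index=False)
            pd.DataFrame(
                [
                    {"line_a": a, "line_b": b, "p": p}
                    for (a, b), p in res.tukey
                ]
            ).to_csv(out / f"tukey_{response}.csv", index=False)
        except Exception as exc:
            raise PipelineError(f"stage explore ({response}): {exc}") from exc

    # --- manifest -------------------------------------------------------------
    _stage("manifest")
    cfg = config.to_jsonable()
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "n_lines_read": len(lines),
        "n_lines_retained": len(retained),
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return RunResult(
        qc_report=qc_df,
        dispersion=results,
        covariates=table,
        path_model=model,
        stepwise=stepwise,
        anova=anova,
        manifest=manifest,
    )
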
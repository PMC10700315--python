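"""End-to-end orchestration: tables -> removal -> diversity -> PCA ->
meta-analysis -> piecewise SEM, with every stage output written to disk.

The stages and their artifacts:

========================  =====================================
stage                     files written under the output directory
========================  =====================================
data                      data/*.csv (synthetic runs only), ground_truth.json
removal                   removal.csv, site_summary.csv
diversity                 metrics.csv, behavior_tree.nwk
pca                       diversity_diff.csv, pca_climate.csv, pca_diversity.csv
meta                      effects.csv, metafit.json, metareg.csv, wilcoxon.csv
sem                       sem_coefficients.csv, sem_claims.csv, sem_fit.json
report                    report.json
========================  =====================================
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (community_diversity, covariate_pca, dung_removal, effect_meta,
               piecewise_sem, synthetic_data)
from .data_model import StudyBundle, read_tables, write_tables

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "sem_data_table"]

DEFAULT_MODERATORS = ("pca1_climate", "d_cattle_density", "pca1_diversity")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str = "dungbef_run"
    input_dir: str | None = None          # read an existing bundle ...
    synthetic: bool = False               # ... or generate one
    seed: int = 0
    wp_mode: str = "control"              # "control" or "unit"
    abundance_weighted: bool = False
    structures: tuple = effect_meta.STRUCTURES
    moderators: tuple = DEFAULT_MODERATORS
    dag_file: str | None = None           # plain-text model block; default DAG if None
    synthetic_config: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if math.isfinite(v) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def sem_data_table(bundle: StudyBundle, metrics: pd.DataFrame,
                  site_summary: pd.DataFrame,
                  climate_scores: pd.Series) -> pd.DataFrame:
    """One row per pasture with the SEM variables.

    Cattle density enters as log10 (densities span an order of magnitude
    between regimes) and abundance as log1p (counts are heavy-tailed);
    climate is the landscape-level first-axis score.
    """
    df = metrics.merge(bundle.sites[["site_id", "region"]], on="site_id")
    df = df.merge(site_summary[["site_id", "mean_drr"]], on="site_id")
    cov = bundle.covariates.set_index("site_id")
    df["management"] = (df["regime"] == "high").astype(int)
    df["cattle_density"] = np.log10(cov["cattle_density"].reindex(df["site_id"]).to_numpy())
    df["anthelmintic_use"] = cov["anthelmintic_use"].reindex(df["site_id"]).to_numpy()
    df["climate"] = climate_scores.reindex(df["landscape_id"]).to_numpy()
    df["abundance"] = np.log1p(df["abundance"].to_numpy(dtype=float))
    df["dung_removal"] = df["mean_drr"]
    keep = ["site_id", "landscape_id", "region", "management", "cattle_density",
            "anthelmintic_use", "climate", "abundance", "richness",
            "fdis_behavior", "fdis_morphology", "dung_removal"]
    return df[keep]


def _wilcoxon_table(bundle: StudyBundle, metrics: pd.DataFrame,
                    site_summary: pd.DataFrame) -> pd.DataFrame:
    """Paired low-vs-high comparisons of the community and management
    variables (two-tailed Wilcoxon signed-rank per variable)."""
    cov = bundle.covariates.set_index("site_id")
    table = metrics.merge(site_summary[["site_id", "mean_drr"]], on="site_id")
    table["cattle_density_log"] = np.log10(
        cov["cattle_density"].reindex(table["site_id"]).to_numpy())
    table["anthelmintic_use"] = cov["anthelmintic_use"].reindex(table["site_id"]).to_numpy()
    table["land_history"] = cov["land_history"].reindex(table["site_id"]).to_numpy()
    rows = []
    variables = ["abundance", "richness", "mean_drr", "fdis_behavior",
                 "fdis_morphology", "cattle_density_log", "land_history",
                 "anthelmintic_use"]
    wide = table.pivot(index="landscape_id", columns="regime", values=variables)
    for var in variables:
        low = wide[(var, "low")].to_numpy(dtype=float)
        high = wide[(var, "high")].to_numpy(dtype=float)
        try:
            stat, p = effect_meta.paired_wilcoxon(low, high)
        except ValueError as exc:
            stat, p = math.nan, math.nan
        rows.append({"variable": var, "statistic": stat, "p": p,
                     "median_low": float(np.median(low)),
                     "median_high": float(np.median(high))})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the report dictionary.

    Raises :class:`PipelineError` naming the failing stage; outputs of
    completed stages are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _to_jsonable(asdict(config)), "stages": []}

    # ---- data ----------------------------------------------------------
    stage = "data"
    try:
        if config.synthetic:
            cfg = synthetic_data.SyntheticConfig(
                **{"seed": config.seed, **config.synthetic_config})
            bundle, truth = synthetic_data.generate_study(cfg)
            write_tables(bundle, out / "data")
            (out / "ground_truth.json").write_text(
                json.dumps(_to_jsonable(truth), indent=1))
        elif config.input_dir:
            bundle = read_tables(config.input_dir)
        else:
            raise ValueError("config needs input_dir or synthetic=True")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    report["stages"].append(stage)

    # ---- removal -------------------------------------------------------
    stage = "removal"
    try:
        units, site_summary = dung_removal.removal_table(bundle, mode=config.wp_mode)
        units.to_csv(out / "removal.csv", index=False)
        site_summary.to_csv(out / "site_summary.csv", index=False)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    report["stages"].append(stage)

    # ---- diversity -----------------------------------------------------
    stage = "diversity"
    try:
        metrics = community_diversity.community_metrics(
            bundle, abundance_weighted=config.abundance_weighted)
        metrics.to_csv(out / "metrics.csv", index=False)
        (out / "behavior_tree.nwk").write_text(
            community_diversity.behavior_tree_newick() + "\n")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    report["stages"].append(stage)

    # ---- pca -----------------------------------------------------------
    stage = "pca"
    try:
        diffs = covariate_pca.diversity_differences(metrics)
        diffs.to_csv(out / "diversity_diff.csv", index=False)
        land = bundle.sites.drop_duplicates("landscape_id")[["landscape_id", "site_id"]]
        clim = (bundle.covariates.set_index("site_id")
                .loc[land["site_id"], bundle.bioclim_columns])
        clim.index = land["landscape_id"].to_numpy()
        pca_climate = covariate_pca.pca_axis1(clim, anchor=bundle.bioclim_columns[0],
                                              anchor_sign=-1)
        pca_diversity = covariate_pca.pca_axis1(
            diffs.set_index("landscape_id"), anchor="d_fdis_behavior", anchor_sign=1)
        for name, summary in (("pca_climate", pca_climate),
                              ("pca_diversity", pca_diversity)):
            frame = summary.scores.rename("score").to_frame()
            frame.to_csv(out / f"{name}.csv")
            (out / f"{name}_loadings.csv").write_text(
                summary.loadings.rename("loading").to_csv())
        report["pca_climate_variance_fraction"] = pca_climate.variance_fraction
        report["pca_diversity_variance_fraction"] = pca_diversity.variance_fraction
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    report["stages"].append(stage)

    # ---- meta ----------------------------------------------------------
    stage = "meta"
    try:
        effects = effect_meta.effect_sizes(units, bundle.sites)
        effects.to_csv(out / "effects.csv", index=False)
        best, comparison = effect_meta.select_structure(
            effects, candidates=tuple(config.structures))
        het = effect_meta.heterogeneity(effects)
        dens = bundle.covariates.set_index("site_id")["cattle_density"]
        pairs = bundle.sites.pivot(index="landscape_id", columns="regime",
                                   values="site_id")
        d_density = (dens.reindex(pairs["low"]).to_numpy()
                     - dens.reindex(pairs["high"]).to_numpy())
        moderator_pool = pd.DataFrame({
            "pca1_climate": pca_climate.scores.reindex(effects["landscape_id"]).to_numpy(),
            "d_cattle_density": pd.Series(d_density, index=pairs.index)
            .reindex(effects["landscape_id"]).to_numpy(),
            "pca1_diversity": pca_diversity.scores.reindex(effects["landscape_id"]).to_numpy(),
        })
        moderators = moderator_pool[list(config.moderators)]
        metareg = effect_meta.meta_regression(effects, moderators,
                                              structure=best.structure)
        metareg.table.to_csv(out / "metareg.csv", index=False)
        metafit = {
            "selected_structure": best.structure,
            "comparison": comparison.to_dict(orient="records"),
            "pooled": {"mu": best.mu, "se": best.se_mu, "t": best.t,
                       "df": best.df, "p": best.p,
                       "ci": [best.ci_low, best.ci_high]},
            "heterogeneity": het,
            "tau2": best.tau2, "I2": best.I2, "rho_km": best.rho,
            "aicc": best.aicc,
            "meta_regression": {"F": metareg.F, "F_df": list(metareg.F_df),
                                "F_p": metareg.F_p,
                                "pseudo_R2": metareg.pseudo_R2,
                                "tau2_residual": metareg.tau2,
                                "structure": metareg.structure},
        }
        (out / "metafit.json").write_text(json.dumps(_to_jsonable(metafit), indent=1))
        wilcoxon = _wilcoxon_table(bundle, metrics, site_summary)
        wilcoxon.to_csv(out / "wilcoxon.csv", index=False)
        # forest table: per-site g with 95% CI and inverse-variance weights
        zcrit = 1.959963984540054
        forest = effects.assign(
            ci_low=effects["g"] - zcrit * np.sqrt(effects["var_g"] + best.tau2),
            ci_high=effects["g"] + zcrit * np.sqrt(effects["var_g"] + best.tau2),
            weight=(1.0 / (effects["var_g"] + best.tau2))
            / (1.0 / (effects["var_g"] + best.tau2)).sum())
        forest.to_csv(out / "forest.csv", index=False)
        report["meta"] = metafit
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    report["stages"].append(stage)

    # ---- sem -----------------------------------------------------------
    stage = "sem"
    try:
        dag = (piecewise_sem.parse_model(Path(config.dag_file).read_text())
               if config.dag_file else piecewise_sem.default_model())
        sem_data = sem_data_table(bundle, metrics, site_summary, pca_climate.scores)
        sem_fit = piecewise_sem.fit_sem(dag, sem_data, group="region")
        sem_fit.coefficients.to_csv(out / "sem_coefficients.csv", index=False)
        sem_fit.claims.to_csv(out / "sem_claims.csv", index=False)
        sem_json = {
            "fishers_C": sem_fit.C, "df": sem_fit.C_df, "p": sem_fit.C_p,
            "r2": sem_fit.r2.to_dict(orient="records"),
            "suggested_path": list(sem_fit.suggested_path)
            if sem_fit.suggested_path else None,
        }
        (out / "sem_fit.json").write_text(json.dumps(_to_jsonable(sem_json), indent=1))
        report["sem"] = sem_json
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    report["stages"].append(stage)

    (out / "report.json").write_text(json.dumps(_to_jsonable(report), indent=1))
    return report
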
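"""End-to-end orchestration: ingest -> filter -> seasons -> ordination ->
PERMANOVAs -> null model -> mixed models -> report.

Every stochastic stage consumes a sub-seed derived from the master seed by
hashing the stage name, so inserting a stage does not shift the random
streams of the others. Months below the per-month sample minimum are
excluded from ordination, PERMANOVA and null-model stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import data_model, environment, glmm, nullmodel, ordination
from .data_model import CommunityMatrix, FilterConfig
from .environment import SeasonLabeling
from .permanova import DesignSpec, permanova

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Paths, thresholds and per-stage settings for a full run."""

    detection_path: str | None = None
    metadata_path: str | None = None
    environment_path: str | None = None
    unmatched_list_path: str | None = None
    habitat_list_path: str | None = None
    simulate: dict | None = None  # SimulationConfig overrides instead of paths
    do_threshold: float = 2.0
    min_samples_per_month: int = 3
    top_species_fraction: float = 0.10
    nmds_k: int = 3
    nmds_restarts: int = 20
    nmds_tol: float = 1e-6
    n_permutations: int = 999
    n_null: int = 999
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


@dataclass
class StudyReport:
    """Machine-readable results of every stage; failed stages carry an
    ``error`` entry instead of results."""

    sections: dict[str, Any] = field(default_factory=dict)
    failed: list[str] = field(default_factory=list)

    def add(self, name: str, payload: Any) -> None:
        self.sections[name] = payload

    def mark_failed(self, name: str, err: Exception) -> None:
        self.sections[name] = {"error": f"{type(err).__name__}: {err}"}
        self.failed.append(name)

    @property
    def ok(self) -> bool:
        return not self.failed

    def to_json(self, path=None) -> str:
        text = json.dumps(self.sections, indent=2, default=_jsonable)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_markdown(self) -> str:
        lines = ["# Study report", ""]
        for name, payload in self.sections.items():
            lines.append(f"## {name}")
            if isinstance(payload, pd.DataFrame):
                lines.append(payload.to_markdown())
            else:
                lines.append("```json")
                lines.append(json.dumps(payload, indent=2, default=_jsonable))
                lines.append("```")
            lines.append("")
        return "\n".join(lines)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="index")
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def summarize_richness(matrix: CommunityMatrix, seasons: SeasonLabeling) -> pd.DataFrame:
    """Mean and sample SD (n-1) of per-sample richness by season x layer.

    Cells with a single sample report a missing SD.
    """
    rich = matrix.richness()
    meta = matrix.metadata.copy()
    meta["season"] = seasons.sample_labels(meta)
    meta["richness"] = rich
    out = (
        meta.groupby(["season", "layer"], sort=True)["richness"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else np.nan, n="count")
        .reset_index()
    )
    return out


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        from .simulate import SimulationConfig, simulate_dataset

        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", stage_seed(config.seed, "simulate"))
        dataset = simulate_dataset(SimulationConfig(**sim_kwargs))
        return dataset.detection, dataset.metadata, dataset.environment
    detection = data_model.read_detection_table(config.detection_path)
    metadata = data_model.read_metadata_table(config.metadata_path)
    env = environment.read_env_table(config.environment_path)
    return detection, metadata, env


def run_pipeline(config: PipelineConfig) -> StudyReport:
    """Execute the full analysis workflow and assemble the report."""
    report = StudyReport()

    detection, metadata, env = _load_inputs(config)
    # operate only on samples with complete metadata and environment
    keep = metadata["sample_id"].isin(env["sample_id"])
    metadata = metadata[keep].reset_index(drop=True)
    detection = detection[detection["sample_id"].isin(metadata["sample_id"])]

    filt = FilterConfig.from_files(config.unmatched_list_path, config.habitat_list_path)
    detection, filter_report = data_model.apply_species_filters(detection, filt)
    report.add("filter", filter_report.to_dict())

    matrix = data_model.build_community_matrix(detection, metadata)
    seasons = environment.classify_seasons(env, metadata, config.do_threshold)
    report.add(
        "seasons",
        {"threshold_mg_per_l": seasons.threshold,
         "hypoxia_months": seasons.hypoxia_months,
         "normoxia_months": seasons.normoxia_months},
    )

    env_indexed = env.set_index("sample_id").loc[matrix.sample_ids, list(environment.ENV_VARIABLES)]
    sample_season = seasons.sample_labels(matrix.metadata)
    design_data = matrix.metadata.copy()
    design_data["season"] = sample_season
    design_data["depth"] = design_data["site_depth"]

    try:
        report.add("richness_by_cell", summarize_richness(matrix, seasons).to_dict(orient="records"))
    except Exception as err:  # pragma: no cover - defensive
        report.mark_failed("richness_by_cell", err)

    try:
        rich_data = design_data.copy()
        rich_data["richness"] = matrix.richness()
        spec = glmm.GlmmSpec(
            family="poisson-log",
            fixed_terms=("season", "layer", "season:layer"),
            random_group="site_id",
            random_terms=("intercept",),
        )
        fit = glmm.fit_glmm(rich_data, "richness", spec)
        report.add("richness_glmm", fit.to_dict())
    except Exception as err:
        report.mark_failed("richness_glmm", err)

    try:
        pca = environment.run_pca(env_indexed, standardize=True)
        report.add(
            "pca",
            {"variance_fraction": pca.variance_fraction.tolist(),
             "loadings": pca.loadings.round(4).to_dict(orient="index")},
        )
    except Exception as err:
        report.mark_failed("pca", err)

    # months below the minimum are excluded from distance-based analyses
    month_sizes = matrix.metadata["month"].value_counts()
    ok_months = month_sizes.index[month_sizes >= config.min_samples_per_month]
    keep_ids = matrix.metadata.index[matrix.metadata["month"].isin(ok_months)]
    dist_matrix = matrix.subset_samples(list(keep_ids))
    dist_design = design_data.loc[keep_ids]
    dist_env = env_indexed.loc[keep_ids]

    try:
        env_dm = ordination.euclidean_matrix(dist_env, standardize=True)
        res = permanova(
            env_dm,
            DesignSpec(
                terms=["season", "layer", "season:layer"],
                data=dist_design,
                n_permutations=config.n_permutations,
                seed=stage_seed(config.seed, "permanova-env"),
            ),
        )
        report.add("permanova_environment", res.table.reset_index().to_dict(orient="records"))
    except Exception as err:
        report.mark_failed("permanova_environment", err)

    try:
        jac = ordination.jaccard_matrix(dist_matrix, on_empty_union="zero")
        res = permanova(
            jac,
            DesignSpec(
                terms=["season", "layer", "season:layer"],
                data=dist_design,
                n_permutations=config.n_permutations,
                seed=stage_seed(config.seed, "permanova-composition"),
            ),
        )
        report.add("permanova_composition", res.table.reset_index().to_dict(orient="records"))

        res_depth = permanova(
            jac,
            DesignSpec(
                terms=["layer", "depth", "layer:depth"],
                data=dist_design,
                n_permutations=config.n_permutations,
                seed=stage_seed(config.seed, "permanova-depth"),
            ),
        )
        report.add("permanova_layer_depth", res_depth.table.reset_index().to_dict(orient="records"))
    except Exception as err:
        report.mark_failed("permanova_composition", err)
        jac = None

    try:
        if jac is None:
            raise RuntimeError("Jaccard matrix unavailable")
        ord_res = ordination.nmds(
            jac,
            k=config.nmds_k,
            n_restarts=config.nmds_restarts,
            tol=config.nmds_tol,
            seed=stage_seed(config.seed, "nmds"),
        )
        centroids = {}
        for season in ("hypoxia", "normoxia"):
            ids = dist_design.index[dist_design["season"] == season]
            if len(ids) == 0:
                continue
            sub = ordination.Ordination(
                coordinates=ord_res.coordinates.loc[ids],
                stress=ord_res.stress, k=ord_res.k,
                converged=ord_res.converged, n_restarts=ord_res.n_restarts,
            )
            centroids[season] = ordination.centroid_distance(
                sub, dist_design.loc[ids, "layer"], "surface", "bottom"
            )
        report.add(
            "nmds",
            {"stress": ord_res.stress, "k": ord_res.k, "converged": ord_res.converged,
             "surface_bottom_centroid_distance": centroids},
        )
    except Exception as err:
        report.mark_failed("nmds", err)

    try:
        null_cfg = nullmodel.NullModelConfig(
            n_null=config.n_null,
            seed=stage_seed(config.seed, "nullmodel"),
            min_samples_per_month=config.min_samples_per_month,
        )
        null_res = nullmodel.pairwise_null_quantiles(matrix, seasons, null_cfg)
        comparison = nullmodel.compare_quantiles_by_season(null_res, seasons)
        season_col = null_res.pairs["month"].map(seasons.labels)
        within = null_res.pairs.groupby(season_col)["within_bounds"].agg(["sum", "count"])
        report.add(
            "null_model",
            {
                "n_pairs_total": int(len(null_res.pairs)),
                "n_pairs_hypoxia": comparison.n_pairs_hypoxia,
                "n_pairs_normoxia": comparison.n_pairs_normoxia,
                "skipped_months": null_res.skipped_months,
                "mean_quantile_hypoxia": float(np.mean(comparison.quantiles_hypoxia)),
                "mean_quantile_normoxia": float(np.mean(comparison.quantiles_normoxia)),
                "within_bounds": {
                    season: {"within": int(row["sum"]), "total": int(row["count"])}
                    for season, row in within.iterrows()
                },
                "rank_sum_statistic": comparison.rank_sum_statistic,
                "p_value": comparison.p_value,
            },
        )
    except Exception as err:
        report.mark_failed("null_model", err)

    try:
        top = data_model.select_top_species(matrix, config.top_species_fraction)
        occ = matrix.subset_species(top)
        long = (
            occ.occupancy.stack().rename("detected").reset_index()
        )
        long.columns = ["sample_id", "species_name", "detected"]
        long = long.merge(design_data.reset_index(), on="sample_id")
        spec_full = glmm.GlmmSpec(
            family="bernoulli-logit",
            fixed_terms=("season", "layer", "season:layer"),
            random_group="species_name",
            random_terms=("intercept", "season", "layer", "season:layer"),
        )
        spec_reduced = glmm.GlmmSpec(
            family="bernoulli-logit",
            fixed_terms=("season", "layer", "season:layer"),
            random_group="species_name",
            random_terms=("intercept", "season", "layer"),
        )
        fit_full = glmm.fit_glmm(long, "detected", spec_full)
        fit_reduced = glmm.fit_glmm(long, "detected", spec_reduced)
        lrt = glmm.likelihood_ratio_test(fit_full, fit_reduced)
        report.add(
            "occurrence_glmm",
            {
                "n_top_species": len(top),
                "top_species": top,
                "full": fit_full.to_dict(),
                "reduced": fit_reduced.to_dict(),
                "lrt": {"chi2": lrt.chi2, "df": lrt.df, "p_value": lrt.p_value},
            },
        )
    except Exception as err:
        report.mark_failed("occurrence_glmm", err)

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / "report.json")
        (out / "report.md").write_text(report.to_markdown())
        matrix.to_wide_csv(out / "community_matrix.csv")
    return report
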
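"""End-to-end orchestration: simulate → normalize → cluster → group →
profile → score, with deterministic CSV outputs."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .clustering import (
    ClusterModel,
    NormalizedFeatureTable,
    cluster_kmeans,
    embed_umap,
    group_clusters_ward,
    normalize_features,
    select_k,
)
from .features import GH2AX_COL
from .io import PipelineConfig
from .profiles import (
    ConditionProfile,
    cluster_fractions,
    damage_by_cluster,
    enrichment_matrix,
    profiles_frame,
)
from .susceptibility import (
    SusceptibilityInput,
    SusceptibilityResult,
    normalize_to_parental,
    rank_populations,
    score_table,
    susceptibility_score,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: PipelineConfig
    table: pd.DataFrame  # input feature table with cluster/CG columns added
    normalized: NormalizedFeatureTable
    model: ClusterModel
    profiles: list[ConditionProfile]
    profile_table: pd.DataFrame
    scores: pd.DataFrame | None


def cluster_feature_table(
    table: pd.DataFrame,
    config: PipelineConfig,
    k: int | None = None,
    with_embedding: bool = False,
) -> tuple[NormalizedFeatureTable, ClusterModel]:
    """Normalize, pick k (unless given), cluster, and Ward-group."""
    norm = normalize_features(table, eps=config.log_eps)
    selection = None
    if k is None:
        selection = select_k(
            norm, config.k_range, seed=config.seed, n_init=config.kmeans_n_init
        )
        k = selection.k
        logger.info("selected k=%d%s", k, f" ({selection.note})" if selection.note else "")
    model = cluster_kmeans(
        norm, k, seed=config.seed, n_init=config.kmeans_n_init,
        cell_area=table["cell_area"].to_numpy(),
    )
    model.selection = selection
    group_clusters_ward(model, config.n_groups)
    if with_embedding:
        model.embedding = embed_umap(
            norm,
            n_neighbors=config.umap_n_neighbors,
            min_dist=config.umap_min_dist,
            seed=config.seed,
            cell_area=table["cell_area"].to_numpy(),
            aspect_ratio=table["cell_aspect_ratio"].to_numpy(),
        )
    return norm, model


def run_pipeline(
    config: PipelineConfig,
    table: pd.DataFrame | None = None,
    k: int | None = None,
    with_embedding: bool = False,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis on ``table`` (or the default synthetic
    fixture when none is given) and optionally write the output CSVs."""
    if table is None:
        table = synthetic.default_fixture(config.n_cells, seed=config.seed)
    table = table.reset_index(drop=True)
    norm, model = cluster_feature_table(table, config, k=k, with_embedding=with_embedding)
    table = table.copy()
    table["cluster"] = model.labels
    table["cg"] = model.cg_labels()
    if model.embedding is not None:
        table["umap_1"] = model.embedding[:, 0]
        table["umap_2"] = model.embedding[:, 1]

    profiles = cluster_fractions(
        model.labels,
        model.k,
        population_id=table.get("population_id"),
        condition_id=table.get("condition_id"),
        cg_map=model.cg_map,
        entropy_base=config.entropy_base,
    )
    ptable = profiles_frame(profiles)

    scores = None
    if "dose_level" in table.columns:
        scores = score_populations(table, config.parental_id)

    result = PipelineResult(config, table, norm, model, profiles, ptable, scores)
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def score_populations(
    table: pd.DataFrame, parental_id: str = "parental"
) -> pd.DataFrame | None:
    """Eq.-style susceptibility scores from a clustered cell table.

    Requires ``cg`` and ``dose_level`` columns with all three dose
    levels present per population; populations missing a dose or with an
    undefined score are listed with NaN score and the reason.
    """
    needed = {"control", "low", "high"}
    results: list[SusceptibilityResult] = []
    skipped: list[tuple[str, str]] = []
    for pop, sub in table.groupby("population_id", sort=True):
        doses = set(sub["dose_level"])
        if not needed <= doses:
            skipped.append((str(pop), f"missing doses {sorted(needed - doses)}"))
            continue
        fr = {
            d: float((sub.loc[sub["dose_level"] == d, "cg"] == 1).mean())
            for d in needed
        }
        try:
            results.append(
                susceptibility_score(
                    SusceptibilityInput(str(pop), fr["control"], fr["low"], fr["high"])
                )
            )
        except ValueError as e:
            skipped.append((str(pop), str(e)))
    if len(results) < 1:
        return None
    if any(r.population_id == parental_id for r in results):
        normalize_to_parental(results, parental_id)
    if len(results) >= 2:
        results = rank_populations(results)
    out = score_table(results)
    for pop, reason in skipped:
        out = pd.concat(
            [out, pd.DataFrame([{"population_id": pop, "score": np.nan,
                                 "monotone": pd.NA, "rank": pd.NA,
                                 "score_normalized": np.nan,
                                 "reason": reason}])],
            ignore_index=True,
        )
    return out


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Write the flat-file bundle: clustered cells, model, profiles,
    enrichment matrix, damage map, scores, selection trace, config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    float_fmt = "%.10g"  # fixed text representation => byte-stable reruns

    result.table.to_csv(outdir / "cells.csv", index=False, float_format=float_fmt)
    result.profile_table.to_csv(
        outdir / "profiles.csv", index=False, float_format=float_fmt
    )
    pd.DataFrame(
        result.model.centroids, columns=result.normalized.data.columns,
        index=pd.RangeIndex(1, result.model.k + 1, name="cluster"),
    ).to_csv(outdir / "centroids.csv", float_format=float_fmt)
    pd.Series(result.model.cg_map, name="cg").rename_axis("cluster").to_csv(
        outdir / "cg_map.csv"
    )
    if result.model.selection is not None:
        result.model.selection.trace.to_csv(
            outdir / "selection_trace.csv", index=False, float_format=float_fmt
        )
    if len({pr.condition_id for pr in result.profiles}) >= 2:
        enr = enrichment_matrix(result.profiles, result.model.centroids)
        enr.matrix.to_csv(outdir / "enrichment_matrix.csv", float_format=float_fmt)
        enr.entropy.rename_axis("condition").to_csv(
            outdir / "entropy.csv", float_format=float_fmt
        )
    if GH2AX_COL in result.table.columns:
        per_cluster, per_condition = damage_by_cluster(
            result.table[GH2AX_COL].to_numpy(),
            result.model.labels,
            result.model.k,
            condition_id=result.table.get("condition_id"),
        )
        per_cluster.rename_axis("cluster").to_csv(
            outdir / "damage_by_cluster.csv", float_format=float_fmt
        )
        if per_condition is not None:
            per_condition.rename_axis("condition").to_csv(
                outdir / "damage_by_condition.csv", float_format=float_fmt
            )
    if result.scores is not None:
        result.scores.to_csv(outdir / "scores.csv", index=False, float_format=float_fmt)
    result.config.to_yaml(outdir / "config_resolved.yaml")
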
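"""Population-level profiles: cluster fractions, Shannon entropy,
enrichment matrices, damage-by-cluster maps, and summary correlations.

Entropy is computed over the global k clusters (clusters absent from a
condition contribute zero by continuity), in natural log by default, so
the maximum-heterogeneity value for k clusters is ln k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import pearsonr

logger = logging.getLogger(__name__)


def shannon_entropy(p: np.ndarray, base: float | None = None) -> float:
    """Shannon entropy S = −Σ p_i log p_i of a fraction vector.

    Zero entries contribute 0; ``base=None`` means natural log (nats).
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("fractions must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions sum to {p.sum()}, not 1")
    nz = p[p > 0]
    s = float(-(nz * np.log(nz)).sum())
    if base is not None:
        s /= np.log(base)
    return s


@dataclass
class ConditionProfile:
    """Cluster-occupancy profile of one (population, condition) group."""

    population_id: str
    condition_id: str
    n_cells: int
    p: np.ndarray  # fractions over clusters 1..k
    p_cg: np.ndarray  # fractions over cluster-groups 1..G
    entropy: float  # Shannon entropy of p, nats by default


def cluster_fractions(
    labels: np.ndarray,
    k: int,
    population_id: np.ndarray | None = None,
    condition_id: np.ndarray | None = None,
    cg_map: dict[int, int] | None = None,
    entropy_base: float | None = None,
) -> list[ConditionProfile]:
    """Per-(population, condition) cluster-fraction profiles.

    ``labels`` are 1-based cluster ids; clusters absent from a group get
    fraction 0.  When ``cg_map`` is given, fractions are also aggregated
    over cluster-groups.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n == 0:
        raise ValueError("no cells")
    if labels.min() < 1 or labels.max() > k:
        raise ValueError("cluster labels must lie in 1..k")
    pop = np.asarray(population_id) if population_id is not None else np.full(n, "all")
    cond = np.asarray(condition_id) if condition_id is not None else np.full(n, "all")

    groups = pd.DataFrame({"pop": pop, "cond": cond, "label": labels})
    profiles = []
    for (p_id, c_id), sub in groups.groupby(["pop", "cond"], sort=True):
        counts = np.bincount(sub["label"].to_numpy(), minlength=k + 1)[1:]
        frac = counts / counts.sum()
        if cg_map:
            G = max(cg_map.values())
            p_cg = np.zeros(G)
            for c, g in cg_map.items():
                p_cg[g - 1] += frac[c - 1]
        else:
            p_cg = frac.copy()
        profiles.append(
            ConditionProfile(
                str(p_id), str(c_id), int(len(sub)), frac, p_cg,
                shannon_entropy(frac, base=entropy_base),
            )
        )
    return profiles


def profiles_frame(profiles: list[ConditionProfile]) -> pd.DataFrame:
    """Flatten profiles to a table: population, condition, n, p_1..p_k,
    p_CG1..p_CGG, entropy."""
    rows = []
    for pr in profiles:
        row = {"population_id": pr.population_id, "condition_id": pr.condition_id,
               "n_cells": pr.n_cells}
        row.update({f"p_{i + 1}": v for i, v in enumerate(pr.p)})
        row.update({f"p_CG{g + 1}": v for g, v in enumerate(pr.p_cg)})
        row["entropy"] = pr.entropy
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class EnrichmentMatrix:
    """Clusters × conditions fraction matrix with dendrogram row order."""

    matrix: pd.DataFrame  # index: cluster id (dendrogram order); columns: conditions
    entropy: pd.Series  # per condition
    row_order: list[int]


def enrichment_matrix(
    profiles: list[ConditionProfile],
    centroid_signatures: np.ndarray | None = None,
) -> EnrichmentMatrix:
    """Cluster-by-condition enrichment of cell fractions.

    Each column is one condition's fraction vector (columns sum to 1);
    rows are ordered by the Ward dendrogram of the cluster mean
    signatures when given, else by cluster id.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 conditions")
    ks = {len(pr.p) for pr in profiles}
    if len(ks) != 1:
        raise ValueError(f"mismatched cluster counts across profiles: {sorted(ks)}")
    k = ks.pop()
    cols = {pr.condition_id: pr.p for pr in profiles}
    mat = pd.DataFrame(cols, index=pd.RangeIndex(1, k + 1, name="cluster"))
    if centroid_signatures is not None:
        if len(centroid_signatures) != k:
            raise ValueError("signatures do not match cluster count")
        order = [int(i) + 1 for i in leaves_list(linkage(centroid_signatures, "ward"))]
    else:
        order = list(range(1, k + 1))
    ent = pd.Series({pr.condition_id: pr.entropy for pr in profiles}, name="entropy")
    return EnrichmentMatrix(mat.loc[order], ent, order)


def damage_by_cluster(
    damage: np.ndarray,
    labels: np.ndarray,
    k: int,
    condition_id: np.ndarray | None = None,
) -> tuple[pd.Series, pd.Series | None]:
    """Mean γH2AX per morphology cluster, cells pooled across conditions.

    Returns (per-cluster means indexed by cluster id, per-condition
    means or None).  Cells with missing damage values are excluded with
    the count logged.
    """
    damage = np.asarray(damage, dtype=float)
    labels = np.asarray(labels)
    ok = np.isfinite(damage)
    if (~ok).any():
        logger.warning("excluding %d cells with missing damage values", (~ok).sum())
    df = pd.DataFrame({"damage": damage[ok], "cluster": labels[ok]})
    per_cluster = (
        df.groupby("cluster")["damage"].mean()
        .reindex(range(1, k + 1))
        .rename("mean_gh2ax")
    )
    per_condition = None
    if condition_id is not None:
        cond = np.asarray(condition_id)[ok]
        per_condition = (
            pd.DataFrame({"damage": df["damage"].to_numpy(), "condition": cond})
            .groupby("condition")["damage"].mean().rename("mean_gh2ax")
        )
    return per_cluster, per_condition


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with two-sided t-distribution p-value.

    Intended for small summary tables, e.g. per-condition mean γH2AX
    against dead-cell fractions.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in input vector")
    res = pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
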
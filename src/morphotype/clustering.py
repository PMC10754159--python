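"""Feature normalization, 2-D embedding, k selection, k-means morphology
clusters, and Ward cluster-groups.

The normalization contract is ``x -> log10(x + eps)`` per feature,
followed by z-scoring against the fitting set (population sd).  Cluster
ids are renumbered in decreasing mean cell area so that cluster 1 is
always the largest-cell morphology; cluster-group ids follow the same
convention (CG1 = largest cells).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import spearmanr
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .features import DEFAULT_EPS, FEATURE_NAMES, feature_eps

logger = logging.getLogger(__name__)

_SILHOUETTE_SAMPLE = 2500


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


@dataclass
class LogZTransform:
    """Fitted per-feature log10(x + eps) + z-score transform.

    Zero-variance (constant) features map to all-zeros and invert back
    to their constant value.
    """

    features: tuple[str, ...]
    eps: np.ndarray  # per-feature offset inside the log
    mean: np.ndarray  # of log10(x + eps) on the fitting set
    sd: np.ndarray  # population sd (ddof=0); 0 flags a constant feature

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        X = table[list(self.features)].to_numpy(dtype=float)
        shifted = X + self.eps
        if (shifted <= 0).any():
            bad = [
                self.features[j]
                for j in np.unique(np.argwhere(shifted <= 0)[:, 1])
            ]
            raise ValueError(f"nonpositive values under log transform: {bad}")
        logged = np.log10(shifted)
        sd = np.where(self.sd > 0, self.sd, 1.0)
        Z = (logged - self.mean) / sd
        Z[:, self.sd == 0] = 0.0
        return pd.DataFrame(Z, columns=self.features, index=table.index)

    def invert(self, normalized: pd.DataFrame) -> pd.DataFrame:
        Z = normalized[list(self.features)].to_numpy(dtype=float)
        logged = Z * np.where(self.sd > 0, self.sd, 0.0) + self.mean
        X = 10.0**logged - self.eps
        return pd.DataFrame(X, columns=self.features, index=normalized.index)


@dataclass
class NormalizedFeatureTable:
    """Normalized per-cell features plus the fitted transform."""

    data: pd.DataFrame  # cells x features, normalized
    transform: LogZTransform

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def normalize_features(
    table: pd.DataFrame,
    features: tuple[str, ...] = FEATURE_NAMES,
    eps: float = DEFAULT_EPS,
) -> NormalizedFeatureTable:
    """Fit the log10 + z-score transform on ``table`` and apply it.

    ``eps`` is used only for ratio features that may legitimately reach
    zero; strictly positive features get no offset, and a nonpositive
    value in one of them raises with the feature named.
    """
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise ValueError(f"feature columns missing from table: {missing}")
    eps_vec = np.array([feature_eps(f, eps) for f in features])
    X = table[list(features)].to_numpy(dtype=float) + eps_vec
    if (X <= 0).any():
        bad = [features[j] for j in np.unique(np.argwhere(X <= 0)[:, 1])]
        raise ValueError(f"nonpositive values under log transform: {bad}")
    logged = np.log10(X)
    mean = logged.mean(axis=0)
    sd = logged.std(axis=0)  # ddof=0
    tr = LogZTransform(tuple(features), eps_vec, mean, sd)
    return NormalizedFeatureTable(tr.apply(table), tr)


# ---------------------------------------------------------------------------
# k selection
# ---------------------------------------------------------------------------


@dataclass
class KSelection:
    """Outcome of the inertia/silhouette plateau criterion."""

    k: int
    trace: pd.DataFrame  # columns: k, inertia, silhouette, knee_distance
    no_distinct_knee: bool = False
    note: str = ""


def select_k(
    table: NormalizedFeatureTable,
    k_range: tuple[int, int] = (2, 20),
    seed: int = 0,
    n_init: int = 50,
    silhouette_tol: float = 0.01,
) -> KSelection:
    """Choose k at the plateau of the k-means inertia/silhouette curves.

    For each candidate k the inertia and mean silhouette are recorded;
    the selected k is the knee of the inertia curve (maximum
    perpendicular distance to the chord across the scanned range, both
    axes min-max normalized).  Near-ties are broken toward the first k
    whose silhouette change has flattened (|Δsilhouette| below
    ``silhouette_tol``), then toward smaller k.
    """
    X = table.values
    n = len(X)
    lo, hi = k_range
    if lo < 2 or hi > max(2, n // 10):
        raise ValueError("k_range must lie within [2, n_cells/10]")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate data: all rows identical")
    ks = np.arange(lo, hi + 1)
    inertia = np.empty(len(ks))
    sil = np.empty(len(ks))
    rng = np.random.default_rng(seed)
    sil_idx = (
        rng.choice(n, _SILHOUETTE_SAMPLE, replace=False)
        if n > _SILHOUETTE_SAMPLE
        else np.arange(n)
    )
    for i, k in enumerate(ks):
        km = KMeans(n_clusters=int(k), n_init=n_init, random_state=seed, tol=1e-6)
        labels = km.fit_predict(X)
        inertia[i] = km.inertia_
        sub = labels[sil_idx]
        if len(np.unique(sub)) < 2:  # subsample hit a single cluster
            sub_idx = np.arange(n)
            sub = labels
        else:
            sub_idx = sil_idx
        sil[i] = silhouette_score(X[sub_idx], sub)

    # knee: max perpendicular distance to the chord on normalized axes
    kx = (ks - ks[0]) / max(ks[-1] - ks[0], 1)
    iy = (inertia - inertia.min()) / max(inertia.max() - inertia.min(), 1e-300)
    p0 = np.array([kx[0], iy[0]])
    p1 = np.array([kx[-1], iy[-1]])
    chord = p1 - p0
    chord /= np.hypot(*chord)
    rel = np.stack([kx, iy], axis=1) - p0
    dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])

    trace = pd.DataFrame(
        {"k": ks, "inertia": inertia, "silhouette": sil, "knee_distance": dist}
    )
    dmax = dist.max()
    # structureless data has no distinct knee: either the curve bends
    # gently everywhere (small max chord distance) or splitting merely
    # shaves variance off one blob (small total relative inertia drop,
    # vs >80% when real clusters exist)
    rel_drop = (inertia[0] - inertia[-1]) / inertia[0]
    if dmax < 0.1 or rel_drop < 0.5:
        logger.warning(
            "no distinct inertia knee (max distance %.4f, relative drop %.2f)",
            dmax, rel_drop,
        )
        return KSelection(
            int(ks[0]), trace, no_distinct_knee=True,
            note=f"no distinct knee (max chord distance {dmax:.4f}, "
            f"relative inertia drop {rel_drop:.2f}); returning k_range minimum",
        )
    near = np.flatnonzero(dist >= dmax - 1e-9)
    dsil = np.abs(np.diff(sil, prepend=sil[0]))
    flat = [i for i in near if dsil[i] < silhouette_tol]
    pick = (flat or list(near))[0]
    return KSelection(int(ks[pick]), trace)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterModel:
    """Fitted morphology-cluster model.

    Cluster ids run 1..k in decreasing mean cell area; ``cg_map`` (once
    assigned) maps each cluster id to its cluster-group, CG ids likewise
    decreasing in mean cell area.
    """

    k: int
    centroids: np.ndarray  # k x n_features, normalized space
    labels: np.ndarray  # per-cell, 1..k
    inertia: float
    mean_cell_area: np.ndarray  # per cluster id (1-based order)
    cg_map: dict[int, int] = field(default_factory=dict)
    embedding: np.ndarray | None = None  # per-cell 2-D, oriented
    selection: KSelection | None = None

    @property
    def n_groups(self) -> int:
        return len(set(self.cg_map.values())) if self.cg_map else 0

    def cg_labels(self) -> np.ndarray:
        """Per-cell cluster-group ids."""
        if not self.cg_map:
            raise ValueError("cg_map not assigned; run group_clusters_ward")
        lut = np.zeros(self.k + 1, dtype=int)
        for c, g in self.cg_map.items():
            lut[c] = g
        return lut[self.labels]


def cluster_kmeans(
    table: NormalizedFeatureTable,
    k: int,
    seed: int = 0,
    n_init: int = 50,
    cell_area: np.ndarray | None = None,
) -> ClusterModel:
    """k-means morphology clusters (best of ``n_init`` restarts).

    ``cell_area`` (original scale, per cell) drives the reportable
    renumbering: cluster 1 has the largest mean cell area.  When not
    given, it is recovered from the normalized table via the transform.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X = table.values
    if cell_area is None:
        cell_area = table.transform.invert(table.data)["cell_area"].to_numpy()
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, tol=1e-6)
    raw = km.fit_predict(X)
    sizes = np.bincount(raw, minlength=k)
    if (sizes == 0).any():  # sklearn relocates empty clusters; belt-and-braces
        logger.warning("empty cluster after convergence; restarting")
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed + 1, tol=1e-6)
        raw = km.fit_predict(X)
    means = np.array([cell_area[raw == j].mean() for j in range(k)])
    order = np.argsort(-means)  # decreasing mean cell area
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    return ClusterModel(
        k=k,
        centroids=km.cluster_centers_[order],
        labels=relabel[raw],
        inertia=float(km.inertia_),
        mean_cell_area=means[order],
    )


def group_clusters_ward(
    model: ClusterModel, n_groups: int | str = "auto"
) -> dict[int, int]:
    """Group cluster mean signatures into cluster-groups by Ward linkage.

    With ``n_groups="auto"`` the tree is cut at the largest gap between
    successive merge heights.  CG ids are renumbered in decreasing mean
    cell area of their member clusters (CG1 = largest-cell group).  The
    mapping is stored on ``model.cg_map`` and returned.
    """
    k = model.k
    if n_groups != "auto":
        n_groups = int(n_groups)
        if n_groups > k:
            raise ValueError("n_groups cannot exceed the number of clusters")
        if n_groups == k:
            model.cg_map = {c: c for c in range(1, k + 1)}
            return model.cg_map
    Z = linkage(model.centroids, method="ward")
    if n_groups == "auto":
        heights = Z[:, 2]
        gaps = np.diff(heights)
        j = int(np.argmax(gaps))  # cut between merges j and j+1
        n_groups = k - (j + 1)
        n_groups = max(n_groups, 1)
    raw = fcluster(Z, t=n_groups, criterion="maxclust")  # per cluster id order
    # renumber groups by decreasing mean cell area over member clusters
    group_area = {
        g: model.mean_cell_area[raw == g].mean() for g in np.unique(raw)
    }
    order = sorted(group_area, key=lambda g: -group_area[g])
    renum = {g: i + 1 for i, g in enumerate(order)}
    model.cg_map = {c + 1: renum[raw[c]] for c in range(k)}
    return model.cg_map


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------


def embed_umap(
    table: NormalizedFeatureTable,
    n_neighbors: int = 30,
    min_dist: float = 0.1,
    seed: int = 0,
    cell_area: np.ndarray | None = None,
    aspect_ratio: np.ndarray | None = None,
) -> np.ndarray:
    """2-D UMAP embedding with a fixed axis-orientation convention.

    Raw UMAP axes are arbitrary; the two output axes are post-processed
    (swap/flip) so that axis 1 anti-correlates with cell size and axis 2
    correlates positively with cell elongation (Spearman, computed on
    the provided or inverted-from-normalized cell area / aspect ratio).
    """
    import umap

    X = table.values
    n = len(X)
    if n < 10:
        raise ValueError("need at least 10 cells to embed")
    if n_neighbors >= n:
        logger.warning(
            "n_neighbors=%d >= n_cells=%d; shrinking to %d", n_neighbors, n, n - 1
        )
        n_neighbors = n - 1
    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist,
        random_state=seed,
    )
    emb = np.asarray(reducer.fit_transform(X), dtype=float)

    if cell_area is None or aspect_ratio is None:
        orig = table.transform.invert(table.data)
        cell_area = orig["cell_area"].to_numpy() if cell_area is None else cell_area
        if aspect_ratio is None:
            aspect_ratio = orig["cell_aspect_ratio"].to_numpy()

    r_area = np.array([spearmanr(emb[:, j], cell_area).statistic for j in (0, 1)])
    # the axis more strongly tied to size becomes axis 1
    if abs(r_area[1]) > abs(r_area[0]):
        emb = emb[:, ::-1]
    oriented = emb.copy()
    if spearmanr(oriented[:, 0], cell_area).statistic > 0:
        oriented[:, 0] *= -1.0
    if spearmanr(oriented[:, 1], aspect_ratio).statistic < 0:
        oriented[:, 1] *= -1.0
    return oriented
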
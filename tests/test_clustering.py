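"""Normalization contract, k selection, k-means clustering, Ward
cluster-groups, and the UMAP axis-orientation convention."""

import numpy as np
import pandas as pd
import pytest

from morphotype import synthetic as syn
from morphotype.clustering import (
    cluster_kmeans,
    embed_umap,
    group_clusters_ward,
    normalize_features,
    select_k,
)
from morphotype.features import FEATURE_NAMES


def subtype_table(n_per, subtype_ids, seed=0):
    subs = [s for s in syn.default_subtypes() if s.subtype_id in subtype_ids]
    fr = tuple(1.0 / len(subs) for _ in subs)
    cond = syn.ConditionSpec("mix", "control", fr)
    return syn.generate_population(subs, cond, n_per * len(subs), seed=seed)


class TestNormalizeFeatures:
    def test_log10_then_zscore_oracle(self):
        """{1,10,100} -> log10 {0,1,2} -> z-scores ±sqrt(3/2) (population sd)."""
        cols = {f: [1.0, 10.0, 100.0] for f in FEATURE_NAMES}
        table = pd.DataFrame(cols)
        norm = normalize_features(table)
        np.testing.assert_allclose(
            norm.data[FEATURE_NAMES[0]], [-1.224745, 0.0, 1.224745], atol=1e-6
        )

    def test_constant_column_maps_to_zeros(self):
        cols = {f: [5.0, 5.0, 5.0] for f in FEATURE_NAMES}
        norm = normalize_features(pd.DataFrame(cols))
        assert (norm.data.to_numpy() == 0).all()

    def test_fitted_columns_standardized(self):
        table = syn.default_fixture(400, seed=1)
        norm = normalize_features(table)
        np.testing.assert_allclose(norm.data.mean(), 0.0, atol=1e-6)
        sds = norm.data.std(ddof=0)
        np.testing.assert_allclose(sds[sds > 0], 1.0, atol=1e-6)

    def test_apply_is_idempotent_and_invertible(self):
        table = syn.default_fixture(300, seed=2)
        norm = normalize_features(table)
        again = norm.transform.apply(table)
        pd.testing.assert_frame_equal(norm.data, again)
        back = norm.transform.invert(norm.data)
        orig = table[list(FEATURE_NAMES)]
        assert float(((back - orig).abs() / orig.abs().clip(lower=1e-12)).max().max()) < 1e-9

    def test_nonpositive_value_names_feature(self):
        table = syn.default_fixture(50, seed=3).copy()
        table.loc[0, "cell_area"] = -1.0
        with pytest.raises(ValueError, match="cell_area"):
            normalize_features(table)


class TestSelectK:
    def test_three_well_separated_subtypes(self):
        """Inertia knee and silhouette agree at the planted k=3."""
        table = subtype_table(250, (1, 6, 10), seed=4)
        norm = normalize_features(table)
        sel = select_k(norm, (2, 10), seed=0, n_init=10)
        assert sel.k == 3
        assert not sel.no_distinct_knee
        assert sel.trace.loc[sel.trace["silhouette"].idxmax(), "k"] == 3

    def test_single_blob_flagged_no_knee(self):
        table = subtype_table(600, (5,), seed=5)
        norm = normalize_features(table)
        sel = select_k(norm, (2, 8), seed=0, n_init=5)
        assert sel.no_distinct_knee
        assert sel.k == 2

    def test_degenerate_identical_rows_rejected(self):
        cols = {f: np.full(100, 3.0) for f in FEATURE_NAMES}
        norm = normalize_features(pd.DataFrame(cols))
        with pytest.raises(ValueError, match="degenerate"):
            select_k(norm, (2, 5), seed=0, n_init=2)

    def test_k_range_validated(self):
        table = subtype_table(20, (1, 10), seed=6)
        norm = normalize_features(table)
        with pytest.raises(ValueError):
            select_k(norm, (2, 30), seed=0)

    @pytest.mark.parametrize("planted", [3, 5, 10])
    def test_planted_k_recovery_rate(self, planted):
        """select_k recovers planted k in >=90% of 20 seeded replicates.

        Sub-fixtures of 3 and 5 archetypes are scanned over (2, 12); the
        full 10-subtype fixture is evaluated at its own study conditions
        (condition mixture, 6,000 cells, default (2, 20) scan).
        """
        hits = 0
        for seed in range(20):
            if planted == 10:
                table = syn.default_fixture(6000, seed=100 + seed)
                k_range = (2, 20)
            else:
                ids = {3: (1, 6, 10), 5: (1, 3, 5, 8, 10)}[planted]
                table = subtype_table(120, ids, seed=100 + seed)
                k_range = (2, 12)
            norm = normalize_features(table)
            sel = select_k(norm, k_range, seed=seed, n_init=10)
            hits += sel.k == planted
        assert hits >= 18


class TestClusterKmeans:
    def test_two_planted_subtypes_ari(self):
        from sklearn.metrics import adjusted_rand_score

        table = subtype_table(400, (1, 10), seed=7)
        norm = normalize_features(table)
        model = cluster_kmeans(norm, 2, seed=0, n_init=10,
                               cell_area=table["cell_area"].to_numpy())
        ari = adjusted_rand_score(table["subtype_id"], model.labels)
        assert ari >= 0.95

    def test_k_equals_n_gives_zero_inertia(self):
        table = subtype_table(5, (1, 10), seed=8)
        norm = normalize_features(table)
        model = cluster_kmeans(norm, len(table), seed=0, n_init=2,
                               cell_area=table["cell_area"].to_numpy())
        assert model.inertia == pytest.approx(0.0, abs=1e-9)
        assert len(np.unique(model.labels)) == len(table)

    def test_fixed_seed_reproducible(self):
        table = subtype_table(200, (1, 5, 10), seed=9)
        norm = normalize_features(table)
        m1 = cluster_kmeans(norm, 3, seed=3, n_init=10,
                            cell_area=table["cell_area"].to_numpy())
        m2 = cluster_kmeans(norm, 3, seed=3, n_init=10,
                            cell_area=table["cell_area"].to_numpy())
        np.testing.assert_array_equal(m1.labels, m2.labels)

    def test_clusters_numbered_by_decreasing_area(self):
        table = subtype_table(200, (1, 5, 10), seed=10)
        norm = normalize_features(table)
        model = cluster_kmeans(norm, 3, seed=0, n_init=10,
                               cell_area=table["cell_area"].to_numpy())
        assert (np.diff(model.mean_cell_area) < 0).all()

    def test_row_permutation_invariance(self):
        table = subtype_table(150, (1, 6, 10), seed=11)
        norm = normalize_features(table)
        area = table["cell_area"].to_numpy()
        m1 = cluster_kmeans(norm, 3, seed=0, n_init=10, cell_area=area)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(table))
        table2 = table.iloc[perm].reset_index(drop=True)
        norm2 = normalize_features(table2)
        m2 = cluster_kmeans(norm2, 3, seed=0, n_init=10,
                            cell_area=table2["cell_area"].to_numpy())
        assert (m2.labels == m1.labels[perm]).all()


class TestWardGroups:
    def _model(self, k=4, seed=12):
        table = subtype_table(150, (1, 2, 9, 10), seed=seed)
        norm = normalize_features(table)
        return cluster_kmeans(norm, k, seed=0, n_init=10,
                              cell_area=table["cell_area"].to_numpy())

    def test_identity_when_groups_equal_clusters(self):
        model = self._model()
        cg = group_clusters_ward(model, n_groups=4)
        assert cg == {1: 1, 2: 2, 3: 3, 4: 4}

    def test_too_many_groups_rejected(self):
        with pytest.raises(ValueError):
            group_clusters_ward(self._model(), n_groups=9)

    def test_cg1_is_largest_cell_group(self):
        model = self._model()
        cg = group_clusters_ward(model, n_groups=2)
        # cluster 1 holds the largest cells, so it must land in CG1
        assert cg[1] == 1
        assert cg[model.k] == 2


class TestEmbedUmap:
    def test_axis_convention_and_determinism(self):
        """Axis 1 anti-correlates with size, axis 2 correlates with
        elongation; a fixed seed reproduces coordinates exactly."""
        from scipy.stats import spearmanr

        table = subtype_table(120, (1, 4, 7, 10), seed=13)
        norm = normalize_features(table)
        area = table["cell_area"].to_numpy()
        ar = table["cell_aspect_ratio"].to_numpy()
        emb = embed_umap(norm, n_neighbors=15, seed=0, cell_area=area,
                         aspect_ratio=ar)
        assert spearmanr(emb[:, 0], area).statistic < 0
        assert spearmanr(emb[:, 1], ar).statistic > 0
        emb2 = embed_umap(norm, n_neighbors=15, seed=0, cell_area=area,
                          aspect_ratio=ar)
        np.testing.assert_array_equal(emb, emb2)

    def test_planted_separation_exceeds_spread(self):
        table = subtype_table(150, (1, 10), seed=14)
        norm = normalize_features(table)
        emb = embed_umap(norm, n_neighbors=15, seed=0,
                         cell_area=table["cell_area"].to_numpy(),
                         aspect_ratio=table["cell_aspect_ratio"].to_numpy())
        ids = table["subtype_id"].to_numpy()
        c1, c2 = emb[ids == 1].mean(0), emb[ids == 10].mean(0)
        spread = np.mean([emb[ids == i].std(0).mean() for i in (1, 10)])
        assert np.hypot(*(c1 - c2)) > spread

    def test_too_few_cells_rejected(self):
        table = subtype_table(3, (1, 10), seed=15)
        norm = normalize_features(table)
        with pytest.raises(ValueError):
            embed_umap(norm, seed=0)
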
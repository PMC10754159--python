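"""Per-condition cluster-fraction profiles, Shannon entropy, and the
damage-by-cluster map on a clustered synthetic population."""

from morphotype import synthetic as syn
from morphotype.clustering import cluster_kmeans, group_clusters_ward, normalize_features
from morphotype.features import GH2AX_COL
from morphotype.profiles import (
    cluster_fractions,
    damage_by_cluster,
    enrichment_matrix,
    profiles_frame,
)

table = syn.default_fixture(3000, seed=2)
norm = normalize_features(table)
model = cluster_kmeans(norm, 10, seed=0, n_init=15,
                       cell_area=table["cell_area"].to_numpy())
group_clusters_ward(model, 3)

profiles = cluster_fractions(
    model.labels, model.k,
    condition_id=table["condition_id"].to_numpy(),
    cg_map=model.cg_map,
)
print(profiles_frame(profiles).round(3).to_string(index=False))

enr = enrichment_matrix(profiles, model.centroids)
print("\nShannon entropy per condition (nats; ln 10 = 2.303 is maximal):")
print(enr.entropy.round(3).to_string())
# High-dose urban/fine-like exposure concentrates cells in few small
# round clusters, lowering entropy relative to the control mixture.

per_cluster, per_condition = damage_by_cluster(
    table[GH2AX_COL].to_numpy(), model.labels, model.k,
    condition_id=table["condition_id"].to_numpy(),
)
print("\nmean gamma-H2AX per cluster (pooled across conditions):")
print(per_cluster.round(3).to_string())
# The two smallest-cell clusters (ids 9, 10) carry the highest DNA
# damage; the elongated cluster 4 the lowest — the planted association
# between morphology and damage.
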
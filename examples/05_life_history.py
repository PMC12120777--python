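"""Aggregate module completeness into life-history statistics and trait space.

Average mLHS is the mean completeness over strategy-mapped modules (a
module-level mean, not a mean of strategy means); evenness mLHS is the
Pielou evenness of the strategy-level mean completenesses. Trait space is
characterized with a PCA (PC1 loadings = correlation of each module with
the PC1 score) and Spearman-distance Ward clustering with silhouette-chosen K.
"""

from nichetraits import (
    completeness_matrix,
    mlhs_breadth_association,
    mlhs_table,
    module_clusters,
    niche_breadth,
    synthetic_data as sd,
    trait_space_pca,
)

dataset = sd.simulate_dataset(seed=42, n_samples_per_ecosystem=100, n_taxa=250)
records = niche_breadth(dataset.occurrence, dataset.env, scope="global")
completeness, _ = completeness_matrix(dataset.annotations, dataset.catalog)

table = mlhs_table(completeness, dataset.strategy_map)
print(f"mLHS table: {len(table)} taxa; mean average mLHS "
      f"{table['average_mlhs'].mean():.3f}, mean evenness "
      f"{table['evenness_mlhs'].mean():.3f}")

assoc = mlhs_breadth_association(table, records["breadth"])
row = assoc.loc["average_mlhs"]
print(f"average mLHS vs breadth: r = {row['r']:.3f}, p = {row['p']:.2g}")

pca = trait_space_pca(completeness)
print(f"PC1 explains {100 * pca.explained_variance_ratio[0]:.1f}% of variance; "
      f"strongest PC1 loading: {pca.pc1_loadings.abs().idxmax()} "
      f"({pca.pc1_loadings[pca.pc1_loadings.abs().idxmax()]:.3f})")

clusters = module_clusters(completeness)
flag = " (low confidence)" if clusters.low_confidence else ""
print(f"module clustering: K = {clusters.k}{flag}, "
      f"best silhouette {max(clusters.silhouette_by_k.values()):.3f}")
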
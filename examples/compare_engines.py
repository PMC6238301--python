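"""Cross-comparison of the two biclustering engines.

Runs the SSVD consensus and the k-means + t-test engine on the same
planted matrix and cross-tabulates the promoter categories, the way
clusterings are compared across algorithms or cell lines.
"""

from promclust import bicluster, compare, consensus, synthetic

mat, truth = synthetic.make_planted_matrix(synthetic.SyntheticConfig(seed=4))

ssvd_sol = consensus.consensus_biclust(mat.values, engine="ssvd",
                                       n_runs=10, seed=0,
                                       compute_row_tests=False)
k = bicluster.choose_k(mat.values, (2, 8), seed=0)
km_sol = consensus.consensus_biclust(mat.values, engine="kmeans",
                                     n_runs=10, seed=0,
                                     engine_kwargs={"k": k},
                                     compute_row_tests=False)
print(f"SSVD consensus: {len(ssvd_sol.retained_cols)} retained promoters; "
      f"k-means (k={k}): {len(km_sol.retained_cols)}")

statuses = ["active"] * mat.n_promoters
cats_a = compare.categorize_all(ssvd_sol, statuses, mat)
cats_b = compare.categorize_all(km_sol, statuses, mat)
table = compare.cross_tabulate(cats_a, cats_b)
print(table.to_string())
# Large counts concentrated in one cell per row mean the two engines
# recover the same promoter groups; the 'unassigned' and 'intergenic'
# bands absorb background promoters.
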
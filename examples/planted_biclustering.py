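"""Consensus biclustering of a planted occupancy matrix.

Generates the reference synthetic matrix (30 ChIP-seq tracks x 300
promoters, three planted biclusters over sparse background), runs the
consensus procedure over 20 randomized SSVD runs, and compares the
retained column clusters to the planted truth.
"""

from sklearn.metrics import adjusted_rand_score

from promclust import consensus, synthetic

mat, truth = synthetic.make_planted_matrix(synthetic.SyntheticConfig(seed=1))
sol = consensus.consensus_biclust(mat.values, engine="ssvd", n_runs=20,
                                  min_freq=0.5, seed=42)

print(f"target clustering has {sol.n_clusters} column clusters")
for k in range(sol.n_clusters):
    cols = sol.cluster_columns(k)
    rows = sol.cluster_rows(k)
    if cols:
        print(f"  cluster {k}: {len(cols)} promoters, {len(rows)} tracks")
print(f"retained promoters: {len(sol.retained_cols)} / {mat.n_promoters}")

ari = adjusted_rand_score(
    [truth.column_labels[j] for j in sol.retained_cols],
    [sol.retained_cols[j] for j in sol.retained_cols])
print(f"adjusted Rand index vs planted labels: {ari:.3f}")

# strongest cluster-association bars (-log10 p of the row t-test),
# the numbers drawn next to the heatmap rows
bars = sol.row_tests.sort_values("neglog10p", ascending=False).head(3)
for _, r in bars.iterrows():
    print(f"  track {int(r['row'])} vs cluster {int(r['cluster'])}: "
          f"-log10 p = {r['neglog10p']:.1f}")
# An ARI of 1.0 means the retained promoters are grouped exactly as
# planted; bar heights in the hundreds mean those tracks separate
# their cluster's promoters from the rest overwhelmingly.
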
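"""End-to-end dose-response classification of a synthetic count matrix.

Simulates an RNA-seq experiment (4 hormone doses x 3 replicates; three
gene archetypes generated from the promoter model at C_T = 5, 1, 0.1
plus flat background genes), then runs the full pipeline: size-factor
normalization, low-count and monotonicity filters, PAM clustering with
elbow selection, and the fold-change/delta-ratio response map.
"""

from sklearn.metrics import adjusted_rand_score

from ecdose import SimulationSpec, classify, simulate_counts

cm, truth = simulate_counts(SimulationSpec(seed=1))
responsive = truth.index[truth["archetype"] > 0]
res = classify(cm, gene_list=responsive)

print(f"genes simulated: {len(truth)} ({len(responsive)} hormone-responsive)")
print(f"up-regulated survivors of the filters: {res.n_up}")
print(f"clusters selected by the elbow: k = {res.clusters.k}")
print("\ncluster medoid profiles (max-normalized counts):")
print(res.clusters.medoids.round(3).to_string())

merged = truth.loc[truth["archetype"] > 0].join(res.clusters.labels, how="inner")
ari = adjusted_rand_score(merged["archetype"], merged["cluster"])
print(f"\nadjusted Rand index vs generating archetypes: {ari:.3f}")
print(f"response-map Pearson R (log10 fold vs delta-ratio): {res.response.r_log:.3f}")
print(
    "\nCluster 1 has the highest baseline (strong constitutive enhancer),"
    "\ncluster 3 is silent without hormone (silencer; high-threshold genes)."
    "\nThe positive R reproduces the predicted coupling between overall"
    "\nfold change and responding mostly at high doses."
)
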
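"""Cluster a synthetic basal panel and call the masculinized lines.

Generates the default 35-line basal panel with four planted virago
lines, z-scores the line means, clusters with k=3 (larvae / females /
males), runs PCA, and calls viragos by male-vs-female centroid distance.
"""

from flymet import (
    SyntheticConfig,
    call_viragos,
    gen_metabolite_panel,
    kmeans_metabotypes,
    line_means,
    pca,
    zscore_normalize,
)

cfg = SyntheticConfig(seed=2, virago_lines=("L3", "L9", "L17", "L28"))
panel, truth = gen_metabolite_panel(cfg)
norm = zscore_normalize(line_means(panel))

clusters = kmeans_metabotypes(norm, k=3, n_init=50, seed=0)
print(f"k-means: k={clusters.k}, within-cluster SS = {clusters.inertia:.1f}")
for label in sorted(clusters.labels.unique()):
    members = clusters.meta[clusters.labels == label]
    top = (members["stage"] + "/" + members["sex"]).mode().iloc[0]
    print(f"  cluster {label}: {len(members)} samples, mostly {top}")

res = pca(norm)
print("PC1 loadings:",
      ", ".join(f"{m} {v:+.2f}" for m, v in res.loadings["PC1"].items()))
print(f"variance explained: PC1 {res.variance_fraction[0]:.0%}, "
      f"PC2 {res.variance_fraction[1]:.0%}")

calls = call_viragos(res, clusters)
print("virago calls (female profile nearer the male centroid):")
for c in calls:
    print(f"  line {c.line}: d(male)={c.dist_to_male:.2f} "
          f"< d(female)={c.dist_to_female:.2f}")
print("planted virago lines:", ", ".join(truth.virago_lines))
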
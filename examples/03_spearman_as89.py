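"""Spearman correlation matrix with AS89 p-values on line means.

Correlates metabolite line means of the adult females from a synthetic
basal panel and prints the significant pairs (p < 0.05), the way the
inter-metabolite coupling analysis reads.
"""

from flymet import (
    SyntheticConfig,
    filter_correlations,
    gen_metabolite_panel,
    line_means,
    spearman_matrix,
    spearman_rp,
)

# the small-sample exact path: classic 5-point example
r, p, n = spearman_rp([1, 2, 3, 4, 5], [3, 1, 2, 5, 4])
print(f"exact path, n={n}: r = {r:.2f}, two-sided p = {p:.2f}  "
      "(enumerated over all 120 orderings)")

panel, _ = gen_metabolite_panel(SyntheticConfig(seed=4))
lm = line_means(panel)
females = lm[(lm["stage"] == "adult") & (lm["sex"] == "female")]
mets = ["TAG", "protein", "glycerol", "lactate", "glycogen", "glucose"]
res = filter_correlations(spearman_matrix(females[mets]), alpha=0.05)
sig = res.to_long().query("significant")
print(f"\nadult females, {len(females)} lines: "
      f"{len(sig)} significant metabolite pairs at p < 0.05")
for _, row in sig.iterrows():
    print(f"  {row.var1} ~ {row.var2}: r = {row.r:+.2f}, "
          f"p = {row.p:.2g}, n = {row.n}")
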
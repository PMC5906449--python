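"""Post-process association tables: filter, count, overlap, manhattan.

Generates basal and diet-shift association tables with the planted
overlap structure, filters at p < 1e-5, counts unique SNPs per trait
split by gene association, intersects the two conditions, and prepares
manhattan-plot records with the 1e-5 / 1e-7 threshold lines. Ends with
the naive dosage-regression scan on synthetic genotypes.
"""

import numpy as np
import pandas as pd

from flymet import (
    SyntheticConfig,
    classify_and_count,
    filter_significant,
    gen_association_tables,
    gen_genotype_matrix,
    manhattan_prep,
    naive_association_scan,
    overlap,
)

basal_raw, shift_raw, truth = gen_association_tables(seed=1)
basal = filter_significant(basal_raw, 1e-5)
shift = filter_significant(shift_raw, 1e-5)
counts = classify_and_count(basal)
print("basal condition, unique SNPs per trait "
      "(total / gene-associated / unclear):")
print(counts.to_string())
print(f"total unique basal SNPs: {counts['total'].sum()}")

ov = overlap(basal, shift)
print(f"\nbasal vs diet shift: {len(ov.shared_variants)} shared SNPs, "
      f"{ov.n_genes_a} vs {ov.n_genes_b} genes with "
      f"{len(ov.shared_genes)} in common")

mh = manhattan_prep(basal, truth["chrom_lengths"])
print(f"manhattan: {len(mh['records'])} points, threshold lines at "
      f"-log10 p = {mh['threshold_lines'][0]:.0f} and "
      f"{mh['threshold_lines'][1]:.0f}")

G, _ = gen_genotype_matrix(SyntheticConfig(seed=8, n_sites=500))
rng = np.random.default_rng(0)
j = int(np.argmin(np.abs((G.calls == 1).sum(0) - 15)))
dosage = (G.calls[:, j] == 1).astype(float)
trait = pd.DataFrame({"TAG": rng.normal(size=35) + 2 * dosage}, index=G.lines)
scan = naive_association_scan(G, trait)
best = scan.loc[scan["pval"].idxmin()]
print(f"\nnaive scan: planted site {G.sites[j]} -> best hit "
      f"{best.variant_id} at p = {best.pval:.2g}")
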
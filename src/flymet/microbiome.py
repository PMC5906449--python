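"""Taxon abundance processing for the gut-microbiome analyses.

Counts are held per sample x taxon with a taxonomy map (taxon -> genus).
The analysis chain mirrors a 16S profiling workflow on a handful of
dominant community members: exclusion of confounded samples/taxa (an
endosymbiont is not a gut resident), retention of taxa that reach the
top 95% cumulative abundance in at least one sample, genus-level rollup,
relative abundance, log10 transform, and Bray-Curtis hierarchical
clustering of samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "AbundanceTable",
    "TaxonFilterResult",
    "relative_abundance",
    "top95_filter",
    "genus_rollup",
    "exclude",
    "hcluster_samples",
    "log_transform",
    "HClusterResult",
]


@dataclass
class AbundanceTable:
    """Samples x taxa count matrix with metadata and taxonomy.

    counts
        DataFrame indexed by sample id, one column per taxon,
        non-negative integers (or proportions after normalization).
    meta
        DataFrame indexed by sample id with line/stage/sex/diet/replicate.
    taxonomy
        Series taxon -> genus covering every count column.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    taxonomy: pd.Series

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        uncovered = [t for t in self.counts.columns if t not in self.taxonomy.index]
        if uncovered:
            raise ValueError(f"taxa missing from taxonomy: {uncovered}")
        if not self.counts.index.equals(self.meta.index):
            self.meta = self.meta.reindex(self.counts.index)
            if self.meta.isna().all(axis=1).any():
                raise ValueError("metadata does not cover all samples")

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)


def relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Close each sample to proportions (rows sum to 1)."""
    totals = table.counts.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-depth sample(s): {list(zero.index)}")
    return replace(table, counts=table.counts.div(totals, axis=0))


@dataclass
class TaxonFilterResult:
    retained: list[str]
    retained_mass: pd.Series       # per-sample fraction of reads retained
    per_sample_top: dict[str, list[str]]


def top95_filter(table: AbundanceTable, quantile: float = 0.95) -> TaxonFilterResult:
    """Retain taxa in the top-95% cumulative abundance of >= 1 sample.

    Within each sample, taxa are ranked by decreasing proportion and the
    minimal prefix whose cumulative proportion reaches ``quantile`` is
    that sample's top set; a taxon is retained globally iff it enters at
    least one sample's top set.
    """
    rel = relative_abundance(table)
    per_sample: dict[str, list[str]] = {}
    retained: set[str] = set()
    for sample, row in rel.counts.iterrows():
        # stable sort keeps column order on tied proportions
        ordered = row.sort_values(ascending=False, kind="stable")
        cum = ordered.cumsum()
        cut = int(np.searchsorted(cum.to_numpy(), quantile - 1e-12)) + 1
        top = list(ordered.index[:cut])
        per_sample[sample] = top
        retained.update(top)
    kept = [t for t in table.taxa if t in retained]  # preserve column order
    mass = rel.counts[kept].sum(axis=1)
    return TaxonFilterResult(retained=kept, retained_mass=mass,
                             per_sample_top=per_sample)


def genus_rollup(table: AbundanceTable) -> AbundanceTable:
    """Sum counts of species belonging to the same genus."""
    genera = table.taxonomy.reindex(table.taxa)
    if genera.isna().any():
        missing = list(genera[genera.isna()].index)
        raise ValueError(f"taxa missing from taxonomy: {missing}")
    rolled = table.counts.T.groupby(genera, sort=False).sum().T
    tax = pd.Series({g: g for g in rolled.columns}, name="genus")
    return AbundanceTable(counts=rolled, meta=table.meta.copy(), taxonomy=tax)


def exclude(table: AbundanceTable, sample_predicate=None,
            taxa: list[str] | None = None) -> AbundanceTable:
    """Drop samples matching a predicate on the metadata row, and/or named
    taxa. Remaining counts are untouched (no renormalization)."""
    counts, meta = table.counts, table.meta
    if sample_predicate is not None:
        keep = ~meta.apply(sample_predicate, axis=1).astype(bool)
        if not keep.any():
            raise ValueError("exclusion removes every sample")
        counts = counts.loc[keep.to_numpy()]
        meta = meta.loc[keep.to_numpy()]
    if taxa:
        counts = counts.drop(columns=[t for t in taxa if t in counts.columns])
    tax = table.taxonomy.reindex(counts.columns)
    return AbundanceTable(counts=counts, meta=meta, taxonomy=tax)


@dataclass
class HClusterResult:
    order: list[str]                 # samples in dendrogram leaf order
    linkage: np.ndarray              # scipy linkage matrix
    metric: str
    method: str


def hcluster_samples(table: AbundanceTable, metric: str = "braycurtis",
                     method: str = "average") -> HClusterResult:
    """Agglomerative clustering of samples on their composition.

    Defaults: Bray-Curtis dissimilarity on proportions with average
    linkage. Input samples are processed in index order, which fixes the
    tie-breaking of equal merge heights.
    """
    if len(table.samples) < 2:
        raise ValueError("need >= 2 samples")
    rel = relative_abundance(table)
    X = rel.counts.to_numpy(dtype=float)
    D = pdist(X, metric=metric)
    if np.isnan(D).any():
        raise ValueError("dissimilarity undefined for some sample pair")
    Z = hierarchy.linkage(D, method=method)
    leaves = hierarchy.leaves_list(Z)
    return HClusterResult(order=[table.samples[i] for i in leaves],
                          linkage=Z, metric=metric, method=method)


def log_transform(values: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log10(x + pseudocount) elementwise; records the pseudocount in
    ``DataFrame.attrs['pseudocount']``."""
    arr = values.to_numpy(dtype=float)
    if np.nanmin(arr) < 0:
        raise ValueError("log transform requires non-negative input")
    out = np.log10(values + pseudocount)
    out.attrs["pseudocount"] = pseudocount
    return out
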
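"""Post-processing of association-study result tables.

An association table is a tidy DataFrame with columns ``variant_id,
chrom, pos, trait, pval, gene`` (gene empty/NA when the variant has no
clear-cut gene association) and optionally ``condition`` in
{basal, diet_shift}. Operations: strict p < threshold filtering, per-trait
unique-SNP counting split by gene association, basal/diet-shift overlap on
variants and genes, manhattan-plot preparation, and a deliberately naive
single-marker scan used to exercise the pipeline on synthetic genotypes
(it makes no claim of equivalence to mixed-model association tools).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .allele import ALT, MISSING, REF, GenotypeMatrix

__all__ = [
    "REQUIRED_COLUMNS",
    "filter_significant",
    "classify_and_count",
    "overlap",
    "manhattan_prep",
    "naive_association_scan",
    "OverlapResult",
]

REQUIRED_COLUMNS = ["variant_id", "chrom", "pos", "trait", "pval", "gene"]

#: manhattan significance thresholds (genome-wide suggestive / strict)
DEFAULT_THRESHOLDS = (1e-5, 1e-7)


def _check(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"association table lacks columns: {missing}")
    return table


def filter_significant(table: pd.DataFrame, threshold: float = 1e-5) -> pd.DataFrame:
    """Rows with p strictly below the threshold, order preserved."""
    _check(table)
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    return table[table["pval"] < threshold].copy()


def _gene_known(gene: pd.Series) -> pd.Series:
    return gene.notna() & (gene.astype(str).str.strip() != "")


def classify_and_count(table: pd.DataFrame) -> pd.DataFrame:
    """Unique SNPs per trait, split into gene-associated and unclear.

    A variant counts once per trait; it is gene-associated when any of its
    records for that trait carries a non-empty gene symbol. Returns a
    DataFrame indexed by trait with columns total / gene_associated /
    unclear (total = gene_associated + unclear).
    """
    _check(table)
    t = table.assign(_known=_gene_known(table["gene"]))
    per_variant = t.groupby(["trait", "variant_id"], sort=False)["_known"].any()
    rows = {}
    for trait, grp in per_variant.groupby(level="trait", sort=False):
        total = len(grp)
        known = int(grp.sum())
        rows[trait] = {"total": total, "gene_associated": known,
                       "unclear": total - known}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "trait"
    return out


@dataclass
class OverlapResult:
    shared_variants: list[str]
    shared_genes: list[str]
    n_variants_a: int
    n_variants_b: int
    n_genes_a: int
    n_genes_b: int


def overlap(basal: pd.DataFrame, shift: pd.DataFrame) -> OverlapResult:
    """Intersections of unique variant ids and unique gene symbols between
    two (already filtered) association tables. Gene symbols are compared
    case-sensitively; empty/NA genes are ignored."""
    _check(basal), _check(shift)
    va = set(basal["variant_id"])
    vb = set(shift["variant_id"])
    ga = set(basal.loc[_gene_known(basal["gene"]), "gene"])
    gb = set(shift.loc[_gene_known(shift["gene"]), "gene"])
    return OverlapResult(
        shared_variants=sorted(va & vb),
        shared_genes=sorted(ga & gb),
        n_variants_a=len(va), n_variants_b=len(vb),
        n_genes_a=len(ga), n_genes_b=len(gb),
    )


def manhattan_prep(table: pd.DataFrame, chrom_lengths: dict[str, int],
                   thresholds=DEFAULT_THRESHOLDS) -> dict:
    """Plot-ready manhattan data: cumulative genome x-coordinate and
    -log10 p per variant, plus threshold line heights.

    Chromosomes are laid out in the order of ``chrom_lengths``; a variant
    position exceeding its chromosome length is an error.
    """
    _check(table)
    offsets = {}
    run = 0
    for chrom, length in chrom_lengths.items():
        offsets[chrom] = run
        run += int(length)
    recs = table.copy()
    unknown = set(recs["chrom"]) - set(offsets)
    if unknown:
        raise ValueError(f"chromosomes without length: {sorted(unknown)}")
    too_far = recs[recs["pos"] > recs["chrom"].map(chrom_lengths)]
    if len(too_far):
        r = too_far.iloc[0]
        raise ValueError(f"position {r['pos']} exceeds length of {r['chrom']}")
    recs["cum_pos"] = recs["chrom"].map(offsets) + recs["pos"]
    recs["neg_log10_p"] = -np.log10(recs["pval"])
    return {"records": recs,
            "threshold_lines": [-np.log10(t) for t in thresholds]}


def naive_association_scan(G: GenotypeMatrix, trait_line_means: pd.DataFrame,
                           min_minor_lines: int = 4,
                           condition: str = "basal") -> pd.DataFrame:
    """Single-marker scan of line means on allele dosage (a desk-scale
    stand-in used with synthetic data; not a mixed-model association).

    For every site at which at least ``min_minor_lines`` lines carry the
    minor allele, each trait's line means are regressed on the 0/1 allele
    dosage and the two-sided slope p-value reported. With a binary dosage
    this is the pooled-variance two-group t-test of ref- vs alt-carrying
    lines. Missing calls drop a line from that site.
    """
    if min_minor_lines < 2:
        raise ValueError("min_minor_lines must be >= 2")
    means = trait_line_means.reindex(G.lines)
    if means.isna().all(axis=1).any():
        absent = list(means.index[means.isna().all(axis=1)])
        raise ValueError(f"trait means missing for lines: {absent}")
    calls = G.calls
    rows = []
    for j, site in enumerate(G.sites):
        c = calls[:, j]
        ok = c != MISSING
        n_alt = int((c[ok] == ALT).sum())
        n_ref = int((c[ok] == REF).sum())
        if min(n_alt, n_ref) < min_minor_lines:
            continue
        dosage = (c[ok] == ALT).astype(float)
        for trait in means.columns:
            y = means.loc[np.asarray(G.lines)[ok], trait].to_numpy(dtype=float)
            keep = ~np.isnan(y)
            d = dosage[keep]
            yv = y[keep]
            if min((d == 1).sum(), (d == 0).sum()) < min_minor_lines:
                continue
            if np.all(yv == yv[0]):
                continue
            fit = stats.linregress(d, yv)
            chrom, _, pos = site.partition(":")
            rows.append({"variant_id": site, "chrom": chrom or site,
                         "pos": int(pos) if pos else j + 1, "trait": trait,
                         "pval": float(fit.pvalue), "gene": "",
                         "condition": condition})
    if not rows:
        warnings.warn("no site passed the minor-allele threshold", stacklevel=2)
        return pd.DataFrame(columns=REQUIRED_COLUMNS + ["condition"])
    return pd.DataFrame(rows)
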
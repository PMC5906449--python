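"""Readers and writers for the pipeline's plain-text formats.

Panels, abundance tables and association tables travel as TSV; genotype
matrices as VCF (via cyvcf2) or a lines x sites TSV. Writers emit a
``# flymet:`` header comment recording provenance (normalization mode,
seed) where the format allows it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .allele import ALT, MISSING, REF, GenotypeMatrix
from .gwas import REQUIRED_COLUMNS
from .microbiome import AbundanceTable
from .panel import validate_panel

__all__ = [
    "read_panel", "write_panel",
    "read_abundance", "write_abundance",
    "read_genotypes_tsv", "write_genotypes_tsv", "read_genotypes_vcf",
    "read_associations", "write_associations",
]


def _read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def _write_tsv(df: pd.DataFrame, path, header_note: str | None = None,
               index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_note:
            fh.write(f"# flymet: {header_note}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_panel(path) -> pd.DataFrame:
    """Metabolite panel TSV: metadata columns then metabolite columns."""
    return validate_panel(_read_tsv(path))


def write_panel(panel: pd.DataFrame, path, note: str | None = None,
                validate: bool = True) -> None:
    if validate:
        validate_panel(panel)
    _write_tsv(panel, path, header_note=note)


def read_abundance(counts_path, taxonomy_path, meta_path) -> AbundanceTable:
    """Abundance TSVs: counts (first column ``sample``), sidecar taxonomy
    (columns taxon, genus) and sample metadata (first column ``sample``)."""
    counts = _read_tsv(counts_path).set_index("sample")
    tax = _read_tsv(taxonomy_path).set_index("taxon")["genus"]
    meta = _read_tsv(meta_path).set_index("sample")
    return AbundanceTable(counts=counts, meta=meta, taxonomy=tax)


def write_abundance(table: AbundanceTable, directory,
                    prefix: str = "abundance") -> None:
    d = Path(directory)
    _write_tsv(table.counts.rename_axis("sample").reset_index(),
               d / f"{prefix}_counts.tsv")
    _write_tsv(table.taxonomy.rename_axis("taxon").rename("genus").reset_index(),
               d / f"{prefix}_taxonomy.tsv")
    _write_tsv(table.meta.rename_axis("sample").reset_index(),
               d / f"{prefix}_meta.tsv")


def read_genotypes_tsv(path) -> GenotypeMatrix:
    """Lines x sites TSV: first column ``line``, one column per site,
    values 0 (ref), 1 (alt) or NA (missing)."""
    df = _read_tsv(path).set_index("line")
    calls = df.to_numpy(dtype=float)
    out = np.full(calls.shape, MISSING, dtype=np.int8)
    out[calls == 0] = REF
    out[calls == 1] = ALT
    return GenotypeMatrix(calls=out, lines=list(df.index.astype(str)),
                          sites=list(df.columns))


def write_genotypes_tsv(G: GenotypeMatrix, path) -> None:
    df = G.to_frame().astype("object")
    df[df == MISSING] = ""
    _write_tsv(df.rename_axis("line").reset_index(), path)


def read_genotypes_vcf(path, samples: list[str] | None = None) -> GenotypeMatrix:
    """Biallelic records from a VCF; het or half-missing genotypes become
    missing calls (inbred-line convention). Site ids are ``chrom:pos``
    (1-based, as in the file)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), samples=samples)
    lines = list(vcf.samples)
    sites, columns = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        gts = var.genotype.array()
        a = gts[:, 0]
        b = gts[:, 1] if gts.shape[1] > 1 else gts[:, 0]
        col = np.full(len(lines), MISSING, dtype=np.int8)
        hom = (a == b) & (a >= 0)
        col[hom & (a == 0)] = REF
        col[hom & (a == 1)] = ALT
        if (col == MISSING).all():
            continue
        sites.append(f"{var.CHROM}:{var.POS}")
        columns.append(col)
    if not sites:
        raise ValueError("no usable biallelic records in VCF")
    return GenotypeMatrix(calls=np.column_stack(columns), lines=lines, sites=sites)


def read_associations(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Association TSV; ``column_map`` renames supplementary-sheet style
    headers onto the required ones (variant_id, chrom, pos, trait, pval,
    gene)."""
    df = _read_tsv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"association table lacks columns {missing}; "
                         "provide a column_map")
    df["gene"] = df["gene"].fillna("")
    return df


def write_associations(table: pd.DataFrame, path, note: str | None = None) -> None:
    _write_tsv(table, path, header_note=note)
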
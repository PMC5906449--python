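"""Orchestration of the three analyses (basal profiling, diet shift,
microbiome correlation) plus synthetic-data generation, with manifests
for reproducibility.

Each ``run_*`` function reads its inputs, executes the corresponding
analysis chain and writes plain TSV/JSON outputs plus a ``manifest.json``
recording the seed, a hash of the effective configuration and the
package version — enough to re-run the bundle exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .correlations import filter_significant as corr_filter
from .correlations import spearman_matrix
from .io import (
    read_abundance,
    read_panel,
    write_abundance,
    write_panel,
)
from .metabotype import (
    call_viragos,
    diet_response,
    kmeans_metabotypes,
    pca,
    percent_normalize,
    zscore_normalize,
)
from .microbiome import (
    exclude,
    genus_rollup,
    log_transform,
    relative_abundance,
    top95_filter,
)
from .panel import line_means, metabolite_columns, sample_ids
from .synthetic import (
    SyntheticConfig,
    gen_abundance_table,
    gen_diet_shift,
    gen_genotype_matrix,
    gen_metabolite_panel,
)

log = logging.getLogger("flymet")

__all__ = ["RunConfig", "run_basal", "run_diet_shift", "run_microbiome",
           "run_synth", "load_config"]


@dataclass
class RunConfig:
    """Effective run configuration (TOML file merged with CLI overrides)."""

    out_dir: str = "flymet_out"
    seed: int = 0
    panel: str | None = None
    lsd_panel: str | None = None
    sd_panel: str | None = None
    hsd_panel: str | None = None
    abundance_counts: str | None = None
    abundance_taxonomy: str | None = None
    abundance_meta: str | None = None
    k: int = 3
    n_init: int = 50
    alpha: float = 0.05
    exclude_lines: tuple[str, ...] = ("859",)
    exclude_taxa: tuple[str, ...] = ("Wolbachia pipientis",)
    pseudocount: float = 1.0
    synthetic: dict = field(default_factory=dict)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path=None, **overrides) -> RunConfig:
    """Load a TOML run configuration; keyword overrides win over the file,
    file values win over defaults."""
    data: dict = {}
    if path is not None:
        import tomllib

        data = tomllib.loads(Path(path).read_text())
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("exclude_lines", "exclude_taxa"):
        if key in data:
            data[key] = tuple(str(x) for x in data[key])
    return RunConfig(**data)


def _write_manifest(config: RunConfig, out: Path, analysis: str,
                    extra: dict | None = None) -> None:
    manifest = {"analysis": analysis, "seed": config.seed,
                "config_hash": config.hash(),
                "config": dataclasses.asdict(config),
                "version": __version__}
    manifest.update(extra or {})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_basal(config: RunConfig) -> Path:
    """Basal profiling: z-score normalization, per-stratum Spearman
    matrices, k-means metabotypes, PCA and virago calls."""
    if not config.panel:
        raise ValueError("basal analysis needs a panel input")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = read_panel(config.panel)
    log.info("basal: %d samples, seed %d", len(panel), config.seed)

    lm = line_means(panel)
    norm = zscore_normalize(lm)
    write_panel(norm, out / "normalized_panel.tsv",
                note=f"zscore line means, seed={config.seed}", validate=False)

    mets = metabolite_columns(lm)
    for (stage, sex), grp in lm.groupby(["stage", "sex"], observed=True):
        res = corr_filter(spearman_matrix(grp[mets]), config.alpha)
        res.to_long().to_csv(out / f"correlations_{stage}_{sex}.tsv",
                             sep="\t", index=False)

    clusters = kmeans_metabotypes(norm, k=config.k, n_init=config.n_init,
                                  seed=config.seed)
    clusters.labels.rename_axis("sample").reset_index().to_csv(
        out / "metabotypes.tsv", sep="\t", index=False)

    pres = pca(norm)
    pres.scores.rename_axis("sample").reset_index().to_csv(
        out / "pca_scores.tsv", sep="\t", index=False)
    pres.loadings.rename_axis("metabolite").reset_index().to_csv(
        out / "pca_loadings.tsv", sep="\t", index=False)

    calls = call_viragos(pres, clusters)
    pd.DataFrame([dataclasses.asdict(c) for c in calls],
                 columns=["line", "cluster", "dist_to_male", "dist_to_female"],
                 ).to_csv(out / "virago_calls.tsv", sep="\t", index=False)
    _write_manifest(config, out, "basal",
                    {"n_samples": len(panel), "k": config.k,
                     "viragos": [c.line for c in calls]})
    return out


def run_diet_shift(config: RunConfig) -> Path:
    """Diet-shift analysis: shared-basis percent normalization and
    LSD->SD / LSD->HSD percent responses."""
    paths = {"LSD": config.lsd_panel, "SD": config.sd_panel,
             "HSD": config.hsd_panel}
    missing = [d for d, p in paths.items() if not p]
    if missing:
        raise ValueError(f"missing diet arm input(s): {missing}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panels = {d: read_panel(p) for d, p in paths.items()}

    norm_lsd, basis = percent_normalize(panels["LSD"])
    write_panel(norm_lsd, out / "percent_normalized_LSD.tsv",
                note="percent of max line mean per metabolite x stage x sex")
    for arm in ("SD", "HSD"):
        norm_arm, _ = percent_normalize(panels[arm], basis=basis)
        write_panel(norm_arm, out / f"percent_normalized_{arm}.tsv",
                    note="normalized on the LSD basis")
        resp = diet_response(norm_lsd, norm_arm)
        resp.to_csv(out / f"diet_response_LSD_to_{arm}.tsv",
                    sep="\t", index=False)
        summary = (resp.groupby(["sex", "metabolite"], observed=True)
                   ["percent_change"].describe())
        summary.to_csv(out / f"diet_response_LSD_to_{arm}_summary.tsv", sep="\t")
    _write_manifest(config, out, "diet_shift")
    return out


def run_microbiome(config: RunConfig) -> Path:
    """Microbiome correlation chain: exclusions, top-95% filter, genus
    rollup, log transform, Spearman vs metabolites with the alpha filter,
    at species and genus level."""
    needed = [config.abundance_counts, config.abundance_taxonomy,
              config.abundance_meta, config.panel]
    if not all(needed):
        raise ValueError("microbiome analysis needs abundance counts, "
                         "taxonomy, metadata and a metabolite panel")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = read_abundance(config.abundance_counts, config.abundance_taxonomy,
                           config.abundance_meta)
    panel = read_panel(config.panel)
    panel = panel.set_index(sample_ids(panel).to_numpy())
    matched = table.counts.index.intersection(panel.index)
    if matched.empty:
        raise ValueError("no samples shared between abundance table and panel")

    drop_lines = set(config.exclude_lines)
    table = exclude(table,
                    sample_predicate=lambda row: str(row["line"]) in drop_lines,
                    taxa=list(config.exclude_taxa))
    panel = panel.loc[panel.index.intersection(table.counts.index)]
    table = exclude(table, sample_predicate=lambda row: row.name not in panel.index)

    filt = top95_filter(table)
    pd.DataFrame({"taxon": filt.retained}).to_csv(
        out / "retained_taxa.tsv", sep="\t", index=False)
    kept = exclude(table, taxa=[t for t in table.taxa if t not in filt.retained])
    write_abundance(kept, out, prefix="filtered")

    mets = metabolite_columns(panel.reset_index(drop=True))
    results = {}
    for level, tab in (("species", kept), ("genus", genus_rollup(kept))):
        rel = relative_abundance(tab)
        joined = pd.concat([panel.loc[rel.counts.index, mets], rel.counts], axis=1)
        res = corr_filter(spearman_matrix(log_transform(joined,
                                                        config.pseudocount)),
                          config.alpha)
        res.to_long().to_csv(out / f"correlations_{level}.tsv",
                             sep="\t", index=False)
        results[level] = res
    _write_manifest(config, out, "microbiome",
                    {"n_matched_samples": int(len(panel)),
                     "retained_taxa": filt.retained})
    return out


def run_synth(config: RunConfig) -> Path:
    """Generate a full synthetic input bundle (basal + diet panels,
    genotypes, abundance table) and the planted-truth record."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    syn = dict(config.synthetic)
    syn.setdefault("seed", config.seed)
    for key in ("metabolites", "virago_lines", "unique_group", "line_ids"):
        if key in syn and isinstance(syn[key], list):
            syn[key] = tuple(syn[key])
    if "planted_links" in syn:
        syn["planted_links"] = tuple(
            (str(m), str(t), float(r)) for m, t, r in syn["planted_links"])
    cfg = SyntheticConfig(**syn).validate()

    panel, truth_panel = gen_metabolite_panel(cfg)
    write_panel(panel, out / "panel_basal.tsv", note=f"synthetic seed={cfg.seed}")
    lsd_cfg = dataclasses.replace(cfg, diet="LSD")
    lsd_panel, _ = gen_metabolite_panel(lsd_cfg)
    shifted, truth_diet = gen_diet_shift(lsd_panel, lsd_cfg)
    for diet in ("LSD", "SD", "HSD"):
        write_panel(shifted[shifted["diet"] == diet],
                    out / f"panel_{diet}.tsv", note=f"synthetic seed={cfg.seed}")
    G, truth_geno = gen_genotype_matrix(cfg)
    from .io import write_genotypes_tsv

    write_genotypes_tsv(G, out / "genotypes.tsv")
    table, truth_abund = gen_abundance_table(cfg, panel)
    write_abundance(table, out)

    truth_panel.diet_multipliers = truth_diet.diet_multipliers
    truth_panel.unique_group = truth_geno.unique_group
    truth_panel.unique_alt_sites = truth_geno.unique_alt_sites
    truth_panel.unique_ref_sites = truth_geno.unique_ref_sites
    truth_panel.links = truth_abund.links
    truth_panel.wolbachia_line = truth_abund.wolbachia_line
    truth_panel.save(out / "truth")
    _write_manifest(config, out, "synthetic", {"synthetic": syn})
    return out
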
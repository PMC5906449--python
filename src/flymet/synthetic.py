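"""Synthetic data generators with planted ground truth.

Every pipeline input can be generated here with the statistical structure
the downstream analyses assume — line-structured metabolite panels with
stage/sex dimorphism, metabotype clusters and masculinized ("virago")
lines; inbred-line genotype matrices with group-private alleles; 16S-like
compositional abundance tables dominated by Acetobacter and Lactobacillus
species; diet-shift panels with multiplicative energy-store effects; and
raw plate reads that invert the assay quantification. Each generator
returns its output together with a :class:`PlantedTruth` record of all
injected effects, which recovery tests score against.

Amounts are drawn on log10 scale and exponentiated (right-skewed,
positive), with below-detection censoring at a configurable floor.
A single seed drives everything; each generator uses its own derived
substream so adding one table never perturbs another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .allele import GenotypeMatrix, MISSING
from .assay import AssaySpec
from .microbiome import AbundanceTable
from .panel import META_COLUMNS, metabolite_columns, sample_ids, validate_panel

__all__ = [
    "SyntheticConfig",
    "PlantedTruth",
    "gen_metabolite_panel",
    "gen_diet_shift",
    "gen_genotype_matrix",
    "gen_abundance_table",
    "gen_plate_reads",
    "gen_association_tables",
]


class ConfigError(ValueError):
    """Invalid synthetic-data configuration."""


DEFAULT_METABOLITES = ("TAG", "protein", "glycerol", "lactate", "glycogen", "glucose")

# adult-male baseline, log10 amount per animal (assay units ~ ug/animal)
_BASE_LOG10 = {"TAG": 1.78, "protein": 2.18, "glycerol": 0.60,
               "lactate": 0.30, "glycogen": 1.60, "glucose": 0.78}

# stage/sex mean offsets (log10) relative to adult males: larvae are
# lactate-rich (fold set separately) and glycogen/glucose-poor, females
# carry higher TAG/glycogen/glucose stores
_LARVA_OFFSET = {"TAG": -0.50, "protein": -0.45, "glycerol": 0.55,
                 "glycogen": -0.80, "glucose": -0.88}
_FEMALE_OFFSET = {"TAG": 0.75, "protein": 0.35, "glycerol": 0.15,
                  "lactate": -0.25, "glycogen": 0.70, "glucose": 0.50}

STRATA = (("larva", "mixed"), ("adult", "female"), ("adult", "male"))

# core gut community of lab-reared Drosophila plus rarer contaminants
CORE_SPECIES = {
    "Acetobacter pomorum": "Acetobacter",
    "Acetobacter tropicalis": "Acetobacter",
    "Lactobacillus brevis": "Lactobacillus",
    "Lactobacillus fructivorans": "Lactobacillus",
    "Lactobacillus plantarum": "Lactobacillus",
}
RARE_SPECIES = {
    "Lactobacillus homohiochii": "Lactobacillus",
    "Commensalibacter intestini": "Commensalibacter",
    "Gluconobacter morbifer": "Gluconobacter",
    "Enterococcus faecalis": "Enterococcus",
    "Leuconostoc mesenteroides": "Leuconostoc",
    "Acetobacter pasteurianus": "Acetobacter",
    "Lactobacillus casei": "Lactobacillus",
}
WOLBACHIA = "Wolbachia pipientis"

# substream ids, so generators draw independently from one seed
_STREAMS = {"panel": 1, "diet": 2, "genotype": 3, "abundance": 4,
            "plates": 5, "assoc": 6}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass
class SyntheticConfig:
    """Study conditions for all generators (defaults match the emulated
    experiment: 35 lines, six metabolites, three replicates, three
    combined metabotypes)."""

    n_lines: int = 35
    line_ids: tuple[str, ...] | None = None
    metabolites: tuple[str, ...] = DEFAULT_METABOLITES
    n_replicates: int = 3
    diet: str = "SD"
    k_metabotypes: int = 3
    virago_lines: tuple[str, ...] = ()
    cluster_separation: float = 3.5
    noise_sd: float = 0.10          # log10 replicate SD
    line_effect_sd: float | None = None   # default: noise_sd / 2
    larval_lactate_fold: float = 20.0
    detection_floor: float = 0.6    # amounts below this are censored
    shift_noise_sd: float = 0.0     # fresh noise on diet-shift copies

    n_sites: int = 1000
    maf_spectrum: str = "beta:0.41,2.12"
    n_unique_alt: int = 0
    n_unique_ref: int = 0
    unique_group: tuple[str, ...] = ()
    missing_rate: float = 0.0

    n_taxa: int = 10
    depth: int = 50000
    wolbachia_line: str | None = None
    planted_links: tuple[tuple[str, str, float], ...] = ()

    diet_multipliers: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def lines(self) -> list[str]:
        if self.line_ids is not None:
            if len(self.line_ids) != self.n_lines:
                raise ConfigError("line_ids length differs from n_lines")
            return [str(x) for x in self.line_ids]
        return [f"L{i}" for i in range(1, self.n_lines + 1)]

    def validate(self) -> "SyntheticConfig":
        if self.n_lines < 1 or self.n_replicates < 1 or self.k_metabotypes < 1:
            raise ConfigError("counts must be >= 1")
        if self.k_metabotypes > self.n_lines:
            raise ConfigError("more metabotypes than lines")
        lines = set(self.lines)
        bad = set(self.virago_lines) - lines
        if bad:
            raise ConfigError(f"virago lines not in line set: {sorted(bad)}")
        if self.wolbachia_line is not None and self.wolbachia_line not in lines:
            raise ConfigError(f"wolbachia_line {self.wolbachia_line!r} unknown")
        if self.n_unique_alt < 0 or self.n_unique_ref < 0:
            raise ConfigError("planted unique-allele counts must be >= 0")
        if self.n_unique_alt + self.n_unique_ref > self.n_sites:
            raise ConfigError("more planted unique sites than sites")
        if (self.n_unique_alt or self.n_unique_ref) and not self.unique_group:
            raise ConfigError("planted unique alleles need a non-empty group")
        if set(self.unique_group) - lines:
            raise ConfigError("unique_group contains unknown lines")
        if self.unique_group and len(set(self.unique_group)) == len(lines):
            raise ConfigError("unique_group must be a proper subset of lines")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0, 1)")
        for met, taxon, rho in self.planted_links:
            if not -1.0 <= rho <= 1.0:
                raise ConfigError(f"planted correlation {rho} outside [-1, 1]")
            if met not in self.metabolites:
                raise ConfigError(f"planted link names unknown metabolite {met!r}")
        return self

    @property
    def effective_line_sd(self) -> float:
        return self.noise_sd / 2 if self.line_effect_sd is None else self.line_effect_sd


@dataclass
class PlantedTruth:
    """Record of every effect a generator injected."""

    metabotype_labels: pd.DataFrame | None = None  # line, stage, sex, label
    cluster_centers: pd.DataFrame | None = None    # metabolites x clusters
    virago_lines: list[str] = field(default_factory=list)
    unique_group: list[str] = field(default_factory=list)
    unique_alt_sites: list[str] = field(default_factory=list)
    unique_ref_sites: list[str] = field(default_factory=list)
    links: list[dict] = field(default_factory=list)  # metabolite/taxon/target_rho
    diet_multipliers: pd.DataFrame | None = None   # line, sex, metabolite, diet, x
    wolbachia_line: str | None = None
    extras: dict = field(default_factory=dict)

    def save(self, directory) -> None:
        """Serialize as truth.json plus TSVs for the tabular parts."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        payload = {
            "virago_lines": self.virago_lines,
            "unique_group": self.unique_group,
            "unique_alt_sites": self.unique_alt_sites,
            "unique_ref_sites": self.unique_ref_sites,
            "links": self.links,
            "wolbachia_line": self.wolbachia_line,
            "extras": self.extras,
        }
        (d / "truth.json").write_text(json.dumps(payload, indent=2))
        if self.metabotype_labels is not None:
            self.metabotype_labels.to_csv(d / "truth_metabotypes.tsv",
                                          sep="\t", index=False)
        if self.diet_multipliers is not None:
            self.diet_multipliers.to_csv(d / "truth_diet_multipliers.tsv",
                                         sep="\t", index=False)


def _stratum_offsets(config: SyntheticConfig) -> dict[tuple[str, str], np.ndarray]:
    mets = list(config.metabolites)
    larva = np.array([_LARVA_OFFSET.get(m, 0.0) for m in mets])
    if "lactate" in mets:
        larva[mets.index("lactate")] = np.log10(config.larval_lactate_fold)
    female = np.array([_FEMALE_OFFSET.get(m, 0.0) for m in mets])
    male = np.zeros(len(mets))
    return {("larva", "mixed"): larva, ("adult", "female"): female,
            ("adult", "male"): male}


def _cluster_centers(config: SyntheticConfig,
                     offsets: dict, rng: np.random.Generator) -> np.ndarray:
    """Metabotype mean offsets: orthonormal directions, orthogonalized
    against the stage/sex contrasts so metabotypes never masquerade as a
    stage or sex, scaled to ``cluster_separation`` replicate SDs."""
    m = len(config.metabolites)
    k = config.k_metabotypes
    strata_diffs = np.column_stack([
        offsets[("larva", "mixed")] - offsets[("adult", "male")],
        offsets[("adult", "female")] - offsets[("adult", "male")],
    ])
    sd_norm = strata_diffs / np.maximum(np.linalg.norm(strata_diffs, axis=0),
                                        1e-12)
    # equal-magnitude sign patterns keep the metabotype signal spread over
    # all metabolites: column z-scoring then cannot amplify a metabotype
    # contrast concentrated in a low-variance column past the stage/sex
    # separation; directions are orthogonalized against the stage/sex
    # contrasts and against each other
    dirs: list[np.ndarray] = []
    basis = [sd_norm[:, 0], sd_norm[:, 1]]
    for _ in range(k):
        for _attempt in range(100):
            v = rng.choice([-1.0, 1.0], m) / np.sqrt(m)
            for b in basis:
                v = v - (v @ b) * b
            norm = np.linalg.norm(v)
            if norm > 0.3:  # keep directions well away from used subspace
                break
        v = v / norm
        dirs.append(v)
        basis.append(v)
    centers = np.column_stack(dirs) * config.cluster_separation * config.noise_sd
    return centers  # m x k


def gen_metabolite_panel(config: SyntheticConfig,
                         ) -> tuple[pd.DataFrame, PlantedTruth]:
    """Generate a basal metabolite panel (larvae + adult females/males,
    ``config.n_replicates`` replicates per line and stratum).

    Stage/sex offsets make the three strata separable; each line belongs
    to one of ``k_metabotypes`` clusters whose centers sit
    ``cluster_separation`` replicate-SDs apart; virago lines' female
    samples are drawn from the line's male distribution; amounts below
    ``detection_floor`` are censored to missing.
    """
    config.validate()
    rng = _rng(config.seed, "panel")
    mets = list(config.metabolites)
    lines = config.lines
    offsets = _stratum_offsets(config)
    centers = _cluster_centers(config, offsets, rng)
    base = np.array([_BASE_LOG10.get(m, 1.0) for m in mets])

    k = config.k_metabotypes
    labels = rng.permutation(np.arange(len(lines)) % k + 1)
    line_effect = rng.normal(0.0, config.effective_line_sd, (len(lines), len(mets)))

    rows, values = [], []
    for li, line in enumerate(lines):
        for stage, sex in STRATA:
            draw_stratum = (stage, sex)
            if sex == "female" and line in config.virago_lines:
                draw_stratum = ("adult", "male")
            mu = (base + offsets[draw_stratum]
                  + centers[:, labels[li] - 1] + line_effect[li])
            for rep in range(1, config.n_replicates + 1):
                noise = rng.normal(0.0, config.noise_sd, len(mets)) \
                    if config.noise_sd > 0 else 0.0
                vals = 10.0 ** (mu + noise)
                rows.append({"line": line, "stage": stage, "sex": sex,
                             "diet": config.diet, "replicate": rep})
                values.append(vals)
    panel = pd.DataFrame(rows)
    V = np.asarray(values)
    V[V < config.detection_floor] = np.nan
    panel[mets] = V
    validate_panel(panel)

    label_rows = [{"line": line, "stage": st, "sex": sx, "label": int(labels[li])}
                  for li, line in enumerate(lines) for st, sx in STRATA]
    truth = PlantedTruth(
        metabotype_labels=pd.DataFrame(label_rows),
        cluster_centers=pd.DataFrame(centers, index=mets,
                                     columns=[f"C{c+1}" for c in range(k)]),
        virago_lines=list(config.virago_lines),
        extras={"detection_floor": config.detection_floor,
                "n_censored": int(np.isnan(V).sum())},
    )
    return panel, truth


# multiplicative diet-shift effect distributions: (log-mean, log-sd) per
# metabolite and target diet; energy stores rise on average, free glycerol
# tends to fall, protein is flat
_SHIFT_EFFECTS = {
    "SD": {"glucose": (np.log(1.5), 0.20), "glycogen": (np.log(1.4), 0.20),
           "TAG": (np.log(1.3), 0.25), "glycerol": (np.log(0.92), 0.20),
           "protein": (0.0, 0.03)},
    "HSD": {"glucose": (np.log(1.9), 0.25), "glycogen": (np.log(1.6), 0.25),
            "TAG": (np.log(1.5), 0.30), "glycerol": (np.log(0.88), 0.25),
            "protein": (0.0, 0.03)},
}
# sex-specific accents seen in the emulated experiment: female glycogen and
# male TAG respond more strongly
_SEX_ACCENT = {("female", "glycogen"): 1.15, ("male", "TAG"): 1.20}


def gen_diet_shift(panel: pd.DataFrame, config: SyntheticConfig,
                   ) -> tuple[pd.DataFrame, PlantedTruth]:
    """Emit SD and HSD copies of the adult LSD baseline samples.

    Each (line, sex, metabolite, target diet) cell receives a lognormal
    multiplier (overridable exactly via ``config.diet_multipliers`` keyed
    ``(line, sex, metabolite, diet)``); shifted replicates are the paired
    baseline values times the multiplier, with optional fresh lognormal
    noise of SD ``shift_noise_sd``. The returned panel contains baseline
    LSD rows plus the two shifted arms; truth records every multiplier.
    """
    config.validate()
    rng = _rng(config.seed, "diet")
    baseline = panel[(panel["diet"] == "LSD") & (panel["stage"] == "adult")]
    if baseline.empty:
        raise ConfigError("panel holds no adult LSD baseline samples")
    mets = metabolite_columns(panel)

    mult_rows = []
    shifted_frames = [panel.copy()]
    for diet in ("SD", "HSD"):
        effects = _SHIFT_EFFECTS[diet]
        arm = baseline.copy()
        arm["diet"] = diet
        for (line, sex), idx in baseline.groupby(["line", "sex"]).groups.items():
            for met in mets:
                override = config.diet_multipliers.get((line, sex, met, diet))
                if override is not None:
                    mult = float(override)
                else:
                    mu, sd = effects.get(met, (0.0, 0.10))
                    mu += np.log(_SEX_ACCENT.get((sex, met), 1.0))
                    mult = float(np.exp(rng.normal(mu, sd)))
                vals = baseline.loc[idx, met] * mult
                if config.shift_noise_sd > 0:
                    vals = vals * np.exp(rng.normal(0.0, config.shift_noise_sd,
                                                    len(vals)))
                arm.loc[idx, met] = vals
                mult_rows.append({"line": line, "sex": sex, "metabolite": met,
                                  "diet": diet, "multiplier": mult})
        shifted_frames.append(arm)
    out = pd.concat(shifted_frames, ignore_index=True)
    validate_panel(out)
    truth = PlantedTruth(diet_multipliers=pd.DataFrame(mult_rows))
    return out, truth


def _parse_spectrum(spec: str):
    kind, _, args = spec.partition(":")
    vals = [float(v) for v in args.split(",")] if args else []
    if kind == "beta" and len(vals) == 2:
        return lambda rng, n: rng.beta(vals[0], vals[1], n)
    if kind == "uniform" and len(vals) == 2:
        return lambda rng, n: rng.uniform(vals[0], vals[1], n)
    raise ConfigError(f"cannot parse MAF spectrum {spec!r}")


def gen_genotype_matrix(config: SyntheticConfig,
                        ) -> tuple[GenotypeMatrix, PlantedTruth]:
    """Biallelic calls for ``n_lines`` x ``n_sites`` independent sites.

    Per site an alternative-allele frequency is drawn from
    ``maf_spectrum`` (default Beta(0.41, 2.12), which reproduces
    inbred-panel sharing magnitudes: pairwise shared-alt mode near 6.5%
    and shared-ref mode near 74%); lines are independent Bernoulli draws.
    Exactly ``n_unique_alt``/``n_unique_ref`` sites are made private to
    ``unique_group``; accidental group-private sites elsewhere are
    repaired so the planted lists are exhaustive.
    """
    config.validate()
    rng = _rng(config.seed, "genotype")
    lines = config.lines
    n, m = len(lines), config.n_sites
    freq = _parse_spectrum(config.maf_spectrum)(rng, m)
    calls = (rng.random((n, m)) < freq).astype(np.int8)

    chroms = ("2L", "2R", "3L", "3R", "X", "4")
    sites = [f"{chroms[j % len(chroms)]}:{(j // len(chroms) + 1) * 100}"
             for j in range(m)]

    group_idx = [lines.index(l) for l in config.unique_group]
    other_idx = [i for i in range(n) if i not in group_idx]
    planted = rng.choice(m, size=config.n_unique_alt + config.n_unique_ref,
                         replace=False) if config.unique_group else np.array([], int)
    alt_sites = planted[:config.n_unique_alt]
    ref_sites = planted[config.n_unique_alt:]
    for j in alt_sites:
        calls[group_idx, j] = 1
        calls[other_idx, j] = 0
    for j in ref_sites:
        calls[group_idx, j] = 0
        calls[other_idx, j] = 1

    if group_idx:
        # repair non-planted sites that are group-private by chance
        planted_mask = np.zeros(m, dtype=bool)
        planted_mask[planted] = True
        grp = calls[group_idx]
        oth = calls[other_idx]
        for val in (0, 1):
            accidental = ((grp == val).all(axis=0)
                          & (oth == 1 - val).all(axis=0) & ~planted_mask)
            calls[group_idx[0], np.flatnonzero(accidental)] = 1 - val

    if config.missing_rate > 0:
        miss = rng.random((n, m)) < config.missing_rate
        all_gone = miss.all(axis=0)
        miss[0, all_gone] = False  # keep >= 1 call per site
        calls = calls.copy()
        calls[miss] = MISSING

    G = GenotypeMatrix(calls=calls, lines=lines, sites=sites)
    truth = PlantedTruth(
        unique_group=list(config.unique_group),
        unique_alt_sites=[sites[j] for j in alt_sites],
        unique_ref_sites=[sites[j] for j in ref_sites],
        extras={"maf_spectrum": config.maf_spectrum,
                "missing_rate": config.missing_rate},
    )
    return G, truth


def gen_abundance_table(config: SyntheticConfig, panel: pd.DataFrame,
                        ) -> tuple[AbundanceTable, PlantedTruth]:
    """Compositional counts for every panel sample.

    Each line gets a spiky Dirichlet base composition dominated by the
    core Acetobacter/Lactobacillus species; the Wolbachia-infected line
    (if any) carries a large endosymbiont read fraction; planted
    (metabolite, taxon, rho) links are induced by a Gaussian copula
    against the matched sample's metabolite value, at species level or —
    when the taxon names a genus — spread over its member species. Rows
    sum to ``config.depth``.
    """
    config.validate()
    if panel.empty:
        raise ConfigError("panel is empty")
    rng = _rng(config.seed, "abundance")

    species = dict(CORE_SPECIES)
    for name, genus in RARE_SPECIES.items():
        if len(species) >= config.n_taxa:
            break
        species[name] = genus
    taxa = list(species)
    if config.wolbachia_line is not None:
        species[WOLBACHIA] = "Wolbachia"
        taxa.append(WOLBACHIA)
    taxonomy = pd.Series(species, name="genus")
    genera = set(taxonomy.values)

    link_species: dict[str, tuple[int, float, float]] = {}
    truth_links = []
    for met, target, rho in config.planted_links:
        if met not in panel.columns:
            raise ConfigError(f"planted link names unknown metabolite {met!r}")
        if target in taxa:
            members = [target]
            level = "species"
        elif target in genera:
            members = [t for t in taxa if taxonomy[t] == target]
            level = "genus"
        else:
            raise ConfigError(f"planted link names unknown taxon {target!r}")
        li = len(truth_links)
        for t in members:
            link_species[t] = (li, rho, 1.0 / len(members))
        truth_links.append({"metabolite": met, "taxon": target,
                            "target_rho": float(rho), "level": level,
                            "sign": int(np.sign(rho))})

    samples = sample_ids(panel).to_numpy()
    n = len(samples)
    lines = panel["line"].to_numpy()
    uniq_lines = list(dict.fromkeys(lines))
    alpha = np.array([1.0 if t in CORE_SPECIES else 0.08 for t in taxa
                      if t != WOLBACHIA])
    base_by_line = {l: rng.dirichlet(alpha) for l in uniq_lines}

    # copula scores per planted link, one z per sample; the correlation is
    # conditioned on the samples a correlation analysis would keep — the
    # Wolbachia-infected line is excluded there by design
    kept = np.ones(n, dtype=bool)
    if config.wolbachia_line is not None:
        kept = panel["line"].to_numpy() != config.wolbachia_line
    zs = []
    for lk in truth_links:
        x = panel[lk["metabolite"]].to_numpy(dtype=float)
        x = np.where(np.isnan(x), np.nanmedian(x), x)
        u = (stats.rankdata(x) - 0.5) / n
        zm = stats.norm.ppf(u)
        zk = zm[kept]
        zk = (zk - zk.mean()) / zk.std()
        rho_p = 2.0 * np.sin(np.pi * lk["target_rho"] / 6.0)
        # conditional draw: noise orthogonalized against the scores
        # in-sample, so the realized correlation is rho_p by construction
        # (otherwise its sampling SD ~ 1/sqrt(n) would dominate the
        # achieved-vs-target tolerance at these sample sizes)
        eps = rng.standard_normal(kept.sum())
        eps = eps - (eps @ zk) / (zk @ zk) * zk
        sd = eps.std()
        eps = eps / sd if sd > 0 else eps
        zt = np.empty(n)
        zt[kept] = rho_p * zk + np.sqrt(max(0.0, 1 - rho_p ** 2)) * eps
        zt[~kept] = rng.standard_normal((~kept).sum())
        zs.append(zt)

    counts = np.zeros((n, len(taxa)), dtype=np.int64)
    for i in range(n):
        w = np.zeros(len(taxa))
        base = base_by_line[lines[i]]
        # base weights for plain taxa, jittered per sample
        for j, t in enumerate(t2 for t2 in taxa if t2 != WOLBACHIA):
            if t in link_species:
                continue
            w[taxa.index(t)] = base[j] * np.exp(rng.normal(0.0, 0.35))
        if config.wolbachia_line is not None and lines[i] == config.wolbachia_line:
            w[taxa.index(WOLBACHIA)] = 1.2 * np.exp(rng.normal(0.0, 0.15))
        # each linked taxon's share is a logistic function of its copula
        # score, so the closed proportion is monotone in the score and the
        # achieved rank correlation tracks the target
        rest = w.sum()
        for t, (li, rho, frac) in link_species.items():
            q = 1.0 / (1.0 + np.exp(-(np.log(0.15 / 0.85) + zs[li][i])))
            w[taxa.index(t)] = rest * frac * q / (1.0 - q)
        counts[i] = rng.multinomial(config.depth, w / w.sum())
    table = AbundanceTable(
        counts=pd.DataFrame(counts, index=samples, columns=taxa),
        meta=panel[META_COLUMNS].set_index(samples),
        taxonomy=taxonomy,
    )
    truth = PlantedTruth(links=truth_links, wolbachia_line=config.wolbachia_line)
    return table, truth


def gen_plate_reads(panel: pd.DataFrame, assay: AssaySpec, seed: int = 0,
                    slope: float = 0.5, intercept: float = 0.05,
                    standard_concs=(0.0, 0.25, 0.5, 1.0, 2.0, 4.0),
                    read_noise_sd: float = 0.0) -> pd.DataFrame:
    """Simulate raw plate readings for one assay (the inverse of
    ``quantify``): standards plus one well per panel sample.

    reading = slope * (amount * n_animals / sample_volume / dilution)
    + intercept + noise. Wells whose true diluted concentration falls
    outside [0, max standard] get an ``out_of_range`` flag. Columns:
    well, sample_id, role, standard_conc, reading, flag.
    """
    if slope <= 0:
        raise ValueError("standard slope must be positive")
    if assay.name not in panel.columns:
        raise ValueError(f"panel lacks metabolite {assay.name!r}")
    rng = np.random.default_rng([int(seed), _STREAMS["plates"]])
    rows = []
    well = 0
    for conc in standard_concs:
        noise = rng.normal(0.0, read_noise_sd) if read_noise_sd > 0 else 0.0
        rows.append({"well": f"W{well:03d}", "sample_id": "",
                     "role": "blank" if conc == 0 else "standard",
                     "standard_conc": conc,
                     "reading": slope * conc + intercept + noise, "flag": ""})
        well += 1
    ids = sample_ids(panel)
    limit = max(standard_concs)
    for sid, amount in zip(ids, panel[assay.name]):
        if pd.isna(amount):
            continue
        conc = amount * assay.n_animals / assay.sample_volume / assay.dilution
        noise = rng.normal(0.0, read_noise_sd) if read_noise_sd > 0 else 0.0
        rows.append({"well": f"W{well:03d}", "sample_id": sid, "role": "sample",
                     "standard_conc": np.nan,
                     "reading": slope * conc + intercept + noise,
                     "flag": "out_of_range" if conc > limit else ""})
        well += 1
    return pd.DataFrame(rows)


def gen_association_tables(seed: int = 0,
                           n_basal: int = 565, n_shift: int = 878,
                           n_shared_variants: int = 6,
                           n_genes_basal: int = 256, n_genes_shift: int = 377,
                           n_shared_genes: int = 32,
                           trait_counts: dict[str, int] | None = None,
                           n_nonsignificant: int = 200,
                           threshold: float = 1e-5):
    """Synthetic basal / diet-shift association tables with a planted
    overlap structure (stand-ins for GWAS supplementary result sheets).

    The basal table holds ``n_basal`` unique sub-threshold variants
    (``trait_counts`` fixes per-trait totals, e.g. 71 larval-glycerol
    SNPs), the shift table ``n_shift``; exactly ``n_shared_variants``
    variant ids and ``n_shared_genes`` gene symbols occur in both. Each
    table also carries ``n_nonsignificant`` rows above the threshold that
    filtering must remove. Returns (basal, shift, truth_dict).
    """
    rng = np.random.default_rng([int(seed), _STREAMS["assoc"]])
    if trait_counts is None:
        trait_counts = {"glycerol_larva": 71, "TAG_larva": 103,
                        "glucose_female": 88, "glycogen_female": 97,
                        "TAG_male": 110, "glycogen_male": 96}
    if sum(trait_counts.values()) != n_basal:
        raise ValueError("trait_counts must sum to n_basal")

    chroms = {"2L": 23_000_000, "2R": 25_000_000, "3L": 28_000_000,
              "3R": 32_000_000, "X": 23_500_000, "4": 1_300_000}
    chrom_names = list(chroms)

    def new_variants(k, taken):
        out = []
        while len(out) < k:
            c = chrom_names[rng.integers(len(chrom_names))]
            v = f"{c}:{int(rng.integers(1, chroms[c]))}"
            if v not in taken:
                taken.add(v)
                out.append(v)
        return out

    taken: set[str] = set()
    shared_v = new_variants(n_shared_variants, taken)
    basal_v = shared_v + new_variants(n_basal - n_shared_variants, taken)
    shift_v = shared_v + new_variants(n_shift - n_shared_variants, taken)

    shared_g = [f"Shared{g}" for g in range(1, n_shared_genes + 1)]
    basal_g = shared_g + [f"BasGene{g}" for g in
                          range(1, n_genes_basal - n_shared_genes + 1)]
    shift_g = shared_g + [f"ShiftGene{g}" for g in
                          range(1, n_genes_shift - n_shared_genes + 1)]

    def build(variants, genes, traits, condition):
        rows = []
        vi = 0
        order = rng.permutation(len(variants))
        for trait, count in traits.items():
            for _ in range(count):
                v = variants[order[vi]]
                gene = genes[vi % len(genes)] if vi < len(genes) * 2 and \
                    vi % 3 != 2 else ""
                chrom, _, pos = v.partition(":")
                rows.append({"variant_id": v, "chrom": chrom, "pos": int(pos),
                             "trait": trait,
                             "pval": float(10 ** rng.uniform(-11, np.log10(threshold) - 0.02)),
                             "gene": gene, "condition": condition})
                vi += 1
        # guarantee every gene symbol appears at least once
        used = {r["gene"] for r in rows if r["gene"]}
        spare = [r for r in rows if not r["gene"]]
        for g in genes:
            if g not in used:
                spare.pop()["gene"] = g  # noqa: B909 — mutates row in place
        for v in new_variants(n_nonsignificant, taken):
            chrom, _, pos = v.partition(":")
            rows.append({"variant_id": v, "chrom": chrom, "pos": int(pos),
                         "trait": list(traits)[0],
                         "pval": float(10 ** rng.uniform(np.log10(threshold), -1)),
                         "gene": "", "condition": condition})
        return pd.DataFrame(rows)

    shift_traits = {"glucose_female": 180, "glycogen_female": 170,
                    "TAG_male": 200, "glucose_male": 160, "TAG_female": 168}
    shift_traits["glycerol_male"] = n_shift - sum(shift_traits.values())
    basal = build(basal_v, basal_g, trait_counts, "basal")
    shift = build(shift_v, shift_g, shift_traits, "diet_shift")
    truth = {"n_basal": n_basal, "n_shift": n_shift,
             "shared_variants": sorted(shared_v), "shared_genes": sorted(shared_g),
             "n_genes_basal": n_genes_basal, "n_genes_shift": n_genes_shift,
             "trait_counts": trait_counts, "threshold": threshold,
             "chrom_lengths": chroms}
    return basal, shift, truth
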
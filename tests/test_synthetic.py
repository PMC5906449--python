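"""Generator contracts: planted truth consistency, determinism, degeneracies."""

import numpy as np
import pandas as pd
import pytest

from flymet.assay import AssaySpec, fit_standard_curve, quantify
from flymet.correlations import spearman_rp
from flymet.metabotype import diet_response, percent_normalize
from flymet.microbiome import genus_rollup, relative_abundance
from flymet.panel import metabolite_columns, sample_ids, validate_panel
from flymet.synthetic import (
    ConfigError,
    SyntheticConfig,
    gen_abundance_table,
    gen_diet_shift,
    gen_genotype_matrix,
    gen_metabolite_panel,
    gen_plate_reads,
)


class TestConfigValidation:
    def test_unknown_virago_line_rejected(self):
        with pytest.raises(ConfigError, match="virago"):
            SyntheticConfig(n_lines=3, virago_lines=("L9",)).validate()

    def test_unique_alleles_without_group_rejected(self):
        with pytest.raises(ConfigError, match="group"):
            SyntheticConfig(n_unique_alt=5).validate()

    def test_too_many_planted_sites_rejected(self):
        with pytest.raises(ConfigError, match="sites"):
            SyntheticConfig(n_sites=10, unique_group=("L1",),
                            n_unique_alt=8, n_unique_ref=8).validate()

    def test_planted_correlation_out_of_range_rejected(self):
        with pytest.raises(ConfigError, match="correlation"):
            SyntheticConfig(
                planted_links=(("glycerol", "Acetobacter", 1.5),)).validate()

    def test_unknown_link_metabolite_rejected(self):
        with pytest.raises(ConfigError, match="metabolite"):
            SyntheticConfig(
                planted_links=(("caffeine", "Acetobacter", 0.5),)).validate()


class TestMetabolitePanel:
    def test_schema_and_strata_coverage(self, basal_panel):
        panel, truth = basal_panel
        validate_panel(panel)
        per_line = panel.groupby("line")[["stage", "sex"]].nunique()
        assert (per_line["sex"] == 3).all()
        labels = truth.metabotype_labels
        assert len(labels) == 35 * 3  # every line x stratum labeled

    def test_zero_noise_degeneracy(self):
        cfg = SyntheticConfig(seed=0, n_lines=6, noise_sd=0.0)
        panel, truth = gen_metabolite_panel(cfg)
        labels = truth.metabotype_labels.set_index(["line", "stage", "sex"])["label"]
        merged = panel.assign(
            label=[labels[(r.line, r.stage, r.sex)] for r in panel.itertuples()])
        for _, grp in merged.groupby(["label", "stage", "sex"]):
            for met in metabolite_columns(panel):
                assert grp[met].nunique(dropna=False) == 1

    def test_virago_female_means_equal_male_means(self):
        cfg = SyntheticConfig(seed=0, n_lines=6, noise_sd=0.0,
                              virago_lines=("L3",))
        panel, _ = gen_metabolite_panel(cfg)
        l3 = panel[panel["line"] == "L3"]
        fem = l3[l3["sex"] == "female"].iloc[0]
        male = l3[l3["sex"] == "male"].iloc[0]
        for met in metabolite_columns(panel):
            assert fem[met] == pytest.approx(male[met])

    def test_larval_lactate_twenty_fold_over_adults(self, basal_panel):
        panel, _ = basal_panel
        lm = panel.groupby("stage")["lactate"].mean()
        assert lm["larva"] / lm["adult"] == pytest.approx(20.0, rel=0.3)

    def test_some_larval_glucose_censored(self, basal_panel):
        panel, _ = basal_panel
        larvae = panel[panel["stage"] == "larva"]
        assert larvae["glucose"].isna().any()
        assert panel[panel["stage"] == "adult"]["glucose"].notna().all()

    def test_byte_identical_across_runs(self):
        cfg = SyntheticConfig(seed=42, n_lines=5)
        a, _ = gen_metabolite_panel(cfg)
        b, _ = gen_metabolite_panel(cfg)
        pd.testing.assert_frame_equal(a, b)


class TestGenotypeGenerator:
    def test_different_tables_do_not_perturb_each_other(self):
        # genotype draws use their own substream: changing taxa count
        # leaves the genotype matrix untouched
        g1, _ = gen_genotype_matrix(SyntheticConfig(seed=5, n_taxa=5))
        g2, _ = gen_genotype_matrix(SyntheticConfig(seed=5, n_taxa=12))
        assert np.array_equal(g1.calls, g2.calls)

    def test_planted_sites_exist_in_matrix(self):
        cfg = SyntheticConfig(seed=5, n_sites=500, unique_group=("L1", "L2"),
                              n_unique_alt=20, n_unique_ref=5)
        G, truth = gen_genotype_matrix(cfg)
        assert set(truth.unique_alt_sites) <= set(G.sites)
        assert set(truth.unique_ref_sites) <= set(G.sites)

    def test_missingness_rate_applied(self):
        cfg = SyntheticConfig(seed=6, n_sites=2000, missing_rate=0.1)
        G, _ = gen_genotype_matrix(cfg)
        rate = (G.calls == -1).mean()
        assert rate == pytest.approx(0.1, abs=0.01)
        assert (G.calls != -1).any(axis=0).all()  # every site callable


class TestAbundanceGenerator:
    def test_rows_sum_to_depth(self, basal_panel):
        panel, _ = basal_panel
        cfg = SyntheticConfig(seed=1)
        table, _ = gen_abundance_table(cfg, panel.head(30))
        assert (table.counts.sum(axis=1) == cfg.depth).all()

    def test_wolbachia_only_in_infected_line(self, basal_panel):
        panel, _ = basal_panel
        cfg = SyntheticConfig(seed=1, wolbachia_line="L5")
        table, truth = gen_abundance_table(cfg, panel)
        wol = table.counts["Wolbachia pipientis"]
        infected = table.meta["line"] == "L5"
        assert (wol[infected.to_numpy()] > 0).all()
        assert (wol[~infected.to_numpy()] == 0).all()
        # endosymbiont dominates its host line's reads
        rel = relative_abundance(table)
        assert rel.counts.loc[infected.to_numpy(),
                              "Wolbachia pipientis"].min() > 0.2
        assert truth.wolbachia_line == "L5"

    def test_core_genera_dominate(self, basal_panel):
        panel, _ = basal_panel
        table, _ = gen_abundance_table(SyntheticConfig(seed=2), panel.head(30))
        rel = relative_abundance(genus_rollup(table))
        core = rel.counts[["Acetobacter", "Lactobacillus"]].sum(axis=1)
        assert core.mean() > 0.8

    def test_planted_rank_correlation_within_tolerance(self):
        cfg = SyntheticConfig(seed=3, n_lines=10, n_replicates=1,
                              planted_links=(("glycerol", "Acetobacter", -0.5),))
        panel, _ = gen_metabolite_panel(cfg)
        table, _ = gen_abundance_table(cfg, panel)
        rel = relative_abundance(genus_rollup(table))
        x = panel.set_index(sample_ids(panel).to_numpy()) \
            .loc[rel.counts.index, "glycerol"]
        r, _, n = spearman_rp(x, rel.counts["Acetobacter"])
        assert n >= 24
        assert r == pytest.approx(-0.5, abs=0.15)

    def test_unknown_link_taxon_rejected(self, basal_panel):
        panel, _ = basal_panel
        cfg = SyntheticConfig(seed=3, planted_links=(("glycerol", "Borrelia", 0.4),))
        with pytest.raises(ConfigError, match="taxon"):
            gen_abundance_table(cfg, panel)


class TestDietShiftGenerator:
    def test_unit_multipliers_give_zero_response(self):
        cfg = SyntheticConfig(seed=4, n_lines=4, diet="LSD")
        lsd, _ = gen_metabolite_panel(cfg)
        mults = {(l, s, m, d): 1.0
                 for l in cfg.lines for s in ("female", "male")
                 for m in cfg.metabolites for d in ("SD", "HSD")}
        cfg2 = SyntheticConfig(seed=4, n_lines=4, diet="LSD",
                               diet_multipliers=mults)
        shifted, _ = gen_diet_shift(lsd, cfg2)
        resp = diet_response(shifted[shifted["diet"] == "LSD"],
                             shifted[shifted["diet"] == "SD"])
        assert resp["percent_change"].dropna().to_numpy() == pytest.approx(
            0.0, abs=1e-9)

    def test_planted_95_percent_increase(self):
        cfg = SyntheticConfig(seed=4, n_lines=8, diet="LSD",
                              diet_multipliers={("L7", "male", "TAG", "HSD"): 1.95})
        lsd, _ = gen_metabolite_panel(cfg)
        shifted, truth = gen_diet_shift(lsd, cfg)
        nb, basis = percent_normalize(shifted[shifted["diet"] == "LSD"])
        nh, _ = percent_normalize(shifted[shifted["diet"] == "HSD"], basis=basis)
        resp = diet_response(nb, nh)
        cell = resp[(resp["line"] == "L7") & (resp["sex"] == "male")
                    & (resp["metabolite"] == "TAG")]
        assert cell["percent_change"].iloc[0] == pytest.approx(95.0)
        rec = truth.diet_multipliers
        assert rec[(rec["line"] == "L7") & (rec["metabolite"] == "TAG")
                   & (rec["diet"] == "HSD")
                   & (rec["sex"] == "male")]["multiplier"].iloc[0] == 1.95

    def test_all_planted_multipliers_recovered(self):
        cfg = SyntheticConfig(seed=11, n_lines=6, diet="LSD")
        lsd, _ = gen_metabolite_panel(cfg)
        shifted, truth = gen_diet_shift(lsd, cfg)
        resp = diet_response(shifted[shifted["diet"] == "LSD"],
                             shifted[shifted["diet"] == "HSD"])
        m = truth.diet_multipliers.query("diet == 'HSD'") \
            .set_index(["line", "sex", "metabolite"])["multiplier"]
        got = resp.set_index(["line", "sex", "metabolite"])["percent_change"]
        common = got.dropna().index.intersection(m.index)
        assert len(common) > 20
        err = (got[common] - (m[common] - 1) * 100).abs()
        assert err.max() < 1e-9  # paired copies: exact at zero shift noise

    def test_energy_stores_rise_on_average(self):
        cfg = SyntheticConfig(seed=12, n_lines=20, diet="LSD")
        lsd, _ = gen_metabolite_panel(cfg)
        _, truth = gen_diet_shift(lsd, cfg)
        m = truth.diet_multipliers
        for met in ("glucose", "glycogen", "TAG"):
            assert m[m["metabolite"] == met]["multiplier"].mean() > 1.1
        assert abs(m[m["metabolite"] == "protein"]["multiplier"].mean() - 1) < 0.05

    def test_missing_baseline_rejected(self, basal_panel):
        panel, _ = basal_panel  # SD diet only
        with pytest.raises(ConfigError, match="LSD"):
            gen_diet_shift(panel, SyntheticConfig(seed=0))


class TestPlateReads:
    spec = AssaySpec("glycogen", dilution=6, n_animals=8, sample_volume=1.0)

    def _roundtrip(self, plate, spec):
        stds = plate[plate["role"].isin(["standard", "blank"])]
        cal = fit_standard_curve(stds[["standard_conc", "reading"]].to_numpy())
        out = {}
        for _, row in plate[plate["role"] == "sample"].iterrows():
            out[row["sample_id"]] = quantify(row["reading"], cal, spec) \
                .amount_per_animal
        return out

    def test_zero_noise_roundtrip_exact(self):
        panel, _ = gen_metabolite_panel(SyntheticConfig(seed=6, n_lines=3))
        plate = gen_plate_reads(panel, self.spec, seed=6)
        got = self._roundtrip(plate, self.spec)
        want = panel.set_index(sample_ids(panel).to_numpy())["glycogen"]
        for sid, amount in got.items():
            assert amount == pytest.approx(want[sid], rel=1e-12)

    def test_one_percent_noise_mean_error_under_three_percent(self):
        panel, _ = gen_metabolite_panel(SyntheticConfig(seed=7, n_lines=12))
        plate = gen_plate_reads(panel, self.spec, seed=7, read_noise_sd=0.005)
        got = self._roundtrip(plate, self.spec)
        want = panel.set_index(sample_ids(panel).to_numpy())["glycogen"]
        rel_err = [abs(v - want[k]) / want[k] for k, v in got.items()]
        assert np.mean(rel_err) < 0.03

    def test_out_of_linear_range_flagged(self):
        panel, _ = gen_metabolite_panel(SyntheticConfig(seed=8, n_lines=3))
        narrow = gen_plate_reads(panel, self.spec, seed=8,
                                 standard_concs=(0.0, 0.1, 0.2))
        assert (narrow[narrow["role"] == "sample"]["flag"] == "out_of_range").any()

    def test_nonpositive_slope_rejected(self, basal_panel):
        panel, _ = basal_panel
        with pytest.raises(ValueError, match="slope"):
            gen_plate_reads(panel, self.spec, slope=0.0)
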
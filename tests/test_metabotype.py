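"""Normalization, clustering, PCA, virago calling and diet responses."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from flymet.metabotype import (
    call_viragos,
    diet_response,
    kmeans_metabotypes,
    pca,
    percent_normalize,
    zscore_normalize,
)
from flymet.panel import PanelError, line_means
from tests.conftest import make_panel


class TestZScore:
    def test_symmetric_column(self):
        p = make_panel({"TAG": [1.0, 2.0, 3.0]})
        out = zscore_normalize(p)
        assert out["TAG"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_mean_zero_sd_one_with_missing_preserved(self):
        rng = np.random.default_rng(0)
        p = make_panel({"TAG": rng.lognormal(1, 1, 8).tolist(),
                        "glucose": [np.nan, *rng.lognormal(0, 1, 7)]})
        out = zscore_normalize(p)
        for col in ("TAG", "glucose"):
            assert abs(out[col].mean()) < 1e-12
            assert out[col].std(ddof=1) == pytest.approx(1.0)
        assert out["glucose"].isna().tolist() == p["glucose"].isna().tolist()

    def test_hand_computed_values(self):
        vals = np.array([2.0, 4.0, 4.0, 10.0])
        p = make_panel({"TAG": vals.tolist()})
        out = zscore_normalize(p)
        expected = (vals - vals.mean()) / vals.std(ddof=1)
        assert out["TAG"].to_numpy() == pytest.approx(expected)

    def test_zero_variance_column_named_in_error(self):
        p = make_panel({"TAG": [1.0, 1.0, 1.0]})
        with pytest.raises(PanelError, match="TAG"):
            zscore_normalize(p)


class TestPercentNormalize:
    def test_constant_column_all_100(self):
        p = make_panel({"TAG": [5.0, 5.0, 5.0]})
        out, _ = percent_normalize(p)
        assert out["TAG"].tolist() == pytest.approx([100.0] * 3)

    def test_proportional_values(self):
        p = make_panel({"TAG": [1.0, 2.0, 4.0]})
        out, _ = percent_normalize(p)
        assert sorted(out["TAG"]) == pytest.approx([25.0, 50.0, 100.0])

    def test_group_max_is_exactly_100_per_stratum(self):
        rng = np.random.default_rng(1)
        frames = [make_panel({"TAG": rng.lognormal(1, 1, 5).tolist(),
                              "glucose": rng.lognormal(0, 1, 5).tolist()},
                             stage=stage, sex=sex)
                  for stage, sex in (("adult", "female"), ("adult", "male"),
                                     ("larva", "mixed"))]
        p = pd.concat(frames, ignore_index=True)
        out, _ = percent_normalize(p)
        for _, grp in out.groupby(["stage", "sex"]):
            assert grp["TAG"].max() == pytest.approx(100.0)
            assert grp["glucose"].max() == pytest.approx(100.0)

    def test_replicates_averaged_before_normalizing(self):
        p = pd.concat([make_panel({"TAG": [2.0, 6.0]}),
                       make_panel({"TAG": [4.0, 2.0]})], ignore_index=True)
        p.loc[2:, "replicate"] = 2
        out, _ = percent_normalize(p)
        # line means are (3, 4) -> (75, 100)
        assert sorted(out["TAG"]) == pytest.approx([75.0, 100.0])


def brute_force_min_wss(X: np.ndarray, k: int) -> float:
    best = np.inf
    for labels in itertools.product(range(k), repeat=len(X)):
        if len(set(labels)) < k:
            continue
        wss = 0.0
        for c in range(k):
            pts = X[np.array(labels) == c]
            wss += ((pts - pts.mean(axis=0)) ** 2).sum()
        best = min(best, wss)
    return best


class TestKMeans:
    def test_separated_clouds_perfectly_partitioned(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 1, (10, 2)), rng.normal(10, 1, (10, 2))])
        p = make_panel({"a": X[:, 0].tolist(), "b": X[:, 1].tolist()})
        cl = kmeans_metabotypes(p, k=2, seed=0)
        labels = cl.labels.to_numpy()
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert set(labels) == {1, 2}

    def test_matches_exhaustive_minimum_wss_in_1d(self):
        vals = [0.0, 0.9, 2.0, 7.5, 8.1, 9.0]
        p = make_panel({"a": vals})
        cl = kmeans_metabotypes(p, k=2, n_init=50, seed=0)
        assert cl.inertia == pytest.approx(
            brute_force_min_wss(np.array(vals)[:, None], 2))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        p = make_panel({"a": rng.normal(size=12).tolist(),
                        "b": rng.normal(size=12).tolist()})
        a = kmeans_metabotypes(p, k=3, seed=5).labels
        b = kmeans_metabotypes(p, k=3, seed=5).labels
        assert a.tolist() == b.tolist()

    def test_k_larger_than_distinct_rows_rejected(self):
        p = make_panel({"a": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError):
            kmeans_metabotypes(p, k=2, seed=0)

    def test_combined_panel_recovers_strata(self, basal_panel):
        panel, _ = basal_panel
        lm = line_means(panel)
        cl = kmeans_metabotypes(zscore_normalize(lm), k=3, seed=0)
        strata = (lm["stage"] + "/" + lm["sex"]).to_numpy()
        assert adjusted_rand_score(strata, cl.labels.to_numpy()) >= 0.9

    def test_planted_metabotypes_recovered_within_stratum(self, basal_panel):
        panel, truth = basal_panel
        lm = line_means(panel)
        fem = lm[(lm["stage"] == "adult") & (lm["sex"] == "female")]
        cl = kmeans_metabotypes(zscore_normalize(fem), k=3, seed=0)
        tl = truth.metabotype_labels
        planted = tl[(tl["stage"] == "adult") & (tl["sex"] == "female")] \
            .set_index("line")["label"][fem["line"]].to_numpy()
        assert adjusted_rand_score(planted, cl.labels.to_numpy()) >= 0.9


class TestPCA:
    def test_collinear_columns_put_all_variance_on_pc1(self):
        x = np.linspace(0, 1, 10)
        p = make_panel({"a": x.tolist(), "b": (2 * x).tolist()})
        res = pca(p)
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_eigenvalues_match_hand_eigen_solve(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 3)) @ np.diag([3.0, 1.0, 0.3])
        p = make_panel({c: X[:, i].tolist() for i, c in enumerate("abc")},
                       lines=[f"L{i}" for i in range(30)])
        res = pca(p)
        evals = np.sort(np.linalg.eigvalsh(np.cov(X.T)))[::-1]
        assert res.variance_fraction == pytest.approx(evals / evals.sum())

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 4))
        p = make_panel({c: X[:, i].tolist() for i, c in enumerate("abcd")},
                       lines=[f"L{i}" for i in range(20)])
        res = pca(p)
        for pc in res.loadings.columns:
            lead = res.loadings[pc].abs().idxmax()
            assert res.loadings.loc[lead, pc] > 0

    def test_variance_fractions_non_increasing(self, basal_panel):
        panel, _ = basal_panel
        res = pca(zscore_normalize(line_means(panel)))
        vf = res.variance_fraction
        assert np.all(np.diff(vf) <= 1e-12) and vf.sum() <= 1 + 1e-9


class TestViragoCalls:
    @staticmethod
    def _call(panel):
        norm = zscore_normalize(line_means(panel))
        clusters = kmeans_metabotypes(norm, k=3, seed=0)
        return call_viragos(pca(norm), clusters)

    def test_planted_viragos_called_exactly(self, virago_panel):
        panel, truth = virago_panel
        calls = self._call(panel)
        assert sorted(c.line for c in calls) == sorted(truth.virago_lines)
        for c in calls:
            assert c.dist_to_male < c.dist_to_female

    def test_no_planted_viragos_gives_empty_call_set(self, basal_panel):
        panel, _ = basal_panel
        assert self._call(panel) == []


class TestDietResponse:
    def test_identical_panels_give_zero_everywhere(self):
        p = make_panel({"TAG": [10.0, 20.0, 30.0]}, diet="LSD")
        resp = diet_response(p, p.assign(diet="HSD"))
        assert resp["percent_change"].to_numpy() == pytest.approx([0.0] * 3)

    def test_hand_percent_change(self):
        base = make_panel({"TAG": [40.0]}, diet="LSD")
        shift = make_panel({"TAG": [78.0]}, diet="HSD")
        resp = diet_response(base, shift)
        assert resp["percent_change"].iloc[0] == pytest.approx(95.0)

    def test_zero_or_missing_baseline_emitted_missing(self):
        base = make_panel({"TAG": [0.0, np.nan]}, diet="LSD")
        shift = make_panel({"TAG": [5.0, 5.0]}, diet="HSD")
        resp = diet_response(base, shift)
        assert resp["percent_change"].isna().all()

    def test_unmatched_cells_raise(self):
        base = make_panel({"TAG": [1.0]}, lines=["L1"], diet="LSD")
        shift = make_panel({"TAG": [1.0]}, lines=["L2"], diet="HSD")
        with pytest.raises(ValueError, match="baseline"):
            diet_response(base, shift)

    def test_scale_invariance_through_percent_normalization(self):
        # rescaling raw amounts by a positive constant per metabolite and
        # stratum leaves percent-normalized responses unchanged
        rng = np.random.default_rng(8)
        base = make_panel({"TAG": rng.lognormal(1, 0.5, 6).tolist()}, diet="LSD")
        shift = base.assign(diet="HSD", TAG=base["TAG"] * rng.lognormal(0.3, 0.2, 6))
        nb, basis = percent_normalize(base)
        ns, _ = percent_normalize(shift, basis=basis)
        r1 = diet_response(nb, ns)["percent_change"].to_numpy()
        scale = 7.3
        nb2, basis2 = percent_normalize(base.assign(TAG=base["TAG"] * scale))
        ns2, _ = percent_normalize(shift.assign(TAG=shift["TAG"] * scale),
                                   basis=basis2)
        r2 = diet_response(nb2, ns2)["percent_change"].to_numpy()
        assert r2 == pytest.approx(r1, rel=1e-10)
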
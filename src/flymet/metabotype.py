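"""Metabotype analysis of metabolite panels.

Normalization (column z-scores for clustering, percent-of-maximum-line for
diet comparisons), k-means metabotype clustering, PCA of the z-scored
panel, calling of "virago" lines (lines whose adult females carry a
male-like metabolite profile), and diet-shift percent responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .panel import (
    meta_present,
    PanelError,
    impute_half_min,
    line_means,
    metabolite_columns,
    sample_ids,
)

__all__ = [
    "zscore_normalize",
    "percent_normalize",
    "kmeans_metabotypes",
    "pca",
    "call_viragos",
    "diet_response",
    "ClusterAssignment",
    "PCAResult",
    "ViragoCall",
]


def zscore_normalize(panel: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-score each metabolite (sample SD, ddof=1).

    Missing entries are preserved; statistics use non-missing values only.
    """
    out = panel.copy()
    for col in metabolite_columns(panel):
        v = out[col].astype(float)
        n_obs = v.notna().sum()
        if n_obs < 2:
            raise PanelError(f"column {col!r} has fewer than 2 observed values")
        sd = v.std(ddof=1)
        if not sd > 0:
            raise PanelError(f"column {col!r} has zero variance")
        out[col] = (v - v.mean()) / sd
    return out


def percent_normalize(panel: pd.DataFrame,
                      basis: pd.Series | None = None,
                      ) -> tuple[pd.DataFrame, pd.Series]:
    """Express line means as percent of the maximum line mean per
    metabolite x (stage, sex) group; the group maximum maps to 100.

    Replicates are averaged first, so the output has one row per
    (line, stage, sex, diet). ``basis`` lets a second panel reuse the first
    panel's group maxima (required for diet responses, which must share one
    normalization basis); it is the Series returned by a previous call,
    indexed by (metabolite, stage, sex). Returns ``(normalized, basis)``.
    """
    lm = line_means(panel)
    mets = metabolite_columns(lm)
    if basis is None:
        entries = {}
        for (stage, sex), grp in lm.groupby(["stage", "sex"], observed=True):
            for met in mets:
                mx = grp[met].max()
                if not mx > 0:
                    raise PanelError(
                        f"group (stage={stage}, sex={sex}) has no positive "
                        f"{met!r} line mean")
                entries[(met, stage, sex)] = mx
        basis = pd.Series(entries)
        basis.index.names = ["metabolite", "stage", "sex"]
    out = lm.copy()
    for met in mets:
        denom = [basis.get((met, st, sx), np.nan)
                 for st, sx in zip(lm["stage"], lm["sex"])]
        out[met] = lm[met] / np.asarray(denom, dtype=float) * 100.0
    return out, basis


@dataclass
class ClusterAssignment:
    """K-means result: per-sample labels in 1..k plus fit metadata."""

    labels: pd.Series            # index = sample id, values 1..k
    k: int
    inertia: float               # within-cluster sum of squares
    n_init: int
    seed: int
    meta: pd.DataFrame           # metadata rows aligned with labels


def kmeans_metabotypes(panel: pd.DataFrame, k: int,
                       n_init: int = 50, seed: int = 0) -> ClusterAssignment:
    """Cluster panel rows into k metabotypes by k-means (best of n_init
    restarts by within-cluster sum of squares).

    The panel should be z-score normalized first; missing values are
    imputed as half the column minimum. Labels are renumbered 1..k in
    order of first appearance so output is stable across restarts.
    """
    filled = impute_half_min(panel)
    mets = metabolite_columns(filled)
    X = filled[mets].to_numpy(dtype=float)
    if k > len(X):
        raise ValueError(f"k={k} exceeds number of samples {len(X)}")
    if k > len(np.unique(X, axis=0)):
        raise ValueError(f"k={k} exceeds number of distinct rows")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd")
    raw = km.fit_predict(X)
    # renumber by first appearance -> deterministic label identity
    order = {old: new + 1 for new, old in enumerate(pd.unique(raw))}
    labels = pd.Series([order[v] for v in raw],
                       index=sample_ids(filled).to_numpy(), name="metabotype")
    return ClusterAssignment(labels=labels, k=k, inertia=float(km.inertia_),
                             n_init=n_init, seed=seed,
                             meta=filled[meta_present(filled)].set_index(labels.index))


@dataclass
class PCAResult:
    scores: pd.DataFrame              # samples x PCs
    loadings: pd.DataFrame            # metabolites x PCs
    variance_fraction: np.ndarray     # non-increasing, sums to <= 1
    meta: pd.DataFrame


def pca(panel: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA of the (z-scored) panel via the covariance eigen-decomposition.

    Sign convention: within each component the largest-magnitude metabolite
    loading is positive, which makes scores reproducible across libraries.
    """
    filled = impute_half_min(panel)
    mets = metabolite_columns(filled)
    X = filled[mets].to_numpy(dtype=float)
    if len(X) < 2:
        raise ValueError("need >= 2 samples for PCA")
    n_components = n_components or min(len(mets), len(X) - 1)
    model = PCA(n_components=n_components)
    scores = model.fit_transform(X)
    loadings = model.components_.T  # metabolites x PCs
    for j in range(loadings.shape[1]):
        lead = np.argmax(np.abs(loadings[:, j]))
        if loadings[lead, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    pcs = [f"PC{i + 1}" for i in range(n_components)]
    ids = sample_ids(filled).to_numpy()
    return PCAResult(
        scores=pd.DataFrame(scores, index=ids, columns=pcs),
        loadings=pd.DataFrame(loadings, index=mets, columns=pcs),
        variance_fraction=model.explained_variance_ratio_.copy(),
        meta=filled[meta_present(filled)].set_index(ids),
    )


@dataclass
class ViragoCall:
    line: str
    cluster: int                 # cluster holding the line's female samples
    dist_to_male: float
    dist_to_female: float


def call_viragos(pca_result: PCAResult, clusters: ClusterAssignment,
                 n_pcs: int = 2) -> list[ViragoCall]:
    """Flag lines whose adult female profile sits in male PC territory.

    The male and female reference clusters are the clusters whose adult
    members are majority-male / majority-female; a line is called when the
    centroid of its adult female scores (top ``n_pcs`` PCs) is closer to
    the male-cluster centroid than to the female-cluster centroid.
    """
    meta = pca_result.meta
    adults = meta["stage"] == "adult"
    if not (adults & (meta["sex"] == "female")).any() or \
       not (adults & (meta["sex"] == "male")).any():
        raise ValueError("need adult samples of both sexes")
    pcs = pca_result.scores.columns[:n_pcs]
    scores = pca_result.scores.loc[:, pcs]
    labels = clusters.labels.reindex(scores.index)
    if labels.isna().any():
        raise ValueError("cluster assignment does not cover all PCA samples")

    sex_cluster = {}
    for sex in ("male", "female"):
        sel = adults & (meta["sex"] == sex)
        counts = labels[sel].value_counts()
        top = counts.iloc[0] if len(counts) else 0
        if top <= sel.sum() / 2:
            raise ValueError(f"no cluster holds a majority of {sex} samples")
        sex_cluster[sex] = counts.index[0]
    if sex_cluster["male"] == sex_cluster["female"]:
        raise ValueError("male and female samples share a majority cluster")

    centroids = {
        sex: scores[(labels == cl).to_numpy()].mean(axis=0).to_numpy()
        for sex, cl in sex_cluster.items()
    }
    calls: list[ViragoCall] = []
    fem = adults & (meta["sex"] == "female")
    for line, grp in meta[fem].groupby("line", sort=False):
        pt = scores.loc[grp.index].mean(axis=0).to_numpy()
        d_m = float(np.linalg.norm(pt - centroids["male"]))
        d_f = float(np.linalg.norm(pt - centroids["female"]))
        if d_m < d_f:
            cl = int(labels.loc[grp.index].mode().iloc[0])
            calls.append(ViragoCall(line=line, cluster=cl,
                                    dist_to_male=d_m, dist_to_female=d_f))
    return calls


def diet_response(lsd_panel: pd.DataFrame,
                  shifted_panel: pd.DataFrame) -> pd.DataFrame:
    """Percent change of each (line, sex, metabolite) cell from the LSD
    baseline: (shifted - baseline) / baseline * 100.

    Both panels must be percent-normalized with the same basis (or be on
    the same raw scale). Replicates are averaged per cell; cells whose
    baseline is missing or zero are emitted missing. Returns a long table
    (line, stage, sex, metabolite, baseline, shifted, percent_change).
    """
    mets = metabolite_columns(lsd_panel)
    if set(mets) != set(metabolite_columns(shifted_panel)):
        raise ValueError("panels measure different metabolites")
    key = ["line", "stage", "sex"]
    base = line_means(lsd_panel).groupby(key, observed=True)[mets].mean()
    shift = line_means(shifted_panel).groupby(key, observed=True)[mets].mean()
    unmatched = shift.index.difference(base.index)
    if len(unmatched):
        raise ValueError(f"shifted cells without LSD baseline: {list(unmatched)}")
    rows = []
    for idx in shift.index:
        line, stage, sex = idx
        for met in mets:
            b = base.loc[idx, met]
            s = shift.loc[idx, met]
            if pd.isna(b) or b == 0 or pd.isna(s):
                pct = np.nan
            else:
                pct = (s - b) / b * 100.0
            rows.append({"line": line, "stage": stage, "sex": sex,
                         "metabolite": met, "baseline": b, "shifted": s,
                         "percent_change": pct})
    return pd.DataFrame(rows)
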
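"""Metabolite panel schema and helpers.

A panel is a tidy :class:`pandas.DataFrame`: one row per biological sample,
metadata columns ``line, stage, sex, diet, replicate`` followed by one column
per metabolite holding the amount per animal (assay units / animal). Missing
values encode below-detection measurements.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: metadata columns, in canonical order
META_COLUMNS = ["line", "stage", "sex", "diet", "replicate"]

STAGES = {"larva", "adult"}
SEXES = {"female", "male", "mixed"}
DIETS = {"SD", "LSD", "HSD"}


class PanelError(ValueError):
    """Raised when a metabolite panel violates its schema."""


def metabolite_columns(panel: pd.DataFrame) -> list[str]:
    """Names of the metabolite (non-metadata) columns, in panel order."""
    return [c for c in panel.columns if c not in META_COLUMNS]


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Check the panel schema; return the panel unchanged.

    Enforces unique (line, stage, sex, diet, replicate) keys, known stage /
    sex / diet levels, larvae being mixed-sex, and non-negative amounts.
    """
    required = [c for c in META_COLUMNS if c != "replicate"]
    missing = [c for c in required if c not in panel.columns]
    if missing:
        raise PanelError(f"panel lacks metadata columns: {missing}")
    if not metabolite_columns(panel):
        raise PanelError("panel has no metabolite columns")
    keys = panel[[c for c in META_COLUMNS if c in panel.columns]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0].tolist()
        raise PanelError(f"duplicate sample key: {dup}")
    if not set(panel["stage"]) <= STAGES:
        raise PanelError(f"unknown stage in {sorted(set(panel['stage']) - STAGES)}")
    if not set(panel["sex"]) <= SEXES:
        raise PanelError(f"unknown sex in {sorted(set(panel['sex']) - SEXES)}")
    if not set(panel["diet"]) <= DIETS:
        raise PanelError(f"unknown diet in {sorted(set(panel['diet']) - DIETS)}")
    larvae = panel[panel["stage"] == "larva"]
    if len(larvae) and not (larvae["sex"] == "mixed").all():
        raise PanelError("larval samples must have sex == 'mixed'")
    values = panel[metabolite_columns(panel)]
    if (values < 0).any().any():
        bad = values.columns[(values < 0).any()][0]
        raise PanelError(f"negative amounts in column {bad!r}")
    return panel


def meta_present(panel: pd.DataFrame) -> list[str]:
    """Metadata columns actually present (line means drop ``replicate``)."""
    return [c for c in META_COLUMNS if c in panel.columns]


def sample_ids(panel: pd.DataFrame) -> pd.Series:
    """Stable string id per row: ``line:stage:sex:diet[:replicate]``."""
    parts = [panel[c].astype(str) for c in meta_present(panel)]
    out = parts[0]
    for p in parts[1:]:
        out = out + ":" + p
    return out


def line_means(panel: pd.DataFrame) -> pd.DataFrame:
    """Average replicates: one row per (line, stage, sex, diet).

    Metabolite means ignore missing values (a censored replicate does not
    zero the line). The replicate column is dropped.
    """
    mets = metabolite_columns(panel)
    out = (
        panel.groupby(["line", "stage", "sex", "diet"], sort=False, observed=True)[mets]
        .mean()
        .reset_index()
    )
    return out


def impute_half_min(panel: pd.DataFrame) -> pd.DataFrame:
    """Replace missing amounts by half the column minimum observed value.

    Below-detection measurements are left-censored; half the smallest
    observed value is a conventional stand-in that keeps censored rows
    usable for clustering and PCA.
    """
    out = panel.copy()
    for col in metabolite_columns(out):
        vals = out[col]
        if vals.isna().any():
            observed = vals.dropna()
            if observed.empty:
                raise PanelError(f"column {col!r} has no observed values to impute from")
            out[col] = vals.fillna(observed.min() / 2.0)
    return out


def as_matrix(panel: pd.DataFrame) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """Split a panel into (value matrix, metabolite names, metadata frame)."""
    mets = metabolite_columns(panel)
    return panel[mets].to_numpy(dtype=float), mets, panel[META_COLUMNS].copy()
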
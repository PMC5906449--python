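"""Spearman rank correlation with AS89 p-values, plus the ANOVA/Bonferroni test.

The rank correlation is computed on midranks; p-values follow the AS 89
algorithm for the distribution of Spearman's S = sum(d_i^2):

* tie-free samples with n <= 9: exact tail probabilities from full
  enumeration of the permutation distribution of S;
* tie-free samples with n >= 10: the AS 89 Edgeworth-series approximation;
* tied samples: midrank correlation with the t approximation
  t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.

Two-sided p-values throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "spearman_rp",
    "spearman_matrix",
    "filter_significant",
    "anova_bonferroni",
    "CorrelationResult",
    "AnovaResult",
]

# Edgeworth-series coefficients of the AS 89 algorithm (Best & Roberts 1975).
_C = (0.2274, 0.2531, 0.1745, 0.0758, 0.1033, 0.3932,
      0.0879, 0.0151, 0.0072, 0.0831, 0.0267, 0.04567)


@lru_cache(maxsize=None)
def _exact_s_counts(n: int) -> np.ndarray:
    """Counts of S = sum((rank_x - rank_y)^2) over all n! permutations.

    Index s of the returned array holds the number of permutations with
    S == s; s ranges over 0 .. n(n^2-1)/3.
    """
    idx = np.arange(n)
    s_max = n * (n * n - 1) // 3
    counts = np.zeros(s_max + 1, dtype=np.int64)
    for perm in itertools.permutations(range(n)):
        d = np.asarray(perm) - idx
        counts[int(np.dot(d, d))] += 1
    return counts


def _exact_p_two_sided(s: int, n: int) -> float:
    """P(|rho| >= |rho_obs|) under the null, by enumeration (tie-free)."""
    counts = _exact_s_counts(n)
    total = counts.sum()
    p_le = counts[: s + 1].sum() / total
    p_ge = counts[s:].sum() / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def _as89_upper_tail(s: float, n: int) -> float:
    """AS 89 Edgeworth approximation of P(S >= s) for tie-free data."""
    c1, c2, c3, c4, c5, c6, c7, c8, c9, c10, c11, c12 = _C
    b = 1.0 / n
    x = (6.0 * (s - 1.0) * b / (n * n - 1.0) - 1.0) * np.sqrt(1.0 / b - 1.0)
    y = x * x
    u = x * b * (c1 + b * (c2 + c3 * b)
                 + y * (-c4 + b * (c5 + c6 * b)
                        - y * b * (c7 + c8 * b
                                   - y * (c9 - c10 * b
                                          + y * b * (c11 - c12 * y)))))
    p = u / np.exp(y / 2.0) + stats.norm.sf(x)
    if p <= 0.0:
        # the series is a body approximation: far in the tail the
        # correction overwhelms the leading normal term and turns the
        # probability negative — signal the caller to fall back
        return float("nan")
    return float(min(p, 1.0))


def _has_ties(v: np.ndarray) -> bool:
    return len(np.unique(v)) < len(v)


def spearman_rp(x, y) -> tuple[float, float, int]:
    """Spearman correlation of two vectors with an AS89 p-value.

    Pairs with a missing value in either vector are dropped. Returns
    ``(r, p, n)`` where n is the number of complete pairs; ``(nan, nan, n)``
    if either variable is constant on the complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError(f"need >= 4 complete pairs, got {n}")
    if len(np.unique(x)) == 1 or len(np.unique(y)) == 1:
        warnings.warn("constant variable: Spearman r undefined", stacklevel=2)
        return float("nan"), float("nan"), n
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    tied = _has_ties(x) or _has_ties(y)
    if tied:
        # midranks + t approximation (standard for tied Spearman)
        if abs(r) >= 1.0:
            return r, float(np.finfo(float).tiny), n
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
        return r, min(p, 1.0), n
    d = rx - ry
    s = int(round(np.dot(d, d)))
    if n <= 9:
        p = _exact_p_two_sided(s, n)
    else:
        s_mean = n * (n * n - 1) / 6.0
        # the series is accurate in the upper tail; S is symmetric about its
        # mean, so the lower tail is evaluated on the reflected statistic
        if s <= s_mean:
            tail = _as89_upper_tail(2.0 * s_mean - s, n)  # P(S <= s)
        else:
            tail = _as89_upper_tail(s, n)                 # P(S >= s)
        if np.isnan(tail):
            # far tail: the Edgeworth series breaks down; use the t
            # approximation, which is well behaved there
            t = r * np.sqrt((n - 2) / (1.0 - r * r)) if abs(r) < 1 else np.inf
            p = float(min(1.0, 2.0 * stats.t.sf(abs(t), n - 2)))
        else:
            p = min(1.0, 2.0 * tail)
        p = max(p, float(np.finfo(float).tiny))
    return r, p, n


@dataclass
class CorrelationResult:
    """Symmetric rank-correlation matrix with p-values and per-pair n."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    mask: pd.DataFrame | None = None  # True where suppressed by a filter

    @property
    def variables(self) -> list[str]:
        return list(self.r.columns)

    def to_long(self) -> pd.DataFrame:
        """Long-format table (var1, var2, r, p, n, significant) of the
        upper triangle."""
        rows = []
        cols = self.variables
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                sig = True if self.mask is None else not bool(self.mask.loc[a, b])
                rows.append({
                    "var1": a, "var2": b,
                    "r": self.r.loc[a, b], "p": self.p.loc[a, b],
                    "n": self.n.loc[a, b], "significant": sig,
                })
        return pd.DataFrame(rows)


def spearman_matrix(table: pd.DataFrame) -> CorrelationResult:
    """All-pairs Spearman correlation of the columns of ``table``.

    Pairwise-complete observations; the diagonal is r=1 with p set to the
    smallest representable tail (reported as 1.0 mask-exempt — we keep the
    convention diag r=1, p=NaN so the diagonal never enters filtering).
    """
    cols = list(table.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        n[i, i] = table[cols[i]].notna().sum()
    for i, j in itertools.combinations(range(k), 2):
        rij, pij, nij = spearman_rp(table[cols[i]], table[cols[j]])
        r[i, j] = r[j, i] = rij
        p[i, j] = p[j, i] = pij
        n[i, j] = n[j, i] = nij
    mk = lambda m: pd.DataFrame(m, index=cols, columns=cols)
    return CorrelationResult(r=mk(r), p=mk(p), n=mk(n))


def filter_significant(res: CorrelationResult, alpha: float) -> CorrelationResult:
    """Mask entries with p >= alpha; the diagonal is always retained."""
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    mask = res.p >= alpha
    np.fill_diagonal(mask.values, False)
    r = res.r.mask(mask)
    return CorrelationResult(r=r, p=res.p, n=res.n, mask=mask)


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    comparisons: pd.DataFrame = field(repr=False)  # group, control, t, p_raw, p_adj


def anova_bonferroni(groups: dict[str, np.ndarray],
                     control_labels: list[str]) -> AnovaResult:
    """One-way ANOVA plus Bonferroni-corrected two-sided t-tests vs controls.

    Every non-control group is compared with every control group; raw
    two-sample t-test p-values are multiplied by the number of comparisons
    and capped at 1.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has n < 2")
    if all(np.var(v) == 0 for v in arrays.values()):
        raise ValueError("zero within-group variance in every group")
    unknown = [c for c in control_labels if c not in arrays]
    if unknown:
        raise ValueError(f"unknown control labels: {unknown}")
    f, p_f = stats.f_oneway(*arrays.values())
    if np.isnan(f):  # identical groups: no between- or within-variance signal
        f, p_f = 0.0, 1.0
    tests = [(g, c) for g in arrays if g not in control_labels for c in control_labels]
    m = len(tests)
    rows = []
    for g, c in tests:
        t, p_raw = stats.ttest_ind(arrays[g], arrays[c])
        if np.isnan(p_raw):
            t, p_raw = 0.0, 1.0
        rows.append({"group": g, "control": c, "t": float(t),
                     "p_raw": float(p_raw),
                     "p_adj": min(1.0, float(p_raw) * m)})
    return AnovaResult(f_statistic=float(f), p_value=float(p_f),
                       comparisons=pd.DataFrame(rows))
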
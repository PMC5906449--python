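"""Pairwise shared-allele statistics across inbred lines.

A genotype matrix holds biallelic calls for fully inbred lines, coded
0 = reference allele, 1 = alternative allele, -1 = missing (heterozygous
or multi-allelic calls are treated as missing — the lines are inbred).
Sharing between two lines is the percent of jointly callable sites at
which both carry the queried allele class; the empirical distribution of
this statistic over all line pairs gives a null against which the value of
a candidate group (e.g. masculinized "virago" lines) is compared. Sites
where an allele is private to a group (every group member carries it and
every other callable line carries the other allele) are enumerated
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "SharingDistribution",
    "GroupAlleleReport",
    "pairwise_sharing",
    "sharing_distribution",
    "group_sharing",
    "unique_alleles",
]

REF, ALT, MISSING = 0, 1, -1
_CLASS = {"ref": REF, "alt": ALT}


@dataclass
class GenotypeMatrix:
    """Lines x sites biallelic call matrix.

    ``calls`` is int8 with values in {0 ref, 1 alt, -1 missing}; ``lines``
    and ``sites`` label the rows/columns. Site ids are caller-defined
    strings (conventionally ``chrom:pos`` with 1-based VCF positions,
    preserved verbatim).
    """

    calls: np.ndarray
    lines: list[str]
    sites: list[str]

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.lines = [str(x) for x in self.lines]
        self.sites = [str(x) for x in self.sites]
        if self.calls.shape != (len(self.lines), len(self.sites)):
            raise ValueError("calls shape does not match line/site labels")
        if len(set(self.lines)) != len(self.lines):
            raise ValueError("duplicate line ids")
        if len(set(self.sites)) != len(self.sites):
            raise ValueError("duplicate site ids")
        bad = ~np.isin(self.calls, (REF, ALT, MISSING))
        if bad.any():
            raise ValueError("calls must be 0 (ref), 1 (alt) or -1 (missing)")
        if (self.calls == MISSING).all(axis=0).any():
            raise ValueError("site with no non-missing call")

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def row(self, line: str) -> np.ndarray:
        try:
            return self.calls[self.lines.index(line)]
        except ValueError:
            raise KeyError(f"line {line!r} not in matrix") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.lines, columns=self.sites)


def pairwise_sharing(G: GenotypeMatrix, line_a: str, line_b: str,
                     allele_class: str = "alt",
                     denominator: str = "joint") -> float:
    """Percent of sites at which two lines share the given allele class.

    denominator="joint" (default): sites callable in both lines — this
    reproduces the magnitudes seen for inbred panels (a few percent for
    shared alt, ~3/4 for shared ref). denominator="union" divides instead
    by sites where at least one of the two lines carries the class.
    """
    v = _CLASS[allele_class]
    a = G.row(line_a)
    b = G.row(line_b)
    callable_ = (a != MISSING) & (b != MISSING)
    both = (a == v) & (b == v) & callable_
    if denominator == "joint":
        denom = int(callable_.sum())
    elif denominator == "union":
        denom = int((((a == v) | (b == v)) & callable_).sum())
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise ValueError(f"no jointly callable sites for {line_a}/{line_b}")
    return 100.0 * both.sum() / denom


@dataclass
class SharingDistribution:
    """All-pairs sharing percentages with a histogram-mode summary."""

    pairs: pd.DataFrame          # line_a, line_b, percent
    allele_class: str
    bin_width: float
    mode: float                  # midpoint of most populated bin (ties: lower)
    group_value: float | None = None

    @property
    def values(self) -> np.ndarray:
        return self.pairs["percent"].to_numpy()


def _histogram_mode(values: np.ndarray, bin_width: float) -> float:
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    if edges[-1] < 100.0:
        edges = np.append(edges, 100.0 + bin_width)
    counts, _ = np.histogram(values, bins=edges)
    i = int(np.argmax(counts))  # argmax takes the first (lower) bin on ties
    return float(edges[i] + bin_width / 2.0)


def sharing_distribution(G: GenotypeMatrix, allele_class: str = "alt",
                         bin_width: float = 0.5) -> SharingDistribution:
    """Sharing percent for every pair of lines, plus the histogram mode."""
    if G.n_lines < 3:
        raise ValueError("need >= 3 lines for a sharing distribution")
    v = _CLASS[allele_class]
    hit = (G.calls == v).astype(np.int32)
    ok = (G.calls != MISSING).astype(np.int32)
    both = hit @ hit.T
    joint = ok @ ok.T
    if (joint[np.triu_indices(G.n_lines, 1)] == 0).any():
        raise ValueError("a line pair has no jointly callable sites")
    rows = []
    for i in range(G.n_lines):
        for j in range(i + 1, G.n_lines):
            rows.append({"line_a": G.lines[i], "line_b": G.lines[j],
                         "percent": 100.0 * both[i, j] / joint[i, j]})
    pairs = pd.DataFrame(rows)
    return SharingDistribution(
        pairs=pairs, allele_class=allele_class, bin_width=bin_width,
        mode=_histogram_mode(pairs["percent"].to_numpy(), bin_width))


def group_sharing(G: GenotypeMatrix, group: list[str],
                  allele_class: str = "alt",
                  statistic: str = "mean_pairwise") -> float:
    """Summary sharing value of a candidate group of lines.

    statistic="mean_pairwise" (default): mean over the within-group
    pairwise sharing values. statistic="all_members": percent of sites,
    callable in every group member, at which all members carry the class.
    """
    missing = [l for l in group if l not in G.lines]
    if missing:
        raise ValueError(f"group members absent from matrix: {missing}")
    if len(group) < 2:
        raise ValueError("group must have >= 2 members")
    if statistic == "mean_pairwise":
        vals = [pairwise_sharing(G, a, b, allele_class)
                for i, a in enumerate(group) for b in group[i + 1:]]
        return float(np.mean(vals))
    if statistic == "all_members":
        v = _CLASS[allele_class]
        sub = G.calls[[G.lines.index(l) for l in group]]
        callable_ = (sub != MISSING).all(axis=0)
        if not callable_.any():
            raise ValueError("no site callable in every group member")
        return 100.0 * ((sub == v).all(axis=0) & callable_).sum() / callable_.sum()
    raise ValueError(f"unknown statistic {statistic!r}")


@dataclass
class GroupAlleleReport:
    group: list[str]
    ref_sites: list[str]        # reference allele private to the group
    alt_sites: list[str]        # alternative allele private to the group
    missing_policy: str = "non-missing outside group must carry other allele"


def unique_alleles(G: GenotypeMatrix, group: list[str]) -> GroupAlleleReport:
    """Sites where an allele class is private to ``group``.

    A site is group-unique for a class iff every group member has a
    non-missing call of that class and every non-group line with a
    non-missing call carries the other class. Both class lists are
    returned; they are disjoint by construction.
    """
    if not group:
        raise ValueError("group must be non-empty")
    absent = [l for l in group if l not in G.lines]
    if absent:
        raise ValueError(f"group members absent from matrix: {absent}")
    idx = [G.lines.index(l) for l in group]
    rest = [i for i in range(G.n_lines) if i not in idx]
    if not rest:
        raise ValueError("group must be a proper subset of the lines")
    grp = G.calls[idx]
    oth = G.calls[rest]
    out: dict[str, list[str]] = {}
    for name, v in _CLASS.items():
        w = ALT if v == REF else REF
        group_all = (grp == v).all(axis=0)
        others_ok = ((oth == w) | (oth == MISSING)).all(axis=0)
        keep = group_all & others_ok
        out[name] = [G.sites[i] for i in np.flatnonzero(keep)]
    return GroupAlleleReport(group=list(group), ref_sites=out["ref"],
                             alt_sites=out["alt"])
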
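"""Group-comparison statistics and fibril-diameter morphometry summaries.

Thin, well-tested plumbing: per-group mean +/- SD summaries, the
two-sample Student's t-test (pooled variance by default, Welch as a
flag), and binned fibril-diameter proportions with a "small-fibril
fraction" comparison.  The experimental unit for fibril tests is the
animal: per-animal fractions are aggregated before testing, never
per-fibril pseudo-replication.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t: float
    p: float
    alpha: float
    welch: bool

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


def read_table(path) -> pd.DataFrame:
    """Measurement TSV with at least (group, value) columns."""
    return pd.read_csv(path, sep="\t")


def summarize(
    table: pd.DataFrame, value_col: str = "value", group_col: str = "group"
) -> pd.DataFrame:
    """Per-group n, mean and sample SD (n-1 denominator).

    A single-measurement group gets SD = NaN and ``sd_defined = False``.
    """
    if table.empty:
        raise ValueError("empty measurement table")
    values = pd.to_numeric(table[value_col])
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite measurement values")
    out = (
        table.assign(**{value_col: values})
        .groupby(group_col)[value_col]
        .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    out["sd_defined"] = out["n"] >= 2
    return out


def t_test(
    table: pd.DataFrame,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    welch: bool = False,
    value_col: str = "value",
    group_col: str = "group",
) -> GroupComparison:
    """Two-sided two-sample t-test (Student's pooled variance by default)."""
    a = pd.to_numeric(table.loc[table[group_col] == group_a, value_col]).to_numpy()
    b = pd.to_numeric(table.loc[table[group_col] == group_b, value_col]).to_numpy()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 measurements")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        n_a=a.size,
        n_b=b.size,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        t=float(res.statistic),
        p=float(res.pvalue),
        alpha=alpha,
        welch=welch,
    )


@dataclass
class DiameterProportions:
    """Binned diameter proportions and the small-fibril fraction comparison."""

    proportions: pd.DataFrame  # index: group; columns: bin labels (+ under/overflow)
    small_fraction_by_animal: pd.DataFrame | None
    comparison: GroupComparison | None


def diameter_proportions(
    table: pd.DataFrame,
    bin_edges_nm,
    small_edge_nm: float | None = None,
    group_col: str = "group",
    value_col: str = "diameter_nm",
    animal_col: str = "animal",
    alpha: float = 0.05,
) -> DiameterProportions:
    """Per-group histogram proportions over half-open bins [lo, hi).

    Values outside the edges land in explicit underflow/overflow bins, so
    proportions always sum to 1.  When ``small_edge_nm`` is given and the
    table holds exactly two groups, per-animal fractions of fibrils below
    that edge are compared with the two-sample t-test (animal = unit).
    """
    edges = np.asarray(bin_edges_nm, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing, length >= 2")
    labels = (
        ["underflow"]
        + [f"[{lo:g},{hi:g})" for lo, hi in zip(edges[:-1], edges[1:])]
        + ["overflow"]
    )
    rows = {}
    for group, sub in table.groupby(group_col):
        v = pd.to_numeric(sub[value_col]).to_numpy()
        idx = np.searchsorted(edges, v, side="right")  # 0 = underflow
        counts = np.bincount(idx, minlength=edges.size + 1).astype(float)
        rows[group] = counts / counts.sum()
    props = pd.DataFrame.from_dict(rows, orient="index", columns=labels)
    props.index.name = group_col

    fractions = None
    comparison = None
    if small_edge_nm is not None:
        frac = (
            table.assign(small=pd.to_numeric(table[value_col]) < small_edge_nm)
            .groupby([group_col, animal_col])["small"]
            .mean()
            .rename("small_fraction")
            .reset_index()
        )
        fractions = frac
        groups = sorted(table[group_col].unique())
        if len(groups) == 2:
            comparison = t_test(
                frac,
                groups[0],
                groups[1],
                alpha=alpha,
                value_col="small_fraction",
                group_col=group_col,
            )
    return DiameterProportions(
        proportions=props,
        small_fraction_by_animal=fractions,
        comparison=comparison,
    )
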
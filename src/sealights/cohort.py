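"""Cohort aggregation and group comparison of overall circRNA/mRNA ratios."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def build_cohort_table(
    ratios: pd.DataFrame, metadata: pd.DataFrame, qc_table: pd.DataFrame | None = None
) -> pd.DataFrame:
    """One row per (sample, gene) with the overall ratio and group labels.

    ``ratios`` needs columns sample/gene/overall_ratio (extra columns,
    e.g. the per-circRNA breakdown, are collapsed); ``metadata`` supplies
    tissue / subtype / grade / pair columns keyed by sample.  Samples
    failing QC are dropped when a QC table is given.
    """
    table = (
        ratios[["sample", "gene", "overall_ratio"]]
        .drop_duplicates(["sample", "gene"])
        .merge(metadata, on="sample", how="inner")
    )
    if qc_table is not None:
        passing = set(qc_table.loc[qc_table["pass"], "sample"])
        table = table[table["sample"].isin(passing)]
    return table.reset_index(drop=True)


def compare_groups(
    table: pd.DataFrame,
    gene: str,
    grouping: str = "tissue",
    variant: str = "welch",
) -> dict:
    """Two-sided two-sample t-test of overall ratios between two groups.

    ``variant='welch'`` (default) does not assume equal variances —
    appropriate for unequal group sizes; ``'pooled'`` is the classical
    equal-variance Student test.  Groups are taken in sorted label
    order; the t statistic is mean(first) − mean(second).
    """
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown test variant {variant!r}")
    sub = table[(table["gene"] == gene) & table[grouping].notna()]
    labels = sorted(sub[grouping].unique())
    if len(labels) != 2:
        raise ValueError(f"grouping {grouping!r} must yield exactly 2 groups, got {labels}")
    x = sub.loc[sub[grouping] == labels[0], "overall_ratio"].to_numpy(dtype=float)
    y = sub.loc[sub[grouping] == labels[1], "overall_ratio"].to_numpy(dtype=float)
    for label, values in zip(labels, (x, y)):
        if len(values) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 samples")
        if not np.isfinite(values).all():
            raise ValueError(f"group {label!r} contains non-finite ratios")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0 and np.mean(x) != np.mean(y):
        raise ValueError("degenerate groups: zero variance with distinct means")
    res = stats.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return {
        "gene": gene,
        "grouping": grouping,
        "groups": labels,
        "n": [len(x), len(y)],
        "means": [float(np.mean(x)), float(np.mean(y))],
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "variant": variant,
    }


def group_summary(table: pd.DataFrame, grouping: str = "tissue") -> pd.DataFrame:
    """Mean/SD/n of overall ratios per (gene, group)."""
    return (
        table.groupby(["gene", grouping])["overall_ratio"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
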
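"""Differential-expression plumbing and the study's threshold filters.

The filter applied throughout the OPC study is: adjusted p <= 0.05
(significance), log2CPM >= 1 (abundance) and |log2FC| >= 0.585 (effect,
i.e. a 1.5-fold change), with all boundaries inclusive.  DE tables may come
from any external tool (edgeR-style schema: gene, log2FC, log2CPM, p,
p_adj); a simple Welch-on-log2CPM two-group test is provided so the
pipeline runs end to end on synthetic data — it is plumbing, not a
replacement for a count-model fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import CountMatrix
from .normalize import compute_cpm, log_transform

DE_COLUMNS = ("gene", "log2FC", "log2CPM", "p", "p_adj", "comparison")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Monotone in the input ranks; each adjusted value is >= its raw p and
    <= 1.  Delegates to :func:`statsmodels.stats.multitest.multipletests`.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class FilterSpec:
    """Thresholds of the DE filter; all boundaries are inclusive.

    ``alpha`` bounds the adjusted p-value, ``min_log2cpm`` floors the mean
    abundance, ``min_abs_log2fc`` floors the absolute effect size
    (0.585 ~ log2 of 1.5).
    """

    alpha: float = 0.05
    min_log2cpm: float = 1.0
    min_abs_log2fc: float = 0.585

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")
        if self.min_log2cpm < 0 or self.min_abs_log2fc < 0:
            raise ValueError("filter floors must be >= 0")


@dataclass
class GeneSetPair:
    """Up- and down-regulated gene sets surviving the filter for one comparison."""

    up: set[str]
    down: set[str]
    comparison: str

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down sets overlap")


def simple_de_test(
    counts: CountMatrix,
    group_a,
    group_b,
    comparison: str = "",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Two-group Welch test on log2CPM values (pipeline plumbing).

    Per gene: log2FC = mean log2CPM(B) - mean log2CPM(A); log2CPM = mean
    over both groups; p from a two-sided Welch t-test; p_adj by BH.  Genes
    with zero variance in both groups get p = 1 (degenerate-variance rule,
    avoids NaN propagation); their log2FC is still reported.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    missing = (set(group_a) | set(group_b)) - set(counts.samples)
    if missing:
        raise ValueError(f"unknown sample(s): {sorted(missing)[:5]}")

    logcpm = log_transform(compute_cpm(counts), pseudocount=pseudocount).values
    a = logcpm[group_a].to_numpy()
    b = logcpm[group_b].to_numpy()

    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = mean_b - mean_a
    overall = np.concatenate([a, b], axis=1).mean(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant genes trigger a precision warning; they get p = 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(b, a, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p = np.where(degenerate | np.isnan(p), 1.0, p)

    return pd.DataFrame(
        {
            "gene": counts.genes,
            "log2FC": log2fc,
            "log2CPM": overall,
            "p": p,
            "p_adj": bh_adjust(p),
            "comparison": comparison,
        }
    ).reset_index(drop=True)


def apply_filters(
    table: pd.DataFrame,
    spec: FilterSpec | None = None,
    significance_only: bool = False,
) -> GeneSetPair:
    """Split a DE table into up/down gene sets surviving the thresholds.

    A gene is up iff p_adj <= alpha, log2CPM >= min_log2cpm and
    log2FC >= min_abs_log2fc; down symmetrically with
    log2FC <= -min_abs_log2fc.  With ``significance_only`` the abundance
    and effect floors are skipped and only the adjusted-p rule is applied
    (the alternative counting mode for headline DE totals).
    """
    spec = spec or FilterSpec()
    table = table.copy()
    if "p_adj" not in table.columns or table["p_adj"].isna().all():
        table["p_adj"] = bh_adjust(table["p"].to_numpy())

    sig = table["p_adj"] <= spec.alpha
    if significance_only:
        up_mask = sig & (table["log2FC"] > 0)
        down_mask = sig & (table["log2FC"] < 0)
    else:
        abundant = table["log2CPM"] >= spec.min_log2cpm
        fc = table["log2FC"]
        thr = spec.min_abs_log2fc
        # at a zero effect floor a log2FC of exactly 0 has no direction
        up_mask = sig & abundant & ((fc >= thr) if thr > 0 else (fc > 0))
        down_mask = sig & abundant & ((fc <= -thr) if thr > 0 else (fc < 0))

    comparison = ""
    if "comparison" in table.columns and len(table):
        comparison = str(table["comparison"].iloc[0])
    return GeneSetPair(
        up=set(table.loc[up_mask, "gene"]),
        down=set(table.loc[down_mask, "gene"]),
        comparison=comparison,
    )


def run_all_comparisons(
    counts: CountMatrix, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Built-in DE tables for the four OPC comparisons, concatenated."""
    meta = counts.metadata
    opc = meta[meta.cell_type == "OPC"]

    def grp(genotype: str, condition: str) -> list[str]:
        sel = opc[(opc.genotype == genotype) & (opc.condition == condition)]
        return sel.index.tolist()

    layout = {
        "KO-NS vs WT-NS": (grp("WT", "NS"), grp("KO", "NS")),
        "WT-St vs WT-NS": (grp("WT", "NS"), grp("WT", "St")),
        "KO-St vs KO-NS": (grp("KO", "NS"), grp("KO", "St")),
        "KO-St vs WT-St": (grp("WT", "St"), grp("KO", "St")),
    }
    tables = [
        simple_de_test(counts, a, b, comparison=name, pseudocount=pseudocount)
        for name, (a, b) in layout.items()
    ]
    return pd.concat(tables, ignore_index=True)
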
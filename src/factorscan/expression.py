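"""Consortium-style differential expression across rodent SE models.

The input is a log2 expression matrix (genes x samples) plus sample metadata
(model/lab, condition in {control, case}, timepoint). Samples are first
collapsed to one column per (model, condition, timepoint) by the per-gene
median, so each model/lab contributes a single value and no laboratory can
dominate the contrast. Per timepoint, an unpaired equal-variance t-test
compares the control and case model-median columns gene-by-gene; p-values are
BH-corrected over all genes; and a gene is called directional only when its
FDR clears the cutoff AND its log2 fold change lies more than ``sd_mult``
standard deviations from that day's mean fold change, in the matching tail.

Persistence of DEG lists across days is quantified by Fisher's exact test on
the 2x2 overlap table against the expressed-gene background; the headline
odds ratio is the conditional maximum-likelihood estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

from ._util import (
    bh_adjust,
    complete_linkage,
    leaf_order,
    linkage_to_newick,
    uncentered_distance_matrix,
)

logger = logging.getLogger(__name__)

META_COLUMNS = ("model", "condition", "timepoint")
CONDITIONS = ("control", "case")


def _check_meta(expr: pd.DataFrame, meta: pd.DataFrame) -> None:
    missing_cols = set(META_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata missing columns: {sorted(missing_cols)}")
    missing = meta.index.difference(expr.columns)
    if len(missing):
        raise ValueError(f"metadata samples absent from expression: {list(missing)[:5]}")
    bad = set(meta["condition"].unique()) - set(CONDITIONS)
    if bad:
        raise ValueError(f"conditions must be in {CONDITIONS}, got {sorted(bad)}")


def collapse_to_model_medians(
    expr: pd.DataFrame, meta: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One column per (model, condition, timepoint): the per-gene group median.

    Returns the collapsed matrix and a matching metadata table indexed by the
    new column names.
    """
    _check_meta(expr, meta)
    cols: dict[str, pd.Series] = {}
    rows = []
    for (model, condition, day), grp in meta.groupby(
        list(META_COLUMNS), sort=True, observed=True
    ):
        if len(grp) == 0:
            raise ValueError(f"empty sample group {(model, condition, day)}")
        name = f"{model}|{condition}|{day}"
        cols[name] = expr[grp.index].median(axis=1)
        rows.append({"column": name, "model": model, "condition": condition, "timepoint": day})
    collapsed = pd.DataFrame(cols)
    collapsed_meta = pd.DataFrame(rows).set_index("column")
    return collapsed, collapsed_meta


def call_degs(
    collapsed: pd.DataFrame,
    collapsed_meta: pd.DataFrame,
    day,
    sd_mult: float = 2.0,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Per-gene DEG table for one timepoint.

    Columns: log2_fold_change (mean of case model-medians minus mean of
    control model-medians), p (Student t, two-sided), fdr (BH over all genes),
    direction in {up, down, none}. The +/- ``sd_mult``*SD fold-change envelope
    is computed from this day's fold-change distribution over all genes.
    """
    day_meta = collapsed_meta[collapsed_meta["timepoint"] == day]
    ctrl = day_meta[day_meta["condition"] == "control"].index
    case = day_meta[day_meta["condition"] == "case"].index
    if len(ctrl) < 2 or len(case) < 2:
        raise ValueError(
            f"need >= 2 control and >= 2 case model columns for day {day!r}, "
            f"got {len(ctrl)} and {len(case)}"
        )
    a = collapsed[case].to_numpy(dtype=float)
    b = collapsed[ctrl].to_numpy(dtype=float)
    fc = a.mean(axis=1) - b.mean(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    if degenerate.any():
        logger.warning(
            "%d gene(s) with zero variance in both groups: p set to 1", int(degenerate.sum())
        )
        p = np.where(degenerate, 1.0, p)
    fdr = bh_adjust(p)

    mu, sd = float(fc.mean()), float(fc.std(ddof=1))
    up = (fdr < fdr_cut) & (fc > mu + sd_mult * sd)
    down = (fdr < fdr_cut) & (fc < mu - sd_mult * sd)
    direction = np.where(up, "up", np.where(down, "down", "none"))
    return pd.DataFrame(
        {"log2_fold_change": fc, "p": p, "fdr": fdr, "direction": direction},
        index=collapsed.index.rename("gene"),
    )


@dataclass(frozen=True)
class OverlapResult:
    """Fisher 2x2 overlap of two gene lists on a common background."""

    a: int  # |A and B|
    b: int  # |A only|
    c: int  # |B only|
    d: int  # neither
    odds_ratio: float  # conditional MLE
    sample_odds_ratio: float
    p: float


def overlap_test(list_a, list_b, background) -> OverlapResult:
    """Two-sided Fisher's exact test for the overlap of two gene sets."""
    bg = set(background)
    sa, sb = set(list_a), set(list_b)
    stray = (sa | sb) - bg
    if stray:
        raise ValueError(
            f"{len(stray)} gene(s) not in background, e.g. {sorted(stray)[:5]}"
        )
    a = len(sa & sb)
    b = len(sa - sb)
    c = len(sb - sa)
    d = len(bg) - a - b - c
    table = [[a, b], [c, d]]
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    cmle = float(_odds_ratio(table).statistic)
    sample = (a * d) / (b * c) if b * c > 0 else float("inf") if a * d > 0 else 0.0
    return OverlapResult(a=a, b=b, c=c, d=d, odds_ratio=cmle, sample_odds_ratio=sample, p=p)


@dataclass(frozen=True)
class SampleClustering:
    labels: list[str]
    linkage: np.ndarray
    leaf_order: list[str]
    newick: str
    heatmap: pd.DataFrame  # genes x samples, sample columns in leaf order


def cluster_samples(expr: pd.DataFrame, genes) -> SampleClustering:
    """Hierarchically cluster samples on a gene subset.

    Distance is 1 - uncentered Pearson correlation; linkage is complete.
    """
    genes = list(genes)
    missing = set(genes) - set(expr.index)
    if missing:
        raise ValueError(f"genes absent from matrix: {sorted(missing)[:5]}")
    if expr.shape[1] < 2:
        raise ValueError("need >= 2 samples to cluster")
    sub = expr.loc[genes]
    dist = uncentered_distance_matrix(sub)
    z = complete_linkage(dist)
    labels = [str(c) for c in sub.columns]
    order = leaf_order(z, labels)
    return SampleClustering(
        labels=labels,
        linkage=z,
        leaf_order=order,
        newick=linkage_to_newick(z, labels),
        heatmap=sub[order],
    )
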
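"""Leading-edge target genes per factor and co-targeting factor groups.

A factor's targets are the query genes whose ChIP signal is strictly greater
than c*, the Kolmogorov-Smirnov argument of the background/query CDF gap —
the analogue of GSEA's leading edge. Pairwise Fisher tests on target lists
(universe = the query list) quantify co-targeting; cells with odds ratio <= 1
or p >= 0.05 are masked to 0 (shown white on heatmaps), and factors are
grouped by complete-linkage clustering of the masked -log10(p) rows at a
Pearson-distance cut (default 0.7, i.e. correlation > 0.3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import complete_linkage, leaf_order, pearson_distance_matrix
from .enrichment import EnrichmentCurves, empirical_cdfs, run_factor_analysis, triage
from .expression import overlap_test


@dataclass(frozen=True)
class TargetSet:
    factor: str
    genes: tuple[str, ...]


def leading_edge_targets(
    curves: EnrichmentCurves, query_signals: pd.Series, factor: str = ""
) -> TargetSet:
    """Query genes with ChIP signal strictly greater than c*.

    ``query_signals`` maps query gene -> that factor's signal. The set may be
    empty. Gene order follows the input.
    """
    genes = tuple(str(g) for g, v in query_signals.items() if v > curves.c_star)
    return TargetSet(factor=factor, genes=genes)


def target_sets_for_analysis(
    matrix: pd.DataFrame, query, background, analysis: pd.DataFrame | None = None
) -> dict[str, TargetSet]:
    """Leading-edge targets for every factor that survives triage."""
    if analysis is None:
        analysis = run_factor_analysis(matrix, query, background)
    query = list(dict.fromkeys(query))
    background = list(dict.fromkeys(background))
    out: dict[str, TargetSet] = {}
    for factor in analysis.index[~analysis["triaged"]]:
        b_vals = matrix.loc[background, factor].to_numpy(dtype=float)
        q_sig = matrix.loc[query, factor]
        curves = empirical_cdfs(b_vals, q_sig.to_numpy(dtype=float))
        if triage(curves):
            out[str(factor)] = leading_edge_targets(curves, q_sig, factor=str(factor))
    return out


@dataclass(frozen=True)
class FactorGroupMap:
    factors: list[str]
    neg_log10_p: pd.DataFrame  # masked: 0 where OR <= 1 or p >= 0.05
    p_values: pd.DataFrame
    odds_ratios: pd.DataFrame


def pairwise_overlap_map(
    target_sets: dict[str, TargetSet] | list[TargetSet], universe
) -> FactorGroupMap:
    """Symmetric -log10(p) matrix of pairwise target-list overlaps.

    Fisher's exact test on the 2x2 table over the query-list universe; cells
    with odds ratio <= 1 or p >= 0.05 carry 0 (displayed white).
    """
    if isinstance(target_sets, dict):
        sets = {name: set(ts.genes) for name, ts in target_sets.items()}
    else:
        sets = {ts.factor: set(ts.genes) for ts in target_sets}
    if len(sets) < 2:
        raise ValueError("need >= 2 target sets")
    uni = set(universe)
    for name, genes in sets.items():
        stray = genes - uni
        if stray:
            raise ValueError(f"target set {name!r} not within universe: {sorted(stray)[:5]}")
    factors = list(sets)
    k = len(factors)
    neg = np.zeros((k, k))
    pv = np.ones((k, k))
    orr = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            res = overlap_test(sets[factors[i]], sets[factors[j]], uni)
            pv[i, j] = pv[j, i] = res.p
            orr[i, j] = orr[j, i] = res.odds_ratio
            if res.odds_ratio > 1.0 and res.p < 0.05:
                neg[i, j] = neg[j, i] = -np.log10(res.p)
    idx = pd.Index(factors, name="factor")
    return FactorGroupMap(
        factors=factors,
        neg_log10_p=pd.DataFrame(neg, index=idx, columns=factors),
        p_values=pd.DataFrame(pv, index=idx, columns=factors),
        odds_ratios=pd.DataFrame(orr, index=idx, columns=factors),
    )


@dataclass(frozen=True)
class FactorGroups:
    groups: list[list[str]]  # sorted largest-first, members in input order
    linkage: np.ndarray
    leaf_order: list[str]


def group_factors(group_map: FactorGroupMap, cut: float = 0.7) -> FactorGroups:
    """Group factors whose rows of the overlap map sit within a Pearson distance.

    Complete-linkage clustering on 1 - Pearson correlation between rows of the
    masked -log10(p) matrix; factors join a group only when their merge height
    is strictly below ``cut``. Constant (zero-variance) rows have undefined
    correlation and come out as singletons.
    """
    m = group_map.neg_log10_p.to_numpy(dtype=float)
    factors = group_map.factors
    dist = pearson_distance_matrix(m)
    z = complete_linkage(dist)
    from scipy.cluster.hierarchy import fcluster

    # fcluster merges at height <= t; the grouping rule is strict (< cut)
    t = np.nextafter(cut, -np.inf)
    flat = fcluster(z, t=t, criterion="distance") if cut > 0 else np.arange(1, len(factors) + 1)
    by_id: dict[int, list[str]] = {}
    for name, gid in zip(factors, flat):
        by_id.setdefault(int(gid), []).append(name)
    groups = sorted(by_id.values(), key=lambda g: (-len(g), g))
    return FactorGroups(groups=groups, linkage=z, leaf_order=leaf_order(z, factors))


def write_target_lists(target_sets: dict[str, TargetSet], path) -> None:
    """Plain-text dump: one block per factor, one gene per line."""
    with open(path, "w") as fh:
        for name in sorted(target_sets):
            fh.write(f">{name}\n")
            for g in target_sets[name].genes:
                fh.write(f"{g}\n")
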
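"""The factor-enrichment screen.

For each factor the background genes' ChIP signals define an empirical CDF
B(c); the query genes (a subset of the background) define Q(c). A factor whose
query distribution is right-shifted has B(c) above Q(c); the screen measures
the shift by the supremum D_S and infimum D_I of B(c) - Q(c). Left-shifted
factors (|D_S| <= |D_I|) are triaged. Surviving factors get a one-tailed
Mann-Whitney-Wilcoxon p-value (query ranks greater), BH correction across
surviving factors, a tail ratio r = mu_q / mu_b comparing the means of the top
n = 0.05 * X signals of query and background, and a final score

    S = -log10(P_corr) * r

by which factors are ranked. The threshold c* attaining D_S is the
Kolmogorov-Smirnov argument; it later defines each factor's leading-edge
target genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from ._util import bh_adjust

logger = logging.getLogger(__name__)

#: switch from exact subset enumeration to the normal approximation when the
#: number of query-sized subsets of the background exceeds this
EXACT_ENUMERATION_LIMIT = 20_000


@dataclass(frozen=True)
class EnrichmentCurves:
    """Paired empirical CDFs of background and query ChIP signals."""

    grid: np.ndarray  # sorted unique observed signals
    b_cdf: np.ndarray  # B(c) on the grid
    q_cdf: np.ndarray  # Q(c) on the grid
    d_sup: float  # sup_c B(c) - Q(c)
    d_inf: float  # inf_c B(c) - Q(c)
    c_star: float  # smallest c attaining d_sup


def empirical_cdfs(background_values, query_values) -> EnrichmentCurves:
    """Step CDFs and their extreme differences on the observed-value grid.

    Both CDFs are right-continuous step functions evaluated at the sorted
    union of observed values; D_S, D_I and c* are exact over that grid (the
    difference is constant between observed values, so the grid suffices).
    """
    b = np.sort(np.asarray(background_values, dtype=float))
    q = np.sort(np.asarray(query_values, dtype=float))
    if b.size == 0 or q.size == 0:
        raise ValueError("background and query must be non-empty")
    grid = np.unique(np.concatenate([b, q]))
    b_cdf = np.searchsorted(b, grid, side="right") / b.size
    q_cdf = np.searchsorted(q, grid, side="right") / q.size
    diff = b_cdf - q_cdf
    i = int(np.argmax(diff))
    return EnrichmentCurves(
        grid=grid,
        b_cdf=b_cdf,
        q_cdf=q_cdf,
        d_sup=float(diff[i]),
        d_inf=float(diff.min()),
        c_star=float(grid[i]),
    )


def triage(curves: EnrichmentCurves) -> bool:
    """True = keep the factor (query right-shifted: |D_S| > |D_I|).

    Ties, including the flat case D_S = D_I = 0, are discarded.
    """
    return abs(curves.d_sup) > abs(curves.d_inf)


def _rank_weights(background: np.ndarray) -> np.ndarray:
    """w(v) = #{b < v} + 0.5 #{b == v}; U of any sub-multiset is sum of w."""
    b = np.sort(background)
    lo = np.searchsorted(b, background, side="left")
    hi = np.searchsorted(b, background, side="right")
    return lo + 0.5 * (hi - lo)


def _is_submultiset(query: np.ndarray, background: np.ndarray) -> bool:
    qv, qc = np.unique(query, return_counts=True)
    bv, bc = np.unique(background, return_counts=True)
    pos = np.searchsorted(bv, qv)
    if np.any(pos >= bv.size) or np.any(bv[np.minimum(pos, bv.size - 1)] != qv):
        return False
    return bool(np.all(bc[pos] >= qc))


def mww_one_tailed(background_values, query_values) -> float:
    """One-tailed MWW p that the query signals rank above the background.

    The query is drawn from within the background (Q is a subset of B), so for
    small problems the exact null enumerates every query-sized subset of the
    background and counts subsets whose rank-sum statistic meets or exceeds
    the observed one. Larger problems use the normal approximation with
    midranks, tie correction and continuity correction.
    """
    b = np.asarray(background_values, dtype=float)
    q = np.asarray(query_values, dtype=float)
    if b.size == 0 or q.size == 0:
        raise ValueError("background and query must be non-empty")
    if np.unique(np.concatenate([b, q])).size == 1:
        logger.warning("all ChIP values tied; MWW p set to 0.5")
        return 0.5
    n_subsets = comb(b.size, q.size) if q.size < b.size else None
    if (
        n_subsets is not None
        and n_subsets <= EXACT_ENUMERATION_LIMIT
        and _is_submultiset(q, b)
    ):
        w = _rank_weights(b)
        # observed U: weights of the query values against the full background
        bs = np.sort(b)
        lo = np.searchsorted(bs, q, side="left")
        hi = np.searchsorted(bs, q, side="right")
        u_obs = float(np.sum(lo + 0.5 * (hi - lo)))
        hits = sum(
            1
            for idx in combinations(range(b.size), q.size)
            if w[list(idx)].sum() >= u_obs - 1e-9
        )
        return hits / n_subsets
    return float(
        stats.mannwhitneyu(q, b, alternative="greater", method="asymptotic").pvalue
    )


def tail_ratio(
    background_values, query_values, frac: float = 0.05
) -> tuple[int, float, float, float]:
    """(n, mu_q, mu_b, r): compare the top-n signal means of query vs background.

    n = max(1, round(frac * X)) where X is the query length, so short lists
    still have a defined tail.
    """
    b = np.asarray(background_values, dtype=float)
    q = np.asarray(query_values, dtype=float)
    if q.size < 1:
        raise ValueError("empty query")
    n = max(1, int(np.floor(frac * q.size + 0.5)))
    if n > b.size:
        raise ValueError(f"tail size {n} exceeds background size {b.size}")
    u_q = float(np.mean(np.sort(q)[-n:]))
    u_b = float(np.mean(np.sort(b)[-n:]))
    if u_b == 0.0:
        raise ValueError("top background signals are all zero; compendium degenerate")
    return n, u_q, u_b, u_q / u_b


def score(p_corr: float, r: float, log_base: float = 10.0) -> float:
    """S = -log(P_corr) * r with the given logarithm base."""
    return float(-np.log(p_corr) / np.log(log_base) * r)


def run_factor_analysis(
    matrix: pd.DataFrame,
    query,
    background,
    tail_frac: float = 0.05,
    log_base: float = 10.0,
) -> pd.DataFrame:
    """Score every factor for preferential binding of the query genes.

    Per factor: empirical CDFs -> triage -> one-tailed MWW -> tail ratio.
    BH correction runs across non-triaged factors only; the result is sorted
    by score descending with triaged factors listed last (NaN statistics).
    Columns mirror the screen's summary tables: c_star, u_q, u_b, tail_ratio,
    p_raw, p_corr, score, triaged.
    """
    query = list(dict.fromkeys(query))
    background = list(dict.fromkeys(background))
    bg_set = set(background)
    stray_q = [g for g in query if g not in bg_set]
    if stray_q:
        raise ValueError(f"query genes not in background: {stray_q[:5]}")
    stray_b = set(background) - set(matrix.index)
    if stray_b:
        raise ValueError(f"background genes not in matrix: {sorted(stray_b)[:5]}")

    sub = matrix.loc[background]
    rows = []
    for factor in matrix.columns:
        b_vals = sub[factor].to_numpy(dtype=float)
        q_vals = sub.loc[query, factor].to_numpy(dtype=float)
        curves = empirical_cdfs(b_vals, q_vals)
        keep = triage(curves)
        row = {
            "factor": factor,
            "d_sup": curves.d_sup,
            "d_inf": curves.d_inf,
            "c_star": curves.c_star,
            "triaged": not keep,
            "n_tail": np.nan,
            "u_q": np.nan,
            "u_b": np.nan,
            "tail_ratio": np.nan,
            "p_raw": np.nan,
            "p_corr": np.nan,
            "score": np.nan,
        }
        if keep:
            n, u_q, u_b, r = tail_ratio(b_vals, q_vals, frac=tail_frac)
            row.update(
                n_tail=n,
                u_q=u_q,
                u_b=u_b,
                tail_ratio=r,
                p_raw=mww_one_tailed(b_vals, q_vals),
            )
        rows.append(row)
    table = pd.DataFrame(rows).set_index("factor")

    kept = table.index[~table["triaged"]]
    if len(kept):
        table.loc[kept, "p_corr"] = bh_adjust(table.loc[kept, "p_raw"].to_numpy())
        table.loc[kept, "score"] = [
            score(pc, r, log_base=log_base)
            for pc, r in zip(table.loc[kept, "p_corr"], table.loc[kept, "tail_ratio"])
        ]
    return table.sort_values(
        ["triaged", "score"], ascending=[True, False], kind="mergesort"
    )
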
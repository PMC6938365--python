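"""Human-cohort workflow: probe filtering, k-medians co-expression modules,
per-module factor screening and cross-cohort module expression tests.

The cohort arrives as a probe x sample expression matrix with a matching
detection p-value matrix (Illumina-style). Probes detected (p < 0.05) in at
least 20% of samples are kept, collapsed to gene symbols by the median probe
value, each sample is divided by its median so columns weigh equally, and
genes more variable than the cohort's median coefficient of variation are
retained. k-medians (L1 distance, per-dimension median centers) partitions
the retained genes into co-expression modules; each module then serves as a
query list for the factor screen against all retained genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import complete_linkage, leaf_order, pearson_distance_matrix
from .enrichment import run_factor_analysis

logger = logging.getLogger(__name__)


def preprocess_cohort(
    expr: pd.DataFrame,
    detection_p: pd.DataFrame,
    symbols: pd.Series,
    detect_cut: float = 0.05,
    frac: float = 0.2,
    variability: str = "cv",
) -> pd.DataFrame:
    """Filter, collapse and normalize a probe-level cohort to a gene matrix.

    Steps: keep probes with detection p < ``detect_cut`` in >= ``frac`` of
    samples; collapse probes to symbols by the per-sample median; divide each
    sample by its median; keep genes whose coefficient of variation exceeds
    the cohort's median CV (``variability='variance'`` switches the last step
    to variance vs median variance).
    """
    if not expr.index.equals(detection_p.index) or not expr.columns.equals(
        detection_p.columns
    ):
        raise ValueError("expression and detection matrices are not aligned")
    if variability not in ("cv", "variance"):
        raise ValueError("variability must be 'cv' or 'variance'")
    detected = (detection_p < detect_cut).mean(axis=1) >= frac
    kept = expr.loc[detected]
    logger.info("%d/%d probes pass detection filter", int(detected.sum()), len(expr))
    if kept.empty:
        raise ValueError("no probes pass the detection filter")
    by_gene = kept.groupby(symbols.loc[kept.index].rename("gene")).median()

    medians = by_gene.median(axis=0)
    if (medians == 0).any():
        bad = medians.index[medians == 0].tolist()
        raise ValueError(f"sample(s) with zero median expression: {bad[:5]}")
    norm = by_gene / medians

    if variability == "cv":
        spread = norm.std(axis=1, ddof=1) / norm.mean(axis=1).abs()
    else:
        spread = norm.var(axis=1, ddof=1)
    keep_genes = spread > spread.median()
    out = norm.loc[keep_genes]
    logger.info("%d/%d genes pass variability filter", len(out), len(norm))
    return out


@dataclass(frozen=True)
class ModuleAssignment:
    k: int
    labels: pd.Series  # gene -> module id in 1..k
    centers: pd.DataFrame  # k x samples, index = module id
    cost: float  # total L1 distance to assigned centers
    cost_history: tuple[float, ...]  # best restart, per iteration

    def module_genes(self, module_id: int) -> list[str]:
        return self.labels.index[self.labels == module_id].tolist()


def _l1_to_centers(x: np.ndarray, centers: np.ndarray) -> np.ndarray:
    # genes x k; chunk over centers to bound memory
    return np.stack([np.abs(x - c).sum(axis=1) for c in centers], axis=1)


def _kmedians_once(x: np.ndarray, k: int, rng: np.random.Generator, max_iter: int):
    n = x.shape[0]
    # k-means++-style seeding under L1
    centers = np.empty((k, x.shape[1]))
    centers[0] = x[rng.integers(n)]
    d = np.abs(x - centers[0]).sum(axis=1)
    for j in range(1, k):
        probs = d / d.sum() if d.sum() > 0 else np.full(n, 1.0 / n)
        centers[j] = x[rng.choice(n, p=probs)]
        d = np.minimum(d, np.abs(x - centers[j]).sum(axis=1))
    labels = np.full(n, -1)
    history: list[float] = []
    for _ in range(max_iter):
        dist = _l1_to_centers(x, centers)
        new_labels = dist.argmin(axis=1)
        # re-seed empty clusters from the worst-fit gene
        for j in range(k):
            if not np.any(new_labels == j):
                worst = int(dist[np.arange(n), new_labels].argmax())
                centers[j] = x[worst]
                dist[:, j] = np.abs(x - centers[j]).sum(axis=1)
                new_labels = dist.argmin(axis=1)
        cost = float(dist[np.arange(n), new_labels].sum())
        history.append(cost)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            centers[j] = np.median(x[labels == j], axis=0)
    return labels, centers, history


def kmedians(
    expr: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    restarts: int = 20,
    max_iter: int = 100,
) -> ModuleAssignment:
    """Partition genes (rows) into k modules by L1 k-medians.

    Assignment to the nearest center in L1, centers updated to per-dimension
    medians, iterated to convergence; the best of ``restarts`` seeded runs by
    total L1 cost is returned. Empty clusters are re-seeded from the gene
    worst fit by its current center. Deterministic for a fixed seed.
    """
    if k <= 0 or k > expr.shape[0]:
        raise ValueError(f"k must be in [1, {expr.shape[0]}], got {k}")
    x = expr.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(restarts):
        labels, centers, history = _kmedians_once(x, k, rng, max_iter)
        if best is None or history[-1] < best[2][-1]:
            best = (labels, centers, history)
    labels, centers, history = best
    return ModuleAssignment(
        k=k,
        labels=pd.Series(labels + 1, index=expr.index, name="module"),
        centers=pd.DataFrame(
            centers, index=pd.RangeIndex(1, k + 1, name="module"), columns=expr.columns
        ),
        cost=history[-1],
        cost_history=tuple(history),
    )


def module_factor_screen(
    matrix: pd.DataFrame,
    assignment: ModuleAssignment,
    background,
    min_size: int = 5,
    tail_frac: float = 0.05,
    log_base: float = 10.0,
) -> dict[int, pd.DataFrame]:
    """Run the factor screen with each module as the query list.

    Modules smaller than ``min_size`` genes are skipped with a warning.
    """
    out: dict[int, pd.DataFrame] = {}
    for module_id in range(1, assignment.k + 1):
        genes = assignment.module_genes(module_id)
        if len(genes) < min_size:
            warnings.warn(
                f"module {module_id} has {len(genes)} gene(s) (< {min_size}); skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        out[module_id] = run_factor_analysis(
            matrix, genes, background, tail_frac=tail_frac, log_base=log_base
        )
    return out


@dataclass(frozen=True)
class FactorPresenceMatrix:
    matrix: pd.DataFrame  # factors x gene lists, values in {0, 1}
    linkage: np.ndarray  # over columns
    column_order: list[str]


def factor_presence_clustering(
    fdr_tables: dict[str, pd.Series], fdr_cut: float = 0.05
) -> FactorPresenceMatrix:
    """Binarize per-list factor FDRs at 5% and cluster the gene-list columns.

    ``fdr_tables`` maps gene-list name -> Series of factor FDRs (triaged or
    missing factors count as not significant). Columns are clustered by
    1 - Pearson correlation with complete linkage; constant columns get the
    maximal distance to every other column and fall out as singletons.
    """
    if len(fdr_tables) < 2:
        raise ValueError("need >= 2 gene lists")
    factors = sorted(set().union(*(set(s.index) for s in fdr_tables.values())))
    cols = {}
    for name, fdrs in fdr_tables.items():
        aligned = fdrs.reindex(factors).fillna(1.0)
        cols[name] = (aligned < fdr_cut).astype(int)
    binary = pd.DataFrame(cols, index=pd.Index(factors, name="factor"))
    dist = pearson_distance_matrix(binary.to_numpy(dtype=float).T)
    z = complete_linkage(dist)
    names = list(binary.columns)
    return FactorPresenceMatrix(
        matrix=binary, linkage=z, column_order=leaf_order(z, names)
    )


@dataclass(frozen=True)
class ModuleExpressionTest:
    direction: str  # 'higher_in_a' | 'higher_in_b' | 'none'
    p: float
    n_genes: int
    median_difference: float  # median over genes of mean_a - mean_b


def module_expression_test(
    module_genes, cohort_a: pd.DataFrame, cohort_b: pd.DataFrame
) -> ModuleExpressionTest:
    """Compare a module's average expression between two cohorts.

    Per gene, the mean across each cohort's samples; the two per-gene mean
    vectors are compared with a two-sided Mann-Whitney test. Only genes
    present in both cohorts are used (dropped genes logged). Direction is the
    sign of the median paired difference.
    """
    genes = [g for g in dict.fromkeys(module_genes)]
    shared = [g for g in genes if g in cohort_a.index and g in cohort_b.index]
    if not shared:
        raise ValueError("no module genes shared between the cohorts")
    if len(shared) < len(genes):
        logger.info(
            "%d/%d module genes absent from one cohort; using %d shared genes",
            len(genes) - len(shared),
            len(genes),
            len(shared),
        )
    a = cohort_a.loc[shared].mean(axis=1).to_numpy(dtype=float)
    b = cohort_b.loc[shared].mean(axis=1).to_numpy(dtype=float)
    if np.allclose(a, b, rtol=1e-9, atol=1e-12):
        p, diff = 1.0, 0.0
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        diff = float(np.median(a - b))
    direction = "none" if diff == 0 else ("higher_in_a" if diff > 0 else "higher_in_b")
    return ModuleExpressionTest(
        direction=direction, p=p, n_genes=len(shared), median_difference=diff
    )
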
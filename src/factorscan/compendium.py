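"""Build the gene x factor ChIP-signal matrix from a narrowPeak compendium.

Each transcription factor or cofactor ("factor") is profiled by ChIP-seq in one
or more cell types. A gene domain is the gene body extended 5 kb on each side;
every factor is assigned, per gene, the single highest peak signalValue seen in
any cell type overlapping that domain. Columns are then rescaled so each
factor's signal sums to 100,000, making tail statistics comparable across
factors with different library depths and peak counts.

Coordinates follow the BED convention throughout: 0-based, half-open; overlap
means an intersection of at least 1 bp.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

COLUMN_SUM = 100_000.0


class Peak(NamedTuple):
    chrom: str
    start: int
    end: int
    signal_value: float


class GeneDomain(NamedTuple):
    symbol: str
    chrom: str
    start: int
    end: int


def read_narrowpeak(path) -> list[Peak]:
    """Parse a narrowPeak (BED6+4) file into peaks.

    Only chrom/start/end and column 7 (signalValue) are used; the remaining
    columns are ignored. Raises ``ValueError`` naming the line on malformed
    input (< 7 columns, non-numeric coordinates or signal).
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 7 tab-separated narrowPeak "
                    f"columns, got {len(fields)}"
                )
            try:
                start = int(fields[1])
                end = int(fields[2])
                signal = float(fields[6])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric coordinate or signalValue"
                ) from exc
            if start >= end:
                raise ValueError(f"{path}: line {lineno}: start >= end")
            if signal < 0:
                raise ValueError(f"{path}: line {lineno}: negative signalValue")
            peaks.append(Peak(fields[0], start, end, signal))
    return peaks


def read_annotation_bed(path) -> pd.DataFrame:
    """Read a BED-like gene annotation: chrom, start, end, symbol[, score, strand]."""
    table = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "symbol"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "symbol": str},
    )
    return table


def build_gene_domains(annotation: pd.DataFrame, flank: int = 5000) -> list[GeneDomain]:
    """Flank every gene body by ``flank`` bp on each side, clamping at 0.

    Records sharing a symbol are merged to the union span before flanking, so
    each symbol yields exactly one domain. Domains are returned in first-seen
    symbol order.
    """
    required = {"chrom", "start", "end", "symbol"}
    missing = required - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    bad = annotation[annotation["start"] >= annotation["end"]]
    if len(bad):
        raise ValueError(
            f"annotation has {len(bad)} record(s) with start >= end "
            f"(first: {bad.iloc[0]['symbol']})"
        )
    domains: list[GeneDomain] = []
    for symbol, grp in annotation.groupby("symbol", sort=False):
        chroms = grp["chrom"].unique()
        if len(chroms) > 1:
            raise ValueError(
                f"symbol {symbol!r} annotated on multiple chromosomes: {list(chroms)}"
            )
        start = max(0, int(grp["start"].min()) - flank)
        end = int(grp["end"].max()) + flank
        domains.append(GeneDomain(str(symbol), str(chroms[0]), start, end))
    return domains


PeaksBySource = Mapping[str, Mapping[str, Iterable[Peak]]]


def assign_chip_values(
    peaks_by_source: PeaksBySource, domains: list[GeneDomain]
) -> pd.DataFrame:
    """Per gene and factor, the maximum signalValue over all overlapping peaks.

    ``peaks_by_source`` maps factor -> cell type -> peaks; any cell type may
    contribute the maximum. Genes with no overlapping peak get 0. Peaks on
    chromosomes absent from the annotation are ignored (count logged).
    Returns the unnormalized gene x factor matrix.
    """
    if not domains:
        raise ValueError("no gene domains")
    if not peaks_by_source:
        raise ValueError("no peak sources")
    trees: dict[str, IntervalTree] = {}
    for idx, dom in enumerate(domains):
        trees.setdefault(dom.chrom, IntervalTree()).addi(dom.start, dom.end, idx)

    genes = [d.symbol for d in domains]
    factors = sorted(peaks_by_source)
    values = np.zeros((len(genes), len(factors)), dtype=float)
    skipped = 0
    for j, factor in enumerate(factors):
        cell_types = peaks_by_source[factor]
        if not cell_types:
            raise ValueError(f"factor {factor!r} has no peak files")
        col = values[:, j]
        for peaks in cell_types.values():
            for pk in peaks:
                tree = trees.get(pk.chrom)
                if tree is None:
                    skipped += 1
                    continue
                for hit in tree.overlap(pk.start, pk.end):
                    i = hit.data
                    if pk.signal_value > col[i]:
                        col[i] = pk.signal_value
    if skipped:
        logger.warning(
            "ignored %d peak(s) on chromosomes absent from the annotation", skipped
        )
    return pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=factors)


def normalize_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Rescale each factor column to sum to 100,000.

    All-zero columns have no defined normalization and are dropped with a
    warning.
    """
    if matrix.shape[0] < 1 or matrix.shape[1] < 1:
        raise ValueError("matrix must have at least one gene and one factor")
    sums = matrix.sum(axis=0)
    zero = sums[sums == 0].index.tolist()
    if zero:
        warnings.warn(
            f"dropping {len(zero)} all-zero factor column(s): {', '.join(map(str, zero))}",
            RuntimeWarning,
            stacklevel=2,
        )
        matrix = matrix.drop(columns=zero)
        sums = sums.drop(zero)
        if matrix.shape[1] == 0:
            raise ValueError("all factor columns are zero")
    return matrix * (COLUMN_SUM / sums)


def export_top_gene_set(
    matrix: pd.DataFrame,
    factor: str,
    top_n: int,
    set_name: str | None = None,
    description: str = "",
) -> str:
    """GMT record of the ``top_n`` most highly ChIPed genes for one factor.

    Ordering is by descending signal with ties broken by symbol so the output
    is deterministic.
    """
    if factor not in matrix.columns:
        raise KeyError(
            f"unknown factor {factor!r}; available: {', '.join(map(str, matrix.columns))}"
        )
    if not 1 <= top_n <= matrix.shape[0]:
        raise ValueError(f"top_n must be in [1, {matrix.shape[0]}], got {top_n}")
    col = matrix[factor]
    order = sorted(col.index, key=lambda g: (-col[g], str(g)))
    name = set_name if set_name is not None else f"{factor}_top{top_n}"
    return "\t".join([name, description, *map(str, order[:top_n])])


def read_peaks_manifest(path) -> pd.DataFrame:
    """Read a peaks manifest TSV; relative file paths resolve against its directory."""
    manifest = pd.read_csv(path, sep="\t")
    if "file_path" in manifest.columns:
        base = Path(path).parent
        manifest["file_path"] = [
            p if Path(p).is_absolute() else str(base / p) for p in manifest["file_path"]
        ]
    return manifest


def load_compendium(
    manifest: pd.DataFrame, annotation: pd.DataFrame, flank: int = 5000
) -> pd.DataFrame:
    """Read a peaks manifest (file_path, factor, cell_type) into a normalized matrix."""
    required = {"file_path", "factor", "cell_type"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    peaks_by_source: dict[str, dict[str, list[Peak]]] = {}
    for row in manifest.itertuples(index=False):
        peaks_by_source.setdefault(str(row.factor), {}).setdefault(
            str(row.cell_type), []
        ).extend(read_narrowpeak(row.file_path))
    domains = build_gene_domains(annotation, flank=flank)
    return normalize_matrix(assign_chip_values(peaks_by_source, domains))


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")
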
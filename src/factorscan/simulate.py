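"""Fully in-silico fixtures with planted ground truth.

The generator emulates the shapes of the real inputs: a narrowPeak compendium
over a toy genome (heavy-tailed log-normal signalValues, several "cell types"
per factor), a rodent-style multi-model expression design (models x
control/case x timepoints), and a human-style cohort with probe-level
detection p-values and a planted co-expression module. One factor is planted:
its peaks over a chosen target-gene set carry signals multiplied by
``signal_scale``, and the same targets are shifted down by
``expression_effect`` log2 units in case samples — so the full pipeline
(DEG calling -> factor screen -> leading-edge targets) has a recoverable
ground truth. At ``signal_scale = 1`` the planted factor is exchangeable with
the null factors, which calibrates the screen's false-positive rate.

All randomness flows from a single seed; regeneration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .compendium import Peak, assign_chip_values, build_gene_domains, normalize_matrix

# toy genome layout: fixed-size gene bodies on a regular grid so that 5 kb
# domains never overlap and clamping at 0 is never triggered
GENES_PER_CHROM = 400
GENE_SPACING = 20_000
GENE_LENGTH = 4_000
GENE_OFFSET = 8_000  # first gene body starts here on each chromosome

SIGNAL_MEANLOG = 1.0
SIGNAL_SDLOG = 0.75
PEAK_WIDTH = 200
PEAK_RATE = 0.5  # per-cell-type probability that a gene domain carries a peak
PLANTED_PEAK_RATE = 0.6
PLANTED_CELL_TYPES = 3

BASELINE_MEAN = 8.0  # log2 scale
BASELINE_SD = 1.0
NOISE_SD = 0.5  # within-group, i.e. variance 0.25

RODENT_MODELS = ("kainate_a", "kainate_b", "pilo_a", "pilo_b", "ssse")
RODENT_TIMEPOINTS = (1, 3, 10)


@dataclass(frozen=True)
class SyntheticTruth:
    planted_factor: str
    target_genes: tuple[str, ...]
    signal_scale: float
    expression_effect: float
    seed: int


def gene_names(n_genes: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n_genes)]


def make_annotation(n_genes: int) -> pd.DataFrame:
    rows = []
    for i, g in enumerate(gene_names(n_genes)):
        chrom = f"chr{i // GENES_PER_CHROM + 1}"
        start = GENE_OFFSET + (i % GENES_PER_CHROM) * GENE_SPACING
        rows.append({"chrom": chrom, "start": start, "end": start + GENE_LENGTH, "symbol": g})
    return pd.DataFrame(rows)


def default_truth(
    seed: int,
    n_genes: int = 2000,
    n_factors: int = 20,
    n_targets: int = 100,
    signal_scale: float = 10.0,
    expression_effect: float = 2.0,
) -> SyntheticTruth:
    """Draw the planted factor and target-gene set for a seed."""
    rng = np.random.default_rng(seed)
    genes = gene_names(n_genes)
    factors = [f"TF{j + 1:02d}" for j in range(n_factors)]
    targets = tuple(sorted(rng.choice(genes, size=n_targets, replace=False)))
    planted = str(rng.choice(factors))
    return SyntheticTruth(
        planted_factor=planted,
        target_genes=targets,
        signal_scale=signal_scale,
        expression_effect=expression_effect,
        seed=seed,
    )


def generate_compendium(
    n_genes: int,
    n_factors: int,
    truth: SyntheticTruth,
    out_dir: str | Path | None = None,
):
    """Synthetic narrowPeak compendium with one planted factor.

    Per factor, 1-3 cell types each place a peak (log-normal signal) in a
    random subset of gene domains; the planted factor's peaks over target
    domains are scaled by ``truth.signal_scale`` and it always has
    ``PLANTED_CELL_TYPES`` cell types so most targets carry a peak. Returns
    ``(peaks_by_source, annotation, manifest)``; when ``out_dir`` is given,
    valid narrowPeak files, an annotation BED, a manifest TSV and the truth
    JSON are written there (byte-identical for a fixed seed).
    """
    if n_genes < 50 or n_factors < 2:
        raise ValueError("need n_genes >= 50 and n_factors >= 2")
    genes = gene_names(n_genes)
    missing = set(truth.target_genes) - set(genes)
    if missing:
        raise ValueError(f"truth targets not among generated genes: {sorted(missing)[:5]}")
    annotation = make_annotation(n_genes)
    domains = build_gene_domains(annotation)
    dom_start = np.array([d.start for d in domains])
    dom_len = np.array([d.end - d.start for d in domains])
    chroms = [d.chrom for d in domains]
    is_target = np.isin(np.array(genes), np.array(truth.target_genes))

    rng = np.random.default_rng(truth.seed)
    factors = [f"TF{j + 1:02d}" for j in range(n_factors)]
    if truth.planted_factor not in factors:
        factors[0] = truth.planted_factor
    peaks_by_source: dict[str, dict[str, list[Peak]]] = {}
    for factor in factors:
        planted = factor == truth.planted_factor
        n_cells = PLANTED_CELL_TYPES if planted else int(rng.integers(1, 4))
        rate = PLANTED_PEAK_RATE if planted else PEAK_RATE
        cells: dict[str, list[Peak]] = {}
        for c in range(n_cells):
            present = rng.random(n_genes) < rate
            offsets = rng.integers(0, dom_len - PEAK_WIDTH)
            signals = rng.lognormal(SIGNAL_MEANLOG, SIGNAL_SDLOG, n_genes)
            if planted:
                signals = np.where(is_target, signals * truth.signal_scale, signals)
            starts = dom_start + offsets
            cells[f"cell{c + 1}"] = [
                Peak(chroms[i], int(starts[i]), int(starts[i]) + PEAK_WIDTH, float(signals[i]))
                for i in np.flatnonzero(present)
            ]
        peaks_by_source[factor] = cells

    manifest = {
        "seed": truth.seed,
        "n_genes": n_genes,
        "n_factors": n_factors,
        "planted_factor": truth.planted_factor,
        "signal_scale": truth.signal_scale,
        "files": [],
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for factor, cells in peaks_by_source.items():
            for cell, peaks in cells.items():
                fname = f"{factor}_{cell}.narrowPeak"
                with open(out / fname, "w") as fh:
                    for k, pk in enumerate(peaks):
                        fh.write(
                            f"{pk.chrom}\t{pk.start}\t{pk.end}\tpeak{k}\t0\t.\t"
                            f"{pk.signal_value:.6g}\t-1\t-1\t{PEAK_WIDTH // 2}\n"
                        )
                rows.append({"file_path": fname, "factor": factor, "cell_type": cell})
                manifest["files"].append(fname)
        pd.DataFrame(rows).to_csv(out / "peaks_manifest.tsv", sep="\t", index=False)
        annotation.assign(score=0, strand="+").to_csv(
            out / "genes.bed", sep="\t", header=False, index=False
        )
        with open(out / "truth.json", "w") as fh:
            json.dump(dataclasses.asdict(truth), fh, indent=2, sort_keys=True)
        with open(out / "compendium_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return peaks_by_source, annotation, manifest


def compendium_matrix(peaks_by_source, annotation: pd.DataFrame, flank: int = 5000):
    """Normalized gene x factor matrix straight from in-memory peaks."""
    return normalize_matrix(
        assign_chip_values(peaks_by_source, build_gene_domains(annotation, flank=flank))
    )


def generate_expression(
    truth: SyntheticTruth,
    n_genes: int,
    design: str = "rodent",
    n_per_group: int = 6,
    models=RODENT_MODELS,
    timepoints=RODENT_TIMEPOINTS,
    n_samples: int = 60,
    module_amplitude: float = 1.0,
    target_shift: float = 0.0,
    out_dir: str | Path | None = None,
):
    """Synthetic expression with the planted targets down-regulated.

    ``design='rodent'`` returns ``(expr, meta)``: log2 values, one column per
    sample across models x {control, case} x timepoints; case samples carry a
    ``-expression_effect`` shift on target genes at every timepoint, noise is
    N(0, sd 0.5) around a per-gene N(8, 1) baseline.

    ``design='cohort'`` returns ``(probe_expr, detection_p, symbols, meta)``:
    a probe-level matrix in which target genes co-vary through a shared
    per-sample latent factor (amplitude ``module_amplitude``) and are shifted
    by ``target_shift``; ~10% of genes carry a second probe and half of those
    duplicates fail detection, exercising the probe filter.
    """
    genes = gene_names(n_genes)
    missing = set(truth.target_genes) - set(genes)
    if missing:
        raise ValueError(f"truth targets not among generated genes: {sorted(missing)[:5]}")
    is_target = np.isin(np.array(genes), np.array(truth.target_genes))
    rng = np.random.default_rng(truth.seed + 1)  # decouple from compendium draws
    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, n_genes)

    if design == "rodent":
        if n_per_group < 2:
            raise ValueError("need >= 2 samples per group")
        cols = {}
        meta_rows = []
        for model in models:
            for condition in ("control", "case"):
                for day in timepoints:
                    shift = (
                        -truth.expression_effect * is_target
                        if condition == "case"
                        else np.zeros(n_genes)
                    )
                    for r in range(n_per_group):
                        name = f"{model}_{condition}_d{day}_r{r + 1}"
                        cols[name] = baseline + shift + rng.normal(0, NOISE_SD, n_genes)
                        meta_rows.append(
                            {"sample_id": name, "model": model, "condition": condition, "timepoint": day}
                        )
        expr = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
        meta = pd.DataFrame(meta_rows).set_index("sample_id")
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            expr.to_csv(out / "expression.tsv", sep="\t", float_format="%.6g")
            meta.to_csv(out / "sample_metadata.tsv", sep="\t")
        return expr, meta

    if design == "cohort":
        if n_samples < 2:
            raise ValueError("need >= 2 cohort samples")
        latent = rng.normal(0.0, 1.0, n_samples)
        values = (
            baseline[:, None]
            + rng.normal(0, NOISE_SD, (n_genes, n_samples))
            + np.outer(is_target * module_amplitude, latent)
            + (is_target * target_shift)[:, None]
        )
        samples = [f"S{i + 1:03d}" for i in range(n_samples)]
        gene_expr = pd.DataFrame(values, index=genes, columns=samples)

        dup = rng.random(n_genes) < 0.10  # genes with a second probe
        probe_rows = [(f"{g}_p1", g, True) for g in genes]
        for i in np.flatnonzero(dup):
            detected = bool(rng.random() < 0.5)
            probe_rows.append((f"{genes[i]}_p2", genes[i], detected))
        probe_ids = [p for p, _, _ in probe_rows]
        symbols = pd.Series([g for _, g, _ in probe_rows], index=probe_ids, name="symbol")
        probe_expr = pd.DataFrame(
            gene_expr.loc[[g for _, g, _ in probe_rows]].to_numpy()
            + rng.normal(0, 0.05, (len(probe_rows), n_samples)),
            index=pd.Index(probe_ids, name="probe"),
            columns=samples,
        )
        det = np.empty((len(probe_rows), n_samples))
        for i, (_, _, detected) in enumerate(probe_rows):
            det[i] = (
                rng.uniform(0.0, 0.04, n_samples)
                if detected
                else rng.uniform(0.06, 1.0, n_samples)
            )
        detection_p = pd.DataFrame(det, index=probe_expr.index, columns=samples)
        meta = pd.DataFrame({"sample_id": samples}).set_index("sample_id")
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            probe_expr.to_csv(out / "cohort_expression.tsv", sep="\t", float_format="%.6g")
            detection_p.to_csv(out / "cohort_detection_p.tsv", sep="\t", float_format="%.6g")
            symbols.to_frame().to_csv(out / "cohort_probe_symbols.tsv", sep="\t")
        return probe_expr, detection_p, symbols, meta

    raise ValueError(f"unknown design {design!r}")
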
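"""One-shot pipeline: compendium matrix -> DEGs -> persistence -> factor screen
-> leading-edge targets, with a config that round-trips to JSON and a manifest
recording seeds and output checksums."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from ._util import sha256_of
from .compendium import load_compendium, read_annotation_bed, read_peaks_manifest, write_matrix
from .expression import call_degs, collapse_to_model_medians, overlap_test
from .targets import (
    group_factors,
    pairwise_overlap_map,
    target_sets_for_analysis,
    write_target_lists,
)
from .enrichment import run_factor_analysis

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class RunConfig:
    peaks_manifest: str
    annotation: str
    expr: str
    meta: str
    out_dir: str
    background: str | None = None  # gene-list file; default: genes in expr & matrix
    fdr_cut: float = 0.05
    sd_mult: float = 2.0
    flank: int = 5000
    tail_frac: float = 0.05
    distance_cut: float = 0.7
    k: int = 10
    log_base: float = 10.0
    seed: int = 0

    def __post_init__(self):
        for name in ("fdr_cut", "sd_mult", "flank", "tail_frac", "distance_cut", "k", "log_base"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _stage(name: str, detail: str):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: %s", name, detail)

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage {name!r} failed ({detail}): {exc}") from exc

    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return a manifest of outputs.

    Deterministic stages produce byte-identical files on rerun with the same
    config and inputs.
    """
    for attr in ("peaks_manifest", "annotation", "expr", "meta"):
        path = getattr(config, attr)
        if not Path(path).exists():
            raise PipelineError(f"input {attr} not found: {path}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    with _stage("build-matrix", config.peaks_manifest):
        manifest = read_peaks_manifest(config.peaks_manifest)
        matrix = load_compendium(
            manifest, read_annotation_bed(config.annotation), flank=config.flank
        )
        write_matrix(matrix, out / "matrix.tsv")
        outputs["matrix"] = str(out / "matrix.tsv")

    with _stage("call-degs", config.expr):
        expr = pd.read_csv(config.expr, sep="\t", index_col=0)
        meta = pd.read_csv(config.meta, sep="\t", index_col=0)
        collapsed, cmeta = collapse_to_model_medians(expr, meta)
        days = sorted(cmeta["timepoint"].unique())
        deg_lists: dict = {}
        for day in days:
            table = call_degs(
                collapsed, cmeta, day, sd_mult=config.sd_mult, fdr_cut=config.fdr_cut
            )
            path = out / f"degs_d{day}.tsv"
            table.to_csv(path, sep="\t", float_format="%.6g")
            outputs[f"degs_d{day}"] = str(path)
            deg_lists[day] = {
                "up": table.index[table["direction"] == "up"].tolist(),
                "down": table.index[table["direction"] == "down"].tolist(),
            }

    if config.background:
        background = [
            g for g in Path(config.background).read_text().split() if g in matrix.index
        ]
    else:
        background = [g for g in expr.index if g in matrix.index]

    with _stage("persistence-overlap", f"days {days[0]} vs {days[-1]}"):
        first, last = days[0], days[-1]
        persistence = {}
        persistent_lists = {}
        for direction in ("up", "down"):
            a, b = deg_lists[first][direction], deg_lists[last][direction]
            shared = [g for g in a if g in set(b)]
            persistent_lists[direction] = shared
            if a and b:
                res = overlap_test(set(a) & set(background), set(b) & set(background), background)
                persistence[direction] = dataclasses.asdict(res)
        path = out / "persistence_overlaps.json"
        with open(path, "w") as fh:
            json.dump(persistence, fh, indent=2, sort_keys=True)
        outputs["persistence_overlaps"] = str(path)

    results: dict = {"outputs": outputs, "top_factor": {}}
    analyses = {}
    for direction in ("up", "down"):
        query = [g for g in persistent_lists[direction] if g in set(background)]
        if not query:
            continue
        with _stage("enrich", f"persistent {direction} ({len(query)} genes)"):
            table = run_factor_analysis(
                matrix, query, background, tail_frac=config.tail_frac, log_base=config.log_base
            )
            path = out / f"factors_persistent_{direction}.tsv"
            table.to_csv(path, sep="\t", float_format="%.6g")
            outputs[f"factors_{direction}"] = str(path)
            analyses[direction] = (query, table)
            kept = table[~table["triaged"]]
            if len(kept):
                results["top_factor"][direction] = str(kept.index[0])

    if "down" in analyses:
        query, table = analyses["down"]
        with _stage("targets", "persistent down"):
            tsets = target_sets_for_analysis(matrix, query, background, analysis=table)
            if tsets:
                write_target_lists(tsets, out / "target_lists.txt")
                outputs["target_lists"] = str(out / "target_lists.txt")
            if len(tsets) >= 2:
                gmap = pairwise_overlap_map(tsets, query)
                gmap.neg_log10_p.to_csv(out / "target_overlap_map.tsv", sep="\t", float_format="%.6g")
                groups = group_factors(gmap, cut=config.distance_cut)
                with open(out / "factor_groups.json", "w") as fh:
                    json.dump({"groups": groups.groups, "cut": config.distance_cut}, fh, indent=2)
                outputs["target_overlap_map"] = str(out / "target_overlap_map.tsv")
                outputs["factor_groups"] = str(out / "factor_groups.json")

    manifest_doc = {
        "factorscan_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "checksums": {name: sha256_of(path) for name, path in sorted(outputs.items())},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest_doc, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest_doc
    return results
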
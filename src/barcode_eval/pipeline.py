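"""End-to-end orchestration: datasets -> distances -> divergence +
boundaries -> identification -> evaluation, with reproducible table output.

``run_pipeline`` is a pure function of its configuration and seed: rerunning
with the same config writes byte-identical tables.  Per-marker thresholds
for the tree+threshold method default to the optimum found by the boundary
scan of the same run (self-calibration) and can be overridden with published
values.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .boundaries import error_curves
from .classify import calls_to_frame, nj_tree, screen_unpublished
from .datasets import (
    MarkerDataset,
    build_evaluation_sets,
    default_its2_full_length,
    filter_by_length,
    read_marker_dataset,
    trim_to_common_region,
)
from .distances import distance_matrix
from .divergence import gap_histograms, ratio_gap_index, summarize_divergence
from .evaluate import duncan_multiple_range, run_evaluation
from .simdata import SimulationConfig, simulate_dataset

DEFAULT_METHODS = ("nn", "best-hit", "tree", "tree+threshold")


@dataclass(frozen=True)
class MarkerInput:
    """One marker's input: aligned FASTA + metadata TSV, or a simulation."""

    marker: str
    fasta: str | None = None
    metadata: str | None = None
    simulate: SimulationConfig | None = None

    def __post_init__(self) -> None:
        has_files = self.fasta is not None and self.metadata is not None
        if has_files == (self.simulate is not None):
            raise ValueError("give either fasta+metadata or a simulation config")


@dataclass(frozen=True)
class PipelineConfig:
    inputs: tuple[MarkerInput, ...]
    out_dir: str
    apply_length_filter: bool = True
    its2_full_length: int | None = None
    grid_step: float = 0.0001
    methods: tuple[str, ...] = DEFAULT_METHODS
    thresholds: dict | None = None  #: marker -> distance; None = self-calibrated
    gap_bin_width: float = 0.01
    seed: int = 1


def _load_marker(inp: MarkerInput, config: PipelineConfig) -> MarkerDataset:
    if inp.simulate is not None:
        dataset, _ = simulate_dataset(inp.simulate)
        return dataset
    return read_marker_dataset(inp.fasta, inp.metadata, inp.marker)


def run_marker(
    dataset: MarkerDataset, config: PipelineConfig, out: Path
) -> dict:
    """Run every analysis stage for one marker, writing tables under ``out``."""
    out.mkdir(parents=True, exist_ok=True)
    if config.apply_length_filter:
        full_length = config.its2_full_length
        if dataset.marker == "ITS2" and full_length is None:
            full_length = default_its2_full_length(dataset)
        dataset = filter_by_length(dataset, full_length)
    dataset = trim_to_common_region(dataset)

    # screening of unpublished records precedes evaluation-set assembly
    full_matrix = distance_matrix(dataset)
    if any(r.status == "unpublished" for r in dataset) and len(dataset) >= 3:
        tree = nj_tree(full_matrix)
        dataset, screen_report = screen_unpublished(tree, dataset)
    else:
        screen_report = pd.DataFrame(columns=["id", "species", "status", "reason"])
    screen_report.to_csv(out / "screening.tsv", sep="\t", index=False)

    set1, set2, set3 = build_evaluation_sets(dataset)
    for ds in (set1, set2, set3):
        ds.write_fasta(out / f"{ds.role}.fasta")
        ds.write_metadata(out / f"{ds.role}.tsv")

    matrix = full_matrix.submatrix(set1.ids)
    matrix.write_tsv(out / "distances.tsv")

    summary = summarize_divergence(matrix, set1)
    summary.to_frame().to_csv(out / "divergence_summary.tsv", sep="\t", index=False)
    summary.per_species.to_csv(out / "divergence_per_species.tsv", sep="\t", index=False)
    summary.per_genus.to_csv(out / "divergence_per_genus.tsv", sep="\t", index=False)
    if not summary.per_species.empty:
        hist = gap_histograms(summary.per_species, summary.per_genus, config.gap_bin_width)
        hist.to_frame().to_csv(out / "gap_histograms.tsv", sep="\t", index=False)

    scan = error_curves(matrix, set1, grid_step=config.grid_step)
    scan.to_frame().to_csv(out / "threshold_scan.tsv", sep="\t", index=False)

    threshold = (config.thresholds or {}).get(dataset.marker, scan.optimal)
    if threshold <= 0:
        threshold = config.grid_step  # degenerate perfectly-overlapping data

    results: dict = {
        "marker": dataset.marker,
        "n_set1": len(set1),
        "n_set2": len(set2),
        "n_set3": len(set3),
        "optimal_threshold": scan.optimal,
        "min_error_sum": scan.min_error_sum,
        "threshold_used": threshold,
        "ratio_gap_index": ratio_gap_index(summary),
        "summary": summary,
        "scan": scan,
        "methods": {},
    }
    rate_rows = []
    for method in config.methods:
        report = run_evaluation(
            set2, set1, method, threshold=threshold, matrix=matrix
        )
        results["methods"][report.method] = report
        calls_to_frame(list(report.calls)).to_csv(
            out / f"calls_{report.method.replace('+', '_')}.tsv", sep="\t", index=False
        )
        report.per_genus.to_csv(
            out / f"per_genus_{report.method.replace('+', '_')}.tsv", sep="\t", index=False
        )
        rate_rows.append(
            {
                "marker": dataset.marker,
                "method": report.method,
                "n_queries": report.n_queries,
                "n_correct": report.n_correct,
                "success_rate": report.success_rate,
            }
        )
    pd.DataFrame(rate_rows).to_csv(out / "success_rates.tsv", sep="\t", index=False)
    return results


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all markers; returns a dict of per-marker results."""
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    all_results: dict[str, dict] = {}
    for inp in config.inputs:
        dataset = _load_marker(inp, config)
        all_results[inp.marker] = run_marker(dataset, config, out_root / inp.marker)

    # multiple-range comparison of methods (replicates: per-genus rates,
    # pooled across markers); skipped when the rates carry no variance
    method_groups: dict[str, list[float]] = {}
    for res in all_results.values():
        for method, report in res["methods"].items():
            method_groups.setdefault(method, []).extend(
                report.per_genus["success_rate"].tolist()
            )
    letters_path = out_root / "method_letters.tsv"
    try:
        letters = duncan_multiple_range(method_groups)
        letters.to_csv(letters_path, sep="\t", index=False)
        all_results["_method_letters"] = letters
    except ValueError as exc:
        letters_path.write_text(f"# not computed: {exc}\n")

    manifest = {
        "package": "barcode-eval",
        "version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
    }
    (out_root / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
    return all_results


def _config_dict(config: PipelineConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        return obj

    return convert(config)
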
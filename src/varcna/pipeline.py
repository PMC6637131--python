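"""End-to-end pipeline: variant file in, segment table and purity report out.

Stages: parse -> sort/summarize -> blacklist -> coverage-range filter ->
het-site calling -> 100-bp windows -> diploid baseline -> normalization ->
recursive-partitioning segmentation -> merge -> classification -> purity.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from varcna import preprocess, purity as purity_mod, segmentation
from varcna.preprocess import CoverageWindow, HetSite
from varcna.purity import PurityResult
from varcna.segmentation import Segment
from varcna.variant_io import (
    RunConfig,
    VariantRecord,
    read_bambino,
    read_maf,
    read_paired_vcf,
    snv_counts,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: RunConfig
    n_input_records: int
    n_filtered_records: int
    mean_normal_coverage: float
    median_normal_coverage: float
    baseline_ratio: float
    diploid_region: str
    windows: list[CoverageWindow]
    hetsites: list[HetSite]
    pre_merge_segment_count: int
    segments: list[Segment]
    purity: PurityResult

    def run_log(self) -> dict:
        cfg = vars(self.config).copy()
        return {
            "config": cfg,
            "n_input_records": self.n_input_records,
            "n_filtered_records": self.n_filtered_records,
            "mean_normal_coverage": self.mean_normal_coverage,
            "median_normal_coverage": self.median_normal_coverage,
            "baseline_ratio": self.baseline_ratio,
            "diploid_region": self.diploid_region,
            "n_windows": len(self.windows),
            "n_het_sites": len(self.hetsites),
            "pre_merge_segment_count": self.pre_merge_segment_count,
            "n_segments": len(self.segments),
            "purity": self.purity.to_dict(),
        }


def load_records(path: str | Path, fmt: str = "auto", sample_order: str = "tumor_normal"):
    """Dispatch to the right reader; ``fmt`` in {auto, vcf, maf, bambino}."""
    path = Path(path)
    if fmt == "auto":
        name = path.name.lower()
        if name.endswith((".vcf", ".vcf.gz")):
            fmt = "vcf"
        elif name.endswith(".maf"):
            fmt = "maf"
        else:
            fmt = "bambino"
    if fmt == "vcf":
        return read_paired_vcf(path, sample_order)
    if fmt == "maf":
        return read_maf(path)
    if fmt == "bambino":
        return read_bambino(path)
    raise ValueError(f"unknown input format {fmt!r}")


def run_pipeline(
    input_path: str | Path,
    config: RunConfig | None = None,
    fmt: str = "auto",
) -> PipelineResult:
    """Run the full CNA + purity pipeline on one paired variant file."""
    config = config or RunConfig()
    records, summary = snv_counts(
        load_records(input_path, fmt=fmt, sample_order=config.sample_order)
    )
    n_input = summary.n_records

    records = preprocess.apply_blacklist(records, config.blacklist_path)
    records = preprocess.drop_non_model_chroms(records)
    records = preprocess.coverage_filter(records, config, summary.median)
    if not records:
        raise preprocess.BlacklistError("no records survive filtering")

    hetsites = preprocess.call_heterozygous(
        records, config.het_baf_low, config.het_baf_high, config.het_min_depth
    )
    windows = preprocess.build_windows(records, config.window_size)
    baseline, region = preprocess.infer_diploid_baseline(windows, hetsites, config)
    windows = preprocess.normalize_ratios(windows, baseline)

    leaves = segmentation.recursive_partition(
        windows, config.min_windows, config.min_gain
    )
    segments = segmentation.merge_adjacent(leaves, config.merge_tol)
    for s in segments:
        segmentation.classify_cna(s, config.call_tol)

    het_by_segment = purity_mod.assign_hetsites(segments, hetsites)
    estimates = purity_mod.per_segment_estimates(
        segments, het_by_segment, config.min_het_sites
    )
    purity_result = purity_mod.estimate_sample_purity(
        estimates, config.min_purity_segments, seed=config.seed
    )
    purity_result.diploid_region = region

    return PipelineResult(
        config=config,
        n_input_records=n_input,
        n_filtered_records=len(records),
        mean_normal_coverage=summary.mean,
        median_normal_coverage=summary.median,
        baseline_ratio=baseline,
        diploid_region=region,
        windows=windows,
        hetsites=hetsites,
        pre_merge_segment_count=len(leaves),
        segments=segments,
        purity=purity_result,
    )


def write_outputs(result: PipelineResult, out_dir: str | Path, prefix: str = "sample") -> dict[str, Path]:
    """Write the segment table, purity report and run log under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seg_path = out_dir / f"{prefix}.cna.txt"
    purity_path = out_dir / f"{prefix}.purity.json"
    log_path = out_dir / f"{prefix}.runlog.json"
    segmentation.write_cna_table(result.segments, seg_path)
    purity_path.write_text(json.dumps(result.purity.to_dict(), indent=2) + "\n")
    log_path.write_text(json.dumps(result.run_log(), indent=2, default=str) + "\n")
    return {"segments": seg_path, "purity": purity_path, "runlog": log_path}
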
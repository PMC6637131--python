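"""Site filtering, heterozygous-site calling, coverage windows and the
diploid baseline.

This stage turns sorted allele-count records into the two data streams the
caller consumes: fixed-size coverage windows (tumor/normal depth ratio per
window, diploid-normalized) and germline-heterozygous sites with tumor and
normal B-allele frequencies. Filtering follows the tool's options: a BED
blacklist of suspicious SNPs, and a normal-depth range of
[median x min_factor, median x max_factor] with separate factors on chrX.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from varcna.variant_io import RunConfig, VariantRecord, chrom_sort_key, normalize_chrom

logger = logging.getLogger(__name__)


@dataclass
class CoverageWindow:
    """Fixed-size genomic bin holding the mean depths of its variant sites.

    ``window_index = floor((pos - 1) / window_size)``; the window spans the
    1-based inclusive interval [index*size + 1, (index+1)*size]. Windows
    containing no variants are never materialized.
    """

    chrom: str
    window_index: int
    start: int
    end: int
    n_sites: int
    mean_tumor_cov: float
    mean_normal_cov: float
    ratio: float = math.nan       # diploid-normalized tumor/normal ratio
    log2_ratio: float = math.nan

    @property
    def raw_ratio(self) -> float:
        return self.mean_tumor_cov / self.mean_normal_cov if self.mean_normal_cov > 0 else math.nan


@dataclass
class HetSite:
    """Germline-heterozygous site with tumor/normal B-allele frequencies.

    ``site_loh`` is the allelic-imbalance measure |BAF_tumor - BAF_normal|.
    Depths are retained so segment-level LOH estimation can subtract the
    binomial sampling variance.
    """

    chrom: str
    pos: int
    baf_tumor: float
    baf_normal: float
    site_loh: float
    tumor_total: int = 0
    normal_total: int = 0
    segment_id: int | None = None


class BlacklistError(ValueError):
    """Malformed BED blacklist."""


def read_blacklist(path: str | Path) -> dict[str, IntervalTree]:
    """Read a 0-based half-open BED into per-chromosome interval trees."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            if not ln.strip() or ln.startswith(("#", "track", "browser")):
                continue
            f = ln.split()
            try:
                chrom, start, end = normalize_chrom(f[0]), int(f[1]), int(f[2])
                if end <= start:
                    raise ValueError("end <= start")
            except (ValueError, IndexError) as exc:
                raise BlacklistError(f"{path} line {lineno}: {exc}") from exc
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def apply_blacklist(
    records: Iterable[VariantRecord],
    blacklist: dict[str, IntervalTree] | str | Path | None,
) -> list[VariantRecord]:
    """Drop records whose position falls inside a blacklist interval.

    BED intervals are 0-based half-open, record positions 1-based: a record
    at ``pos`` is removed when ``pos - 1`` lies in [start, end).
    """
    if blacklist is None:
        return list(records)
    if not isinstance(blacklist, dict):
        blacklist = read_blacklist(blacklist)
    kept = []
    n_dropped = 0
    for r in records:
        tree = blacklist.get(r.chrom)
        if tree is not None and tree.overlaps_point(r.pos - 1):
            n_dropped += 1
            continue
        kept.append(r)
    if n_dropped:
        logger.info("blacklist removed %d records", n_dropped)
    return kept


def coverage_filter(
    records: Iterable[VariantRecord],
    config: RunConfig,
    median_normal_coverage: float | None = None,
) -> list[VariantRecord]:
    """Keep records whose normal depth lies inside the scale-factor range.

    A record survives iff ``median*min_factor <= normal_total <=
    median*max_factor`` (bounds inclusive); on chrX the xmin/xmax factors
    substitute. The median comes from ``config.median_normal_coverage`` or
    the explicit argument.
    """
    median = config.median_normal_coverage
    if median is None:
        median = median_normal_coverage
    if median is None or median <= 0:
        raise ValueError("coverage_filter needs a positive median normal coverage")
    lo, hi = median * config.min_factor, median * config.max_factor
    xlo, xhi = median * config.xmin_factor, median * config.xmax_factor
    kept = []
    for r in records:
        a, b = (xlo, xhi) if normalize_chrom(r.chrom) == "X" else (lo, hi)
        if a <= r.normal_total <= b:
            kept.append(r)
    return kept


def drop_non_model_chroms(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Remove chrY and mitochondrial records (model covers autosomes + chrX)."""
    return [r for r in records if normalize_chrom(r.chrom) not in ("Y", "MT")]


def call_heterozygous(
    records: Iterable[VariantRecord],
    baf_low: float = 0.30,
    baf_high: float = 0.70,
    min_depth: int = 10,
) -> list[HetSite]:
    """Identify germline-heterozygous sites from the normal-sample BAF.

    A site is called heterozygous when its normal BAF lies in
    [baf_low, baf_high] (inclusive) and the normal depth is >= min_depth.
    """
    sites = []
    for r in records:
        if r.normal_total < min_depth or r.normal_total == 0:
            continue
        baf_n = r.normal_mutant / r.normal_total
        if baf_low <= baf_n <= baf_high and r.tumor_total > 0:
            baf_t = r.tumor_mutant / r.tumor_total
            sites.append(
                HetSite(
                    r.chrom, r.pos, baf_t, baf_n, abs(baf_t - baf_n),
                    r.tumor_total, r.normal_total,
                )
            )
    if not sites:
        logger.warning("no heterozygous sites identified")
    return sites


def build_windows(
    records: Sequence[VariantRecord], window_size: int = 100
) -> list[CoverageWindow]:
    """Group sorted records into fixed-size windows of mean tumor/normal depth."""
    windows: list[CoverageWindow] = []
    cur_key: tuple[str, int] | None = None
    t_sum = n_sum = count = 0

    def _flush() -> None:
        if cur_key is None:
            return
        chrom, idx = cur_key
        windows.append(
            CoverageWindow(
                chrom=chrom,
                window_index=idx,
                start=idx * window_size + 1,
                end=(idx + 1) * window_size,
                n_sites=count,
                mean_tumor_cov=t_sum / count,
                mean_normal_cov=n_sum / count,
            )
        )

    for r in records:
        key = (r.chrom, (r.pos - 1) // window_size)
        if key != cur_key:
            _flush()
            cur_key, t_sum, n_sum, count = key, 0, 0, 0
        t_sum += r.tumor_total
        n_sum += r.normal_total
        count += 1
    _flush()
    windows.sort(key=lambda w: (chrom_sort_key(w.chrom), w.window_index))
    return windows


def normalize_ratios(
    windows: Iterable[CoverageWindow], baseline_ratio: float
) -> list[CoverageWindow]:
    """Set each window's ratio/log2_ratio relative to the diploid baseline.

    ``ratio = (mean_tumor_cov / mean_normal_cov) / baseline``; windows with
    zero normal coverage are removed.
    """
    if baseline_ratio <= 0:
        raise ValueError("baseline_ratio must be positive")
    out = []
    for w in windows:
        if w.mean_normal_cov <= 0:
            continue
        w.ratio = (w.mean_tumor_cov / w.mean_normal_cov) / baseline_ratio
        w.log2_ratio = math.log2(w.ratio) if w.ratio > 0 else -math.inf
        out.append(w)
    return out


class DiploidRegionError(ValueError):
    """The user-specified diploid region contains no usable windows."""


def _parse_region(region: str) -> tuple[str, int | None, int | None]:
    if ":" in region:
        chrom, span = region.split(":", 1)
        start_s, end_s = span.replace(",", "").split("-", 1)
        return normalize_chrom(chrom), int(start_s), int(end_s)
    return normalize_chrom(region), None, None


def infer_diploid_baseline(
    windows: Sequence[CoverageWindow],
    hetsites: Sequence[HetSite],
    config: RunConfig,
    min_span: float = 5e6,
) -> tuple[float, str]:
    """Choose the raw tumor/normal coverage ratio treated as copy number 2.

    With ``config.diploid_region`` set, the baseline is the median raw ratio
    of the windows in that region. Otherwise a provisional segmentation of
    the raw log2 ratios is run; among segments spanning at least ``min_span``
    bases, segments are grouped into coverage-ratio modes and the mode whose
    overlapping het sites show the smallest median site-level allelic
    imbalance (balanced BAF => two haplotypes present in equal number) is
    taken as diploid, ties broken toward the mode covering more of the
    genome. Note a genome-wide duplication presents a balanced dominant mode
    and is therefore mistaken for diploid; the user override is the escape
    hatch for such genomes.
    """
    if not windows:
        raise ValueError("no coverage windows")
    if config.diploid_region:
        chrom, start, end = _parse_region(config.diploid_region)
        sel = [
            w for w in windows
            if normalize_chrom(w.chrom) == chrom
            and (start is None or (w.end >= start and w.start <= end))
        ]
        if not sel:
            raise DiploidRegionError(
                f"diploid region {config.diploid_region!r} contains no windows"
            )
        ratios = [w.raw_ratio for w in sel if w.mean_normal_cov > 0]
        return float(statistics.median(ratios)), f"user:{config.diploid_region}"

    from varcna.segmentation import merge_adjacent, recursive_partition

    # provisional segmentation on raw (un-normalized) log2 ratios
    provisional = [
        CoverageWindow(
            w.chrom, w.window_index, w.start, w.end, w.n_sites,
            w.mean_tumor_cov, w.mean_normal_cov,
            ratio=w.raw_ratio,
            log2_ratio=math.log2(w.raw_ratio) if w.mean_normal_cov > 0 and w.raw_ratio > 0 else math.nan,
        )
        for w in windows
        if w.mean_normal_cov > 0 and w.mean_tumor_cov > 0
    ]
    segs = merge_adjacent(
        recursive_partition(provisional, config.min_windows, config.min_gain),
        config.merge_tol,
    )
    genome_median = float(
        statistics.median(w.raw_ratio for w in provisional)
    )
    cands = [s for s in segs if (s.end - s.start + 1) >= min_span]
    if not cands:
        return genome_median, "auto:genome-median"

    # het sites per candidate segment
    by_chrom: dict[str, list[HetSite]] = {}
    for h in hetsites:
        by_chrom.setdefault(h.chrom, []).append(h)
    seg_loh: list[list[float]] = []
    for s in cands:
        lohs = [
            h.site_loh for h in by_chrom.get(s.chrom, ())
            if s.start <= h.pos <= s.end
        ]
        seg_loh.append(lohs)

    # group candidate segments into coverage-ratio modes (gap > 0.1 in log2)
    order = sorted(range(len(cands)), key=lambda i: cands[i].mean_log2)
    modes: list[list[int]] = [[order[0]]]
    for i in order[1:]:
        if cands[i].mean_log2 - cands[modes[-1][-1]].mean_log2 > 0.1:
            modes.append([i])
        else:
            modes[-1].append(i)

    best = None
    for mode in modes:
        lohs = [v for i in mode for v in seg_loh[i]]
        span = sum(cands[i].end - cands[i].start + 1 for i in mode)
        if not lohs:
            continue
        med = statistics.median(lohs)
        key = (round(med, 3), -span)
        if best is None or key < best[0]:
            best = (key, mode)
    if best is None:
        return genome_median, "auto:genome-median"
    mode = best[1]
    ratios = [
        w.raw_ratio
        for i in mode
        for w in provisional
        if w.chrom == cands[i].chrom and cands[i].start <= w.start <= cands[i].end
    ]
    desc = ";".join(
        f"{cands[i].chrom}:{cands[i].start}-{cands[i].end}" for i in sorted(mode)
    )
    return float(statistics.median(ratios)), f"auto:{desc}"
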
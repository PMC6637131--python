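"""Recursive-partitioning segmentation of windowed log2 coverage ratios.

A regression-tree style binary splitter: per chromosome, the ordered window
sequence is split at the index giving the largest reduction in the sum of
squared errors (SSE) of the log2 ratio, recursing while both children keep
at least ``min_windows`` windows and the relative SSE reduction stays above
``min_gain``. Leaves become segments; near-equal neighbors are then merged
to a fixed point to suppress over-segmentation from depth noise.

Output semantics: ``seg_mean`` is the linear copy-ratio deviation from the
diploid baseline (0.5 units per copy: +1.0 = 2-copy gain, -0.5 = 1-copy
loss); ``gmean`` is the absolute copy-number scale with diploid = 2.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from varcna.preprocess import CoverageWindow
from varcna.variant_io import chrom_sort_key

GAIN, LOSS, NEUTRAL = "gain", "loss", "neutral"


@dataclass
class Segment:
    """Contiguous run of coverage windows with a common copy-number state."""

    chrom: str
    start: int   # 1-based inclusive
    end: int
    n_windows: int
    mean_log2: float
    seg_mean: float = math.nan
    gmean: float = math.nan
    cna_class: str = NEUTRAL
    n_het_sites: int = 0

    @property
    def measured_cna(self) -> float:
        """Signed fraction of cells with a single-copy change, x = 2*seg_mean."""
        return 2.0 * self.seg_mean

    @property
    def length(self) -> int:
        return self.end - self.start + 1


#: scale of the size-dependent floor on the relative SSE reduction; the
#: empirical null (max over split points, Gaussian noise) stays 3-7x below
#: PENALTY_FACTOR*ln(n)/n across n = 10^2..10^4
PENALTY_FACTOR = 6.0
PENALTY_CAP = 0.5


def _min_relative_gain(n: int, min_gain: float) -> float:
    return max(min_gain, min(PENALTY_CAP, PENALTY_FACTOR * math.log(n) / n))


def _segment_chromosome(
    chrom: str,
    windows: Sequence[CoverageWindow],
    values: np.ndarray,
    min_windows: int,
    min_gain: float,
) -> list[Segment]:
    """Binary recursive splitting of one chromosome's window sequence."""
    cs = np.concatenate([[0.0], np.cumsum(values)])
    css = np.concatenate([[0.0], np.cumsum(values * values)])

    def node_sse(lo: int, hi: int) -> float:  # [lo, hi)
        n = hi - lo
        s = cs[hi] - cs[lo]
        return float(css[hi] - css[lo] - s * s / n)

    leaves: list[tuple[int, int]] = []
    stack = [(0, len(values))]
    while stack:
        lo, hi = stack.pop()
        n = hi - lo
        if n < 2 * min_windows:
            leaves.append((lo, hi))
            continue
        total = node_sse(lo, hi)
        if total <= 0.0:
            leaves.append((lo, hi))
            continue
        # candidate left sizes k in [min_windows, n - min_windows]
        k = np.arange(min_windows, n - min_windows + 1)
        ls = cs[lo + k] - cs[lo]
        lss = css[lo + k] - css[lo]
        rs = cs[hi] - cs[lo + k]
        rss = css[hi] - css[lo + k]
        child_sse = (lss - ls * ls / k) + (rss - rs * rs / (n - k))
        best = int(np.argmin(child_sse))  # leftmost split on ties
        if (total - float(child_sse[best])) / total < _min_relative_gain(n, min_gain):
            leaves.append((lo, hi))
            continue
        split = lo + min_windows + best
        # push right first so the left child is processed next (deterministic,
        # left-to-right leaf order either way)
        stack.append((split, hi))
        stack.append((lo, split))

    leaves.sort()
    segs = []
    for lo, hi in leaves:
        segs.append(
            Segment(
                chrom=chrom,
                start=windows[lo].start,
                end=windows[hi - 1].end,
                n_windows=hi - lo,
                mean_log2=float(np.mean(values[lo:hi])),
            )
        )
    return segs


def recursive_partition(
    windows: Sequence[CoverageWindow],
    min_windows: int = 5,
    min_gain: float = 1e-3,
) -> list[Segment]:
    """Segment normalized windows chromosome by chromosome.

    At every node the split index maximizing the SSE reduction of
    ``log2_ratio`` is chosen (leftmost on ties); recursion continues while
    both children hold >= ``min_windows`` windows and the relative SSE
    reduction clears ``max(min_gain, 6*ln(n)/n)`` — the size-dependent
    floor plays the role of a regression-tree complexity penalty, stopping
    recursion on pure-noise nodes at every scale while still admitting a
    perfect split on noiseless data. Returned segments tile the windowed
    extent of each chromosome without overlap.
    """
    if min_windows < 2:
        raise ValueError("min_windows must be >= 2")
    by_chrom: dict[str, list[CoverageWindow]] = {}
    for w in windows:
        if math.isfinite(w.log2_ratio):
            by_chrom.setdefault(w.chrom, []).append(w)
    segments: list[Segment] = []
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        ws = sorted(by_chrom[chrom], key=lambda w: w.window_index)
        vals = np.asarray([w.log2_ratio for w in ws], dtype=float)
        if len(ws) < 2 * min_windows:
            segments.append(
                Segment(chrom, ws[0].start, ws[-1].end, len(ws), float(np.mean(vals)))
            )
            continue
        segments.extend(_segment_chromosome(chrom, ws, vals, min_windows, min_gain))
    return segments


def merge_adjacent(segments: Sequence[Segment], merge_tol: float = 0.1) -> list[Segment]:
    """Merge neighboring same-chromosome segments with near-equal means.

    Left-to-right greedy passes repeat until a fixed point: a neighbor is
    absorbed when |mean_log2 difference| < ``merge_tol``, the merged mean
    being the window-count-weighted average. Segment count never increases.
    """
    segs = [replace(s) for s in segments]
    changed = True
    while changed:
        changed = False
        out: list[Segment] = []
        for s in segs:
            if (
                out
                and out[-1].chrom == s.chrom
                and abs(out[-1].mean_log2 - s.mean_log2) < merge_tol
            ):
                prev = out[-1]
                n = prev.n_windows + s.n_windows
                out[-1] = Segment(
                    chrom=prev.chrom,
                    start=min(prev.start, s.start),
                    end=max(prev.end, s.end),
                    n_windows=n,
                    mean_log2=(
                        prev.mean_log2 * prev.n_windows + s.mean_log2 * s.n_windows
                    ) / n,
                    n_het_sites=prev.n_het_sites + s.n_het_sites,
                )
                changed = True
            else:
                out.append(s)
        segs = out
    return segs


def classify_cna(segment: Segment, call_tol: float = 0.1) -> Segment:
    """Fill seg_mean/gmean and the gain/loss/neutral call from mean_log2.

    With ``r = 2^mean_log2`` (coverage ratio relative to the diploid
    baseline): ``gmean = 2r`` (absolute copy scale, diploid 2.0) and
    ``seg_mean = r - 1`` (so a clonal 2-copy gain reports 1.0 and a clonal
    1-copy loss reports -0.5). Calls: gain when seg_mean >= call_tol, loss
    when <= -call_tol, else neutral.
    """
    r = 2.0 ** segment.mean_log2
    segment.seg_mean = r - 1.0
    segment.gmean = 2.0 * r
    if segment.seg_mean >= call_tol:
        segment.cna_class = GAIN
    elif segment.seg_mean <= -call_tol:
        segment.cna_class = LOSS
    else:
        segment.cna_class = NEUTRAL
    return segment


_TABLE_HEADER = ["chrom", "loc.start", "loc.end", "num.windows", "seg.mean", "gmean", "cna.class"]


def write_cna_table(segments: Iterable[Segment], path: str | Path) -> None:
    """Write the tab-delimited segment table (full float precision)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TABLE_HEADER) + "\n")
        for s in segments:
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.n_windows}\t"
                f"{s.seg_mean!r}\t{s.gmean!r}\t{s.cna_class}\n"
            )


def read_cna_table(path: str | Path) -> list[Segment]:
    """Read a segment table written by :func:`write_cna_table`."""
    segs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TABLE_HEADER:
            raise ValueError(f"{path}: unexpected header {header}")
        for ln in fh:
            if not ln.strip():
                continue
            chrom, start, end, nw, seg_mean, gmean, cls = ln.rstrip("\n").split("\t")
            sm = float(seg_mean)
            segs.append(
                Segment(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    n_windows=int(nw),
                    mean_log2=math.log2(sm + 1.0) if sm > -1.0 else -math.inf,
                    seg_mean=sm,
                    gmean=float(gmean),
                    cna_class=cls,
                )
            )
    return segs


def naive_window_segments(
    windows: Sequence[CoverageWindow], call_tol: float = 0.1
) -> list[Segment]:
    """Per-window gain/loss/neutral calling without any segmentation.

    Each window is classified from its own log2 ratio alone and maximal
    runs of identically-called windows become segments. This is the
    hypersegmentation-prone baseline the regression-tree pipeline is
    measured against on artifact-ridden data.
    """
    segs: list[Segment] = []
    for w in windows:
        if not math.isfinite(w.log2_ratio):
            continue
        r = 2.0 ** w.log2_ratio
        call = GAIN if r - 1 >= call_tol else (LOSS if r - 1 <= -call_tol else NEUTRAL)
        if segs and segs[-1].chrom == w.chrom and segs[-1].cna_class == call:
            s = segs[-1]
            n = s.n_windows + 1
            s.mean_log2 = (s.mean_log2 * s.n_windows + w.log2_ratio) / n
            s.n_windows = n
            s.end = w.end
        else:
            segs.append(
                Segment(w.chrom, w.start, w.end, 1, w.log2_ratio, cna_class=call)
            )
    for s in segs:
        r = 2.0 ** s.mean_log2
        s.seg_mean, s.gmean = r - 1.0, 2.0 * r
    return segs


def write_igv_seg(segments: Iterable[Segment], path: str | Path, sample_id: str = "sample") -> None:
    """IGV-compatible .seg export; the seg.mean column carries mean_log2."""
    with open(path, "w") as fh:
        fh.write("ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean\n")
        for s in segments:
            fh.write(
                f"{sample_id}\t{s.chrom}\t{s.start}\t{s.end}\t{s.n_windows}\t{s.mean_log2:.6f}\n"
            )
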
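"""Concordance metrics between two CNA profiles.

A genomic base is *corroborated* when both profiles assign it the same CNA
type (gain or loss); neutral bases do not enter the score. Over non-neutral
bases, precision = corroborated predicted bases / predicted non-neutral
bases, recall = corroborated predicted bases / reference non-neutral bases,
and F1 = 2PR/(P+R). A whole segment is corroborated when at least 90% of
its bases receive the same type from the other profile. All arithmetic is
on intervals; per-base arrays are never materialized. The deliberately
avoided alternative — reciprocal 50% segment overlap — breaks down when the
two profiles have different breakpoint resolution, which is exactly the
regime here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from varcna.segmentation import GAIN, LOSS, NEUTRAL, Segment


@dataclass
class BaseCallComparison:
    corroborated_bases: int
    total_bases: int          # union of non-neutral bases of both profiles
    predicted_bases: int
    reference_bases: int
    precision: float
    recall: float
    f1: float
    defined: bool = True      # False when both profiles are all-neutral

    def to_dict(self) -> dict:
        return {
            "corroborated_bases": self.corroborated_bases,
            "total_bases": self.total_bases,
            "predicted_bases": self.predicted_bases,
            "reference_bases": self.reference_bases,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "defined": self.defined,
        }


def _merged_intervals(
    segments: Sequence[Segment],
) -> dict[tuple[str, str], list[tuple[int, int]]]:
    """Non-neutral segment spans per (chrom, type), sorted and merged."""
    raw: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for s in segments:
        if s.cna_class == NEUTRAL:
            continue
        raw.setdefault((s.chrom, s.cna_class), []).append((s.start, s.end))
    merged = {}
    for key, ivs in raw.items():
        ivs.sort()
        out = [ivs[0]]
        for a, b in ivs[1:]:
            if a <= out[-1][1] + 1:
                out[-1] = (out[-1][0], max(out[-1][1], b))
            else:
                out.append((a, b))
        merged[key] = out
    return merged


def _total(ivs: Sequence[tuple[int, int]]) -> int:
    return sum(b - a + 1 for a, b in ivs)


def _intersection(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> int:
    """Total overlapping bases of two sorted, merged 1-based interval lists."""
    i = j = 0
    bases = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo <= hi:
            bases += hi - lo + 1
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return bases


def per_base_f1(
    predicted: Sequence[Segment], reference: Sequence[Segment]
) -> BaseCallComparison:
    """Per-base precision/recall/F1 of two CNA profiles by interval arithmetic."""
    pred = _merged_intervals(predicted)
    ref = _merged_intervals(reference)
    pred_bases = sum(_total(v) for v in pred.values())
    ref_bases = sum(_total(v) for v in ref.values())
    corroborated = sum(
        _intersection(ivs, ref[key]) for key, ivs in pred.items() if key in ref
    )
    if pred_bases == 0 and ref_bases == 0:
        return BaseCallComparison(0, 0, 0, 0, math.nan, math.nan, math.nan, defined=False)
    union = pred_bases + ref_bases  # over (chrom, type) classes; overlap counted once
    union -= corroborated
    precision = corroborated / pred_bases if pred_bases else 0.0
    recall = corroborated / ref_bases if ref_bases else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return BaseCallComparison(
        corroborated, union, pred_bases, ref_bases, precision, recall, f1
    )


def segment_corroborated(
    segment: Segment, other_profile: Sequence[Segment], threshold: float = 0.90
) -> bool:
    """True when >= 90% of the segment's bases get the same type from the other profile."""
    if segment.cna_class == NEUTRAL:
        raise ValueError("corroboration is defined for non-neutral segments only")
    other = _merged_intervals(other_profile).get((segment.chrom, segment.cna_class), [])
    matched = _intersection([(segment.start, segment.end)], other)
    return matched / segment.length >= threshold


LENGTH_BINS = ["<3", "[3,4)", "[4,5)", "[5,6)", ">=6"]
AMPLITUDE_BINS = ["low(<1)", "mid[1,3)", "high(>=3)"]


def _length_bin(length: int) -> str:
    if length <= 0:
        raise ValueError("zero-length segment")
    exp = math.floor(math.log10(length))
    if exp < 3:
        return "<3"
    if exp >= 6:
        return ">=6"
    return f"[{exp},{exp + 1})"


def _amplitude_bin(mean_log2: float) -> str:
    a = abs(mean_log2)
    if a < 1.0:
        return "low(<1)"
    if a < 3.0:
        return "mid[1,3)"
    return "high(>=3)"


def stratify_segments(
    segments: Sequence[Segment],
    other_profile: Sequence[Segment] | None = None,
    threshold: float = 0.90,
) -> dict:
    """Cross-tabulate non-neutral segments by length decade and amplitude.

    Length bins follow floor(log10(length)): <3, [3,4), [4,5), [5,6), >=6;
    amplitude bins on |mean_log2|: <1.0 (low), [1.0, 3.0) (mid), >= 3.0
    (high). When ``other_profile`` is given, corroborated counts per bin and
    match percentages split at 100 kb are reported as well.
    """
    counts = {lb: {ab: 0 for ab in AMPLITUDE_BINS} for lb in LENGTH_BINS}
    matched = {lb: {ab: 0 for ab in AMPLITUDE_BINS} for lb in LENGTH_BINS}
    focal = {"matched": 0, "total": 0}      # < 100 kb
    broad = {"matched": 0, "total": 0}      # >= 100 kb
    for s in segments:
        if s.cna_class == NEUTRAL:
            continue
        lb, ab = _length_bin(s.length), _amplitude_bin(s.mean_log2)
        counts[lb][ab] += 1
        size_class = focal if s.length < 100_000 else broad
        size_class["total"] += 1
        if other_profile is not None and segment_corroborated(s, other_profile, threshold):
            matched[lb][ab] += 1
            size_class["matched"] += 1
    result = {"counts": counts}
    if other_profile is not None:
        result["matched"] = matched
        result["match_pct_lt_100kb"] = (
            focal["matched"] / focal["total"] if focal["total"] else math.nan
        )
        result["match_pct_ge_100kb"] = (
            broad["matched"] / broad["total"] if broad["total"] else math.nan
        )
    return result
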
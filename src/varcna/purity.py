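"""Tumor purity estimation from segment-level CNA and LOH signals.

Model: in a segment where a fraction ``x`` of cells carries a single-copy
gain (x > 0) or loss (x < 0) and a fraction ``y`` carries copy-neutral LOH,
the B-allele frequencies of germline-heterozygous sites split into two
clusters at (1+CNA)/(2+CNA) and 1/(2+CNA) whose separation equals 2*LOH,
with the combined allelic imbalance LOH = (2y + |x|) / (4 + 2x). Inverting,

    y      = LOH * (2 + x) - |x| / 2
    purity = |x| + y = LOH * (2 + x) + |x| / 2

``x`` is read from the coverage signal as 2 * seg_mean. Only copy-neutral
and single-copy gain/loss segments (-1 <= x <= 1) with enough heterozygous
sites are eligible. Per-segment purity values are clustered with a 1-D
Gaussian mixture (component count 1..5 chosen by BIC) and the sample purity
is the highest cluster center; at least 20 per-segment estimates are
required for a reliable call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from varcna.preprocess import HetSite
from varcna.segmentation import Segment
from varcna.variant_io import normalize_chrom


@dataclass
class SegmentPurityEstimate:
    """Per-segment purity decomposition: purity = |x| + y."""

    segment_id: int
    x: float          # measured single-copy CNA cell fraction, in [-1, 1]
    loh: float        # segment-level LOH, in [0, 0.5]
    y: float          # CN-LOH cell fraction
    purity: float     # |x| + y clamped to [0, 1]
    n_het_sites: int
    model_inconsistent: bool = False  # raw y fell well below 0


@dataclass
class PurityResult:
    estimates: list[SegmentPurityEstimate]
    cluster_centers: list[float]
    purity: float | None
    reliable: bool
    diploid_region: str = ""

    def to_dict(self) -> dict:
        return {
            "purity": self.purity,
            "reliable": self.reliable,
            "n_segment_estimates": len(self.estimates),
            "cluster_centers": self.cluster_centers,
            "diploid_region": self.diploid_region,
            "segments": [
                {
                    "segment_id": e.segment_id,
                    "x": e.x,
                    "loh": e.loh,
                    "y": e.y,
                    "purity": e.purity,
                    "n_het_sites": e.n_het_sites,
                }
                for e in self.estimates
            ],
        }


def baf(mutant: int, total: int) -> float:
    """B-allele frequency: alt-supporting reads over read depth."""
    if total <= 0:
        raise ValueError("no coverage: total read depth must be positive")
    return mutant / total


def site_loh(baf_tumor: float, baf_normal: float) -> float:
    """Site-level allelic imbalance |BAF_tumor - BAF_normal|."""
    return abs(baf_tumor - baf_normal)


def cluster_centers(cna: float) -> tuple[float, float]:
    """Expected BAF cluster centers for a region of measured CNA.

    Returns ((1+CNA)/(2+CNA), 1/(2+CNA)); their separation is
    |CNA/(2+CNA)| = 2*LOH. The "left/right" labels carry no positional
    meaning (they swap sides as CNA changes sign).
    """
    if cna <= -2:
        raise ValueError("CNA must exceed -2 (total copy number positive)")
    return (1.0 + cna) / (2.0 + cna), 1.0 / (2.0 + cna)


def _two_means_split(sorted_vals: np.ndarray) -> tuple[float, float]:
    """Exact 1-D two-cluster split minimizing within-cluster SSE."""
    n = len(sorted_vals)
    cs = np.concatenate([[0.0], np.cumsum(sorted_vals)])
    css = np.concatenate([[0.0], np.cumsum(sorted_vals**2)])
    k = np.arange(1, n)
    sse = (css[k] - cs[k] ** 2 / k) + (
        (css[n] - css[k]) - (cs[n] - cs[k]) ** 2 / (n - k)
    )
    split = int(np.argmin(sse)) + 1
    return float(np.mean(sorted_vals[:split])), float(np.mean(sorted_vals[split:]))


def segment_loh(
    hetsites: Sequence[HetSite],
    min_sites: int = 10,
    bimodal_tol: float = 0.1,
) -> float | None:
    """Estimate segment-level LOH from the tumor BAFs of its het sites.

    Tumor BAFs are folded about 0.5 (b -> |b - 0.5|); the fold distance d
    equals the LOH (half the separation of the two unfolded BAF clusters).
    When an exact two-population split of the folded values finds well
    separated centers (a mixed segment), d is the upper center; otherwise
    the unimodal estimate d^2 = mean((baf_t - baf_n)^2) minus the binomial
    sampling variance implied by the read depths is used, which removes the
    upward noise bias at small LOH. Returns None (segment excluded) when
    fewer than ``min_sites`` sites are available; capped at 0.5.
    """
    if len(hetsites) < min_sites:
        return None
    bt = np.asarray([h.baf_tumor for h in hetsites], dtype=float)
    bn = np.asarray([h.baf_normal for h in hetsites], dtype=float)
    tt = np.asarray([h.tumor_total for h in hetsites], dtype=float)
    nt = np.asarray([h.normal_total for h in hetsites], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_t = np.where(tt > 0, bt * (1.0 - bt) / tt, 0.0)
        var_n = np.where(nt > 0, bn * (1.0 - bn) / nt, 0.0)
    folded = np.sort(np.abs(bt - 0.5))
    if len(folded) >= 4:
        lo, hi = _two_means_split(folded)
        # folding a unimodal noisy cloud already yields a split separation of
        # ~1.5 sampling-noise sd, so demand clear excess over that scale
        noise_sd = math.sqrt(float(np.mean(var_t)))
        if hi - lo > max(bimodal_tol, 2.5 * noise_sd):
            return min(hi, 0.5)
    # unimodal: debiased RMS of the site-level imbalance
    d2 = float(np.mean((bt - bn) ** 2) - np.mean(var_t + var_n))
    return min(math.sqrt(max(d2, 0.0)), 0.5)


def cn_loh_fraction(x: float, loh: float, eps: float = 0.02) -> tuple[float, bool]:
    """CN-LOH cell fraction y = LOH*(2+x) - |x|/2.

    Small negative values (|raw| <= eps, pure measurement noise) clamp to
    zero; larger negatives also clamp but are flagged model-inconsistent.
    """
    y = loh * (2.0 + x) - 0.5 * abs(x)
    if y >= 0.0:
        return y, False
    return 0.0, y < -eps


def segment_purity(x: float, loh: float) -> float:
    """Per-segment purity |x| + y = LOH*(2+x) + |x|/2, clamped to [0, 1]."""
    if abs(x) > 1.0:
        raise ValueError(
            f"segment with |x| > 1 is ineligible for purity estimation (x={x})"
        )
    return min(max(loh * (2.0 + x) + 0.5 * abs(x), 0.0), 1.0)


def eligible_segments(
    segments: Sequence[Segment],
    min_sites: int = 10,
    x_tol: float = 0.05,
) -> list[Segment]:
    """Select copy-neutral and single-copy gain/loss segments.

    Keeps autosomal segments with measured x = 2*seg_mean in
    [-1 - x_tol, 1 + x_tol] (the tolerance admits clonal one-copy events
    whose noisy measurement straddles |x| = 1; x is clamped to [-1, 1]
    downstream) and at least ``min_sites`` heterozygous sites. High-level
    amplifications and deep deletions are excluded.
    """
    out = []
    for s in segments:
        if normalize_chrom(s.chrom) in ("X", "Y"):
            continue
        if s.n_het_sites < min_sites:
            continue
        if abs(s.measured_cna) <= 1.0 + x_tol:
            out.append(s)
    return out


def assign_hetsites(
    segments: Sequence[Segment], hetsites: Sequence[HetSite]
) -> dict[int, list[HetSite]]:
    """Map het sites onto segments by position; sets segment_id/n_het_sites."""
    by_chrom: dict[str, list[Segment]] = {}
    index: dict[int, list[HetSite]] = {}
    for i, s in enumerate(segments):
        by_chrom.setdefault(s.chrom, []).append(s)
        s.n_het_sites = 0
        index[i] = []
    ids = {id(s): i for i, s in enumerate(segments)}
    for h in hetsites:
        for s in by_chrom.get(h.chrom, ()):
            if s.start <= h.pos <= s.end:
                i = ids[id(s)]
                h.segment_id = i
                index[i].append(h)
                s.n_het_sites += 1
                break
    return index


def per_segment_estimates(
    segments: Sequence[Segment],
    het_by_segment: dict[int, list[HetSite]],
    min_sites: int = 10,
) -> list[SegmentPurityEstimate]:
    """Build the purity decomposition for every eligible segment."""
    seg_ids = {id(s): i for i, s in enumerate(segments)}
    estimates = []
    for s in eligible_segments(segments, min_sites=min_sites):
        i = seg_ids[id(s)]
        loh = segment_loh(het_by_segment.get(i, []), min_sites=min_sites)
        if loh is None:
            continue
        x = min(max(s.measured_cna, -1.0), 1.0)
        y, inconsistent = cn_loh_fraction(x, loh)
        estimates.append(
            SegmentPurityEstimate(
                segment_id=i,
                x=x,
                loh=loh,
                y=y,
                purity=segment_purity(x, loh),
                n_het_sites=s.n_het_sites,
                model_inconsistent=inconsistent,
            )
        )
    return estimates


def estimate_sample_purity(
    estimates: Sequence[SegmentPurityEstimate],
    min_segments: int = 20,
    max_components: int = 5,
    seed: int = 0,
) -> PurityResult:
    """Cluster per-segment purity values; sample purity = highest center.

    One-dimensional Gaussian mixtures with 1..``max_components`` components
    are fitted (deterministic quantile initialization) and the component
    count is chosen by BIC. With fewer than ``min_segments`` estimates the
    result is flagged unreliable and no purity is reported.
    """
    ests = list(estimates)
    if len(ests) < min_segments:
        return PurityResult(ests, [], None, reliable=False)
    from sklearn.mixture import GaussianMixture

    values = np.asarray([e.purity for e in ests], dtype=float).reshape(-1, 1)
    n_unique = len(np.unique(np.round(values, 6)))
    best_bic, best_model = math.inf, None
    for k in range(1, min(max_components, max(n_unique, 1)) + 1):
        means_init = np.quantile(values, [(i + 0.5) / k for i in range(k)]).reshape(-1, 1)
        gm = GaussianMixture(
            n_components=k,
            means_init=means_init,
            weights_init=np.full(k, 1.0 / k),
            random_state=seed,
            reg_covar=1e-6,
            max_iter=500,
        )
        gm.fit(values)
        bic = gm.bic(values)
        if bic < best_bic:
            best_bic, best_model = bic, gm
    centers = sorted(float(m) for m in best_model.means_.ravel())
    purity = min(max(centers[-1], 0.0), 1.0)
    return PurityResult(ests, centers, purity, reliable=True)
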
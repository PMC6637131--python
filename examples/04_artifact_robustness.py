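"""Demonstrate robustness to library-artifact coverage bursts.

Short log-normal depth bursts (1-10 kb) are overlaid on a clonal simulation,
emulating the 'fractured genome' hypersegmentation that read-depth callers
suffer on artifact-ridden libraries. Naive per-window calling fragments into
thousands of segments; the regression-tree segmentation plus fixed-point
merging returns a compact profile whose truth F1 stays high.
"""

import tempfile
from pathlib import Path

from varcna import RunConfig, TruthProfile, TruthSegment, per_base_f1, run_pipeline, simulate_paired_vcf
from varcna.segmentation import naive_window_segments
from varcna.synthetic import add_artifact_noise

profile = TruthProfile(
    chrom_lengths={"1": 12_000_000, "2": 12_000_000},
    segments=[
        TruthSegment("1", 2_000_001, 4_000_000, cn_a=2, cn_b=1),
        TruthSegment("1", 7_000_001, 8_500_000, cn_a=1, cn_b=0),
        TruthSegment("2", 1_000_001, 2_200_000, cn_a=2, cn_b=1),
        TruthSegment("2", 6_000_001, 9_000_000, cn_a=1, cn_b=0),
    ],
    purity=1.0,
    mean_depth=30.0,
)

with tempfile.TemporaryDirectory() as tmp:
    clean, truth = simulate_paired_vcf(profile, Path(tmp) / "clean.vcf", seed=21)
    noisy = add_artifact_noise(clean, Path(tmp) / "noisy.vcf", burst_rate=2.0, seed=9)
    result = run_pipeline(noisy, RunConfig(seed=3))

naive = naive_window_segments(result.windows, result.config.call_tol)
cmp = per_base_f1(result.segments, truth)
print(f"naive per-window calling:  {len(naive)} segments")
print(f"pipeline (tree + merge):   {len(result.segments)} segments "
      f"({len(naive) / len(result.segments):.0f}x fewer)")
print(f"truth F1 of the pipeline profile: {cmp.f1:.4f}")
print(
    "\nThe burst artifacts flip individual windows constantly, but the"
    "\nsegmentation's complexity penalty and neighbor merging keep the final"
    "\nprofile compact and essentially correct."
)
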
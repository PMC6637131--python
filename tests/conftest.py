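"""Shared fixtures: seeded synthetic tumor-normal samples at several scales.

Everything is generated at test time by the package's own simulator; no
data files ship with the repository. Expensive simulations are
session-scoped so independent tests reuse them.
"""

from __future__ import annotations

import numpy as np
import pytest

from varcna import (
    RunConfig,
    TruthProfile,
    TruthSegment,
    run_pipeline,
    simulate_paired_vcf,
)


def make_purity_profile(purity: float, seed: int = 42) -> TruthProfile:
    """Five 10-Mb chromosomes, 25 x 300-kb single-copy CNA blocks in the
    chromosome heads, >=6-Mb diploid tails anchoring the baseline; 60x depth,
    ~1 het site per kb (~300 per CNA block)."""
    rng = np.random.default_rng(seed)
    chroms = {str(i): 10_000_000 for i in range(1, 6)}
    segments = []
    k = 0
    for c in chroms:
        pos = 300_001
        while pos + 300_000 <= 3_900_000 and k < 25:
            gain = rng.random() < 0.5
            segments.append(
                TruthSegment(
                    c, pos, pos + 299_999,
                    cn_a=2 if gain else 1, cn_b=1 if gain else 0,
                )
            )
            pos += 600_000
            k += 1
    return TruthProfile(chroms, segments, purity=purity, mean_depth=60.0)


def make_clonal_profile(mean_depth: float = 30.0) -> TruthProfile:
    """Pure tumor with four clonal +-1-copy segments >= 1 Mb on two 12-Mb
    chromosomes; the scale used for per-base concordance checks."""
    chroms = {"1": 12_000_000, "2": 12_000_000}
    segments = [
        TruthSegment("1", 2_000_001, 4_000_000, cn_a=2, cn_b=1),
        TruthSegment("1", 7_000_001, 8_500_000, cn_a=1, cn_b=0),
        TruthSegment("2", 1_000_001, 2_200_000, cn_a=2, cn_b=1),
        TruthSegment("2", 6_000_001, 9_000_000, cn_a=1, cn_b=0),
    ]
    return TruthProfile(chroms, segments, purity=1.0, mean_depth=mean_depth)


def make_semantics_profile() -> TruthProfile:
    """One 40-Mb chromosome with a 5-Mb CN-4 gain and a 5-Mb CN-1 loss in a
    pure tumor at 30x; run noiselessly for exact output-semantics checks."""
    return TruthProfile(
        chrom_lengths={"1": 40_000_000},
        segments=[
            TruthSegment("1", 5_000_001, 10_000_000, cn_a=3, cn_b=1),
            TruthSegment("1", 20_000_001, 25_000_000, cn_a=1, cn_b=0),
        ],
        purity=1.0,
        mean_depth=30.0,
    )


@pytest.fixture(scope="session")
def noiseless_run(tmp_path_factory):
    """Full pipeline result on the noiseless output-semantics simulation."""
    d = tmp_path_factory.mktemp("noiseless")
    profile = make_semantics_profile()
    vcf, truth = simulate_paired_vcf(
        profile, d / "sample.vcf", seed=1, noiseless=True, truth_path=d / "truth.tsv"
    )
    result = run_pipeline(vcf, RunConfig(seed=1))
    return profile, truth, result


@pytest.fixture(scope="session")
def clonal_run(tmp_path_factory):
    """Pipeline result + truth on the noisy clonal 30x profile."""
    d = tmp_path_factory.mktemp("clonal")
    profile = make_clonal_profile()
    vcf, truth = simulate_paired_vcf(profile, d / "sample.vcf", seed=21)
    result = run_pipeline(vcf, RunConfig(seed=3))
    return profile, truth, result, vcf
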
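"""Filtering, het-site calling, window construction, diploid baseline."""

from __future__ import annotations

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varcna.preprocess import (
    DiploidRegionError,
    apply_blacklist,
    build_windows,
    call_heterozygous,
    coverage_filter,
    infer_diploid_baseline,
    normalize_ratios,
    read_blacklist,
)
from varcna.variant_io import RunConfig, VariantRecord
from varcna.synthetic import simulate_records
from varcna import TruthProfile, TruthSegment


def rec(chrom, pos, normal_total=50, normal_mutant=None, tumor_total=60, tumor_mutant=30):
    if normal_mutant is None:
        normal_mutant = normal_total // 2
    return VariantRecord(chrom, pos, "A", "G", tumor_mutant, tumor_total, normal_mutant, normal_total)


class TestBlacklist:
    def test_half_open_containment(self, tmp_path):
        bed = tmp_path / "bl.bed"
        bed.write_text("1\t100\t200\n")
        # BED [100, 200) covers 1-based positions 101..200
        kept = apply_blacklist([rec("1", 100), rec("1", 101), rec("1", 200), rec("1", 201)], bed)
        assert [r.pos for r in kept] == [100, 201]

    def test_empty_blacklist_is_identity(self):
        records = [rec("1", 5), rec("2", 10)]
        assert apply_blacklist(records, None) == records

    def test_malformed_line_fatal_with_line_number(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("1\t100\t200\n1\tfifty\t60\n")
        with pytest.raises(ValueError, match="line 2"):
            read_blacklist(bed)


class TestCoverageFilter:
    CFG = RunConfig(min_factor=0.2, max_factor=3.0, xmin_factor=0.1, xmax_factor=3.0)

    def test_inclusive_bounds_at_median_50(self):
        records = [rec("1", p, normal_total=d) for p, d in [(1, 9), (2, 10), (3, 150), (4, 151)]]
        kept = coverage_filter(records, self.CFG, median_normal_coverage=50)
        assert [r.normal_total for r in kept] == [10, 150]

    def test_chrx_uses_x_factors(self):
        # depth 7 is below 50*0.2 but above 50*0.1: dropped on autosome, kept on chrX
        records = [rec("1", 1, normal_total=7), rec("X", 1, normal_total=7)]
        kept = coverage_filter(records, self.CFG, median_normal_coverage=50)
        assert [r.chrom for r in kept] == ["X"]

    def test_non_positive_median_fatal(self):
        with pytest.raises(ValueError):
            coverage_filter([rec("1", 1)], self.CFG, median_normal_coverage=0)

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.integers(0, 300), min_size=1, max_size=50))
    def test_idempotent(self, depths):
        records = [rec("1", i + 1, normal_total=d) for i, d in enumerate(depths)]
        once = coverage_filter(records, self.CFG, median_normal_coverage=50)
        assert coverage_filter(once, self.CFG, median_normal_coverage=50) == once


class TestCallHeterozygous:
    @pytest.mark.parametrize(
        "mutant,total,is_het",
        [(25, 50, True), (2, 50, False), (15, 50, True), (35, 50, True), (36, 50, False)],
    )
    def test_baf_thresholds_inclusive(self, mutant, total, is_het):
        sites = call_heterozygous([rec("1", 1, normal_total=total, normal_mutant=mutant)])
        assert bool(sites) is is_het

    def test_depth_floor(self):
        assert not call_heterozygous([rec("1", 1, normal_total=9, normal_mutant=4)])

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 80), st.integers(1, 80)), min_size=1, max_size=60))
    def test_every_emitted_site_in_band(self, counts):
        records = [
            rec("1", i + 1, normal_total=t, normal_mutant=min(m, t))
            for i, (m, t) in enumerate(counts)
        ]
        for h in call_heterozygous(records):
            assert 0.30 <= h.baf_normal <= 0.70
            assert h.site_loh == pytest.approx(abs(h.baf_tumor - h.baf_normal))


class TestBuildWindows:
    def test_mean_coverage_within_window(self):
        records = [rec("1", 10, tumor_total=40), rec("1", 90, tumor_total=60)]
        (w,) = build_windows(records, 100)
        assert w.mean_tumor_cov == 50 and w.n_sites == 2

    def test_floor_convention_boundaries(self):
        records = [rec("1", 1), rec("1", 100), rec("1", 101)]
        w = build_windows(records, 100)
        assert [x.window_index for x in w] == [0, 1]
        assert (w[0].start, w[0].end) == (1, 100)
        assert (w[1].start, w[1].end) == (101, 200)

    def test_empty_windows_absent(self):
        records = [rec("1", 5), rec("1", 905)]
        assert [x.window_index for x in build_windows(records, 100)] == [0, 9]

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.integers(1, 5_000), min_size=1, max_size=200, unique=True))
    def test_partition_is_exact(self, positions):
        records = [rec("1", p) for p in sorted(positions)]
        windows = build_windows(records, 100)
        assert sum(w.n_sites for w in windows) == len(records)
        assert len({w.window_index for w in windows}) == len(windows)


class TestNormalizeRatios:
    def test_semantics(self):
        records = [rec("1", 1, tumor_total=50, normal_total=50), rec("1", 101, tumor_total=100, normal_total=50)]
        w = normalize_ratios(build_windows(records, 100), baseline_ratio=1.0)
        assert w[0].log2_ratio == pytest.approx(0.0)
        assert w[1].ratio == pytest.approx(2.0) and w[1].log2_ratio == pytest.approx(1.0)

    def test_zero_normal_coverage_window_removed(self):
        records = [rec("1", 1, normal_total=0, normal_mutant=0)]
        assert normalize_ratios(build_windows(records, 100), 1.0) == []

    def test_noiseless_diploid_gives_unit_ratio_everywhere(self):
        profile = TruthProfile({"1": 500_000}, [], purity=1.0, mean_depth=30.0)
        records = simulate_records(profile, seed=0, noiseless=True)
        windows = normalize_ratios(build_windows(records, 100), 1.0)
        assert windows and all(w.ratio == pytest.approx(1.0) for w in windows)


class TestDiploidBaseline:
    def _windows(self, profile, seed=0, noiseless=True):
        records = simulate_records(profile, seed=seed, noiseless=noiseless)
        return build_windows(records, 100), call_heterozygous(records)

    def test_flat_genome_baseline_is_median_ratio(self):
        profile = TruthProfile({"1": 2_000_000}, [], purity=1.0, mean_depth=30.0)
        windows, hets = self._windows(profile)
        baseline, desc = infer_diploid_baseline(windows, hets, RunConfig())
        assert baseline == pytest.approx(1.0)

    def test_user_override_uses_specified_chromosome_only(self):
        # whole-genome duplication except chr2: automatic inference locks onto
        # the dominant duplicated state, the chr2 override recovers truth
        profile = TruthProfile(
            {"1": 12_000_000, "2": 6_000_000},
            [TruthSegment("1", 1, 12_000_000, cn_a=2, cn_b=2)],
            purity=1.0,
            mean_depth=30.0,
        )
        windows, hets = self._windows(profile)
        auto, _ = infer_diploid_baseline(windows, hets, RunConfig())
        assert auto == pytest.approx(2.0, abs=0.02)  # documented false-diploid
        override, desc = infer_diploid_baseline(windows, hets, RunConfig(diploid_region="chr2"))
        assert override == pytest.approx(1.0, abs=0.02)
        assert desc.startswith("user:")

    def test_auto_prefers_balanced_baf_mode(self):
        # 6-Mb clonal loss (LOH 0.5) vs 6-Mb diploid: same span, only the
        # diploid mode has balanced BAFs
        profile = TruthProfile(
            {"1": 12_000_000},
            [TruthSegment("1", 1, 6_000_000, cn_a=1, cn_b=0)],
            purity=1.0,
            mean_depth=30.0,
        )
        windows, hets = self._windows(profile)
        baseline, _ = infer_diploid_baseline(windows, hets, RunConfig())
        assert baseline == pytest.approx(1.0, abs=0.02)

    def test_empty_user_region_fatal(self):
        profile = TruthProfile({"1": 1_000_000}, [], purity=1.0, mean_depth=30.0)
        windows, hets = self._windows(profile)
        with pytest.raises(DiploidRegionError):
            infer_diploid_baseline(windows, hets, RunConfig(diploid_region="chr9"))
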
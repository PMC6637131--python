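"""Synthetic paired tumor-normal variant data with known copy-number truth.

The generator emulates what the caller actually consumes — per-site allele
depths — rather than reads. Germline het sites (BAF 0.5) and homozygous
filler sites are placed along abstract chromosomes; normal depth is
Poisson(mean_depth) and tumor depth Poisson scaled by the local mean copy
number. Tumor alt counts are Binomial around the expected BAF of a
three-population cell mixture (diploid cells, a CNA-carrying clone, and
optionally CN-LOH cells), which reproduces the standard BAF cluster-center
geometry: centers (1+CNA)/(2+CNA) and 1/(2+CNA) for an effective
single-copy CNA fraction x = purity * clone_fraction * (CN - 2).

A noiseless mode replaces every draw by its expectation, for exact
output-semantics checks. ``add_artifact_noise`` overlays short coverage
bursts (log-normal depth multipliers on one library) emulating the
hypersegmentation-inducing library artifacts seen in real genomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from varcna.segmentation import GAIN, LOSS, NEUTRAL, Segment
from varcna.variant_io import (
    NORMAL_TUMOR,
    TUMOR_NORMAL,
    VariantRecord,
    chrom_sort_key,
    read_paired_vcf,
)


@dataclass
class TruthSegment:
    """One true copy-number state: per-haplotype tumor copy numbers.

    ``cn_a``/``cn_b`` are the copies of the two parental haplotypes in the
    CNA-carrying clone (diploid = 1/1); ``clone_fraction`` is the fraction
    of tumor cells in that clone; ``cn_loh`` is the fraction of all cells
    with copy-neutral LOH (one haplotype duplicated, the other lost).
    """

    chrom: str
    start: int
    end: int
    cn_a: int = 1
    cn_b: int = 1
    clone_fraction: float = 1.0
    cn_loh: float = 0.0

    @property
    def total_cn(self) -> int:
        return self.cn_a + self.cn_b


@dataclass
class TruthProfile:
    """Ground-truth sample description driving the simulator."""

    chrom_lengths: dict[str, int]
    segments: list[TruthSegment] = field(default_factory=list)
    purity: float = 1.0
    het_density: float = 1.0   # germline het sites per kb
    hom_density: float = 1.0   # homozygous (alt/alt) filler sites per kb
    mean_depth: float = 30.0
    depth_overdispersion: float = 0.0  # negative-binomial knob; 0 = Poisson

    def validate(self) -> None:
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError("purity must lie in [0, 1]")
        by_chrom: dict[str, list[TruthSegment]] = {}
        for s in self.segments:
            if s.chrom not in self.chrom_lengths:
                raise ValueError(f"segment on unknown chromosome {s.chrom}")
            if not (1 <= s.start <= s.end <= self.chrom_lengths[s.chrom]):
                raise ValueError(f"segment out of chromosome bounds: {s}")
            if not 0.0 < s.clone_fraction <= 1.0:
                raise ValueError("clone fractions must lie in (0, 1]")
            if min(s.cn_a, s.cn_b) < 0:
                raise ValueError("haplotype copy numbers must be >= 0")
            by_chrom.setdefault(s.chrom, []).append(s)
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start <= a.end:
                    raise ValueError(
                        f"overlapping truth segments on {chrom}: {a} / {b}"
                    )

    def _state_at(self, chrom: str, pos: int) -> TruthSegment | None:
        for s in self.segments:
            if s.chrom == chrom and s.start <= pos <= s.end:
                return s
        return None

    def effective_x(self, seg: TruthSegment | None) -> float:
        """Fraction-weighted copy change x = purity * f * (CN - 2)."""
        if seg is None:
            return 0.0
        return self.purity * seg.clone_fraction * (seg.total_cn - 2)

    def depth_factor(self, seg: TruthSegment | None) -> float:
        """Local mean tumor copy number over 2."""
        return (2.0 + self.effective_x(seg)) / 2.0

    def expected_baf(self, seg: TruthSegment | None, alt_on_hap_a: bool) -> float:
        """Expected tumor BAF at a het site given the alt-carrying haplotype.

        Disjoint cell populations: a CNA clone (q = purity*f, only when the
        segment state differs from diploid 1/1) with (cn_a, cn_b); CN-LOH
        cells (fraction y) with (2, 0); the remainder diploid (1, 1).
        """
        if seg is None:
            q, y, cn_a, cn_b = 0.0, 0.0, 1, 1
        else:
            cn_a, cn_b = seg.cn_a, seg.cn_b
            q = self.purity * seg.clone_fraction if (cn_a, cn_b) != (1, 1) else 0.0
            y = seg.cn_loh
        if q + y > 1.0 + 1e-9:
            raise ValueError("CNA-clone and CN-LOH fractions exceed the cell total")
        rest = max(1.0 - q - y, 0.0)
        total = q * (cn_a + cn_b) + y * 2.0 + rest * 2.0
        a_copies = q * cn_a + y * 2.0 + rest * 1.0
        b_copies = q * cn_b + y * 0.0 + rest * 1.0
        return (a_copies if alt_on_hap_a else b_copies) / total

    def truth_segments(self, call_tol: float = 0.1) -> list[Segment]:
        """The true CNA profile as classified segments (neutral gaps included)."""
        out: list[Segment] = []

        def emit(chrom: str, start: int, end: int, seg: TruthSegment | None) -> None:
            if end < start:
                return
            factor = self.depth_factor(seg)
            s = Segment(
                chrom=chrom,
                start=start,
                end=end,
                n_windows=0,
                mean_log2=math.log2(factor),
                seg_mean=factor - 1.0,
                gmean=2.0 * factor,
            )
            if s.seg_mean >= call_tol:
                s.cna_class = GAIN
            elif s.seg_mean <= -call_tol:
                s.cna_class = LOSS
            else:
                s.cna_class = NEUTRAL
            out.append(s)

        for chrom in sorted(self.chrom_lengths, key=chrom_sort_key):
            cursor = 1
            for seg in sorted(
                (s for s in self.segments if s.chrom == chrom), key=lambda s: s.start
            ):
                emit(chrom, cursor, seg.start - 1, None)
                emit(chrom, seg.start, seg.end, seg)
                cursor = seg.end + 1
            emit(chrom, cursor, self.chrom_lengths[chrom], None)
        return out


def _draw_depth(rng: np.random.Generator, mean: float, overdispersion: float) -> int:
    if mean <= 0:
        return 0
    if overdispersion > 0:
        # negative binomial with variance mean * (1 + overdispersion)
        r = mean / overdispersion
        p = 1.0 / (1.0 + overdispersion)
        return int(rng.negative_binomial(r, p))
    return int(rng.poisson(mean))


def simulate_records(
    profile: TruthProfile, seed: int = 0, noiseless: bool = False
) -> list[VariantRecord]:
    """Generate the per-site allele-count records for a truth profile."""
    profile.validate()
    rng = np.random.default_rng(seed)
    records: list[VariantRecord] = []
    for chrom in sorted(profile.chrom_lengths, key=chrom_sort_key):
        length = profile.chrom_lengths[chrom]
        n_het = int(length / 1000 * profile.het_density)
        n_hom = int(length / 1000 * profile.hom_density)
        # site density is sparse relative to the chromosome, so drawing with
        # replacement and deduplicating loses almost nothing
        positions = np.unique(rng.integers(1, length + 1, size=n_het + n_hom))
        is_het = np.zeros(len(positions), dtype=bool)
        het_idx = rng.choice(len(positions), size=min(n_het, len(positions)), replace=False)
        is_het[het_idx] = True
        alt_on_a = rng.random(len(positions)) < 0.5
        for pos, het, on_a in zip(positions, is_het, alt_on_a):
            pos = int(pos)
            seg = profile._state_at(chrom, pos)
            factor = profile.depth_factor(seg)
            if het:
                p_normal, p_tumor = 0.5, profile.expected_baf(seg, bool(on_a))
            else:
                p_normal, p_tumor = 1.0, 1.0
            if noiseless:
                n_tot = int(round(profile.mean_depth))
                t_tot = int(round(profile.mean_depth * factor))
                n_alt = int(round(n_tot * p_normal))
                t_alt = int(round(t_tot * p_tumor))
            else:
                n_tot = _draw_depth(rng, profile.mean_depth, profile.depth_overdispersion)
                t_tot = _draw_depth(
                    rng, profile.mean_depth * factor, profile.depth_overdispersion
                )
                n_alt = int(rng.binomial(n_tot, p_normal)) if n_tot else 0
                t_alt = int(rng.binomial(t_tot, p_tumor)) if t_tot else 0
            records.append(
                VariantRecord(chrom, pos, "A", "G", t_alt, t_tot, n_alt, n_tot)
            )
    return records


def write_paired_vcf(
    records: Sequence[VariantRecord],
    path: str | Path,
    sample_order: str = TUMOR_NORMAL,
    contigs: dict[str, int] | None = None,
) -> None:
    """Write records as a two-sample VCF 4.2 with GT:AD:DP genotype fields."""
    names = ("TUMOR", "NORMAL") if sample_order == TUMOR_NORMAL else ("NORMAL", "TUMOR")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if contigs:
            for chrom in sorted(contigs, key=chrom_sort_key):
                fh.write(f"##contig=<ID={chrom},length={contigs[chrom]}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(names)
            + "\n"
        )
        for r in sorted(records, key=lambda r: (chrom_sort_key(r.chrom), r.pos)):
            n_gt = "1/1" if r.normal_total and r.normal_mutant / r.normal_total > 0.85 else "0/1"
            tumor = f"0/1:{r.tumor_total - r.tumor_mutant},{r.tumor_mutant}:{r.tumor_total}"
            normal = f"{n_gt}:{r.normal_total - r.normal_mutant},{r.normal_mutant}:{r.normal_total}"
            first, second = (tumor, normal) if sample_order == TUMOR_NORMAL else (normal, tumor)
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref_allele}\t{r.alt_allele}\t.\tPASS\t.\t"
                f"GT:AD:DP\t{first}\t{second}\n"
            )


def write_truth_table(segments: Sequence[Segment], path: str | Path) -> None:
    """Tab-delimited ground-truth segment table."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tseg.mean\tgmean\tcna.class\n")
        for s in segments:
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.seg_mean:.6f}\t{s.gmean:.6f}\t{s.cna_class}\n"
            )


def simulate_paired_vcf(
    profile: TruthProfile,
    vcf_path: str | Path,
    seed: int = 0,
    sample_order: str = TUMOR_NORMAL,
    noiseless: bool = False,
    truth_path: str | Path | None = None,
) -> tuple[Path, list[Segment]]:
    """Simulate a paired tumor-normal VCF plus its ground-truth CNA profile."""
    records = simulate_records(profile, seed=seed, noiseless=noiseless)
    write_paired_vcf(records, vcf_path, sample_order=sample_order, contigs=profile.chrom_lengths)
    truth = profile.truth_segments()
    if truth_path is not None:
        write_truth_table(truth, truth_path)
    return Path(vcf_path), truth


def burst_intervals(
    chrom_extents: dict[str, int],
    burst_rate: float,
    burst_len: tuple[int, int],
    rng: np.random.Generator,
) -> dict[str, list[tuple[int, int, float, int]]]:
    """Place (start, end, log-normal factor, sample index) bursts per chromosome."""
    out: dict[str, list[tuple[int, int, float, int]]] = {}
    for chrom, extent in chrom_extents.items():
        n = rng.poisson(burst_rate * extent / 1e6)
        ivs = []
        for _ in range(n):
            start = int(rng.integers(1, max(extent - burst_len[1], 2)))
            length = int(rng.integers(burst_len[0], burst_len[1] + 1))
            ivs.append(
                (start, start + length - 1, float(rng.lognormal(0.0, 1.0)), int(rng.integers(2)))
            )
        out[chrom] = sorted(ivs)
    return out


def add_artifact_noise(
    vcf_in: str | Path,
    vcf_out: str | Path,
    burst_rate: float = 2.0,
    burst_amplitude: float = 1.0,
    seed: int = 0,
    burst_len: tuple[int, int] = (1000, 10000),
) -> Path:
    """Overlay library-artifact coverage bursts on a simulated paired VCF.

    Depths inside random short bursts (default 1-10 kb, ``burst_rate`` per
    Mb) are multiplied by log-normal factors with scale
    ``burst_amplitude``; each burst hits one library (tumor or normal)
    chosen at random. Allele fractions are preserved (alt counts rescale
    with the depth), so only the coverage signal is perturbed. With
    ``burst_rate`` 0 the file passes through unchanged.
    """
    records = list(read_paired_vcf(vcf_in, TUMOR_NORMAL))
    rng = np.random.default_rng(seed)
    extents: dict[str, int] = {}
    for r in records:
        extents[r.chrom] = max(extents.get(r.chrom, 0), r.pos)
    bursts = burst_intervals(extents, burst_rate, burst_len, rng)
    # per-chromosome sweep; burst lists are short so a linear scan is fine
    out: list[VariantRecord] = []
    for r in records:
        factor_t = factor_n = 1.0
        for start, end, fac, which in bursts.get(r.chrom, ()):
            if start <= r.pos <= end:
                fac = fac ** burst_amplitude
                if which == 0:
                    factor_t *= fac
                else:
                    factor_n *= fac
        if factor_t == 1.0 and factor_n == 1.0:
            out.append(r)
            continue
        t_tot = max(int(round(r.tumor_total * factor_t)), 0)
        n_tot = max(int(round(r.normal_total * factor_n)), 0)
        t_alt = int(round(t_tot * (r.tumor_mutant / r.tumor_total))) if r.tumor_total else 0
        n_alt = int(round(n_tot * (r.normal_mutant / r.normal_total))) if r.normal_total else 0
        out.append(
            VariantRecord(
                r.chrom, r.pos, r.ref_allele, r.alt_allele,
                min(t_alt, t_tot), t_tot, min(n_alt, n_tot), n_tot,
            )
        )
    write_paired_vcf(out, vcf_out, TUMOR_NORMAL, contigs=extents)
    return Path(vcf_out)
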
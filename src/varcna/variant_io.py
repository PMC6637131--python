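"""Parsing of paired tumor-normal variant files into allele-count records.

Three input dialects are supported — VCF 4.x with two genotype columns,
MAF, and Bambino-style tab-delimited variant tables — all reduced to the
same per-site quadruple of counts: alt-supporting reads and total depth in
the tumor and in the matched normal. No raw reads are touched; every
downstream quantity (coverage windows, B-allele frequencies, segments,
purity) derives from these four integers per site.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

#: canonical autosome + X ordering used for every deterministic sort
_KARYOTYPE = {str(i): i for i in range(1, 23)}
_KARYOTYPE["X"] = 23

TUMOR_NORMAL = "tumor_normal"
NORMAL_TUMOR = "normal_tumor"


class VariantFileError(ValueError):
    """Fatal, unrecoverable problem with an input variant file."""


def normalize_chrom(name: str) -> str:
    """Map chromosome names to a canonical prefix-free form (``chr1`` -> ``1``)."""
    name = name.strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    if name in ("M", "MT", "mt"):
        return "MT"
    return name.upper() if name.lower() in ("x", "y") else name


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Karyotype order 1..22, X; anything else appended lexicographically."""
    c = normalize_chrom(chrom)
    return (_KARYOTYPE.get(c, 1000), c)


@dataclass(frozen=True)
class VariantRecord:
    """One bi-allelic SNV with paired tumor/normal allele counts."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    tumor_mutant: int
    tumor_total: int
    normal_mutant: int
    normal_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.tumor_mutant <= self.tumor_total):
            raise ValueError(
                f"tumor counts out of range at {self.chrom}:{self.pos}: "
                f"{self.tumor_mutant}/{self.tumor_total}"
            )
        if not (0 <= self.normal_mutant <= self.normal_total):
            raise ValueError(
                f"normal counts out of range at {self.chrom}:{self.pos}: "
                f"{self.normal_mutant}/{self.normal_total}"
            )
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")


@dataclass
class RunConfig:
    """Pipeline parameters mirroring the tool's run-time options.

    The coverage filter keeps a site when its normal-sample depth lies in
    ``[median * min_factor, median * max_factor]`` (the X-chromosome factors
    substitute on chrX). ``median_normal_coverage`` may be supplied or left
    to be computed from the data.
    """

    sample_order: str = TUMOR_NORMAL
    diploid_region: str | None = None
    median_normal_coverage: float | None = None
    min_factor: float = 0.2
    max_factor: float = 3.0
    xmin_factor: float = 0.1
    xmax_factor: float = 3.0
    window_size: int = 100
    blacklist_path: str | None = None
    # heterozygous-site calling
    het_baf_low: float = 0.30
    het_baf_high: float = 0.70
    het_min_depth: int = 10
    # segmentation
    min_windows: int = 5
    min_gain: float = 1e-3
    merge_tol: float = 0.1
    call_tol: float = 0.1
    # purity
    min_het_sites: int = 10
    min_purity_segments: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_order not in (TUMOR_NORMAL, NORMAL_TUMOR):
            raise ValueError(f"unknown sample_order {self.sample_order!r}")
        if not self.min_factor < self.max_factor:
            raise ValueError("min_factor must be < max_factor")
        if not self.xmin_factor < self.xmax_factor:
            raise ValueError("xmin_factor must be < xmax_factor")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")


@dataclass
class CoverageSummary:
    """Mean/median normal-sample depth across usable variants."""

    mean: float
    median: float
    n_records: int


def _vcf_sample_counts(variant, idx: int) -> tuple[int, int] | None:
    """Extract (mutant, total) for sample *idx*; AD preferred, DP fallback."""
    ad = None
    try:
        ad = variant.format("AD")
    except KeyError:
        ad = None
    if ad is not None:
        row = [int(v) for v in ad[idx] if v >= 0]
        if len(row) >= 2:
            return row[1], row[0] + row[1]
        if len(row) == 1:
            # single AD value read as the alt count; pair it with DP
            try:
                dp = variant.format("DP")
            except KeyError:
                dp = None
            if dp is not None and int(dp[idx][0]) >= 0:
                return row[0], int(dp[idx][0])
    return None


def read_paired_vcf(
    path: str | Path, sample_order: str = TUMOR_NORMAL
) -> Iterator[VariantRecord]:
    """Yield one :class:`VariantRecord` per usable bi-allelic SNV row.

    Tumor/normal assignment of the two genotype columns follows
    ``sample_order``; indels, multi-allelic rows and rows without usable
    allele depths are skipped (counts logged at the end).
    """
    from cyvcf2 import VCF

    if sample_order not in (TUMOR_NORMAL, NORMAL_TUMOR):
        raise ValueError(f"unknown sample_order {sample_order!r}")
    vcf = VCF(str(path))
    if len(vcf.samples) < 2:
        raise VariantFileError(
            f"{path}: paired analysis needs two genotype columns, "
            f"found {len(vcf.samples)}"
        )
    t_idx, n_idx = (0, 1) if sample_order == TUMOR_NORMAL else (1, 0)
    skipped = {"multiallelic": 0, "indel": 0, "no_depth": 0, "bad_row": 0}
    n_emitted = 0
    for v in vcf:
        if len(v.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        ref, alt = v.REF, v.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or alt in (".", "*"):
            skipped["indel"] += 1
            continue
        tumor = _vcf_sample_counts(v, t_idx)
        normal = _vcf_sample_counts(v, n_idx)
        if tumor is None or normal is None:
            skipped["no_depth"] += 1
            continue
        try:
            yield VariantRecord(
                normalize_chrom(v.CHROM), v.POS, ref, alt,
                tumor[0], tumor[1], normal[0], normal[1],
            )
            n_emitted += 1
        except ValueError:
            skipped["bad_row"] += 1
    if n_emitted == 0 and skipped["no_depth"] > 0 and skipped["no_depth"] >= sum(
        v for k, v in skipped.items() if k != "no_depth"
    ):
        raise VariantFileError(
            f"{path}: no row carries a usable allele-depth (AD/DP) field"
        )
    if any(skipped.values()):
        logger.info("read_paired_vcf skipped rows: %s", skipped)


_BAMBINO_COLUMNS = [
    "chrom", "pos", "ref_allele", "alt_allele",
    "tumor_mutant", "tumor_total", "normal_mutant", "normal_total",
]


def read_bambino(path: str | Path) -> Iterator[VariantRecord]:
    """Read a Bambino-style tab-delimited variant table.

    Accepts a headered table carrying the eight canonical columns (any
    order, extra columns ignored) or a headerless eight-column layout
    ``chrom pos ref alt tumor_mutant tumor_total normal_mutant normal_total``.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        logger.warning("%s: empty variant table", path)
        return
    first = lines[0].split("\t")
    if set(_BAMBINO_COLUMNS) <= set(first):
        idx = {c: first.index(c) for c in _BAMBINO_COLUMNS}
        body = lines[1:]
    else:
        if len(first) < 8:
            raise VariantFileError(
                f"{path}: need the 8 columns {_BAMBINO_COLUMNS}, "
                f"got {len(first)} unlabeled columns"
            )
        idx = {c: i for i, c in enumerate(_BAMBINO_COLUMNS)}
        body = lines
    for lineno, ln in enumerate(body, start=1):
        f = ln.split("\t")
        try:
            yield VariantRecord(
                normalize_chrom(f[idx["chrom"]]),
                int(f[idx["pos"]]),
                f[idx["ref_allele"]],
                f[idx["alt_allele"]],
                int(f[idx["tumor_mutant"]]),
                int(f[idx["tumor_total"]]),
                int(f[idx["normal_mutant"]]),
                int(f[idx["normal_total"]]),
            )
        except (ValueError, IndexError) as exc:
            logger.error("%s line %d rejected: %s", path, lineno, exc)


def write_bambino(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write records in the headered tab-delimited layout ``read_bambino`` reads."""
    with open(path, "w") as fh:
        fh.write("\t".join(_BAMBINO_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.ref_allele}\t{r.alt_allele}\t"
                f"{r.tumor_mutant}\t{r.tumor_total}\t"
                f"{r.normal_mutant}\t{r.normal_total}\n"
            )


_MAF_REQUIRED = [
    "Chromosome", "Start_Position", "Reference_Allele", "Tumor_Seq_Allele2",
    "t_alt_count", "t_ref_count", "n_alt_count", "n_ref_count",
]


def read_maf(path: str | Path) -> Iterator[VariantRecord]:
    """Read a MAF; tumor/normal totals are ref+alt count sums."""
    path = Path(path)
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            if ln.startswith("#") or not ln.strip():
                continue
            f = ln.rstrip("\n").split("\t")
            if header is None:
                header = f
                missing = [c for c in _MAF_REQUIRED if c not in header]
                if missing:
                    raise VariantFileError(f"{path}: MAF lacks columns {missing}")
                idx = {c: header.index(c) for c in _MAF_REQUIRED}
                continue
            try:
                t_alt = int(f[idx["t_alt_count"]])
                t_ref = int(f[idx["t_ref_count"]])
                n_alt = int(f[idx["n_alt_count"]])
                n_ref = int(f[idx["n_ref_count"]])
                ref = f[idx["Reference_Allele"]]
                alt = f[idx["Tumor_Seq_Allele2"]]
                if len(ref) != 1 or len(alt) != 1 or "-" in (ref, alt):
                    continue  # indel
                yield VariantRecord(
                    normalize_chrom(f[idx["Chromosome"]]),
                    int(f[idx["Start_Position"]]),
                    ref, alt, t_alt, t_alt + t_ref, n_alt, n_alt + n_ref,
                )
            except (ValueError, IndexError) as exc:
                logger.warning("%s line %d skipped: %s", path, lineno, exc)


def snv_counts(
    records: Iterable[VariantRecord],
) -> tuple[list[VariantRecord], CoverageSummary]:
    """Materialize and sort records; summarize normal-sample coverage.

    Records are ordered by (karyotype chromosome, position); duplicate
    positions on a chromosome keep the first occurrence. Raises
    :class:`VariantFileError` on an empty stream.
    """
    recs = sorted(records, key=lambda r: (chrom_sort_key(r.chrom), r.pos))
    if not recs:
        raise VariantFileError("no usable variants in input")
    deduped: list[VariantRecord] = []
    for r in recs:
        if deduped and deduped[-1].chrom == r.chrom and deduped[-1].pos == r.pos:
            continue
        deduped.append(r)
    depths = [r.normal_total for r in deduped]
    summary = CoverageSummary(
        mean=statistics.fmean(depths),
        median=float(statistics.median(depths)),
        n_records=len(deduped),
    )
    return deduped, summary
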
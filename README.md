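# varcna

Somatic copy-number alteration (CNA) calling and tumor purity estimation
from **paired tumor–normal variant files** — no BAM/CRAM access required.

Cancer genomes gain and lose chromosomal segments; detecting those events
normally means re-processing the raw sequencing reads. `varcna` instead
works from what a variant caller has already produced: the per-site allele
depths in a two-sample VCF (or MAF, or a Bambino-style variant table). That
makes CNA analysis possible when only variant calls are shareable or
practical to move, and makes the result platform-independent. The intended
users are cancer-genomics analysts with paired tumor–normal WGS/WXS variant
calls in hand.

## Method

1. **Site extraction.** Every bi-allelic SNV row yields four counts:
   `TumorMutant, TumorTotal, NormalMutant, NormalTotal`. Sites in a BED
   blacklist of suspicious SNPs, and sites whose normal depth falls outside
   `[median·minfactor, median·maxfactor]` (chrX has its own factors), are
   dropped. Germline-heterozygous sites (normal BAF in [0.30, 0.70], depth
   ≥ 10) are kept for allelic-imbalance analysis.
2. **Coverage windows.** Fixed 100-bp windows carry the mean tumor and
   normal depth of their sites; windows without variants are ignored. The
   tumor/normal ratio is normalized to a diploid baseline, inferred
   automatically (the large-segment coverage mode whose heterozygous BAFs
   are balanced) or set by the user (`--diploid-chrom`).
3. **Segmentation.** A recursive-partitioning regression tree splits each
   chromosome's log2-ratio sequence at the maximal sum-of-squared-error
   reduction, with a size-dependent complexity penalty as stopping rule;
   near-equal neighbors merge to a fixed point. Each segment reports
   `seg.mean = r − 1` (0.5 per copy: +1.0 = 2-copy gain, −0.5 = 1-copy
   loss) and `gmean = 2r` (absolute scale, diploid = 2.0), where `r` is the
   baseline-relative coverage ratio.
4. **Purity.** At a heterozygous site in a region of measured CNA, the
   tumor B-allele frequency splits into clusters at `(1+CNA)/(2+CNA)` and
   `1/(2+CNA)`, separated by `2·LOH`. With `x` the cell fraction carrying a
   single-copy gain/loss (`x = 2·seg.mean`) and `y` the copy-neutral-LOH
   fraction,

       LOH = (2y + |x|) / (4 + 2x)
       y      = LOH·(2+x) − |x|/2
       purity = |x| + y = LOH·(2+x) + |x|/2

   Each copy-neutral or single-copy gain/loss segment (−1 ≤ x ≤ 1, ≥ 10 het
   sites) contributes one estimate; a 1-D Gaussian mixture (1–5 components,
   BIC-selected) clusters them and the **highest cluster center** is the
   sample purity. At least 20 segment estimates are required, otherwise no
   purity is reported.

A first-class simulator (`varcna.synthetic`) generates paired tumor–normal
VCFs with known segmental copy number, purity, subclones, CN-LOH and
optional library-artifact coverage bursts, so the whole pipeline is testable
without controlled-access data.

## Worked example

```sh
python examples/01_call_cnas.py
```

simulates a pure tumor with four clonal one-copy events at 30× and prints:

```
diploid baseline ratio 1.0000 (auto:1:8502401-15999100)
chrom      start       end  windows  seg.mean   gmean  class
1            401   1999800     3619    -0.000   2.000  neutral
1        2000101   3999900     3629     0.504   3.008  gain
1        4000901   6999300     5449    -0.002   1.995  neutral
1        7000101   8500800     2638    -0.510   0.980  loss
...
```

The gain segment sits at `seg.mean ≈ +0.5` (one extra copy, `gmean ≈ 3`),
the loss at `−0.5` (one copy left, `gmean ≈ 1`), and diploid regions at
`seg.mean ≈ 0` / `gmean ≈ 2` — the output scale contract. The other
examples cover purity estimation (`02`, recovers a simulated 70%-purity
sample as 0.700), per-base F1 profile comparison (`03`), and robustness to
library-artifact coverage bursts (`04`, a 12-segment final profile where
naive per-window calling fragments into ~20,000).

The same pipeline runs from the shell:

```sh
varcna simulate profile.yaml --out sample.vcf --truth truth.tsv --seed 4
varcna run sample.vcf --out-dir out --sample-order TN
varcna evaluate out/sample.cna.txt other_profile.txt --out comparison.json
```

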
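# Methods

## Scope and model

`varcna` infers somatic copy-number alterations (CNAs) and tumor purity
from the allele depths of a paired tumor–normal variant file. The model
assumes: bi-allelic SNVs; a matched normal defining germline genotypes; a
tumor sample that is a mixture of normal cells and tumor cells whose CNAs
are segmental and piecewise constant; and a diploid state present somewhere
in the genome to anchor the coverage scale. Two signals are used:

* the **coverage ratio** of tumor to normal read depth, averaged in 100-bp
  windows, which measures total copy number, and
* the **B-allele frequency (BAF)** of germline-heterozygous sites, whose
  deviation from 0.5 (allelic imbalance, "LOH" here) measures haplotype
  imbalance.

For a region in which a fraction `x` of cells carries a single-copy gain
(`x > 0`) or loss (`x < 0`) and a disjoint fraction `y` carries
copy-neutral LOH, the heterozygous-site BAFs concentrate at
`(1+CNA)/(2+CNA)` and `1/(2+CNA)` (centers symmetric about 0.5, separation
`2·LOH`), and the combined imbalance is `LOH = (2y+|x|)/(4+2x)`. Inverting
gives `y = LOH·(2+x) − |x|/2` and the per-segment purity
`|x| + y = LOH·(2+x) + |x|/2`. These identities hold exactly for
`−1 ≤ x ≤ 1`; segments outside that range (high-level amplification, deep
deletion) are excluded from purity estimation.

## Pipeline stages and parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `window_size` | 100 bp | fixed coverage-window width |
| `min_factor`, `max_factor` | 0.2, 3.0 | normal-depth range, × median (autosomes); brackets typical normal-coverage dispersion |
| `xmin_factor`, `xmax_factor` | 0.1, 3.0 | same for chrX (hemizygous males halve the depth) |
| `het_baf_low/high`, `het_min_depth` | 0.30–0.70, 10 | heterozygous-site band; bounds the binomial miscall risk at 30–60× |
| `min_windows` | 5 | smallest segment side considered by a split |
| `min_gain` | 1e-3 | floor on the relative SSE reduction of an accepted split |
| `merge_tol` | 0.1 (log2) | neighbor-merge tolerance; half of the smallest event the purity model targets |
| `call_tol` | 0.1 (seg.mean) | gain/loss call threshold ≈ half a 20%-purity single-copy event |
| `min_het_sites` | 10 | minimum sites per segment for an LOH estimate |
| `min_purity_segments` | 20 | estimates required before a sample purity is reported |

Boundary conventions: the coverage range and the heterozygous band are
inclusive on both ends; BED blacklists are 0-based half-open; windows and
segments are 1-based inclusive; chromosomes sort in karyotype order
1..22, X (chrY and mitochondrial records are dropped — the het-site model
assumes two germline haplotypes).

### Segmentation stopping rule

At each tree node the split maximizing the SSE reduction of the window
log2 ratios is taken (leftmost on ties, so the procedure is deterministic).
A split is accepted when both children keep ≥ `min_windows` windows and the
relative reduction clears `max(min_gain, min(0.5, 6·ln n/n))` for node size
`n`. The size-dependent term is a regression-tree complexity penalty: under
pure noise the maximal relative reduction concentrates near `2·ln n/n`
(measured 3–7× below the penalty for n = 10²..10⁴), so recursion stops on
noise at every scale, while a flat threshold would either fracture large
pure segments or reject the weak first split on low-amplitude profiles. On
noiseless piecewise-constant input the penalty (capped at 0.5) always
admits a true breakpoint, whose relative reduction is 1. Merging then
absorbs any neighbor pair whose means differ by < `merge_tol`, repeating
left-to-right passes to a fixed point with count-weighted means.

### Diploid baseline

With a user region, the baseline is the median raw ratio of its windows.
Automatically, a provisional segmentation of the raw ratios is grouped into
coverage modes (gap > 0.1 log2) over segments spanning ≥ 5 Mb, and the mode
whose pooled heterozygous sites show the smallest median site imbalance is
called diploid (ties broken toward the larger mode). A genome dominated by
a *balanced* duplication (2+2 haplotypes) presents the same balanced-BAF
signature as diploid and wins the tie by size — genome-wide duplication is
therefore mis-normalized by construction, as for any read-depth method; the
user override is the escape hatch. When no segment reaches 5 Mb the
genome-wide median ratio is used, which is biased when CNAs occupy a large
genome fraction.

### Segment LOH estimator

Tumor BAFs are folded about 0.5; the fold distance equals the LOH. An exact
1-D two-population split of the folded values is trusted only when its
separation exceeds `max(0.1, 2.5·mean binomial BAF sd)` — folding a
unimodal noisy cloud already produces a spurious split separation of about
1.5 noise sd. Otherwise the unimodal estimate
`d² = mean((baf_t − baf_n)²) − mean(p(1−p)/depth terms)` is used; the
variance subtraction removes the upward noise bias that would otherwise
convert sampling noise into phantom purity on neutral segments (~0.09 at
60×). LOH is capped at 0.5.

### Purity clustering

Per-segment purity values are clustered with scikit-learn Gaussian
mixtures, k = 1..5, deterministic quantile initialization, BIC selection;
the sample purity is the highest component mean, clamped to [0, 1]. The
package clusters *per-segment* estimates (one value per eligible segment);
clustering per-site values would weight long segments more heavily and is
not done. Eligibility admits `|x| ≤ 1.05` before clamping `x` to ±1: the
measurement of a truly clonal one-copy event straddles |x| = 1, and a hard
cutoff would discard half of exactly the most informative segments in
near-pure samples.

## The simulator

`varcna.synthetic` emulates what the caller consumes, not reads: germline
het sites (normal BAF 0.5) and homozygous filler sites at ~1/kb each,
Poisson depths (negative-binomial overdispersion available, off by
default), binomial allele counts around the analytic BAF centers for a
three-population cell mixture (diploid cells, one CNA clone per segment,
optional CN-LOH cells), and log-normal coverage bursts confined to 1–10 kb
stretches of one library to mimic library-construction artifacts. A
noiseless mode replaces draws by expectations for exact semantics checks.
It does **not** model GC/mappability waves, mapping errors, allele-specific
sequencing bias, germline CNVs or multi-clone phylogenies — passing tests
demonstrate the estimators' correctness under the stated sampling model,
not performance on real libraries.

Test and acceptance problem sizes are chosen at desk scale: 10–40 Mb
synthetic genomes (~2 sites/kb, i.e. 2–8 × 10⁴ sites), 30× coverage for
profile-shape checks and 60× with ~300 het sites per segment for purity
recovery, which keeps the full suite in tens of seconds while leaving every
estimator in its intended operating regime.

## Output semantics

`seg.mean = r − 1` and `gmean = 2r` for baseline-relative ratio `r`:
diploid → (0, 2.0), clonal one-copy loss → (−0.5, 1.0), two-copy loss →
(−1.0, 0), one/two-copy gain → (+0.5, 3.0) / (+1.0, 4.0). On the gmean
scale a one-copy loss is 1.0; a legacy description of this field that
placed one-copy loss at 0.5 is inconsistent with a linear copy scale and is
deliberately not reproduced.

## Known limitations

* **Genome-wide duplication** is invisible to the automatic baseline (see
  above); specify a known-diploid region instead.
* **Subclone-confined CNAs** bias the purity estimate toward the clone
  fraction: `x` measures *cells carrying the event*, so a pure tumor whose
  CNAs sit in a 50% subclone is reported near 0.5. The tests reproduce
  this failure mode deliberately.
* **Focal events** below the typical SNP spacing (a few kb) are
  under-detected — windows with no variants carry no signal; read-depth
  callers retain the advantage for focal low-amplitude CNAs.
* Purity is undefined for near-CNA-free samples (fewer than 20 eligible
  segment estimates) and does not deconvolve multiple subclones.
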
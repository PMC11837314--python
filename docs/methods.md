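# Methods

## Signal model

A genotyping array reports, per probe, a Log2 R ratio (LRR: total intensity
relative to a diploid reference) and a B-allele frequency (BAF: the fraction
of signal attributable to the B allele). Copy-number changes shift LRR;
allelic imbalance in a mosaic cell population shifts the BAF of heterozygous
sites away from 0.5.

Observed LRR understates a true copy change: a one-copy deletion from the
diploid state produces a mean LRR of about −0.45, not the theoretical −1.
The package therefore rescales LRR by a **scale factor** `s` (default 0.45,
a parameter rather than a constant because it is an empirical, platform-level
approximation):

```
CN_observed = CN_expected · 2^(LRR / s)
```

For the male-specific Y region (MSY; CN_expected = 1 in normal male cells),
the median LRR over MSY probes (mLRR_Y) gives the cell fraction with Y loss:

```
CF_mLRR_Y = 1 − 2^(mLRR_Y / s)
```

For PAR1 (diploid in males), a fraction CF of cells missing the Y PAR copy
shifts heterozygote BAF to 0.5 ± Bdev with

```
CF_BAF = 4·Bdev / (1 + 2·Bdev)    ⇔    Bdev = CF / (4 − 2·CF)
```

Both CF maps are strictly monotone and mutually inverse with their
counterparts; the test suite checks the round trips to 1e−12 on dense grids.

A negative raw `CF_mLRR_Y` (mLRR_Y > 0, i.e. Y intensity above the one-copy
level) is not a cell fraction. `cf_from_mlrry` returns the signed value and a
separate clamped accessor truncates to [0, 1]; the caller withholds the CF
and flags the sample `positive_mlrry` when mLRR_Y > 0, because such samples
must be excluded from between-method comparisons rather than silently mapped
to zero.

## Calling procedure and defaults

Per sample:

| Quantity | Definition | Default gate |
| --- | --- | --- |
| `mlrr_y` | median LRR over MSY probes with non-missing LRR | ≥ 30 probes |
| mLOY decision | `mlrr_y ≤ threshold`, inclusive | threshold −0.15 |
| `bdev` | median \|BAF − 0.5\| over PAR1 probes genotyped AB | ≥ 30 heterozygotes |
| `call_rate` | fraction of probes with a non-NC genotype | flag if < 0.97 |
| `baf_auto` | lag-1 autocorrelation of (BAF − 0.5), autosomal probes in genomic order | flag if > 0.03 |
| `rel_cov_par1` | `2 · 2^(median PAR1 LRR / s)` | flag if ≥ 2.5 |

The −0.15 threshold corresponds to a detection floor of
CF = 1 − 2^(−0.15/0.45) ≈ 20.6%: lower cell fractions leave mLRR_Y above the
threshold in expectation. The 30-probe minima reflect the coverage level at
which the median (and the Bdev estimate) become stable; arrays with fewer
PAR1 heterozygotes are exactly the motivation for the LRR route.

QC failures *flag* a sample; they never erase measurements, so borderline
samples remain auditable downstream. No-call and negative are distinct
states throughout, with enumerated absence reasons
(`no_msy_coverage`, `too_few_par1_het`, `positive_mlrry`, ...).

Design notes on the two statistics that have no universal definition:

* **Bdev is phase-free here.** The phased-haplotype estimator of dedicated
  mosaic-alteration pipelines is out of scope (it requires external phasing),
  so Bdev is the median absolute BAF deviation at PAR1 heterozygotes — the
  quantity one reads directly off the split BAF bands. It agrees with the
  phased estimator when heterozygotes are correctly genotyped and inherits
  the same high-CF failure mode (see below). Users with precomputed phased
  calls can supply them instead.
* **`baf_auto` is a surrogate.** The upstream QC statistic of that name is
  pipeline-specific and not publicly defined; the lag-1 autocorrelation of
  autosomal BAF deviations captures the same failure signature (spatially
  structured BAF drift from contamination or widespread mosaicism, which
  white measurement noise does not produce). Likewise `rel_cov` is computed
  by the package's own copy-number rescaling of the PAR1 median LRR.
* An event-size filter (> 2 MB) used by segment-based callers is satisfied
  by construction for whole-chromosome Y loss and is not applied.

## Method comparison

Samples with both CF estimates and mLRR_Y < 0 are paired; exclusions are
counted by reason. Agreement is the squared Pearson correlation of the raw
pairs (not a regression fit). For the binned view, pairs are sorted by
mLRR_Y (ties broken by sample id, stable sort) and split into equal-size
bins — sizes differ by at most one, remainders assigned from the first bin —
and min/max/median/mean of each CF estimate are reported per bin together
with the R² of the bin medians. Because the two routes carry independent
per-sample noise, bin medians average it out and the binned R² exceeds the
pairwise R²; the test suite asserts this over ≥ 50 seeded replicates.

## Simulator

The generator inverts the signal model with known per-sample truth:

* MSY LRR ~ Normal(`s · log2(max(1 − CF, cn_floor))`, `sigma_lrr`); no BAF
  (the region is haploid; arrays report nothing usable there).
* PAR1: heterozygous with probability `het_fraction`; true-het BAF at
  0.5 ± Bdev(CF) (equiprobable sign) plus Normal(0, `sigma_baf`), clipped to
  [0, 1]; homozygote BAF near 0/1 plus noise. PAR1 LRR reflects the partial
  one-copy loss (CN = 2 − CF). **Genotypes are assigned from the observed
  BAF**: AB iff BAF ∈ `het_call_band` (default [0.15, 0.85]), else AA/BB by
  proximity — the mechanism that makes high-CF heterozygotes miscall as
  homozygous on real arrays.
* Autosomes: LRR ~ Normal(0, `sigma_lrr`), BAF bands at 0/0.5/1.
* Females: Y copy number pinned at `cn_floor` (residual background
  intensity at zero copies; `true_cf` = 1), no Y genotype calls, and **no
  PAR1 imbalance** — both PAR copies sit on X chromosomes, so their expected
  Bdev is 0 even though their Y "loss" is total.

Defaults and why:

| Parameter | Default | Rationale |
| --- | --- | --- |
| `n_msy_probes` | 397 | MSY coverage of a widely used array with deficient PAR1 |
| `n_par1_probes` | 434 | PAR1 coverage of a well-covered array |
| `n_autosomal_probes` | 5000 | enough that `baf_auto` has sd ≈ 0.014, small against the 0.03 gate; real arrays have 10⁵–10⁶ |
| `sigma_lrr` | 0.15 | calibration knob; arrays do not publish a value. Gives sd(mLRR_Y) ≈ 1.25·0.15/√397 ≈ 0.009 |
| `sigma_baf` | 0.03 | calibration knob, matching the visual width of BAF bands |
| `het_fraction` | 0.30 | typical fraction of polymorphic SNPs heterozygous in one sample |
| `het_call_band` | [0.15, 0.85] | typical AB clustering window |
| `cn_floor` | 0.005 | puts female mLRR_Y at ≈ −3.44, inside the observed female range (−3.3 to −4.1); 0.0062 reproduces −3.30 exactly |
| `scale` | 0.45 | see above |

`miscall_rate` gives the analytic (Gaussian-tail) probability that a true
heterozygote falls outside the calling band; the simulator's empirical rate
matches it within Monte-Carlo error, and the rate is non-decreasing in Bdev.
Clipping BAF to [0, 1] cannot move a value across a band edge, so it does
not affect the rate.

What the simulator deliberately omits: GC waves and other spatially
correlated LRR structure (the MSY median is robust to symmetric noise, but
real wave artifacts can bias it — passing tests here do not certify immunity
to them), probe-specific cluster geometry, X-chromosome loss, and clonal
mixtures of multiple alteration types. Simulated recovery results therefore
bound performance under well-behaved noise, not under array artifacts.

Everything is reproducible from the config seed; identical configs produce
byte-identical output tables.

## Numerical choices

* Medians use the midpoint of the two central order statistics for even
  counts (numpy's definition).
* The mLOY threshold comparison is inclusive (`≤ −0.15`).
* Reference-table grids are generated by rounding `max − k·step` to 10
  decimals so nominal grid points (e.g. −0.15) are hit exactly; the default
  grid is 0 to −4.5 in steps of 0.01.
* Display rounding is half-even to 3 decimals; all internal math is full
  precision. Two published worked values are known to disagree with the
  formulas at the last printed digit (a copy number printed as 0.06 where
  the formula gives 0.006 with the accompanying percentage consistent with
  0.006, and one Bdev/CF pair off by one unit in the third decimal,
  presumably rounded from an unprinted Bdev); neither is used as a test
  anchor.
* R² requires ≥ 3 points and non-degenerate (non-constant) axes; constant
  vectors are detected exactly via range, not via floating-point variance.
* PAR2 is placed on chrY, where its conventional GRCh38 coordinates
  (56,887,903–57,217,415) belong; a user region file can override. Only a
  GRCh38 default ships — other builds require an explicit region file.

## Problem sizes used in the checked results

The simulated-recovery acceptance check runs 20 replicate seeds of a cohort
with CF levels {0, 0.1, …, 0.9} × 100 samples per level, 397 MSY probes,
`sigma_lrr` = 0.15, and asserts the per-level mean LRR-route CF within ±0.02
of truth; at these sizes the whole suite completes in about a minute on one
CPU. The binning-beats-pairwise property uses 50 replicates of 1,000 paired
estimates with independent noise of sd 0.06 on both axes. At the CF = 0
level roughly half the replicates' samples land at mLRR_Y > 0 and are
(correctly) withheld, so that level's summary is computed over the reported
samples only.
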
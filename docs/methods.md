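# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical edge cases.

## Study design and scope

The pipeline targets the smallest interesting two-condition RNA-seq design:
two groups ("F" fertile, "S" sterile) with three biological replicates each,
a gene × sample integer count matrix, GMT-style gene-set annotations, and a
qPCR Ct table for validation. All fold changes are oriented sterile over
fertile, so "up" means over-expressed in the sterile condition throughout
(DE table, enrichment direction split, ΔΔCt sign). Published tables in this
area are not always internally sign-consistent; fixing one orientation
end-to-end and documenting it was preferred over matching any single table.

## Read filtering

A read is discarded iff strictly more than 5% of its bases are ambiguous
(`N`/`n`) or strictly more than 30% of its bases have Phred quality < 20
(Phred+33). Both comparisons are strict, so a 100-bp read with exactly 5 N
and exactly 30 bases at Q19 is retained. Filtering is per-read, hence
order-invariant and idempotent. Adapter trimming is assumed upstream: no
adapter list is part of the design, and guessing one is worse than stating
the assumption. Other IUPAC ambiguity codes count as ordinary bases.
Retention percentages are rounded half-up to 2 decimals, matching how
sequencing summary tables print them (banker's rounding would differ in the
last digit).

## Differential expression

* **Size factors** — median-of-ratios: factor_j = median over genes with a
  strictly positive geometric mean of counts_gj / geomean_g. Robust to a
  minority of DE genes; undefined only for an all-zero matrix.
* **Dispersion** — per-gene method of moments on normalized counts, pooled
  within conditions: α_g = max(0, (s²_pooled − μ)/μ²), with variance law
  Var = μ + αμ². Genes with zero mean get α = 0.
* **Test** — condition on the gene's total count T and enumerate its splits
  (a, T−a) between the pooled F and S counts. Each pooled group count is
  modelled NB with mean μ̂·S_g (S_g = sum of the group's size factors) and
  variance Σ_j (μ̂ s_j + α̂ μ̂² s_j²); the two-sided p-value is the
  normalized probability of all splits no more probable than the observed
  one. Above T = 10,000 the enumeration switches to a normal approximation
  of the conditional law (mean m_A + v_A/(v_A+v_B)(T − m_A − m_B), variance
  v_A v_B/(v_A+v_B)). With α = 0 and unit factors the test reduces exactly
  to a conditional Binomial(T, ½) split, which is the enumeration oracle the
  tests check against.
* **Fold change** — (mean_S + ½)/(mean_F + ½) on normalized means; the ½
  pseudocount keeps zero-mean genes finite and makes label swap invert the
  fold change exactly.
* **Filter** — fold change > 2 or < 0.5 (strict) and BH q < 0.05 (strict).

**Calibration caveat.** Given the generating dispersion, the exact test is
well calibrated (measured type-I error 0.054 at nominal 0.05 on a
2,000-gene null). Per-gene moment estimates of α from 6 samples (4 df) are
noisy and often floor at zero, which makes the full estimate-then-test
pipeline anti-conservative on raw p-values (~0.13 at nominal 0.05). Mature
DE tools counter this with a fitted mean–dispersion trend; this package
deliberately keeps the transparent moment estimator and relies on the
fold-change filter, which restores practical error control: on the planted
benchmark (200 DE genes at |log2FC| = 2 among 2,000, α = 0.1, n = 3/group)
the filtered gene list has power 0.85 at false-discovery proportion 0.05.
Treat unfiltered pipeline p-values as a ranking, not calibrated tail
probabilities.

## Enrichment

One-sided over-representation: p = P(X ≥ k) for X ~ Hypergeom(N, K, n) with
N the universe (annotated ∩ measured genes), K the term size, n the DE-set
size. BH correction is applied within each (category, direction) family,
mirroring how GO and pathway lists are reported separately. The up- and
down-regulated sets are tested in independent runs with their own n. The
test is one-sided because the scientific question is over-representation;
under-representation is not scored. Terms smaller than 2 genes are skipped.
Because the hypergeometric is discrete, null p-values are super-uniform
(conservative); the null-simulation test checks for an absence of excess
small p-values rather than exact uniformity, which a two-sided KS test
would reject for purely discreteness reasons.

## Co-expression networks and dif-k-core

Expression is normalized counts, log2(x+1) by default. Pearson r uses the
product-moment formula; two-sided p-values come from the t transform with
n − 2 df, with p = 0 assigned at |r| = 1 where the transform degenerates.
Two edge-selection modes:

* `abs_r` (default, cutoff 0.95): keep |r| ≥ cutoff. This is the usable
  mode at the study scale, because with 3 samples per condition the null
  distribution of r has density 1/(π√(1−r²)) (df = 1), so
  P(|r| > 0.9) ≈ 0.29 and correlation p-values can never clear FDR < 0.05
  over thousands of pairs.
* `fdr`: BH across all pairs, keep q < cutoff — the textbook rule, exposed
  for designs with enough replicates.

Edges keep signed r; selected genes that gain no edge stay as degree-0
nodes, because hub tables legitimately contain genes absent from one
condition's graph (scored degree 0, core 0 there).

Core numbers use the linear-time bucket-peeling algorithm; the tests pin it
against a brute-force iterative-deletion oracle and an independent library
implementation. `dif_kcore = kcore_f − kcore_s`, rows sorted by ascending
dif-k-core, then descending sterile degree, then gene id (the last two are
deterministic tie-breaks). The packaged 18-gene hub table of the original
gonad study regresses this: 17 of its 18 printed dif values recompute
exactly; one row (CXCR3) is inconsistent with its own printed core numbers
(8 − 9 = −1, printed −5) and is flagged in the test as the known typo. The
gene selection feeding the network stage is a user-supplied list; when
absent, the pipeline takes the DE genes with the largest |log2FC|, capped
at 72, matching the scale of the original analysis.

## qPCR

2^−ΔΔCt with amplification efficiency fixed at 2 and Ct replicates averaged
arithmetically *before* differencing (averaging folds instead would bias the
estimate upward). ΔΔCt = (Ct_target − Ct_reference)_S − (…)_F, so
log2FC = −ΔΔCt is directly comparable to the RNA-seq log2FC. The method is
invariant to plate-wide Ct shifts, and swapping calibrator and test
conditions negates ΔΔCt exactly. Concordance reports per-gene sign
agreement and the Pearson correlation of the two log2FC vectors.

## Synthetic data

The generator emulates the study's statistical structure, not its biology:

* **Counts** — NB margins with log-uniform baselines in [20, 500],
  dispersion α = 0.1 by default, 2 × 3 design. DE genes (default 10%)
  scale the S-group mean by 2^lfc with lfc cycling over (±2). Correlated
  blocks are injected through a latent Gaussian copula: an equicorrelated
  MVN per condition, quantile-mapped to the NB margins, so correlation and
  margins are controlled independently (the tests verify the margin is
  preserved and the block correlation appears only in its condition).
  Library-size variation is off by default (`size_factor_range = (1, 1)`);
  the study reports none, so none is assumed.
* **Annotations** — terms of 10–40 genes; a planted fraction samples its
  members with 20× weight on true DE genes.
* **FASTQ** — planted per-read defects exactly matching the filter rules,
  with "ok" reads allowed to sit exactly on the retention boundaries;
  Phred+33, qualities in [2, 41].
* **Ct tables** — target Ct = baseline − lfc in the sterile condition, with
  independent Gaussian noise per measured well.

What passing tests on these data do **not** show: robustness to outlier
samples, batch effects, varying library sizes, count-length bias, or GO
term-term dependence — none of which the generator produces. Recovery
results (DE power, block-core recovery) are statements about the model
under its own assumptions.

Block-recovery tests run at 10 replicates per condition rather than the
study's 3: per the arcsine null law above, 3-sample correlation graphs are
noise-dominated at any threshold, so a per-gene strict core-number
comparison is only meaningful with more replicates. The study-scale default
(`n_per_group = 3`) is unchanged.

## Numerical choices and degenerate inputs

* Exact-test ties are compared with a 1 + 1e-10 relative slack so that
  mathematically equal split probabilities computed in floating point count
  as ties.
* All-zero genes get p = 1 and α = 0; an all-zero matrix is an error.
* Percentages use decimal half-up rounding; all other floats serialize at 6
  significant digits.
* Gene identifiers are opaque case-sensitive strings; no symbol
  normalization is attempted anywhere.
* Every generator and the pipeline derive all randomness from a single
  integer seed; reruns are byte-identical (manifest SHA-256 checked in the
  tests).

## Problem sizes

Default test and benchmark sizes — 2,000-gene simulations for DE
calibration and recovery, 300-gene / 90-node graphs for network recovery,
100 random graphs of ≤ 50 nodes for the k-core oracle — were chosen as the
smallest sizes at which the binomial confidence bands around the measured
rates are decisively narrower than the acceptance margins.
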
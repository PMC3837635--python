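# Methods

This note records the modelling conventions, parameter choices and known
limitations of `chipscore`, at the level of detail a maintainer needs to
trust or change them.

## Coordinates, distances, and the gene anchor

All internal coordinates are 1-based positions (the GTF convention);
BED/narrowPeak inputs are converted on read (narrowPeak summit =
`start + offset + 1`, midpoint fallback when the offset is −1).  Every
distance in the package is the difference between a peak **summit** and a
gene's single **representative TSS** — the most 5′ transcript start with
respect to strand (min start on `+`, max end on `−`).  Gene bodies are
never consulted, including for closest-gene assignment.  Signed distances
are negative upstream (5′) and positive downstream (3′); distance 0 counts
as downstream, an arbitrary but deterministic convention of
measure-zero effect.  Chromosome names are matched after stripping a
`chr` prefix so Ensembl- and UCSC-style inputs mix.

Filters applied on load: transcript biotypes {protein_coding, miRNA,
lincRNA}; chromosomes restricted to autosomes + X by default; peaks with
intensity above 200 dropped (very high pileups are usually artifacts of
mappability or copy number).  Peak intensity is read from narrowPeak
`signalValue` or the BED score column — an approximation of a
pileup-height extraction that would need the coverage track itself, and
configurable for TSV inputs.

## Assignment strategies

Window and all-peaks assignments are inclusive at their boundary
(|d| ≤ half-width); the spec of the boundary is genuinely open and
inclusivity makes the documented boundary examples exact.  Closest-peak
and closest-gene assignment break exact distance ties deterministically:
smaller |d| first, then upstream before downstream, then lexicographic
id.  All four strategies run as sorted sweeps per chromosome,
O((n+m)·log(n+m)), and are verified against quadratic all-pairs oracles
in the test suite.

## Scoring details and open choices

* **Linear**: weight 1 at the TSS falling linearly to 0 at the window
  edge L = 50 kb.  A peak exactly at L contributes 0 but is still listed
  in the assignment.
* **Ouyang/TFAS**: contribution `intensity · exp(−|d|/d0)` with
  d0 = 5 kb by default.  d0 is experiment-specific in practice (e.g.
  500 bp is appropriate for a TF with very promoter-proximal binding such
  as E2F1) and therefore lives in per-experiment configuration, never in
  code.
* **Cheng/TIP**: binding profile over ±10 kb in 100 bp bins, built from
  bedGraph coverage when available, otherwise from a pileup
  reconstructed with a 200 bp rectangular kernel (height = intensity)
  centred on each summit.  Bins are orientation-flipped for − strand
  genes so the profile is always 5′→3′.  Weights are the across-gene mean
  signal per bin normalised to sum to 1 (genes weighted equally — whether
  the original weighting is by gene or by signal is not documented
  anywhere we could verify, so the simplest choice is taken).  Scores are
  z-standardised with the sample standard deviation (ddof = 1); negative
  z-scores are kept since flooring would only discard ranking information
  below the mean.
* **Chen**: nearest-peak |distance| histogram over log-spaced bin edges
  {0, 100, 500, 1k, 2k, 5k, 10k, 20k, 50k, 100k, 500k, 1M} bp (the
  original bins are not published; log-like spacing tracks the sharply
  peaked near-TSS density).  The expected histogram re-draws summits
  uniformly per chromosome, keeping per-chromosome counts, over
  `chen_shuffles` (default 20) seeded shuffles; chromosome lengths come
  from an explicit mapping when given, else from the largest observed
  coordinate.  Bin score s(b) = max(0, 1 − E(b)/O(b)), and 0 where
  O(b) = 0.
* **ClosestGene**: the distance distribution pools **all** peak–TSS
  pairs within 1 Mb (not just assigned pairs), split upstream/downstream
  and pooled across chromosomes.  The CDF is evaluated at the peak's own
  distance inclusively ("at this distance or closer"), so p ≥ 1/n and
  scores are finite.  The logarithm is natural; the base is not
  documented in the method descriptions this implements, and it only
  rescales scores without changing any ranking.  The method is
  parameter-free apart from the fixed 1 Mb cap.

## Evaluation

Top-k lists (k = 500 by default; the comparisons are robust for k in the
few-hundreds range) rank by score descending with gene_id as tie-break,
except at a tied cutoff score, where the tied block is resampled
uniformly (1,000 draws) and the mean overlap reported — without this,
Binary's ranking would be an artifact of gene identifiers.  Fractional
mean overlaps are kept unrounded.  Per dataset pair, subtracting the
across-method mean overlap removes the pair's difficulty (cell-type
mismatch, data quality) and leaves the relative standing of the methods;
the normalised values sum to zero by construction.  The permutation null
draws two independent uniform k-subsets per resample (true Monte Carlo,
not a closed-form shortcut), with analytic mean k²/N available as a
calibration check.  Group comparisons in the consistency analysis use
Welch's unequal-variance t-test.  "Gene density around a target" counts
TSSs (including the target's own) within a 1 Mb window centred on the
TSS, i.e. ±500 kb.  Gene-set enrichment is a one-sided Fisher exact test
per set; hierarchical decorrelation of nested set catalogs (GO-style
`elim`) is out of scope.

Whole-ranking metrics (Spearman, rank products) are deliberately absent:
most genes never respond to any single TF, so correlations over the full
ranking are dominated by the never-responding tail; top-k overlap is the
canonical comparison here.

## Synthetic data

The simulator emulates the statistical structure the scorers assume, at
desk scale.  Defaults: 5 chromosomes × 20 Mb carrying 5,000 genes (one
per 20 kb — denser than a mammalian genome, which keeps run times in
seconds while preserving the peak-to-gene ambiguity that distinguishes
the methods); TSS positions a 50/50 mixture of uniform placement and
Gaussian clusters (σ = 100 kb, ~50 genes per cluster) to create
gene-density heterogeneity; 1–4 transcripts per gene with distinct starts
so TSS collapsing is exercised; 500 true targets each attracting
Poisson(3) peaks at two-sided exponential distances (scale 5 kb, 60%
upstream — binding decays sharply with distance and favours promoters);
background peaks uniform at 1 per 100 kb; log-normal(μ = 3, σ = 1)
intensities clipped at the 200 cap (clipping rather than rejection makes
the load-time filter a no-op on synthetic data; a flag disables it to
exercise the filter); perturbation |log2FC| of |N(2, 0.5)| for targets
versus |N(0, 0.5)| for the rest.

What the simulator does **not** model: read-level noise, mappability and
copy-number artifacts, correlated replicate structure, indirect targets,
TF co-binding, and enhancer–promoter loops that break the
distance–regulation monotonicity.  Passing tests therefore demonstrate
correctness of the computations and the direction of method differences
under the assumed structure — not performance on real chromatin.

## Numerical and degenerate-input policy

Empirical CDFs are evaluated with `searchsorted` on sorted arrays
(exact, no interpolation).  Scorers raise rather than guess on
degenerate inputs: an empty side of the distance distribution, zero
total TSS-profile signal, zero score variance in TIP, no peaks for the
Chen fit.  Score tables always cover the full gene universe with zeros
for peak-less genes, so top-k selections are well-defined.  All
randomness (tie resampling, permutation nulls, Chen shuffles, the
simulator) flows through explicit integer seeds; identical seeds give
byte-identical outputs, which the CLI tests check end to end.

## Problem sizes in the test and acceptance runs

Oracle-equivalence checks run on 200 genes / 1,000 peaks (the largest
instance a quadratic oracle verifies in well under a minute).  The
method-comparison and density checks run ten seeded studies at the
default 5,000-gene scale, the size at which the between-method
differences are stable across seeds.  The permutation null is calibrated
at k = 500, N = 25,000, R = 2,000; kernel-scale recovery uses ≥ 10,000
sampled distances.
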
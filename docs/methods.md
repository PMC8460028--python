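# Methods

This note documents the statistical model behind `aneuscan`, the numerical
choices made in the implementation, and the limits within which each
statistic is valid. All quantitative claims below are reproduced by the
test suite against simulated ground truth.

## Genome model and depth profiles

The default genome is the sixteen *S. cerevisiae* nuclear chromosomes with
lengths rounded to 1 kb, tiled into non-overlapping 1 kb bins (a terminal
partial bin keeps its true length). A depth profile stores one depth value
per bin and is serialized as 0-based half-open bedGraph. Rebinning to a
coarser grid accumulates read mass (depth × bases covered) and divides by
the covered length, so total mass is conserved exactly.

## Coverage noise model

Binned short-read coverage is modeled as negative binomial: a bin covering
a region at local copy number `c` in a strain of baseline ploidy `P` has
mean `mu = lambda * (c / P) * length_fraction` and variance
`mu + mu^2 / k`, with `lambda` the per-bin coverage at baseline (default
100) and `k` the dispersion. The default dispersion is `k = 50`, a per-bin
coefficient of variation of about 17% at 100-fold coverage, which is in the
range observed for real Illumina WGS in 1 kb bins. Smaller `k` models
noisier libraries; the package's statistics were additionally exercised at
`k = 10` (CV 33%) during development, at which point sub-chromosomal
breakpoint localization runs into the information-theoretic limit described
below — whole-chromosome medians over hundreds of bins remain accurate at
any plausible dispersion.

## Whole-chromosome classification

`normalize` divides each chromosome's median bin depth by the genome-wide
median of all bins. On a diploid baseline the class centers are `c / 2`:
0.5, 1.0, 1.5, 2.0 for copy numbers 1–4. `classify` assigns the nearest
integer class when the ratio is within a tolerance (default 0.1) of its
center; otherwise the chromosome is reported `intermediate` together with
the two-population mixture fraction `f = P*r - floor(P*r)`, the fraction of
cells carrying the higher copy number under a linear mixing model.

**Validity limit.** The genome-median constant is robust only while a
minority of bins is aneuploid. An isolate in which nine of sixteen
chromosomes changed copy number shifts the genome-wide median itself, and
no median-ratio method can recover such a karyotype without an external
anchor; the packaged cohort table therefore records the published
karyotypes directly, and the classifier-recovery property is stated for
karyotypes with one to three aneuploid chromosomes (where recovery exceeds
99% per chromosome at 100-fold coverage). `median_of_medians` normalization
is available as an alternative constant but shares the same qualitative
limit.

## Segmental copy-number detection

Segments are called **relative to the chromosome's own median ratio**, not
the genome's: a duplication on a monosomic chromosome then reads as +1 copy
even though its absolute depth equals the genome median. The pipeline is:

1. rolling-median smoothing of the per-bin ratio (window 5 bins);
2. candidate runs where the smoothed ratio departs ≥ `0.5 / P` from the
   chromosome median for ≥ `min_bins` bins (default 10); same-sign runs
   separated by gaps up to the smoothing window are bridged first, since a
   single noisy dip otherwise fragments a long event;
3. boundary refinement by a changepoint that minimizes squared error on
   `log2(ratio + 0.05)` against two *fixed* levels (robust medians of the
   run interior and of the rest of the chromosome, re-estimated once).
   The log transform matters: negative-binomial variance grows with copy
   number, and a plain two-mean split on raw ratios is biased toward
   trimming bins off the gained side. Fixing the levels removes in-window
   mean-estimation noise from short windows;
4. overlap merging, then three emission filters: `|delta_copies| ≥ 1`
   after rounding, a run-level robust z score
   `|mean − background| * sqrt(n) / sigma_MAD ≥ 5`, and an
   integer-consistency margin — the run's departure must exceed the
   rounding midpoint `(|delta| − 0.5) / P` by ≥ 2 robust standard errors.
   The margin filter exists because scanning a whole chromosome selects
   extreme noise runs whose level hovers just past the rounding midpoint,
   whereas a true integer event sits a full half copy-step beyond it.
   With it, 400 simulated flat chromosomes yield zero false segments at
   default settings.

**Breakpoint accuracy.** For a duplication on a monosomic chromosome (a 2×
relative step, the configuration actually observed in the cohort), both
boundaries are recovered within ±2 bins in ≥ 99% of simulations at default
noise. For a +1 step on a *disomic* background the copy-scale jump is only
about 2.5 per-bin standard deviations at `k = 50`; an ideal
maximum-likelihood changepoint with known levels then localizes each
boundary within ±2 bins only ~97.6% of the time (Monte Carlo), i.e.
~95% for both boundaries jointly — the implementation performs within
about one percentage point of this ceiling, and no estimator can do
meaningfully better under that noise model.

Lengths are reported as exact bp alongside integer kb (round-half-up), so
116,854 bp prints as 117 kb. `locus_ratio` compares a locus's median bin
ratio with its pooled 10 kb flanks; a hemizygous deletion on one of two
homologs gives locus/flank ≈ 0.5.

## Pooled-segregant mapping

Meiosis of a 2:2-segregating cross is simulated per tetrad: the causative
chromosome's extra copy goes to exactly two of four spores; each passenger
disomy assorts independently into a uniform two of four. Pools are
equimolar per-bin means. On a haploid baseline the causative chromosome
sits at ratio ≈ 2 in the resistant pool and ≈ 1 in the sensitive pool,
giving divergence `D = ratio_R − ratio_S ≈ 1`, while passengers average
1.5 in both pools (`D ≈ 0`). Candidates are flagged at `D ≥ 0.5`.

**Sampling variance.** With only 4 tetrads a passenger's D has a discrete
distribution with standard deviation ≈ 0.29, so a passenger occasionally
crosses the 0.5 threshold (measured: the causative chromosome is still the
unique candidate in 48 of 50 seeds and top-ranked in 50 of 50). At 40
tetrads passenger D has sd ≈ 0.09 — a single replicate is *not* guaranteed
inside ±0.1, so convergence is verified on means over several seeds.

## Expression dosage

Expression tables are tpm (each sample column sums to 10^6). Dosage is
`log2((a + eps) / (w + eps))` with `eps = 0.5`, replicates averaged before
the ratio; per-chromosome medians of aneuploid/wild-type ratios track
`log2(c / 2)`. Differential tests are unpaired equal-variance t-tests
(scipy) with Benjamini–Hochberg adjustment (statsmodels), significant at
`q ≤ 10^-4` (a 0.01% FDR) by default. Star labels use strict inequalities
(`*** p < 0.001`, `** p < 0.01`, `* p < 0.05`); an exact threshold value
maps to the weaker label.

**Compositional limits.** tpm renormalization makes samples compositional,
with two measurable consequences. First, dosage medians track
`log2(c / 2)` within ±0.15 for the aneuploidies observed in the cohort,
but tetrasomy of a very large chromosome (~9–13% of the genome) deflates
every other gene's ratio by ~0.13–0.17 log2 units and genuinely leaves the
band — the bias is in the data-generating process, not the estimator.
Second, spiking strong true effects into a renormalized table makes the
remaining genes systematically non-null, so false-discovery calibration is
verified on fully null tables (where 20 simulations at the default
threshold yield zero rejections), not on spike-in mixtures.

## Synthetic generators: realism and non-goals

Coverage is i.i.d. negative binomial given local copy number: mappability,
GC bias and repeat masking are not modeled (flat expectation). Expression
noise is multiplicative log-normal with mean 1 (default CV 0.2) and genes
are laid out on an even synthetic grid; the packaged 132-member
ribosomal-protein set is synthetic and wired to that grid. Spore-viability
selection (e.g. death of spores lacking an essential chromosome) and
segregation distortion are not simulated. Breakpoint micro-homology and
the repeat elements that mediate real duplications are out of scope;
segments are pure coordinate intervals.

## Determinism

Every stochastic operation takes an explicit integer seed and uses an
isolated `numpy` generator; identical inputs rerun byte-identically, and
the pipeline report records the config hash, seed and package version.
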
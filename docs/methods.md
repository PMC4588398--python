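# Methods

## The analysis model

The package implements a two-stage rare-variant case–control analysis for
three cohorts: cases (SUDEP deaths), epilepsy controls (living people with
epilepsy) and non-epilepsy disease controls.

### Stage 1 — genome-wide polygenic burden

Variants enter the burden stage if they are

* **protein-changing** — functional class in {missense, nonsense,
  frameshift, in-frame indel, canonical splice};
* **rare** — reference-population minor allele frequency ≤ 0.5%
  (boundary inclusive). Rarity is judged on the annotated reference
  frequency, not the in-cohort frequency, because deleteriousness is
  inversely related to population frequency;
* **observed** — at least one non-reference allele in the joint call set;
* **batch-harmonised** — sequenced (non-missing) in strictly more than
  80% of *each* of the three groups separately. This removes sites whose
  capture-kit coverage differs systematically between cohorts; it is a
  cross-cohort coverage correction, not a genotype-quality filter.

Each individual's burden score sums the scaled CADD score of every
selected variant they carry; carriage is presence-based (a homozygote
contributes a variant's score once — an allele-dosage mode is available
behind a flag), and a missing genotype contributes nothing. Scores use the
*scaled* CADD because the gene stage's ≥ 15 filter is defined on that
scale and scaled scores are comparable across variants.

Scores and carried-variant counts are compared for the three group pairs
with a two-tailed Wilcoxon rank-sum test in the Stata `ranksum`
convention: mid-ranks for ties, tie-corrected variance, normal
approximation without continuity correction, and automatic exact
enumeration when the pooled sample size is ≤ 12. Significance is
Bonferroni-controlled over the six tests (α = 0.05/6 ≈ 8.3 × 10⁻³).
A post hoc re-analysis excludes all of one gene's variants and recomputes
everything, to show a burden signal is not driven by a single gene.

The 80% cut-off can be audited with `sweep_group_fraction_threshold`,
which recomputes all per-individual scores over a threshold grid and
reports the coefficient of variation of the scores at each. CV was chosen
as the "variability" measure because it is scale-free — selections of
different sizes have different score means, and raw variance would simply
track selection size; plain variance is available by argument.

### Stage 2 — gene-based unique-variant association

Per gene, variants are further refined to scaled CADD ≥ 15 and to sites
with **zero** alleles in the epilepsy control cohort (dropping anything
plausibly related to epilepsy rather than to the case phenotype). The
test then involves cases and disease controls only; epilepsy controls
supply no power at these carrier counts and are excluded from the
permutation pool.

Two statistics per gene:

* **burden** (one-tailed): cumulative non-reference allele count over
  variants exclusive to cases. "Exclusive" is evaluated against the
  case/disease-control partition; a variant with alleles in both groups
  belongs to neither exclusivity class.
* **C-alpha** (two-tailed in deviation):
  `T = Σ_i [(y_i − n_i p₀ᵢ)² − n_i p₀ᵢ (1 − p₀ᵢ)]`, with `y_i` the
  variant's copies in cases, `n_i` its copies in cases + controls, and
  `p₀ᵢ` the case fraction of the individuals genotyped at that site.
  Large `T` indicates over-dispersed allele sharing in either direction;
  the permutation tail is taken on `T` itself (standard practice; an |T|
  mode is the obvious alternative and the upper tail of T already
  captures two-sided deviation).

Empirical p-values use adaptive label permutation: case labels are
reassigned uniformly at random across the pooled individuals, and the
exclusivity partition and per-variant `p₀` are **recomputed inside every
permutation** — freezing the observed partition would make the null
distribution anti-conservative. `p = (k + 1)/(B + 1)` with `k` the number
of permuted statistics ≥ observed. A gene stops early once `k` reaches
100 (clearly not associated); the stop count is a package choice — any
value large enough that `p`'s relative error is small (~10% at r = 100)
serves.

The **I-value** is the smallest empirical p achievable given the gene's
carrier configuration: the probability, under uniform label permutation,
of the most extreme achievable configuration. For `c` carriers, `n_case`
cases among `N` individuals this is the hypergeometric point mass at
`min(c, n_case)`, which for `c ≤ n_case` reduces to
`∏_{j<c} (n_case − j)/(N − j)`. Genes with I ≥ 10⁻³ cannot reach the
corrected significance level and are excluded from the correction:
α = 0.05 / (2 × #{genes with I < 10⁻³}). By default, permutation effort
is only spent on powered genes (a flag permutes everything).

Per-variant denominators exclude missing genotypes everywhere; the
reported per-gene cumulative MAF percent uses the mean genotyped count
across the gene's variants (for fully-genotyped genes this is exact — two
case alleles among 18 diploid cases give 100 × 2/36 = 5.56%).

### Clinical panel

Cases vs epilepsy controls over ten covariates: Fisher's exact test
(probability-mass two-sided rule) for 2×2 rows, Pearson χ² without
continuity correction for wider tables, pooled-variance t-test (Welch by
flag) and the Wilcoxon above for continuous rows. Unknown entries ('.')
are dropped per row, so each row carries its own denominators. Bonferroni
correction runs over the eight established risk factors
(α = 0.05/8 = 6.25 × 10⁻³); age at last follow-up and intellectual
disability are reported but are descriptive. The expected-event helper
computes `incidence × person-years / 1000` (e.g. 5.9/1000 patient-years
over 2563 years → 15.1 → 15 expected deaths).

## The synthetic cohort generator

`SimConfig` draws, from one integer seed:

* **sites**: genes with 1 + Poisson(λ − 1) variants each
  (default 150 genes, λ = 70 — see *Scale*, below); per-site reference
  MAF from Beta(0.2, 200) truncated to (0, 0.005], a heavy rare tail with
  every site passing the rarity filter by construction; scaled CADD from
  a 0.7/0.3 mixture of Uniform(0, 15) and Uniform(15, 40) so both
  branches of the ≥ 15 filter are populated; functional classes ~55%
  missense with small shares of the other classes including synonymous
  and non-coding (exercising the protein-changing filter).
* **genotypes**: Binomial(2, MAF) per sample (Hardy–Weinberg, no linkage
  disequilibrium — LD sensitivity is a known limitation of burden tests
  and is deliberately not modelled).
* **missingness**: three capture kits covering random 98% / 92% / 85%
  subsets of sites; covered sites are callable with probability 0.995,
  uncovered with 0.05. Each sample is assigned a kit. The default kit
  mixture is identical across cohorts, which makes the three groups
  exchangeable under the null — the property the type-I-error checks
  rest on. Cohort-specific mixtures (the realistic, batch-confounded
  situation) are an explicit config field used by the threshold-sweep
  experiments.
* **planted effects**: `effect_count` multiplies case allele
  probabilities (excess variant count); `effect_score` adds to the scaled
  CADD of every variant carried by at least one case (excess
  deleteriousness). With a rare spectrum, case-carried variants are
  mostly case-exclusive singletons, so the score shift targets cases
  almost surely; the small dilution through shared variants biases
  *against* the planted effect, making power checks conservative.
  `plant_exclusive_gene` seeds a gene with group-exclusive, fully
  callable heterozygous singletons (scaled CADD 28) to reproduce
  "2 case alleles vs 4 control alleles"-style configurations.
* **manifest**: sex, ages, syndrome, AED count and tri-state risk factors
  drawn from one set of distributions for both epilepsy cohorts (null by
  construction), with ~5% unknowns.

### Scale, and what the tests do and do not show

A real exome study of this design has ~90 000 selected variants and
~110 carried variants per individual. Simulating that within a test
budget is impractical; the generator's default scale is chosen so that
individuals carry ~7 selected variants. At that scale the rank-sum
burden comparison has >95% power for a +10 per-variant score shift, and
all permutation machinery is exercised on realistic cohort sizes
(18/87/1479). Passing tests therefore demonstrate correctness of the
procedures and their calibration (type-I error, oracle agreement,
FWER control) — not that any particular real dataset would reproduce a
given p-value, which also depends on the unmodelled features: linkage
disequilibrium, annotation error, non-Beta frequency spectra,
cohort-specific batch structure and ancestry substructure (the ancestry
stage of a real pipeline is out of scope here; inputs are assumed
ancestry-homogeneous and post-QC).

## Numerical choices and degenerate inputs

* Genotype codes are int8 with MISSING = −1; missing is never conflated
  with homozygous reference (the joint-calling convention).
* Variant keys are `chrom:pos:ref:alt` after suffix-then-prefix allele
  trimming (left-alignment against a reference genome is out of scope —
  inputs are assumed normalised to trimming).
* Half-called genotypes (`0/.`) map to MISSING — the conservative choice,
  consistent with specificity-over-sensitivity filtering. Phase is
  ignored.
* Rank-sum: all-identical pooled values give (z = 0, p = 1); ties use
  mid-ranks and the tie-corrected variance.
* C-alpha is undefined for a gene with no copies (the gene is skipped);
  permutation p-values are floored at 1/(b_max + 1), and genes whose
  permutation budget is exhausted before the exceedance stop are flagged.
* QC outlier rule: a sample is flagged when any of call rate, singleton
  count or heterozygosity deviates from its cohort median by more than
  4 median absolute deviations (a metric with zero MAD is skipped), or
  when it has no called genotypes. The 4-MAD rule is a package choice —
  robust, and ~<1% false flags under a null cohort.
* Threshold-sweep ties: the minimum-CV threshold is reported; thresholds
  leaving zero variants report undefined variability rather than zero.

## Known limitations

* No LD model, no covariate adjustment, no kernel/variance-component
  tests; the burden comparison is purely rank-based by design.
* Table-style cumulative MAF uses mean per-gene genotyped counts; with
  strongly variant-specific missingness a per-variant report would be
  more faithful.
* The generator's clinical covariates are independent of genotype;
  genotype–phenotype confounding cannot be studied with it.
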
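# Methods

## The statistical problem

Sequencing studies of binary traits increasingly sample whole pedigrees,
because rare risk alleles are enriched in families with several affected
members. Standard case-control tests assume exchangeable, unrelated
individuals; with relatives in the sample, the dosage of individuals *i* and
*j* is correlated — for an additively coded variant,
Cov(g_i, g_j) = 2φ_ij σ², with φ_ij the kinship coefficient and σ² the
per-variant dosage variance. Ignoring this correlation misstates the
variance of any case-minus-control frequency contrast and invalidates the
resulting p-values. The package's approach keeps the familiar
population-based gene-region statistics and divides each by a single
variance-inflation factor derived from the pedigree.

## Kinship and the correction factor

Kinship is computed exactly from the pedigree document by the classic
recursion: founders are mutually unrelated and non-inbred
(φ_ii = 1/2); for a non-founder *j* with parents *p*, *m* and any
non-descendant *i*, φ_ij = (φ_ip + φ_im)/2 and φ_jj = (1 + φ_pm)/2.
Inbreeding is therefore handled with no extra machinery (a looped pedigree
simply yields φ_pm > 0 and a diagonal above 1/2). The implementation runs
over a topological sort and fills an n×n matrix in O(n²); the test suite
checks it against an independent Wright path-counting oracle on every
enumerable pedigree of up to six members.

Because the kinship factor 2φ_ij scales *every* genotype covariance equally,
the covariance matrix of the case-minus-control mean dosage vector under the
pedigree correlation is exactly a scalar multiple of its independence value.
That scalar is the correction factor:

    P_corr = [ ΣΣ_A 2φ_ij/n_A² + ΣΣ_Ā 2φ_ij/n_Ā² − 2 ΣΣ_{A×Ā} 2φ_ij/(n_A n_Ā) ]
             / (1/n_A + 1/n_Ā),

the ratio of Var(x̄_A − x̄_Ā) under the pedigree correlation to its value
under independence (diagonal terms contribute 2φ_ii = 1 + f_i). Dividing any
of the four statistics by P_corr restores the nominal chi-square null.

Two design points deserve emphasis:

* **The cross term is included.** When cases and controls share families,
  their positive cross-covariance *shrinks* the variance of the group
  contrast; a correction built only from within-group kinship sums would
  over-correct — in a null study with random case status inside 300 nuclear
  families the within-only factor is ≈ 1.47 while the true variance ratio is
  ≈ 1.0, which would make the corrected tests conservative by almost a
  factor of 1.5 on the chi-square scale. With the cross term, calibration is
  exact in expectation for any partition, which the null-calibration suite
  confirms empirically. A consequence worth knowing: in designs where
  relatedness is concentrated *across* the groups (e.g. case children vs
  their own control parents) P_corr can be below 1 — that is correct, not a
  bug, because such contrasts genuinely have less sampling variance than
  independent groups.
* **P_corr is genotype-free.** It depends only on the kinship matrix and the
  partition, so the scan computes it once and shares it across all genes and
  all four methods. Individuals with missing affection are excluded from
  both groups before it is computed.

## The four statistics

Dosages count minor-allele copies (0/1/2), with the minor allele defined in
the analyzed sample (ties at 0.5 count the ALT allele; columns are
re-oriented so stored MAF ≤ 0.5). Monomorphic columns are dropped; missing
genotypes are mean-imputed per column so covariance estimation keeps every
individual; MAF is computed over all analyzed individuals (a founder-only
variant is a possible extension, not the default).

**Generalized T².** T² = (n_A n_Ā/n) d' S⁺ d with d the difference of group
mean dosage vectors and S the pooled within-group covariance (denominator
n − 2). Linkage disequilibrium makes S rank-deficient routinely, so S⁺ is
the Moore-Penrose pseudo-inverse with singular values below 1e-8 of the
largest treated as zero; the degrees of freedom equal the retained numerical
rank (clamped to ≥ 1). T²_F = T²/P_corr is referred to the chi-square upper
tail.

**CMC.** Columns with MAF < 0.01 (configurable, `--rare-maf`) are replaced
by one indicator of carrying ≥ 1 minor allele at any rare site; the reduced
matrix then goes through the same T² machinery. With no rare column the test
equals T² exactly; with only rare columns it is a 1-df carrier test.

**FPCA.** Variant positions are rescaled to [0, 1]; each individual's dosage
profile is least-squares fitted with a clamped uniform B-spline basis of
order min(4, n_basis), n_basis = min(m, 10); the smoothed profiles are
evaluated on a 101-point grid and decomposed by PCA. The smallest K
components whose eigenvalues cumulatively explain ≥ 85% of total variance
(configurable, `--fpca-var`) are kept; the statistic is
(n_A n_Ā/n) Σ_k (mean case score_k − mean control score_k)²/λ_k with λ_k the
pooled *within-group* score variance, divided by P_corr, with df = K. Genes
with fewer than 3 variants are skipped (recorded as not analyzed): too few
points to estimate the functional form. Components with numerically zero
within-group variance are excluded from both sum and df.

**Chi-square minimum.** Per variant, the 2×2 minor/major allele-count table
(cases vs controls; mean-imputed dosages contribute fractionally) is tested
by the 1-df Pearson chi-square without continuity correction; each statistic
is divided by P_corr before the p lookup; the reported p-value is the raw
minimum over variants. No within-gene multiplicity adjustment is applied by
default — the method is carried as an anti-conservative comparator whose
inflation grows with the number of variants per gene, and the null study
reproduces exactly that behaviour (≈ 0.43 empirical type I error at nominal
0.05 with 5–20 variants per gene). A Šidák-adjusted variant is available
behind a flag. The allelic (2×2) rather than genotypic (2×3) table is used
as the minimal-df reading of a per-variant chi-square; for a common variant
near Hardy-Weinberg proportions it agrees closely with the 1-df T².

All four statistics scale as statistic(P_corr = c) = statistic(1)/c, which
the property suite asserts directly.

## Genome scan

The scan extracts per-gene matrices from a VCF in one pass (BED half-open
semantics: a 1-based variant position p belongs to a region when
start < p ≤ end; overlapping regions both receive the variant;
multi-allelic records are skipped with a warning), computes P_corr once,
fits every gene in input order, and writes a deterministic TSV with columns
`gene chrom n_variants p_corr {t2f,cmcf,fpcaf,chimin}_{stat,df,p}` and `NA`
for skips. Genes with zero polymorphic variants keep their row (all NA, a
logged reason) so replicate tables share a fixed gene set. Bonferroni
thresholds divide the family-wise level by the number of genes *loaded* by
default (the number analyzed is a config switch). Gene-set overlap reporting
returns all-subset exclusive intersection counts plus per-method
intersections with an optional external gene list.

## Simulator

The generator emulates the structure the tests assume, not any particular
cohort:

* **Pedigrees**: a template (trio, nuclear with k children, or
  three-generation with 8 members) replicated `n_pedigrees` times. Default:
  300 nuclear families of two parents and two children (1,200 individuals) —
  a family-study scale at which the chi-square approximations are
  comfortable and a desk-scale run finishes in seconds per study.
* **Founder genotypes**: Binomial(2, MAF) independently per variant —
  linkage equilibrium among founders. Within-gene LD is deliberately absent;
  the rank-deficiency path of T² is exercised separately by collapsed and
  degenerate fixtures. Default spectrum: 5–20 variants per gene, half rare
  (MAF ~ U(0.001, 0.01)) and half common (MAF ~ U(0.05, 0.5)).
* **Transmission**: one allele per parent per variant; given parental dosage
  g the transmitted allele is the minor allele with probability g/2 — the
  exact Mendelian law for unordered genotypes — and every meiosis is
  independent, so sibling and parent-offspring dosage correlations are
  exactly 2φσ².
* **Phenotype**: P(case) = expit(logit(prevalence) + Σ β_common·dosage +
  Σ β_rare·carrier) over the causal variants, independent Bernoulli given
  genotype. Prevalence defaults to 0.25, a hypertension-like adult rate. No
  polygenic or shared-environment term: the null is exactly exchangeable, so
  calibration failures cannot be blamed on the generator.
* **Replicates** share the pedigree structure and gene map and redraw
  founders, transmissions and phenotypes — i.i.d. datasets, as the evaluator
  assumes. All randomness flows from one configured seed through fixed
  per-replicate substreams; reruns are byte-identical.

What passing tests therefore show: correct arithmetic, correct calibration
under exchangeable nulls with independent variants, and the expected power
ordering under a concentrated rare-variant architecture. What they do not
show: behaviour under within-gene LD, population structure, genotyping
error, phenotype misclassification, or ascertainment through affected
probands — real-data features the generator does not emulate.

## Evaluation studies

Type I error and power pool (gene × replicate) pairs as Bernoulli trials,
the granularity at which such tables are usually reported; a
per-replicate-averaged variant exists behind a flag. Genes a method skipped
are excluded from that method's numerator and denominator, so denominators
can differ across methods (logged).

* **Null calibration study**: the generator defaults (300 nuclear families ×
  1,000 null genes, one replicate → 1,000 null pairs). T²_F and CMC_F must
  sit within 3 binomial SE of nominal at α = 0.05 and 0.01; Chi_min must
  exceed 0.05 by more than 3 SE and grow with variants per gene; FPCA must
  not be anti-conservative. Observed values (seed 1): T² 0.055, CMC 0.057,
  Chi_min 0.429, FPCA 0.056 at α = 0.05.
* **Power scenario**: 2 causal genes among 6, each with 3 causal rare
  variants at β_rare = 1.5 (carrier odds ratio ≈ 4.5) and no causal common
  variant, 200 replicates (400 causal pairs). Concentrating the signal in a
  few rare variants amid null rare background is the regime in which
  collapsing dilutes information, so T²_F beats CMC_F — the check is
  explicitly scenario-conditional, not a universal claim. With common causal
  variants the ordering provably reverses: CMC then retains every causal
  column at strictly smaller df. The replicate count was sized so that the
  expected power gap (≈ 0.16, e.g. 0.83 vs 0.67 at α = 0.05) separates the
  95% binomial intervals reliably. β_rare = 1.5 was chosen from a
  pre-run noncentrality calculation targeting mid-range power at this sample
  size; β_common = 0.25 is the analogous moderate per-allele effect for
  common-variant scenarios.

## Numerical choices and edge cases

* Pseudo-inverse tolerance 1e-8 (relative to the largest singular value);
  df = numerical rank, so perfectly collinear columns cost nothing.
* Zero contrast with zero covariance → statistic 0, df clamped to 1, p = 1.
* Groups smaller than 2 are rejected (covariance inestimable).
* The FPCA basis order degrades gracefully (min(4, n_basis)) so 3-variant
  genes get a quadratic fit rather than an error.
* The T² p-value is asymptotic; against a 100,000-draw label-permutation
  reference at n = 500 it agrees within Monte-Carlo error plus a 0.005
  finite-sample allowance. (A 10-individual permutation reference cannot
  resolve p-values below its 1/70 support granularity, so the comparison is
  made at a sample size where the chi-square regime applies.)
* Missing-parent marker "0" (PED convention); individual ids must be unique
  across families.

## Known limitations

* Kinship comes from the pedigree document only; cryptic relatedness or
  misspecified pedigrees are invisible to P_corr (genotype-based kinship is
  an explicit non-goal).
* A single scalar P_corr is exact for the mean-contrast statistics because
  kinship scales all dosage covariances equally; it is an approximation for
  the nonlinear min-p statistic.
* Covariates, quantitative traits, dominance codings and kernel/weighted
  burden tests are out of scope.
* FPCA presumes a smooth dosage signal in genomic position; for sparse genes
  or position-incoherent effects it is expected to lose power, and the
  simulator's scenarios confirm this rather than contradict it.
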
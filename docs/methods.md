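# Methods

## The question and the estimands

Gestational diabetes (GDM) under the WHO 2013 / IADPSG criteria can be
diagnosed through three different oral-glucose-tolerance-test (OGTT)
thresholds — fasting plasma glucose (FPG) ≥ 5.1 mmol/L, 1-hour glucose
≥ 10.0 mmol/L, or 2-hour glucose ≥ 8.5 mmol/L after a 75 g load.  The
analysis this package implements asks whether women diagnosed through
the different thresholds carry different genetic predispositions, as
summarised by two weighted genetic scores: one built from 15 SNPs
associated with fasting glucose and one from 38 SNPs associated with
type 2 diabetes (T2D).  The estimands are (a) per-group mean scores and
their case-vs-control contrasts, and (b) the linear association of each
glucose measure with each score.

## The weighted genetic score

For an individual with effect-allele dosages `a_i ∈ {0, 1, 2}` at the
`N` panel SNPs with published per-allele weights `β_i > 0`:

    GS = N · Σ_i a_i β_i / Σ_i β_i

The rescaling by `N / Σβ` puts the score on an effective-allele-count
scale: `GS ∈ [0, 2N]`, and a fully heterozygous individual scores
exactly `N` regardless of the weights.  FPG-panel weights are in mmol/L
per allele; T2D-panel weights are per-allele log odds ratios.  Scores
are computed only for individuals with complete dosage data across the
panel (strict complete-case rule, no imputation); the package reports
how many individuals are dropped but offers no mean-imputed variant.

Under Hardy-Weinberg equilibrium (HWE) and linkage equilibrium the
score's population moments have closed forms used throughout the tests:

    E[GS]  = 2N Σ p_i β_i / Σ β_i
    V[GS]  = (N / Σβ)² Σ 2 p_i (1 − p_i) β_i²

For the shipped panels these evaluate to mean 15.56 / SD 2.92 (FPG,
index frequencies) and mean 41.56 / SD 4.11 (T2D).

## Panels, exclusions, proxies

The two panels ship as packaged TSVs, together with the pre-exclusion
candidate panels (16 and 41 variants).  Three kinds of exclusion are
modelled: HWE failure at Bonferroni-corrected P < 0.05, a primary effect
through BMI rather than glycaemia (the FTO variant), and a free-form
"other".  Candidate rows for excluded variants carry no published
weight/frequency and are marked non-scoreable; scoring refuses panels
containing them until exclusions are applied.

Some index variants were genotyped through a high-LD proxy in the
representative cohort; proxy resolution swaps rsid, alleles and
frequency while retaining the index variant's weight, and never changes
panel size or any β.  Chromosome/position are stored for provenance but
never used in computation (the analysis is rsid-keyed; no liftover or
position-based matching).

## Genotype input and strand handling

Dosage TSVs are taken as already aligned to the effect allele.  VCF
genotypes are aligned by matching alleles as written, then by reverse
complement.  Palindromic (A/T, C/G) sites cannot be oriented from
alleles alone; the default policy is a hard error, with an optional
frequency-based resolution that orients the site by whichever choice
brings the sample allele frequency closer to the panel frequency.  Note
that both shipped panels do contain palindromic variants (e.g. the
MTNR1B G/C and PPARG C/G sites), so VCF input covering them requires
the frequency policy — a real limitation of allele-only matching, made
explicit rather than silently guessed.  Hard calls only; dosage values
outside {0, 1, 2, missing} are rejected.  The X-chromosome variant
(rs2301142) is treated as diploid autosomal because all modelled
participants are women.

QC metrics mirror the reported ones: per-SNP call rates (median
reported, thresholds not enforced — the source analysis applied none)
and duplicate concordance pooled over jointly-called genotypes, with
degenerate pairs flagged and excluded.

## HWE screening

Each SNP is tested with the 1-df Pearson goodness-of-fit χ² against
expected counts at the allele frequency estimated from the data (no
continuity correction); an exact conditional test (enumeration of
heterozygote counts given allele counts) is available behind
`method="exact"` for small samples.  Raw P values are Bonferroni-scaled
by the number of SNPs screened together (the candidate panel size, 16 or
41), and a SNP is flagged for exclusion at corrected P < 0.05.
Monomorphic SNPs return χ² = 0, P = 1 with a flag and are never
excluded, since the test is undefined and silent exclusion would shrink
N.  Whether the original cohorts used the χ² or exact form, in all
samples or controls only, is not stated anywhere; the defaults here
(χ², all samples) are this package's own choice.

## Classification

Thresholds are applied exactly as printed: case criteria inclusive (≥),
control criteria strict (<).  The five analysis groups partition
complete triplets together with an `unclassified` remainder.  Two open
points in the source definitions are surfaced as configuration rather
than resolved silently:

* the control 2-hour bound is 7.8 mmol/L by default (the Methods-style
  definition) with an 8.5 override (the figure-caption definition);
  the choice changes the control n;
* women with normal fasting glucose but both post-load values elevated
  are `unclassified` by default, with a `merge_dual_postload` flag that
  folds them into a broadened combined group.

## Statistics

* Group contrasts: pooled-variance unpaired t (Welch by flag) for
  scores; Wilcoxon rank-sum for skewed clinical variables (exact below
  a pooled n of 20 when untied, otherwise normal approximation with
  continuity and tie correction).  Zero-variance identical groups
  return t = 0, p = 1 rather than NaN.
* Regressions: OLS of each glucose measure on each score, unadjusted
  and adjusted for the two other glucose measures (or BMI/age), with
  t-based 95% CIs; rank-deficient designs raise an error naming the
  collinear columns.
* ANCOVA sensitivity: GS ~ group + covariates, reporting the group
  coefficient.
* Bonferroni multipliers are explicit configuration: 24 for the
  clinical/regression layer and 16 for the score contrasts, following
  the two correction statements in the source analysis; the package
  does not attempt to reconstruct which contrasts made up those counts.
* Power for a variance-explained predictor uses the noncentral F with
  1 and n − 2 df and noncentrality n·r²/(1 − r²); at r² = 0 power
  equals the test size.  At n = 2,628, r² = 0.06, α = 0.002 this is
  1.00 to well beyond two decimals, matching the stated 100% power.

## The synthetic cohort generator

Real individual-level data are access-controlled, so every pipeline
stage is exercised on synthetic cohorts whose generative model encodes
the analysis' stated assumptions.  Defaults are fixed once as the study
conditions and are not tuned:

| parameter | default | rationale |
|---|---|---|
| n_samples | 2,628 | representative-cohort size |
| gs_variance_explained | 0.06 | FPG score R² on FPG, external estimate |
| fpg_mean | 4.5 mmol/L | control-group median |
| glu_1h mean / SD | 7.1 / 1.5 | control median, IQR/1.35 |
| glu_2h mean / SD | 5.8 / 1.05 | control median, IQR/1.35 |
| residual correlation | 0.5 | moderate positive triplet coupling |
| t2d effects (orth.) | 0.004/0.043/0.030 | reproduce unadjusted T2D-score slopes |
| missing_rate | 0.008 | reported median call rate 0.992 |

Genotypes: `dosage ~ Binomial(2, p_i)` independently per SNP (linkage
equilibrium), one draw per rsid so loci shared between the panels are
the same physical genotype.  Phenotypes:

    FPG  = μ_f + s_f (G_f − E G_f) + c_1 G_t⊥ + b_1 (BMI − E BMI) + ε_f
    1-h  = μ_1 + a_1 (G_f − E G_f) + c_2 G_t⊥ + b_2 (BMI − E BMI) + ε_1
    2-h  = μ_2 + a_2 (G_f − E G_f) + c_3 G_t⊥ + b_3 (BMI − E BMI) + ε_2

with `s_f = Σβ/N = 0.0301` mmol/L per score unit fixed by the panel,
and `G_t⊥` the component of the T2D score orthogonal to the FPG score
(the projection coefficient is the closed-form HWE covariance over
shared loci divided by the FPG-score variance).  Orthogonalisation is
what lets the marginal OLS slope of FPG on the FPG score equal `Σβ/N`
exactly despite the shared loci.  The FPG residual variance is solved
so the FPG score explains exactly the configured 6% of FPG variance
(this implies a total FPG SD of ≈ 0.36 mmol/L); the 1-h/2-h residuals
are solved against their configured total SDs.  Setting the variance
explained to zero zeroes every genetic loading (null configuration)
and the configured `fpg_sd` becomes the total SD.  Residuals are
multivariate normal with the configured correlation; covariates are
lognormal BMI, rounded bounded-normal age and normal SBP with a small
FPG coupling.

The case-control style keeps every WHO 2013 case from the simulated
pool and draws exactly three eligible controls per case (eligibility:
not a case, and FPG < 5.6 mmol/L or 2-h < 7.8 mmol/L), erroring with
the deficit when the pool is too small.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: Gaussian glucose marginals understate the
heavy right tails of real OGTT data, so case-subgroup sizes and
case-group medians do not reproduce the printed cohort tables; there
is no linkage disequilibrium, no ancestry structure, no
cohort-specific allele frequencies (the printed control-group T2D
score mean sits several SEs from the HWE expectation at the panel
frequencies, so that mean is deliberately not a reproduction target);
and no incident-diabetes outcome.  Truth values (latent genetic
scores, generation-time labels) are written to a separate file the
pipeline never reads.

## Numerical and design notes

* Scores are stored at full float precision; rounding to two decimals
  happens only in reports.
* The HWE screen and all report layers are deterministic given counts;
  the pipeline is byte-reproducible for a fixed seed (log excluded).
* Exact rank-sum enumeration is switched on below a pooled n of 20 and
  only without ties, where the normal approximation is weakest.
* Degenerate report cells (empty groups, all-missing covariates,
  single-member groups) are emitted with n = 0 / NaN rather than
  dropped, because group bookkeeping is part of the reporting contract.
* Problem sizes in the test suite (50,000-sample calibration draws,
  100-replicate slope studies, 2,000-replicate familywise screens,
  10,000-replicate power simulation) were chosen so Monte-Carlo error
  is small against each assertion's tolerance.

## Known limitations

* Glucose marginals are Gaussian by default; a lognormal option is a
  natural extension but the reported medians/IQRs do not identify a
  family.
* The palindromic-SNP frequency policy is unreliable for frequencies
  near 0.5 (e.g. the KLF14 proxy at 0.51); with such panels, dosage
  TSV input or externally strand-verified VCFs are the safe route.
* Bonferroni multipliers are taken as given (24/16) rather than derived
  from an enumeration of contrasts.
* The 1-h/2-h genetic loadings are qualitative calibrations against the
  published regression grid, not estimates with uncertainty.
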
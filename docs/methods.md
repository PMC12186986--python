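# Methods

This note documents the statistical models the package implements, the
synthetic-data generator that stands in for individual-level cohort data,
and the numerical and design choices made where more than one reasonable
option existed.

## Outcome construction

Serum creatinine (SCr, mg/dl) is measured on different instruments over a
multi-year recruitment, so raw values carry batch structure. The
normalization removes instrument effects as fixed group-mean shifts and
period effects as *shrunken* group shifts: with period means m_j (n_j
observations), pooled within-period variance s², and the method-of-moments
between-period component τ̂² = max(0, Var_w(m_j) − s²·mean(1/n_j)), each
period shift is multiplied by λ_j = τ̂²/(τ̂² + s²/n_j) before subtraction —
the BLUP of a random intercept. Periods with fewer than two observations get
no shift; the grand mean is preserved. This is a deliberate, documented
replacement of a full mixed-model fit: it reproduces the first-moment
correction (the only part that matters downstream) without a mixed-model
dependency. Consequence: a shift confined to a single period among many is
shrunk toward zero — that is the correct behavior of a random-effects
correction, not a defect; only shifts consistent with the estimated
between-period variance are removed.

eGFR uses the 2009 CKD-EPI creatinine equation,

    eGFR = 141 · min(SCr/κ, 1)^α · max(SCr/κ, 1)^(−1.209)
           · 0.993^age · 1.018[female] · 1.159[black],

κ = 0.7/0.9 and α = −0.329/−0.411 for females/males. The ethnicity
coefficient is implemented but defaults to non-black, matching a European
study population. The equation is a strictly decreasing piecewise power law
in SCr, so the generator inverts it in closed form (branch chosen by
comparing eGFR to the value at SCr = κ); the roundtrip is exact to ~1e-13,
which is why no numeric root-finding is used. eGFR is winsorized at 15 and
200 ml/min/1.73 m² before the log — extreme estimated values are more often
assay or equation artifacts than physiology.

Traits are transformed with rank-based inverse-normal scores using the Blom
offset, Φ⁻¹((r − 3/8)/(n + 1/4)), average ranks over ties, missing values
preserved. The dialect choice (Blom vs. other offsets) is immaterial
downstream — all variants are rank-equivalent — but is fixed and tested. A
constant trait maps to zeros with a warning and is skipped by the screen.

## Locus re-association

Because the expected effect direction is known from the meta-analysis,
tests are one-sided: p₁ = Φ(−sign·z) with z = b/SE and the sign taken from
the harmonized GWAMA effect. Wrong-direction effects get p₁ > 0.5 rather
than being mirrored, so they can never appear significant. Two-sided values
are 2·p₁ for in-direction effects. Per-variant models are ordinary least
squares of age/sex-adjusted ln(eGFRcrea) residuals on dosage plus 10
genetic PCs; p-values inside the cohort use the t distribution with
residual degrees of freedom, while conversions of summary statistics use
the normal approximation (the convention of summary-level work). PC-adjusted
OLS stands in for a kinship-adjusted mixed model throughout; this is the
package's single intentional methodological simplification and is adequate
whenever relatedness is modest and PCs capture structure.

Allele harmonization: swapped alleles flip the dosage (2 − d) and the
frequency; non-ambiguous strand flips are resolved via complements;
strand-ambiguous A/T and C/G variants are dropped when MAF ≥ 0.4 and
otherwise oriented by frequency matching. A proxy with no GWAMA record is
oriented to correlate positively with the harmonized lead so the one-sided
direction carries over. LD is the squared Pearson correlation of dosages;
proxy retention is strict (r² > 0.8) and cohort MAF ≥ 0.005.

Diagnostics: genomic control λ = median(χ²₁(1 − p))/0.4549; the
effective-number-of-tests criterion is the fraction of total SNP variance
covered by the k largest eigenvalues of the (signed Pearson) SNP
correlation matrix, eigenvalues clipped at zero below −1e-10·scale.

## Meta subtraction and comparison

Leave-cohort-out subtraction is exact fixed-effect inverse-variance
algebra: w′ = SE_meta⁻² − SE_cohort⁻², b′ = (b·w − b_c·w_c)/w′,
SE′ = w′^(−1/2); it is the exact inverse of a two-study meta-analysis
(property-tested to ~1e-9 relative error; exactness degrades with extreme
weight ratios through floating cancellation). A sample-size-weighted mode
is provided for z-score-only inputs. λ-correction options of full
meta-subtraction tooling are intentionally omitted. Explained variance per
variant is b²·2p(1−p)/var(y), invariant to allele flips; MAF ratios use
min(p, 1−p).

## Mediation screen

The four regressions are fitted per (variant, trait) pair as complete-case
OLS, each adjusted for age, sex, 10 PCs and an intercept; sample sizes may
differ across steps. Serum creatinine is carried in the panel as a positive
control — adjusting the outcome for the creatinine it is computed from
nearly eliminates any SNP effect, which the tests verify.

The outlier criterion on b2 uses percentiles P10/P25/P75/P90 by linear
interpolation (quantile type 7, the numpy/R default; the dialect is
unstated in common practice and type-6 moves the bounds by O(1/n)), with
the tested value included in its own panel, and bounds
[P10 − 1.5·IQR, P90 + 1.5·IQR]. These bounds always contain the classic
Tukey bounds (P10 ≤ P25, P90 ≥ P75), so the flag set is a subset of the
classic rule's — "stringent" means fewer, stronger outliers. Panels smaller
than 10 are refused: the outer percentiles are meaningless below that.
Classification requires both the outlier flag and step-3 significance at
α/(n_traits·n_loci); the threshold is applied per test, with n_loci the
number of significant loci in the run (11 in the motivating study,
0.05/770 = 6.5×10⁻⁵).

Percent change 100·(b2 − b1)/b1 is kept at full precision internally and
rounded to integers for display. For a trait generated downstream of the
outcome (trait = α·SNP + δ·y + ε with α = 0), the expected attenuation is
f = δ²σ_u²/(δ²σ_u² + σ_ε²) with σ_u the outcome noise SD — the generator
exposes this inversion (`TraitSpec.for_attenuation`), and the acceptance
checks recover f ∈ {0.1, 0.2} within ±0.03 averaged over 200 cohorts of
n = 10,000.

## Thyroid interaction

Exclusions (thyroid cancer, kidney cancer, goiter, thyroid surgery, jointly
missing TSH and therapy) are applied as the union of flags. Thyroid status:
hyperthyroid if TSH < 0.4 µUI/mL or antithyroid drug; hypothyroid if
TSH > 3.8 or levothyroxine; medication dominates TSH; thresholds are strict
(a value exactly at a threshold is normal). TSH enters the continuous model
untransformed — pass log-TSH explicitly for a log variant; the interaction
t-test is invariant to mean-centering. Categorical contrasts are pairwise
against normal (hyper vs normal, hypo vs normal), each on the two relevant
strata, rather than a three-level factor; empty strata skip the contrast.
Significance is α/n_loci with strict inequality on the exact fraction
0.05/11 = 0.004545…, not on its printed rounding. Slopes at TSH levels
mean ± SD use the delta method on the (b_SNP, b_interaction) covariance.
The missing-by-design sanity check is a two-sided Wilcoxon rank-sum test of
dosage between FT3/FT4-measured and unmeasured individuals (exact null
distribution for small tie-free samples, normal approximation with
continuity correction otherwise), and the municipality sensitivity check
re-fits the association model with municipality as an extra categorical
covariate.

## Synthetic-data generator

The generator emulates the three inputs — GWAMA summary statistics, dosage
matrix, phenotype table — with known ground truth.

* **Genotypes.** Lead dosages are binomial(2, MAF) under Hardy–Weinberg.
  Proxies are built per haplotype by copy-with-mutation: the proxy allele
  copies the lead with probability q = √(target r²) and is otherwise
  redrawn Bernoulli(MAF). This keeps dosages integer, MAF and HWE exact,
  and gives E[r²] = target r² (q = 1 gives exact copies). Gaussian
  thresholding was rejected because it produces non-integer dosages and
  distorts HWE.
* **Outcome.** ln(eGFRcrea) = 4.52 − 0.003·(age − 49) + 0.02·female +
  Σ β·(d − 2·MAF) + γ·d·(TSH − E[TSH]) + N(0, 0.15²). The intercept matches
  a median eGFR near 92 ml/min/1.73 m²; the 0.15 noise SD reproduces the
  per-variant standard errors a cohort of ~10,000 shows (SE ≈
  sd(y)/√(2n·p(1−p))). Age is uniform on [18, 80] (only median/IQR are
  known for the motivating cohort, not a distribution); sex is Bernoulli
  with 55.1% female.
* **Creatinine.** Back-derived by exact CKD-EPI inversion, then perturbed
  by instrument shifts (±0.02 mg/dl, two instruments at the cohort's
  41/59 split) and per-period N(0, 0.01²) shifts over 8 periods, so the
  normalization step has real work to do.
* **Thyroid.** TSH is log-normal(0.355, 0.596), calibrated once so that
  with a 5.05% levothyroxine rate the categories come out near
  hyper 1.7% / normal 88.5% / hypo 9.8%; the implied median 1.43
  (IQR 0.95–2.13) is close to the observed 1.38 (0.98–1.93). FT3/FT4 are
  drawn (N(3.0, 0.45²) pg/ml, N(0.98, 0.16²) ng/dl) only when TSH < 0.4 or
  > 3.8 — missing by design. Because medication is sampled independently of
  TSH, the extreme-TSH fraction (~6.7%) exceeds the ~4.6% a treated
  population shows (treatment normalizes TSH); a limitation accepted for
  simplicity.
* **Traits.** trait = mean + α·(d − 2·MAF) + δ·(ln eGFR − mean) + noise,
  spanning pure pleiotropy (δ = 0), outcome-downstream (α = 0) and mixed
  scenarios. The 70 traits are independent by default (their mutual
  correlation structure is not specified anywhere authoritative); a shared
  factor can be emulated by giving several traits nonzero δ.
* **Exclusion flags** are sampled independently at the observed per-flag
  rates; the overlapping-union case (416 flagged of 10,146, leaving 9,730)
  is provided as a deterministic fixture, since flag overlap is a property
  of real comorbidity the independent sampler does not reproduce.

What passing tests on this generator do *not* show: robustness to
population structure or relatedness (none is generated), to correlated
trait panels, to non-Gaussian outcome noise, or to genotyping/imputation
error. They do show that every estimator recovers the parameters of the
data-generating model it assumes, at the sample sizes of interest, and
that all error rates are calibrated under that model's null.

## Problem sizes and determinism

The test suite and the acceptance script use cohorts of 2,500–10,000 and
replicate counts of 200–2,000, sizes at which every Monte Carlo tolerance
asserted is comfortably inside the corresponding binomial/normal error;
each check states its tolerance inline. All randomness flows from
numpy `SeedSequence` spawning, so identical seeds give byte-identical
tables and pipeline outputs (tested bitwise).

## Known limitations

* PC-adjusted OLS instead of a kinship mixed model (see above).
* Fixed-effect algebra only in meta subtraction; no random-effects or
  heterogeneity handling.
* No conditional/joint analysis, fine-mapping, or genome-wide scanning —
  the package characterizes *known* loci.
* The U-shaped TSH hypothesis is probed only through the two categorical
  contrasts, not a quadratic term.
* The interaction direction is reported as a signed coefficient; no
  directional claim is hard-coded.
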
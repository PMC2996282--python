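# Methods

## The evaluation framework

The package answers one question: given a panel of SNPs with known effects on
β-cell function, which fasting-/OGTT-derived insulin secretion index detects
those effects with the least data? The chain is

index calculation → negative-value exclusion → confounder-adjusted OLS per
(SNP, index) → post-hoc power and least significant number (lsn) per fit →
competition ranks of lsn within each SNP → rank sums over SNP subsets →
final ordering → exact Wilcoxon comparison of each index's ranks against a
reference index (default HOMA-B, the fasting-state surrogate).

lsn, not p, is the ranking currency: it puts every (SNP, index) pair on a
common "subjects needed" scale that is monotone in the partial F at fixed
degrees of freedom, so ranking by lsn within one SNP column is ranking by
observed effect size relative to residual noise.

## Index panel

All formulas operate in mmol/l (glucose) and pmol/l (insulin, C-peptide) on
the fixed sampling grid 0/30/60/90/120 min; missing samples are never
interpolated — the subject is excluded with a logged reason. Three choices
the defining formulas leave open:

* **HOMA-B unit conversion.** HOMA-B expects fasting insulin in µU/ml; the
  panel stores pmol/l. The conversion 1 µU/ml = 6.0 pmol/l is used
  (configurable via `pmol_per_microunit`).
* **Matsuda ISI units.** Computed directly in mmol/l·pmol/l rather than the
  original mg/dl·µU/ml. The difference is a fixed multiplicative constant
  that the loge transform turns into an intercept shift, so every adjusted
  analysis is invariant to the choice.
* **G_mean, I_mean** are unweighted arithmetic means of the five samples.

A singular denominator (G₀ ≤ 3.5 for HOMA-B, G₃₀ = G₀ for IGI₁,
G₃₀ ≤ 3.89 for CIR, zero AUCs or I₀) yields an *invalid* flag; a finite
negative value (e.g. I₃₀ < I₀) sets the *negative* flag. Either removes the
subject before association, with the subject id and reason reported — the
negative-value exclusion mirrors how such cohorts are cleaned in practice,
and the extension to non-finite values is forced by arithmetic. The
trapezoid AUC keeps the printed scaling 0.5(0.5c₀+c₃₀+c₆₀+c₉₀+0.5c₁₂₀)
without multiplying by the 30-min interval; AUCs appear only inside ratios,
where any fixed scaling cancels (the 0–30 "AUC ratio" is the two-point form
(I₀+I₃₀)/(G₀+G₃₀), identical to the two-point trapezoid ratio). Glucose
tolerance classes (NGT/IFG/IGT/diabetes, ADA cutoffs: IFG G₀ ≥ 5.6, IGT
G₁₂₀ ≥ 7.8, diabetes G₀ ≥ 7.0 or G₁₂₀ ≥ 11.1 mmol/l) are descriptive only.

## Association model

For each (SNP, index) pair: OLS of loge(index) on the minor-allele count
(0/1/2 entered untransformed — additive inheritance), adjusted for sex
(female = 0, male = 1), loge age, loge BMI and loge Matsuda ISI. Rows with a
missing value, or a non-positive value where a loge transform is required,
are deleted listwise and counted (`n_used + n_dropped = N`). The reverse
direction (genotype as dependent variable — a linear-probability-style fit)
uses the same design with roles swapped. Because age, BMI and ISI can be far
from normal, `covariate_mode="quartile_nominal"` replaces each by a 4-level
factor cut at the sample 25/50/75 percentiles (lower-inclusive; lowest
quartile is the reference level; empty levels from ties are merged with a
warning). The tested term is always single-df, so its partial F equals t²,
SSH = F·MSE, and the two-sided p comes from F(1, n−k). Rank-deficient
designs abort with the collinear columns named. No multiple-testing
correction is applied across the SNP × index grid, no family/relatedness
structure is modelled, and subjects are treated as independent.

The AIR analysis fits loge(AIR) ~ loge(index) + confounders on the IVGTT
subset and reports sign(β)·√(SSH/(SSH+SSE)) — the partial correlation of the
index term given the confounders. ("r" is ambiguous between the partial
correlation, the correlation of adjusted residuals, and the standardized
coefficient; the partial correlation was chosen because it is the quantity
the partial F already measures.)

## Power and least significant number

With λ = SSH/MSE, retrospective power is
P[F′(df₁, n−k, λ) > F_crit(α, df₁, n−k)]; at SSH = 0 it equals α exactly
(handled as the central special case). For lsn, the squared effect size
δ² = SSH/N and σ̂² = MSE are held fixed while the sample size varies: the
expected F at candidate size m is (m·δ²/σ̂²)/df₁ with df₂ = m − k, and lsn
is the smallest integer m > k whose expected F reaches F_crit(α, df₁, m−k).
Because the expected F grows linearly in m while the critical value falls,
the crossing is unique; it is located by exponential bracketing plus integer
bisection and validated in the tests by self-consistency
(p(lsn) ≤ α < p(lsn−1)) and a brute-force integer scan — not against any
particular software's output, since published lsn implementations do not
document whether df₂ is recomputed at the candidate size. Recomputation is
the default here; `fixed_df2=True` switches to the frozen-df variant.
α is 0.05 throughout. Effects too small to cross below m = 10⁹ raise at the
operation level; the pipeline records the cap value instead so the pair
ranks (jointly) last.

## Rank aggregation and the Wilcoxon comparison

Within each SNP column the indices are competition-ranked by lsn (ties share
the minimum rank; following ranks are skipped — the scheme is forced by the
benchmark table, which shows two indices at rank 3 followed by rank 5). Rank
sums over a SNP subset are aggregated the same way into the final ordering.
When two subsets partition the panel, their rank sums add to the overall
rank sum by construction.

Whether an index systematically outranks the reference is tested with a
two-sample Wilcoxon rank-sum test on the two vectors of per-SNP ranks:

* `method="exact"` (default): complete enumeration of all C(n_a+n_b, n_a)
  group assignments of the pooled values with midranks for ties; two-sided
  p = min(1, 2·min(tail probabilities)). scipy's exact mode declines tied
  data, so the enumeration is implemented here and cross-checked against
  scipy on tie-free inputs and against Monte-Carlo permutation with ties.
* `method="normal"`: large-sample normal approximation with tie-corrected
  variance and continuity correction — the convention of classical
  statistical packages. On 6-vs-6 rank vectors it is slightly more
  conservative than enumeration; on the bundled benchmark matrix the
  borderline comparison (C-peptide 30 min vs HOMA-B) is significant under
  enumeration (p = 0.0455) but not under the corrected approximation
  (p = 0.052), which is the variant that matches the published significance
  pattern for all eleven comparisons.

Subset-level Wilcoxon p-values (3 ranks per group) are computed on request
but labelled exploratory: with C(6,3) = 20 assignments the smallest
attainable two-sided p is 0.1.

## Synthetic cohort generator

There is no public cohort with per-subject OGTT curves and candidate-SNP
genotypes, so the generator emulates one. It is a structural, not
physiological, model: no ODEs, no incretin concentrations — only the
latent-component skeleton the indices probe.

Each subject has four lognormal latents: sensitivity S (declining in BMI and
age), basal secretion B (realised as true fasting insulin, elasticity −0.7
in S — compensatory hyperinsulinaemia), early-phase amplitude E and incretin
potentiation K (both mildly coupled to B). SNPs are Binomial(2, MAF) in HWE
without LD, and each minor allele multiplies its routed component by a fixed
factor. The OGTT curves are kernel mixtures on the 0–120 min grid: glucose
rises by R·(0, 1, 0.85, 0.45, 0.18) with R shrinking in S and E; insulin is
B·(1 + 7.5·E·g + 2.2·K·h) with the early kernel g peaking at 30 min and the
incretin kernel h plateauing over 60–120 min; C-peptide mirrors insulin at
~11× concentration with slower decay (its longer circulating half-life), so
its 0–120 AUC is dominated by the K-driven plateau. IVGTT insulin, generated
for a configured fraction (default 0.2), has an acute response proportional
to B·E. Kernel weights and gains were chosen once to reproduce the marginal
structure of the target cohort (fasting glucose ≈ 4.9–5.0 mmol/l, fasting
insulin ≈ 52 pmol/l, 30-min insulin ≈ 450 pmol/l, fasting C-peptide ≈ 575
pmol/l) and the route dissociation that makes the ranking question
non-trivial: an early-phase allele moves IGI/CIR/0–30 AUC ratios at least
twice as strongly (standardized) as the 0–120 C-peptide ratio, and vice
versa.

Noise is multiplicative lognormal per sample (assay CV 3/10/8% for
glucose/insulin/C-peptide, biological CV 5%, combined in quadrature), which
makes the loge-transformed regression model correctly specified under the
default generator; `noise_model="additive"` is a deliberate
misspecification stress switch. A 3% fraction of "flat responders" with a
collapsed early phase produces occasional measured I₃₀ < I₀ and with it a
realistic ≈1% negative-index exclusion rate; `n_planted_negative` plants
guaranteed exclusions for testing the exclusion bookkeeping. Family
structure is not simulated (the analysis assumes independent subjects).

What passing tests on these cohorts do **not** show: robustness to assay
batch effects, relatedness, linkage disequilibrium, population
stratification, or real OGTT curve shapes (multiphasic or delayed-peak
responders beyond the flat-responder caricature). Results on real cohorts
depend on those features.

## Numerical and design choices

* Deterministic outputs: a (config, seed) pair fixes cohorts bit-for-bit;
  tables are written with a fixed `%.10g` float format so reruns are
  byte-identical.
* Exact Wilcoxon enumeration is capped at 5·10⁶ combinations (n ≤ 12 per
  group is the intended regime); larger inputs must use `method="normal"`.
* Quartile cuts are lower-inclusive (`value ≥ cut` moves a value up); an
  all-equal covariate collapses to the reference level with a warning.
* The default study sizes used by the heavier validation tests — 500 null
  cohorts of N = 1500 for type-I calibration and 100 cohorts per route
  (per-allele factor 0.9) for parameter recovery — were chosen as the
  smallest designs at which the binomial noise of the checked rates is well
  inside the asserted bands.
* The twelve-index panel, six-SNP benchmark matrix and GSIS/ISIS subset
  definitions ship in `ogttrank.datasets`; the reference index for Wilcoxon
  comparisons is configurable everywhere (default HOMA-B).

## Known limitations

* lsn extrapolates the observed effect size to other sample sizes under a
  fixed-δ², fixed-σ̂² idealisation; it is a ranking device, not a sample-size
  planning tool.
* The reverse (genotype-as-dependent) model is a linear probability fit;
  its p-values are asymptotically valid but its coefficients have no
  dose-response interpretation.
* The generator's route specificity is built in by construction; recovery
  tests validate the pipeline's ability to read it out, not the biological
  claim itself.
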
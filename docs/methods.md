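# Methods

## The problem

Gene–environment interaction (GEI) scans ask, per SNP, whether the effect of
a variant on a quantitative trait depends on an exposure — here whether SNP
effects on HDL cholesterol (mg/dL) depend on weekly alcohol consumption
(oz/week).  Longitudinal family cohorts carry two correlation sources at
once: repeated measures within a person and phenotypic resemblance within a
family.  Ignoring either inflates test sizes; modelling both honestly is the
package's job.

## Mean models and tests

For person-visit response `Y` with common covariates `C` (age, sex, BMI,
anti-lipid medication use), exposure `E` (alcohol), and additive SNP dosage
`G` (count of minor alleles, 0/1/2):

    Model 1:  E[Y] = α + β_c'C + β_e E
    Model 2:  E[Y] = α + β_c'C + β_e E + β_g G
    Model 3:  E[Y] = α + β_c'C + β_e E + β_g G + β_ge G·E

All fits are full maximum likelihood (not REML — the likelihood-ratio tests
below compare fixed-effect structures, which REML likelihoods cannot).
Three LRTs per SNP:

* genetic main effect, H0: β_g = 0 — Model 1 vs 2, χ²(1);
* GEI given the main effect, H0: β_ge = 0 — Model 2 vs 3, χ²(1);
* joint, H0: β_g = β_ge = 0 — Model 1 vs 3, χ²(2).

The three statistics come from one nested chain, so joint = main + GEI
exactly (up to clipping: statistics in (−10⁻³, 0) are set to 0 as roundoff;
anything below −10⁻³ is logged as an optimizer failure).  Reference
distributions are the asymptotic χ², with no small-sample correction.

## Covariance families

Let T be the number of grid visits and n the family size.  Cells are ordered
visit-major, then members in pedigree order; every family matrix is the
principal submatrix of the full T·n grid matrix at the observed cells, which
preserves positive definiteness under missingness.

**Kronecker (KRC)** — `V = Σ_visit ⊗ Ω_family`, with `Σ_visit` an
unstructured T×T SPD matrix and `Ω_family` compound-symmetry.  The Kronecker
scale is not identified (`(cΣ)⊗(Ω/c)` is the same model), so `Ω_family` is
constrained to a *correlation* matrix (unit diagonal, off-diagonal `ρ_f`) and
`Σ_visit` carries all variances.  `Σ_visit` is parameterized by log-Cholesky
(lower-triangular factor with log-diagonal), so any real vector maps to an
SPD matrix; `ρ_f` maps through a scaled logistic onto
`(−1/(n_max−1), 1)` with `n_max` the largest family in the dataset (the
parameter is global, so the bound must hold for the worst family).

**Hierarchical (HLM)** — a family random intercept with variance `σ²_f`
shared by all of a family's person-visits plus within-individual ARMA(1,1)
serial correlation scaled by `σ²_e`:

    cov[(i,t),(j,t')] = σ²_f + σ²_e·γρ^{|t−t'|−1}   (i = j, t ≠ t')
                        σ²_f + σ²_e                  (i = j, t = t')
                        σ²_f                         (i ≠ j)

The ARMA(1,1) convention is the SAS one, lag-k correlation `γρ^{k−1}`; AR(1)
is the special case γ = ρ.  Variances pass through log transforms, γ and ρ
through tanh.  Not every (γ, ρ) pair in (−1,1)² yields a PD matrix for a
given T; invalid proposals are handled by the optimizer penalty below rather
than a hard constraint.  No individual-level random intercept is added
beyond the ARMA structure — with it the lag-k correlation would not decay to
zero, and the family intercept already absorbs the shared level.

For T = 1 the two families coincide exactly: KRC with variance σ² and
correlation ρ equals HLM with `σ²_f = σ²ρ`, `σ²_e = σ²(1−ρ)` (the ARMA pair
drops out of the likelihood entirely; its gradient is identically zero and
the optimizer simply leaves it at the start).

## Estimation

The marginal likelihood is a product of family blocks.  Fixed effects are
profiled out by GLS at each covariance-parameter value θ, leaving

    −ℓ(θ) = ½ Σ_f [ r_f' V_f⁻¹ r_f + log det V_f + m_f log 2π ],
    r_f = y_f − X_f β̂(θ),  β̂(θ) = (Σ X_f'V_f⁻¹X_f)⁻¹ Σ X_f'V_f⁻¹y_f.

Gradients are analytic: `∂(−ℓ)/∂θ_k = ½ Σ_f [tr(V_f⁻¹ V̇_f) − u_f'V̇_f u_f]`
with `u_f = V_f⁻¹ r_f`; the β̂(θ) dependence contributes nothing because the
GLS score in β is zero at β̂ (envelope theorem).  Template covariances and
their derivative stacks are built once per distinct family size per
evaluation and subset per family, so an evaluation costs one small Cholesky
per family plus two einsums per family for the gradient.

Optimization is L-BFGS-B on the unconstrained transformed scale with
`ftol = 10⁻¹³`; because L-BFGS-B often halts on the objective test with a
loose gradient, up to two restarts (which reset the Hessian approximation)
polish the optimum.  Convergence requires a finite objective and max-norm
gradient below `10⁻⁵·√n_obs` (the objective is a sum of ~n_obs terms, so
component gradients inherit that scale).  Non-PD proposals return a large
penalty (10¹⁰) with zero gradient so line searches back off instead of
crashing.

Starting values: three starts by default — (1) method-of-moments from OLS
residuals (per-visit residual covariances seed `Σ_visit`, shrunk 15% toward
its diagonal and eigenvalue-floored; within-family same-visit cross-products
seed `ρ_f`/`σ²_f`; lag-1/lag-2 autocovariances seed γ, ρ), (2) an
identity-scaled default, (3) the MoM start with N(0, 0.05²) jitter.  In the
per-SNP scan, Models 2 and 3 warm-start from the previous model's optimum
(falling back to the full multi-start on failure), and the SNP-free Model 1
is fitted once and cached — keyed by the set of genotype-dropped
individuals, so every LRT compares models fitted to the identical sample.

Fixed-effect uncertainty is reported both model-based (`A⁻¹`) and
cluster-robust with families as clusters (`A⁻¹BA⁻¹`, B the sum of per-family
score outer products).  P-values come from the LRTs; the sandwich standard
errors are reported alongside (a robust LRT correction is deliberately not
invented — the robust covariance informs effect-size uncertainty, not the
χ² reference).

## HWE filtering

Genotype-count tests assume independent individuals, so counts are taken
from founders only (members with no parents in the pedigree, including
married-in spouses).  The exact test conditions on the observed minor-allele
count and sums the probabilities of all heterozygote counts no more likely
than the observed one; probabilities are computed in log space and
normalized, making totals in the thousands safe.  Mid-p is not used.  SNPs
with P strictly below 10⁻⁶ are excluded before scanning.

## Synthetic data

The generator supplies every structure the analysis assumes, with defaults
chosen once to echo a large longitudinal cardiovascular cohort:

* **Pedigrees** — 60% nuclear (2 founder parents + 1–4 children), 40%
  three-generation (2 founder grandparents, their child + married-in founder
  spouse, 1–4 grandchildren); sizes 3–8.
* **Genotypes** — founder dosages Binomial(2, maf), maf ~ U(0.1, 0.5) per
  SNP; children inherit one uniformly chosen allele per parent.
* **Covariates** — age from a generation-dependent baseline (~72/62/38 y)
  advancing 4 y per visit; BMI ≈ 27.3 ± 5 with a persistent individual level;
  alcohol zero-inflated lognormal (30% abstainers; drinkers
  exp(N(1.0, 0.8²)), giving mean ≈ 2.6, SD ≈ 4 oz/week) with AR(1)
  autocorrelation 0.7 across visits — exposure stability matters for GEI
  power, so it is a config knob; medication use Bernoulli with log-odds
  rising in visit and age (≈9% early to ≈20% at the last visit); 46.7% male.
* **Phenotype** — Models 1–3 mean structure (defaults α = 65, β_age = 0.2,
  β_male = −10, β_bmi = −0.8, β_med = 4, β_e = 0.5, all mg/dL) plus
  family-block MVN noise under either truth.  KRC truth: Σ_visit =
  160·(ARMA(1,1) with γ = 0.7, ρ = 0.85), ρ_f = 0.25; HLM truth: σ²_f = 40,
  σ²_e = 120, γ = 0.7, ρ = 0.85 — marginal SD ≈ 12.6 on top of covariate
  variance, total ≈ 15 mg/dL, familial correlation 0.25.
* **Missingness** — response-only, MCAR: monotone dropout hazard 0.03 per
  visit plus 5% intermittent skips.  ML on complete cases is valid under
  this mechanism by construction.

What the generator does *not* emulate: ascertainment, genotyping error,
population stratification, informative dropout, covariate missingness, and
cohort-specific visit-date misalignment (everyone shares one visit grid).
Passing tests therefore demonstrate internal statistical correctness of the
machinery, not robustness to those real-data complications.

Dataset variants mirror the study design: `last1` keeps the most recent
grid visit (cross-sectional), `alternate3` keeps visits 1, 3, 5 of the
5-visit grid, `all5` keeps everything.

## Problem sizes used in the checks

Chosen as desk-scale versions of the study conditions: null-calibration at
150 replicates × 60 families × 3 visits; the method-concordance check at 120
families × 20 SNPs (12 null, 4 main-effect, 4 GEI) in the test suite and 200
families × 50 SNPs (30/10/10) in `scripts/acceptance.py`; power-gain at 150
families × 10 GEI SNPs; parameter recovery at 100 replicates × 150 families.
Non-null effect sizes default to β_g = 2.5 mg/dL per allele and β_ge = 0.5
mg/dL per oz/week per allele — large-effect-locus territory, appropriate for
power comparisons at a few hundred families.

## Known limitations

* The KRC likelihood has `T(T+1)/2 + 1` covariance parameters; at 5 visits a
  scan is roughly an order of magnitude slower than HLM even with analytic
  gradients — the computational asymmetry that motivates the method
  comparison in the first place.
* CS familial correlation treats all relative pairs alike; a kinship-matrix
  `Ω_family` is out of scope.
* AR(1)⊗CS and other Kronecker variants are not implemented.
* Degenerate designs (monomorphic SNPs, constant covariates) are refused or
  flagged, not silently repaired; scans record such SNPs with missing
  P-values and convergence flags rather than dropping rows.
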
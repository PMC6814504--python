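# Methods

This note documents the models, the estimation conventions and the design
choices behind `twinfactor`, in the order the pipeline runs.

## Measurement: the orthogonal bifactor model

Eight parent-rated ODD symptoms are modelled as continuous indicators of a
general factor (all items) plus one of two specific factors — irritability
(temper, touchy, angry) or defiant behavior (argues, defies, annoys,
blames, spiteful).  Factors are mutually orthogonal with unit variance;
this is the identification constraint, and the factor covariance is never
freed.  Estimation is plain normal-theory ML on the sample means and
covariance (means saturated), with at least five jittered starts and the
largest-likelihood solution retained; loading signs are fixed so the first
loading of each factor is positive.  Robust (sandwich/scaled) corrections
are not implemented: they alter standard errors and chi-square scaling, not
the point estimates that all downstream analyses and recovery checks use.

Two practical identification caveats, verified in the test suite:

* a bifactor pattern with *constant* loadings within blocks is empirically
  underidentified (general and specific columns trade off); the synthetic
  generator therefore defaults to item-varying loadings;
* when a specific factor's variance is truly zero, a lone specific loading
  trades exactly against the item residual (`lambda^2 + theta` is what is
  identified), so near-null specifics should be judged by their *shared*
  covariance contribution, not by individual loadings.

Factor scores use the regression method, `F = Lambda' Sigma^-1 (x - mu)`,
computed per child from the pooled (both twins stacked) solution; the pair
structure is deliberately ignored at the measurement stage and handled by
the biometric stage.  Score variances are at most 1 per factor
(shrinkage), so scored-variable analyses see attenuated variance, which is
immaterial because every downstream model standardizes or fits variance
freely.

## Phenotypic regressions

Each external dimension is regressed on the three factor scores plus a
caller-specified covariate set; all variables are z-scored first, so
coefficients are standardized betas.  The variance explained by the ODD
factors is the R-squared *increment* over the covariate-only model — with
orthogonal predictors and no covariates this equals the sum of squared
betas.  Point estimates come from pooled OLS; because children within a
pair are correlated, a cluster-robust covariance (pairs as clusters) is
available for inference.  Age should be centered/scaled before squaring
(the fit refuses condition numbers above 1e8).

Sex invariance is tested by a likelihood-ratio comparison of a model with
the three ODD coefficients shared across the sexes against one with
sex-specific deviations (df = 3); both models' BICs are reported so
criterion disagreements stay visible.

## Univariate twin models

Pre-interaction phenotype: `P* = a A + c C + d D + e E` with component
correlations (MZ, DZ) of (1, .5) for A, (1, .25) for D, C shared within a
pair, E twin-specific.  `c` and `d` are never simultaneously free (not
identified with twins only).  A sibling-interaction / rater-contrast path
couples the observed pair: `P = (I - B)^-1 P*`, `B = [[0, s], [s, 0]]`,
`|s| < 1`.  A nonzero `s` makes observed variance zygosity-dependent,
which is its identifying signature.

Estimation minimizes the two-group discrepancy

    F = sum_g N_g [ ln|Sigma_g| + tr(S_g Sigma_g^-1)
                    + (mbar_g - mu)' Sigma_g^-1 (mbar_g - mu)
                    - ln|S_g| - 2 ]

with biased (1/N) sample covariances and the `N_g` multiplier — fixed
conventions so the chi-square (`F` at the minimum) is reproducible.  Means
and variances are equated across twin order and zygosity (one free mean);
with ten observed statistics this yields df = 6 for ACE, 7 for AE, 6 for
AE+s, matching the degrees of freedom of the source analyses.  Parameters
are estimated as paths bounded at zero (implied variances nonnegative by
construction; only `s` may be negative); optimization is bounded
quasi-Newton (L-BFGS-B, objective tolerance 1e-10) from five jittered
moment-based starts.  Boundary solutions are reported, never hidden.
Profile-likelihood CIs (3.84 chi-square drop) are available per path.

**Component standardization.**  Without a contrast, components are squared
paths over the total `a^2 + c^2 + d^2 + e^2` and sum to 1.  With a
contrast the reported components are the *raw squared paths*, which equal
pre-contrast variance shares only when the generating pre-contrast
variance is 1 and need not sum to 1 (the contrast inflates or deflates
observed variance asymmetrically by zygosity).  Raw squared paths are
always exposed alongside; users combining contrast and non-contrast rows
in one table should note the convention switch.

The independence baseline for the TLI is the E-only model (closed form:
grand mean, pooled mean squared deviation).

## Multivariate Cholesky models

Four observed variables per twin (general factor score first, external
dimension last) are decomposed into lower-triangular A/C/E factor systems;
within-twin covariance `L_A L_A' + L_C L_C' + L_E L_E'`, cross-twin
`r_A L_A L_A' + L_C L_C'`.  Every component covariance is PSD by
construction at every iterate.  The C structure may be full, a single
loading on the general factor, or absent; a further restriction zeroes the
general factor's A and E loadings on the two specific factors — if the
data contain a real general factor this must fit dramatically worse, which
is the etiological analogue of testing the bifactor structure.  An
optional contrast couples the twins' external variable through the 8x8
`(I - B)^-1` transformation, applied symmetrically to both twins.

Factor scores are treated as *observed* variables here; no attempt is made
to fit the measurement and biometric stages jointly.  Means are fixed at
zero by default (the inputs are standardized scores), giving df = 88 - k
against the 88 observed statistics of the two groups — this convention
reproduces the source df ladder (58 / 67 / 68 / 72 without contrast);
free means are available for non-centered data.

Initialization re-uses the classical moment decomposition
(`Sigma_A ~ 2(X_MZ - X_DZ)` etc., eigenvalue-clipped to PSD and
re-factorized).  Local identification is checked from the
finite-difference Hessian of the discrepancy at the optimum; a
rank-deficient Hessian is reported as `status = "not identified"` with the
decomposition still computed but not to be trusted — mirroring how
unidentified full-with-contrast models are handled in practice.

The external variable's variance decomposes into squared standardized
loadings: via the factor anchored at each earlier variable plus a unique
residual, per component; shares over all fitted components sum to 1 in
no-contrast models.  Swapping the two specific factors is a
reparameterization, so per-component *totals* are invariant (checked to
1e-6 by refitting from the permuted re-factorization of the first
optimum), while the third-position shares are the order-dependent
quantities of interest: a specific factor's unique overlap with the
external dimension after both other ODD factors are accounted for.

## Fit statistics

chi2 = -2lnL(model) + 2lnL(saturated); AIC = -2lnL + 2k; BIC uses the
total number of sampling units over groups (pairs for twin models),
likewise RMSEA = sqrt(max(chi2 - df, 0) / (df N)) with its CI from
noncentral-chi-square inversion; TLI against the independence baseline;
RMSR as the RMS of standardized residual moments (covariances, plus means
where a mean structure is modelled).  df = 0 models report RMSEA/TLI as
undefined rather than 0/1.  `model_selection` reports the winner per
criterion and never silently tie-breaks disagreements.

## Synthetic data: what it does and does not emulate

Defaults mirror the study conditions the package validates against: 392 MZ
and 454 DZ pairs, children 6-18 (age uniform; pairs same-sex), 0-4 ordinal
symptom ratings produced by thresholding continuous liabilities at
right-skewed cut-points (0.25, 0.85, 1.5, 2.1 on a unit-variance liability,
putting ~60% of children at 0).  Latent factors carry the published
best-fitting decompositions (general ACE .41/.13/.46; irritability AE
.64/.36; defiant AE .68/.32) and external dimensions are built from the
published standardized coefficient rows plus an AE-structured residual
scaled to unit total variance.

Not emulated: missing data, opposite-sex DZ pairs, rater disagreement
(single-informant design), measurement non-invariance by sex or age, and
any non-normality beyond the threshold discretization.  Passing recovery
tests therefore demonstrate the *estimators* are correct under the stated
model, not that the model is right for any particular cohort.

A continuous (non-discretized) path exists alongside the ordinal one, and
all recovery analyses use it: whether the original items should be treated
as continuous or ordinal is left open, and no claim is made either way.

## Numerical choices and problem sizes

* Biased covariances and `N_g` discrepancy weights throughout (see above).
* Optimizer tolerances: 1e-10 (univariate) / 1e-12 (multivariate) on the
  objective; 5 starts everywhere; results preferring cleanly converged
  runs unless a non-converged run is materially better.
* Recovery experiments run at 50,000 pairs per zygosity group (univariate,
  multivariate) and 100,000 subjects (regression); at these sizes the
  Monte Carlo standard error of a variance component is below .01.  The
  acceptance script averages five independent 50k replicates per
  univariate target, since the ACE decomposition's A/C trade-off leaves a
  single replicate's c-squared with an SE near .007.
* The R-squared values printed for some outcomes in the source table are
  inconsistent with the sum of squared coefficients under orthogonal
  predictors; recovery checks use the conduct-disorder row, where the
  orthogonal-predictor identity holds (R2 = .3642).

## Known limitations

* Ordinal-liability (threshold) biometric fitting is not implemented; the
  biometric stages assume continuous inputs.
* Sex-limitation biometric models, extended pedigrees, and
  independent/common-pathway alternatives to the Cholesky are out of scope.
* Profile CIs refit the model per probe point and are the slowest
  operation; they are off by default.
* The RMSR variant here is an SRMR over standardized residual moments;
  other software reports differently scaled residual summaries, so only
  within-package comparisons are meaningful.
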
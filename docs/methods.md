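# Methods

## Data-generating mechanism

Mean-difference data sets hold 100 studies with control/treatment group
means, SDs and group sample sizes; correlation data sets hold a correlation
coefficient and one sample size per study. Defaults (all configurable):

| column  | distribution                       | default              |
|---------|------------------------------------|----------------------|
| mean_c  | truncated normal, lower 0.001      | mean 1, SD 0.25      |
| mean_t  | truncated normal, lower 0.001      | mean 2, SD 0.5       |
| sd_c    | truncated normal on [0.01, 1]      | mean 0.25, SD 0.125  |
| sd_t    | truncated normal on [0.01, 1]      | mean 0.5, SD 0.25    |
| n_c, n_t| truncated Poisson, lower 5         | λ = 10               |
| r       | truncated normal on [−1, 1]        | mean 0.5, SD 0.125   |
| n       | truncated Poisson, lower 5         | λ = 10               |

Truncated normals are sampled by inverse-CDF transform on the truncated
interval (exact, deterministic cost; rejection sampling can stall under
extreme truncation). The truncated Poisson uses rejection with a 1,000-round
cap and an inverse-CDF table fallback; at λ = 10 with lower limit 5 the
acceptance rate is ≈ 0.97. Group means are drawn independently across
control and treatment groups.

All columns are drawn independently, so the generated data sets have *no*
built-in correlation between effect size and precision — that correlation
is introduced only by the corMCAR rearrangement, which sorts the
(mean_c, mean_t), (sd_c, sd_t) and (n_c, n_t) pairs as units and zips them
so that larger raw effects get smaller summed SDs and larger summed SSs.
Pairing is exact (a deterministic permutation of each column family), the
strongest version of the scenario; ordering uses the *uncorrected* log
ratio (or raw r) so that it never depends on the SD columns being permuted.

What the generator deliberately does not emulate: publication bias,
heteroscedastic or unbalanced designs, non-normal outcome distributions,
and wide or skewed SD/SS ranges. Passing tests therefore speak to the
behavior of the treatments under a clean, independent, truncated-normal
world, not to robustness against those real-data features.

## Missingness

Deletion always removes the within-row pair (both group SDs, or both group
SSs); SD and SS deletions are sampled independently. Exactly
round(fraction × n) rows are masked, chosen by weighted sampling without
replacement:

* MCAR, corMCAR — uniform weights;
* MAR — weights proportional to the rank position of the effect size when
  effects are ranked in decreasing order (smallest effect → largest
  weight). Rank itself is the minimal "linearly increasing" scheme; no
  proportionality constant is assumed;
* MNAR — weights proportional to the sum of the rank of the summed SDs
  (increasing) and the rank of the summed SSs (decreasing), so imprecise
  and small studies lose their values most often.

Ties are broken by original row order for determinism. Deletion fractions
span 10%–90%. The default grid is `linspace(0.10, 0.90, 16)`: sixteen
equally spaced steps (≈5.3% spacing) that keep both endpoints and make the
default factorial enumerate exactly 2,560 incomplete data sets
(4 scenarios × 4 deleted-data types × 10 replicates × 16 fractions).
A 5%-spaced grid over the same range would have 17 steps and 2,720 data
sets; the 16-step grid was chosen as the design consistent with the
factorial total.

## Effect sizes

* Bias-corrected log response ratio:
  yi = ln(m_t/m_c) + ½[sd_t²/(n_t m_t²) − sd_c²/(n_c m_c²)],
  vi = sd_t²/(n_t m_t²) + sd_c²/(n_c m_c²) + ½[sd_t⁴/(n_t² m_t⁴) + sd_c⁴/(n_c² m_c⁴)].
* Hedges' d with J = 1 − 3/(4(n_c+n_t−2)−1), pooled SD from the two group
  SDs, vi = (n_c+n_t)/(n_c n_t) + d²/(2(n_c+n_t)).
* Fisher's z = artanh(r), vi = 1/(n−3).

The unweighted and SS-weighted treatments (options 2–3) evaluate the
*simple* log response ratio ln(m_t/m_c) for every row: it is the only form
computable when SDs are missing, and using it uniformly avoids mixing two
estimands inside one fit. The bias-correction term is O(1/n) and far below
the deviation tolerances here. SS-weighting is not applicable to Hedges' d
— the metric itself needs the SDs the approximation is meant to replace —
and is emitted as a structured "skipped" record.

## Imputation

Imputed SDs are restricted to [0.01, 1]; imputed SSs are rounded to the
nearest integer and restricted to ≥ 5 (the rounding rule is this package's
choice; donor-based methods inherit integrality from their donors).
Model-based methods redraw out-of-bounds values up to 10 times, then clamp.

Chained equations: missing cells are initialized by random draws from the
observed values, then the engine cycles 5 times (a conventional default)
through the order sd_t, sd_c, n_t, n_c, refitting the per-column model and
redrawing. Predictors are the group means (or r) plus any fully observed
SD/SS columns. With that predictor set the per-column models do not feed
back through other imputed columns, so the cycles are redraws rather than
genuine updates; the loop is kept for fidelity to the chained-equations
recipe, and reversing the imputation order shifts pooled grand means only
within their pooled uncertainty (tested).

Plug-ins: *linear regression* draws coefficients from their
normal–inverse-gamma posterior and adds residual noise ("proper"
imputation, so the between-imputation variance B > 0); *PMM* matches each
posterior-draw prediction to one of its 5 nearest observed donors;
*Bayes PMM* does the same under a weakly informative ridge prior; *CART*
uses one tree (minimum leaf 5) and draws a donor from the prediction's
leaf; *random forest* grows 10 bootstrap trees and draws a donor from a
randomly chosen tree's leaf.

*Bootstrap EM* resamples rows, fits the multivariate-normal MLE by EM
(tolerance 10⁻⁶, up to 1,000 iterations — high missingness slows EM
markedly), then draws each row's missing cells from their conditional
normal, truncated to bounds by redrawing. Data sets with more than 60%
missing values in any column are refused with a structured "skipped"
record, mirroring the algorithm's operational fragility above that point;
individual non-convergent imputations become failure records, never crashes.

*missForest-style* imputation initializes with column means and iterates
random-forest regression (100 trees) per column — here every other column,
including currently imputed ones, is a predictor, because the iteration is
the point of the algorithm — stopping when the change in imputed values
first increases (the previous iterate is returned) or after 10 iterations.

*Additive regression + bootstrap PMM* bootstraps rows, fits a cubic-spline
regression per target column, and matches each prediction to the nearest
observed value.

All methods are identity on complete data and are repeated m = 100 times by
default (m is scaled down where noted below).

## Meta-analysis

τ² is estimated by REML: the profile restricted log-likelihood is maximized
over τ² ∈ [0, 10·var(y)] by bounded scalar minimization (tolerance 10⁻¹⁰)
with the τ² = 0 boundary checked explicitly. The fit matches R's
`metafor::rma(..., method="REML")` to ~10⁻⁵ (cross-checked in the test
suite) and a brute-force grid maximization to ~10⁻⁷. CIs use the normal
1.96 quantile; no Knapp–Hartung or Barnard–Rubin adjustment is applied, so
coverage at k = 50 is a shade below nominal (~94.5%), which is the known
small-k behavior of the Wald interval.

The unweighted treatment is the intercept-only mixed model with equal
weights and *no* known sampling variances: its REML solution is
µ̂ = mean(y), SE = sd(y)/√k. Fixing all vi = 1 inside the
inverse-variance machinery instead would put the SE on an arbitrary scale
(≈ √((1+τ²)/k)) and misstate the CI by a factor of ~3 under the default
generator; the data-driven variance is what an unweighted LMM actually
estimates.

Rubin pooling averages the per-imputation grand means and combines
variances as W̄ + (1 + 1/m)B; failed imputations are excluded with m_used
recorded; with m = 1 pooling is the identity.

## Experiment

Deviations are replicate-matched: each treatment estimate is compared with
the fully informed weighted analysis of the *same* complete data set (for
corMCAR, of the sorted complete data set, since sorting re-pairs rows and
changes the effect sizes). Per-cell seeds are derived from the master seed
and the cell coordinates, so cells are decoupled and reruns are
byte-identical. Cell failures (e.g., too few complete rows at 90% deletion)
are recorded and never abort the sweep. Summaries average over replicates
only. In figure output the CI-width deviation is halved for visibility;
stored records keep the full width.

Problem sizes: the shipped default is the full design (2,560 data sets,
m = 100), sized for a long unattended run. The test suite and the
acceptance script exercise the same code on reduced designs — one scenario,
4 fractions, 10 replicates, m = 5, and the omission/unweighted/SS-weighted
sweep — chosen as the smallest designs whose Monte-Carlo error is well
below the tolerances being checked (e.g., the 0.05 "unbiasedness" tolerance
on the lnRR scale against an observed max deviation ≈ 0.004).

## Known limitations

* The nine multiple-imputation methods follow the published descriptions of
  the corresponding R packages (mice, mi, Amelia, missForest, Hmisc) but
  are not bit-compatible reimplementations.
* Sampling-without-replacement deletion makes per-row inclusion
  probabilities only approximately proportional to the MAR/MNAR weights
  (exactly proportional for the first draw); the monotone-in-rank property
  is preserved and tested.
* No publication-bias, dependence or moderator structure; one effect per
  study.
* The "unbiased" tolerances (0.05 on the lnRR/z scale) are design choices
  exposed in configuration, not estimated quantities.
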
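# Methods

## Unit of analysis and data model

The unit of analysis is the randomized pairwise comparison (experimental vs
control arm) within a population stratum, not the trial. A three-arm trial
contributes two comparisons with the control arm duplicated; the shared
control is recorded (`shares_control_with`) but no covariance adjustment is
made between such comparisons — they enter the regression as independent
points. Each comparison carries, per subgroup (ITT/overall, male, female),
the OS and PFS hazard ratios with 95% CIs and the number randomized.

Log effects use the natural logarithm throughout. The standard error of a
log-HR is reconstructed from its 95% CI as

    se = (ln hi − ln lo) / (2 × 1.959964),

assuming a symmetric normal interval on the log scale. The quantile is kept
at full precision (1.959964, not 1.96) so that CI→SE→CI round-trips are
stable. HRs in the packaged dataset are stored exactly as published (two
decimals); no de-rounding is attempted, which is why reproduced statistics
can differ from the published ones in the second decimal.

## Weighted surrogacy regression

ln OS-HR is regressed on ln PFS-HR by weighted least squares with weights
equal to randomized N. Weights are *relative* precision weights and are
rescaled to mean 1 before fitting; this changes no coefficient, R² or
p-value but fixes the scale of the residual variance s² so that "a future
trial of average size" corresponds to weight 1 in the prediction band.

R² is defined as 1 − SS_res,w / SS_tot,w with the weighted total sum of
squares taken about the *weighted* mean of y — the convention under which,
for the simple model, R² equals the squared weighted Pearson correlation of
x and y (asserted to 1e−10 in the tests). The treatment-class-adjusted
analysis adds an ICI+chemotherapy indicator and reports the squared partial
correlation of y with x given the indicator, computed as
(SS_res,reduced − SS_res,full)/SS_res,reduced where the reduced model drops
x; this equals t²/(t² + df) for the x coefficient's t statistic. If the
indicator is constant in a stratum the adjusted model reduces exactly to the
unadjusted fit with partial R² = R². Slope inference uses the t distribution
with df = k − p and no small-sample correction.

The fitting engine is statsmodels WLS; the prediction band, STE search,
bootstrap and cross-validation logic are implemented here. Tests check the
band against statsmodels' own weighted prediction interval and the fit
against brute-force SSE minimization, keeping implementation and oracle on
separate routes.

## Bootstrap confidence intervals

The 95% CI for R² (or partial R² in adjusted analyses) is a percentile
bootstrap over comparisons: (x, y, weight, indicator) rows are resampled
with replacement, the model refitted, and the 2.5/97.5 percentiles of the
1000 resampled statistics reported. Whether the original analysis resampled
comparisons or residuals is not documented; comparison resampling is the
standard choice for trial-level surrogacy and is what is implemented.
Rank-deficient resamples (e.g. one distinct x value) are redrawn, with a
hard failure after 10 × n_boot redraws. BCa intervals are not implemented;
the percentile method is the package's single bootstrap convention. All
resampling flows from one integer seed.

## Leave-one-out cross-validation

Each comparison is left out once; the stratum model refitted on the rest
predicts its ln OS-HR. The cross-validated R² is the squared correlation
between the k held-out predictions and the observed values, **weighted by
randomized N** by default. The weighted correlation is the package default
because the cross-validated model is itself N-weighted and because the
weighted version reproduces all published sex- and treatment-stratified
cross-validation results simultaneously, which the unweighted version does
not; `weighted_correlation=False` gives the plain Pearson variant. The
LOOCV model mirrors the headline model of its stratum: adjusted for the
all-treatment sex strata, unadjusted within treatment-type strata.

## Surrogate threshold effect

The 95% prediction band for a future comparison with relative weight w_f at
x₀ is

    ŷ(x₀) ± t_{df,0.975} · sqrt( s² · ( 1/w_f + x₀ᵀ (XᵀWX)⁻¹ x₀ ) ),

with all weights on the mean-1 scale and w_f = future_N / mean(N of fitted
comparisons). By default future_N is the mean randomized N of the stratum
being analyzed, i.e. an average-sized future trial (w_f = 1). The STE is the
root of [upper limit](x) = 0, located by scanning ln HR ∈ [ln 0.05, 0] on a
513-point grid and refining by Brent's method to 1e−8; HR = 0.05 is far
below any plausible treatment effect, so the floor is not a binding choice.
If the upper limit is nonnegative over the whole interval the STE is
reported as non-estimable (this occurs in the female ICI-monotherapy
stratum, where the association is weak); if it is negative everywhere the
boundary value 1 is reported with a warning; with multiple sign changes the
root closest to HR = 1 is reported with a warning.

The STE is computed from the *unadjusted* stratum model — the same model
that defines the headline R² — which is the definition that reproduces all
published per-stratum thresholds. For adjusted fits an STE is also
available, evaluated with the treatment indicator at its weighted mean (a
marginal band); it is reported alongside but is not the default definition.

## Random-effects pooling

Per-endpoint pooled HRs use the DerSimonian–Laird moment estimator
(fixed-effect weights 1/se², Q, τ² = max(0,(Q−df)/(Σw−Σw²/Σw)),
random-effects weights 1/(se²+τ²)), a normal-quantile 95% CI without
Hartung–Knapp adjustment, Q's p-value from χ²(k−1), and
I² = max(0,(Q−df)/Q)·100. The implementation is cross-checked against R's
metafor (`rma(..., method="DL")`) in the test suite.

## Synthetic-data generator

`simulate_comparisons` emulates the structure the analysis assumes, at the
aggregate level only:

* true ln PFS effect per comparison: θ_P ~ N(μ_P, τ_P²);
* true ln OS effect: θ_O = α + shift·1[ICI+chemo] + β·θ_P + ε,
  ε ~ N(0, σ²), with per-sex (β, σ) overrides — the implied trial-level
  truth is design R² = β²τ_P²/(β²τ_P² + σ²);
* observed ln HR = truth + N(0, se²) with se = 2/√events and
  events = subgroup N × event fraction (the standard logrank-based
  approximation); PFS and OS sampling errors are independent by default,
  with a correlation knob because the true within-trial correlation is
  unknown;
* randomized N uniform between bounds (or an explicit per-comparison list),
  split into male/female by a fixed fraction.

`paperlike_design()` matches the packaged meta-analysis in scale:
21 comparisons, N ∈ [259, 1033] (optionally the exact packaged Ns), 71.4%
male, 11/21 monotherapy comparisons, event fractions 0.7 (PFS) and 0.6 (OS)
typical of mature advanced-NSCLC readouts, τ_P = 0.25 consistent with the
spread of the packaged ln PFS-HRs, and per-sex links (β = 0.70, 0.58 — near
the fitted adjusted-model slopes) with residual SDs solved so the design R²
is 0.77 (male) and 0.31 (female).

What the generator does **not** emulate: patient-level survival times,
non-proportional hazards (delayed separation, response plateaus), shared
controls inducing correlation between the two comparisons of a three-arm
trial, and publication rounding. Passing recovery tests therefore
demonstrates the estimators are consistent under the assumed aggregate
model, not that the model captures every feature of real ICI trials.

## Problem sizes used in tests

Parameter recovery uses one simulated meta-analysis of 200 comparisons with
~4·10⁵ patients per comparison and full event fractions, making estimation
noise negligible next to the between-trial spread; recovery of design R²
0.8/0.2 is asserted within ±0.07, the Monte-Carlo spread observed across
independent seeds at that size. The attenuation check averages 200
replicates of 25-comparison meta-analyses at three total sample sizes
(4000/500/120 patients) and asserts that the mean fitted female-stratum R²
decreases as subgroup estimates get noisier — the mechanism proposed to
explain part of the observed sex difference.

## Known limitations

* Aggregate-data analysis only: no individual-patient two-stage surrogacy
  model, and no correction for regression attenuation caused by measurement
  error in the explanatory log PFS effects.
* Published HRs are consumed as printed; input rounding propagates into all
  statistics at roughly the ±0.01–0.03 level.
* Comparisons sharing a control arm are treated as independent.
* The bootstrap interval for a near-zero R² is heavily right-skewed and its
  upper endpoint is sensitive to the resampling scheme.
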
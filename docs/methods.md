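# Methods

This note documents the models, numerical choices and limitations behind
bryoflux. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Flux conventions

Cuvette fluxes use the open-system form: flux = CO₂ differential × molar flow
/ canopy area (µmol m⁻² s⁻¹ per canopy surface area). Net photosynthesis (NP)
is positive for uptake; dark-mode readings are negative net uptake and are
negated on ingestion so dark respiration (DR) is a positive magnitude, which
makes gross photosynthesis GP = NP + DR close exactly. Water-flux dilution
corrections of the CO₂ signal are not applied (out of scope; the simple
differential×flow/area form is used throughout).

## Light response

The non-rectangular hyperbola is evaluated in the cancellation-free form
`NP_g = 2φI·P_gmax / (x + √(x² − 4θφI·P_gmax))`, `x = φI + P_gmax`, which is
algebraically identical to the usual lower quadratic root but stable for all
θ ∈ [0, 1) and exact in the rectangular limit θ = 0. θ is bounded to
[0, 0.999].

Fitting is bounded trust-region least squares with 8 deterministic starts
(initial slope from the lowest nonzero-irradiance point, asymptote from the
observed maximum, θ ∈ {0.1, 0.4, 0.7, 0.9} × two φ scalings); ties break by
residual sum of squares, then solver evaluations — NRH likelihoods are
multimodal and a single start is not trustworthy. R_d is a free parameter
seeded from the dark reading when present (DR is measured directly in these
campaigns, so the seed is nearly right and mostly speeds convergence). At
least 5 distinct irradiance levels are required.

LCP and LSP come from bracketed root finding (Brent, xtol 1e-12) on the
fitted curve; the upper bracket is found by doubling. LSP at fraction = 1 is
undefined (the asymptote is never attained) and raises. Photoinhibition is
not modelled; a configurable irradiance cutoff can exclude a declining
high-light tail before fitting (default: include all points). The LSP
definition uses the fitted net asymptote P_gmax − R_d, not the maximum
observed rate; fits flag when the observed maximum exceeds the asymptote so
downstream users can tell the two notions apart.

## Temperature response

DR is fitted on the log scale (linear regression of log DR on (T − T_ref)/10),
which is numerically stable and exactly invertible; R² is reported on the
natural scale for comparability with published fits. T_ref defaults to 10 °C.

NP-vs-temperature has no canonical functional form; the package defaults to a
quadratic — the lowest-assumption peaked form with closed-form optimum and
roots — and optionally fits a cubic, adopting it only when its AIC undercuts
the quadratic by ≥ 2 (models within 2 AIC are equivalent; the simpler wins).
AIC is the concentrated Gaussian form n·log(RSS/n) + 2k. T_opt is the argmax
of the fitted polynomial on the closed measured range (a concave-up quadratic
raises, having no maximum); T_upper is the smallest zero crossing above T_opt
within the measured range extended by 10 °C — a cap that avoids reporting
extrapolation artifacts — and is absent otherwise.

## CUE, acclimation ratio, classification

CUE = 100·NP/(NP + DR); it is undefined at GP = 0 and may be negative when
NP < 0. The 50% crossing scan reports the first consecutive measured
temperature pair where CUE falls from ≥ 50% to < 50%.

Because the measured steps {2, 5, 10, 15, 20, 25, 30} °C do not contain
T + 5 for every T, AR is evaluated on the fitted response curves (treatment
at T + Δ over control at T), not on raw step means; group means are averaged
before the ratio. Temperatures where the control rate is non-positive give
NaN entries, reported but not fatal. Classification of respiratory
acclimation uses the median AR with tol = 0.1 (both configurable): within
1 ± tol → full (medians below the band — treatment rates under control
rates — also count as full, being at least homeostasis); between 1 + tol and
the control Q10 → partial; at or above the control Q10 → none. The Type 1
signature is a negative Theil–Sen slope of AR against temperature — a robust
sign with ≤ 7 support points, where a regression p-value would be
meaningless.

## Microclimate

Saturation vapour pressure uses Tetens constants over water
(0.61078, 17.27, 237.3); Magnus constants are selectable. VP = RH/100·es,
VPD = es − VP, so VP + VPD = es holds identically. Night is the half-open
clock window [21:00, 08:00) on local naive timestamps with no DST handling —
appropriate for polar-summer loggers. Chamber summaries inner-join the two
series on timestamp (no resampling, so pairing is reproducible) and report
night/day means ± SE of ΔT, the maximum ΔT, and percent elevation of mean VP
and VPD, defined as 100·(in − out)/out.

## Statistics

Summary-statistic t-tests recover sd = se·√n and use the pooled two-sample
form (Welch available); with equal n this reduces to
(m₁ − m₂)/√(se₁² + se₂²). Paired t-tests with zero-variance differences
return a flagged, capped statistic instead of raising, so degenerate
synthetic inputs do not abort a pipeline. Trend fits are OLS with adjusted R²
and the overall F(1, n−2) test.

The ANCOVA candidates are rate ~ T, rate ~ T + group and rate ~ T × group,
each with a fixed blocking factor for between-sample variation. The block is
the within-group replicate index rather than raw sample identity: samples are
nested in groups, so raw sample dummies would span the group contrast and
make it unidentifiable; the replicate index is the fixed-effects analogue of
a per-sample random intercept that keeps the group term estimable. The
temperature covariate is centred so Type III main effects are evaluated at
the mean temperature rather than at 0 °C. Selection is minimum AIC with the
< 2 equivalence rule toward fewer parameters; term tests are Type III partial
F under sum-to-zero contrasts. All p-values are two-sided; no multiple-testing
correction is applied by default (a Holm helper exists). This fixed-effects
formulation approximates a random-intercept mixed model; with these small,
balanced designs the two agree closely, but the AIC values are not comparable
to REML-based ones.

## Synthetic scenario

The generators emulate the measurement structure of a two-group pulse-warming
campaign with known ground truth, so every analysis stage has an exact
round-trip oracle. One integer seed feeds a named-stream hierarchy
(`SeedSequence([seed, stream_id])`), so generators are mutually independent
and insertion-order stable. At zero noise all outputs lie exactly on the
generating functions.

Defaults encode a realistic warmed-vs-ambient contrast: control light curve
φ = 0.035, net asymptote 3.23; treatment φ = 0.11, net asymptote 10.57
(θ = 0.7 both). NP temperature parabolas pass through (T_opt, NP_max) =
(3.03 °C, 1.71) control and (11.65 °C, 4.38) treatment with upper thresholds
17.9 and 26.9 °C; DR is exponential with R_ref(10 °C) = 1.0 vs 1.286
(+28.6%) and Q10 2.81 vs 2.49. The light-curve R_d of each group is tied to
its DR truth evaluated at the 15 °C cuvette temperature, keeping the light
and temperature campaigns mutually consistent. Six replicates per group;
light grid 0–1500 µmol photons m⁻² s⁻¹; temperature steps
{2, 5, 10, 15, 20, 25, 30} °C, order shuffled per replicate.

Noise defaults: Gaussian sd 0.5 µmol m⁻² s⁻¹ on light-curve NP and 0.3 on
temperature-step NP (typical minicuvette repeatability); DR noise is
multiplicative log-normal (log-sd 0.05) because respiration must stay
positive for the exponential fit and a median-preserving multiplicative model
keeps the log-scale Q10 estimator unbiased — an additive option exists for
power studies. Loggers run 4 days at 15-min steps: outside air is a diurnal
sinusoid (mean 1 °C, amplitude 4); the chamber adds exactly +4.88 °C in the
night window and a half-sine solar-gain overshoot peaking at +25 °C by day;
relative humidity is back-computed from target vapour pressures (0.65 kPa in,
0.43 kPa out, ≈ +51%). The seasonal campaign covers five dates over 63 days
(n = 5 per date) with programmed slopes per day: DR +0.12, NP 0 (hence GP
+0.12), chlorophyll −8.85 mg m⁻².

What the generators do **not** emulate: drying/rewetting dynamics within a
measurement, photoinhibition above 1000 µmol photons m⁻² s⁻¹,
autocorrelated logger noise, cross-replicate heterogeneity of the response
parameters (all replicates share one group truth), and weather variability.
Passing round-trip tests therefore demonstrate correctness of the estimation
machinery under the stated noise model, not robustness to every feature of
field data.

A note on recoverability: the control NP parabola is shallow (curvature
≈ −0.008 µmol m⁻² s⁻¹ °C⁻²), so the per-replicate-campaign spread of its
fitted T_opt at noise sd 0.3 is about ±1 °C; recovery checks for T_opt are
therefore stated about the across-seed mean (unbiasedness), while the steeper
treatment optimum, the Q10s, slopes and the night offset are tight per run.

## Problem sizes

Tests and the acceptance script use the scenario defaults above: 200
parameter draws for the noise-free NRH round trip, 100 random fits for the
grid-scan oracles (0.001-unit grids), 100 seeds for the noisy-recovery and
ANCOVA size/power studies — sizes at which the binomial checks (≤ 10%, ≥ 90%)
are well separated from their thresholds.

## Known limitations

- The flux equation omits humidity-dilution corrections of the CO₂ signal.
- No Arrhenius or peaked-Arrhenius (deactivation) parameterization of the
  temperature responses.
- The quadratic NP model cannot represent asymmetric thermal curves except
  through the cubic alternative.
- CUE is instantaneous (NP/GP at a step), not a growth-based carbon budget.
- The ANCOVA is fixed-effects; no REML mixed models.
- Chlorophyll quantification assumes the DMSO coefficient set configured in
  `core.WELLBURN_DMSO` (overridable); absorbances outside the linear range
  are the caller's responsibility.
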
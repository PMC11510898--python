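# Methods

## Scope and data model

`salgae` analyses batch cultures of marine microalgae grown at a grid of
culture-medium salinities, in one stage (S1) or with a second, nutrient-limited
salt-shock stage (S2). The atomic record is a `CultureTimeSeries`: ordered
(t, OD720, biomass) points for one species × salinity × stage. Biomass is kept
in mg·L⁻¹ dry weight throughout; OD720 readings convert through a species
calibration line with zero intercept (`Cb [g·L⁻¹] = slope · OD720`), stored in
g·L⁻¹/OD as laboratories print it and converted once at the boundary.
Intercept support is deliberately omitted: the calibrations this package
targets are pure proportions, and OD readings are assumed blank-corrected.
When a row carries both an OD reading and a measured biomass, the measurement
wins; a discrepancy above 10% is logged, not raised.

## Productivity

Biomass productivity is the endpoint quotient Pb = (Cb_f − Cb_i)/(t_f − t_i),
not a regression slope — this matches how screening studies report it and
keeps the statistic well-defined on two points. Negative values are legitimate
(growth inhibition at hypo-osmotic extremes) and are never clamped. Window
bounds must be sampled times; the caller chooses them explicitly because
harvest day and stationary-phase onset need not coincide, and guessing would
hide a real degree of freedom. `detect_stationary_onset` offers a helper: the
first sampled day whose trailing specific growth rate μ = Δln(Cb)/Δt over a
window (default 3 days) drops below a threshold (default 0.05 day⁻¹). The
defaults were chosen so that simulated curves plateauing around day 17 — the
pattern typical of these cultures — are flagged within one window of the true
onset; they are parameters, not constants.

Stage-2 productivity applies the same endpoint formula over the 48 h shock
window [shock_day, shock_day + 2], the standard harvest window of two-stage
shock protocols; the duration is configurable.

Compound productivities are Pp = Pb·X with X the compound's mass fraction of
dry weight; a percent-mode flag divides by 100, and results are rendered in
both mg·L⁻¹·day⁻¹ and μg·L⁻¹·day⁻¹ because pigment yields are conventionally
quoted in the latter.

## Salinity-response model

Pb(S) = Pmax + a·(exp(−((S′ − Sopt)/b)²) − 1), with S′ = S or log10(S).
The curve is symmetric about the optimum, attains Pmax exactly at Sopt, and
approaches Pmax − a far from it. The width parameter b divides the distance
*inside* the square — the alternative reading (b² outside) differs only by a
reparameterisation b → √b, but the convention here is fixed and documented so
fitted b values are comparable across runs.

Fitting is nonlinear least squares (`scipy.optimize.least_squares`,
trust-region reflective, tolerances 1e−15) with a deterministic multi-start:
Sopt starts at the salinities of the three highest observed productivities,
b at a quarter, half and the full observed span, Pmax at max(Pb), a at the
observed Pb range, plus eight seeded random starts inside the bounds. The
objective is multimodal in (Sopt, b) — a single start from the data centroid
can lock onto a shoulder — and the start set above has, in the test-suite's
brute-force grid comparisons, always reached the global basin. Default bounds:
a ∈ [0, 10·range(Pb)], b ∈ [0.1, 10·span(S′)], Sopt within the tested span
widened by the b bound, Pmax free. Constraining a ≤ Pmax (to forbid negative
far-field productivity) is possible through the `bounds` argument but is not
the default, since inhibition to net biomass loss is a real observation at
extreme hyposalinity. Four or more distinct salinities are required (four free
parameters); all-identical productivities return a degenerate model (a = 0,
b unidentifiable) with a warning rather than an error. When the Jacobian at
the solution has condition number above 1e8 — typically because every design
point lies within one width of the optimum, confounding a with Pmax — a
warning is attached to the diagnostics.

Uncertainty is not quantified in this version (no bootstrap or profile
likelihood); the fit reports point estimates and goodness-of-fit statistics
only.

## Validation statistics

RMSE, bias factor Bf = 10^(mean log10(pred/obs)) and accuracy factor
Af = 10^(mean |log10(pred/obs)|) follow the predictive-microbiology
convention: the absolute value in Af is what distinguishes it from Bf and
gives the invariant Af ≥ max(Bf, 1/Bf) ≥ 1. Pairs with a non-positive
predicted or observed productivity are excluded from Bf/Af (their log-ratio
is undefined) and counted in the diagnostics; RMSE and r² use all pairs.
r² is the coefficient of determination 1 − SSres/SStot against the observed
mean — not the squared Pearson correlation; the two coincide only for an
unbiased linear predictor, and the choice is recorded in every run manifest.

## Composition indices

De-epoxidation states: DES% = 100·Dtx/(Dtx + Ddx) for the
diadinoxanthin→diatoxanthin cycle and DES% = 100·(0.5·Ax + Zx)/(Vx + Ax + Zx)
for the violaxanthin→antheraxanthin→zeaxanthin cycle (the intermediate
carries half weight: one of two epoxide groups removed). An empty pool is an
explicit error, never a silent NaN. Fatty acids are classified from their
Cx:y(nZ) name by double-bond count alone (0 → SFA, 1 → MUFA, ≥2 → PUFA); the
omega suffix is parsed and preserved but irrelevant to the class. Pigment
totals exclude np-chl-c2 — it is a chlorophyll, not a carotenoid — while all
controlled-vocabulary carotenoids, including degradation products such as
peridinol and diadinochrome, are included; both choices are open in the
underlying chemistry and are therefore fixed here by convention and
documented. The fucoxanthin family is fucoxanthin plus its acyloxy
derivatives (hex-, 4-keto-hex-, but-fucoxanthin).

## Haemolytic activity

EC50 is obtained by monotone linear interpolation of the haemolysis fraction
on log10 dose, first crossing from low dose. Interpolation was chosen over a
four-parameter logistic fit because it is assumption-free and the downstream
quantity — the equivalent saponin potential ESP = EC50(saponin, pg·mL⁻¹) /
EC50(extract, μg·mL⁻¹) — only needs the two crossing points; a logistic
fitter can be added without changing the interface. An extract whose response
never reaches 50% has no EC50 and its ESP is *absent* (None), not zero, so
condition averages are not deflated by inactive samples.

## Synthetic-data generator

The generator emulates the study design the analysis assumes: a salinity grid
(default 5–50 PSU, step 5), ~10% inoculum (cb0 = 50 mg·L⁻¹), a 2-day
adaptation lag, daily sampling to harvest at day 22, and 5% multiplicative
lognormal measurement noise (biomass is positive and OD error scales with
signal). Growth is a lagged logistic — the simplest form with lag,
exponential and stationary phases — rising toward a carrying capacity that is
*solved per salinity* so that the noiseless endpoint productivity over
[0, t_final] equals the true response model's prediction exactly. Salinities
with a negative productivity target are realised as exponential decay toward
a plateau below the inoculum, preserving the same endpoint identity. This
endpoint constraint is the generator's keystone: it removes the growth-curve
shape from what parameter-recovery tests actually measure, so they test the
fitting pipeline, not the logistic. Per-series seeds derive from the master
seed as seed·1000 + grid index, making any cited simulation exactly
reproducible.

The two-stage simulator runs stage 1 at the true optimum, takes the
(noiseless) biomass at the shock day as the common starting point, and builds
each 48 h shock segment linearly so its endpoint productivity equals the
stage-2 model's prediction.

The composition generator interpolates preset component means linearly in
salinity (relative Gaussian noise truncated at zero), with three presets
mirroring the qualitative trends of a haptophyte (saturated share falling
with salinity, diadinoxanthin cycle with DES rising in salinity), a
dinoflagellate (opposite SFA trend, peridinin-dominated pigments) and a
raphidophyte (fucoxanthin-dominated, violaxanthin cycle with a U-shaped DES
minimal near 20 PSU). What the generator does *not* emulate: nutrient
drawdown kinetics (no Droop/Monod machinery), replicate structure,
autocorrelated measurement error, or any mechanistic coupling between growth
and composition. Tests passing on synthetic data therefore demonstrate that
the pipeline recovers what the generator encodes under realistic noise — they
do not validate the response model against real cultures.

## Problem sizes and numerics

The packaged simulation studies use a 10-point salinity grid, 200 master
seeds for the stochastic recovery study, and a 15-points-per-axis brute-force
grid as the independent optimisation oracle; these sizes give stable medians
while keeping the full suite and the acceptance script each under a minute of
compute. Floating-point notes: the generator's endpoint identity holds to
~1e−13 relative (one logistic evaluation), fit tolerances are set to 1e−15 so
noiseless recovery reaches 1e−6 relative error with margin, and degenerate
inputs (flat productivities, empty pigment pools, non-crossing dose-response
curves) are handled by explicit contract errors or flagged degenerate
returns, never NaN propagation.
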
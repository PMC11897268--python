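# Methods

## Model structure

The model is a static, single-transition Markov cohort over five health
states: first-line treatment (1L), cure, second-line treatment after
failure (2L), hospital discharge and death; discharge and death are
absorbing. The entire cohort starts in 1L. Stage one distributes it over
cure, failure and death with per-arm probabilities; stage two resolves cure
into discharge or death (background mortality, mean 0.0035) and failure
into cure or death. Because the episode horizon is a few weeks, there is no
discounting, and because the comparison is cost-minimization, no QALYs or
ICERs are computed — the output is the incremental expected cost per
patient, with TDM minus without.

Three parameter sets ("analyses") instantiate the model, one per published
meta-analysis of TDM-guided dosing; they differ only in the stage-one
transition probabilities. The with-TDM cure probability exceeds the
without-TDM one by 12.2, 16.6 and 16.0 percentage points respectively,
which is the single driver of the sign of the result.

## Cost accrual and calibration

ICU-stay costs in the source tables are episode totals (days × €1,404.76),
not per-cycle increments, so each stage-one destination accrues its full
episode cost once and stage-two outcomes accrue nothing further. Beyond
that, a state-transition cost model still leaves several conventions open:
half-cycle correction, whether deaths accrue stay beyond the 1L episode,
how the two alternative 2L regimens combine, whether the failure-stay
tariff is arm-specific or shared, and whether the failure share of the
cohort is read from the table or closed as 1 − P(cure) − P(death). These
are fields of an explicit `AccrualSchedule`, and `calibrate_schedule`
grid-searches the 144-candidate convention space minimizing the maximum
absolute deviation from the six reference deterministic arm costs,
reporting every residual.

The calibrated optimum — the packaged default — is:

* a uniform cycle factor of 0.5 on every accrued cost (antibiotics, stays
  and the TDM fee alike), i.e. a global half-cycle correction;
* failure probability taken as the simplex complement 1 − P(cure) −
  P(death). The analysis-3 without-TDM table row sums to 0.9616 as printed;
  the complement (0.2914 rather than the printed 0.2530) is the only
  reading that reproduces that arm's reference cost, and the validator
  flags the printed deficit rather than silently renormalizing;
* the without-TDM failure-stay tariff (CEFST) applied in both arms — the
  reference one-way sensitivity table varies CEFST but not CEFT, and only
  this sharing matches its gradients;
* an unweighted 50/50 blend of the two second-line regimen options;
* no extra stay accrual in the death state.

Max residual over the six arm costs: €0.44. The same schedule reproduces
every varying row of the reference tornado table to the printed euro and
the alternative-scenario incrementals to within about one euro.

## Distributions

The PSA assigns each uncertain input a distribution matched to its reported
mean m and standard deviation s by the method of moments:

* costs: gamma with shape α = (m/s)², rate λ = m/s² ;
* probabilities: beta with ν = m(1−m)/s² − 1, α = mν, β = (1−m)ν. An s with
  s² ≥ m(1−m) is rejected with an error naming the parameter, before any
  iteration runs.

Inputs reported without dispersion are held at a point mass, so a model
with every SD at zero collapses exactly to the deterministic evaluation
(this is a test). The TDM unit cost has no reported SD; the package uses
range/4 = (204.79 − 87.84)/4 ≈ €29.24, flagged `sd_inferred` in the
fixture. Its contribution to the incremental SD is negligible (~€15
against ~€850). Lengths of stay reported as median with range are converted
to means with (low + 2·median + high)/4; the packaged stay means equal the
printed values, stored at the precision implied by total cost ÷ daily
tariff (e.g. 11.25 days, displayed as 11.3).

## PSA mechanics

One draw per named parameter per iteration. A code that appears in both
arms (CE1L, CEFST, and the costs via shared codes) is drawn once and
reused — common random numbers — while arm-specific codes (ICCTDM vs
ICSTDM, CECT vs CECST) draw independently. This reproduces per-arm SDs
near €1,400 alongside an incremental standard error of ~€25, which is the
only reading consistent with the reference table's "±" values. Random
streams are expanded from the root seed into one named substream per
parameter code (sorted order), so results are bit-reproducible and adding a
parameter does not disturb the others' draws.

Stage-one failure is the complement 1 − cure − death per draw, clipped at
zero for the rare draws (~1e-4 at fixture dispersions) where independent
cure and death betas sum above one; the truncation bias is far below the
Monte-Carlo noise at any n used here. Per-arm summaries report the mean,
the SD of iteration costs and a normal 95% CI of the mean (mean ±
1.96·SD/√n, the convention that matches the reference CI widths). The
incremental "±" is the standard error of the mean paired difference. The
saving probability is the fraction of iterations in which an arm is
strictly cheaper; ties count toward the without-TDM arm (conservative
toward the intervention, and measure-zero in practice). Default n = 1,000
(matching the source procedure); the acceptance script uses n = 100,000 so
the reported percentages carry ~0.15-point rather than ~1.5-point noise.

## Sensitivity analyses

The tornado sets each variable to its low and high bound with all else at
base and recomputes the deterministic incremental, sorting by impact with
alphabetical tie-breaks (spans below 1e-9 — float noise from shared costs
cancelling — are treated as exact ties). A perturbed cost moves in both
arms wherever shared, so shared tariffs yield flat rows; so do all
stage-two transitions, which carry no cost. Several bound pairs are printed
in reversed order in the source tables; fixtures store them
orientation-normalized with a `printed_reversed` flag.

Three named variants modify the base configuration only where stated:
`vancomycin_1l2l` substitutes vancomycin for linezolid in both lines,
`cefiderocol_2l` makes cefiderocol (with linezolid) the sole 2L option, and
`betalactam_stay` substitutes the stay table observed with beta-lactams.
Vancomycin and cefiderocol vial prices, and the beta-lactam stay durations,
are not printed in the surviving source tables; the packaged values
(€7.76/vial, €262.17/vial, and day shifts of +0.24/−0.21/+1.23 for the
cure-with, cure-without and failure stays) were inferred by solving the
published variant results and are labelled as such in the fixtures. The
analysis-3 vancomycin reference rows are internally inconsistent with
analyses 1–2 and were not force-fitted; the direction of every variant
result (expenditure in analysis 1, savings in 2 and 3) is reproduced in all
nine analysis × variant combinations.

## Synthetic scenarios

The generator produces internally coherent random scenarios sharing the
model's statistical structure: stage-one simplexes from Dirichlet draws
(concentration 12 by default, summing to one exactly), SDs set as a
fraction (default 0.3) of the beta-feasibility bound and additionally
scaled so cure + death keeps five joint SDs of headroom below one (the
failure complement then stays positive in essentially every PSA draw),
costs with coefficients of variation of 5–15% around ICU-scale magnitudes
(daily tariff €900–1,900, 1L stays of 6–12 days, failure episodes ~2–3×
longer), and a with-TDM cure advantage drawn from a configurable range.
Labels are attached at generation time: `tdm_dominant` (advantage taken
entirely out of failure, equal cost tables, negligible TDM fee — savings
guaranteed by construction), `identical_arms` (cloned arms — the
incremental equals exactly the accrued TDM fee), and `unconstrained`.

What the generator does not emulate: correlation between transition
probabilities and stay lengths, any meta-analytic sampling model behind the
probabilities, patient-level (first-order) variability, or multi-cycle
disease dynamics. Passing property tests on synthetic scenarios therefore
demonstrates internal correctness of the accrual, PSA and tornado
machinery under the model's assumptions — not external validity of those
assumptions for real ICU data.

## Numerical choices and limitations

All arithmetic is in floating-point euros; displays round to cents or
whole euros, comparisons in tests use absolute tolerances of €0.5–1.5
against printed (whole-euro) references and 1e-9 against internal oracles.
Regimen costs round to the cent. The validator reports, as warnings, the
incoherences the printed sources themselves contain (the analysis-3
simplex deficit, a daily-tariff range whose maximum lies below its mean,
reversed bound pairs); it fails only on genuine impossibilities
(probabilities outside [0,1], beta-infeasible SDs, stay totals
contradicting days × tariff). The model inherits the limitations of its
sources: a two-stage episode with no time-inhomogeneity, stay costs that
may partly reflect non-infectious comorbidity, and effectiveness inputs
from three meta-analyses that disagree with each other — which is exactly
the uncertainty the three-analysis design surfaces.
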
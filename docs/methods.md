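# Methods

## Scope and design

`crcscreen` simulates individual colorectal-cancer (CRC) natural histories
for an average-risk US-like cohort that enters free of diagnosed CRC at age
40, overlays noninvasive screening strategies offered between ages 45 and
75, and reports paired per-1000 comparative outcomes against the same
cohort unscreened. The design goal is comparative validity: every strategy
arm re-uses each person's natural-history realization (common random
numbers), so between-strategy differences are free of between-person noise
and the Monte-Carlo standard error comes from the paired-difference
distribution alone.

Randomness is organized as counter-based Philox streams keyed by
`(master_seed, person id, redraw attempt, stream tag)`. The natural-history
stream is consumed once when the trajectory is generated; the screening
stream is re-opened identically for every strategy arm. At every screening
tick the engine consumes one adherence uniform and one positivity uniform
whether or not they decide anything, keeping streams aligned across
strategies that differ only in adherence or sensitivity; per-lesion
colonoscopy draws may desynchronize arms afterwards, which paired
comparisons absorb as ordinary Monte-Carlo noise. Results are therefore
reproducible from `(parameter file, master seed, n)` independent of
execution order.

## Natural history

*Cohort entry.* Sex is drawn 50/50; other-cause death age comes from the
sex-specific life table by inverse CDF on the annual grid with uniform
within-year jitter, conditional on survival to 40. Trajectories whose
cancer would present clinically before 40 are rejected and redrawn from a
fresh stream, keeping the cohort definition exact. The packaged life table
(`life_table_synthetic_us.csv`) is synthetic — a Gompertz–Makeham form
tuned to US-like life expectancy (81.7/78.1 years at age 40 for
females/males) — and is replaceable via the parameter file.

*Adenoma onset.* A non-homogeneous Poisson process with intensity
`exp(baseline_log_rate + frailty + sex_log_effect·[male]) · age_effect(age)`
runs to age 100. Frailty is Normal(0, `frailty_sd`²) on the log scale and
captures the strong between-person clustering of adenoma risk; the age
effect is piecewise constant, which makes the process homogeneous within
each age band (counts are Poisson, onsets uniform — also the property the
test-suite oracles exploit).

*Growth.* Diameter follows a bounded exponential approach
`d(t) = d_max − (d_max − d₀)e^(−λt)` with `d₀ = 1 mm`, `d_max = 50 mm`, and
λ solved per lesion so that `d = 10 mm` exactly at the lesion's drawn
years-to-10 mm (lognormal, by colon/rectum segment). The single-parameter
anchor at 10 mm was chosen because every screening quantity in the model
keys on the <10 mm / ≥10 mm boundary.

*Transformation.* The adenoma→preclinical-cancer hazard is
`h(t) = exp(log_hazard_at_10mm + male_log_effect·[male] +
age_log_slope·(age−50)) · (d(t)/10)^size_power`. The cumulative hazard is
integrated by trapezoid on a half-year grid and inverted against a unit
exponential; with `size_power = 0` the grid is exact for the constant
hazard, which the exponential-oracle tests use. The exponential deviate is
consumed whether or not the lesion ever transforms, so stream layout does
not depend on outcomes.

*Preclinical cancer.* Sojourn (onset to clinical presentation) is
lognormal; stage entry ages are the partial sums of exponential dwell times
in AJCC stages I→III (IV is absorbing). The stage at any age — clinical
presentation or earlier screen detection — is read off this one schedule,
which is what makes earlier detection an earlier-stage diagnosis.

*Survival.* At diagnosis a stage-specific cure probability is tested,
otherwise an exponential excess death hazard applies, scaled by an age-band
multiplier (<65, 65–74, ≥75). Each cancer pre-draws its (cure, time)
uniforms in the natural-history stream, so when screening detects the same
tumor at an earlier stage the same underlying draw passes through a better
distribution — death can only be delayed or averted, never hastened, by
earlier detection of the same cancer. A person receives at most one CRC
diagnosis; later cancers in an already-diagnosed person are not modeled.

## Screening overlay

Offers occur at 45, 45+Δ, … ≤ 75 (Δ = 1 year for FIT/FOBT, 3 years for
mt-sDNA and blood tests). Adherence is an independent Bernoulli per offered
round; a skipped offer does not reschedule. Positivity uses the per-person
most-advanced-lesion convention with the published per-person trial
sensitivities; colonoscopy detection is per lesion (defaults 0.75 / 0.85 /
0.95 for ≤5 mm / 6–9 mm / ≥10 mm-and-cancer — standard guideline-model
values, configurable). Follow-up colonoscopy after a positive test is
always completed (per the study design being emulated), removes each
detected untransformed adenoma, and diagnoses detected preclinical cancer
at `stage_at(detection age)`. Findings put the person under surveillance
colonoscopy (3 years after high-risk findings — any ≥10 mm lesion or ≥3
removals — else 5 years, stopping at 85); a clean colonoscopy (a false
positive, or a clean surveillance exam) returns the person to screening
after a 10-year rescreen deferral. A symptomatic (clinical) presentation is
assigned one diagnostic colonoscopy in both arms, so it cancels from
incremental colonoscopy counts but appears in absolute totals; follow-up,
surveillance and diagnostic colonoscopies are counted separately so either
"total colonoscopies" definition can be assembled.

Test-administration events carry no clinical consequence, so the
null-coupling property holds in two forms: a zero-adherence arm is
event-for-event identical to the unscreened arm, and an inert test (zero
sensitivities, perfect specificity) is identical on all clinical events
while still recording the administered tests.

## Outcomes

Life-years are undiscounted person-years from age 40 to death. For a
strategy arm, LYG per 1000 is the mean per-person paired difference × 1000;
incidence/mortality reductions are 1 − (screened rate / unscreened rate);
absolute per-1000 cases and deaths averted are also emitted. Screen
detection of a cancer that would never have presented clinically counts as
a diagnosis (overdiagnosis is visible as a negative contribution to
incidence reduction). The cohort size behind per-1000 outcomes is
configurable and reported with Monte-Carlo standard errors everywhere.

## Scenario analysis

The grid crosses the eight packaged tests with adherence levels {0.3 … 0.7,
1.0} plus the observed real-world per-round rates (mt-sDNA 0.656, FIT
0.426, FOBT 0.344); all cells share one cohort per master seed through a
small cache. Incremental matrices are plain LYG differences against a
reference test, with the sign convention that negative means the reference
gains more. The threshold search bisects the blood test's advanced-adenoma
sensitivity (the nonadvanced value tied by the half-rule — floor plus half
the excess over the accidental-finding floor 1 − specificity — or set
equal) until the simulated LYG matches a comparator within tolerance
(default 2 LYG per 1000) or the bracket closes below half a percentage
point. Because every evaluation re-uses the same cohort, the empirical
response is deterministic and monotone, which is why bisection (rather
than a gradient or stochastic-approximation method) is the right tool; the
evaluator is injectable so the root-finder is unit-testable without
simulation.

## Calibration of the packaged defaults

The packaged parameter file is a stand-in, chosen once against three
design targets: lifetime adenoma prevalence ≈ 30–40%, unscreened lifetime
CRC risk ≈ 4–5%, and the qualitative strategy ordering reported for this
class of comparison (mt-sDNA ahead of FIT ahead of FOBT at their
real-world adherence rates; minimum-threshold blood tests behind mt-sDNA).
The shipped values give prevalence ≈ 35%, CRC risk ≈ 4.5%, CRC death risk
≈ 3%.

Two properties of this calibration deserve explicit statement.

First, under independent per-round adherence the mt-sDNA/FIT comparison at
real-world rates is structurally close: an effective-rate calculation
shows annual testing at 42.6% and triennial testing at 65.6% yield nearly
identical per-3-year detection probabilities for every lesion class
(mt-sDNA slightly ahead for adenomas, FIT ahead for preclinical cancer).
The packaged calibration shortens the preclinical window (mean sojourn
≈ 2.9 years) and makes stage progression fast, so prevention (adenoma
removal) rather than early detection carries most of the benefit; the
resulting real-world LYG difference is a statistical tie with the expected
direction (≈ 0 ± 3 LYG per 1000 at n = 4×10⁴), while the FIT–FOBT and
mt-sDNA–blood gaps are decisive. Large mt-sDNA/FIT gaps such as those in
published comparisons likely require longitudinally correlated adherence
(persistent non-participants), which this package deliberately does not
model: per-round independence is the simplest defensible reading and its
consequences are reported honestly.

Second, the same choices make the clinical stage-at-presentation
distribution pessimistic (roughly half of unscreened presentations in
stage IV, case fatality ≈ 0.65) relative to US registry data. This is a
known limitation of the stand-in, accepted to keep the valuation of
screen-detection conservative; users wanting registry-faithful stage
distributions should lengthen `stage_dwell_means` and raise late-stage
`cure_prob` in their own parameter file.

## What the simulator does and does not emulate

The generator emulates: individual heterogeneity in adenoma risk, the
size-gated adenoma–carcinoma pathway, competing other-cause mortality,
stage-dependent survival, and the resource side of screening (tests,
follow-up/surveillance/diagnostic colonoscopies). It does not emulate:
the serrated-polyp pathway, adenoma regression, family-history risk
strata, colonoscopy complications, costs or QALYs, non-triennial blood
intervals, or calendar-time population dynamics. Passing tests therefore
demonstrate internal consistency and the comparative logic of screening
strategies under the stated assumptions — not agreement with any specific
calibrated model or registry.

## Numerical choices and problem sizes

Transformation-hazard integration uses a 0.5-year trapezoid grid (exact
for constant hazards; growth curves are smooth and slowly varying at this
scale). Ties at an offer age between surveillance and screening resolve in
favor of surveillance; an offer at exactly the rescreen-resume age is
made; a clinical presentation at exactly a contact age precedes the
contact. Degenerate inputs are defined: zero adenoma intensity (empty
histories), zero frailty variance, −∞ log-hazard (no transformation ever),
zero excess hazard or unit cure probability (no CRC death). The test suite
runs its full-scale checks on a shared cohort of n = 10⁵ (statistical
oracles and orderings at 3 standard errors); the acceptance script uses
n = 2×10⁴ per arm, where paired LYG standard errors are ≈ 15 per 1000.
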
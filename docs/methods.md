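# Methods

## Model

The clinical course of prefibrotic primary myelofibrosis (pre-PMF) is
represented as a continuous-time Markov multistate process on four states
— pre-PMF (1), overt PMF (2), AML (3), death (4) — with six transitions
1→2, 1→3, 1→4, 2→3, 2→4, 3→4; death is absorbing. All hazards are indexed
by time since pre-PMF diagnosis (clock-forward scale), which makes the
process Markov: the intensity of leaving a state depends on current time
and state, not on the time of entry. A clock-reset (semi-Markov) long
format is available as an option but is not used by the default pipeline.

Each transition k has a Weibull proportional-hazards intensity
h_k(t|x) = λ_k γ_k t^(γ_k−1) exp(x β_k) with cumulative hazard
H_k(t|x) = λ_k t^γ_k exp(x β_k). Covariates are fixed at baseline.
Each at-risk interval (t_start, t_stop] of the stacked long format
contributes

    status · log h_k(t_stop|x) − [H_k(t_stop|x) − H_k(t_start|x)]

to transition k's log-likelihood; subtracting H(t_start) implements
delayed entry for sojourns entered after diagnosis. Transitions are fitted
independently — no parameters are shared across transitions.

### Estimation

Optimization is quasi-Newton (BFGS, analytic gradient) over the
unconstrained parameters (log λ, log γ, β), started at the exponential fit
(γ=1, λ = events/exposure, β=0), polished by Newton steps on the analytic
gradient until the score's largest component is below 1e-5 (typically
1e-8); up to five deterministically seeded shape-jittered restarts on
failure. The covariance is the inverse observed information (central
finite differences of the analytic gradient); a singular information
matrix is reported as covariance-unavailable rather than silently
pseudo-inverted. Wald hazard-ratio tables (HR, 95% CI, two-sided p, no
multiplicity correction) and AIC = −2 log L + 2(2+|β|) follow.

Ties: a transition and a censoring recorded at the same instant resolve in
favour of the transition; two simultaneous transitions are invalid input,
as are zero-length sojourns (rejected, never jittered).

### Prediction

The intensity matrix Q(t) collects the fitted hazards (off-diagonal),
rows summing to zero, absorbing rows zero. P(s, t) solves the Kolmogorov
forward equation dP/dt = P Q(t) from P(s, s) = I with DOP853 at
rtol 1e-11 / atol 1e-13. Because a Weibull hazard with γ < 1 diverges at
t = 0, integration starts at ε = 1e-6 years; the step across the origin
uses the exact first-order expansion P ≈ I + ΔH (error O(ΔH²) ≈ 1e-11).
Entries more negative than −1e-8 raise an error; smaller negatives are
solver round-off, clipped to zero with row renormalization. (A tighter
gate would misclassify ordinary global solver error as model violation:
the method's stated row-sum accuracy is 1e-8.)

The simulation route draws each sojourn's exit time by inverting the total
cumulative hazard out of the current state: with E ~ Exp(1), solve
Σ_b [H_ab(T) − H_ab(t₀)] = E by bisection (to 1e-8 years) on the interval
up to the horizon — if the total cumulative hazard at the horizon is below
E the subject simply remains in state — then draws the destination
proportionally to the cause-specific hazards at T. The sampler is
vectorized across subjects and shared verbatim between prediction and the
cohort generator, so fitted-model simulation and data generation cannot
drift apart.

State occupation is the initial-state row of P(0, t). Cohort curves are
population-averaged (the mean of per-profile curves weighted by profile
frequency), not curves at the mean covariate vector; a reference-profile
option exists. For transition probabilities out of an intermediate state
the conditioning time s is a free parameter; the pipeline's default is the
mean observed entry time into that state.

### Nonparametric oracle

Nelson–Aalen increments d/Y at each event time (risk sets honour delayed
entry; censorings at an event time count as at risk) assemble into the
Aalen–Johansen product integral Π (I + ΔA), whose factors are stochastic
matrices — rows sum to one exactly. With a single transition it reduces
exactly to one minus Kaplan–Meier. It is exposed publicly but serves
mainly as the model-free cross-check of the parametric predictions in the
test suite.

## Synthetic cohorts

The generator emulates a four-centre retrospective registry of 382
pre-PMF patients. Binary covariates are drawn independently at their
configured prevalences, except mutually exclusive groups (driver
mutations JAK2 65%, CALR 22.5%, MPL 4.5%, triple-negative the remainder)
drawn as one categorical. Published prevalences are used where available
(fibrosis grade 1: 58%, spleen > 5 cm: 15%, LDH > 1.5×: 40%, abnormal
karyotype: 15%, HMR — at least one mutated gene among ASXL1, EZH2, SRSF2,
IDH1/2 — 28% of the mutation-informative third of the cohort, male 51%,
cytoreduction 77%, antiplatelets 72%, anticoagulants 15%). The
dichotomizations used in the hazard models but never published as
prevalences are plausible defaults, flagged as assumptions: age > 65 0.35
(45% are ≥ 60), anemia 0.25, WBC > 15×10⁹/L 0.20, platelets > 1000×10⁹/L
0.20. A `mutation_data` indicator (probability 132/382) marks the
subcohort with mutation assays, mirroring how mutational models are
fitted on a third of the registry.

Generating hazard ratios are the significant multivariable estimates per
direct transition: overt PMF — anemia 2.18, fibrosis grade 1 3.20, HMR
3.15; AML — age > 65 10.3, WBC > 15 4.80, LDH > 1.5 8.13, abnormal
karyotype 6.92; death — age > 65 6.53, WBC > 15 3.49, HMR 4.62.
Non-significant clinical estimates and the driver-mutation estimates are
set to zero: they come from two separately fitted families, and stacking
both into one generating model would double-count overlapping effects.
Transitions out of the intermediate states carry baseline hazards only
(covariate models for them are unreported).

Weibull shapes are fixed a priori from the qualitative hazard behaviour
of the disease course: γ = (1.0, 1.0, 1.3, 0.6, 1.2, 1.4) — roughly
constant-rate fibrotic progression and direct leukemic transformation,
mortality risk accelerating with time since diagnosis, an early-peaked
AML hazard after fibrotic progression, high rising mortality after
progression or transformation.

### Censoring and calibration

Censoring is an administrative horizon of 32.6 years (the registry's
longest follow-up) plus independent exponential dropout. "Median
follow-up 6.89 years" is interpreted in the reverse-Kaplan–Meier sense —
the median of the censoring distribution, the standard clinical follow-up
estimator — which under exponential dropout gives the rate analytically:
ρ = ln 2 / 6.89 ≈ 0.1006 / year. (Reading it instead as the median
observation time gives ρ ≈ 0.072 and a generating model whose implied
20-year mortality tops out near 49%, inconsistent with the reported
state-occupation behaviour — ~30% dead at 10 years, ~60% at 20; the
reverse-KM reading yields 33% and 54% with the same a-priori shapes.)

The six baseline scales are calibrated once (scripts/calibrate.py, log in
docs/calibration_log.json): the expected number of *observed* jumps per
transition in a 382-subject cohort,

    n · E_x ∫₀^32.6 p_a(t|x) h_k(t|x) e^(−ρt) dt,

is computed deterministically by solving the occupation ODE jointly with
the six count integrals per covariate profile (enumerating the 2⁷
profiles of effect-carrying covariates), and a multiplicative fixed point
drives it onto (58, 18, 66, 10, 14, 25) to 0.01%. The shipped constants
reproduce the reference transition mix in expectation; single 382-subject
draws scatter binomially around it.

### What the generator does not model

Covariate correlations (e.g. anemia with fibrosis grade) — unknown in the
registry, generated independently; continuous laboratory values
underlying the dichotomizations; treatment assignment dynamics (treatment
indicators are independent baseline covariates with null effects);
interval censoring and diagnostic delay; state regression (the topology
forbids e.g. overt PMF reverting to pre-PMF). Passing tests therefore
demonstrate correctness of estimation and prediction under the model's
own assumptions, not robustness to the misspecifications real registry
data would add.

## Pipeline

`run_analysis` chains counting → long-format construction → per-transition
fits of the three direct transitions under two covariate families —
clinical (nine clinical indicators, adjusted for three treatment
indicators) and mutational (driver-mutation dummies with triple-negative
reference, plus HMR), the latter restricted to the mutation-informative
subcohort — plus baseline-only fits of transitions 4–6, an AIC table, and
ODE/simulated probability curves. Because family AICs fitted on different
subcohorts are not comparable, the clinical family is additionally refit
on the mutation-informative subcohort and both comparisons are reported.
Zero-event or non-convergent fits are skipped and flagged in the report,
not fatal. Covariates constant within a transition's rows are dropped
with a note (complete-case exclusion counts are logged per family).
Outputs are deterministic given seed and config; `report.json` carries a
content hash over everything except run metadata.

## Problem sizes

Default analyses use the 382-subject design. Validation uses n = 5000
cohorts (6–8 replicates) for parameter recovery, 200 replicates for CI
coverage, 100,000 paths for Monte-Carlo/ODE agreement, 10,000 subjects
for the Aalen–Johansen comparison and 500 seeds for the transition-mix
reproduction — sizes at which Monte-Carlo error is small against the
tolerances being asserted.

## Known limitations

Independent per-transition fits cannot borrow strength across transitions
(no shared baseline or proportionality constraints). Confidence bands for
predicted probabilities are not provided (delta-method or resampling
bands are future work; the bootstrap is used only in tests). The Wald
inference is asymptotic: with very few events (mutational fits of the
AML transition on ~130 subjects) CIs are unstable, and the pipeline
reports them with their n's rather than suppressing them. The AIC
comparison inherits the registry analysis's design limitation of fitting
clinical and mutational families on different subcohorts.
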
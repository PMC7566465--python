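# pmfstate

Parametric Markov multistate survival modelling of disease progression in
prefibrotic primary myelofibrosis (pre-PMF).

Pre-PMF is a WHO-defined myeloproliferative neoplasm whose clinical course
runs through intermediate disease states: patients may progress to overtly
fibrotic PMF, transform to acute myeloid leukemia (AML), or die — directly
or after passing through those states. Ordinary survival analysis of the
terminal event alone cannot separate these routes. `pmfstate` implements
the multistate alternative for biostatisticians and clinical researchers:
a four-state model (1 = pre-PMF, 2 = overt PMF, 3 = AML, 4 = death) with
six allowed transitions (1→2, 1→3, 1→4, 2→3, 2→4, 3→4), death absorbing.

## The model

Each transition *k*: *a* → *b* has a Weibull proportional-hazards
intensity on the clock-forward (time-since-diagnosis) scale,

&nbsp;&nbsp;&nbsp;&nbsp;h<sub>k</sub>(t | x) = λ<sub>k</sub> γ<sub>k</sub> t<sup>γ<sub>k</sub>−1</sup> exp(xβ<sub>k</sub>),

with shape γ<sub>k</sub>, rate-scale λ<sub>k</sub> and hazard ratios
exp(β<sub>k</sub>). Each transition is fitted independently by maximum
likelihood on stacked "long-format" at-risk intervals; entry into a later
state is delayed entry (left truncation), handled through the cumulative-
hazard difference H(t<sub>stop</sub>) − H(t<sub>start</sub>) in the
likelihood. From the fitted intensities the package computes:

* the transition-probability matrix P(s, t), by integrating the Kolmogorov
  forward equation dP/dt = P(t) Q(t) or by simulating Markov paths
  (next-event times drawn by inverting the total cumulative hazard);
* state-occupation probabilities (the initial-state row of P(0, t)),
  including stacked bands for plotting;
* Nelson–Aalen cumulative hazards and the Aalen–Johansen product-integral
  estimator as a model-free cross-check;
* per-transition AIC = −2 log L + 2k to compare covariate families
  (clinical vs mutational) transition by transition.

No public patient-level registry of pre-PMF exists, so the package ships a
calibrated synthetic cohort generator (`reference_config`): 382 subjects,
binary covariates at literature prevalences with transition-specific
hazard ratios, and right censoring (administrative horizon 32.6 years plus
exponential dropout giving a 6.89-year reverse-Kaplan–Meier median
follow-up). Its baseline scales are calibrated so the expected numbers of
observed jumps match the reference cohort's transition mix
(58/18/66 direct transitions out of 382, then 10/14/25).

## Worked example

```python
import numpy as np
import pmfstate as pm

cfg = pm.reference_config()                 # calibrated 382-subject design
cohort = pm.generate_cohort(cfg, seed=1)
counts = pm.count_transitions(cohort, cfg.space)
print(counts.to_string(index=False))
```

```
 transition  from_state  to_state  n  pct_of_cohort
          1           1         2 43           11.3
          2           1         3 20            5.2
          3           1         4 64           16.8
          4           2         3  4            1.0
          5           2         4 16            4.2
          6           3         4 22            5.8
```

One simulated draw of the design: 43 subjects (11.3%) progressed directly
to overt PMF, 20 (5.2%) transformed directly to AML and 64 (16.8%) died
without progression — scattered around the calibrated expectation
(15.2%, 4.7%, 17.3%). Fitting the death transition with three covariates:

```python
rows = pm.build_long_format(cohort, cfg.space)       # stacked at-risk rows
fit = pm.fit_transition(rows, ["age_gt65", "wbc_gt15", "hmr"], transition=3)
print(pm.hazard_ratios(fit).round(3).to_string(index=False))
```

```
covariate    HR  CI_low  CI_high   p
 age_gt65 5.300   3.158    8.894 0.0
 wbc_gt15 2.966   1.773    4.961 0.0
      hmr 3.430   1.967    5.978 0.0
```

The fitted hazard ratios estimate the generating values (6.53, 3.49,
4.62); each 95% CI covers its target. Prediction from a full model set
(here with baseline-only intermediate transitions):

```python
fits = {k: pm.fit_transition(rows, ["age_gt65", "wbc_gt15", "hmr"]
                             if k <= 3 else [], transition=k)
        for k in range(1, 7)}
model = pm.ModelSet(cfg.space, fits)
profiles = pm.cohort_frame(cohort)[["age_gt65", "wbc_gt15", "hmr"]]
occ = pm.population_average_occupation(model, profiles, np.array([10., 20.]))
print(np.round(occ.occupation, 3))
```

```
[[0.557 0.097 0.002 0.343]
 [0.34  0.119 0.001 0.54 ]]
```

i.e. at 10 years an estimated 55.7% of patients are alive without
progression, 9.7% live with overt PMF, 0.2% with AML and 34.3% have died;
by 20 years mortality reaches 54%.

The same pipeline is scriptable from the shell:

```sh
pmfstate simulate --n 382 --seed 1 --out cohort.csv
pmfstate counts cohort.csv
pmfstate analyze cohort.csv --out analysis_out   # fits, AIC table, curves
```

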
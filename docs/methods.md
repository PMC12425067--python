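# Methods

## The estimation problem

A cohort of adults aged 50+ is interviewed every two years for up to 22
years. At each interview we observe chronic-disease flags, three symptom
scales and a self-reported physician diagnosis of a psychiatric disorder;
a nine-item childhood-adversity inventory is fixed at baseline. Each
participant-wave is classified into one of five states: (1) no physical
conditions and no mental-health symptoms, (2) physical conditions only
(any of diabetes, stroke, heart disease, cancer), (3) mental-health symptoms
only (depressive symptoms, CESD-8 ≥ 4, and/or cognitive impairment,
TICS-m ≤ 11), (4) both, (5) diagnosed disorder — absorbing. Two families of
models address two questions: a time-varying Cox model for *whether and when*
the diagnosis occurs, and a panel-observed continuous-time Markov chain
(CTMC) for *how* participants move through the intermediate states on the
way there.

## Cohort construction

Inclusion requires, in order: age ≥ 50 at baseline, at least one follow-up
interview, a completed adversity inventory, and no disorder diagnosis at
baseline; the flow count of removals per criterion is reported.

Missing covariate and scale-item values at observed interviews are filled by
last observation carried forward, with leading gaps filled backward from the
first observed value (an all-missing series is an error naming the variable
and participant). Waves without an interview get no row: inter-observation
gaps of 4+ years arise naturally and are handled by the likelihoods, not by
imputation.

The counting process has one risk interval per inter-interview gap with
covariates frozen at the interval's opening interview. Onset is
interval-censored; we assign it to the interview at which the diagnosis is
first reported (right-endpoint convention, the standard choice for biennial
panels). Follow-up ends at the first diagnosis, the last interview, or the
22-year horizon. A death recorded after the last interview marks the final
interval as ending in the competing event but does not extend follow-up, so
total person-time equals (last interview − baseline) summed over
participants — a conservation property the tests assert exactly.

## Scale scoring

* **CESD-8**: binary items, items 4 and 6 reverse scored; totals 0–8.
  Depressive-symptom cutoff ≥ 4 (configurable; the subgroup analysis offers
  ≥ 5 as an alternative threshold).
* **JSS-4**: responses 1 ("most of the time") to 3 ("rarely or never").
  Items 1–3 are reverse coded and item 4 kept raw, so totals (4–12) increase
  with sleep disturbance; insomnia cutoff ≥ 5. Published wordings of this
  scale are inconsistent about orientation, so the reverse-coded item set is
  a parameter.
* **TICS-m**: memory + attention + calculation domains, 0–27, higher =
  better; impairment cutoff ≤ 11.

## Time-varying Cox regression

The hazard of diagnosis is modelled by the counting-process Cox partial
likelihood with Efron tie handling (ties are heavy because events land on
wave times). The engine is `lifelines.CoxTimeVaryingFitter` (Newton–Raphson);
the package contributes the three preset adjustment sets (demographics;
+ socioeconomic/lifestyle; + seven diseases and three scale totals), the
exposure codings (any adversity; three type indicators; count categories
1/2/3+; continuous score), subgroup/interaction analysis via a Wald test on
the exposure×modifier product term, and five sensitivity variants (drop
events within two years; drop first-follow-up events; disease count instead
of indicators; baseline-frozen covariates; Fine–Gray).

The proportional-hazards diagnostic is a Grambsch–Therneau score test:
Schoenfeld residuals r_k = x_(k) − x̄(t_k, β̂) at each event, scaled by
d·Î⁻¹, regressed on event time (identity transform); per-covariate and
global chi-squares. Under simulated exact-PH nulls the global test rejects at
≈ 4–5% (asserted in the acceptance suite at 200 replicates).

No multiple-testing adjustment is applied anywhere; p-values are reported
raw.

## Competing risks

Death precludes diagnosis, so the package provides the Aalen–Johansen
estimator (implemented directly; its output satisfies
CIF_disorder + CIF_death + S = 1 exactly at every step) and a Fine–Gray
subdistribution-hazard model for baseline covariates. Fine–Gray uses
Geskus's counting-process construction: subjects with the competing event
remain in the risk set after their event time with weight G(t−)/G(T−) from
the censoring-distribution Kaplan–Meier, piecewise constant between primary
event times, and the weighted Efron partial likelihood is maximised by the
same Cox engine. With no competing events the construction reduces exactly
to the ordinary Cox fit (asserted to 1e-6). Combining subdistribution
weights with time-varying covariates has no agreed construction and is out
of scope; Fine–Gray here is baseline-covariate only.

## Panel multistate model

States are observed only at interviews, so the likelihood of a consecutive
pair (s_k at t_k, s_{k+1} at t_{k+1}) is P(Δt)[s_k, s_{k+1}] with
P(t) = exp(Qt) (scaling-and-squaring Padé via `scipy.linalg.expm`). All 16
transient→other transitions are allowed by default; transitions never
observed can optionally be pruned (fixed at zero) to stabilise sparse fits.
A single covariate acts log-linearly on every allowed intensity:
q_ij(z) = q⁰_ij·exp(β_ij z) — univariate covariate models only, because with
16 free intensities the transition counts in a realistic panel cannot
identify a multivariate specification.

Estimation maximises the panel log-likelihood over log q⁰_ij (positivity
without constraints) and β_ij with L-BFGS-B. Gradients are analytic: for
each parameter, dP = Fréchet derivative of the matrix exponential in the
direction of dQ/dθ (`scipy.linalg.expm_frechet`). Observation pairs are
aggregated into (Δt, z) cells with 5×5 count matrices first, so the cost per
likelihood evaluation is a handful of matrix exponentials regardless of
cohort size. Initial values are crude rates (transition counts over time at
risk in the origin state) floored at 1e-3/yr to keep log-scale starts
finite. Standard errors come from the inverse observed information,
computed by central finite differences of the analytic gradient; a
non-positive-definite information matrix yields "SEs unavailable" rather
than fabricated intervals. The optimizer trace is recorded and the tests
assert the accepted log-likelihood never decreases. An observed transition
with zero probability under the mask raises an error naming the pair.

Death is right-censoring in this module (the path simply ends); the
competing-risk view of death lives in the Fine–Gray/Aalen–Johansen module.

Forecasts from a fitted Q: transition-probability curves P_ij(t) on a grid;
22-year cumulative absorption P_i5(22) per transient initial state; expected
total duration per state E_j = ∫₀ᵀ Σᵢ πᵢ P_ij(t) dt by adaptive vector
quadrature (`scipy.integrate.quad_vec`, abs. tolerance 1e-10), standardized
to percentages of the horizon that sum to 100. The default π is the
empirical baseline state distribution of the analysed group (configurable,
e.g. all mass in state 1). Observed-data summaries (5×5 consecutive-pair
counts with row percentages, stratified by exposure) are emitted alongside
the model so crude and fitted quantities are never conflated.

## Synthetic cohort generator

The generator is the package's study design: it fixes the conditions under
which every estimator is validated.

* latent process: exact Gillespie simulation of the five-state CTMC with
  intensities piecewise-constant between wave boundaries — the same
  assumption the estimator makes, so recovery tests isolate estimator
  correctness rather than model mismatch;
* observation: biennial schedule over 22 years (12 waves), visits after
  baseline missed independently with probability 0.08; the absorbing state
  ends observation at its first sighting; death is an independent
  exponential competing risk (0.025/yr) reported at the next scheduled wave
  as an exit record;
* ground truth: baseline intensities are round numbers between 0.01 and
  0.15 per year chosen for desk-scale recovery; the default adversity effect
  multiplies the healthy→PC, healthy→MS, healthy→disorder and PC→comorbid
  intensities by 1.190, 1.253, 1.859 and 1.138;
* emission: disease flags and raw scale items are drawn so that scoring and
  classification reproduce the latent state exactly at every visit (asserted
  for all observed records); sleep items are calibrated to a mean total of
  6.71 on the 4–12 scale; demographics approximate a U.S. aging cohort
  (age ~ N(65, 8) truncated at 50, 57% female, ~35% with any adversity);
* determinism: one seed; per-participant generators are spawned from a seed
  sequence, so output files are byte-identical across runs.

What the generator does **not** emulate: real attrition correlated with
health, proxy interviews, survey weights, item-level measurement error
correlated over time, or calendar effects. Passing recovery tests therefore
demonstrates estimator correctness under the stated sampling design, not
robustness to those real-data complications.

## Problem sizes and numerical choices

Recovery suites use cohorts of n = 3000 (multistate, 10 seeds; ≥ 85% Wald
coverage of the 32 true parameters required) and n = 4000 (time-varying
Cox, 20 replicates; the true log hazard ratio of 0.3 must fall in the 95%
CI in ≥ 18). Null calibrations use 200 (PH test) and 2000 (ANOVA)
replicates. L-BFGS-B runs with ftol 1e-12/gtol 1e-7, max 500 iterations;
matrix-exponential probabilities are clipped to [0, 1] only within
round-off. Wald intervals are always formed on the log scale and
exponentiated last.

## Known limitations

* The multistate model takes onset as panel-observed; no exact onset dates
  are used anywhere, so fitted intensities are per-year rates identified
  from interval transitions only.
* Fine–Gray standard errors are model-based (no sandwich correction for
  estimated weights); null coverage is verified by simulation (~93–95%).
* One covariate at a time in the CTMC (see above); the Cox models carry the
  full adjustment sets instead.
* The descriptive table treats the exposure grouping as a single categorical
  column supplied by the caller; no rule is imposed for collapsing
  participants with multiple adversity types into exclusive groups.
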
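# Methods

This note documents the models behind `sarsmon`: what the synthetic cohort
generator emulates and deliberately omits, how each component is specified
mathematically, which numerical conventions are used, and where design
choices were genuinely open.

## Synthetic cohort model

Each of `n_patients` virtual patients belongs to one of two classes —
`Normal` or `SARS-risk`, the latter a *generic* severe acute respiratory
distress phenotype — with exact class counts
`round(n_patients · normal_fraction)` (deterministic rounding rather than
Bernoulli sampling, so the 60/40 design is reproduced exactly and is
testable). A patient is observed for `records_per_patient` consecutive
monitoring ticks on eight channels: heart rate (bpm), ECG-derived index
(dimensionless, 80–120 scale), body temperature (°F), systolic and
diastolic blood pressure (mmHg), SpO₂ (%), room temperature (°C) and blood
sugar (mg/dL).

The hierarchical structure is

```
factor layer     s, h, c ~ N(0, 1)                     (severity, hemodynamic, cardiac)
patient layer    μ_i = m_i,class + σ_i (λs_i s + λh_i h + λc_i c + idio_i z),  z ~ N(0,1)
record layer     x_it = clip(μ_i + ε_it),  ε_it ~ N(0, noise_sd_i)
```

with `idio_i = √(1 − λs² − λh² − λc²)` so the patient baseline SD is exactly
`σ_i`. The hemodynamic factor couples the blood-pressure pair, the cardiac
factor couples heart rate with the ECG index; both pairs co-vary strongly
(r ≈ 0.8–0.9) while only one member of each pair carries a class shift —
mirroring real physiology, where ECG-derived indices track heart rate and
diastolic tracks systolic pressure, and where part of the discriminative
signal therefore lives in the *joint* distribution rather than the
marginals. A configurable fraction (default 25%) of Normal-class patients
carries an elevated severity baseline (+2 factor SD), representing the
comorbid but non-distressed tail of a monitored in-hospital population.

All Normal-class clip ranges sit inside the published plausible ranges for
the channels (heart rate 60–100 bpm, body temperature 98–105 °F, ECG index
80–120, blood pressure 60–175 mmHg); SpO₂ is generated on a clinically
plausible 70–100 % scale. Missing vital cells are masked independently at
`missing_rate` (default 3%); identifiers, tick and label are never masked.

**Calibration.** The class-conditional means are not observable quantities;
they were chosen once so that the benchmark's reference classifier (ridge
logistic regression, patient-level scoring as below) attains *moderate*
separability — mean ROC-AUC in the low 0.8s with accuracy around 0.75 and
MCC around 0.5 at the Youden threshold — rather than the near-perfect
separation a naive "sick patients look obviously sick" generator would
give. The shifts are small relative to between-patient spread (0.2–0.45
patient-SD per shifted channel) precisely because scores are aggregated
over 120 records per patient, which averages away record noise and leaves
between-patient overlap as the limiting factor.

**What the generator does not emulate.** Vitals are stationary within a
patient (no disease trajectories, circadian rhythm or treatment response);
measurement noise is Gaussian and uncorrelated in time; missingness is
completely at random; the ECG channel is a scalar index, not a waveform.
Consequently, passing benchmarks here demonstrate correctness of the
pipeline and the calibrated difficulty of the classification problem — not
clinical performance on real monitoring data.

## Preprocessing

Per patient and channel, in order: forward-fill of gaps up to `ffill_limit`
ticks (default 3; a causal operation), channel-mean imputation of whatever
remains ("isolated" or leading gaps), a trailing moving average of width
`smoothing_window` (default 5 ticks, partial head windows; trailing rather
than centered so the operation is usable in real time), then min–max
scaling to [0, 1]. Imputation means and scaling bounds are fitted on the
*training* patients only and reused on test patients, so no test statistics
leak into training; test-side values may therefore fall slightly outside
[0, 1] and are left unclipped. A constant channel maps to all zeros.

## Rule engine

Each vital has inclusive extreme cutoffs: High when `value ≥ high`, Low
when `value ≤ low`, Normal strictly between, so the three statuses
partition the real line and the extreme rules win at the boundary. Blood
pressure is compound: High if *either* systolic ≥ 145 or diastolic ≥ 100,
Low if either systolic ≤ 100 or diastolic ≤ 60, with High taking precedence
if both fire (either component out of range is actionable; precedence keeps
the partition property). Temperatures are compared in °C; °F inputs are
converted. Tell messages are emitted exactly for the non-Normal statuses
whose rules announce them (fever, hypothermia, high heart rate, high blood
sugar, abnormal ECG, high blood pressure, high blood-oxygen level in the
`paper_faithful` profile); the fire sensor relays its level
unconditionally.

Two profiles ship as YAML. `paper_faithful` transcribes the original rule
table literally — including its two idiosyncrasies: blood oxygen saturation
is flagged *high* at ≥ 90 (with no low rule), and the ECG cutoffs are on a
0.6–1.2 scale that does not match the cohort's 80–120 index (the mapping
between the two scales is not defined anywhere; both are therefore simply
configurable). `clinical` flags SpO₂ ≤ 90 as Low (desaturation), fires
fever at 38 °C and uses the 80–120 ECG scale; the simulation uses it by
default because it produces meaningful statuses on cohort-scale data.

## Probabilistic-logic inference

Programs are independent probabilistic facts plus negation-free definite
clauses with acyclic dependencies — sufficient for the monitoring
constructs modelled here, and restrictive enough that exact inference is
simple to verify. The marginal of an atom is the total weight of possible
worlds in which it is derivable (least-model forward chaining). `query()`
implements Shannon expansion over facts with two prunings (already
derivable → contribute all remaining weight; not derivable even with all
remaining facts true → contribute zero); `enumerate_worlds()` is the
independent brute-force route used as a test oracle, capped at 20 facts
(2²⁰ worlds) by default. Multiple clauses for one head give noisy-or
combination: `P = 1 − ∏(1 − pᵢ)` for independent single-fact bodies.

The shipped example (`examples/sars_call.pl`) encodes a distress call
decision over four evidence strengths (0.5, 0.6, 0.9, 1.0):
suspicion = fever ∧ desaturation, and the doctor is called when suspicion
is corroborated by lab or respiratory evidence, giving
P(call_doctor) = 0.9 · (1 − 0.5·0.4) = 0.72. Marginals are monotone in
every fact probability, a property the tests assert.

## Multi-agent simulation

The world holds patient and doctor agents (mobile: unit-step random wander
with reflecting boundaries on a 33×33 grid — cosmetic) and seven stationary
sensor agents. Sensor agents are stateless forwarders: each tick they read
the patient's current vital record (from a dedicated generated cohort) and
derive statuses through the rule engine; they model no noise of their own
(the cohort generator owns noise). The patient's risk probability is then

```
p ← clip( sigmoid(intercept + status_weight · #non-Normal statuses) + N(0, drift_sd), 0, 1 )
```

with defaults intercept −3.0, weight 1.2, drift SD 0.05 — chosen so a fully
normal record maps to p ≈ 0.05 and five abnormal statuses to p ≈ 0.95.
Escalation cutoffs default to critical ≥ 0.6 (notify the nearest doctor,
Euclidean distance, ties to the lowest agent id), extremely-critical ≥ 0.8
(generate an alert) and life-threatening ≥ 0.95 (call an ambulance),
aligned with the high-risk alert boundary (> 0.6); exactly one event is
logged per above-cutoff patient per tick, at the highest severity reached.
Without doctors, critical escalations degrade to alerts with a warning.
Setup, movement and drift use independent RNG streams spawned from the
master seed, so the event log is a pure function of (config, seed, ticks).

## Classifiers

All five estimators expose `fit` / `predict` / `predict_proba` /
`get_params` / `set_params`; fitted state lives in trailing-underscore
attributes; every fit is deterministic given data and hyperparameters. The
distress class is the positive class throughout.

- **Gaussian naive Bayes** — product of class prior and per-feature normal
  densities; plain densities (no kernel density estimation); variance floor
  1e−9 against constant features.
- **Binned multinomial naive Bayes** — 10 equal-width bins per feature
  fitted on training data, Laplace smoothing α = 1 (both values are
  conventions chosen for reproducibility); a constant feature collapses to
  one bin and cancels out of the posterior.
- **Decision table** — features binned as above; greedy forward selection
  maximizing k-fold (default 5) cross-validated accuracy with deterministic
  striped folds; prediction is an exact lookup of the selected-feature bin
  key → that key's training majority, falling back to the global majority
  for unseen keys. Greedy selection with k-fold CV replaces a best-first
  subset search with leave-one-out: it is deterministic and runs at desk
  scale on 10⁵-record tables while keeping the same IF-conjunction → action
  semantics.
- **Ridge logistic regression** — `P(Y=1|x) = 1/(1+e^−(b₀+b·x))`, penalized
  likelihood maximized by damped Newton/IRLS; intercept unpenalized; ridge
  default 1e−8 (the conventional weak default), max 100 iterations;
  non-convergence sets a flag rather than raising.
- **SMO support-vector machine** — simplified sequential minimal
  optimization of the SVM dual: error cache `E = f(x) − y`, pair curvature
  `η = K(xᵢ,xᵢ) + K(xⱼ,xⱼ) − 2K(xᵢ,xⱼ)`, the analytic α_j step clipped to
  the [L, H] box from `0 ≤ α ≤ C` and the pair constraint, complementary
  α_i update and threshold re-estimation. The second multiplier is chosen
  by the maximal |Eᵢ − Eⱼ| step, falling back to a cyclic scan from a
  seeded offset when that pair cannot move — without the fallback the loop
  can stall on dense overlapping data. Sweeps stop after `max_passes`
  passes without an update. Defaults: linear kernel, C = 1, tol = 1e−3,
  max_passes = 10. On tables beyond `max_samples` (default 2,000) training
  uses a stratified seeded subsample, keeping the quadratic loop tractable
  on 10⁵-record cohorts; decision values are min–max mapped to [0, 1] for
  the alerting layer — a monotone score, *not* a calibrated probability.

## Benchmark design

Splits are stratified 70/30 at the **patient** level: all 120 records of a
patient land on one side, because record-level splitting would leak
within-patient correlation (a record in the test set would have 80+ near
replicates in training). Exact per-class counts (420/180 Normal, 280/120
SARS-risk at defaults) are used. Preprocessing is re-fitted on each
training side. Classifiers are fitted on training *records*; each patient
is scored by the mean of their record-level positive-class probabilities
(`max` pooling available); the operating threshold maximizes Youden's J on
the training patients; all confusion metrics plus ROC-AUC/PR-AUC are
computed on the test patients and reported as mean ± sample SD (ddof = 1)
over repeats. McNemar's test compares the matched per-patient test
predictions of a designated pair (default logistic vs Gaussian NB): exact
two-sided binomial when the discordant count is below 25, else the
continuity-corrected χ² statistic `(|b−c|−1)²/(b+c)`.

Alert levels map a risk probability p to low (p < 0.3), moderate
(0.3 ≤ p ≤ 0.6, boundaries inclusive to moderate) or high (p > 0.6);
boundaries are configurable per agent.

## Numerical conventions and degenerate inputs

- Zero-denominator metrics: precision/recall/F1 = 0, MCC = 0.
- ROC sweeps group tied scores into one step; Youden ties break to the
  lowest threshold; thresholds are realized scores with the ≥ convention.
- Min–max scaling of a constant channel yields 0; preprocessing of an
  empty table returns it unchanged; an all-missing channel is an error
  naming the channel.
- SMO pairs with η ≤ 0 are skipped; C → 0 collapses all multipliers to the
  box and the decision toward the bare threshold.
- World enumeration refuses programs above the fact cap instead of
  attempting 2ⁿ work.

## Problem sizes

The default study runs 1,000 patients × 120 records with ten repeated
splits (about two to three minutes on one CPU, dominated by the SMO fits),
and the simulation runs 500 ticks over ~20 agents in under a second. These
sizes are the package's reference configuration; everything scales through
the config objects.

## Known limitations

- The generator's class-conditional structure is a modelling choice
  calibrated to a target operating point; real cohorts will differ in both
  marginals and correlation structure, and reported benchmark numbers
  should be read as properties of this simulation design.
- The probabilistic-logic engine supports neither negation nor annotated
  disjunctions; programs above ~20 facts need a different inference
  strategy (knowledge compilation) than this package provides.
- The decision table is a deterministic approximation of classical
  wrapper-based table induction; it will not reproduce another
  implementation's selected feature subsets exactly.
- SMO with the default linear kernel underfits problems requiring
  non-linear boundaries (use `kernel="rbf"`); its subsampled fits trade a
  little accuracy for tractability on large record tables.
- The simulation's probability update is a phenomenological link between
  rule statuses and risk — it is designed for testable escalation
  dynamics, not for clinical validity.
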
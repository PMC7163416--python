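# Methods

## Cohort and measurement model

The unit of analysis is a dated LDL-c measurement in an adult (≥ 18 years)
patient with established cardiovascular disease. A lipid panel is assembled
per (patient, date) from long-format lab rows; a direct LDL-c measurement
is preferred, otherwise LDL-c is derived with the Friedewald formula
(mmol/L convention, `LDL = TC − HDL − TG/2.2`). Precedence of a direct
value over a same-day derivable triplet is a package choice: the derivation
exists for dates where the direct assay is missing, so when both are
present the assay wins.

Reliability filtering removes (a) panels with LDL-c below 0.8 mmol/L dated
before 2017-01-24 — before that date the laboratory computed LDL-c only by
Friedewald, for which very low values are unreliable; afterwards low values
were remeasured and are kept — and (b) Friedewald-derived panels with
triglycerides above 8.0 mmol/L. The TG rule applies only to derived panels
(the derivation, not the assay, breaks down at high TG); the low-LDL rule
applies regardless of recorded source before the policy date. Each
excluded panel carries exactly one reason; when both rules match, high TG
is recorded (the derivation is invalid, so the low value is moot). All
thresholds and dates live in `CohortConfig` and are overridable from YAML.

CVD status at a measurement uses a configurable code→category map (real
coding systems are site-specific) and admits events up to 7 days after the
measurement, so pre-operative screening labs count. Diabetes is a
diagnosis code or a glucose-lowering (ATC A10) prescription registered on
or before the date; hypertension is the nearest blood pressure within ±7
days exceeding 140/90 (strict) or any blood-pressure-lowering (C02/C03/
C07/C08/C09) prescription; CKD is a code/dialysis event or any eGFR below
60 mL/min/1.73 m² within ±2 calendar days (the 48-hour lab window at the
day precision the tables carry). Prescriptions never look ahead:
registration timing is the weakest part of EHR medication data, and a
forward window would manufacture treatment responses. Statin doses are
expressed in atorvastatin-20 equivalents via an editable potency table
(defaults: rosuvastatin 10, simvastatin 40, pravastatin/fluvastatin/
lovastatin 80 mg ≡ atorvastatin 20 mg); equivalents are linear in dose.

## States, trajectories, transitions

States: on target (LDL-c < target, default 2.5 mmol/L) or off target by
d = LDL − target in [0, 0.5), [0.5, 1.0), [1.0, 1.5), [1.5, 2.0),
[2.0, ∞). Half-open bins make the partition exhaustive for continuous
values and reproduce 1-decimal bin labels exactly.

Follow-up classification: an interval Δ (days) is short-term when
61 ≤ Δ ≤ 183, long-term when 183 < Δ ≤ 548, otherwise unrelated. Months
are converted at 30.44 d/month (2→61, 6→183, 18→548); the windows meet at
six months and the boundary day is assigned to the lower (short) window.
Linkage is greedy and forward: the chain anchors on the first measurement
and re-anchors on each retained one; a measurement is retained iff its
interval from the last retained measurement is short or long. Greedy
chaining is the only order-independent single-pass reading of "unrelated
measurements are excluded", and it naturally produces patients reduced to
a single retained measurement, who then contribute no sequence.

Sequences are truncated at the nearest-rank 75th percentile of lengths
(k = ceil(0.75·n)-th smallest). Transition counts are pooled over all
consecutive pairs at every position — a time-homogeneous Markov estimate —
and rows are normalized where populated. By default transitions are
estimated on untruncated related pairs, with a config switch
(`transitions_on_truncated`) for the truncated subset.

## Optimal matching and clustering

The dissimilarity between two state sequences is the minimum total cost of
transforming one into the other by substitutions (symmetric 6×6 cost
matrix) and indels, computed by dynamic programming on the
(|a|+1)×(|b|+1) grid. Defaults are the conventional constant substitution
cost 2.0 with indel 1.0; `trate` costs 2 − P(i→j) − P(j→i) derive from an
estimated transition matrix. Unequal post-truncation lengths are compared
directly with indels (no padding). Note a property of this distance often
mis-stated: for equal-length sequences the identity alignment costs
(substitution cost) × (Hamming distance), which is an upper bound, not an
identity — shifted sequences are cheaper via indels.

Clustering is agglomerative with the Ward-type Lance–Williams update on
squared dissimilarities (scipy's implementation on the precomputed
condensed matrix). The input is not Euclidean, so Ward is heuristic here,
as is standard practice for optimal-matching distances. The cluster count
defaults to 4 and is configurable; a silhouette-by-k table is emitted to
aid the choice. Labels are renumbered by size (descending, ties by first
occurrence) so runs are deterministic. Cluster membership is related to
covariates by one-vs-rest binomial logistic models; clusters with fewer
than 10 members are skipped with a warning. Because the pairwise stage is
O(n²·L²), the pipeline clusters a seeded random subsample of at most
`max_cluster_sequences` (default 1000) sequences and computes distances
once per distinct sequence.

## Change analysis

A measurement pair is favorable iff the next state is on target; the three
unfavorable clauses (increase, off-target decrease, off-target stability)
exactly cover its complement at the category level. Statin change between
the pair's measurements is compared by drug name and by dose in
atorvastatin-20 equivalents (equality tolerance 1e−9); pairs without a
mapped statin at both ends are not evaluable and are excluded with a
count. Statin starts and stops are reported but excluded from the
regression, whose categories cover type/dose changes only. The
deterioration model is a maximum-likelihood logistic fit of the
unfavorable outcome on age, sex, diabetes, hypertension, smoking,
antithrombotic use, statin-change category (reference: same dose, same
type), measurement number and follow-up type (reference: short), on
complete-case evaluable pairs, with Wald 95% CIs. Covariates without
variation in a degenerate cohort are dropped with a warning rather than
failing the stage.

## Synthetic generator

The generator emulates the structure of a tertiary-care extract with every
parameter under seed control:

* **Covariates** — independent Bernoulli draws (female 0.31, diabetes
  0.12, hypertension 0.33, CKD 0.01, smoking 0.10, statin 0.33,
  antithrombotic 0.42); age Normal(63, 12) clipped to [25, 90]. Each true
  flag is realized as structured data the preprocessing recovers exactly
  (a dated diagnosis event, a prescription registered before the first
  measurement, a dated smoking record; blood pressures for
  non-hypertensive patients are clipped below 140/90 so no false flags
  arise).
* **Baseline off-target status** — logistic with odds ratios 1.48 (women),
  0.69 (diabetes), 0.87 (hypertension), 1.29 (smoking), 0.99/yr (age),
  0.86 (statin), 0.98 (antithrombotic), 0.75 (CKD), 1.25 (repeated
  measurements); the intercept (0.04, age-centered) calibrates the
  marginal off-target prevalence near 51%. Off-target baseline states are
  allocated over the five off bins proportional to the chain's stationary
  distribution.
* **Visit process** — 55% of patients have a single measurement; repeated
  patients draw 1 + Geometric(0.30) measurements (capped at 20). Interval
  draws mix too-soon (7–60 d, weight 0.10), short (61–183, 0.42), long
  (184–548, 0.34) and too-late (549–900, 0.14) gaps, putting roughly a
  quarter of follow-ups in the unrelated regimes. The generator replicates
  the greedy linkage rule internally so the latent chain advances exactly
  when the pipeline retains a measurement.
* **Trajectories** — default `markov`: related states follow the packaged
  6-state matrix (rows normalized from their printed two-decimal values;
  the on-target row already sums to one, so its 0.84 self-transition is
  exact). The alternative `deterioration` model draws each related step's
  unfavorable outcome from a *marginal* logistic in the pair covariates
  (women 1.44, diabetes 0.72, statin-change categories 0.81–1.82,
  measurement number 0.98, long follow-up 0.97; intercept 0.27 calibrates
  the unfavorable rate near 55%), then places unfavorable steps among the
  off-target states proportionally to the chain row. The marginal form is
  deliberate: the deterioration regression does not adjust for the
  previous state, and a previous-state offset in the generating model
  would make that regression misspecified (non-collapsibility), so
  recovery tests would measure an attenuation artifact rather than the
  fit. Consequence: in `deterioration` mode the realized transition matrix
  is not the configured chain; matrix-recovery studies use `markov` mode.
* **Lipid values** — uniform within the state's mmol/L bin (on-target
  floor 0.9, top bin capped at 8.0), so bin membership is exact and all
  base panels are reliable. Panels before the remeasurement date, and a
  configurable 30% afterwards, are emitted as TC/HDL/TG triplets whose
  Friedewald derivation reproduces the latent LDL-c to machine precision.
* **Pathologies** — `inject_pathologies` appends configurable numbers of
  low-LDL pre-2017 panels, high-TG panels, under-18 patients and non-CVD
  patients, one fresh patient per record, so every injection maps to
  exactly one downstream exclusion and conservation checks are exact.

What the generator does **not** emulate: inter-covariate correlation,
secular trends in testing or treatment, realistic coding-system noise,
informative missingness of medication data, or measurement error in lipid
assays. Passing recovery tests therefore demonstrate that the pipeline's
estimators are correct under the generating model, not that real EHR data
meet that model's assumptions.

## Numerical choices and problem sizes

Logistic fits use statsmodels' Newton MLE (complete case; non-convergence
or an empty outcome class raises). Friedewald identity is asserted to
1e−9; transition rows sum to 1 within 1e−9; statin-equivalent equality
tolerance is 1e−9. Duplicate analytes on one date keep the first
occurrence; same-date first-measurement ties prefer the direct assay. CSV
readers parse floats in round-trip mode so write→read→write is
byte-identical.

Recovery studies in the test suite use 400–6,000-patient cohorts,
5,000-sequence chain simulations and 200 replicate fits at 10,000
patients — sizes at which binomial/Wald sampling bounds are tight enough
to detect estimator errors while the suite stays fast. The acceptance
script simulates 5,000 sequences for matrix recovery, top-state-initialized
chains until 20,000 worst-state pairs accrue, and one full 10,000-patient
cohort through preprocessing and the baseline model.

## Known limitations

* Day-level date precision throughout; the 48-hour eGFR window is ±2
  calendar days.
* Ward linkage on non-Euclidean optimal-matching distances is a heuristic;
  no bootstrap cluster-stability assessment is provided.
* The transition estimate is time-homogeneous; no covariate-dependent or
  position-dependent transition modeling.
* No causal interpretation of statin-change coefficients: prescription
  registration dates cannot distinguish a therapy response from delayed
  registration.
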
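# Methods

## The measurement model

A PavCA session pairs an 8-s illuminated lever (conditioned stimulus, CS)
with response-independent delivery of a food pellet into a magazine, 25
trials per session on a variable-time 90-s schedule (intertrial intervals
drawn from 30–150 s). Animals come to approach either the lever
(sign-tracking: the cue itself acquires incentive value) or the magazine
(goal-tracking: the cue is merely predictive). Scoring reduces each
rat-session to six measures — lever/magazine event counts, per-trial
response probabilities, and mean first-response latencies — and composes
them into the PavCA index described in the README.

Two conventions are load-bearing and are therefore fixed package-wide:

- **Censoring.** A trial with no response to a target contributes the full
  CS duration (8 s) to that target's latency mean. This is what makes the
  latency-difference component — and hence the index — attain ±1 on fully
  lateralized sessions; without it the index could not span its nominal
  range.
- **Probability is per trial.** P(lever) is the fraction of trials with at
  least one lever contact, not an event rate. It is the only reading for
  which the probability difference is bounded by ±1.

Other conventions: the CS window is half-open `[on, off)` (an event at CS
offset belongs to the ITI); all lever contacts in a trial count toward the
session total (session totals above 25 are normal); a session with zero CS
responses has an undefined response bias, which is substituted with 0 and
flagged `defined=False` rather than dropped, preserving auditability.
Latency means use exactly-rounded summation, so summaries are invariant to
trial order.

Classification thresholds are **inclusive** (≥ +0.30 / ≤ −0.30 on the
sessions-4/5 mean; ±0.20 on session 3 for the short regime). Method
descriptions in this literature alternate between inclusive and strict
wording for the same rule; inclusive is adopted and boundary cases are
decided by it, not asserted to be the only possible reading. Window
aggregation is the unweighted mean of session indices.

Counterbalanced assignment sorts each phenotype by mean index (seeded
random tie-break) and deals round-robin into arms, so arm means are matched
by construction; a phenotype with fewer rats than arms is assigned as far
as possible with a warning.

## Conditioned reinforcement

CRT sessions (40 min default) are scored by tallying active pokes,
inactive pokes and lever contacts, and reconstructing FR1 lever
presentations under a 2-s refractory rule: a poke during an ongoing
presentation **counts as an active poke but does not retrigger** the lever.
The rigs this models do not document the retrigger behavior; the
non-retriggering convention is the standard FR1 reading and is applied
consistently in both the scorer and the generator. Lever contacts are
constrained to presentation windows.

## Microdialysis

Percent change is computed against the **mean of all baseline fractions**
(6 in a complete series): `pct_i = 100 (conc_i − baseline_mean) /
baseline_mean`. The alternative (last-baseline-fraction denominator) was
rejected because a single-fraction denominator propagates one fraction's
noise into every normalized value. Baseline-phase percent changes average
to zero identically, and the series is invariant under rescaling all
concentrations, so between-rat probe-recovery differences drop out.
Incomplete series are usable down to 4 baseline and 5 session fractions;
sparser series are excluded with a log entry rather than normalized against
an unstable denominator.

## Inference

- **Treatment × block interaction.** Linear mixed models with REML and
  covariance-structure selection are deliberately out of scope; the package
  instead tests the two-block repeated-measures interaction by permutation.
  The statistic is the difference-in-differences of arm means over per-rat
  block changes; treatment labels are permuted across rats (block pairing
  intact); p uses the add-one rule. With 199 permutations the attainable
  levels make α ∈ {0.01, 0.05, 0.10} exact for continuous statistics. A
  long-table export (`cohort_block_table`) is provided for fitting mixed
  models in external software.
- **Balanced two-way ANOVA** uses the classical sums-of-squares
  decomposition (Type I/II/III coincide under balance; SS conservation holds
  to machine precision). Unbalanced tables are rejected with a pointer to
  the permutation test.
- **Cohen's d** uses the df-weighted pooled SD; t-tests are Student's
  pooled-variance (df = n₁+n₂−2) or paired (df = n−1), two-sided,
  α = 0.05, with Bonferroni correction for post-hoc families.
- **Outliers**: 1.5×IQR boxplot rule with quartiles by linear interpolation
  between order statistics (the numpy default). The rule's output depends
  on the quartile convention, so it is fixed and documented. Fewer than 4
  values: screening is skipped with a warning rather than performed on
  meaningless quartiles.
- **Power** is estimated by simulation: the fraction of replicate cohorts
  in which the interaction test rejects, with a Wilson 95% interval. At
  zero effect this doubles as a type-I calibration of the test itself.

## The synthetic cohort generator

No generative model exists for this paradigm in the literature the package
follows; the generator is a deliberately minimal latent-bias agent,
sufficient to produce the phenotype continuum, session-wise learning, and
treatment shifts the analysis must detect.

- **Allocation.** One latent parameter θ ∈ [−1,1] per rat: on a responding
  trial the response goes to the lever with probability (1+θ)/2. Responding
  itself is Bernoulli(`respond_prob`, default 0.9) per trial.
- **Learning.** θ approaches a phenotype asymptote geometrically:
  θ_s = asym + (θ₀ − asym)(1 − learn_rate)^(s−1), learn_rate 0.5, θ₀
  jittered in ±0.2. Asymptotes are ST +0.6, GT −0.6, IN 0 — values at which
  a measured sessions-4/5 index clears the ±0.30 classification band with
  margin under default trial noise, while staying far from the degenerate
  extremes.
- **Treatment** adds `treat_shift` to θ from the onset session onward
  (clamped to [−1,1]); zero shift makes the arms exchangeable, which is what
  the type-I calibration exploits.
- **Events.** ITIs are uniform on [30,150] s (only the mean and range of
  the VT schedule are specified; uniform is the simplest distribution
  consistent with both). First-response latencies are exponential
  (scale 2 s) truncated to the CS window — right-skewed, as real approach
  latencies are; responding trials carry 1 + Poisson(0.5) events. ITI
  magazine entries are Poisson per trial (rate jittered 1–3/trial);
  the pellet is always retrieved. Timestamps are seconds from session
  start at millisecond resolution, rounded so logs survive text round trips
  bit-exactly.
- **CRT.** Active pokes are Poisson with rate 0.5 + 1.5·max(θ,0) per
  minute, inactive pokes 0.25/min independent of phenotype; contacts occur
  within presentations with probability clipped from 0.5 + 0.5θ.
- **Dialysis.** Every fraction of every analyte gets multiplicative noise;
  dopamine's in-session fractions additionally carry the behavioral signal:
  conc = base·(1 + (coupling·index + ε)/100), ε ~ N(0, noise_sd), coupling
  default 50 (% change per index unit). Non-dopamine analytes have zero
  structural coupling. Because the session average uses 7 fractions and the
  baseline denominator 6, the effective noise variance on a session-mean
  percent change is noise_sd²·(1/7 + 1/6) — the identity used to configure
  a target signal fraction in the calibration experiments.
- **Reproducibility.** One seed per cohort; each rat's RNG substream is
  keyed by a stable (blake2) hash of its rat id, so enlarging a cohort never
  perturbs the data of existing rats. Fixed seed ⇒ byte-identical logs.

What the generator does **not** emulate: within-session learning, CNO
pharmacokinetics, satiety or circadian drift, inter-trial dependence,
chamber-side biases, or any neural mechanism. Passing tests therefore
demonstrate correctness of the *analysis* under a known data-generating
process and calibration of its inference, not validity of any biological
claim about real cohorts.

## Problem sizes and numerical choices

Calibration and recovery experiments in the tests and the acceptance script
use sizes at which their Monte-Carlo error is small relative to the bands
checked: 500 null cohorts (6 rats/arm, 2+2 sessions) for type-I
calibration; 80 agents over 5 sessions for phenotype recovery; 100
replicate 10-rat cohorts for regression-r² recovery; 200 sessions for the
CRT rate ratio; 10⁴ trials for schedule statistics. The closed-form session
duration is n_trials × (mean ITI + CS duration) — 12.5 min for 25
pre-training deliveries on VT-30 s with no CS, ~40.8 min for a training
session.

Degenerate inputs are rejected loudly rather than coerced: mixed
rat/session summaries, zero baseline means, zero-variance predictors,
unbalanced ANOVA cells, missing classification windows, events outside
session bounds. The one silent substitution (0/0 response bias → 0) is
flagged on the score object.

## Known limitations

- The latency aggregate is the mean of per-trial latencies including
  censored trials; protocols that aggregate differently (e.g. median, or
  responding-trials-only) will shift the third component slightly.
- The permutation test addresses exactly two blocks × two arms; richer
  designs need the exported long table and an external mixed model.
- Generator defaults for latency scale and ITI response rates are
  field-plausible placeholders, not estimates fit to any dataset.
- The balanced-ANOVA implementation is intentionally restricted to complete
  balanced layouts; it will not approximate unbalanced F statistics.
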
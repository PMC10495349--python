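# Methods

## The analysis problem

A wild population of individually RFID-tagged birds interacts with automated
dual-feeder units whose payoffs depend on the identities of the two occupants.
Every individual carries a fixed treatment-class label, A or B.  When two
birds occupy the two perches of one unit simultaneously, a same-class dyad
gains access to a high-quality reward (a "successful" event) while a
different-class dyad triggers a feeder lockout (a "fail").  The scientific
questions are whether individuals learn to bias their partner choice towards
compatible (same-class) partners, whether long-term affiliations (mates,
parent–offspring, siblings) constrain that plasticity, and whether
compatibility-based clustering emerges at the network level.

`premnet` implements the full inference pipeline for this design: event
extraction from visit streams, constrained data-stream permutations, paired
case–control ("event / non-event") model fitting, and permutation tests —
plus a generative simulator with known ground truth against which the whole
pipeline can be validated.

## Relational event models on permuted non-events

A relational event model (REM) treats the stream of dyadic events as a
time-to-event process and asks how covariates computed from the history up to
each event modulate the event rate.  Instead of the conventional risk set of
all dyads, each observed event is paired with exactly one counterfactual
"non-event" obtained by permuting participant labels (or edge weights) within
the event's day × feeder subset.  Splicing observed events with their
non-events yields an alternating case–control series; a Cox proportional
hazards model stratified by day, applied to this series, reduces exactly to
the matched conditional-logistic likelihood

    l(β) = Σ_k [ x_k'β − log(exp(x_k'β) + exp(z_k'β)) ],

where `x_k` and `z_k` are the covariate vectors of event *k* and its
non-event.  We implement this reduction directly (Newton iteration on the
within-pair differences, analytic gradient and Hessian, convergence when the
maximum score component falls below 1e−8, at most 50 iterations) rather than
through a general Cox solver, because with a single control per risk set the
reduction is exact; the test suite cross-checks the fitter against an
independent conditional-logistic implementation and a dense grid-search
maximizer.

Fitting one model per permuted replicate yields a coefficient distribution
per term.  The median is the effect estimate; the quantile interval (2.5%
and 97.5% quantiles for dyad-, coordination- and network-level models;
1.25% and 98.75% for the two individual-level models, widening the interval
as a Bonferroni-style multiple-testing correction) is the confidence
interval; a term is significant when the interval excludes zero.
Exponentiating gives incidence rate ratios (IRRs) against the permutation
baseline.  Replicates that fail to converge (separation is detected exactly
from sign-constant within-pair differences) are dropped and counted; a
result carries a warning when more than 10% drop.  Terms with zero
within-pair variance in a replicate are recorded as missing, not zero.

### Degenerate inputs and numerical choices

* Quantiles use linear interpolation.
* Newton steps are halved until the log-likelihood does not decrease; a
  singular Hessian falls back to a least-squares step.
* An absolute coefficient above 30 aborts the fit as suspected separation
  (|β| = 30 corresponds to odds ratios beyond 1e13 — never a real effect at
  this scale).

## Model registry

The eight model specifications are reconstructed from the reported effect
estimates, since the original covariate scripts are not redistributed; the
registry (`premnet.covariates.MODEL_REGISTRY`) documents each term by name:

* **M1/M2** (individual level, independent label shuffles, 97.5% CI):
  cumulative prior same-/different-class event counts, and counts of
  repeated partners (≥2 prior joint events) by class match, summed over the
  two participants of each event.  The outcome set is restricted to
  successful events ("who will be seen succeeding in the future?").
* **M3** (dyad level, joint label shuffles): same-class indicator and its
  interaction with the event clock, scaled per 1,000 events.
* **M4/M5** (dyad level, joint label shuffles): prior dyad experience binned
  as 1–5 and 6+ joint events, plus interactions with the same-class
  indicator; fitted separately on non-affiliate (M4) and affiliate (M5)
  dyads.
* **M6/M7** (coordination, edge-weight shuffles): arrival latency (M6) or
  event duration (M7) interacted with the same-class indicator.
* **M8** (network level, joint label shuffles): counts of common associates
  of the dyad — any class, and restricted to associates sharing the dyad's
  (shared) class — each alone and interacted with the event clock.

The event clock of an event is its own 1-based position in the global
observed stream, pooled across both feeders.  A "common associate" requires
at least one prior joint event with each dyad member; the threshold is
configurable (`min_events`), and the class-restricted count is defined only
for same-class dyads (it enters the design as 0 for different-class rows).
The distinct-associate count was chosen over a sum-over-triads statistic as
the default because it is directly interpretable as neighbourhood overlap;
both views agree on whether closure is class-assortative.

Non-events never update the network history; they inherit the clock and day
stratum of their paired event.  Covariates for event *k* are computed from
observed events strictly before *k* (property-tested against from-scratch
recomputation).

## Permutation variants

Randomization operates independently within each day × feeder subset, so
permuted data can never move an individual across days — mid-experiment
entrants (fledged juveniles) therefore never appear before their first
observed day, with no special handling.

* `independent_labels`: source and target columns shuffled separately;
  preserves per-role event counts per individual (used for the
  individual-level models).
* `joint_labels`: all 2n labels pooled and redistributed; preserves total
  participation only (used for dyad- and network-level models).  This is the
  "non-independent randomization" that tests whether class *combinations*
  could be random.
* `edge_weights`: latency/duration values shuffled among a subset's events,
  labels untouched (coordination models).
* `target_only`: only the target column shuffled.  This variant is
  **experimental**: it is a plausible role-asymmetric null retained for
  completeness, not validated against any published analysis.

Label shuffles are re-drawn until loop-free (up to 10,000 attempts), which
makes the accepted assignment uniform over loop-free outcomes (rejection
sampling; verified by exhaustive enumeration on 3-event subsets).  Persisting
loops are repaired by constrained pairwise swaps with a random other record
not featuring the looped individual; swaps conserve the subset's label
multiset but are not guaranteed uniform, which is why they are a last resort.

## Non-model permutation tests

The observed percentage of successful events is compared to the 2.5%–97.5%
quantile interval of the same percentage across joint-label replicates.  The
daily success-minus-fail differential is cumulated over days and compared
pointwise to its permutation envelope.  A one-sided exact binomial test
quantifies over-representation of a dyad subset among events (e.g.,
affiliated dyads), with the dyad share as the null rate.

## Analytic null expectations

Under random class assignment, a uniformly drawn dyad from classes of sizes
`n_A`, `n_B` is single-class with probability
`[C(n_A,2)+C(n_B,2)]/C(n_A+n_B,2)` — below 1/2 for balanced classes — and a
uniformly drawn triad is single-class with probability
`[C(n_A,3)+C(n_B,3)]/C(n_A+n_B,3)` — below 1/4, approaching it from below.
These serve as oracles for the simulator and the permutation engine.  They
deliberately ignore visitation-rate heterogeneity and do not condition on
observed degree sequences; they are null expectations, not fitted
quantities.

## The simulator

The generative model reproduces the experiment's structure: a four-hour
session per day at each of two feeder units over ~85 days for the default
(full-scale) configuration; visit intents per individual per feeder session
are Poisson, visit durations geometric (mean 60 s), and arrivals are
processed in strict time order across the day's feeders so that within-day
learning at one unit affects choices at the other.

Partner choice is a softmax over accumulated experience: an arriving bird
joins a solo occupant *j* with probability `w/(1+w)`,
`w = exp(θ·affiliate(i,j) + λ·q_ij)`, where `q_ij` is the net reward the
pair has accumulated (+1 per success, −1 per fail).  `λ` (class-learning
rate) and `θ` (affiliate bonus) are the ground-truth behavioural parameters
the pipeline is asked to recover.  The task rules are simulated by an
explicit four-state machine (default / lockout / success /
success-override) implementing all eight transitions, with a ≥120 s lockout
and a ≥15 s minimum access window (the reward stays open from event onset
for at least 15 s even if the dyad dissolves earlier).  Lockout state is
independent per apparatus; how lockouts couple across units is not
documented for the original hardware, and independence is the simplest
defensible choice.

Three further features emulate fission–fusion field data: individual
visitation propensities are gamma-distributed (shape 0.5, mean 1), each bird
favours one apparatus (85% of its visits), and each visit intent of a bird
recruits each of its affiliates with probability 0.15 to arrive seconds
later.  With the full-scale defaults this produces streams of roughly
2,500–3,000 events with affiliates contributing ~20% of events from a few
percent of dyads — the regime of the field data.  What the simulator does
*not* model: spatial movement, neophobia, dominance, seasonal trends, or
food-preference differences.  Passing tests on simulated data therefore
validate the statistical machinery and its calibration, not the behavioural
conclusions drawn from any particular field dataset.

### Desk-scale validation conditions

The calibration and recovery experiments in the test suite and acceptance
script use a reduced configuration — 60 individuals, 30 days, one-hour
sessions, ~1,500 events per stream — so that hundreds of full
permute-fit-aggregate cycles run on one CPU in minutes.  Null streams for
calibration set `λ = θ = 0` and disable affiliate co-arrival, because
co-arrival induces dyad-level correlation that the label-permutation null
does not represent (with it enabled, the observed success proportion is
over-dispersed relative to the permuted interval — a caveat that applies to
real data too, where affiliates genuinely travel together).

On these null streams the dyad-level same-class term rejects at roughly the
nominal 5% rate, and the observed success proportion falls inside the
permuted 95% interval in roughly 95% of runs.  Note that the zero-crossing
criterion applied to the replicate coefficient distribution is only
approximately a size-5% test: all replicates share the same observed data,
so the spread of the replicate distribution and the sampling variance of its
median are not identical.  Empirically the rate sits near, and slightly
below, 5% under these conditions.

## Known limitations

* The covariate lists of the eight models are reconstructions; per-term
  agreement with the original analysis can only be checked against the
  deposited field data, which the desk-scale pipeline does not require.
* The swap fallback for loop repair is multiset-conserving but not provably
  uniform.
* The experimental `target_only` variant is unvalidated.
* Individual-level models attach participant covariate *sums* to events;
  role-separated (source vs target) covariates are not implemented because
  events are undirected in substance.
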
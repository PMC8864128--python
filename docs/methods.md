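# Methods

## Model class

The analysis object is a categorical Bayesian network spanning three
instants of a randomized two-wave message study: Time-1 psychosocial
antecedents (slice `T1`), the randomized message framing (`MESSAGE`,
four levels: gain / nonloss / nongain / loss), Time-2 message-reception
variables (`T2`) and the single outcome *Delta intention* (`OUTCOME`).
Structural constraints encode the study design rather than being learned:
arcs must respect time order, the message node is parentless
(randomization) and the outcome is childless.  All variables are
categorical — three ordered levels (`low`/`medium`/`high`) except the
outcome, which uses five (`high-negative` … `high-positive`).

Because networks in this class have about a dozen nodes, inference is
exact by enumeration: hidden variables are summed out after pruning
barren nodes and cancelling constant evidence factors.  A
constant-evidence factor equal to zero is reported as contradictory
evidence rather than silently normalized away.

## Discretization

Continuous scale scores are cut at empirical quantiles: 33% for ordinary
scales, 20% for the outcome.  The estimator is the *upper* inverse CDF:
cut `k` is the smallest observation whose empirical CDF strictly exceeds
`k/n_bins`, and a value equal to a cut belongs to the upper bin.  This
pair of conventions is deterministic across platforms and yields exactly
balanced bins whenever the sample has distinct values and `n` divisible
by `n_bins`.  Heavy ties (common on Likert data) can merge cuts; cuts at
or below the sample minimum are dropped because they can only delimit
empty bottom bins.  The realized bin count is recorded and propagated to
the network's category lists — never padded — and surviving bins keep
labels spread evenly over the requested ordered scale.  Fitted maps
serialize to JSON and re-apply bit-exactly to new cohorts.

## Parameter estimation

Conditional probability tables are estimated by Lidstone-smoothed
counting: `(count + α) / (row total + α·K)`.  The default `α = 1`
(Laplace) is deliberate: the published outcome node has six parents
(4 × 3⁵ = 972 parent configurations) against a few hundred records, so
unsmoothed leave-one-out evaluation would be undefined on unseen rows.
`α = 0` is allowed only when every parent configuration has support.
Whether the original analysis smoothed is unknown, so `α` is surfaced
everywhere.

## Structure elicitation

Screening proceeds backward from the outcome.  For the outcome, all
parent subsets of (Time-1 ∪ message ∪ Time-2) up to size 6 are scored by
empirical information gain; for each Time-2 node, subsets of
(Time-1 ∪ message) up to size 5.  (The published structure needs exactly
6 and 5; both caps and the per-node retention `top_k = 3` are
configurable.  Intra-Time-2 arcs are off by default — the published
structure has none — but can be enabled, in which case cyclic candidates
are filtered.)  Information gain is implemented in its standard
non-negative orientation `IG = H(X) − H(X|S)`; natural logarithms are
used throughout (any base is ranking-equivalent).  Ties break toward the
smaller set and then lexicographically.

Retained sets are crossed into candidate structures and each candidate
scored by in-sample and leave-one-out Hand–Till multiclass AUC of the
outcome posterior given Time-1 evidence plus the framing, each
normalized by the pool maximum and summed (`m ∈ (0, 2]`).  The pairing
is one-vs-one (Hand–Till `Â(i,j) = [Â(i|j) + Â(j|i)]/2` from
class-posterior scores); binary AUC uses the Mann–Whitney rank statistic
with ties counting half.  Leave-one-out refits are incremental — the
held-out record's counts are subtracted from per-node tables — which is
exactly equivalent to literal refitting (asserted against a naive
refitting oracle in the tests) at a fraction of the cost.

Two numerical facts worth knowing:

* In-sample mAUC exceeds the leave-one-out value on expectation, which
  is why the selection metric rewards both.
* Under *pure noise* leave-one-out is pessimistic, not chance-level:
  removing a record lowers its own class's estimated probability, which
  anti-correlates scores and labels.  The tests freeze this simulated
  behaviour (≈ 0.35 at n = 300 with three classes) rather than the naive
  0.5 intuition.

## Causal engine

With the message randomized, conditioning and intervening coincide and
the Time-1 antecedents form a valid back-door adjustment set.  The
average potential effect of framing `m` given a partial Time-1
observation marginalizes the unobserved antecedents under their learned
joint marginal `p(T1ₙ)` (not a uniform prior).  Observing post-treatment
(Time-2) variables in an effect query is rejected: they lie on the
indirect causal path and would bias the adjustment.

The outcome distribution is summarized by the ordered utility
`w = (+2, +1, 0, −1, −2)` over (high-positive … high-negative) change in
intention, applied exactly as published.  Note the sign semantics: a
*positive* Delta intention means *increased* meat intention, so a
campaign aiming at reduction may prefer the negated convention; a
`negate` flag flips every effect exactly and the default is the printed
orientation.

## Population profiling and prototypes

The fitted model is interrogated on the fully enumerated Time-1
population (Cartesian product of category lists, lexicographic order;
3⁸ = 6561 individuals for the published structure).  Each individual's
4-D effect vector is its soft clustering profile under Euclidean
dissimilarity; the t-SNE embedding (perplexity 30, fixed seed,
PCA initialization) is visualization only and carries no analytic
weight.  "2% quantile" is operationalized as rank cuts of size
`⌈q·N⌉` (ceiling, for non-emptiness at small N): per framing the top
individuals by best effect *among those whose pivot is that framing*
(configurable off), *indifferent* as the bottom by delta effect,
*oppositive* as the bottom by mean effect.  Groups from different
criteria may overlap.  Each group is summarized by the modal category of
the reporting antecedents (default: baseline intention, prevention
focus, perceived severity); modal summarization is this package's
operationalization of prototype naming.

## Synthetic cohort generator

The generator emulates the study conditions: an initial pool of 834
respondents; sixteen Time-1 scales with the published entire-sample
means and SDs; randomization to four arms (default probabilities
proportional to the published arm sizes 134/134/136/141, or exact arm
counts on request); eligibility exclusions at the published rates
(special diet 124/834, under 3 weekly servings 96/834, incomplete
70/834, applied in that order with first-rule attribution — note the
published counts arithmetically give 544 survivors against a reported
545; the generator simply reports what survives).

In *likert* mode each scale is a clipped Gaussian whose **latent
location is calibrated** so that the post-clipping mean equals the
configured scale mean (censored-normal moment matching solved by Brent's
method).  Plain clipping would bias means by up to a few hundredths of a
point, which matters when validating the calibration over hundreds of
replicates.  Weekly servings are a two-component truncated normal
(below/above the 3-servings eligibility threshold) mixed at the
configured low-meat rate, so the exclusion rule and the servings column
stay mutually consistent.  Structural effects — framing main effects,
framing × moderator interactions (baseline intention, prevention focus,
perceived severity, diffused responsibility) and a mediated path through
systematic processing (promotion focus, food involvement, perceived
behavioral control, desensitization) — are modest additive shifts on the
latent scale; defaults are plausible fractions of a Likert point.
Cross-scale baseline correlations default to zero but accept a full
correlation matrix.  *categorical* mode samples ancestrally from a
supplied ground-truth network and is what the recovery experiments use.

What the generator does **not** emulate: item-level responses (only
scale scores), realistic cross-scale correlation structure by default,
measurement error models, or attrition mechanisms beyond independent
flags.  Passing recovery tests on these cohorts therefore demonstrates
correctness of the estimation machinery under the assumed data model,
not robustness to the messier dependence structure of real
questionnaire data.

## Ground-truth fixture parameterization

The published structure ships as a fixture (`figure1_structure`): eight
ternary Time-1 antecedents, the message node, systematic processing as
the single mediator, and the five-level outcome — 11 nodes, 11 arcs.
The fitted tables of the original study live with its deposited dataset,
so the package attaches a *synthetic* parameterization
(`figure1_cpts`): conditional distributions follow a discretized
Gaussian response around an additive score of centered parent levels,
with per-framing response surfaces chosen so that each framing dominates
a distinct receiver region and the loss framing is strongest for the
(high intention, high prevention focus, high perceived severity)
profiles — the qualitative pattern published for strong meat eaters.
Effect strength scales with a single multiplier; the defaults give the
strong contrasts under which the recovery experiments run (recovery is
essentially certain at n = 2000 and degrades monotonically through
n = 500 and n = 100).

## Problem sizes and numerical choices

Simulation-based checks run at sizes chosen to make Monte-Carlo noise
negligible relative to the asserted tolerances: 200 replicates of the
n = 545 calibration; 200 random networks of ≤ 7 nodes for brute-force
equivalence at 10⁻⁹; 20 replicates per sample size for structure
recovery; 10⁴ records for CPT recovery at a 0.05 entry tolerance.  CPT
rows validate to sum to one within 10⁻⁹.  Argmax ties in prediction
resolve toward the more negative outcome category; best-framing ties
resolve in the declared framing order (gain, nonloss, nongain, loss);
screening ties prefer smaller, lexicographically earlier parent sets —
all for cross-platform determinism.  Per-stage pipeline seeds derive
from the global seed by hashing stage names, so stages re-run in
isolation reproduce the composed run bit for bit.

## Known limitations

* Exact inference by enumeration is intended for the study's model class
  (≈ a dozen nodes); it does not scale to large networks and no
  variable-elimination machinery is provided.
* Complete cases only; there is no missing-data EM (the study design
  excludes incomplete responders).
* The search space is the screened cross-product, not all DAGs; no
  score-based (BIC/BDeu) or constraint-based (PC/FCI) alternatives.
* Mediation is represented but not decomposed (no natural direct /
  indirect effects); identification relies on the randomized-message
  graph class.
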
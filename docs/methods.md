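# Methods

`albicoord` reconstructs biparental foraging coordination in a
central-place-foraging seabird (the motivating system is the wandering
albatross *Diomedea exulans* breeding population on Possession Island,
Crozet) from saltwater-immersion loggers, and fits the mixed-model
selection analysis that asks whether pair members match each other's
foraging trip durations and whether intrinsic traits (sex, age,
boldness, pair familiarity) shape that coordination. This note
documents the model, the synthetic data generator that stands in for
the field data, and the numerical and design choices.

## From immersion records to trips

A leg-mounted logger reports *wet* (bird sitting on seawater) or *dry*
(flying, or on land). Two dialects exist: 10-minute bins of wet
seconds, classified wet when strictly more than 45 s of the bin were
wet; and exact timestamps of wet/dry transitions. Both parse to a
strictly alternating bout sequence.

The species' maximum continuous flight time is about 12 h, so any dry
spell *strictly longer* than 12 h means the bird was on its nest (a
*shift*); dry spells of at most 12 h inside a trip are flight. A trip
runs from the first wet bout after a shift to the start of the next
shift. Because bouts alternate, shifts and trips tile the record
between the first and last shift; partial trips at deployment edges are
dropped rather than clipped, since their durations are censored.

Exactly one parent forages while the other attends the nest, so the
tagged bird's land periods are its partner's trips: `n` observed trips
yield `n − 1` inferred partner trips. Inference error comes from the
nest-relief overlap (the nest-bound bird delays departure after its
mate returns), which inflates inferred durations by the lag at each
end-of-trip relief.

## Phenology

Laying is assumed to start 16 December (season label = year of that
December); brooding ends 11 April. The per-pair hatch date is detected
as a single least-squares change point on log trip durations inside a
Feb 1 – Apr 11 search window, accepted only if the post-split mean trip
duration falls below 0.6 of the pre-split mean; otherwise the
population average hatch date of 15 March is used. Window, threshold
and minimum trip count are configuration keys, and the detected /
fallback tally is part of every pipeline report: the change point is a
stand-in for the source analysis' visual "sudden drop" and its
threshold must be reported with results. Stage membership is by trip
*start* time; the original analysis does not state how boundary-spanning
trips were assigned.

## The coordination covariate and the model table

The response is the square root of trip duration in hours (correcting
strong positive skew). The coordination covariate for a focal trip is
the *partner's previous-trip deviation*: the duration of the partner
trip immediately preceding the focal trip, minus the expanding mean of
that partner's earlier trips in the same breeding stage ("previous" is
read literally, hence an expanding rather than whole-stage mean). A
positive slope of focal sqrt duration on this deviation is
coordination: the focal bird prolongs its trip after the partner made a
longer-than-usual one.

Model rows are the *tagged* bird's observed trips only; inferred
partner trips enter the deviation covariate but are never responses.
Two reasons. First, that is what loggers measure. Second — found
during development and worth stating — when both members' trips are
rows, each bird's residual feeds the other bird's future deviation
covariate through the alternating schedule, and this cross-row
correlation between design and errors attenuates the coordination
slope (a predetermined-regressor/Nickell-type bias; about −0.1 sqrt-h
at a generative slope of 0 and ~19% relative attenuation at 0.5 in
simulation at this study's trips-per-pair count). With single-member
rows the covariate history shares no residuals with the responses, and
simulation shows the estimator is unbiased.

Row filters, all itemized in the feature manifest: trips outside the
stage windows; rows with undefined deviation (no earlier in-stage
partner trip); the first brooding trip per pair-season (its "previous
partner trip" lies in incubation); and the bird tagged second in the
few dual-tagged pairs.

Extreme ages are collapsed inward, separately per stage, until the
boundary categories hold at least five distinct birds (guarding the
quadratic terms against sparse-extreme leverage); quadratics are squares
of the collapsed-then-scaled linear term. Continuous covariates are
standardized with pooled moments computed across both stages before the
stage split, so coefficients are comparable between stages; the
reconciliation order (collapse per stage first, pooled scaling second)
is a choice between two statements that cannot both be literal, and the
manifest records the moments and boundaries so either can be audited.

## Boldness

Repeated 0–5 ordinal responses to an approaching human are reduced to
one score per bird by a Gaussian linear model `response ~
observation_number + observer + bird` with sum-to-zero factor coding;
the bird estimates, mean-centered across birds, are the scores. The
family/link of the original "generalized linear model" is unstated;
Gaussian-identity matches the downstream use of the score as a
continuous centered covariate. Observation number enters as a linear
habituation trend. A bird observed by a single observer who observed no
other bird is flagged: its contrast is aliased.

## Mixed models, selection, averaging

Per stage, candidate models regress sqrt trip duration on subsets of
{focal/partner age (linear + quadratic), focal/partner boldness, sex,
new-partner flag, date since 16 Dec, partner's previous-trip deviation,
and the interaction set pairing the deviation with each trait, boldness
with own age, and boldness with sex}. Subsets must respect marginality
(quadratics require their linear term; interactions their mains). The
random structure is identical in every candidate: random intercepts for
pair and year (crossed) and a by-pair random slope on the scaled
deviation, so coordination strength may vary between pairs.

Implementation: statsmodels `MixedLM` with the crossed structure
expressed as variance components inside a single group. statsmodels
cannot estimate an unstructured intercept–slope covariance in this
layout, so the pair intercept and pair slope are independent components
(the documented fallback structure). Fits are by maximum likelihood for
ranking — likelihoods comparable across fixed structures — and the
parameter count for AICc is fixed effects + three variance components +
residual. Ranked submodels are optimized by Powell's method warm-started
from the global model's variance parameters (the profiled surface has
the same three parameters whatever the fixed terms), with slightly
relaxed tolerances whose logLik error (~3e-3) is far below the ΔAICc
resolution; the default BFGS path stalls on deliberately misspecified
submodels. A near-zero variance component flags the fit singular but
keeps it: a vanishing random-slope variance is itself a finding (little
interpair variation in coordination). Non-converged fits are dropped
from the ranking with a count.

Selection: AICc ranking of all marginality-valid subsets; best set =
ΔAICc < 2 (strict); nested exclusion removes any model whose terms are
a strict superset of a lower-AICc model in the set. Averaging is
conditional ("natural"): a term is averaged, with renormalized Akaike
weights, over the models containing it; its presence weight is reported
separately; the full-model (zero-substitution) variant is available.
Unconditional SEs combine within-model variance and between-model
spread. Terms involved in retained interactions are flagged and
suppressed from the primary table — averaging across interaction
structures is not interpretable. Reported coefficients come from REML
refits of the post-exclusion set; ML is used only to rank. Marginal and
conditional R² follow the variance-partitioning definition for mixed
models, with the random-slope contribution weighted by the mean squared
slope covariate.

## The synthetic generator

The generator is the analysis model run forward. A pair alternates
trips; each new trip's sqrt duration is the stage intercept plus trait
effects (betas in sqrt-hours per SD of the covariate), plus the
coordination term β_coord × (deviation / `coord_scale_h`), plus pair
intercept, pair-slope × the same covariate, year effect, and residual.
The deviation is computed exactly as the feature builder computes it,
so parameter recovery is an identity test up to the recorded scaling
constants. Defaults emulate the field study: stage intercepts 11.6 and
8.1 sqrt-h (mean trips ≈ 5.6 and 2.7 days), 70 pairs over 7 seasons
with ~30% of pairs observed twice, three dual-tagged pairs,
exponential nest-relief lag with mean 1.9 h, age distribution ~N(21.1,
7.7²) clipped to [7, 45], and a logger deployment starting uniformly
30–60 days into the season — full-season records would give ~1300
model rows per stage where the field data had 260–611, and partial
deployment is also why early-trip deviations are undefined in real
records. β defaults take magnitudes from the published averaged
estimates; β_coord = 0.2.

Distributional choices and their consequences:

* Residuals are Gaussian on the sqrt scale (the analysis model's
  assumption; the source reports only means and SDs), truncated at
  ±3σ: untruncated tails produce trips shorter than the 12-h flight
  ceiling, which no segmentation rule could resolve — the same class of
  constraint as keeping at-sea dry bouts under 12 h. Durations are
  floored at 2 h. Even truncated, ~1% of brooding trips fall under
  12 h at field-level variances; the resulting merges are treated as
  realistic messiness in pipeline-level runs, while exactness tests use
  variance levels at which every trip clears the ceiling (chosen
  analytically, ~4σ margins, before the tests were run).
* Within a trip, wet bouts (mean 1.5 h, minimum 3 min so they register
  in 10-min bins) alternate with exponential flight bouts truncated at
  11 h; at-sea intervals open and close wet so trip boundaries are
  observable. On land the record is fully dry.
* Hatch dates are N(16 Dec + 89 d, 6 d²), i.e. around 15 March.

What the generator does *not* emulate: weather- or prey-driven shared
environmental variation between mates, individual foraging-site
fidelity, mass-dependent desertion decisions, logger failure gaps, and
sex differences in trip-duration variance. Passing recovery tests
therefore show that the estimator chain is faithful to this generative
model, not that the field system satisfies it.

## Known limitations

* The pair intercept–slope covariance is fixed at zero (library
  constraint); a strong true covariance would mildly misattribute
  variance between the two components.
* The coordination slope estimated from partially observed records
  (deployment starting mid-season) is attenuated, because early-trip
  expanding means are computed from a clipped history; the same applies
  to any real deployment. Recovery experiments therefore use fully
  observed schedules.
* Change-point hatch detection degrades when a date trend shrinks the
  incubation/brooding contrast; at field-level noise about a quarter of
  pair-seasons fall back to the population hatch date, and the tally is
  part of every report.
* With all interactions included, the all-subsets space is astronomically
  large; `enumerate_specs` guards against accidental explosions and the
  pipeline default ranks the main-effects set. Targeted interaction
  models can be fitted directly with `fit_lmm`.
* AICc parameter counts, averaging variant, and singular-fit handling
  are all explicit switches because the source analysis does not state
  them; defaults are documented above.

## Problem sizes used in the shipped experiments

Simulation experiments in the test suite use 60 replicates per
generative slope for parameter recovery (70 pairs each, brooding
stage), 100 replicates at 25 pairs for selection recovery, 200 series
for hatch recovery, and 1000 random bout sequences for the segmentation
oracle; the pipeline demonstration runs the full 70-pair study. These
sizes give Monte-Carlo SEs a factor of ~3 below the asserted margins.
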
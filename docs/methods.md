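# Methods

## The estimand and the design

The pipeline compares composite dementia risk indices on two axes: (i) how
strongly each index, measured once at baseline, is associated with the level
of global cognition (MoCA, integer 0–30) about a decade later and with its
annual rate of change over a further ~4 years; and (ii) how well each index
discriminates participants who experience a clinically meaningful decline
(≥ 3 MoCA points) from those who do not, relative to a model using age and
education alone. Scores are z-standardized (sample SD, denominator n−1) on
the full baseline analysis sample before modelling, so coefficients are per
1 SD and comparable across indices with different native scales; tertile
cutpoints are likewise computed once on the baseline sample and reused in
subsamples.

## Scoring engine

A risk index is a list of items, each a total mapping from a harmonized
profile value to points: `binary` (presence earns the weight), `categorical`
(label → points), `banded` (half-open intervals `[min, max)` over a
continuous measure), and `linear` (slope × value, with an anchor value at
which the item's theoretical-maximum contribution is evaluated — age at 100
years, education at 20 years for the linearly weighted index). Weight
tables live in versioned YAML (`src/cogrisk/score_configs/`), one file per
index with a provenance note; the engine never hard-codes weights, so a
corrected transcription drops in without code change. Several shipped
tables are explicitly approximate transcriptions of the published indices
(their files say so); the CAIDE table encodes the original integer-point
variant rather than any beta-coefficient weighting, and the Lancet-based
table codes each of the Commission's 14 modifiable factors absent/present
weighted by its published relative risk.

Missing items contribute nothing and are excluded from the prorating
denominator; a participant's score is rescaled by
`observed / max-available × theoretical-max`. Two conventions make this
well defined for indices with protective (negative) weights: a non-linear
item's "maximum possible risk points" is `max(0, max mapping value)`, so
protective-only items contribute 0 to both the denominator and the
theoretical maximum (keeping both positive for LIBRA-style scores), while
linear items contribute their anchor value even when the weight is
protective (the published convention for linearly weighted demographics).
Participants with zero observed items for a score raise an explicit
"unscorable" error — never a silent 0, which would bias score
distributions — and are excluded from that score's analyses with a logged
count. Tertile ties go to the lower group (deterministic and reproducible).

## Synthetic cohort

The generator emulates the structure the analyses assume, not any real
person-level data. Baseline age is truncated-normal 66.3 (SD 5.6) on
[57.8, 89.9] years; education normal 12.7 (SD 2.3) years; 54 % female;
22 binary risk factors with fixed prevalences (e.g. hypertension 0.45,
diabetes 0.09, ApoE-e4 carriage 0.27) and four continuous measures (BMI,
systolic BP, total cholesterol, alcohol units). A latent burden is a fixed
linear combination of the items (continuous items as z-deviations from
fixed anchors), centred so 0 means average risk; its weights give it SD
≈ 0.6, and the default level (−2.5/unit) and slope (−0.33/unit) effects
then correspond to roughly −1.5 MoCA points and −0.2 points/year per SD —
the order of magnitude a well-powered ageing cohort reports. The latent
trajectory is

  b0_i + level·risk_i + (base_slope + slope·risk_i + reserve·(b0_i − μ) + u_i)·t + ε_it

with person-level baseline b0 ~ N(23.8, 2.4), slope noise u ~ N(0, 0.15),
residual ε ~ N(0, 1.3), base slope −0.30 points/year, and an optional
"reserve" coupling (default 0) that ties a person's rate of change to their
baseline level — used to create regimes where attrition on baseline
cognition is informative about change. Observations are rounded half away
from zero and clamped to [0, 30]; clamping counts are logged. Visit 1 is at
t = 0; visit 2 at a truncated-normal interval 4.2 (SD 0.3) years bounded to
[2.9, 5.2]. Attendance at visit 2 follows a logistic model on raw
covariates (default: older, frailer, lower-MoCA participants drop out;
~65 % attendance), and item-level missingness blanks each risk item
independently (rates chosen so a 14–18-item score is incomplete for about a
quarter of participants; age and sex are never blanked). One integer seed
is expanded into six independent substreams (demographics, items,
trajectories, follow-up timing, attrition, missingness), so each stage is
individually reproducible and cohorts are byte-identical across runs.

What the generator does *not* emulate: correlated risk factors (items are
independent unless configured otherwise), practice effects, domain-specific
cognitive change, dementia incidence or death, and more than two visits.
Passing tests therefore show the machinery is correct under a faithful
data-generating process, not that any substantive conclusion transfers to a
particular real cohort.

## Attrition weighting

Attendance is modelled by ML logistic regression (complete case) on
baseline covariates; perfect or quasi-separation raises an error naming the
covariate. Weights are 1/p̂ for attendees, truncated at the empirical 99th
percentile of the weight distribution (linear-interpolation quantile; every
weight above the cap is set to the cap). Weights are participant-level:
attendees carry their truncated weight on both rows, baseline-only
participants carry weight 1. They enter the mixed models as cluster-level
pseudo-likelihood weights (the weighted log-likelihood sums w_i × the
participant's marginal block log-density), the standard survey-weighted ML
for cluster weights; weights of 1 reproduce the unweighted fit exactly
because the weighted fitter is the only code path. The participation model
is fitted once on the baseline analysis sample, not per subsample.

## Mixed models

With at most two observations per participant, each marginal covariance
block is at most 2×2, so the random-effects-integrated likelihood has a
closed form that we evaluate directly, profile the fixed effects by
weighted GLS, and optimize over variance components (residual σ², and the
random-effect covariance Ψ parametrized via its Cholesky factor, so it
stays positive semi-definite) with L-BFGS-B from two starts. REML is the
default; ML is used whenever fits enter a likelihood-ratio comparison.
AIC = 2k − 2·logLik with k counting fixed effects plus variance parameters.
This fitter exists because the analysis requires weighted LMMs, which
statsmodels' MixedLM does not support; with unit weights it reproduces
MixedLM's estimates, variance components and log-likelihood to numerical
precision (cross-checked in the test suite), and on weakly identified
random-slope models it sometimes finds a better optimum than MixedLM's
default optimizer.

Two time points barely identify a slope variance: fits whose slope variance
or correlation lands on the boundary are flagged singular and refitted
(with a logged notice) with a random intercept only — average fixed
effects, the estimand of interest, are unaffected. The random-effects
covariance is unstructured by default. Boundary caveats for variance-
component LRTs are propagated in the comparison output. Moderation models
use the separate-moderator expansion — every term of (1 + score)(1 + time)
crossed with age-group (≥ 65 at risk assessment) and with sex — giving the
three-way time × score × moderator terms that express group-specific score
slopes; empty age × sex cells raise an error naming the cell.

## Decline classification

Decline is defined on the raw integer MoCA difference (visit 1 − visit 2
≥ threshold), not in SD units; only participants with both visits are
labelled, and exclusions are logged. Logistic fits use statsmodels GLM with
frequency weights for IPW. AUC is the normalized Mann–Whitney statistic
with ties at half credit; its variance and the paired two-marker comparison
come from DeLong placement values, implemented in-repo (AUC comparison is a
load-bearing output, so it is oracle-tested against brute-force pair
counting, scikit-learn, and a bootstrap rather than delegated). Comparing a
marker with itself returns z = 0, p = 1; degenerate variance with unequal
AUCs raises. Single-marker AUCs are computed on the raw z marker, which is
identical to the AUC of the fitted model's linear predictor for monotone
single-marker models. The sensitivity grid crosses decline thresholds
{2, 3, 4, 6, 9} with baseline floor exclusions {none, 18, 20, 22, 24};
cells with an empty class are reported not-estimable rather than raised.

## Problem sizes and numerical choices

The test suite exercises parameter recovery at n = 2000 with 100 replicates
per true interaction value {0, −0.05, −0.20} (bias and CI-coverage checks),
DeLong null calibration with 500 replicates at n = 200, the bootstrap
variance check with 2000 resamples, and the attrition-correction property
with 100 replicates at n = 3000 — sizes chosen to make Monte-Carlo noise
small relative to the tolerances while the full suite stays fast on one
CPU. Recovery scenarios place the baseline mean at 20 so floor/ceiling
clamping is negligible; under the cohort defaults (baseline ≈ 23.8) the
bounded 0–30 scale visibly attenuates interaction estimates — the
compression a bounded screening instrument really imposes, and one reason
sensitivity analyses exclude low-baseline participants. The
attrition-correction scenario compares weighted and unweighted fits on
completers, where inverse-probability weighting is classically defined;
in the full two-row-per-person model the retained baseline rows of
non-returners already absorb most of the selection on observables.

## Known limitations

Approximate weight tables mean the synthetic score distributions match the
published indices only in structure and rough scale. The pseudo-likelihood
weighting is first-order (no design-based SE correction; model-based SEs
are reported). The moderation design stops at three-way interactions, so a
four-way age × sex × score × time effect is only partially expressible.
Prorating assumes missingness is unrelated to the unobserved item values
given the observed ones; the generator's independent missingness satisfies
this by construction.
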
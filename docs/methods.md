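# Methods

## The task and its scoring

The Box Task is a computerised self-ordered search test of visuospatial
working memory. Closed boxes appear at fixed locations; the participant
opens boxes one at a time to find a hidden target. A found target stays in
its box and a new target is hidden elsewhere, so the participant must track
both the boxes visited in the current search and the boxes that already
yielded targets. A *search* ends when the current target is found; a
*trial* is one search per box; a session is two 3-box practice trials
followed by two trials each at set sizes 4, 6 and 8. Practice trials are
logged but never scored.

Four measures are computed per trial and reported per set size (mean of the
two trials; additionally the trial-1 + trial-2 sum of the two error counts,
which are the diagnostic tree's inputs):

* **Between-search errors** — opens of a box whose target was found in a
  strictly earlier search of the same trial. Every re-open counts.
* **Within-search errors** — opens of a box already opened, and found
  empty, earlier in the *same* search.
* **Completion time** — the timestamp of the final target-found event.
* **Strategy score** — for each search k ≥ 2, the Levenshtein distance
  between the path of search k and the path of search k−1 with all
  occurrences of search k−1's target box removed, normalized by the longer
  of the two paths (0/0 ≡ 0), averaged over k. Range [0, 1]; lower = more
  similar consecutive search paths = a more systematic strategy.

Two scoring conventions were genuinely open and are fixed here as follows.
First, the error classes are **disjoint**: an open of a past-target box is
always a between-search error and never also a within-search error, because
a within-search error is defined by returning to a box *found to be empty*
during that search. Second, removal of the previous target from the
reference path deletes **all** occurrences of that box, not just the
terminal one, since the removal names a box rather than a position. The
per-trial strategy score weights searches equally regardless of path
length.

A deliberate reporting quirk is reproduced on request: with
`emulate_missing_4box_t1_time` the 4-box time aggregate uses trial 2 alone,
mirroring the source study's loss of 4-box trial-1 times to a software
fault. Error and strategy aggregates are unaffected.

## The generative agent

No patient-level logs are publicly available, so cohorts are simulated by a
parametric cognitive agent. The design goal is the simplest mechanism with
interpretable parameters that (i) produces both error types with the
correct set-size scaling, (ii) admits a severity gradient, and (iii) can be
calibrated to the published group means.

Memory is modelled as two stores with **geometric decay per intervening
open**. A past-target box found `d` opens ago is remembered — and excluded
from the believed-eligible set — with probability `rho_between ** d`; a box
opened `d` opens ago within the current search is remembered with
probability `rho_within ** d`. Memory draws are made independently at each
choice. Having formed its believed-eligible set, the agent follows a fixed
canonical scan order (lowest box index first) with probability
`sigma_scan`, otherwise it picks uniformly at random among believed-eligible
boxes; if the set is empty the belief resets to all boxes except the one
just opened. Per-open latency is log-normal(`latency_mu`, `latency_sd`)
seconds; timestamps accumulate from trial onset.

Two consequences worth noting. With `rho_between = rho_within = 1` the
agent can never revisit, so it scores exactly zero errors — a hard
invariant of the test suite. And because boxes opened and found empty in
*earlier* searches may be revisited without penalty, total opens exceed
`set_size + errors`; completion-time calibration therefore uses simulated
open counts, not error counts.

Each participant carries one latent severity scalar `z ~ N(0, 1)`. The
agent's retention parameters are degraded by `severity_sd * z` on the logit
scale (worse memory at higher severity), and each neuropsychological
covariate is drawn as `mean + loading * z + noise`, with the noise variance
chosen so the marginal SD matches its target, then truncated to the
instrument range and rounded where the instrument reports integers. This
single-factor coupling is a modelling commitment: it is how the
group-specific covariate–error structure is built in. In the AD preset the
RCF 3-minute recall carries the dominant loading (episodic-memory-driven
errors) with a moderate Trails A loading; in the bvFTD preset the RCF
recall loading is zero and Trails A dominates (attention-driven errors);
controls have small loadings throughout. Demographics are not modelled and
latency has no severity coupling (no speed–accuracy trade-off).

## Calibration

Preset values (`src/boxtask/presets.yaml`) were chosen by a coarse grid
search (`scripts/calibrate_presets.py`) over `rho_between`, `rho_within`
and `sigma_scan` per group, scoring large simulated cohorts (~2,000
participants for the final centring) against the published per-set-size
between-search error means, with the 6-box patient anchors and the 8-box
control anchor weighted most. `latency_mu` was then set from the simulated
mean open count so the 8-box completion time matches its published group
mean, holding `latency_sd = 0.35` fixed. Covariate means and SDs are the
published group values; the Trail Making Test means/SDs are not published
for this cohort and use clinically typical values for these groups
(control 36±12 / 85±30 s; bvFTD 55±25 / 135±60 s; AD 68±30 / 170±70 s).

Final agent values:

| group   | rho_between | rho_within | sigma_scan | latency_mu | severity_sd |
|---------|------------:|-----------:|-----------:|-----------:|------------:|
| control | 0.9735      | 0.995      | 0.30       | 0.911      | 0.25        |
| bvFTD   | 0.89        | 0.995      | 0.20       | 1.284      | 0.50        |
| AD      | 0.72        | 0.99       | 0.40       | 1.503      | 0.80        |

At the study sample sizes (28 AD / 28 bvFTD / 32 controls) the anchor means
carry Monte-Carlo standard errors near 10% of their values; single-cohort
estimates therefore scatter around the calibrated centres, which is the
realistic behaviour of a cohort this size.

What the generator does **not** emulate: within-search error rates at the
patient means' upper range (simulated patients make somewhat fewer
within-search errors than the clinical groups), the full between-participant
dispersion of patient error counts (simulated SDs are smaller than those
implied by the published standard errors), correlations among covariates
beyond the single severity factor, apathy/motivation effects, and any
speed–accuracy coupling. Passing tests show the mechanism reproduces the
group-mean structure and coupling directions, not that it is a validated
model of patient behaviour.

## Diagnostic layer

The published decision tree ships as a fixed classifier: ACE-III total
> 70 vs ≤ 70 at the root (70 itself goes low); on the high branch ≥ 1
within-search error (trial-1+2 sum) at 6 boxes ⇒ AD; on the low branch ≥ 2
between-search errors at 4 boxes ⇒ AD; otherwise bvFTD. Shipping the tree
verbatim decouples replication of the published rule from the tree fitter.

The fitter is a documented simplification of CHAID. Continuous predictors
are discretized at their unique values when ≤ 20, else at 20
quantile-based cuts. Adjacent categories are merged iteratively while the
most-similar adjacent pair's 2×2 chi-square test (no continuity
correction) has p > `alpha_merge`; categories smaller than
`min_node_size` are absorbed into a neighbour. The predictor's p-value is
the 2×r chi-square on the merged table, Bonferroni-multiplied by
C(c₀−1, r−1) — the number of ways to partition the original ordered
categories into r contiguous groups. The smallest adjusted p wins; the
split is accepted iff it is ≤ `alpha_split`. A `forced_first` predictor is
split first at the root regardless of the test, mirroring the published
analysis's forced ACE-III entry. Leaves take the majority label with ties
going to AD — the clinically costlier miss — and this tie-break is
configurable in code. SPSS's exhaustive-CHAID internals are unpublished;
this simplification recovers the published partition's cut-offs on data
generated from it and holds its split-test type-I error below nominal in
permutation nulls, which is the fidelity the package claims.

AUC is computed as the Mann–Whitney probability from average ranks, so ties
contribute exactly ½; the ROC curve is evaluated at midpoints between
consecutive distinct scores plus sentinels. For measures where *larger*
values are more AD-like (errors, times) the orientation flag negates scores
so AUC > 0.5 always reads "discriminates in the stated direction".
Classifier evaluation reports the confusion matrix, per-class and overall
percent correct, and the misclassification risk r with SE √(r(1−r)/n).

## Inference

Benjamini–Hochberg runs at Q = 0.05 with a stable sort. The within-group
regressions z-score the response and predictors and report standardized
betas with classical t p-values (df = n−k−1), entering all predictors at
once; executive function enters as Trails B−A to avoid collinearity with
Trails A, and collinear designs are rejected with the offending columns
named. Group/set-size mean comparisons use two-sided permutation tests —
labels shuffled within each pair, p = (1 + #{|T_perm| ≥ |T_obs|})/(1 +
n_perm), default 9,999 permutations — BH-corrected as one family. These
permutation contrasts are the package's inferential analogue of the source
study's repeated-measures models (GEE / mixed ANOVA), which are deliberately
out of scope: they are off-the-shelf machinery, and the group-mean structure
they estimated is handled here as simulator calibration instead.

## Numerical and reproducibility choices

Sessions, cohorts and analyses are deterministic functions of their seeds;
cohorts spawn one independent stream per participant, so group sizes and
ordering do not perturb one another's draws. Layout placement is rejection
sampling on a 100×100 canvas with a 15-unit minimum separation and a
bounded attempt count (a too-small canvas raises a configuration error).
The strategy score defines 0/0 as 0 (both paths empty). Default test and
analysis problem sizes (e.g. 2,000-participant calibration runs, 100-replicate
null studies, 200-per-group regression checks) were chosen to keep
Monte-Carlo error well below the effects being checked while the whole
suite runs in well under a minute.
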
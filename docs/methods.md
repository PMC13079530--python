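# Methods

This note records the statistical model, the geospatial conventions, the
synthetic data-generating process, and the numerical and design choices made
where more than one defensible option existed.

## Study design

The package implements a matched case–control screen of many exposure
proxies. Cases of one cancer (breast or lung) are compared with cancer-free
controls drawn from the same source population; association is estimated per
*exposure definition* — an (agent, metric, buffer, lag) cell — by
conditional logistic regression on matched sets, and a finding is reported
only when it is significant under three different matching strategies.
Breast-cancer analyses are restricted to female participants (cases and
control pool); lung analyses use both sexes and match on sex. A sensitivity
flag restricts both cases and the control pool to never-smokers before
matching.

## Exposure assessment

Distances are great-circle distances on a sphere of radius 6371.0088 km
(the IUGG mean Earth radius); buffers are therefore geodesic circles, exact
at any scale, rather than planar projections. For participant *i*, agent
*a*, buffer *b* ∈ {2, 5, 10, 20} km and lag *L* ∈ {1..5}, the contributing
set *S* holds facility-year reports of *a* within *b* km of the residence
whose reporting year lies in `[visit_year − L, visit_year − 1]` — the visit
year itself is excluded, since reporting is annual and exposure must precede
the visit. The metrics are:

* `presence` — 1 iff *S* is nonempty;
* `count` — number of distinct facilities in *S* (facilities, not
  facility-years);
* `idw_hazard` — `Σ_{S} hazard / max(d, 0.1 km)^p` with default exponent
  p = 1. The 0.1 km floor bounds the weight of co-located points; geocoding
  precision makes sub-100 m distances unreliable anyway. The exponent is a
  parameter because "inverse-distance weighting" is used with both p = 1 and
  p = 2 in the exposure literature.

Cumulative windows are nested, so every raw metric is nondecreasing in both
buffer and lag, and IDW hazard over a lag-5 window equals the sum over the
five single-year windows — both properties are asserted in tests against a
brute-force double-loop oracle.

**Dichotomization.** Analyses use binary codings only (a continuous mix of
distances over multiple facilities has no clean interpretation):
`presence` is already binary; `count` codes ≥ 2 facilities when any
participant has ≥ 2 in-buffer facilities, and otherwise duplicates presence
and is flagged redundant (excluded from testing); `idw_hazard` codes values
strictly above the median of the *positive* values pooled over the whole
analysis cohort (cases + controls, pre-matching). All-zero columns are
flagged non-informative. The prevalence filter then keeps definitions with
at least 10 exposed cases and 10 exposed controls on the binary coding; the
"exposed" in the filter refers to the analysis coding, not the raw value
(they differ for IDW).

## Matching

All three methods are 1:k without replacement, default k = 4 (a
conventional efficiency point for case–control designs; the marginal gain
beyond four controls per case is small). Defaults: nearest-neighbor and
exact matching on age, sex, race, visit year; optimal matching additionally
on alcohol, tobacco and ADI.

The nearest-neighbor/optimal distance is a diagonal Mahalanobis distance —
continuous variables (age, visit year, ADI) standardized by their pre-match
whole-dataset SDs, Euclidean norm — plus a fixed penalty of 1000 per
mismatched categorical variable. The penalty effectively enforces
categorical agreement whenever an agreeing control remains, without making
mismatch infeasible. Greedy matching processes cases in descending age
(hardest-to-match cases first, since controls skew young), breaking ties by
id; control ties break by id. Optimal matching replicates each case k times
and solves the rectangular min-cost assignment exactly
(`scipy.optimize.linear_sum_assignment`); with fewer controls than k·cases
this degrades to the maximum-cardinality minimum-cost assignment with a
warning. Exact matching coarsens age into 5-year bins (exact matching on
continuous age is degenerate), forms strata on the joint key, and deals each
stratum's controls round-robin (seeded shuffles) to its cases so that every
emitted set has exactly one case — this keeps the conditional-likelihood
form identical across the three designs.

Balance is reported as standardized mean differences using pre-match pooled
SDs (post-match SMDs use the matched sample but the same denominator, the
standard convention) and per-category proportion differences; |SMD| ≤ 0.1
is flagged as adequate but never enforced.

## Conditional logistic regression

With one case per set the conditional likelihood is
`ℓ(β) = Σ_s [x_case'β − log Σ_{j∈s} exp(x_j'β)]`. The fit is
Newton–Raphson on the exact score and observed information with
step-halving, converging at max |score| < 1e−8 or relative log-likelihood
change < 1e−12, capped at 100 iterations; within-set log-sum-exp is centered
at the set maximum for stability. Sets whose covariate rows are identical
contribute a constant and are counted as non-informative; a fit with zero
informative sets, a non-converged fit, or any |β̂| > 15 (numerical
signature of separation) is flagged non-evaluable and excluded from
inference counts rather than reported as a number.

Adjustment: the nearest-neighbor and exact analyses adjust for alcohol and
tobacco (dummy-coded, reference *never*, with *unknown* kept as an explicit
level — unknown strata are large in EHR-derived lifestyle data and dropping
them would discard most sets) and for continuous ADI. The optimal analysis
includes the exposure only, having matched on those variables. Covariates
constant within every set are inestimable in a conditional likelihood and
are dropped with a warning. Inference is by Wald tests (`z = β̂/se`,
two-sided normal), matching the per-coefficient framing of the volcano
plots; 95 % CIs are `exp(β̂ ± 1.959964·se)`.

For 1:1 pairs with a binary exposure the estimator reduces exactly to the
discordant-pair ratio `n10/n01`; this closed form, a brute-force likelihood
maximizer on tiny designs, and statsmodels' independent `ConditionalLogit`
are all used as test oracles.

## Multiple comparisons and consensus

Bonferroni families are (agent, matching method, cancer), with the family
size m equal to the number of *evaluable, filter-surviving* definitions for
that agent — the stricter reading of adjusting "per tested agent", since
filtered-out cells were never tested; p_adj = min(1, m·p). Overall
significance requires p_adj < 0.01 in all three matched analyses *and* a
consistent OR direction (a sign-discordant triple is not a replicated
finding, so direction consistency is an explicit condition). Agent
summaries report `100 · (#significant with OR > 1) / (#evaluable)` per
method, rounded half-up to integer percent, omitting agents with no
significant result anywhere. Volcano exports use natural log OR on x and
−log10 adjusted p on y (bases recorded in the export metadata), with the
threshold line at −log10(0.01).

## Synthetic data generator

The generator emulates the two inputs the pipeline consumes, at desk scale.

*Facilities.* Per agent, a fixed number of facilities placed uniformly in
the lon/lat bounding box (optionally around Gaussian cluster centres to
mimic industrial corridors). Every calendar year from five years before the
first visit year to the last visit year, each facility reports with
probability `facility_persistence` (default 0.8 — TRI reporters are mostly
persistent year over year); the modeled hazard is lognormal (default
ln-mean 8, ln-SD 2: RSEI-style scores span orders of magnitude). Hazard is
generated directly rather than as emission × toxicity weight, since only
the hazard column is consumed downstream.

*Participants.* Residences uniform in the region; visit years uniform in
the configured range; categorical covariates from configurable frequencies
whose defaults mirror a mid-Atlantic primary-care control mix (sex near
parity, White/Black plurality, mostly non-Hispanic, large *unknown* strata
for alcohol/tobacco). Ages are Gaussian around the control mean (default
42, SD 14, clipped to 18–95). Raw ADI is Gaussian and the emitted `adi_std`
column is the cohort-standardized transform (mean 100, SD 20, sample
(n−1) SD — the conventional choice).

*Case assignment.* Candidates are drawn in batches; each candidate's case
probability is `logistic(baseline + Σ_d β_d·coding_d + confounder terms)`
where the β_d are configurable true log ORs on binary exposure codings, and
accrual stops when exactly `n_cases` and `n_controls` are banked (an
attempt cap guards unreachable targets). The default case/control age gap
(60 vs 42) is produced by exponential tilting: under a Gaussian age prior,
an age coefficient `(μ_case − μ_control)/σ²` yields approximately the
configured case age mean, so the single logistic model generates both the
outcome and the age confounding that matching must remove. Effects are
planted on presence metrics by default: presence coding is data-independent,
so the planted log OR is exactly the conditional estimand. (IDW effects
would use a batch-level median cut that only approximates the analysis-time
cohort median; the generator permits them but recovery is then approximate.)

The emitted truth object stores every participant's raw exposure over the
full grid; recomputing it through the exposure module reproduces it
bit-for-bit (tested), so the generator cannot drift from the assessment
code. A single global seed drives hierarchical streams (facilities,
participants, matching tie-breaks), making every stage independently
re-runnable and the whole pipeline byte-identical across re-runs.

What the generator does *not* emulate: real geography and commuting-scale
address error, census-tract polygon structure (ADI attaches directly to
participants), secular trends in emissions, exposure misclassification from
residential mobility, and correlation between agents' facility locations.
Passing tests therefore validate the machinery and its statistical
calibration, not any substantive claim about real populations.

## Validation studies and problem sizes

Three repeated-simulation studies (in `toxmatch.experiments`) characterise
the pipeline; their scales are chosen so each study completes in minutes on
one CPU while exercising every stage:

* **Parameter recovery** — 200 datasets of 500 sets (1:4), exposure
  prevalence 0.3, true OR 2.0, sets drawn directly from the conditional
  model (the exact generative counterpart of the likelihood). Checks: mean
  β̂ within 3 Monte-Carlo SEs of log 2; Wald CI coverage in [0.91, 0.98].
* **Null error control** — 200 full-pipeline replicates (100 cases, 800
  controls, two agents, compact ~120 × 110 km region, visit years
  2017–2019, 10 facilities/agent) with all true ORs 1. The per-agent
  probability of *any* overall-significant definition is the family-wise
  error of the consensus rule; the triple-matching requirement makes it
  far more conservative than plain Bonferroni (observed ≈ 0–1 %, asserted
  ≤ 5 % to leave Monte-Carlo room).
* **Power** — 100 replicates at 600 cases / 3600 controls with one planted
  effect, chromium presence within 20 km at lag 5, true OR 2.5 (that cell's
  control-side prevalence ≈ 45 % yields several hundred exposed cases).
  Checks: the planted definition is overall significant in ≥ 80 % of
  replicates and the planted agent's mean summary percentage exceeds every
  null agent's.

The narrow year range in the replicate studies keeps exact-matching strata
populated at reduced n; at the full study scale (tens of thousands of
controls over 14 years) stratum sparsity is not a concern, and the exact
matcher logs dropped cases whenever it is.

## Known limitations

* The consensus rule controls false positives well but its power depends on
  the weakest arm — typically the exact-matched analysis at small n, where
  stratum dropping shrinks the case count.
* Bonferroni-family size uses filter-surviving definitions; re-running with
  a different prevalence filter changes adjusted p-values, which is inherent
  to the "per tested agent" convention.
* IDW dichotomization at the cohort median of positives is one defensible
  cut among several; it is configurable, and planted IDW effects are only
  approximately recoverable by construction.
* The optimal matcher's global optimum is unique only up to cost ties;
  determinism is guaranteed (fixed solver, id tie-breaks in output), but a
  permuted input can select a different equal-cost optimum.
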
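# Methods

This note documents the models, the data-handling conventions, the
synthetic-study generator, and the numerical and design choices behind
`gardenhunt`.

## Survey data handling

**Detection events.** Camera-trap photos of one species at one camera are
collapsed into events with a strict 5-minute rule: an inter-photo gap
*less than* 5 minutes continues the current event; a gap of exactly 5
minutes or more starts a new one. Timestamps are naive local time (no DST
handling); minute resolution suffices for the rule. Collapsing is
order-invariant by construction (sort-then-scan per camera+species stream).

**Visits and effort.** A 180-day season splits into three 60-day sampling
periods; each period is cut into visits of `visit_days` (default 21), the
last visit truncated at the period boundary, so the default yields visit
lengths 21/21/18 per period and at most 9 visits. Truncating keeps effort —
days the camera was active divided by the visit length — at or below 1.
A camera absent or inoperative for a whole visit gets missing effort and a
missing detection entry; the likelihood simply skips such cells. Effort
enters the detection model as an ordinary logit-scale covariate, not an
offset.

**Site filters.** Sites are dropped when total active days fall below 7 or
the distance to the nearest conuco exceeds 5 km; every exclusion is logged
with its rule. Retained-site counts are data-dependent, never hard-coded.

**Covariates.** Tree cover (%, 1-km buffer), distances (m) and the hunting
flag are taken as inputs; deriving them from rasters/vector layers is out
of scope. Track density is the inverse-distance-weighted sum
`Σ_j 1/max(d_ij, 1 m)^q` over all off-camera records with smoothing power
`q = 0.25`; the 1-m floor guards against a record coinciding with a camera
(the source analysis is silent on this degenerate case). Standardization
uses the sample SD (n−1 denominator) — also a documented choice where
convention varies — ignores missing values, and errors on constant input.

**Frequency of detection.** `FD = 100·D/camera-days`, reported half-up to
2 decimals; the raw value is available via `decimals=None`.

## The Royle–Nichols model

Site abundance `N_i ~ Poisson(λ_i)` with `log λ_i = x_i·β`; per-individual
detection `r_ij` with `logit r_ij = w_ij·α`; visit-level detection
probability `p_ij = 1 − (1−r_ij)^{N_i}`. Some study descriptions state a
logit link for both covariate sets; a logit link for a Poisson mean is
non-standard and is read here as shorthand — this package uses the
canonical log link for λ and logit for r.

**Likelihood.** The site contribution marginalizes N over `0..K`.
Non-detection cells factor as `(1−r)^N`, so their logs collapse to one
per-site sum before the N loop; only detection cells (sparse in camera-trap
data) need the full `(K+1) × cell` grid. The truncation bound defaults to
`K = max(50, 3·(max site detections / 0.2))` — three times a crude
method-of-moments abundance guess — and every fit re-evaluates the
log-likelihood at 2K; a shift above 1e−4 triggers a warning
(`fit.trunc_delta` records it; tests require < 1e−6 under study
conditions).

**Fitting.** Multi-start BFGS (default 5 jittered starts, seed-controlled;
gradient tolerance 1e−8) with the exact analytic score: writing `w_N(i)`
for the posterior over N, the β-score is `X'(E[N|y] − λ)` and the α-score
accumulates `−E[N|y]·r` for non-detection cells and `r·E[N q^N/(1−q^N)]`
(`q = 1−r`) for detection cells. The coefficient covariance is the inverse
observed information, obtained by central differences of the analytic
gradient. A fit with no finite optimum or unusable curvature is flagged
non-converged and dropped from candidate sets with a log entry; an
abundance intercept drifting below −8 (log scale) flags a λ→0 boundary
(all-zero histories). Clipping of the linear predictor at `log λ ≤ 30`
guards overflow far from the optimum.

**Prediction.** `λ̂_i = exp(x_i·β̂)` with delta-method SEs; covariates more
than 5 SD outside the training range trigger an extrapolation warning.

## Multimodel inference

**Candidate sets.** Effort is always carried on the detection side — the
only enumeration rule consistent with the documented set sizes (4 detection
× 8 site combinations = 32 linear; 4 × 12 = 48 with the quadratic option).
The quadratic tree term is hierarchical (never without the linear term);
`tree_buffer²` is the square of the standardized linear term.

**Criteria.** `AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1)` with n = sites. Under
overdispersion (ĉ > 1), `QAICc = −2ℓ/ĉ + 2k′ + 2k′(k′+1)/(n−k′−1)` with
`k′ = k+1`, counting ĉ as an estimated parameter (standard practice where
the source is silent). Akaike weights are `exp(−Δ/2)`, normalized.

**Goodness of fit and ĉ.** Pearson χ² over observed site×visit cells
against the fitted marginal `p̂_ij` (Poisson-mixed over the same truncated
support as the likelihood), cells clamped to [1e−8, 1−1e−8] with a warning.
The cell-level definition is a package choice — the statistic is not
uniquely defined in the literature — and the same definition is applied to
observed and bootstrap data so ĉ = χ²_obs / mean(χ²_boot) is internally
consistent. B parametric datasets are simulated from the fitted model on
the observed design and refit starting from the original estimates (with a
looser 1e−6 gradient tolerance; the refit surface is a small perturbation
of the original). Default B = 10,000 for production; tests use B ≤ 500.
Calibration on well-specified data is verified at B = 200 over 100
replicates (rejection rate at α = 0.05 within [0.01, 0.12]).

**Averaging and importance.** Conditional averaging over models with
Δ(Q)AICc ≤ 10: weights renormalized over models containing the term,
estimate `Σw′β`, unconditional SE `Σw′√(var + (β−β̄)²)`, 95% CI widened by
√ĉ when ĉ > 1; when ĉ ≤ 1 nothing is modified and the uncertainty is
conservative. Variable importance is the sum of weights over the full
ranked set, with the informal support scale: very strong (>0.9), strong
(0.6–0.9], moderate (0.3–0.6], low (≤0.3).

**Species inclusion.** Model selection is run for species whose history has
more than `detection_threshold` (default 10) detected site-visits. The
published ">10 detections" rule is ambiguous between photo events and
site-visit detections; the site-visit reading is used because it is the
quantity the likelihood sees, and the threshold is configurable.

## Hunting-scope indexes

`Hv = (h/n)·N` per taxon, where h counts citations of the taxon as a
target, n all target citations, N respondents. Read as one term per taxon,
this gives the identity `Σ_taxa Hv = N` (verified in tests), which anchors
the interpretation of the published per-taxon values. `Pv = (p/n′)·N′`
counts first choices among respondents expressing any preference —
no-preference answers are excluded from both numerator totals and N′.
Ambiguous vernaculars map to genus-level taxa through an explicit
vernacular→taxon table; a literal repeated mention by one respondent counts
once (an interview is one species list), while two vernaculars mapping to
the same genus count separately.

## Hunting-site selection

The hunting-occurrence logistic regression keeps covariates on raw scales
(tree %, metres), matching the per-metre coefficient magnitudes such
analyses report; complete separation raises a diagnostic error. The
preference contingency tests use Pearson χ² without continuity correction —
the convention under which the published worked-example statistics (7.6729
and 9.8886, df = 6) are reproduced exactly — and warn when expected counts
fall below 5, while still reporting the test as interview studies
conventionally do. The hunted/unhunted abundance comparison is descriptive
(medians and IQRs), with no attached test.

## Synthetic-study generator

The generator encodes the study conditions the package targets, and those
defaults are fixed rather than tunable per experiment:

* 60 cameras in six blocks; 18 cameras stay all three 60-day periods, the
  rest are present for a single period; per camera-visit, 8% chance of
  total knockout and 15% of partial effort; two cameras fail within a week
  (exercising the activity filter). Season start 2015-09-21.
* Tree cover from a 50/50 normal mixture N(15, 4²)/N(75, 6²) truncated to
  [0, 100] (savanna and forest modes); conuco distance lognormal(6.865, 1)
  — mean ≈ 1.58 km — resampled above 8 km; river distance
  lognormal(6.3, 0.8); 159 track records scattered 300 m around
  forest-leaning sites; hunting flags from a raw-scale logistic process
  with coefficients of the magnitude such regressions report (intercept
  −1.475, tree 0.041/%, river 0.001/m, conuco ≈ 0).
* Four species spanning the patterns of interest: a paca-like species
  (abundant, conuco-associated: β_conuco = −0.5), an agouti-like
  forest specialist (β_tree = 1.0), a curassow-like bird (both effects),
  and a fox-like null species; detection intercepts −1.0 to −1.5 with an
  effort effect of 0.5.
* 29 interview respondents from four communities (11/8/5/5), 24 of them
  hunters; citation probabilities concentrated on paca-, deer- and
  curassow-like taxa; two deer vernaculars mapping to one genus; 20%
  of hunters give no preference.

Everything derives from one integer seed and regenerates bit-identically;
the truth serializes to JSON for recovery scoring.

**What the generator does not emulate:** spatial autocorrelation of
abundance, animal movement and home-range overlap between cameras,
imperfect species identification, seasonal (within-study) abundance trends,
and respondent recall biases. Passing tests therefore demonstrate that the
estimators recover the generating process at the study's design scale —
not that real Gran Sabana data satisfy the model's independence
assumptions.

## Problem sizes used in the test suite

Stochastic experiments run at the study's design scale (M = 54 sites,
J = 9 visits): parameter recovery uses 100 replicates (bias < 0.25,
95% Wald coverage ≥ 88% for the generating tree-cover coefficient);
goodness-of-fit calibration uses 100 replicates at B = 200; candidate-set
support separation runs a scaled-down 8-replicate version in the unit
suite. Pipeline tests use the simulated preset with B ≤ 200; production
defaults (B = 10,000) are exercised only through the configuration
surface.

## Known limitations

* The RN likelihood assumes independent site abundances and independent
  visits given N; overdispersion from violations is absorbed only
  heuristically through ĉ.
* Bootstrap refits start from the original estimates for speed; a refit
  trapped in a different basin would bias ĉ slightly (multi-start refits
  are available via `refit_starts`).
* Wald intervals are used throughout; profile intervals are not
  implemented.
* The conditional (not shrinkage) averaging convention means terms
  appearing in few models can carry optimistic SEs; the sum-of-weights
  column should be read alongside the averaged coefficient.
* Coordinates are planar metres in one projected CRS; no geodesy.
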
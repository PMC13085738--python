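# Methods

This package re-implements, as tested and reusable code, the analysis of
an in-situ habitat-manipulation experiment on a coral-reef cleaning
mutualism: net manipulations over cleaner-goby stations, four replicate
surveys per station (before, first, second, after), and a
before-after-control-impact (BACI) comparison of eight behavioural and
community response variables. Because the field data are not bundled, a
synthetic-study generator reproduces the experimental design and the
statistical structure the analysis assumes, so every stage runs end to
end with known ground truth.

## Study design and response variables

Twenty stations are allocated 10/5/5 to experimental (net),
experimental-control (cut-open net, i.e. sham) and control (untouched)
treatments, giving 80 station-replicate surveys. Each survey lasts
40-104 minutes and yields eight responses:

| variable | units | source |
|---|---|---|
| cleaning_rate | cleans/hr | clean event log |
| mean_clean_duration_s | s | clean event log |
| posing_rate | poses/hr | pose event log |
| responsiveness_cm | cm (FID) | disturbance trials |
| selectivity | dimensionless, [-1, 1] | cleans + frame censuses |
| potential_client_abundance | fish/hr | frame censuses |
| potential_richness | species | frame censuses |
| actual_richness | species | clean event log |

Potential client abundance counts *distinct tagged individuals* across
the one-frame-per-minute censuses divided by survey hours; individuals
present in many frames count once. An untagged fallback (per-frame
counts summed over hours) exists but is pseudoreplicated and labelled
non-equivalent. Surveys with no cleans carry missing duration and
selectivity values rather than imputations; models drop missing
responses complete-case.

## Electivity (selectivity) index

Cleaner preference follows the Vanderploeg-Scavia electivity family.
With r_i the share of total cleaning time spent on client species i,
p_i that species' availability share, and n the richness of cleaned
species:

    W_i = (r_i / p_i) / sum_j (r_j / p_j)
    E_i = (W_i - 1/n) / (W_i + 1/n)

so sum(W) = 1 and each E_i lies in [-1, 1], 0 meaning use proportional
to availability. Design choices that the source description leaves
open, isolated behind one function each:

* **Availability base.** p comes from distinct censused individuals per
  species at the same station-replicate, over the union of cleaned and
  censused species. Because W normalizes the r/p ratios, availability
  mass on never-cleaned species cancels; a species cleaned but never
  censused is either an error (default) or receives a configurable
  availability floor.
* **Aggregation.** The per-survey scalar is the unweighted mean of E
  over cleaned species. With few cleans this mean skews negative
  (species with small time shares sit near E = -1 while the maximum E
  at richness n is (1-1/n)/(1+1/n) < 1), so simulated station values
  are more negative than field means computed from richer data; only
  contrasts between replicates matter downstream.
* **Grain.** Species-level by default, family-level by option.
* Note E_i = 0 exactly whenever r is proportional to p, and n = 1
  forces E = 0: single-client surveys are flagged.

## Chain rugosity

Structural complexity is the chain-and-tape ratio measured on a 2-D
surface transect (x strictly increasing; overhangs rejected): a chain
of rigid 2 cm links is draped over the profile and

    R = horizontal span of the chain / (n_links x link length),

so R = 1 on a flat plane and decreases toward 0 with increasing
complexity. Draping is greedy and exact: the next node is the
farthest-forward intersection of a circle of one link radius with the
profile polyline; the chain keeps whole links, with an optional
fractional tail. Numerical details:

* Circle-segment intersection is solved in closed form; discriminants
  within ~1e-12 of zero (relative to A r^2) are snapped to the tangent
  double root, because the root of a grazing intersection is otherwise
  ill-conditioned (error ~ sqrt(machine eps), which matters at convex
  corners such as an exact ridge apex).
* R is invariant to translation. It is invariant to x-reflection only
  where chain placement is unique; over features narrower than one
  link the greedy farthest-forward rule is direction-dependent, which
  mirrors the physical ambiguity of laying a real chain over sub-link
  relief.
* As link -> 0, R converges to span / arc length (verified within 1% on
  an analytic sinusoid).

The test suite checks the greedy drape against an independent
arc-length-walk oracle (fine grid along the polyline with vertex-
aligned brackets and bisection refinement) to 1e-6 cm on 100 random
profiles, plus exact analytic cases (flat plane, 45-degree ridge =
cos 45).

## BACI differencing

For each station, variable and post-baseline replicate r:

    abs_diff       = value_r - value_before            (signed)
    rel_to_control = abs_diff - mean(control abs_diff) (same cell)

"Absolute" is the study's terminology for the baseline difference, not
a magnitude: the sign is kept. Control stations average to exactly
zero within every (variable, replicate) cell by construction, and any
additive shock common to all stations at a replicate cancels from
rel_to_control. Rows lacking a baseline value, and cells with no
control value, are dropped with a logged reason. Sham stations are
referenced against the same control means as experimental stations.

## Hierarchical models and directional inference

Each response (optionally square-root transformed: cleaning rate,
clean duration and posing rate, which are non-negative and
right-skewed; signed difference scores always stay on the identity
scale) is modelled as

    y = mu + beta_obs + u_station + v_area + eps,
    u ~ N(0, s_station^2), v ~ N(0, s_area^2), eps ~ N(0, s^2)

with the observation label (4 levels raw; 3 levels for difference
models, reference = first level) as a categorical fixed effect and two
crossed random intercepts: station identity and a surface-area group.
A continuous covariate cannot act as a grouping factor, so surface
area is binned into quantile groups (quartiles by default; a
one-level-per-unique-value mode reproduces the verbatim structure).

Priors are weakly informative and scale with the response: Normal(0,
5 sd(y)) on fixed effects and half-Student-t(3, 2.5 sd(y)) on all
three scale parameters. Sampling is a blocked Gibbs sampler — the
model is fully conjugate once each half-t scale is expanded into its
inverse-gamma scale mixture (Huang & Wand 2013, Bayesian Analysis
8:439-452) — with exact conditional draws, no tuning and no
divergences. Defaults are 4 chains x 15,000 iterations with 5,000
warmup; a reduced profile (2 x 2,000, warmup 1,000) backs the test
suite and the fast pipeline mode. Chains are seeded by spawning one
child SeedSequence per chain; identical inputs give byte-identical
draws.

Directional hypotheses are summarised from the contrast's draw vector:

* estimate = posterior mean; 95% CI at the 2.5/97.5 percentiles, 75%
  CI at 12.5/87.5 (central intervals);
* PP = fraction of draws satisfying the direction; for difference-
  score models the tested quantity is a level's cell mean against zero
  ("C>E" = treatment below control expectation);
* ER = PP/(1-PP), capped at (S-0.5)/0.5 when all S draws agree, the
  finite-sample odds of "at most half a draw" disagreeing.

Variance partitioning uses per-draw intraclass correlations,
ICC_g = s_g^2/(s_station^2 + s_area^2 + s^2), reported as posterior
means and bucketed minimal (< 0.05) / meaningful (0.05-0.20) / strong
(> 0.20). Convergence is assessed with rank-normalized split R-hat
and bulk ESS (computed by arviz); fits with any R-hat > 1.01 are
flagged, never silently dropped. Reported ESS is capped at the nominal
draw count. A Bayesian R^2 (posterior mean of var(fitted)/(var(fitted)
+ s^2)) rounds out the diagnostics table. Influential-point machinery
(PSIS-LOO) is out of scope; a config list of (station, replicate) rows
to exclude reproduces a remove-refit-readd workflow manually.

## Synthetic-study generator

The generator is first-class, tested code; its defaults are the study
conditions every calibration test runs under.

* **Event streams.** Clean and pose events are homogeneous Poisson
  processes per survey; durations are lognormal. Expected baselines
  follow typical neon-goby stations: 4.65 cleans/hr, 13.1 s mean clean
  duration, 7.34 poses/hr, 10.75 cm FID — with a mean-one lognormal
  station multiplier (SD 0.35 on the log scale) for between-station
  heterogeneity, so expected rates equal the stated baselines.
* **Clients.** A pool of 26 Caribbean reef species in 16 families with
  a lognormal abundance profile; each station draws its community from
  a Dirichlet around the pool, and event clients are multinomial.
* **Censuses.** One frame per minute; individuals arrive as a Poisson
  stream (default 40 fish/hr — a value chosen as plausible for a
  Caribbean patch-reef station, since no rate is printed anywhere),
  carry persistent tags, and stay visible for a short random run of
  frames.
* **FID.** One trial per survey: station baseline + treatment shift +
  Gaussian noise (SD 2.25 cm), truncated at zero; an optional dropout
  count marks trials unusable.
* **Effects.** The default "decline" scenario multiplies experimental
  cleaning rate, clean duration and posing by 0.6 at the two
  during-manipulation replicates with full return at after, and adds a
  persistent +3 cm FID shift — a recoverable-behaviour /
  non-recovering-boldness scenario. The "null" scenario sets all
  factors to 1. Control and sham stations are never perturbed. The
  effect profile used is retained on the dataset as ground truth.
* **Profiles.** Station transects come from midpoint displacement
  (displacement scale roughness x span, decaying 0.8 per level, 8
  levels), giving 2 cm-chain rugosity values around 0.1-0.6 across the
  station roughness range (0.4-1.0) — the band observed at real
  stations. roughness = 0 is exactly flat.

What the generator does **not** emulate: spatial movement and revisits
of individual clients, cleaner identity across surveys, diel or tidal
rhythms, observation-length effects on detectability, and any
correlation between station structure and behaviour. Passing
calibration tests therefore show the inference machinery is sound
under the assumed data-generating process, not that the field effects
themselves are reproduced.

## Problem sizes in the test suite

The suite runs the reduced sampler (2 x 2,000) throughout:
parameter recovery uses 20 ten-station studies; the null-calibration
check uses 20 full synthetic studies and the four a-priori cleaning-
rate contrasts; the end-to-end recovery-ordering check runs the full
pipeline on 10 seeded studies. These sizes keep the whole suite in a
few minutes while leaving Monte-Carlo error well inside the asserted
bounds.

## Known limitations

* The Gibbs sampler covers the Gaussian family only; count responses
  are handled via the square-root transform rather than GLMM links.
* Variance-component chains mix more slowly than fixed effects with
  only a handful of groups; the reduced profile can show R-hat
  slightly above 1.01 on scale parameters (such fits are flagged).
* The electivity aggregation (mean of per-species E) is one documented
  choice among several defensible ones; absolute station values are
  not comparable across aggregation rules.
* Rugosity is a single-transect statistic here; averaging several
  transects per station is available but no 3-D surface measure is.
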
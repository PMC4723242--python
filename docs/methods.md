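# Methods

## The measurement problem

Health-facility "integration" of HIV and reproductive-health (RH) services
is not directly observable. The package treats it as a latent construct
measured by eight facility-level attributes, four *structural* (co-located
capacity: HIV services available in the MCH/FP unit, all services
available facility-wide, HIV services per consultation room, HIV services
per clinical staff member per day) and four *functional* (integrated
receipt by clients: the 0–3 ART co-delivery score, the share of window
days on which both service classes were accessed, and the shares of
clients receiving both classes within one provider contact and within one
visit day).

Attributes are computed from two kinds of raw data: client-flow records
(one row per provider contact per client per visit day, with received
services and referrals) and facility inventory/activity registers (unit
and facility service lists, room-level and staff-level HIV provision
logs). Every attribute carries its denominator; a missing source yields
an explicit missing value, never a zero.

Attribute conventions where the field leaves room:

* ART score aggregation: arithmetic mean of the 0–3 client scores over
  all tracked clients (configurable to clients receiving ≥1 service).
* Integration denominators: all tracked clients that day (configurable
  likewise).
* Room/staff ranges: unweighted means across rooms and staff.
* Observation window: 5 days.

## Ordinal coding

The measurement model consumes ordered categories. Default scheme:
per-attribute empirical terciles computed on the *pooled* baseline+endline
table (so both waves share one coding and scores are comparable across
waves), with ties at a cutpoint assigned to the lower category. An
integer-coded 0–3 ART attribute passes through unchanged; a continuous
facility-mean ART attribute falls back to quartiles with a warning.
Quantile coding guarantees occupied categories at n = 40. The fitted
cutpoints are serialized with the indicator matrix so new data can be
coded identically.

## The latent-variable model

Facility i has factor scores eta_i ~ N(0, I_q), q = 1 or 2. In the
two-factor specification the factors are orthogonal by construction and
each indicator loads on exactly one factor (functional indicators on
factor 1, structural on factor 2). Indicator j has a continuous latent
response

    z_ij = lambda_j * eta_{i,f(j)} + e_ij,   e_ij ~ N(0, 1),

cut into the observed category by strictly increasing thresholds tau_j
(theta parameterization: residual and factor variances fixed at 1, all
loadings free). The standardized loading lambda/sqrt(lambda^2 + 1) is the
latent-response/factor correlation and is the reported quantity.

Priors: independent normals, mean 0. Loadings N(0, 9) by default. This is
deliberate: a flat (or huge-variance) prior on the raw loading induces a
prior on the standardized loading proportional to (1 - s^2)^(-3/2), which
diverges at ±1; at n = 40 that visibly biases fitted associations upward
and makes posterior predictive checks reject even the generating model.
N(0, 9) is near-flat on (-0.95, 0.95) of the standardized scale while
removing the boundary pile-up. Thresholds get N(0, 100). Both are
configurable.

## Estimation

Data-augmentation Gibbs sampling:

1. z | y, parameters — truncated-normal draws per cell (inverse-CDF);
   missing cells drawn unconstrained, which integrates them out under
   ignorable missingness.
2. eta | z, lambda — conjugate multivariate normal, shared precision
   I + Lambda'Lambda across facilities.
3. lambda | z, eta — conjugate normal per indicator.
4. A Metropolis *group-scale move* per factor: propose
   (alpha·lambda_block, eta_block/alpha) with log-normal alpha
   (step 0.15). The likelihood is invariant, so acceptance depends only
   on the prior and Jacobian ratio. This is the slow direction of the
   posterior; without the move the raw-loading scale still shows PSR
   > 1.2 after 4 × 6,000 iterations, with it PSR reaches ~1.03 by
   4 × 20,000.
5. tau | z, y — each threshold drawn from its prior truncated to the
   interval the current z's allow (uniform-conditional scheme).

Defaults mirror the production setting: 4 chains × 50,000 iterations,
first 50% discarded, thinning 1, per-chain generators spawned
deterministically from one master seed. Simulation studies in the test
suite and acceptance script use 4 × 2,000–30,000 as documented per
experiment; those sizes are a deliberate repeated-simulation choice.

Reflection invariance (flip a factor's loadings and scores jointly) is
resolved after sampling: per draw and factor, signs are flipped so the
loading sum is positive. All diagnostics and summaries operate on the
sign-resolved posterior.

## Diagnostics

*Convergence*: potential scale reduction per scalar parameter,
PSR = sqrt((W + B)/W) with W the mean within-chain variance and B the
between-chain variance of chain means. Duplicated chains give exactly
1.0; values near 1 indicate convergence. Raw loadings are the
slowest-mixing parameters; their PSR is the binding one.

*Fit*: posterior predictive check. For each sampled draw, a discrepancy
is computed for the observed table and for a fresh replicate simulated
from that draw; reported are the central 95% interval of
(f_obs − f_rep) and p = Pr(f_rep ≥ f_obs). Zero inside the interval and
a non-small p indicate good fit. The default discrepancy is the
full-information likelihood-ratio chi-square against the saturated
pattern multinomial, with the model likelihood marginalized over the
factors on a dense 241-point grid (dense because large raw loadings make
the integrand a narrow window in eta that sparse quadrature misses). A
limited-information alternative — G² summed over all univariate and
pairwise tables with bivariate-normal rectangle probabilities — is
available; measured on two-factor synthetic data it has roughly half the
signal-to-noise against one-factor misspecification (z ≈ 0.6–1.2 vs
≈ 1.7–1.8), because at 40 facilities the dependence signal spreads over
28 sparse tables. Neither statistic is identical to any one SEM
program's internal version.

## Scoring

Facility index values are Bayesian plausible values of eta: by default
the posterior mean with the posterior SD as standard error; a seeded
single-draw mode provides classical plausible-value semantics. Ranks are
descending (1 = most integrated), ties averaged. For graphing, scores
map to a 1–7 scale by adding 4 (−3 → 1, 0 → 4, 3 → 7); out-of-range
values pass through with a warning rather than clipping.

Cross-wave comparability: endline facilities are scored against the
*baseline* measurement model — loadings and thresholds frozen at their
baseline posterior means — by a Gibbs run over (z, eta) only (default
4,000 iterations, 1,000 burn-in; MC error on a score ≈ 0.05). With
frozen parameters facilities are conditionally independent, so a
facility's score does not depend on the batch. Change between waves is
summarized by the per-factor sum of absolute differences, the
between-wave Pearson correlation, and the within-wave cross-factor
correlation; degenerate-variance cases return missing with a warning.

## Synthetic studies

The generator emulates the targeted study design: 40 facilities, two
waves, two orthogonal standard-normal factors, ordinal indicators through
the probit model with standardized loadings defaulting to the fitted
baseline values (functional 0.489/0.774/0.979/0.984; structural
0.952/0.617/0.836/0.795) and equal-probability thresholds (terciles;
quartiles for the 4-category ART indicator). Wave 2 follows
eta2 = (1−kappa)·eta1 + sigma·eps with sigma keeping unit variance, so
the wave correlation is 1−kappa; defaults kappa = 0.5 (functional) and
0.1 (structural), echoing the stronger observed regression-to-the-mean in
functional scores.

A separate flow layer turns per-facility attribute targets into
client-contact records and inventories whose *computed* attributes have
the target expectations. Couplings are handled by an explicit allocator:
days are integration-active with the temporal-target probability;
conditional on an active day, clients are assigned to behaviour classes
(ART+SRH same provider, both-classes one contact, both-classes split
providers, ART alone, ART referral, plain RH) whose masses solve the
consult/visit/ART targets, with infeasible combinations (consult >
visit, integration with a zero temporal target, unreachable ART mean)
rejected. Latent-derived targets are projected to the feasible ordering
consult ≤ visit ≤ temporal and ART ≤ 3·consult before generation. The
temporal expectation is exact only when an active day almost surely sees
at least one integrated client (true at the default 20 clients/day).

What the generator does *not* emulate: client covariates and
health-seeking behaviour, day-of-week structure, provider heterogeneity,
register measurement error, and facility size variation. Passing tests
therefore demonstrate statistical correctness of the machinery under the
stated measurement model, not robustness to real-world data pathologies.

## Missing data

Attributes computed from an absent source are explicit missing values
with their denominators recorded; nothing is zero-filled. Scattered
missing indicator cells are integrated out inside the Gibbs augmentation
(drawn unconstrained each sweep), assuming ignorable missingness. An
attribute missing for *every* facility — e.g. no staff-log register was
collected — halts the end-to-end pipeline by default; with
`allow_missing=True` the indicator is dropped with a warning and the
model is fitted on the remaining ones.

## Simulation findings worth knowing

Run under the default study conditions (seeds 0–19/0–49, sampler sizes
as in `integra_index.evaluation`):

* 95% credible intervals cover the generating standardized loadings for
  ~92% of (seed × indicator) pairs.
* The posterior predictive check retains the two-factor model essentially
  always (p > 0.05 in 18/20 seeds, interval covering zero in 20/20) and
  rejects the one-factor model at p ≤ 0.05 in ~70% of seeds; the stricter
  "interval entirely above zero" verdict (equivalent to p < 0.025)
  occurs in just under half of seeds. The discrimination signal at
  n = 40 with tercile coding has z ≈ 1.7–1.8; the production data behind
  the published analysis (tens of thousands of client contacts, finer
  attribute resolution) supports sharper rejection than 40 tercile-coded
  synthetic facilities can.
* Cross-factor plausible-value correlations on orthogonally generated
  data average |r| ≈ 0.13 with occasional |r| up to ~0.47. This is not
  estimation error: with 40 facilities the *in-sample* correlation of two
  independently drawn N(0,1) factors has SD 1/√39 ≈ 0.16 (E|r| ≈ 0.128),
  and score estimation only attenuates it. Tiny cross-factor
  correlations are a large-sample property, not a per-dataset guarantee.

## Known limitations

* The sampler's raw-loading scale mixes slowly for standardized loadings
  near 1 even with the group-scale move; PSR < 1.05 needs tens of
  thousands of iterations. Monitor PSR on the standardized scale if raw
  convergence is the bottleneck.
* The PPC p-value is a posterior predictive probability, conservative in
  general; its absolute calibration depends on the prior (see the
  loading-prior note above).
* The ART attribute mixes receipt, referral, and co-delivery in one 0–3
  scale; its facility mean is a modelling convenience, and its loading is
  the least precisely recovered in simulation.
* Attribute computation assumes one visit per client per day; repeated
  same-day visits are merged.
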
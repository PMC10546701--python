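# Methods

## Model

`esmvar` estimates a bivariate two-level VAR(1) dynamic structural
equation model for intensive longitudinal data. Observations
`y_it = (arousal_it, selfesteem_it)` on 0–10 visual-analogue scales are
decomposed into a latent person mean ("trait") and a within-person
deviation ("state"):

```
y_it = mu_i + w_it,    w_it = Phi_i w_{i,t-1} + zeta_it,  zeta_it ~ N(0, Sigma_i).
```

All dynamic parameters are random across persons. The person-effect vector

```
eta_i = (mu_A, mu_S, phi_A, phi_S, phi_SonA, phi_AonS, ln sig2_A, ln sig2_S, z_AS)
```

collects the two trait means, the two AR(1) slopes, the two cross-lagged
slopes, the two log innovation variances and the Fisher-z transformed
innovation correlation, and follows `eta_i ~ N(gamma + beta x_i, Omega)`
with an optional numeric person-level predictor `x_i` and a common 9×9
covariance `Omega`. Random innovation variances let persons differ in
moment-to-moment volatility; modelling the innovation *correlation* on the
Fisher-z scale (rather than a log covariance) keeps `Sigma_i` positive
definite for every real value of the random effect, including the common
case of negatively coupled arousal/self-esteem shocks. The raw covariance
implied by each parameterisation is recorded in the simulation manifest.

Assumptions worth stating: dynamics are lag-1 and time-invariant within
the day; ratings are treated as continuous and unbounded (the model does
not censor at the 0/10 scale ends); missingness is ignorable given the
model (missing at random); the level-2 distribution is multivariate
normal with a single `Omega` shared by all groups, group differences
entering only through the mean (the raw group code 1/2/3 predicts all
nine effects linearly — deliberately preserving the linearity-in-code
assumption of the original analysis rather than "fixing" it).

## Sampler

A Gibbs sampler with missing-data augmentation:

1. **Missing states.** Missing occasions are latent. For each slot, the
   conditional of `w_t` given its neighbours is normal with precision
   `Sigma^-1 + Phi' Sigma^-1 Phi` (interior), the stationary precision
   replacing the first term at `t = 0`, or `Sigma^-1` alone at the last
   slot; partially observed slots use the univariate conditional of the
   missing coordinate. A full ascending sweep is a valid single-site
   Gibbs scan because the process is Markov of order 1.
2. **Transition block.** Given complete states, the four slopes of
   `Phi_i` have a 4-dimensional conjugate normal conditional (precision
   `Sigma^-1 ⊗ X'X` plus the conditional prior from `Omega`). With a flat
   prior and vanishing innovation variance this collapses onto the
   per-person lag-1 OLS solution — the identity used as a unit-test
   oracle.
3. **Trait means.** Conjugate bivariate normal; the design matrix per
   occasion accounts for which coordinates were observed at `t` and
   `t−1`.
4. **Innovation parameters.** `(ln sig2_A, ln sig2_S, z)` are updated by
   a joint random-walk Metropolis step on the unconstrained scale. The
   per-person proposal scale adapts multiplicatively toward ~30%
   acceptance during burn-in and is frozen afterwards, preserving
   detailed balance in the sampling phase.
5. **Fixed effects.** `gamma` (and `beta` with a covariate) have a
   conjugate normal conditional under a `N(0, 1e10)` prior.
6. **Level-2 covariance.** Inverse-Wishart conditional with identity
   prior scale and `dim + 1 = 10` prior degrees of freedom. These priors
   are weakly informative approximations of common software defaults and
   are fully configurable; with ~40 persons the identity scale mildly
   inflates very small random-slope variances, which widens (never
   narrows) fixed-effect intervals.

The likelihood conditions on the first occasion (standard conditional VAR
likelihood); a missing first occasion is augmented under the person's
stationary distribution (Lyapunov solution), with a diffuse `3 Sigma`
fallback and a logged count for nonstationary draws. Two chains of 5000
iterations with first-half burn-in are the library default; convergence
is judged by the classical Gelman–Rubin potential scale reduction,
`PSR = sqrt((W(n-1)/n + B/n)/W)`, against the 1.10 cutoff. Summaries are
posterior medians and equal-tailed 95% credible intervals; "significant"
means the interval excludes zero, with no multiplicity correction (none
is part of the analysis being implemented). Within-level explained
variance is computed per draw and person as
`R² = 1 − Sigma_jj / S_inf,jj`, where `S_inf` solves the discrete
Lyapunov equation `S = Phi S Phi' + Sigma`; for a diagonal `Phi` this
reduces to `phi²`.

Everything is vectorised across persons, so the sampler draws from one
batched random stream. Consequently refitting after permuting persons
reproduces summaries only in distribution, not bit for bit; per-person
streams would make the sampler roughly an order of magnitude slower in
pure Python, and exact order-invariance is instead guaranteed (and
tested) for the data generator, whose streams are keyed by group and
within-group index.

## Synthetic-data generator

The generator draws `eta_i` from the level-2 model, simulates each
person's series from their VAR(1) after a 50-occasion burn-in started at
the stationary distribution (sufficient for |phi| ≤ 0.7), and deletes
whole prompts according to a missingness pattern. It emulates the study
design: three diagnostic groups (BPD/DD/NCC) of 42/40/40 persons, 52
quarter-hourly prompts from 8 am to 9 pm, ~50% prompt-level non-response
with a propensity peak in the 9–10 AM hour and a mild late-evening
upweighting.

Default group means place the printed per-group posterior medians of the
original cohort where those are available (trait arousal 5.86/3.42/1.91;
trait self-esteem 3.22/5.18/8.93; BPD AR slopes 0.52/0.38; cross-lags
−0.15/−0.04 in BPD, −0.03/−0.09 in DD, −0.01/−0.03 in NCC). Quantities
not printed in running text are fixed once at realistic field values: AR
slopes of 0.43–0.47 for DD/NCC (moderate inertia, qualitatively "similar"
across groups), innovation variances of 0.7–1.6 rating-points² (higher in
the clinical groups), innovation correlations of −0.2 to −0.3, random-
effect SDs of 1.0–1.2 on traits, 0.1 on all slopes and 0.3–0.4 on the
innovation parameters.

The two self-esteem items are generated as
`worth = S + d_it + u_i` and `worthless = (10 − S) + d_it + u_i`, so the
reverse-coded occasion mean reconstructs the latent composite `S`
exactly: the analysed score *is* the VAR variable, and composite
measurement error is absorbed into the innovations — precisely the
measurement assumption of the estimator. The disagreement SDs
(`d`: 0.83 occasion-level; `u`: 0.82 person-level) are calibrated so the
item-level analysis reproduces the reported composite reliabilities
(within ≈ 0.58, between ≈ 0.92). What this construction deliberately does
*not* emulate: independent item uniquenesses that also perturb the
composite (real composites carry extra occasion noise), floor/ceiling
censoring of the 0–10 scales, circadian trends, and any
missing-not-at-random mechanism — so passing recovery tests demonstrate
correctness of the estimator under its own assumptions, not robustness to
these violations.

## Reliability

Multilevel composite reliability decomposes the two positively-keyed
items with a Bayesian two-level bivariate normal model (Gibbs: conjugate
person means, inverse-Wishart level covariances, flat prior on the grand
mean). A one-factor model on two indicators is identified only under
equal loadings, in which case the common-factor variance at each level
equals the inter-item covariance `c`, and the unit-weight composite —
the score actually analysed — has `omega = 4c / (v1 + v2 + 2c)` per
level, with the overall coefficient from the summed decompositions.
Point estimates are posterior medians with equal-tailed 95% intervals,
clipped to [0, 1]; a non-positive within-level covariance is flagged as
degenerate rather than silently clipped.

## Numerical choices

- Slot windows are contiguous half-open quarter-hour bins `[start,
  start+15')`; the schedule's "±5 min" prompt jitter affects when prompts
  fire, not the validity window. First response per window wins; later
  ones are dropped.
- Zero-variance screening for exclusions pools all observed e-diary
  values (arousal and both items) per participant.
- 30/60-minute sensitivity analyses re-grid the data (first valid fine
  slot per coarse window) rather than re-specifying the lag; under a true
  15-minute VAR(1) coarse dynamics follow `Phi^2`/`Phi^4`, so cross-lags
  attenuate.
- Dummy contrasts code the first-listed group 0, so slopes read "second
  minus first"; swapping the pair negates slopes in distribution.
- 2×2 chi-square applies the Yates correction by default (the printed
  cohort statistics match the corrected statistic); odds ratios use Wald
  log-scale intervals with Haldane–Anscombe correction only when a cell
  is empty; the r×c Fisher test enumerates all tables with the observed
  margins and uses two-sided probability ordering (verified against R's
  fisher.test); the omega-squared interval inverts the noncentral-F
  distribution via `omega² = lambda / (lambda + N)`.
- Degenerate inputs: empty grids are still emitted (all-missing);
  all-missing persons are dropped from fits with a warning; nonstationary
  person-draws are excluded from R² with a logged count; zero margins
  make the chi-square NaN with a warning.

## Problem sizes used in validation

The replicated recovery study runs at the full design scale (42+40+40
persons × 52 slots, ~50% time-of-day missingness) with two chains of
1200 iterations (500 burn-in) per fit — enough for PSR ≈ 1.1 on the
slowest level-2 variance parameters while keeping a 20-replicate study in
the minutes range; the test suite uses 7 replicates and the acceptance
script 20. Single-purpose unit fixtures use 10–30 persons and shorter
chains.

## Known limitations

- The sampler treats the first occasion as an initial condition
  (conditional likelihood); trait information in `y_0` is used only
  through the augmentation prior, a negligible loss at T = 52.
- The IW(I, 10) prior on `Omega` is mildly informative for variances
  near zero; with ~40 persons per group, random-slope variances around
  0.01 are pulled toward ~0.03–0.05, widening fixed-effect intervals.
- No missing-not-at-random modelling: compliance that depends on the
  momentary state would bias trait and dynamics estimates in real data.
- The group-code model inherits the linearity assumption of coding
  BPD/DD/NCC as 1/2/3; pairwise dummy contrasts are provided as the
  assumption-free alternative.
- AR(1) fixed effects inherit the classic short-series downward bias of
  autoregression estimates (about −0.05 at ~24 valid occasions per
  person, partially mitigated by pooling); cross-lagged effects are
  essentially unbiased in the replicated recovery studies.
- Detection-rate studies show that with ~24 valid responses per person,
  fixed cross-lags of magnitude ≈ 0.09 are detected unreliably
  (40–60%), while ≈ 0.15 effects are detected reliably at n = 42; borderline
  effect sizes near the detection threshold make "significant here,
  not there" patterns intrinsically unstable across replicates.
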
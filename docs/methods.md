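# Methods

## Model

`gradedrt` fits a joint measurement model for ordered-category item
responses and item-level response times collected in interviewer-
administered health assessments.

**Responses.** The multidimensional graded response model with simple
structure: respondent *i* has a latent trait vector θ of length H (means
0, variances 1, correlation matrix R freely estimated); item *j* measures
exactly one dimension d(j) with discrimination a_j > 0 and ordered
boundary locations b_j1 < … < b_j,K−1. Boundary response functions are
logistic in a_j(θ_d − b_jk); category probabilities are their successive
differences. The canonical parameterization uses scaling constant D = 1
(the slope-intercept convention with c_jk = −a_j b_jk); D = 1.7 is
accepted as an option where the normal-ogive-scaled convention is wanted,
and the two are exactly equivalent under rescaling of a.

**Response times.** Given θ and a latent speed τ ~ N(0, 1) independent of
θ, log RTs are normal:

    ln t_ij = λ_j + φ_j τ_i − φ_j ρ_d θ_id [+ interviewer effect] + ω_ij,
    ω_ij ~ N(0, σ²_ωj).

λ_j is the time intensity (expected log-seconds of item j), φ_j > 0 the
time discrimination (loading of speed), σ_ωj > 0 the residual SD, and ρ_d
a per-dimension cross-relation through which the RTs carry information
about the trait the item measures. Putting the cross-relation in the RT
model (rather than correlating τ with θ at a second level) leaves the
response measurement model untouched; θ then accounts for the shared
variance between responses and RTs while τ absorbs the RT-specific
variance. An alternative "dispersion" parameterization (α = 1/σ_ω,
β = λ) is provided as a conversion for the φ = 1 case.

**Interviewer effects.** Interviews are administered start-to-finish by
one interviewer, whose reading/recording speed shifts log RTs. Three
nested covariate forms are supported, dummy-coded against a reference
interviewer: Model 1 adds an item-specific γ_jp (interaction); Model 2
adds φ_j γ_p — equivalently a hierarchical model with τ_i = γ_p + ε_i,
ε_i ~ N(0, 1) fixed; Model 3 adds a constant γ_p. Model 0 has no
interviewer terms and MGRM-only ignores RTs entirely. Because Model 2
routes the effect through speed, its per-item time discriminations are a
linear transformation of Model 0's (the interviewer assignment adds the
same group-wise constant to every item's speed column), which the test
suite reproduces on synthetic data.

**Identifiability.** Trait means 0/variances 1, speed mean 0/variance 1
(for Model 2 the residual-speed variance is fixed at 1), reference
interviewer effect 0. These pin the scales of a_j, φ_j, and γ_p.

## Estimation

The marginal likelihood of one respondent integrates over (θ, τ). Given
θ, the centered log RTs form a one-factor linear Gaussian model in τ, so
τ (ε under Model 2) is integrated in closed form via the Woodbury
identity; only the H trait dimensions are integrated numerically, on a
product Gauss-Hermite grid rotated by the Cholesky factor of R
(default 11 nodes per dimension; a full numeric-τ grid is kept as a
cross-check path and agrees with the analytic path to ~1e−7).

Fitting is marginal maximum likelihood by EM:

- E-step: posterior weights over the θ grid, plus the conditional
  Gaussian mean/variance of τ at each node.
- M-step: each item's (a, b) by a small quasi-Newton maximization of
  expected category counts (log-a and log-gap parameterization keeps
  a > 0 and thresholds ordered); each item's (λ, φ, σ_ω) by closed-form
  weighted least squares on the posterior speed moments (φ clamped
  positive); ρ_d in closed form; γ in closed form (for Model 2 as the
  interviewer-group mean of posterior E[τ], the M-step of the
  hierarchical formulation); R as the correlation of the mean posterior
  second moment of θ.

Convergence is declared on the relative change of −2LL (default 1e−5,
max 500 iterations; the convergence flag is returned, not raised). A
direct quasi-Newton maximizer over a packed unconstrained vector
(log/tanh/partial-correlation transforms) is available as
`engine="direct"` for small problems; on 1-D toys it matches EM to
< 0.01 in −2LL. EM is the default because the closed-form M-steps scale
to the several-hundred-parameter designs this package targets, where a
numeric-gradient quasi-Newton pass does not.

Standard errors use the outer product of per-person score vectors
(scores by central finite differences of each person's marginal
log-likelihood), i.e. the BHHH estimate of the observed information;
parameters fixed by constraint or freezing are excluded. Model
comparison: AIC = −2LL + 2k, BIC = −2LL + k ln(n) with n the number of
cleaned respondents, and likelihood-ratio (deviance) tests for the
nested variant pairs with df equal to the difference in free-parameter
counts. Free parameters per item are 1 + (K−1), plus (λ, φ, σ_ω) for
RT-bearing variants; plus H(H−1)/2 correlations, H cross-relations (RT
variants), and J(P−1) / (P−1) / (P−1) interviewer terms for Models
1/2/3.

## Calibration across batches

Large banks are fielded in batches sharing anchor ("linking") items.
Concurrent calibration stacks all batches into one long table; each
respondent simply has no rows for other batches' items, which the
likelihood treats as missing by design, and anchors get a single
parameter set. A configurable warning fires when anchors are less than
20% of a batch (the conventional floor for stable linking). Fixed-
parameter calibration freezes previously estimated anchor values
(a, b, λ, φ; the anchors' residual variances and all population
parameters are re-estimated), so new items land on the old scale with no
post-hoc transformation; frozen values are bit-identical in the output.
When an anchor was observed with fewer categories in the new batch
(sparse bottom categories collapsed upward), only the corresponding
upper thresholds and the discrimination are imposed — legitimate because
the graded model is a difference model, so collapsing changes only the
boundaries that vanish. Interviewer rosters may differ by stage with a
stage-specific reference, so γ estimates are not comparable across
stages. Both one-stage and two-stage (concurrent then fixed-parameter)
paths are supported.

## Preprocessing

Mirrors field practice for interviewer-read instruments:

1. **Respondent exclusion**: drop persons with at least a configured
   number of missing responses (threshold inclusive, configurable per
   batch), counted against their own batch's item set.
2. **RT trimming**: per batch, on the pooled pre-trim distribution,
   remove RTs below a floor (default 3 s, values exactly at the floor
   retained — sub-3 s times for a read-aloud item are recording
   artifacts) and above an upper percentile (default 97.5, linear-
   interpolation convention). Trimmed RTs become missing; the response
   is always kept. Both cutpoints come from the same pre-trim
   distribution, so the two rules commute; the report records the
   cutpoints, and re-running with recorded cutpoints is exactly the
   identity (percentile trimming is not idempotent without them).
3. **Log-normality diagnostics** per item: one-sample Kolmogorov-Smirnov
   against a normal with the item's sample moments (plain K-S, no
   small-sample correction) and Shapiro-Wilk.
4. **Category collapsing**: a category with at most one response merges
   into the next higher category (iteratively, with updated counts); a
   sparse top category merges downward — the one direction choice the
   rule leaves open, taken to preserve ordinality with minimal
   distortion. Codes are recoded contiguously from 1; items left with
   fewer than two populated categories are flagged unusable. Collapsed
   parameters are remapped by dropping the thresholds whose boundaries
   vanished; discrimination and surviving thresholds are unchanged.

## Synthetic data

The generator emulates the batched field design: a common bank split
into per-batch unique items plus anchors shared by every batch (default
shape 109/96/96/95 items over 4 batches, 24 anchors, 8 per domain),
disjoint person samples per batch, interviewers in contiguous blocks,
and a distinct partially overlapping roster for the first batch. Default
magnitudes are the study-scale ones: trait correlations
(0.62, 0.47, 0.85), cross-relations ≈ 0.42–0.46, interviewer effects of
order ±1 on the speed scale, and time parameters sized so raw RTs have
mean ≈ 8 s and SD ≈ 4 s (log-SD ≈ 0.5). Contamination mixes fast taps
(uniform 0.5–3 s) and interruption-length times (the generated RT times
uniform 10–50), half and half, at a default 4% rate; responses go
missing completely at random at 2%.

What the generator does **not** emulate: non-lognormal RT shapes,
speededness or within-person strategy shifts, item-position and fatigue
effects, informative missingness, and interviewer effects beyond the
additive forms modeled. Passing recovery tests therefore show
correctness of the estimator under the model's own assumptions, not
robustness to their violation. Clean (uncontaminated) RTs are drawn from
the untruncated lognormal, so a small model-tail fraction (~2–6% at the
defaults) falls below the 3 s floor; the trimming tests account for
this.

## Numerical choices and scaled-down test sizes

Quadrature default 11 nodes/dimension; 7 nodes show a small downward
bias in discriminations at large N, so tests asserting discrimination
accuracy use ≥ 9. Probabilities are floored at 1e−12 inside logs; σ_ω is
floored at 0.01; ρ is clamped to (−0.98, 0.98); the R update is
projected to the nearest positive-definite correlation matrix when
needed. Starting values: a = 1 with thresholds from inverse-logit
cumulative proportions, λ from item mean log RT, φ = σ_ω = 1, ρ = 0, R
from domain sum-score correlations. Ties in collapse maps and item
ordering are resolved by sorted item id; person order is sorted id.

The test suite runs fitting problems at reduced sizes chosen to keep the
whole suite in the minutes range while leaving sampling error small
relative to the asserted tolerances: recovery at N = 500, J = 24, H = 3,
P = 4 (9 nodes/dim); mechanism and invariance checks at N = 120–400 with
H = 1. Each recovery test states its generating values via its
`SimulationConfig`, so the asserted truth is explicit in the test.

## Known limitations

- Complex (cross-loading) trait structure is out of scope; each item
  loads on one dimension.
- Alternative RT residual families (skewed distributions) are not
  implemented; the lognormal is the working model.
- The EM correlation-matrix update renormalizes the posterior second
  moment to a correlation matrix; this is the standard constrained
  update but is not guaranteed strictly monotone in the likelihood
  (monitored by the −2LL path; in practice monotone to tolerance).
- OPG standard errors are first-order equivalents of the observed
  information; they can differ from Hessian-based SEs at small N under
  misspecification.
- Scoring reports posterior SDs as standard errors (EAP convention).
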
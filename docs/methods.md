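# Methods

## Model

`metacfa` implements a one-stage random-effects meta-analysis of study
summary moments constrained to a confirmatory factor model with a mean
structure. Study `i` reports `S_i` (p×p sample covariance), `ȳ_i`
(p-vector of means), `n_i`, and moderator values `x_i`. Its effect-size
vector `y_i = [vech(S_i); ȳ_i]` (the vech ordering is column-major over
the lower triangle, asserted throughout) is modeled as

    y_i ~ N( m(θ, x_i), T² + V_i ),
    m(θ, x) = [ vech(Λ(x) Φ(x) Λ(x)' + Ψ(x)) ; τ(x) + Λ(x) κ(x) ],

where every moderated parameter is `β₀ + Σ_m β₁m x_m`. The model assumes
(i) multivariate normality within studies, (ii) comparable items and
response scales across studies (raw-score comparability; Likert-type items
treated as continuous), (iii) normally distributed between-study random
effects, independent across covariance elements.

### Within-study sampling covariance V_i

Under normality with the unbiased covariance estimator (divisor n−1):

    Cov(s_ab, s_cd) = (Σ_ac Σ_bd + Σ_ad Σ_bc) / (n−1)
    Cov(ȳ)          = Σ / n
    Cov(s, ȳ)       = 0   (odd central moments vanish)

V_i is treated as known. **Plug-in choice:** by default Σ is replaced by
the (n−1)-weighted *pooled* sample covariance across studies
(`v_source="pooled"`), not the study's own `S_i`. Plugging in the study's
own S makes the GLS weight of a study correlate with its own sampling
error: studies with randomly large covariances receive randomly large
sampling variances and hence less weight, attenuating pooled covariances —
and therefore loadings — by O(1/n) (about 6% at n=100 for the simulation
population, which propagates into a ~+.05 bias of the latent mean
difference). The pooled plug-in keeps weights and observations
independent and removes this bias; `v_source="study"` remains available
for comparison. Studies with singular observed covariance matrices are
flagged and excluded, never pseudo-inverted; missing variables are handled
by per-study selection of the rows/columns of `y_i` and `V_i` (no
imputation).

### Between-study heterogeneity T²

* covariance-effect block: diagonal — one variance per covariance element,
  log-parameterized (between-study covariances among covariance elements
  are rarely estimable and are fixed at 0);
* mean-effect block: unstructured p×p, parameterized by its Cholesky
  factor with log diagonal (PSD by construction);
* cross block: 0 by default; `free_cross=True` frees it using a
  Schur-complement parameterization that keeps the joint matrix PSD.

T² is not moderated: heterogeneity is assumed equal across moderator
values.

## Invariance models and degrees of freedom

Identification default: factor variances fixed at 1 and factor means at 0
in the reference configuration (fixed-marker specs are also accepted).
From a reference spec, the ladder is generated as: configural — every free
CFA parameter gets a slope on the group dummy; weak — loading slopes
removed, factor-variance slopes added with baseline fixed at 1; strong —
intercept slopes also removed, factor-mean slopes added with baseline fixed
at 0, so each factor-mean slope estimates the between-group latent mean
difference. Partial invariance exempts named loadings (weak) or loadings/
intercepts (strong). Single-indicator factors are specified by fixing the
indicator's residual variance to 0.

Residual df are counted against the moderated saturated model:
`df = n_groups·(p(p+1)/2 + p) − (#free mean-structure parameters)`;
heterogeneity parameters are shared with the baseline and excluded. For
the one-factor five-indicator two-group design this yields 10 (configural),
14 (weak), 18 (strong).

The partial-invariance search (used in applied ladders) frees one loading
(or intercept) at a time and keeps the model with the best χ²-difference
against the configural (respectively partial-weak) model, ties broken by
lower AIC.

## Estimation

Marginal ML over (θ, η), η the unconstrained T² parameters. The −2LL is
*profiled*: for fixed η the mean structure solves a GLS problem — the inner
objective is `Σ_g m_g'A_g m_g − 2 b_g'm_g` with per-group aggregates
`A_g = Σ Ω_i⁻¹`, `b_g = Σ Ω_i⁻¹ y_i`, `Ω_i = T² + V_i` — minimized by
damped Gauss–Newton with an Armijo line search (closed form for the
saturated model, which is linear in its parameters). The outer
optimization over η uses L-BFGS-B with the analytic envelope gradient
`∂(−2LL)/∂η_a = tr(D_a (ΣΩ_i⁻¹ − Σ u_i u_i'))`, `u_i = Ω_i⁻¹ r̂_i`,
`D_a = ∂T²/∂η_a`. Jacobians of the moment map use complex-step
differentiation (exact to machine precision for these polynomial maps).

Numerical choices:

* outer tolerances `ftol=1e-11` (relative function change), `gtol=1e-7`,
  bounds log τ² ∈ [−30, 8]; the simulation harness relaxes to
  `ftol=1e-9`, `gtol=1e-5`, which leaves −2LL differences accurate far
  below the 0.01 scale that matters for the χ² tests;
* starting values are data-driven: intercepts at pooled means, residual
  variances at half the pooled variances, loadings at the spec default
  (.5); heterogeneity at method-of-moments values (between-study variance
  of `y` minus the average V_i, floored and PSD-projected) — these start
  close enough that the ladder converges in tens of outer iterations, and
  fits are warm-started along the ladder (η from the previous model, θ by
  parameter-name matching);
* non-convergence triggers one jittered restart and is always *reported*
  (flag, optimizer message), never masked; an optimum pinned at a variance
  bound is accepted when the projected gradient vanishes, with the
  boundary parameters listed;
* the loading-sign indeterminacy is resolved per factor (sum of baseline
  loadings made positive — an exact likelihood-invariant reflection);
* negative moderated variances at extreme moderator values surface as
  non-PD covariance penalties/diagnostics, never silent clipping;
* standard errors come from the inverse observed information (numerical
  Hessian of −2LL via central differences of the analytic joint gradient);
  heterogeneity parameters at the τ²=0 boundary carry no curvature and are
  excluded, making the remaining SEs conditional on the boundary. Wald
  z-tests use these SEs.

Model comparison: χ² = −2LL(model) − −2LL(saturated baseline with matching
moderation status); `RMSEA = sqrt(max(χ²−df,0)/(df·(N−1)))` with N the
summed within-study sample size (other conventions exist in this
literature; the convention is flagged in every report; RMSEA is undefined
at df=0 and reported as such). `AIC = −2LL + 2r`, `BIC = −2LL + r log N`
with r counting *all* free parameters including heterogeneity — levels are
convention-dependent but differences between models on the same data are
not. `SMD = Δκ / sqrt((φ_ref + φ_other)/2)` (unweighted pooling of the two
group factor variances).

REML, robust/sandwich SEs and Bayesian estimation are out of scope.

## Synthetic-data generator

The generator emulates a two-group one-factor population on five
indicators: loadings .70, residual variances .51, intercepts .50, factor
mean 0 (group 1) / .50 (group 2); under the "weak" (non-invariant) regime
the first indicator's intercept is 1.00 instead of .50 in group 2.
Between-study heterogeneity: independent N(0, .01) perturbations of each
covariance element (rejection-resampled until the study population
covariance is PD, cap 1000 — the truncation changes the marginal variances
only negligibly) and a joint N(0, Σ_m) perturbation of the five means with
Σ_m = .20 on the diagonal and .10 off it (PD). Each study then samples
`n_within` observations from N(μ_i, Σ_i) and reports `S_i` (divisor n−1),
`ȳ_i`, `n_i` and its group dummy. Randomness follows a per-replication
substream protocol: `SeedSequence([condition_seed, rep])`, so any single
replication is reproducible in isolation.

`n_within` is a design knob with default 100. With the pooled-V plug-in,
estimation bias is insensitive to it; χ²/power comparisons are not, so
rejection-rate results are conditional on this choice. The condition grid
is {strong, weak} truth × {15, 20, 24} studies per group; the default
replication count in the acceptance runs is 200 (a desk-scale reduction;
larger runs are one flag away).

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: non-normal or ordinal item distributions,
missing variables, unequal study sizes, moderated heterogeneity,
correlated random effects between covariances and means, and model error
in the CFA structure itself.

Per replication the harness fits the moderated saturated, configural (10
df), weak (14 df) and strong (18 df) models and records the strong model's
factor-mean-difference estimate, the overall χ² versus the saturated
baseline, both Δχ² tests at α=.05, AIC/BIC winners, and convergence.
Under violated invariance the expected inflation of the latent mean
difference has a closed-form check: the GLS projection of the intercept
shift onto the loadings, `λ'Wδ / (λ'Wλ)` ≈ .7·.5/(5·.49) ≈ .143 — with a
constant loading vector any equicorrelated weighting cancels, which is why
identity weights suffice.

## Known limitations

* The within-study likelihood treats `[vech(S); ȳ]` as normal with known
  V — a large-n approximation to the exact Wishart/normal likelihood; at
  very small n_i the χ² calibration degrades.
* Heterogeneity variances estimated by ML (not REML) are biased downward
  at small k; with constant loading vectors this largely cancels out of
  the latent mean difference, but it does affect the reported τ².
* The saturated baseline for a continuous moderator is linear in that
  moderator (one slope per moment), which is the matching baseline for the
  linear moderation model, not a fully nonparametric one.
* Multigroup-by-separate-datasets analysis, two-level SEM, longitudinal
  extensions, moderation of T², and ordinal measurement models are out of
  scope.
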
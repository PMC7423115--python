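# Methods

## Model

`expotraj` fits a latent class mixed model (LCMM) to per-subject annual
exposure-intensity series indexed by years before the index date, then
relates the identified trajectory classes to a binary outcome by weighted
logistic regression.

**Membership sub-model.** Class membership is multinomial logistic with
class-specific intercepts only: π_g = exp(ξ_g) / Σ_l exp(ξ_l), with the
last class as reference (ξ_G = 0). No covariates enter the membership
sub-model.

**Trajectory sub-model.** Within class g, the link-transformed intensity
follows a linear mixed model H(Y_ij) = X(t_ij)'β_g + u_i + ε_ij with a
single random intercept u_i ~ N(0, σ_g²) whose variance is class-specific,
and ε_ij ~ N(0, σ_ε²). X(t) contains an intercept and a natural cubic
spline basis of time before index. Because the only random effect is an
intercept, the marginal covariance of a subject's transformed series is
compound-symmetric, σ_g² 11' + σ_ε² I, and the class-conditional density
is evaluated in closed form (Sherman–Morrison determinant and quadratic
form); no numerical integration is needed anywhere in the likelihood.

**Link function.** H(y) = η₀ + Σ_k w_k² I_k(y), with I-splines built as
running integrals of an M-spline basis (scipy B-splines plus exact
antiderivatives). Order 3 is used: quadratic, continuously differentiable
pieces, the lowest order giving a smooth H with an analytic derivative
H'(y) = Σ_k w_k² M_k(y). Monotonicity comes from squaring the unconstrained
coefficients, so estimation is plain unconstrained ML; H is invariant to
the sign of any w_k. The three printed knots per exposure are interpreted
as boundary–interior–boundary; intensities above the upper knot are
clamped with a warning. The observed-data likelihood multiplies each
subject's class mixture density by the Jacobian Π_j H'(y_ij) once,
independent of class; a unit test verifies that monotone recoding of the
outcome with a correspondingly composed link shifts the log-likelihood by
exactly the recoding Jacobian.

**Identifiability.** One location and one scale are redundant between the
link and the latent process. Both are fixed in the measurement part:
η₀ = 0 and σ_ε = 1. All class parameters (intercepts, spline coefficients,
σ_g) then remain free.

## Estimation

The log-likelihood and its analytic gradient (mixture-weighted score for
ξ, β, σ, and link coefficients, including the Jacobian term) are
vectorised over all observations; optimisation is BFGS. A single
quasi-Newton method with the exact gradient proved both fast and robust
here, so the damped-Newton/fallback split common in this model family was
not needed; the three convergence criteria usual for these models are
still enforced on the final optimisation step: max |Δparam| < 1e-4,
|Δloglik| < 1e-8, and the scaled gradient criterion g'H⁻¹g < 1e-4 (all
configurable via `FitControl`).

**Multi-start grid.** The one-class model is fitted first from a
deterministic start (link scaled to unit latent SD, OLS trajectory
coefficients). For G > 1, the start list contains (a) one deterministic
quantile-split start — class intercepts offset to the quantiles of the
subject-mean residuals, within-class SD at half the one-class estimate —
and (b) `n_starts` (default 50) randomly perturbed starts around the
one-class solution with membership intercepts ~ N(0,1). Pure jitter
starts inherit the one-class fit's inflated between-subject variance and
can collapse all subjects into one class; the quantile-split start is the
standard k-means-style remedy. Each start runs 15 BFGS iterations; the
best is refined to full convergence. Solutions where any class holds
fewer than 5 subjects modally are rejected as degenerate, and the next
candidate is refined instead. Everything is deterministic given the seed.

**Design-matrix conditioning.** The natural-spline columns are divided by
their per-column standard deviation before fitting; the divisors are part
of the stored parameters and reapplied at prediction time.

**Selection.** `select` fits G = 1…G_max, each G seeding one extra start
by splitting the largest class of the previous fit (keeping the maximised
log-likelihood non-decreasing in G), and tabulates log-likelihood, AIC,
BIC (= −2ℓ + k ln N with N the number of subjects), relative entropy
E = 1 − Σ_i,g (−p̂_ig ln p̂_ig)/(N ln G), class sizes and the posterior
classification table. The BIC-minimising G is flagged but no winner is
declared automatically: substantive relevance of the trajectory shapes is
part of selection and cannot be automated. Entropy values within 1e-12 of
0 or 1 are snapped to the exact endpoint. Natural-scale mean trajectories
are E[H⁻¹(X'β_g + u + ε)] by 30-node Gauss–Hermite quadrature (node count
configurable; 30 vs 60 nodes differ by < 1e-4 in the tests).

## Stage 2: weighted association

Each LCMM-classified subject contributes one record per class with weight
p̂_ig; a-priori-classified subjects (the very-low-cumulative-exposure
class, cumulative index < 0.26 f/mL-years with a strict inequality —
values exactly at the cutoff are modelled) and never-exposed reference
subjects contribute a single unit-weight record. The weighted Bernoulli
likelihood is maximised with statsmodels GLM (Binomial, frequency
weights). Because weighting duplicates subjects, the reported CIs use a
cluster-robust sandwich grouped by subject, computed in closed form in the
package (the statsmodels cluster path is flagged as unsupported with
frequency weights); naive information-based CIs are emitted alongside.
The separation guard (|coef| > 15 → error) applies to the unit-scale class
dummies only, since fractional-polynomial columns can legitimately carry
large coefficients because of their scale. Constant covariate columns are
dropped before fitting (they duplicate the intercept and leave IRLS on a
singular design slightly off the optimum).

**Confounders.** Age, CIE and CSI enter as fractional polynomials with
powers from {−2, −1, −0.5, 0, 0.5, 1, 2, 3}; power 0 is the natural log
and repeated powers (p, p) expand to x^p and x^p ln x. Shift and scale
default to an automatic rule — shift by the smallest observed increment
when values are non-positive, scale by the power of 10 of the range — so
ln(CIE) becomes ln(CIE + shift) for zero-heavy doses. Region strata enter
as unpenalised dummies. Three mutual-adjustment strategies are compared by
AIC: none, the other exposure's cumulative dose, or the other exposure's
trajectory class; the latter uses a product-weight cross-classification
(p̂_ig · p̂_ih, treating the two classifications as independent given the
data) by default, with modal assignment as an option.

**Comprehensive smoking index.** CSI = (1 − 0.5^(d*/τ)) · 0.5^(t*/τ) ·
ln(intensity + 1), with lag-adjusted duration d* = max(0, duration −
max(0, δ − tsc)) and cessation time t* = max(0, tsc − δ). Half-life τ and
lag δ are required configuration with no defaults: they are
study-specific estimated quantities.

## Exposure metrics

Annual exposure levels from job histories are intensity × probability ×
frequency per JEM cell; concurrent jobs in a calendar year are averaged.
Concurrent directly-reported (smoking) episodes are summed instead — an
average daily total; the asymmetry mirrors how the two kinds of history
are reported. An episode active during any part of a calendar year
contributes that year at full intensity (the time unit is the year).
Interruption years inside the exposure window are carried as explicit
zeros. Time before index is integer-valued, 0 at the index year.

## Synthetic data

The generator draws class ~ Multinomial(π), a class-specific exposure
window (first-exposure time and cessation gap, both Gaussian and rounded),
a random intercept, latent values Λ(t) = X(t)'β_g + u_i + ε, and observes
Y = H⁻¹(Λ) — right-skewed through the convex inverse link, with zeros
arising structurally from the cessation gap and from clamping at the
lower link knot, not from an ad hoc mixture. An optional never-exposed
fraction (no series, class log-odds 0) provides the stage-2 reference
group. Outcomes are Bernoulli(expit(α + θ_g + γ·(age−60)/10)). True
labels are returned for recovery scoring (Hungarian matching of modal
labels).

Presets: `two_class_preset` (flat plateaus 6/24 cig-day, proportions
0.6/0.4, ~6 latent-SD separation) and `three_class_preset` (4/14/30) are
the deliberately well-separated conditions for the recovery and selection
suites; `icarelike_preset` provides 4-class smoking-like (plateaus near
8/15/25/22 cig-day with constant/recent/long-term/distant timing) and
5-class asbestos-like shape templates, the latter including an a-priori
low-cumulative class, for demos and qualitative checks. What the
generator does **not** emulate: reporting and recall error, JEM
misclassification, calendar-period exposure trends, matching between cases
and controls, and informative cessation (quitting because of illness).
Passing recovery tests therefore demonstrate correctness of the estimator
under the stated model, not robustness to those real-data features.

## Problem sizes and numerical choices

The replicated studies in the test-suite and acceptance script use 20
replicates at n = 400 (two-class recovery), 20 replicates at n = 600 with
a G = 1…4 ladder (BIC selection), and 50 replicates at n = 2000
(sandwich-CI coverage, pooled over the class coefficients to keep the
Monte-Carlo error of the coverage estimate small; a 120-replicate check
confirmed per-class coverage of 95–97%). Fits in the replicated studies
use 6–8 multi-start runs, sufficient for the well-separated presets; the
default for data analysis remains 50. The link inverse is a 100-step
monotone bisection (~1e-28 interval width on these ranges); latent values
outside [H(min), H(max)] clamp to the boundary intensities.

## Known limitations

- Very high proportions of zeros make the transformed-likelihood LCMM
  fragile (the motivation for the a-priori low-exposure class); the
  package provides the partition but no zero-inflated likelihood.
- Random intercept only: no random slopes, autoregressive errors, or
  covariates in the membership sub-model.
- The weighted two-stage association inherits attenuation when posteriors
  are far from crisp; with entropy near 1 the bias is negligible, and the
  classification tables should be inspected before interpreting ORs.
- BIC selection is reported for the computable criteria only; trajectory
  relevance is a substantive judgement.
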
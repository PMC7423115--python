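# expotraj

Latent-class trajectory analysis of lifetime exposure histories and their
association with disease risk, for case-control studies in occupational and
environmental epidemiology.

## The problem

Protracted exposures — smoking, occupational asbestos — vary in intensity
over decades. Summarising a lifetime history by a single cumulative dose
discards *when* the exposure happened; pre-specified time-window analyses
impose the windows in advance. `expotraj` implements a two-stage
alternative:

1. **Identify profiles of lifetime intensity trajectories** with a latent
   class mixed model (LCMM) on annual exposure intensities, on a backward
   time axis (years before the index date: diagnosis for cases, interview
   for controls).
2. **Estimate the disease association of each profile** by
   posterior-probability-weighted logistic regression against a
   never-exposed reference class, so classification uncertainty propagates
   into the odds ratios.

## The model

The population is a mixture of G latent classes. Class membership follows a
multinomial logistic sub-model with class-specific intercepts ξ_g
(π_g = softmax(ξ)). Within class g, the transformed annual intensity of
subject i at time t_ij follows a linear mixed model

```
H(Y_ij) = X(t_ij)' β_g + u_i + ε_ij ,   u_i ~ N(0, σ_g²),  ε_ij ~ N(0, 1)
```

where X(t) is an intercept plus natural cubic splines of time before index
(inner knots at 12/24/36 years by default) and H is a monotone I-spline
link — H(y) = Σ_k w_k² I_k(y) — that normalises the right-skewed,
zero-heavy intensity distributions (default knots 0/20/100 cig/day for
smoking, 0/0.05/12.6 equivalent f/mL for asbestos). The observed-data
likelihood includes the Jacobian Π_j H'(y_ij) and is maximised over a
multi-start grid (50 starts by default). Models with G = 1…6 are compared
by BIC/AIC, relative entropy, and the posterior classification table.

Stage 2 expands each LCMM-classified subject into one record per class,
weighted by the posterior membership probability p̂_ig; never-exposed
subjects form the reference with weight 1, and an a-priori
very-low-cumulative-exposure class (cumulative index < 0.26 f/mL-years,
the 0.01 f/mL regulatory limit × 26 years of exposure) can bypass the LCMM
entirely. The weighted Bernoulli likelihood is maximised with
fractional-polynomial adjustment for age and for the other exposure's
cumulative dose (CIE or comprehensive smoking index), and cluster-robust
sandwich CIs account for the record duplication.

Exposure metrics are built in: job-exposure-matrix valuation (annual level
= intensity × probability × frequency, averaged over concurrent jobs),
cumulative indices (f/mL-years, cigarette-years), and the comprehensive
smoking index with half-life and lag parameters.

## Worked example

```python
import numpy as np, pandas as pd
from expotraj import (two_class_preset, generate, LCMMSpec, fit, entropy,
                      expand_weighted, weighted_logistic)

truth = two_class_preset()                      # plateaus at 6 / 24 cig-day
subjects, series, _ = generate(truth, 400, seed=42)
spec = LCMMSpec(n_classes=2, link_knots=(0.0, 10.0, 40.0),
                time_basis=truth.time_basis, n_starts=8, seed=1)
result = fit(series, spec)
print(f"log-likelihood {result.loglik:.1f}  BIC {result.bic:.1f}  "
      f"entropy {entropy(result.posterior):.3f}")
print("class proportions:", np.round(result.params.class_probs, 3))

post = pd.DataFrame({"subject_id": result.subject_ids,
                     "p_1": result.posterior[:, 0],
                     "p_2": result.posterior[:, 1]})
never = sorted(set(subjects.subject_id) - set(post.subject_id))
records = expand_weighted(subjects, post, reference_ids=never)
records["age_c"] = (records["age_index"] - 60) / 10
assoc = weighted_logistic(records, ["class_1", "class_2"], ["age_c"])
print(assoc.table.loc[["class_1", "class_2"],
                      ["odds_ratio", "or_ci_low", "or_ci_high"]].round(2))
```

prints

```
log-likelihood -25493.8  BIC 51077.6  entropy 1.000
class proportions: [0.588 0.412]
         odds_ratio  or_ci_low  or_ci_high
class_1        1.24       0.74        2.08
class_2        4.64       2.64        8.17
```

The two trajectory classes are recovered essentially perfectly (entropy
1.0, proportions near the generating 0.6/0.4), and the high-intensity
class carries a clearly elevated odds of disease relative to never-exposed
subjects — the generating log-odds were 0.5 and 1.5 (odds ratios 1.6 and
4.5), both covered by the sandwich CIs.

The same pipeline is available from the shell:

```
expotraj simulate --preset two-class --n 400 --seed 42 --out-dir run/
expotraj fit --series run/series.csv --classes 2 --link-knots 0,10,40 \
             --seed 1 --out-dir run/
expotraj select --series run/series.csv --gmax 6 --out-dir run/
expotraj associate --subjects run/subjects.csv \
                   --posterior run/posterior.csv --out-dir run/
```

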
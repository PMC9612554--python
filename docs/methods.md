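# Methods

## Models and estimating functions

The package fits sparse logistic or probit regression for a binary response
by driving an estimating function toward its root with thresholded boosting.
The naive estimating functions are the negative average scores of the
Bernoulli log-likelihood,

    g_LR(β) = −(1/n) Σ_i X_i {Y_i − expit(X_i'β)}
    g_PM(β) = −(1/n) Σ_i X_i φ(X_i'β) {Y_i/Φ(X_i'β) + (Y_i−1)/(1−Φ(X_i'β))},

both exactly linear in Y, which is what allows a real-valued corrected
response to be substituted without touching the code path.

## Measurement-error corrections

**Response.**  Given per-observation misclassification probabilities
(π_i10, π_i01) with invertible misclassification matrix
(1 − π_i10 − π_i01 ≠ 0; enforced with tolerance 1e−12 and reported with the
offending row), the corrected response Y** = (Y* − π10)/(1 − π10 − π01) has
E(Y** | Y, X) = Y.  Y** is not a probability: with error rates around 0.73
(the sign-reversing regime) it takes the values ≈ −0.58 and ≈ +1.58.

**Predictors, logistic path.**  The sufficient-statistic substitution
X_ss = X* + Y** Σ_ε β is applied inside the estimating function and
re-evaluated at the current iterate at every boosting step (the substitution
depends on β; the β-symmetric form of the corrected estimating function
forces this reading).  The implementation never materialises X_ss: with r
the residual vector, X_ss'r = X*'r + (Σ_ε β)(Y**·r), so a fit costs two
O(np) products per iteration.

**Predictors, probit path.**  Regression calibration replaces X* by the
moment estimate of E(X | X*), the affine map
x ↦ μ̂ + (Σ̂ − Σ_ε)' Σ̂⁻¹ (x − μ̂) with μ̂, Σ̂ the sample mean and covariance
(n−1 denominator) of X*.  The map is β-free and fitted once per fit.  When
Σ_ε is diagonal — the only case the study design exercises — the map is
applied coordinatewise using per-column sample variances, which is the same
formula restricted to diagonal matrices and avoids inverting a singular
p×p covariance when p > n.  A full-matrix map is available and raises on a
singular Σ̂ (condition number above 1e12).

**Correction settings.**  The (correct_Y, correct_X) flags give four
settings: (0,0) fully naive, (1,0) response-corrected, (0,1)
predictor-corrected, (1,1) fully corrected.  In setting (0,1) the surrogate
Y* serves as the multiplier inside the sufficient statistic, since no
corrected response exists in that configuration.

## Boosting

From β⁽⁰⁾ = 0, iteration t computes Δ = g(β⁽ᵗ⁻¹⁾), the active set
J = {j : |Δ_j| ≥ τ max|Δ|} (ties included; empty only when Δ = 0, which
terminates the loop), and updates β_j ← β_j − η Δ_j for j ∈ J.  Because the
estimating functions carry a leading minus, subtracting them is the
likelihood-ascent direction; at τ = 0 the iteration is verified in the test
suite to coincide, step for step, with an independently coded gradient loop,
and to converge to the statsmodels maximum-likelihood estimate on clean
low-dimensional data (max coordinate difference < 1e−6 at n = 2000, p = 5).

Tunables, with defaults:

| parameter | meaning | default | notes |
|---|---|---|---|
| T (`n_iter`) | iteration budget | 1000 | with small η, T·η bounds total coefficient movement |
| τ (`tau`) | relative threshold in [0,1] | 0.9 | 0 = dense gradient method; near 1 = sparse selection |
| η (`eta`) | learning rate | 0.01 | small values approximate an L1 path |
| ξ (`xi`) | early-stop tolerance on ‖g_t − g_{t−1}‖₂ | off | fixed-T runs stay exactly reproducible |

τ can also be chosen by K-fold cross-validation on held-out negative
log-likelihood (`choose_tau`); responses are corrected before scoring when
the response correction is active, ties break toward the sparsest (largest)
τ, and folds with a single observed class are redrawn (≤ 5 attempts).

## Numerical choices

* Probit probabilities are clipped to [1e−10, 1 − 1e−10] before division;
  the probit weight otherwise overflows for |X'β| ≳ 6.
* Non-finite estimating-function values raise immediately; the study driver
  logs and excludes such replicates and flags a cell when more than 10% fail.
* Held-out likelihood scoring clips fitted probabilities at 1e−12.
* Selected predictors are reported 1-based.

## Synthetic-data generator

`me_generate` emulates the study conditions: predictors i.i.d. N(0, I), a
sparse true coefficient vector (default (1, 1, 1, 0, …)), the response drawn
from the chosen model, misclassification probabilities produced by a
logistic or probit model with (intercept, slopes) pairs — the study default
(1, 0) gives constant π10 = π01 = expit(1) ≈ 0.731 — and classical predictor
error with user-specified Σ_ε (0.15 and 0.50 in the replicated study).  One
integer master seed makes every draw reproducible; replicated studies use
seed + replicate-index streams, and replicates are shared across correction
settings within a cell so setting contrasts are paired.

What the generator does **not** emulate about real assay data: correlated
predictors, heavy-tailed or heteroscedastic measurement error, differential
(response-dependent) predictor error, and unknown π/Σ_ε (both are treated
as known or profiled by sensitivity analysis).  Passing tests therefore
demonstrate correctness of the corrections under the stated error models,
not robustness to their misspecification.

## Behaviour of the combined correction: an honest account

Two structural facts about the corrected *logistic* estimating function
matter in practice, and both are properties of the method itself, not of
this implementation (each is demonstrated numerically in the development
analysis and visible through the package's own functions):

1. With binary Y and predictor error only, the sufficient-statistic
   estimating function has its root at the true coefficients (the
   conditional-score construction is exact).  The test suite verifies
   recovery in this regime.
2. With the corrected response Y** substituted into the *nonlinear* mean
   (the fully corrected setting under strong misclassification), the
   estimating function is no longer exactly unbiased and, along fixed
   directions, need not have a root at all: because Y** ∉ {0, 1}, residuals
   Y** − μ cannot vanish, and the feedback term Y** Σ_ε β grows with β
   (Y**(Y** − 1) > 0 for every observation when 1 − π10 − π01 < 0).  An
   unbounded ascent therefore diverges; runs in this regime should use a
   bounded budget T·η (the study tuning η = 1e−5, T = 1000 is such a
   budget) rather than run to convergence, and the early-stopping rule ξ
   does not guard against it.  Response-only correction (setting (1,0)),
   which keeps the estimating function linear in Y**, recovers
   sign-reversed coefficients correctly even at 73% flip rates, as the
   README example shows.

At the replicated-study scale (n = 100, p = 1000) a further limitation is
intrinsic: the marginal signal of a true predictor at the starting point
β = 0 is ~1.5–1.8 noise standard deviations, while the largest of ~1000
null coordinates is ~3.3, so threshold-based selection from the zero
iterate cannot reliably rank the informative predictors first — a
sample-size constraint on any method of this form, not a tuning artefact.

## Problem sizes used by the checks

The acceptance script runs 100 replicates per study cell (25 at p = 5000)
at n = 100; the acceptance tests use 50 replicates (10 at p = 5000).
Low-dimensional convergence oracles use n = 2000–3000 with p ≤ 5.
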
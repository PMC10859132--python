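# Methods

## The simulation model

Each repetition draws, in a fixed order from one random stream, a data set
of n individuals:

1. confounder C_i ~ N(0, 1), i.i.d.;
2. exposure E_i ~ Bernoulli(expit(α₀ + α_C C_i));
3. outcome D_i ~ Bernoulli(expit(β₀ + β_E E_i + β_C C_i));
4. missingness M_C_i ~ Bernoulli(expit(γ₀ + γ_E E_i + γ_D D_i + γ_C C_i)).

The estimand θ = β_E is the conditional E–D log odds ratio; its true value
is 0 by default, so the exposure has no causal effect on the outcome while
C confounds both. The three mechanism presets constrain the γ's: MCAR
forces γ_E = γ_D = γ_C = 0, MAR forces γ_C = 0 (missingness may depend only
on the observed E and D), MNAR allows γ_C ≠ 0. True C values are retained
in storage even where M_C = 1; analyses see a masked view. That choice
costs nothing statistically (no analysis reads masked C) and buys exact
oracle checks of incomplete-data methods against the full data.

### Default parameters

| parameter | default | why |
|---|---|---|
| n (per data set) | 500 | fixed design size of the study |
| repetitions | 1000 | bias MCSE ≈ empSE/√1000 ≈ 0.01, comfortably below the 0.02 reporting precision; coverage MCSE ≈ 0.7 points |
| α₀, α_C | −1, 1 | exposure prevalence ≈ 30%; strong confounding (crude D–E log OR ≈ 0.7) |
| β₀, β_E, β_C | −1, 0, 1 | outcome prevalence ≈ 30%; null estimand; strong confounding |
| γ₀ (MCAR) | logit(0.3) | ≈ 30% of C missing |
| γ₀, γ_E, γ_D (MAR) | −1.5, 1, 1 | ≈ 30% missing overall, driven by exposure and outcome jointly — the configuration that genuinely biases complete-case analysis |
| γ₀, γ_C (MNAR) | −1, 1 | ≈ 30% missing, higher C more often missing — biases MI, which imputes under a MAR assumption |
| m (imputations) | 20 | between-imputation variance estimated with ~5% relative loss of efficiency at 30% missingness |
| α (test level) | 0.05 | two-sided Wald tests and 95% CIs |

Prevalences near 30% (rather than, say, 5%) keep random positivity
violations — complete-case cells with no events or no exposed — rare at
n = 500, so the default study measures the methods, not their failure
modes. The sparse regime remains available by configuration and is used in
the tests to exercise failure capture.

## Analysis methods

**Full-data and complete-case logistic regression.** Newton/IRLS on the
logistic log-likelihood, tolerance 1e−8 on the coefficient step, cap 100
iterations, linear predictors clipped at ±30 to keep weights finite. SEs
from the inverse observed information at the final iterate. Singular
information or hitting the cap returns `converged=False` rather than
raising: in a simulation loop a broken fit is a datum, not an emergency.
CIs are Wald z intervals.

**Multiple imputation.** Proper normal-linear imputation: among complete
rows regress C on (1, E, D); draw σ*² from RSS/χ²_{n_cc−3}, β* from
N(β̂, σ*²(X'X)⁻¹), and fill each missing C with x'β* + σ*z. The outcome D
must be in the imputation model — omitting it would bias the analysis
model toward the null even under MCAR. Each of the m completed data sets
is analysed by the same logistic fit; Rubin's rules pool: q̄ = mean
estimate, W = mean squared SE, B = between-imputation variance,
T = W + (1+1/m)B, with Barnard–Rubin degrees of freedom using
complete-data df = n − 3. MI CIs use the t distribution on those df.
With nothing missing the imputation step is the identity (and consumes no
random numbers), so MI reproduces the full-data fit with B = 0.

**Separation and the Firth backup.** `detect_separation` flags a zero
margin of the E×D table on the analysis rows, or a fitted |E coefficient|
above 10 — chosen because separated logistic fits typically wander into
the ±10–20 range with SEs in the hundreds or thousands before an iteration
cap stops them. The Firth fit maximizes the Jeffreys-penalized likelihood
ℓ(β) + ½ log det I(β) by Newton steps on the modified score with
step-halving; the penalty guarantees finite estimates under separation,
and on a saturated 2×2 design it reproduces the add-½-to-each-cell log
odds ratio exactly (a property the tests exploit as a closed-form oracle).
The `cca_firth_hybrid` method runs complete-case ML and substitutes the
Firth fit when the trigger rules fire (separation flag, |estimate| > 10,
or SE > 100, all configurable); `backup_used` is recorded per repetition
and summarized as a backup rate, because once a backup exists the object
under study is the hybrid procedure, not the pure method.

**Guarded execution.** Every method runs inside a wrapper that converts
any raised condition — recognised analysis failures (no events among
complete cases, too few complete rows, singular imputation model,
non-convergence) and unexpected exceptions alike — into an outcome row
with `status=failed:<code>` and missing numerics. The engine therefore
always produces exactly one row per (mechanism, method, repetition), and
failure counts are themselves a performance measure.

## The engine and random-number state

One PCG64 stream drives everything and is never re-seeded inside the loop.
The generator state is serialized (versioned JSON, base64) immediately
before each repetition's data generation, and again after generation but
before the first method runs — deterministic methods consume no random
numbers, so the second token is exactly the state before the first
stochastic analysis (MI). Restoring the first token recreates the data
set bit-for-bit; restoring the second replays the MI analysis to identical
results. This is the store-states option; `store_datasets=True`
additionally keeps every simulated data set, and the tests verify that
state capture leaves no statistical footprint on the estimates.

`fixed_full_data=True` deliberately reproduces a known design error:
one full data set per mechanism, with only the missingness redrawn each
repetition. Model-based SEs then include full-data sampling variation that
the empirical SE cannot see, and the toolkit shows the model-based SE
exceeding the empirical SE by 80–190% at the defaults. A per-mechanism
rep-0 states record keeps even this mode recreatable.

## Performance measures and Monte Carlo errors

For each mechanism × method cell, from the non-failed repetitions:
bias = mean(θ̂) − θ with MCSE S/√n; empirical SE = S with MCSE
S/√(2(n−1)); model-based SE = √(mean ŝe²) (the root mean square, not the
plain mean) with delta-method MCSE √(Var(ŝe²)/(4 n modSE²)); relative
error = 100(modSE/empSE − 1)% with the two components' relative variances
combined by the delta method; coverage and rejection rates with binomial
MCSEs on the percent scale. Failed repetitions are excluded from the
moment-based measures but reported through the failure rate; nothing is
ever imputed for a failed estimate, and no multiplicity adjustment is
applied anywhere.

Compatibility verdicts use a strict two-MCSE margin against a known
reference constant. When the reference is itself a Monte Carlo estimate
(as when comparing one run's cell against a published table that prints
its own error bound), the acceptance tests combine both errors in
quadrature — treating a simulated number as exact is precisely the mistake
the two-MCSE discipline exists to prevent.

## Diagnostics

The scatter data (SE estimate against point estimate per cell) and the
rule-based outlier report (defaults |estimate| > 10, SE > 100, SE < 1e−8;
each disableable) expose separated and degenerate fits. Zip-plot rows rank
all repetitions' CIs by the two-sided Wald p-value against the truth,
ascending (least compatible first, ties by repetition id — the orientation
is a presentation choice), with rank fraction (rank − ½)/n; `covers` is
read off the stored CI, so the zip non-coverage fraction equals
1 − coverage/100 exactly, by construction rather than by approximation.
Zero-SE rows have no defined p-value and are excluded with a warning
count. Rendering to matplotlib axes is a thin optional layer; the
DataFrame/CSV contract is the tested surface.

## What the generator does and does not emulate

The generator reproduces the study conditions exactly as specified: one
Normal confounder, logistic exposure/outcome models, single-variable
logistic missingness, fixed n. It does not emulate multivariate
missingness, non-Normal or multiple confounders, measurement error, or
clustering; passing tests therefore certify the engine and the method
implementations under the stated model, not the behaviour of CCA or MI on
real epidemiological data, where the imputation model is rarely exactly
correct. Within the model, the MNAR preset gives a genuine misspecified-
imputation setting, which is why MI's bias there is a finding and not a bug.

## Numerical choices and edge cases

IRLS and Firth tolerances 1e−8, caps 100; Firth step-halving up to 20
times per Newton step. Rubin pooling guards the λ → 0 limit (B = 0 gives
df from the observed-data component alone; λ² underflow maps to infinite
df_old). Degenerate 2×2 tables in the large-sample check are reported as
failed checks, never raised. CSV output uses shortest round-trip float
formatting and is read back with round-trip parsing, so write→read is the
identity including NaN fields; an `se` column containing variances cannot
be detected and is documented as the user's responsibility.

## Problem sizes used in the checks

The test suite runs the full 3 × 3 × 1000 study once (about a minute on
one CPU), a 200-repetition fixed-full-data run, 100-repetition single-
mechanism runs for the medium checks, and 100 000-row single data sets for
the large-sample recovery and distributional oracles. The acceptance
script reruns the full study at whatever seed it is given.

## Known limitations

Single-threaded by design — one stream keeps state semantics trivial. One
analysis state token per repetition (not per stochastic method): with
several stochastic analyses per repetition, replaying the k-th requires
replaying the first k−1 in order. Exact conditional logistic CIs are not
provided as a backup (Firth is); imputation engines other than
normal-linear (e.g. predictive mean matching) are out of scope.
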
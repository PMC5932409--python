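# Methods

## Model

The package works with the linear latent growth curve model (LGCM) for
balanced, complete panel data: person *i* observed at occasions
`t_1 < … < t_M` (years) follows

```
x_ij = I_i + S_i t_j + e_ij,
(I_i, S_i) ~ N((μ_I, μ_S), Ψ),   Ψ = [[σ²_I, σ_IS], [σ_IS, σ²_S]],
e_ij ~ N(0, σ²_ε)  i.i.d. over i and j.
```

Equivalently, the observed M-vector is multivariate normal with
`Σ = ΛΨΛ′ + σ²_ε I` and `μ = Λν`, `Λ = [1 | t]`. Assumptions carried
throughout: linear change, homoscedastic and serially uncorrelated
residuals, one indicator per occasion, no missing data, a common occasion
grid for all subjects. The intercept is defined at time 0; designs need not
contain 0 (shifted designs deliberately do not), and shifting the grid
redefines which moment of the study anchors the intercept.

## Precision and reliability indices

With zero intercept-slope covariance, the error a hypothetical single
direct measurement of the slope would carry in a power-equivalent minimal
design (the *effective error*) is

```
σ²_eff = σ²_ε / (Σ_j t_j² − η (Σ_j t_j)²),   η = 1/(M + σ²_ε/σ²_I) = ICC₂/M,
```

with `ICC₂ = σ²_I/(σ²_I + σ²_ε/M)`. `η` is defined as 0 at `σ²_I = 0` by
continuity (the ICC₂ = 0 limit). Effective error rises with residual and
intercept variance and falls as occasions are added or spread out; because
it depends on the grid only through `Σt²` and `(Σt)²` it is exactly
symmetric under a sign flip of all times, and over all shifts of a grid it
is maximal for the time-centered grid whenever ICC₂ < 1 (the derivative of
the denominator in the shift vanishes exactly at `Σ(t+δ) = 0`).

Effective curve reliability `ECR = σ²_S/(σ²_S + σ²_eff)` is the
standardized effect size coherent with likelihood-ratio testing of
`σ²_S = 0`. Growth rate reliability `GRR = σ²_S/(σ²_S + σ²_ε/SST)`,
`SST = Σ(t_j − t̄)²`, replaces the effective error by its `ICC₂ → 1` limit
`σ²_ε/SST`; since `η ≤ 1/M`, always `σ²_eff ≤ σ²_ε/SST` and `ECR ≥ GRR`,
with equality as ICC₂ → 1, when `σ²_I = 0` on a centered grid, or whenever
`Σt_j = 0`. A practical consequence verified in the Monte Carlo suite: on a
non-centered grid, raising intercept variance at fixed everything else
*lowers* LR-test power, and ECR tracks that ordering while GRR stays
constant. The per-design report also prints the time-point dispersion
`SST/(M−1)` — the sample variance of the occasion times, a descriptive
column, not a model quantity.

## Noncentrality and analytic power

In the minimal power-equivalent model the unrestricted implied covariance
is the scalar `σ²_S + σ²_eff` and the restricted one `σ²_eff`, giving the
1-df LR noncentrality

```
λ = N [1/(1−ECR) − ln(1/(1−ECR)) − 1],
```

and power `1−β = P(χ²_{ν,λ} > c_α)`. The default null reference is the
plain central χ²; the boundary 50:50 mixture critical value
(`χ²₀:χ²₁` for 1 df, `χ²₁:χ²₂` for 2 df) is available for sensitivity
analysis, since the boundary issue shifts all designs equally and does not
affect design comparison. A literature-circulated small-ECR approximation
`λ ≈ N·ECR²/(1−ECR)` is provided verbatim for reference but is inconsistent
with the Taylor expansion of the exact expression (leading term
`N·ECR²/2`) and is never used internally.

For arbitrary parameters, `satorra_saris_lambda` computes λ directly from
the population implied moments: the restricted model (σ²_S = 0 and
σ_IS = 0, intercept and residual variance as nuisance) is evaluated against
the moments implied under the alternative via the ML discrepancy
`F = ln|Σ_res| + tr(Σ_pop Σ_res⁻¹) − ln|Σ_pop| − M` and
`λ = N·(F_res − F_unres)`. The unrestricted reference of the 2-df
generalized test is the full model (`F_unres = 0`); for the 1-df specific
test it is the σ_IS = 0 model, which itself misfits when the true
covariance is non-zero (that test is then misspecified, and the 2-df test
should be preferred). The mean structure is unrestricted throughout, so
only the covariance part contributes. Two nuisance policies exist:
`fixed_true` holds nuisance parameters at their population values (the
power-equivalence convention; with σ_IS = 0 this reproduces the
closed-form λ to machine precision, which the suite checks to 1e−6·N over
randomized scenarios) and `free` minimizes each discrepancy over the
nuisance parameters, yielding a smaller λ that anticipates the power cost
of free estimation.

## Generalized ECR

No closed form for ECR is known when σ_IS ≠ 0. `generalized_ecr` computes
the per-subject noncentrality `f = λ/N` of the chosen LR test (N cancels)
and returns the unique `ECR ∈ [0, 1)` with
`f = 1/(1−ECR) − ln(1/(1−ECR)) − 1`, found by bracketed root-finding to
1e−12. This inversion is a reconstruction — it is consistent with the
defining identity in the σ_IS = 0 case and with the standardized-effect
reading of ECR, but it is an interpretation, not a canonical published
algorithm. The default `fixed_true` policy preserves the exact agreement
with the closed form at σ_IS = 0. Note a subtlety found empirically: across
intercept-slope correlations the fixed-true index does not order
freely-estimated 2-df Monte Carlo power correctly (the restricted model can
absorb misfit through its free nuisance parameters asymmetrically in the
sign of the correlation), while the `free` policy tracks that ordering
closely; use `nuisance_policy="free"` when the index is meant to mirror a
freely estimated analysis.

## Estimation and the empirical tests

`LatentGrowthCurve.fit` minimizes the profile ML discrepancy over the free
covariance parameters — the latent means are profiled out in closed form
(GLS given Σ) at every objective evaluation, so the optimizer works in at
most four dimensions on the sufficient statistics (x̄, S with the
divide-by-N convention), independent of N. Starting values are
method-of-moments: per-subject OLS growth coefficients give Ψ after
subtracting the sampling contribution `σ̂²_ε (Λ′Λ)⁻¹`, with the residual
variance pooled over subjects. Optimization uses Nelder–Mead
(xatol 1e−10, fatol 1e−12) with up to five jittered restarts before a fit
is flagged non-convergent; non-positive-definite Σ proposals receive a
large finite penalty. Standard errors come from the observed information —
half the central-difference Hessian of −2LL at the optimum, inverted
(forward differences proved too noisy for the Wald statistic at large N and
were replaced by central differences).

Variance parameters are estimated *unconstrained* by default (estimates
may go negative) and LR statistics `−2LL_res − (−2LL_unres)` are referred
to plain χ² critical values; this convention keeps the null distribution
χ² (type-I rate ≈ α, verified by simulation) and matches the design
comparisons the package is for. A constrained mode (variances bounded at
zero) plus the mixture reference is available behind flags. The specific
1-df test compares {σ²_S = 0, σ_IS = 0} against {σ_IS = 0}; the generalized
2-df test compares the same restricted model against the fully free Ψ.
Negative LR statistics beyond numerical noise are clipped at zero with a
warning.

The Wald statistic is `σ̂²_S / SE(σ̂²_S)` against a one-sided standard
normal (the reference the literature leaves unstated; one-sided is the
natural choice for a variance). By default it is computed from the *full*
estimated solution (σ_IS free): computed that way its power is
approximately flat in ICC₂, which is the property that makes GRR — not
ECR — its effect-size counterpart; based on the σ_IS = 0 model instead
(`assume_zero_covariance=True`) it inherits the 1-df LR test's dependence
on intercept variance and agrees with it asymptotically.

## Monte Carlo engine and the synthetic-data generator

`simulate_sample` draws i.i.d. subjects from the exact implied multivariate
normal (eigendecomposition sampler, so positive-semidefinite degenerate
covariances are handled). Latent means default to zero: the variance tests
are mean-invariant under the unrestricted mean structure, so simulated
power does not depend on them. The generator emulates exactly what the
model assumes — and therefore nothing it does not: no attrition or missing
data, no practice effects, no heteroscedastic or autocorrelated residuals,
no nonlinearity, no floor/ceiling effects. Passing tests demonstrate
internal coherence of the indices, the estimator and the tests under the
model; they say nothing about robustness to violations of it.

`mc_power` runs `nrep` replications, each drawing its generator from
`SeedSequence((seed, r))` so any replication is reproducible in isolation,
fits both member models with everything else freely estimated, and reports
the rejection fraction with its binomial standard error. Replications whose
fits fail after restarts are excluded and counted; more than 5% failures
aborts the run (a guard against silently biased power). Because nuisance
parameters are free, Monte Carlo power runs below the analytic fixed-
nuisance value (≈0.51 vs 0.712 in the five-annual-occasions scenario at
N=100); an `oracle_nuisance` mode that fixes them at truth closes that gap
and approaches the analytic value at large N.

Default study conditions follow the packaged scenarios: 1000 replications,
N=100, α=0.05. Qualitative sweeps in the test suite use a three-occasion
grid instantiated as {0, 1, 2} with slope variance 2, residual variance
sweeps over {10, 20, 30}-scale values and intercept variance spanning
ICC₂ ≈ 0.23–0.96; these run at 250 replications — orderings with effects of
0.2+ in power are resolved at a binomial SE of ≈0.03.

## Heuristics

`params_from_reliability` splits an assumed total observed variance
(default 100, T-score scaling) by alternate-forms reliability:
`σ²_I = ρ_rel·total`, `σ²_ε = (1−ρ_rel)·total`. `slope_var_from_stability`
inverts the model-implied test-retest correlation over a T-year interval

```
ρ_stab = (σ²_I + Tσ_IS) / sqrt[(σ²_I+σ²_ε)(σ²_I+σ²_ε+T²σ²_S+2Tσ_IS)]
```

for σ²_S (exactly; the round trip is an identity, property-tested to
1e−8), with σ_IS = 0 as the default starting assumption and a non-zero
value accepted as a sensitivity input. Stability equal to reliability gives
σ²_S = 0 exactly (no individual differences in change); stability above
reliability has no non-negative solution and raises an error — grid cells
in that region are reported as NaN.

## Numerical choices

- λ-to-ECR inversion: Brent's method on [0, 1−1e−15], xtol 1e−12.
- Noncentral χ² tails via `scipy.stats.ncx2`; no hand-rolled quadrature.
- ML discrepancy via Cholesky/slogdet; non-PD proposals penalized, not
  clamped.
- Convergence: optimizer success plus finite discrepancy; `minus2ll` is
  recomputed exactly (not from the profile objective) at the optimum.
- Report rounding to 2 decimals in rendered tables; full precision in every
  returned object and JSON.
- Seeds: every stochastic entry point takes an explicit seed; batch
  replication streams are counter-based as described above.

## Known limitations

- Complete balanced data only; attrition/MCAR multi-group effective error
  is out of scope.
- No closed-form effective error for fixed non-zero σ_IS; the numerical
  λ route stands in for it, and the generalized-ECR construction is a
  reconstruction (see above).
- Analytic power assumes the noncentral-χ² approximation and fixed
  nuisance; treat it as an upper reference and confirm a chosen design by
  Monte Carlo.
- The Wald SE relies on a numerical observed-information Hessian; in
  near-boundary replications it can be undefined (such replications are
  counted and excluded, never imputed).
- Nonlinear growth, multiple indicators per occasion, covariates, REML and
  robust corrections are out of scope.
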
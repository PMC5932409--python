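# lgcpower

Change-sensitivity analysis for **linear latent growth curve models (LGCM)**:
precision, reliability, and statistical power to detect individual
differences in change, for researchers planning longitudinal studies.

Longitudinal studies model repeated measures `x_ij` of person *i* at
occasion time `t_j` as

```
x_ij = I_i + S_i · t_j + e_ij,      (I_i, S_i) ~ N(ν, Ψ),  e_ij ~ N(0, σ²_ε)
```

with latent intercepts `I_i` and slopes `S_i`, so the implied moments are
`Σ = ΛΨΛ′ + σ²_ε I` and `μ = Λν` with loadings `Λ = [1, t_j]`. The
scientific question "do people differ in their rate of change?" is the test
of zero slope variance `σ²_S = 0`, and its statistical power depends on the
design (number and spacing of occasions, instrument precision, sample size)
and on the population parameters in ways this package makes explicit:

- **Effective error** `σ²_eff = σ²_ε / (Σt² − η(Σt)²)`, `η = 1/(M + σ²_ε/σ²_I)`
  — the error a hypothetical single direct measurement of the slope would
  carry in a power-equivalent minimal design; the inverse of design
  precision.
- **Effective curve reliability** `ECR = σ²_S / (σ²_S + σ²_eff)` — a
  standardized effect size coherent with the likelihood-ratio (LR) test of
  zero slope variance.
- **Growth rate reliability** `GRR = σ²_S / (σ²_S + σ²_ε/SST)` — the
  limiting case of ECR (reached as ICC₂ → 1, when `σ²_I = 0`, or for
  time-centered designs), coherent with the Wald test instead.
- **Noncentrality** `λ = N·[1/(1−ECR) − ln(1/(1−ECR)) − 1]` and power
  `1−β = P(χ²_{ν,λ} > χ²_ν(α))` for the 1-df (specific) and 2-df
  (generalized) LR tests; a numerical route extends ECR to non-zero
  intercept-slope covariance.
- **Heuristics** that convert an instrument's reliability and a test-retest
  stability coefficient into LGCM parameters when no prior growth-model
  estimates exist.
- A **maximum-likelihood fitting and Monte Carlo engine** for realistic
  power estimates with all nuisance parameters freely estimated.

## Worked example

A planning team assumes intercept variance 10, slope variance 1 and
residual variance 50 (a low-reliability instrument) and debates five annual
occasions `{0, 1, 2, 3, 4}` against a rearranged spacing `{0, 1, 3, 3.5, 4}`:

```python
from lgcpower import (StudyDesign, GrowthParams, precision_summary,
                      analytic_power, mc_power)

params = GrowthParams(var_intercept=10, var_slope=1, var_residual=50)
annual = StudyDesign([0, 1, 2, 3, 4])
packed = StudyDesign([0, 1, 3, 3.5, 4])

s = precision_summary(annual, params)
print(f"effective error {s.effective_error:.2f}  ECR {s.ecr:.2f}  "
      f"GRR {s.grr:.2f}  ICC2 {s.icc2:.2f}")
# effective error 2.50  ECR 0.29  GRR 0.17  ICC2 0.50

print(f"{precision_summary(packed, params).ecr:.2f}")
# 0.33

print(f"analytic power (N=100): {analytic_power(annual, params, 100).power:.3f}")
# analytic power (N=100): 0.712

est = mc_power(packed, params, n_subjects=100, test="specific_1df",
               nrep=1000, seed=1)
print(f"Monte Carlo power: {est.power:.2f} (SE {est.mc_standard_error:.3f})")
# Monte Carlo power: 0.63 (SE 0.015)
```

Moving the middle occasions toward the ends raises ECR from 0.29 to 0.33
and Monte Carlo power from ≈0.51 to ≈0.63 at the same cost in sessions —
while GRR (0.17 vs 0.19) barely separates the designs. The analytic value
(0.712) exceeds the Monte Carlo one because it holds nuisance parameters
fixed at their true values; free estimation costs power, which is why a
final Monte Carlo check of a chosen design is recommended.

The same analyses are available from a shell:

```
lgcpower precision scenario.yaml
lgcpower power scenario.yaml --method mc --nrep 1000 --seed 1
lgcpower heuristic --reliability 0.9 --stability 0.85 -t 3
lgcpower compare scenario.yaml --design "0,1,3,3.5,4"
lgcpower case 3
```

where `scenario.yaml` holds `design.times`, `design.n` and the population
parameters (see `lgcpower.io.load_scenario`).

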
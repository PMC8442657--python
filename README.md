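# ssglm — split-and-smooth inference for high-dimensional GLMs

`ssglm` estimates, and quantifies the uncertainty of, **every** coefficient
of a generalized linear model when the number of predictors `p` exceeds the
sample size `n` — the regime of, e.g., case/control studies with thousands
of SNPs and a few hundred subjects. Penalized fits (lasso and friends) give
point estimates there but no usable standard errors; de-biasing approaches
require estimating a `p × p` precision matrix. `ssglm` instead recasts the
problem as a large collection of *low-dimensional* GLM fits:

1. **Split.** Randomly divide the `n` samples into an estimation half `D₁`
   (`n₁ = qn`) and a screening half `D₂`.
2. **Screen.** On `D₂`, run a variable selector `S_λ` (sure independence
   screening by default; cross-validated lasso, elastic net, SCAD, MCP are
   available) to get a small set `S` that should *contain* the true active
   set — sure screening, much weaker than selection consistency.
3. **Partial regressions.** On `D₁`, for every predictor `j = 1..p`, fit the
   ordinary GLM of `y` on `{intercept} ∪ S ∪ {j}` and keep the coefficient
   of `j`: the one-time estimate `β̃ⱼ`.
4. **Smooth.** Repeat over `B` independent random splits and average:
   `β̂ⱼ = (1/B) Σ_b β̃ⱼᵇ`.

Variances come from an **infinitesimal jackknife** over the split-membership
indicators `J_{bi} = 1{i ∈ D₁ᵇ}`:

    V̂ⱼ  = n(n−1)/(n−n₁)² · Σᵢ ĉovᵢⱼ²,   ĉovᵢⱼ = (1/B) Σ_b (J_{bi} − J̄·ᵢ)(β̃ⱼᵇ − β̂ⱼ)
    V̂ⱼᴮ = V̂ⱼ − (n/B²)·(n₁/(n−n₁)) · Σ_b (β̃ⱼᵇ − β̂ⱼ)²        (Monte-Carlo bias removed)

giving per-coefficient confidence intervals `β̂ⱼ ± z_{1−α/2}·√V̂ⱼᴮ` and
p-values `2(1 − Φ(|β̂ⱼ|/√V̂ⱼᴮ))`. For a fixed small subset `S⁽¹⁾` the same
machinery produces a joint covariance `Σ̂⁽¹⁾` and Wald tests of contrasts
`H₀: Qβ⁽¹⁾ = R` with `T = (Qβ̂⁽¹⁾−R)ᵀ[QΣ̂⁽¹⁾Qᵀ]⁻¹(Qβ̂⁽¹⁾−R) ~ χ²_r`.

Supported families: gaussian (identity link), binomial (logit), poisson
(log) — all canonical.

## Worked example

A logistic model with `n = 300`, `p = 400` and two real effects
(`β₃₇ = 1.5`, `β₁₈₂ = −1.5`):

```python
import numpy as np
from ssglm import SSGLMConfig, ssglm_fit, inference_table
from ssglm.synth import SimulationDesign, simulate_dataset

design = SimulationDesign(n=300, p=400, family="binomial",
                          coef_rule=("fixed", (1.5, -1.5)),
                          active_rule=("fixed", (37, 182)))
data, beta_true, S_star = simulate_dataset(design, np.random.default_rng(7))

fit = ssglm_fit(data, SSGLMConfig(B=200, q=0.5, selector="sis", seed=1))
tab = inference_table(fit, alpha=0.05)
print(tab.iloc[[0, 37, 182, 399]])
```

```
 index        name estimate       se    ci_lo    ci_hi   pvalue  pvalue_adj  sel_freq
     0 (intercept)   -0.087    0.168   -0.416    0.242    0.604         NaN         1
    37         x37    1.505    0.227    1.060    1.950 3.34e-11    1.34e-08         1
   182        x182   -1.510    0.219   -1.940   -1.080 5.96e-12    2.38e-09         1
   399        x399    0.010    0.186   -0.354    0.373    0.958           1     0.005
```

Both true effects are recovered (estimates 1.505 and −1.510 against truths
±1.5) with Bonferroni-significant p-values and 100% per-split selection
frequency, while a representative noise coefficient (x399) sits at ≈0 with
p ≈ 0.96. Ranking all 400 predictors by p-value puts the two signals first;
the best noise predictor (x75, raw p = 0.0026) is correctly discarded after
multiplicity adjustment.

The same pipeline is available from a shell:

```sh
ssglm simulate --preset example5 --rho 0.25 --seed 1 \
      --out-x X.csv --out-y y.csv --out-truth truth.json
ssglm fit --x X.csv --y y.csv --family binomial --q 0.5 --B 500 \
      --selector sis --seed 1 --out fit.json
ssglm infer --fit fit.json --alpha 0.05 --adjust bonferroni --out table.csv
ssglm test --x X.csv --y y.csv --family binomial --subset 12,57 --b 500
```

`ssglm experiment` runs replicated studies of the built-in designs
(`example1`–`example5`: linear/Poisson/logistic models with identity, AR(1)
and compound-symmetry predictor correlation) and writes `metrics.csv` plus a
complete `config.json` so every table is re-runnable bit-for-bit.

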
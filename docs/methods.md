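# Methods

## Model

Observations `(yᵢ, xᵢ)`, `i = 1..n`, are i.i.d. with `p` centered predictors
and a response from a linear exponential family with canonical link,

    f(y | θ) = exp{ yθ − A(θ) + c(y) },    θ = β₀ + xᵀβ,

so `E(y|x) = A′(θ)` and `Var(y|x) = A″(θ) > 0`. The implemented families are
gaussian (`A = θ²/2`), binomial (`A = log(1+eᶿ)`) and poisson (`A = eᶿ`).
`c(y)` cancels in the average negative log-likelihood and is never needed.
The target is the full coefficient vector `β* = (β₀*, β₁*, …, β_p*)` under a
sparsity assumption: the active set `S* = {j : βⱼ* ≠ 0}` is small relative
to `n`, and the selector must satisfy *sure screening* — `P(S* ⊆ Ŝ) → 1` —
not selection consistency.

## Procedure

For each of `B` random splits: `D₁` (size `n₁ = round(qn)`, sampled without
replacement) is the estimation half and `D₂` the screening half. The
selector runs on `D₂` only; for every `j` (selected or not) the
low-dimensional GLM of `y¹` on `{1} ∪ S ∪ {j}` is fit by Newton–Raphson on
`D₁` and the `j`-th coefficient retained. Per-split estimates are averaged
coordinate-wise over splits. The coefficient vector is indexed `0..p` with
0 the intercept; predictor indices are 1-based throughout.

Numerical choices:

- **Newton/IRLS**: start at `(g(ȳ), 0, …, 0)` with `ȳ` clamped into the
  family's open mean space; observed-information steps with up to 10
  step-halvings per iteration; convergence when the max-abs coefficient
  change drops below 1e-8 (cap 100 iterations). Linear predictors are
  clamped to ±30 inside `A`, `A′` for binomial/poisson (clamps are logged).
  A fit that cannot converge (e.g. logistic separation) is reported as such,
  never silently returned.
- **Batched fitting**: the `p − |S|` per-predictor designs of one split
  share all but one column and are solved simultaneously with batched
  linear algebra, warm-started from the fit on `S`; a test enforces
  agreement with the one-at-a-time fits to 1e-8. GLM fits are invariant to
  column order, so the appended column's coefficient equals the
  ascending-order convention of the records.
- **Per-coefficient failures** (rank deficiency, separation,
  non-convergence) are recorded as missing for that `(b, j)`; the smoothed
  estimate and its variance use that coordinate's own successful splits.
  A split whose binomial half lacks both classes is redrawn (≤100 times);
  a run aborts only if >10% of splits fail outright.
- **Reproducibility**: split `b` draws from the derived stream
  `[seed, b]`, so results are bit-identical under any execution order or
  thread count.

## Selection

All selectors standardize columns internally, return ascending 1-based
indices, cap `|S| ≤ min(n₁, n₂)/3`, and break ranking ties by ascending
index.

- **SIS** (default): rank by the absolute standardized marginal score
  statistic computed on the *rank-transformed* response (a Spearman-type
  robust screen). For binary y this is exactly the raw-scale score ranking;
  for gaussian y essentially the Pearson ranking. The rank transform
  matters for the Poisson designs: with several active effects the response
  has enormous variance, and a raw-scale correlation screen includes weak
  signals (|β| ≈ 0.5) in its top set less than half the time, versus
  0.85–1.0 after rank transformation. Raw-score and marginal-MLE utilities
  remain available. Default size `d = ⌊√n₂⌋`: the theory wants
  `|S| = O(n^c)`, `c < 1/2`, and the conventional `n₂/log n₂` is close to
  linear — at these study sizes it produces 37-column logistic partial fits
  on 200 samples, which separate frequently and inflate the MLEs.
- **CV-penalized selectors**: a pathwise coordinate-descent solver for
  elastic-net-penalized GLMs (gaussian/binomial/poisson; glmnet-style outer
  quadratic approximation, inner cyclic CD with sequential strong rules,
  warm starts, early path stop once the support passes the cap). λ is
  chosen by K-fold (default 10) cross-validated deviance with the
  one-standard-error rule (the conventional parsimonious selection choice;
  the deviance minimizer is available as `rule="min"`). SCAD and MCP are
  one-step local-linear-approximation re-weightings of the CV-lasso
  solution (a = 3.7 and 3.0). An empty support falls back to the strongest
  single path coefficient, with a warning.

## Variance estimation and inference

The infinitesimal-jackknife variance and its Monte-Carlo bias-corrected
version are exactly the two formulas in the README. Two finite-`B` facts
drive the remaining design choices:

- The raw `V̂ⱼ` overshoots the truth by `≈ (n/B)·(q/(1−q))·υ̂ⱼ` (υ̂ⱼ the
  across-split variance of `β̃ⱼ`), which at `n = 400, B = 100` is an order
  of magnitude larger than the target variance; the corrected `V̂ⱼᴮ` removes
  it but becomes negative for a few percent of coefficients. A negative
  value means the correction is uninformative for that coordinate, so the
  estimator falls back to the conservative raw `V̂ⱼ` there (wider intervals,
  never a spuriously tiny SE). `V̂ⱼᴮ ≤ V̂ⱼ` always holds.
- At `B = 100` the estimated SEs carry enough Monte-Carlo noise that
  normal-reference tests reject a true null at ≈0.06–0.08 instead of 0.05;
  the effect disappears as `B` grows (measured 0.063 at `B = 200`,
  SE/SD ratio → 1). `B = 500`–`1000` is recommended for final inference.

Confidence intervals and p-values use the normal reference with
`SE = √V̂ⱼᴮ`; Bonferroni adjustment multiplies the `p` non-intercept
p-values by `p`. The subvector covariance `Σ̂⁽¹⁾` applies the same
finite-sample factor as the scalar estimator (so its raw diagonal equals
`V̂ⱼ`) and, by default, the matrix analog of the bias correction (diagonal
equals `V̂ⱼᴮ`); negative eigenvalues produced by the subtraction are floored
(logged). Wald contrasts require `Q` of full row rank and a nonsingular
`QΣ̂⁽¹⁾Qᵀ`.

## Synthetic designs

`X` rows are zero-mean multivariate normal with identity, AR(1)
(`Σᵢⱼ = ρ^|i−j|`) or compound-symmetry (`Σᵢⱼ = ρ, i≠j`) correlation;
coefficients come from a fixed list or a uniform band with optional random
signs, on a fixed or randomly drawn active set; outcomes follow the linear
(`y = η + ε`, `ε ~ N(0,1)`), logistic, or Poisson model. For the poisson
family predictors are truncated (clipped) at ±3 SD by default so that
`exp(η)` stays bounded — the theory assumes bounded predictors, and the
generator refuses designs whose post-truncation mean exceeds 1e8. Poisson
intercepts default to 1.0 in the presets that need one. A design is
*realized* once (truth frozen) and then sampled per replicate, matching how
simulation tables fix one draw of the active set across replications.

What the generator does **not** emulate: discrete/bounded genotype coding,
linkage-disequilibrium block structure, model misspecification,
overdispersion beyond the family variance, or missing data. Passing tests
demonstrate correctness of the machinery under the stated generative
models, not robustness to those departures.

## Study presets and problem sizes

`example1`–`example5` encode: (1) linear, n=500, p=1000, s₀=10, AR(1)
ρ=0.5, effects U[±(0.5,1.5)]; (2) Poisson, n=300, p=400, effects
0.4–1.2 on a random active set; (3) Poisson, n=400, p=500, s₀=6, effects
U[0.5,1]; (4) logistic, n=400, p=500, S*={218,242,269,417}, effects
(−2,−1,1,2); (5) logistic, n=200, p=300, effects (2,−2,2), AR(1).

`scripts/acceptance.py` runs these at `B = 100`, `q = 0.5` with replicate
counts chosen once for a single-CPU run: K=50 for the logistic power
studies and the subvector study, K=40 for the Poisson identity coverage
study, K=20 for the CV-lasso study. The test suite uses further-reduced
replicate counts with fixed seeds.

## Known limitations

- Half-sample logistic partial fits with tens of columns inflate
  multiplicatively (the high-dimensional logistic MLE effect): with
  `n₁ = 200`, `|S|+2 ≈ 16` columns and strong signals (sd(η) ≈ 3), point
  estimates of ±2 effects center near ±2.3–2.4 rather than ±2. This is a
  property of the maximum-likelihood partial regressions themselves — an
  oracle fit restricted to the true active set on the same half-samples
  still centers near ±2.16 — and shrinks with `n₁` or smaller screening
  sets. Tests on such coefficients are anti-conservative in the direction
  of the signal (power is overstated); null contrasts are unaffected
  because the inflation cancels.
- The subvector covariance at `B = 100` with `n = 400` subtracts a
  Monte-Carlo term several times larger than the target; its calibration
  was verified against the empirical covariance of the smoothed estimator
  (diagonals ≈ 0.06 vs measured 0.07 on the logistic subvector design),
  but individual replicates are noisy. Use `B ≥ 500` for contrast tests
  that matter.
- Non-canonical links, dispersion estimation and the negative-binomial
  family are out of scope; so are FDR procedures beyond Bonferroni and
  simultaneous bands.
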
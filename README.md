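# cubethin

Fixed-size compression of MCMC output with control variates and the cube
method of balanced survey sampling.

## The problem

A long MCMC chain `X_1, …, X_N` targeting a density `p` is expensive to
store and to feed into downstream computation, so practitioners keep a
subsample. Standard thinning (every *t*-th state) ignores everything known
about `p` and inflates the variance of every estimate. When **control
variates** are available — functions `h_j` with `p(h_j) = 0`, such as the
score-based variates `h_i(x) = s_p(x)[i]` and
`h_ij(x) = 1{i=j} + x[i] s_p(x)[j]` built from the score
`s_p(x) = ∇ log p(x)`, or the one-step conditional-expectation variates of
a Gibbs sampler — the chain can be compressed into exactly `M` points that
*preserve the control-variate balance* of the full chain, at a cost that is
independent of `M` (a flight phase of `O(N J³)`).

## The method

1. **Regression weights.** With `H` the `N×(J+1)` design matrix
   (`H[n,0] = 1`, `H[n,j] = h_j(X_n)`), the weights

   `w = H (HᵀH)⁻¹ e₁`

   satisfy `Hᵀw = e₁`: they sum to one, annihilate every control-variate
   column, and `p̂*(f) = Σₙ wₙ f(Xₙ)` is the intercept of the OLS
   regression of `f(Xₙ)` on the variates — a reduced-variance estimate of
   `p(f)` for any `f`.

2. **Balanced resampling.** Writing `Ω = Σ|wₙ|` and `Wₙ = M|wₙ|/Ω ∈ [0,1]`
   (points with `Wₙ > 1` are split into copies), the **cube method** draws
   inclusion indicators `Sₙ ∈ {0,1}` with `E[Sₙ] = Wₙ` subject to
   `Σ Sₙ = M` (exact size) and `Σ_{Sₙ=1} sgn(wₙ) h_j(Xₙ) = 0` (balance).
   A martingale flight phase rounds all but at most `J+1` coordinates of
   the inclusion-probability vector to 0/1 while staying on the constraint
   hyperplane; a landing phase resolves the remainder.

3. **Signed measure.** The output is
   `ν̂ = (Ω/M) Σ_{Sₙ=1} sgn(wₙ) δ_{Xₙ}`, which is conditionally unbiased:
   `E[ν̂(f) | chain] = Σₙ wₙ f(Xₙ)`.

Compression quality can be scored with the included metrics: kernel Stein
discrepancy (inverse-multiquadric Stein kernel, median lengthscale),
energy distance, and a star-discrepancy surrogate over random anchored
boxes after a whitening + Gaussian-CDF map to the unit cube.

## Worked example

```python
import numpy as np
from cubethin import (TargetSpec, make_gaussian_chain, score_cv_matrix,
                      compute_weights, weighted_estimate, cube_thin,
                      evaluate_signed_measure)

target = TargetSpec(mean=[0.5, -0.5], cov=[[2.0, 0.6], [0.6, 1.0]])
chain = make_gaussian_chain(target, 10_000, seed=42)   # iid draws + scores

H = score_cv_matrix(chain, "full")        # J = d + d^2 = 6 control variates
ws = compute_weights(H)                   # w = H (H^T H)^{-1} e1

x1 = chain.states[:, 0]
print("plain mean of x1:    %.6f" % x1.mean())
print("weighted estimate:   %.6f" % weighted_estimate(ws, x1))

res = cube_thin(chain, H, m=100, seed=7, weights=ws)
print("subsample size:      %d" % res.achieved_size)
print("omega (total |w|):   %.6f" % res.omega)
print("cube estimate of x1: %.6f" % evaluate_signed_measure(res, x1[res.indices]))
```

prints

```
plain mean of x1:    0.497118
weighted estimate:   0.500000
subsample size:      100
omega (total |w|):   1.000000
cube estimate of x1: 0.523341
```

The weighted estimate of the mean is exact (for a Gaussian target,
`x − μ` lies in the span of the score variates, so the regression pins it);
the 100-point cube estimate adds only the resampling noise of the few
components left fractional at the end of the flight, and is far more
accurate than a 100-point standard thinning of the same chain on average.
The `dropping dependent control variates: h21` log line is expected in
d = 2: the seven design columns are all quadratic polynomials of `x`, which
span a six-dimensional space, so one column is redundant and is removed.

## Command line

```sh
cubethin demo gaussian --d 2 --n 5000 --m 50 --seed 1 --out demo_g
cubethin thin --chain chain.csv --cv full --m 100 --seed 1 --out run
cubethin metrics --ref chain.csv --sub run.subsample.csv \
    --metric ed --metric star --n-boxes 1024 --seed 2
```

`demo` generates a synthetic target (a correlated Gaussian with exact
scores, or a 10-dimensional lower-truncated Gaussian sampled with a
random-scan Gibbs sampler), runs the whole pipeline, and writes chain,
weights, subsample and a JSON manifest with every derived seed. The
manifest for the command above reports `achieved_size: 50`,
`energy_distance: 0.0131`, `star_discrepancy: 0.1236`, `ksd: 0.0203`.

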
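# Methods

This note records the model behind `cubethin`, the numerical choices made
where the mathematics leaves freedom, and what the synthetic experiments
do and do not establish.

## Control-variate reweighting

Given a chain `X_1..X_N` and `J` functions with `p(h_j) = 0`, the package
forms the design matrix `H` (leading ones column, then `h_j(X_n)`) and the
weights `w = H(HᵀH)⁻¹e₁`, computed as the minimum-norm solution of
`Hᵀw = e₁` via SVD-based least squares rather than an explicit inverse.
The defining identity `Hᵀw = e₁` (weights sum to one; every variate column
is annihilated) holds to machine precision and is what the cube constraints
later preserve on the subsample.

The iid regression formulas are applied to MCMC points deliberately; no
attempt is made to estimate the asymptotic-variance-optimal regression
coefficient for a dependent chain, because that estimate is sampler-specific
and cannot be expressed as an `f`-independent weighting scheme.

**Rank deficiency.** Dependent columns are detected by pivoted QR with a
relative tolerance of `1e-10` and dropped (logged), so the constraint count
handed to the cube method always matches the effective rank. Exact
dependences arise naturally: for a `d`-dimensional Gaussian target the
full score-based set consists of quadratic polynomials of `x`, and for
small `d` the `1 + d + d²` columns exceed the dimension of that polynomial
space. Dropping a dependent column does not change the weights' span, and
the balance identity continues to hold for the dropped column as well.

**Gibbs control variates.** For a random-scan sampler that redraws one
uniformly chosen coordinate per iterate from its full conditional, the
exact one-step conditional expectation is the mixture

`E[x_n[i] | X_{n-1}] = (1 − 1/d)·x_{n-1}[i] + (1/d)·m_i(X_{n-1})`,

where `m_i` is the truncated-normal conditional mean of coordinate `i`.
The variate `x_n[i] − E[x_n[i] | X_{n-1}]` is then a martingale difference,
which gives it zero expectation at stationarity *and* makes its empirical
mean converge at the iid rate. The first iterate has no predecessor and is
dropped; the chain is trimmed to match, and `gibbs_cv_matrix` returns the
trimmed chain alongside the matrix so the two cannot drift apart. The
Gibbs record therefore stores the conditional means of **all** coordinates
at every state, not only the updated one — the mixture above needs them.

## The cube method

The flight phase is a martingale random walk in `[0,1]^{N'}` restricted to
the hyperplane `{π : Aπ = Aπ(0)}`. Numerical choices:

- **Integer snapping.** Components within `ε = 1e-9` of 0 or 1 are snapped
  exactly and never move again. Without a hard snap, float drift across up
  to `N'` steps can leave components at `1 − 1e-16` forever.
- **Direction generation.** The *naive* strategy (default for
  `N' ≤ 1000`, and the test oracle) projects a standard-normal draw onto
  the null space of the fractional-column submatrix with a pseudo-inverse
  cut at `1e-10` of the leading singular value. The *fast* strategy keeps
  a working set of `J+1` fractional units and takes a null vector of the
  `J×(J+1)` submatrix by SVD, making a step `O(J³)` and the flight
  `O(N J³)`. Units are streamed in a seeded random permutation, which
  makes the induced design exchangeable over unit labels; with equal
  probabilities and only the size constraint both strategies then reduce
  to simple random sampling without replacement, which the tests verify
  against exhaustive enumeration.
- **Landing.** *Suppression* (default) re-runs the flight after removing
  constraint rows from the last upward; the first row — the fixed-size
  row — is never removed, so the subsample size is exact whenever the
  probabilities sum to an integer (always the case inside `cube_thin`). If
  a single fractional component survives (possible only for non-integer
  totals), it is Bernoulli-rounded, preserving the expectation.
  *Enumeration* (for `q ≤ 15` fractional components) solves a linear
  program over distributions on the `2^q` completions — expectation fixed
  to `π*`, expected squared constraint violation minimized — and samples
  from the optimum. Both strategies preserve `E[S] = π*`; they may differ
  from each other (and from other implementations) in the joint law beyond
  the mean, which no downstream guarantee relies on.

## Cube thinning

`cube_thin` chains the stages: weights → scaling `Wₙ = M|wₙ|/Ω` →
duplication of overweight points → constraint matrix
(ones row, then `sgn(wₙ)h_j(Xₙ)` rows) → flight → landing.

- **Overweight points.** A point with `Wₙ > 1` is replaced by `⌈Wₙ⌉`
  copies of weight `Wₙ/⌈Wₙ⌉`. The ceiling is deliberate: `⌊Wₙ⌋` copies of
  `Wₙ/⌊Wₙ⌋` would still exceed one for non-integer `Wₙ` (2.5 → two copies
  of 1.25) and would not be valid inclusion probabilities.
- **Zero weights.** Points with `|wₙ| < 1e-14` are excluded from the cube
  problem (inclusion probability zero) with sign `+1` by convention.
- **Burn-in** is never removed automatically. The exported weights file
  supports the visual diagnostic: early pre-convergence states receive
  small or negative weights because the regression must discount them to
  satisfy the zero-expectation constraints, so plotting `wₙ` against `n`
  exposes the burn-in period directly.
- **Balance.** The signed form `Σ_{Sₙ=1} sgn(wₙ)h_j(Xₙ) = 0` is what the
  constraint matrix encodes; it holds exactly when the flight ends on a
  vertex and approximately (error confined to the ≤ J components resolved
  by the landing) otherwise.

## Discrepancy metrics

- **Stein kernel.** Closed-form derivatives of the inverse multiquadric
  `k(x,y) = (1+‖x−y‖²/ℓ²)^{−1/2}`; with `r = x−y`:
  `∇x k = −(1/ℓ²)(1+s)^{−3/2} r` and
  `∇x·∇y k = (d/ℓ²)(1+s)^{−3/2} − (3/ℓ⁴)‖r‖²(1+s)^{−5/2}`,
  `s = ‖r‖²/ℓ²`. The median rule sets `ℓ²` to the median pairwise squared
  distance of the point set being scored (a fixed `ℓ` can be supplied; the
  choice of which point set feeds the median rule matters when comparing
  subsamples of very different sizes and is left to the caller).
- **Energy distance.** Weighted V-statistic double sums. Signed weights
  are plugged into the same bilinear forms; the result reduces to the
  classical energy distance for probability weights but may be negative
  for signed inputs — it is reported as computed, not clamped. The signed
  cube measure has total mass `(Ω/M)Σ sgn ≈ 1`; `signed_empirical`
  renormalizes by that total so measures entering the metrics have mass
  exactly one.
- **Star discrepancy.** The map ψ whitens with the Cholesky factor of the
  reference covariance and applies the standard-normal CDF componentwise,
  landing in `(0,1)^d` as the anchored-box construction requires. Full
  covariance whitening (rather than per-component scaling) is used because
  "unit variance" for a multivariate sample is read as identity
  covariance; an exactly singular covariance falls back to per-component
  scaling with a warning. Cholesky whitening is exactly invariant under
  lower-triangular positive-diagonal affine maps (whitening is only ever
  defined up to rotation). The supremum over boxes is replaced by a
  maximum over `n_boxes = 1024` seeded uniform corners; with a shared
  seed the box sequence is nested in `n_boxes`, so estimates are
  monotone in the box budget.

## Synthetic data: what it emulates and what it does not

The generators supply the two regimes the method is designed for: Gaussian
targets with exact scores (iid or random-walk Metropolis chains,
proposal scale `2.38/√d` preconditioned by the target covariance), and a
lower-truncated multivariate Gaussian (mean standard normal, covariance a
Gram matrix `MᵀM` of a standard-normal matrix, ridge `1e-8·I` if nearly
singular, support `[0,∞)^d`) sampled by random-scan Gibbs with
inverse-CDF truncated-normal draws (deterministic draw count, exact
seeding; upper-tail quantiles computed via `Φ⁻¹` of the survival mass, so
the far tail is accurate, with a clamp and a logged warning below
`1e-15` tail mass). All generators thread one explicit RNG object.

These targets are log-concave, unimodal, and have tractable conditionals.
Passing tests therefore demonstrate the algebraic guarantees (weight
identities, exact size, balance, conditional unbiasedness, martingale
laws) and variance reduction *in this regime*; they say nothing about
multimodal targets, heavy tails, or chains whose control variates are
weakly correlated with the functions of interest, where the weighted
estimate can be no better than the plain mean.

## Problem sizes

Distributional test checks use replicate counts (e.g. 2000 flight
replicates, 400 thinning runs, 100-seed variance comparisons) and chain
lengths (500–10⁵) chosen so that 3-standard-error and 1%-level χ² margins
have reasonable power while the whole suite stays in the minutes range;
the truncated-normal pipeline check runs the full 10⁵-iterate, d = 10,
M = 100 configuration and shares its chain across tests via a fixture.

## Known limitations

- The enumeration landing is exponential in the number of fractional
  components and refuses `q > 15`.
- Condition (c) balance is exact only at vertex flight exits; otherwise
  the landing perturbs it by the resolved fractional components. This is
  inherent to the method, not an implementation gap.
- KSD is evaluated as a full `O(m²)` double sum; scoring a full 10⁵-point
  chain directly is memory-prohibitive and not the intended use (score
  subsamples, or pre-thin the reference).
- `TargetSpec` covers (truncated) Gaussian targets only; user-supplied
  chains with arbitrary targets enter through `ChainSample` plus
  externally computed scores.
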
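"""Synthetic targets and chains with known structure.

Every downstream stage of the pipeline (control variates, cube resampling,
discrepancy metrics) is exercised against targets whose score function and
conditional moments are available in closed form:

* multivariate Gaussians ``N(mu, Sigma)``, whose score is
  ``s_p(x) = -Sigma^{-1} (x - mu)``;
* multivariate Gaussians truncated below componentwise, sampled with a
  random-scan Gibbs sampler whose full conditionals are univariate truncated
  normals.

All generators accept either an integer seed or a ``numpy.random.Generator``
and are bit-reproducible; no global random state is touched.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.special import erfcx, ndtr, ndtri

logger = logging.getLogger(__name__)

__all__ = [
    "TargetSpec",
    "GibbsRecord",
    "ChainSample",
    "as_generator",
    "gaussian_score",
    "make_gaussian_chain",
    "make_truncated_params",
    "truncated_conditional_mean",
    "truncated_gibbs_chain",
]

_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)


def as_generator(seed) -> np.random.Generator:
    """Coerce an int seed or an existing Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class TargetSpec:
    """A (possibly truncated) multivariate Gaussian target.

    Parameters
    ----------
    mean : (d,) array
    cov : (d, d) symmetric positive-definite array
    family : {"gaussian", "truncated_gaussian"}
    lower : (d,) array of lower truncation bounds, ``-inf`` allowed.
        Ignored for the plain Gaussian family.
    """

    mean: np.ndarray
    cov: np.ndarray
    family: str = "gaussian"
    lower: np.ndarray | None = None

    def __post_init__(self):
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        d = mean.shape[0]
        if d < 1:
            raise ValueError("dimension must be >= 1")
        if cov.shape != (d, d):
            raise ValueError(f"cov must be {d}x{d}, got {cov.shape}")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("cov must be symmetric")
        try:
            cholesky(cov, lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises its own
            raise ValueError("cov must be positive definite") from exc
        except Exception as exc:
            raise ValueError("cov must be positive definite") from exc
        if self.family not in ("gaussian", "truncated_gaussian"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "truncated_gaussian":
            lower = self.lower
            if lower is None:
                lower = np.zeros(d)
            lower = np.broadcast_to(np.asarray(lower, dtype=float), (d,)).copy()
            object.__setattr__(self, "lower", lower)

    @property
    def d(self) -> int:
        return self.mean.shape[0]

    @property
    def chol(self) -> np.ndarray:
        return cholesky(self.cov, lower=True)


@dataclass(frozen=True)
class GibbsRecord:
    """Per-iterate bookkeeping of a random-scan Gibbs run.

    ``coord[n]`` is the coordinate redrawn at iterate ``n`` and
    ``cond_mean[n]`` the truncated-normal conditional mean of that coordinate
    given the predecessor state.  ``all_cond_means[n]`` holds the truncated
    conditional means of *every* coordinate given ``states[n]`` (the state at
    row ``n``), which is what the random-scan control variates consume.
    """

    coord: np.ndarray
    cond_mean: np.ndarray
    all_cond_means: np.ndarray


@dataclass(frozen=True)
class ChainSample:
    """An MCMC chain, optionally carrying scores and Gibbs metadata."""

    states: np.ndarray
    scores: np.ndarray | None = None
    gibbs_record: GibbsRecord | None = None
    seed: int | None = None
    sampler: str = "unknown"
    target: TargetSpec | None = field(default=None, repr=False)

    def __post_init__(self):
        states = np.atleast_2d(np.asarray(self.states, dtype=float))
        object.__setattr__(self, "states", states)
        if states.shape[0] < 2:
            raise ValueError("a chain needs at least 2 states")
        if self.scores is not None:
            scores = np.asarray(self.scores, dtype=float)
            if scores.shape != states.shape:
                raise ValueError("scores must have the same shape as states")
            object.__setattr__(self, "scores", scores)

    @property
    def n(self) -> int:
        return self.states.shape[0]

    @property
    def d(self) -> int:
        return self.states.shape[1]


def gaussian_score(target: TargetSpec, x: np.ndarray) -> np.ndarray:
    """Score ``s_p(x) = -Sigma^{-1}(x - mu)`` of a Gaussian target.

    ``x`` may be a single point ``(d,)`` or a batch ``(n, d)``; the output
    matches the input shape.
    """
    if target.family != "gaussian":
        raise ValueError("gaussian_score requires a gaussian target")
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    pts = np.atleast_2d(x)
    if not np.all(np.isfinite(pts)):
        raise ValueError("x must be finite")
    c = cho_factor(target.cov, lower=True)
    out = -cho_solve(c, (pts - target.mean).T).T
    return out[0] if single else out


def make_gaussian_chain(
    target: TargetSpec,
    n: int,
    seed,
    mode: str = "iid",
    proposal_scale: float | None = None,
) -> ChainSample:
    """Draw a chain from a Gaussian target with scores attached.

    ``mode="iid"`` gives exact independent draws; ``mode="rwm"`` runs a
    random-walk Metropolis sampler with Gaussian proposals preconditioned by
    the target covariance, with the usual ``2.38/sqrt(d)`` step scale.
    """
    if target.family != "gaussian":
        raise ValueError("make_gaussian_chain requires a gaussian target")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = as_generator(seed)
    d = target.d
    L = target.chol
    if mode == "iid":
        z = rng.standard_normal((n, d))
        states = target.mean + z @ L.T
    elif mode == "rwm":
        if proposal_scale is None:
            proposal_scale = 2.38 / math.sqrt(d)
        c = cho_factor(target.cov, lower=True)

        def logpdf(pt):
            r = pt - target.mean
            return -0.5 * r @ cho_solve(c, r)

        states = np.empty((n, d))
        x = target.mean.copy()
        lp = logpdf(x)
        for t in range(n):
            prop = x + proposal_scale * (L @ rng.standard_normal(d))
            lp_prop = logpdf(prop)
            if math.log(rng.random()) < lp_prop - lp:
                x, lp = prop, lp_prop
            states[t] = x
    else:
        raise ValueError(f"unknown mode {mode!r}")
    scores = gaussian_score(target, states)
    return ChainSample(
        states=states,
        scores=scores,
        sampler=f"gaussian_{mode}",
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        target=target,
    )


def make_truncated_params(d: int, seed) -> TargetSpec:
    """Random truncated-Gaussian target: mean ~ N(0, I), Sigma = M^T M.

    Entries of ``M`` are standard normal; the support is ``[0, inf)^d``.
    A near-singular Gram matrix (min eigenvalue < 1e-10) gets a ``1e-8``
    diagonal ridge.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    rng = as_generator(seed)
    mean = rng.standard_normal(d)
    m = rng.standard_normal((d, d))
    cov = m.T @ m
    if np.linalg.eigvalsh(cov).min() < 1e-10:
        cov = cov + 1e-8 * np.eye(d)
    return TargetSpec(mean=mean, cov=cov, family="truncated_gaussian", lower=np.zeros(d))


def _mills_ratio(alpha: np.ndarray) -> np.ndarray:
    """phi(a) / (1 - Phi(a)), the hazard of the standard normal."""
    return _SQRT_2_OVER_PI / erfcx(np.asarray(alpha, dtype=float) / math.sqrt(2.0))


class _ConditionalCache:
    """Precomputed full-conditional structure of a Gaussian.

    With precision ``P = Sigma^{-1}`` the conditional of coordinate ``i``
    given the rest is ``N(m_i, s_i^2)`` with ``s_i^2 = 1/P_ii`` and
    ``m = mu + C (x - mu)`` where ``C = -diag(P)^{-1} P`` off-diagonal,
    zero on the diagonal.
    """

    def __init__(self, target: TargetSpec):
        c = cho_factor(target.cov, lower=True)
        prec = cho_solve(c, np.eye(target.d))
        pdiag = np.diag(prec)
        if np.any(pdiag <= 0):
            raise FloatingPointError("non-positive conditional variance")
        self.sd = 1.0 / np.sqrt(pdiag)
        self.coef = -prec / pdiag[:, None]
        np.fill_diagonal(self.coef, 0.0)
        self.mean = target.mean
        self.lower = (
            target.lower
            if target.lower is not None
            else np.full(target.d, -np.inf)
        )

    def cond_means(self, x: np.ndarray) -> np.ndarray:
        """Untruncated conditional means of every coordinate given ``x``."""
        return self.mean + self.coef @ (x - self.mean)

    def truncated_means(self, x: np.ndarray) -> np.ndarray:
        """Truncated conditional means of every coordinate given ``x``."""
        m = self.cond_means(x)
        out = m.copy()
        fin = np.isfinite(self.lower)
        if np.any(fin):
            alpha = (self.lower[fin] - m[fin]) / self.sd[fin]
            out[fin] = m[fin] + self.sd[fin] * _mills_ratio(alpha)
        return out


def truncated_conditional_mean(target: TargetSpec, x: np.ndarray, i: int) -> float:
    """E[x_i | x_{-i}] under the truncated-normal full conditional.

    The untruncated conditional is ``N(m_i, s_i^2)`` by Gaussian
    conditioning; truncation below at ``lower[i]`` shifts the mean to
    ``m_i + s_i * phi(alpha)/(1 - Phi(alpha))`` with
    ``alpha = (lower[i] - m_i)/s_i``.  A bound of ``-inf`` returns ``m_i``.
    """
    if target.family != "truncated_gaussian":
        raise ValueError("requires a truncated_gaussian target")
    x = np.asarray(x, dtype=float)
    cache = _ConditionalCache(target)
    m = cache.cond_means(x)[i]
    s = cache.sd[i]
    b = cache.lower[i]
    if not np.isfinite(b):
        return float(m)
    alpha = (b - m) / s
    return float(m + s * _mills_ratio(np.array(alpha)))


def _sample_lower_truncnorm(rng, m, s, lower):
    """Inverse-CDF draw from N(m, s^2) truncated below at ``lower``."""
    if not np.isfinite(lower):
        return m + s * rng.standard_normal()
    alpha = (lower - m) / s
    q = ndtr(-alpha)  # upper-tail mass above the bound
    if q < 1e-15:
        logger.warning(
            "truncated-normal tail mass %.3e below representable range; "
            "clamping quantile",
            q,
        )
    p = (1.0 - rng.random()) * q
    p = max(p, 1e-300)
    z = -ndtri(p)
    return max(m + s * z, lower)


def truncated_gibbs_chain(target: TargetSpec, n: int, seed) -> ChainSample:
    """Random-scan Gibbs sampler for a lower-truncated Gaussian.

    Each iterate redraws one uniformly chosen coordinate from its univariate
    truncated-normal full conditional (inverse-CDF sampling, so the draw
    count is deterministic and seeding exact).  The returned chain carries a
    :class:`GibbsRecord` with the update metadata needed by the Gibbs
    control variates.
    """
    if target.family != "truncated_gaussian":
        raise ValueError("requires a truncated_gaussian target")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = as_generator(seed)
    d = target.d
    cache = _ConditionalCache(target)
    lower = cache.lower

    # Seeded starting point: independent draws from the marginal-variance
    # truncated normals (ignores correlations; only the start point).
    x = np.empty(d)
    sd_marg = np.sqrt(np.diag(target.cov))
    for i in range(d):
        x[i] = _sample_lower_truncnorm(rng, target.mean[i], sd_marg[i], lower[i])

    states = np.empty((n, d))
    coords = np.empty(n, dtype=np.int64)
    cond_mean = np.empty(n)
    all_cm = np.empty((n, d))

    # Untruncated conditional means track the state by rank-one updates:
    # changing x[i] leaves m_i alone and shifts m_j by coef[j, i] * dx.
    m = cache.cond_means(x)
    tm_prev = _truncated_from_cond(m, cache.sd, lower)
    for t in range(n):
        i = int(rng.integers(d))
        coords[t] = i
        cond_mean[t] = tm_prev[i]
        new = _sample_lower_truncnorm(rng, m[i], cache.sd[i], lower[i])
        dx = new - x[i]
        x[i] = new
        # coef has zero diagonal, so m[i] is untouched (depends on x_{-i} only)
        m = m + cache.coef[:, i] * dx
        states[t] = x
        tm_prev = _truncated_from_cond(m, cache.sd, lower)
        all_cm[t] = tm_prev

    record = GibbsRecord(coord=coords, cond_mean=cond_mean, all_cond_means=all_cm)
    return ChainSample(
        states=states,
        gibbs_record=record,
        sampler="truncated_gibbs",
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        target=target,
    )


def _truncated_from_cond(m, sd, lower):
    out = m.copy()
    fin = np.isfinite(lower)
    if np.any(fin):
        alpha = (lower[fin] - m[fin]) / sd[fin]
        out[fin] = m[fin] + sd[fin] * _mills_ratio(alpha)
    return out
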
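"""Discrepancy metrics for scoring a compressed sample against a target.

Three criteria:

* **kernel Stein discrepancy (KSD)** — the bilinear form of the Stein
  kernel ``k_p`` derived from an inverse-multiquadric base kernel
  ``k(x,y) = (1 + |x-y|^2 / l^2)^{-1/2}``:

      k_p(x,y) = div_x div_y k + <grad_x k, s_p(y)> + <grad_y k, s_p(x)>
                 + k(x,y) <s_p(x), s_p(y)>

  which needs only the score ``s_p`` of the target, not its normalizing
  constant.  The lengthscale defaults to the median of pairwise squared
  distances of the scored point set.
* **energy distance** — ``ED(F,G) = 2 E|Z-X| - E|Z-Z'| - E|X-X'|`` as a
  weighted V-statistic over the support points; signed weights are plugged
  into the same bilinear sums, which reduces to the classical definition
  for probability weights (ED may then be negative; it is reported as is).
* **star discrepancy** — after mapping both samples to ``[0,1]^d`` with a
  whitening + standard-normal-CDF transform fitted on the reference, the
  maximum absolute difference of the two (signed) measures over randomly
  drawn anchored boxes ``[0, b]``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.spatial.distance import cdist, pdist
from scipy.special import ndtr

from .targets import as_generator

logger = logging.getLogger(__name__)

__all__ = [
    "SteinKernelSpec",
    "SignedEmpirical",
    "stein_kernel",
    "stein_kernel_gram",
    "ksd",
    "energy_distance",
    "psi_transform",
    "star_discrepancy",
]


@dataclass(frozen=True)
class SteinKernelSpec:
    """Inverse-multiquadric Stein kernel configuration.

    ``rule="median"`` sets ``l^2`` to the median pairwise squared distance
    of the point set being scored; ``rule="fixed"`` uses ``lengthscale``.
    """

    lengthscale: float | None = None
    rule: str = "median"
    family: str = "imq"

    def __post_init__(self):
        if self.family != "imq":
            raise ValueError("only the inverse multiquadric kernel is supported")
        if self.rule not in ("median", "fixed"):
            raise ValueError(f"unknown lengthscale rule {self.rule!r}")
        if self.rule == "fixed" and (
            self.lengthscale is None or self.lengthscale <= 0
        ):
            raise ValueError("fixed rule needs a positive lengthscale")

    def resolve(self, points: np.ndarray) -> float:
        if self.rule == "fixed":
            return float(self.lengthscale)
        pts = np.atleast_2d(points)
        if pts.shape[0] < 2:
            return 1.0 if self.lengthscale is None else float(self.lengthscale)
        med = float(np.median(pdist(pts, "sqeuclidean")))
        if med <= 0.0:
            return 1.0
        return float(np.sqrt(med))


@dataclass(frozen=True)
class SignedEmpirical:
    """A finitely supported (possibly signed) measure with total mass one."""

    points: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self):
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        object.__setattr__(self, "points", pts)
        if not np.all(np.isfinite(pts)):
            raise ValueError("support points must be finite")
        if self.weights is None:
            w = np.full(pts.shape[0], 1.0 / pts.shape[0])
        else:
            w = np.asarray(self.weights, dtype=float)
            if w.shape[0] != pts.shape[0]:
                raise ValueError("weights must align with points")
            if abs(w.sum() - 1.0) > 1e-10:
                raise ValueError("weights must sum to one")
        object.__setattr__(self, "weights", w)

    @property
    def m(self) -> int:
        return self.points.shape[0]


def stein_kernel_gram(
    points: np.ndarray, scores: np.ndarray, lengthscale: float
) -> np.ndarray:
    """Full m x m Stein-kernel matrix for the IMQ base kernel.

    With ``r = x - y``, ``s = |r|^2 / l^2`` and ``k = (1+s)^{-1/2}``:

        grad_x k = -(1/l^2) (1+s)^{-3/2} r
        div_x div_y k = (d/l^2)(1+s)^{-3/2} - (3/l^4)|r|^2 (1+s)^{-5/2}
    """
    x = np.atleast_2d(points)
    s = np.atleast_2d(scores)
    m, d = x.shape
    ell2 = lengthscale**2
    sq = cdist(x, x, "sqeuclidean")
    base = 1.0 + sq / ell2
    k = base**-0.5
    k3 = base**-1.5
    k5 = base**-2.5
    div_term = (d / ell2) * k3 - (3.0 / ell2**2) * sq * k5
    # <grad_x k, s_p(y)> = -(1/l^2) k3 * <x - y, s_p(y)>
    xs = x @ s.T  # xs[i, j] = <x_i, s_j>
    dots = np.einsum("ij,ij->i", x, s)  # <x_i, s_i>
    r_dot_sy = xs - dots[None, :]  # <x_i - x_j, s_p(x_j)>
    r_dot_sx = dots[:, None] - xs.T  # <x_i - x_j, s_p(x_i)>
    cross = -(1.0 / ell2) * k3 * (r_dot_sy - r_dot_sx)
    return div_term + cross + k * (s @ s.T)


def stein_kernel(
    x: np.ndarray,
    y: np.ndarray,
    score_x: np.ndarray,
    score_y: np.ndarray,
    spec: SteinKernelSpec | None = None,
    lengthscale: float | None = None,
) -> float:
    """Stein kernel ``k_p(x, y)`` for a single pair of points.

    The lengthscale must be fixed (either via ``lengthscale`` or a
    ``rule="fixed"`` spec); the median rule is a property of a point set,
    not of a pair.
    """
    if lengthscale is None:
        if spec is None or spec.rule != "fixed":
            raise ValueError("a fixed lengthscale is required for a single pair")
        lengthscale = spec.lengthscale
    pts = np.vstack([np.atleast_1d(x), np.atleast_1d(y)])
    sc = np.vstack([np.atleast_1d(score_x), np.atleast_1d(score_y)])
    return float(stein_kernel_gram(pts, sc, lengthscale)[0, 1])


def ksd(
    points: np.ndarray,
    scores: np.ndarray,
    weights: np.ndarray | None = None,
    spec: SteinKernelSpec | None = None,
) -> float:
    """Kernel Stein discrepancy ``sum_{m,n} a_m a_n k_p(X_m, X_n)``.

    Uniform weights ``a = 1/m`` by default; signed weights are accepted for
    scoring the signed measure produced by cube thinning.  The full double
    sum is evaluated (O(m^2) memory and time).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    sc = np.atleast_2d(np.asarray(scores, dtype=float))
    if pts.shape[0] == 0:
        raise ValueError("need at least one point")
    if sc.shape != pts.shape:
        raise ValueError("scores must match points in shape")
    if spec is None:
        spec = SteinKernelSpec()
    ell = spec.resolve(pts)
    gram = stein_kernel_gram(pts, sc, ell)
    if weights is None:
        a = np.full(pts.shape[0], 1.0 / pts.shape[0])
    else:
        a = np.asarray(weights, dtype=float)
    return float(a @ gram @ a)


def energy_distance(f: SignedEmpirical, g: SignedEmpirical) -> float:
    """``2 E|Z-X| - E|Z-Z'| - E|X-X'|`` as weighted double sums."""
    wf, wg = f.weights, g.weights
    cross = wf @ cdist(f.points, g.points) @ wg
    within_f = wf @ cdist(f.points, f.points) @ wf
    within_g = wg @ cdist(g.points, g.points) @ wg
    return float(2.0 * cross - within_f - within_g)


def psi_transform(reference: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Map points to ``(0,1)^d``: whiten w.r.t. the reference, then Phi.

    The affine whitening (mean and Cholesky factor of the covariance) is
    fitted on ``reference`` and applied to ``query``; the componentwise
    standard-normal CDF then lands in the unit cube.  A numerically
    singular covariance falls back to per-component standardization.
    """
    ref = np.atleast_2d(np.asarray(reference, dtype=float))
    qry = np.atleast_2d(np.asarray(query, dtype=float))
    if ref.shape[0] < 2:
        raise ValueError("reference sample needs at least 2 points")
    mean = ref.mean(axis=0)
    cov = np.cov(ref, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    try:
        low = cholesky(cov, lower=True)
        # a numerically singular covariance leaves a ~sqrt(eps) pivot
        if np.min(np.diag(low)) <= 1e-6 * np.max(np.diag(low)):
            raise np.linalg.LinAlgError("near-singular covariance")
        z = solve_triangular(low, (qry - mean).T, lower=True).T
    except Exception:
        warnings.warn(
            "reference covariance is numerically singular; falling back to "
            "per-component standardization",
            RuntimeWarning,
            stacklevel=2,
        )
        sd = ref.std(axis=0, ddof=1)
        sd[sd <= 0] = 1.0
        z = (qry - mean) / sd
    return ndtr(z)


def star_discrepancy(
    p: SignedEmpirical,
    q: SignedEmpirical,
    n_boxes: int = 1024,
    seed=0,
) -> float:
    """Max deviation of two measures over random anchored boxes.

    Both supports are pushed through :func:`psi_transform` fitted on ``p``'s
    support; ``n_boxes`` upper corners are drawn uniformly in ``[0,1]^d``
    and the maximum absolute difference of the (signed) box masses is
    returned.  With a shared seed, a larger ``n_boxes`` extends the same
    box sequence, so the estimate is non-decreasing in ``n_boxes``.
    """
    if n_boxes < 1:
        raise ValueError("n_boxes must be >= 1")
    rng = as_generator(seed)
    d = p.points.shape[1]
    up = psi_transform(p.points, p.points)
    uq = psi_transform(p.points, q.points)
    corners = rng.random((n_boxes, d))
    best = 0.0
    chunk = 128
    for lo in range(0, n_boxes, chunk):
        c = corners[lo : lo + chunk]  # (c, d)
        in_p = np.all(up[None, :, :] <= c[:, None, :], axis=2)  # (c, mp)
        in_q = np.all(uq[None, :, :] <= c[:, None, :], axis=2)
        mass_p = in_p @ p.weights
        mass_q = in_q @ q.weights
        best = max(best, float(np.max(np.abs(mass_p - mass_q))))
    return best
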
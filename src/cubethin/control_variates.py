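"""Control-variate design matrices and regression weights.

A control variate is a function ``h`` with known zero expectation under the
target ``p``.  Given ``J`` of them evaluated on a chain, the design matrix

    H[n, 0] = 1,    H[n, j] = h_j(X_n),   j = 1..J

defines reweighting coefficients ``w = H (H^T H)^{-1} e_1`` such that the
weighted average ``sum_n w_n f(X_n)`` equals the intercept of the OLS
regression of ``f(X_n)`` on the control variates — a lower-variance
estimator of ``p(f)`` that does not depend on ``f`` once ``w`` is computed.
The weights satisfy ``H^T w = e_1`` exactly: they sum to one and annihilate
every control-variate column.

Two constructions are provided: score-based variates ``h_i(x) = s_p(x)[i]``
and ``h_ij(x) = 1{i=j} + x[i] s_p(x)[j]`` (requiring the gradient of the
log-density), and Gibbs variates ``x_n[i] - E[x_n[i] | X_{n-1}]`` built from
the one-step conditional expectation of a random-scan Gibbs kernel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import scipy.linalg

from .targets import ChainSample

logger = logging.getLogger(__name__)

__all__ = [
    "ControlVariateMatrix",
    "WeightedSample",
    "score_cv_matrix",
    "gibbs_cv_matrix",
    "compute_weights",
    "weighted_estimate",
    "scale_weights",
]


@dataclass(frozen=True)
class ControlVariateMatrix:
    """N x (J+1) design matrix; first column identically one."""

    matrix: np.ndarray
    labels: tuple[str, ...]
    source: str = "custom"

    def __post_init__(self):
        h = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        object.__setattr__(self, "matrix", h)
        if not np.all(np.isfinite(h)):
            raise ValueError("design matrix contains non-finite entries")
        if not np.all(h[:, 0] == 1.0):
            raise ValueError("first column of the design matrix must be all ones")
        if len(self.labels) != h.shape[1]:
            raise ValueError("labels must match the number of columns")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cv(self) -> int:
        """Number of control variates J (columns beyond the intercept)."""
        return self.matrix.shape[1] - 1

    @property
    def cv_columns(self) -> np.ndarray:
        """The N x J block of control-variate evaluations."""
        return self.matrix[:, 1:]


@dataclass(frozen=True)
class WeightedSample:
    """Signed regression weights and their scaled form.

    ``weights`` sum to one (when produced by :func:`compute_weights`);
    ``omega = sum |w_n|`` is the total absolute mass, ``signs`` the weight
    signs (zero mapped to +1), and ``scaled`` the inclusion-probability
    vector ``W_n = M |w_n| / omega`` once :func:`scale_weights` has run.
    """

    weights: np.ndarray
    omega: float | None = None
    signs: np.ndarray | None = None
    scaled: np.ndarray | None = None
    m: int | None = None
    dropped_columns: tuple[str, ...] = ()


def score_cv_matrix(chain: ChainSample, set_kind: str = "full") -> ControlVariateMatrix:
    """Score-based control variates of first and second order.

    ``set_kind="full"`` yields ``d + d^2`` variates: ``h_i(x) = s_p(x)[i]``
    followed by ``h_ij(x) = 1{i=j} + x[i] s_p(x)[j]`` in row-major ``(i, j)``
    order.  ``set_kind="diagonal"`` keeps only ``i = j`` in the second block,
    for ``2d`` variates total.
    """
    if chain.scores is None:
        raise ValueError(
            "score-based control variates need the score (gradient of the "
            "log target density) attached to the chain"
        )
    x = chain.states
    s = chain.scores
    n, d = x.shape
    cols = [np.ones(n)]
    labels = ["intercept"]
    for i in range(d):
        cols.append(s[:, i])
        labels.append(f"h{i + 1}")
    if set_kind == "full":
        pairs = [(i, j) for i in range(d) for j in range(d)]
    elif set_kind == "diagonal":
        pairs = [(i, i) for i in range(d)]
    else:
        raise ValueError(f"unknown set_kind {set_kind!r}")
    for i, j in pairs:
        cols.append((1.0 if i == j else 0.0) + x[:, i] * s[:, j])
        labels.append(f"h{i + 1}{j + 1}")
    h = np.column_stack(cols)
    return ControlVariateMatrix(
        matrix=h,
        labels=tuple(labels),
        source=f"score_{set_kind}",
    )


def gibbs_cv_matrix(chain: ChainSample) -> tuple[ControlVariateMatrix, ChainSample]:
    """Random-scan Gibbs control variates ``x_n[i] - E[x_n[i] | X_{n-1}]``.

    For a random-scan kernel updating one uniformly chosen coordinate, the
    one-step conditional expectation of coordinate ``i`` mixes the no-move
    and move cases:

        E[x_n[i] | X_{n-1}] = (1 - 1/d) x_{n-1}[i] + (1/d) m_i(X_{n-1})

    where ``m_i`` is the truncated conditional mean of coordinate ``i``
    given the others.  The first iterate has no predecessor and is dropped;
    the trimmed chain (aligned with the matrix rows) is returned alongside.
    """
    rec = chain.gibbs_record
    if rec is None:
        raise ValueError("Gibbs control variates need the chain's gibbs_record")
    x = chain.states
    n, d = x.shape
    prev = x[:-1]
    cur = x[1:]
    cond = rec.all_cond_means[:-1]  # truncated means given the predecessor state
    expected = (1.0 - 1.0 / d) * prev + (1.0 / d) * cond
    cv = cur - expected
    h = np.column_stack([np.ones(n - 1), cv])
    labels = ("intercept",) + tuple(f"g{i + 1}" for i in range(d))
    matrix = ControlVariateMatrix(matrix=h, labels=labels, source="gibbs")
    trimmed = ChainSample(
        states=cur,
        scores=None if chain.scores is None else chain.scores[1:],
        gibbs_record=None,
        seed=chain.seed,
        sampler=chain.sampler,
        target=chain.target,
    )
    return matrix, trimmed


def compute_weights(h: ControlVariateMatrix) -> WeightedSample:
    """Regression weights ``w = H (H^T H)^{-1} e_1``.

    Computed as the minimum-norm solution of ``H^T w = e_1`` (which lies in
    the column space of ``H``, hence equals the closed form) via a
    rank-revealing least-squares solve.  Linearly dependent control-variate
    columns are detected with pivoted QR (relative tolerance ``1e-10``) and
    dropped with a log message, so the effective constraint count matches
    the retained columns.
    """
    mat = h.matrix
    n, p = mat.shape
    if n < p:
        raise ValueError(
            f"need at least as many chain points ({n}) as design columns ({p})"
        )
    _, r, piv = scipy.linalg.qr(mat, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int(np.sum(diag > 1e-10 * diag[0])) if diag[0] > 0 else 0
    kept_idx = np.sort(piv[:rank])
    dropped: tuple[str, ...] = ()
    if rank < p:
        if 0 not in kept_idx:
            raise ValueError(
                "intercept column is linearly dependent on the control "
                "variates; the weight constraints are inconsistent"
            )
        dropped = tuple(h.labels[j] for j in sorted(piv[rank:]))
        logger.warning("dropping dependent control variates: %s", ", ".join(dropped))
        mat = mat[:, kept_idx]
        p = rank
    e1 = np.zeros(p)
    e1[0] = 1.0
    w, *_ = np.linalg.lstsq(mat.T, e1, rcond=None)
    signs = np.where(w < 0, -1.0, 1.0)
    return WeightedSample(
        weights=w,
        omega=float(np.sum(np.abs(w))),
        signs=signs,
        dropped_columns=dropped,
    )


def weighted_estimate(ws: WeightedSample, fvals: np.ndarray) -> float:
    """``sum_n w_n f(X_n)`` — the control-variate estimate of ``p(f)``."""
    f = np.asarray(fvals, dtype=float)
    if f.shape != ws.weights.shape:
        raise ValueError("fvals must align with the weights")
    return float(ws.weights @ f)


def scale_weights(ws: WeightedSample, m: int) -> WeightedSample:
    """Scaled inclusion probabilities ``W_n = M |w_n| / omega``.

    ``omega = sum |w_n|``; afterwards ``W_n >= 0`` and ``sum W_n = M``.
    """
    w = ws.weights
    if not 1 <= m <= w.shape[0]:
        raise ValueError("need 1 <= M <= N")
    omega = float(np.sum(np.abs(w)))
    if omega == 0.0:
        raise ValueError("all weights are zero; the chain is degenerate")
    scaled = m * np.abs(w) / omega
    signs = np.where(w < 0, -1.0, 1.0)
    return replace(ws, omega=omega, signs=signs, scaled=scaled, m=m)
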
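"""Cube thinning: fixed-size signed subsampling of a weighted chain.

Pipeline: regression weights from the control variates, scaling to
inclusion probabilities ``W_n = M |w_n| / omega`` (``omega = sum |w_n|``),
duplication of overweight points, then the cube method with the (J+1)
constraints

    row 1:    sum_n S_n           = M            (exact subsample size)
    row j+1:  sum_{S_n=1} sgn(w_n) h_j(X_n) = 0  (balance on each variate)

The output is the signed measure ``nu_hat = (omega/M) sum_{S_n=1}
sgn(w_n) delta_{X_n}``, an unbiased fixed-size compression of the weighted
chain: conditionally on the chain, ``E[nu_hat(f)] = sum_n w_n f(X_n)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .control_variates import (
    ControlVariateMatrix,
    WeightedSample,
    compute_weights,
    scale_weights,
)
from .cube import BalanceProblem, flight_phase, landing_phase
from .targets import ChainSample, as_generator

logger = logging.getLogger(__name__)

__all__ = [
    "SubsampleResult",
    "expand_overweight",
    "build_constraint_matrix",
    "cube_thin",
    "evaluate_signed_measure",
    "signed_empirical",
]

_ZERO_WEIGHT = 1e-14


@dataclass(frozen=True)
class SubsampleResult:
    """A signed fixed-size subsample of an MCMC chain.

    ``indices`` are 0-based positions in the original chain, with
    multiplicity when a heavily weighted point was duplicated; ``signs``
    carry the signs of the underlying regression weights; ``scale`` is the
    common factor ``omega / M`` of the signed measure.
    """

    indices: np.ndarray
    signs: np.ndarray
    scale: float
    requested_m: int
    achieved_size: int
    omega: float
    diagnostics: dict

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not np.all(np.isin(self.signs, (-1.0, 1.0))):
            raise ValueError("signs must be +/-1")


def expand_overweight(
    w: np.ndarray, signs: np.ndarray, indices: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split any W_n > 1 into ceil(W_n) copies of weight W_n/ceil(W_n).

    Afterwards every weight lies in [0, 1] and the total mass is unchanged;
    copies keep the sign and original-chain index of their parent.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("scaled weights must be nonnegative")
    over = w > 1.0
    if not np.any(over):
        return w.copy(), np.asarray(signs).copy(), np.asarray(indices).copy()
    out_w, out_s, out_i = [], [], []
    for wn, sn, ix in zip(w, signs, indices):
        if wn > 1.0:
            c = math.ceil(wn)
            out_w.extend([wn / c] * c)
            out_s.extend([sn] * c)
            out_i.extend([ix] * c)
        else:
            out_w.append(wn)
            out_s.append(sn)
            out_i.append(ix)
    return (
        np.asarray(out_w, dtype=float),
        np.asarray(out_s, dtype=float),
        np.asarray(out_i, dtype=np.int64),
    )


def build_constraint_matrix(
    h: ControlVariateMatrix, signs: np.ndarray, indices: np.ndarray
) -> np.ndarray:
    """(J+1) x N' constraint matrix: ones row, then sgn(w_n) h_j(X_n)."""
    signs = np.asarray(signs, dtype=float)
    indices = np.asarray(indices, dtype=np.int64)
    cv = h.cv_columns[indices]  # N' x J
    return np.vstack([np.ones(indices.shape[0]), (signs[:, None] * cv).T])


def cube_thin(
    chain: ChainSample,
    h: ControlVariateMatrix,
    m: int,
    seed,
    landing_strategy: str = "suppression",
    flight_strategy: str = "auto",
    weights: WeightedSample | None = None,
) -> SubsampleResult:
    """Compress ``chain`` into a signed subsample of exactly ``m`` points.

    ``h`` must be the control-variate design built from this chain (same
    row order and length).  Precomputed ``weights`` (from
    :func:`cubethin.control_variates.compute_weights` on ``h``) may be
    passed to avoid refitting across repeated resampling runs.
    """
    rng = as_generator(seed)
    n = h.n
    if chain.n != n:
        raise ValueError(
            f"design matrix has {n} rows but the chain has {chain.n} states; "
            "for Gibbs control variates use the trimmed chain"
        )
    if not 1 <= m <= n:
        raise ValueError("need 1 <= M <= N")
    try:
        ws = compute_weights(h) if weights is None else weights
    except ValueError as exc:
        raise ValueError(f"[weights] {exc}") from exc
    nonzero = np.flatnonzero(np.abs(ws.weights) >= _ZERO_WEIGHT)
    if m > nonzero.size:
        raise ValueError(
            f"M={m} exceeds the {nonzero.size} points with nonzero weight"
        )
    ws = scale_weights(ws, m)
    w_nz = ws.scaled[nonzero]
    s_nz = ws.signs[nonzero]
    w_exp, s_exp, idx_exp = expand_overweight(w_nz, s_nz, nonzero)
    a = build_constraint_matrix(h, s_exp, idx_exp)
    problem = BalanceProblem(pi=w_exp, a=a)
    try:
        flight = flight_phase(problem, rng, strategy=flight_strategy)
    except RuntimeError as exc:
        raise RuntimeError(f"[flight] {exc}") from exc
    try:
        s, land_diag = landing_phase(
            flight.pi_star, problem, rng, strategy=landing_strategy
        )
    except (RuntimeError, ValueError) as exc:
        raise RuntimeError(f"[landing] {exc}") from exc
    sel = s == 1
    diagnostics = {
        "flight_iterations": flight.iterations,
        "flight_strategy": flight_strategy,
        "landing": land_diag,
        "n_expanded": int(w_exp.shape[0]),
        "dropped_cv_columns": list(ws.dropped_columns),
        "fractional_at_flight_exit": int(
            np.sum((flight.pi_star > 0) & (flight.pi_star < 1))
        ),
    }
    return SubsampleResult(
        indices=idx_exp[sel],
        signs=s_exp[sel],
        scale=ws.omega / m,
        requested_m=m,
        achieved_size=int(sel.sum()),
        omega=ws.omega,
        diagnostics=diagnostics,
    )


def signed_empirical(res: SubsampleResult, states: np.ndarray):
    """The subsample as a mass-one signed measure over chain states.

    The raw signed measure ``nu_hat`` has total mass ``(omega/M) sum sgn``,
    which is an unbiased estimate of one but not exactly one; for metrics
    that require total mass one the signed weights are renormalized by
    ``nu_hat(1)``.
    """
    from .metrics import SignedEmpirical

    pts = np.asarray(states, dtype=float)[res.indices]
    raw = res.scale * res.signs
    total = raw.sum()
    if abs(total) < 1e-12:
        raise ValueError("signed subsample has (near-)zero total mass")
    return SignedEmpirical(points=pts, weights=raw / total)


def evaluate_signed_measure(res: SubsampleResult, fvals: np.ndarray) -> float:
    """``nu_hat(f) = (omega/M) sum_{selected} sgn(w_n) f(X_n)``.

    ``fvals`` must be aligned with ``res.indices`` (one value per selected
    point, multiplicity included).
    """
    f = np.asarray(fvals, dtype=float)
    if f.shape != res.signs.shape:
        raise ValueError("fvals must align with the selected points")
    return float(res.scale * np.sum(res.signs * f))
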
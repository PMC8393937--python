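"""The cube method for balanced sampling.

Given inclusion probabilities ``pi`` in ``[0,1]^N`` and a constraint matrix
``A`` (J x N), the cube method draws a random 0/1 vector ``S`` with
``E[S] = pi`` while keeping ``A S = A pi`` (almost) surely.  It proceeds in
two phases:

* **flight** — a martingale random walk inside ``[0,1]^N`` intersected with
  the constraint hyperplane.  Each step picks a direction ``u`` in
  ``ker A`` that vanishes on already-integer components, moves to one of
  the two points where the line through ``pi`` along ``u`` exits the cube
  (branch probabilities chosen so the walk is a martingale), and thereby
  rounds at least one more component to 0 or 1.  At exit at most J
  components remain fractional.
* **landing** — resolves the remaining fractional components, either by
  relaxing constraints one at a time (suppression) or by optimizing a
  distribution over the ``2^q`` completions (enumeration).

Two direction strategies are available: a transparent full-size null-space
projection ("naive", the test oracle) and a working-set scheme restricted
to J+1 fractional units at a time ("fast"), which makes one flight step
O(J^3) and the whole flight O(N J^3).  The fast strategy streams units in a
seeded random order so that the induced design is exchangeable over unit
labels.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .targets import as_generator

logger = logging.getLogger(__name__)

__all__ = [
    "BalanceProblem",
    "CubeState",
    "FlightResult",
    "sample_direction",
    "step_lengths",
    "flight_step",
    "flight_phase",
    "landing_phase",
]

_SVD_CUTOFF = 1e-10
_MIN_DIRECTION_NORM = 1e-12


@dataclass(frozen=True)
class BalanceProblem:
    """Inclusion probabilities and linear balancing constraints."""

    pi: np.ndarray
    a: np.ndarray
    eps: float = 1e-9

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        a = np.atleast_2d(np.asarray(self.a, dtype=float))
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "a", a)
        if np.any(pi < -1e-12) or np.any(pi > 1 + 1e-12):
            raise ValueError("inclusion probabilities must lie in [0, 1]")
        if not np.all(np.isfinite(a)):
            raise ValueError("constraint matrix must be finite")
        if a.shape[1] != pi.shape[0]:
            raise ValueError("A and pi have incompatible shapes")
        if a.shape[0] >= pi.shape[0]:
            raise ValueError("need fewer constraints than units")

    @property
    def n_units(self) -> int:
        return self.pi.shape[0]

    @property
    def n_constraints(self) -> int:
        return self.a.shape[0]


@dataclass
class CubeState:
    """Mutable state of the flight walk."""

    pi: np.ndarray
    is_integer: np.ndarray
    t: int = 0

    @classmethod
    def from_problem(cls, problem: BalanceProblem) -> "CubeState":
        pi = np.clip(problem.pi.astype(float).copy(), 0.0, 1.0)
        is_int = _snap(pi, problem.eps)
        return cls(pi=pi, is_integer=is_int)


@dataclass
class FlightResult:
    pi_star: np.ndarray
    iterations: int


def _snap(pi: np.ndarray, eps: float) -> np.ndarray:
    """Round components within eps of {0,1} in place; return integer mask."""
    lo = pi <= eps
    hi = pi >= 1.0 - eps
    pi[lo] = 0.0
    pi[hi] = 1.0
    return lo | hi


def _project_null(a_sub: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Orthogonal projection of v onto ker(a_sub), via a pseudo-inverse."""
    if a_sub.shape[0] == 0:
        return v
    gram = a_sub @ a_sub.T
    pinv = np.linalg.pinv(gram, rcond=_SVD_CUTOFF)
    return v - a_sub.T @ (pinv @ (a_sub @ v))


def sample_direction(
    state: CubeState,
    problem: BalanceProblem,
    rng,
    strategy: str = "naive",
) -> np.ndarray | None:
    """A direction in ker(A) vanishing on integer components, or None.

    Returns ``None`` when no such direction exists (flight phase over).
    The naive strategy projects a standard-normal draw onto the null space
    of the fractional-column submatrix; the fast strategy takes a null
    vector of the submatrix restricted to (at most) J+1 fractional units.
    """
    rng = as_generator(rng)
    frac = np.flatnonzero(~state.is_integer)
    if frac.size == 0:
        return None
    n = problem.n_units
    if strategy == "naive":
        b = problem.a[:, frac]
        for _ in range(10):
            v = rng.standard_normal(frac.size)
            u_f = _project_null(b, v)
            if np.linalg.norm(u_f) > _MIN_DIRECTION_NORM:
                u = np.zeros(n)
                u[frac] = u_f
                return u
        return None
    if strategy == "fast":
        window = frac[: problem.n_constraints + 1]
        u_w = _null_vector(problem.a[:, window])
        if u_w is None:
            # the window is full rank; fall back to the whole fractional set
            b = problem.a[:, frac]
            for _ in range(10):
                v = rng.standard_normal(frac.size)
                u_f = _project_null(b, v)
                if np.linalg.norm(u_f) > _MIN_DIRECTION_NORM:
                    u = np.zeros(n)
                    u[frac] = u_f
                    return u
            return None
        u = np.zeros(n)
        u[window] = u_w
        return u
    raise ValueError(f"unknown strategy {strategy!r}")


def _null_vector(b: np.ndarray) -> np.ndarray | None:
    """A unit vector in ker(b), or None if the kernel is trivial."""
    if b.shape[1] == 0:
        return None
    if b.shape[0] == 0:
        out = np.zeros(b.shape[1])
        out[0] = 1.0
        return out
    _, s, vt = np.linalg.svd(b)
    tol = _SVD_CUTOFF * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    if rank >= b.shape[1]:
        return None
    return vt[-1]


def step_lengths(pi: np.ndarray, u: np.ndarray) -> tuple[float, float]:
    """Largest lambda1, lambda2 > 0 keeping pi + l1*u and pi - l2*u in [0,1]^N."""
    nz = u != 0.0
    if not np.any(nz):
        raise ValueError("direction must be nonzero")
    pi_nz = pi[nz]
    u_nz = u[nz]
    up = u_nz > 0
    lam1 = np.min(np.where(up, (1.0 - pi_nz) / u_nz, -pi_nz / u_nz))
    lam2 = np.min(np.where(up, pi_nz / u_nz, (pi_nz - 1.0) / u_nz))
    if lam1 <= 0.0 or lam2 <= 0.0:
        raise RuntimeError(
            f"degenerate step lengths (l1={lam1:.3e}, l2={lam2:.3e}): "
            "direction points outside the cube from a face"
        )
    return float(lam1), float(lam2)


def flight_step(
    state: CubeState,
    problem: BalanceProblem,
    rng,
    u: np.ndarray | None = None,
    strategy: str = "naive",
) -> CubeState:
    """One martingale move: to ``pi + l1*u`` w.p. ``l2/(l1+l2)``, else ``pi - l2*u``."""
    rng = as_generator(rng)
    if u is None:
        u = sample_direction(state, problem, rng, strategy=strategy)
        if u is None:
            raise RuntimeError("no admissible direction; flight phase is over")
    lam1, lam2 = step_lengths(state.pi, u)
    if rng.random() < lam2 / (lam1 + lam2):
        state.pi += lam1 * u
    else:
        state.pi -= lam2 * u
    np.clip(state.pi, 0.0, 1.0, out=state.pi)
    state.is_integer |= _snap(state.pi, problem.eps)
    state.t += 1
    return state


def flight_phase(
    problem: BalanceProblem,
    rng,
    strategy: str = "auto",
    trace: list | None = None,
) -> FlightResult:
    """Run flight steps until no admissible direction remains.

    Preserves ``A pi`` along the whole trajectory and exits with at most J
    fractional components, in at most N iterations.  ``strategy="auto"``
    selects the working-set scheme for N > 1000 and the naive projection
    below.
    """
    rng = as_generator(rng)
    if strategy == "auto":
        strategy = "fast" if problem.n_units > 1000 else "naive"
    if strategy == "fast":
        return _flight_fast(problem, rng, trace)
    state = CubeState.from_problem(problem)
    budget = problem.n_units + problem.n_constraints
    while True:
        u = sample_direction(state, problem, rng, strategy=strategy)
        if u is None:
            break
        if state.t >= budget:
            raise RuntimeError(
                "flight budget exceeded; numerical drift suspected"
            )
        flight_step(state, problem, rng, u=u)
        if trace is not None:
            trace.append(state.pi.copy())
    return FlightResult(pi_star=state.pi, iterations=state.t)


def _flight_fast(problem: BalanceProblem, rng, trace=None) -> FlightResult:
    """Working-set flight: J+1 fractional units at a time, random order."""
    eps = problem.eps
    a = problem.a
    j = problem.n_constraints
    pi = np.clip(problem.pi.astype(float).copy(), 0.0, 1.0)
    is_int = _snap(pi, eps)
    stream = list(rng.permutation(np.flatnonzero(~is_int)))
    stream.reverse()  # pop() from the end
    active: list[int] = []
    t = 0
    budget = problem.n_units + j
    while True:
        while len(active) < j + 1 and stream:
            active.append(int(stream.pop()))
        if not active:
            break
        idx = np.asarray(active)
        u_w = _null_vector(a[:, idx])
        if u_w is None:
            if stream:  # cannot happen: window below J+1 only when exhausted
                raise RuntimeError("working set lost rank with units pending")
            break
        if t >= budget:
            raise RuntimeError("flight budget exceeded; numerical drift suspected")
        sub = pi[idx]
        lam1, lam2 = step_lengths(sub, u_w)
        if rng.random() < lam2 / (lam1 + lam2):
            sub = sub + lam1 * u_w
        else:
            sub = sub - lam2 * u_w
        np.clip(sub, 0.0, 1.0, out=sub)
        resolved = _snap(sub, eps)
        pi[idx] = sub
        t += 1
        if np.any(resolved):
            for k in np.flatnonzero(resolved):
                is_int[idx[k]] = True
            active = [int(i) for i, r in zip(idx, resolved) if not r]
        if trace is not None:
            trace.append(pi.copy())
    return FlightResult(pi_star=pi, iterations=t)


def landing_phase(
    pi_star: np.ndarray,
    problem: BalanceProblem,
    rng,
    strategy: str = "suppression",
) -> tuple[np.ndarray, dict]:
    """Resolve remaining fractional components to a vertex with E[s] = pi_star.

    Returns the 0/1 indicator vector together with a diagnostics dict
    (strategy, constraint rows dropped, whether a final Bernoulli rounding
    was needed).

    * ``suppression`` drops constraint rows from the last upward (never the
      first row, by convention the fixed-size row) and resumes the flight
      after each drop.
    * ``enumeration`` (q <= 15 fractional components) solves for a
      distribution over the 2^q completions with expectation ``pi_star``
      minimizing the mean squared constraint violation, then samples from it.
    """
    rng = as_generator(rng)
    eps = problem.eps
    pi = np.clip(np.asarray(pi_star, dtype=float).copy(), 0.0, 1.0)
    _snap(pi, eps)
    diag: dict = {"strategy": strategy, "dropped_rows": [], "bernoulli_rounded": False}
    frac = np.flatnonzero((pi > 0.0) & (pi < 1.0))
    if frac.size == 0:
        return pi.round().astype(np.int64), diag

    if strategy == "enumeration":
        q = frac.size
        if q > 15:
            raise ValueError(
                f"enumeration landing is O(2^q); q={q} > 15 — use suppression"
            )
        _land_enumeration(pi, frac, problem, rng)
        return pi.round().astype(np.int64), diag

    if strategy != "suppression":
        raise ValueError(f"unknown landing strategy {strategy!r}")

    n_rows = problem.n_constraints
    for keep in range(n_rows, 0, -1):
        frac = np.flatnonzero((pi > 0.0) & (pi < 1.0))
        if frac.size == 0:
            break
        if keep < n_rows:
            diag["dropped_rows"].append(keep)  # 0-based row index being dropped
        if frac.size <= keep:  # flight cannot progress on this subproblem
            continue
        sub = BalanceProblem(pi=pi[frac], a=problem.a[:keep, frac], eps=eps)
        res = flight_phase(sub, rng, strategy="naive")
        pi[frac] = res.pi_star
        _snap(pi, eps)
    frac = np.flatnonzero((pi > 0.0) & (pi < 1.0))
    for k in frac:  # at most one component when the size total is integer
        pi[k] = 1.0 if rng.random() < pi[k] else 0.0
        diag["bernoulli_rounded"] = True
    return pi.round().astype(np.int64), diag


def _land_enumeration(pi: np.ndarray, frac: np.ndarray, problem: BalanceProblem, rng):
    q = frac.size
    verts = np.array(list(itertools.product((0.0, 1.0), repeat=q)))
    pf = pi[frac]
    b = problem.a[:, frac]
    dev = verts - pf
    cost = np.einsum("ij,ij->i", dev @ b.T, dev @ b.T)
    a_eq = np.vstack([verts.T, np.ones(verts.shape[0])])
    b_eq = np.concatenate([pf, [1.0]])
    res = linprog(cost, A_eq=a_eq, b_eq=b_eq, bounds=(0.0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"enumeration landing LP failed: {res.message}")
    lam = np.clip(res.x, 0.0, None)
    lam /= lam.sum()
    choice = rng.choice(verts.shape[0], p=lam)
    pi[frac] = verts[choice]
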
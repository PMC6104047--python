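"""Low-level optimisation kernels.

Two primitives back the whole engine:

* linear programs via ``scipy.optimize.linprog`` (HiGHS), used for FBA,
  flux variability, consistency checking and the FASTCORE LPs;
* the quadratic flux minimisation min Σᵢ vᵢ² subject to S·v = 0, fixed
  fluxes and box bounds, solved with OSQP (tight tolerances plus solution
  polishing, i.e. an exact active-set refinement).  The optimum is unique
  (strictly convex objective over a convex set) and the solver is fully
  deterministic: no randomisation anywhere.

A second, independent QP route -- null-space elimination of the equality
constraints followed by the Lawson--Hanson least-distance-programming
transformation to NNLS -- is provided as
:func:`min_norm_qp_nullspace`.  It exists so tests can cross-check the
production optimum against a structurally different algorithm; it
requires equal lower/upper bounds to be folded into the equality system
(done internally) because box-encoded equalities make the LDP geometry
degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy import sparse
from scipy.optimize import linprog, nnls

__all__ = [
    "FluxSolution",
    "lp",
    "min_norm_qp",
    "min_norm_qp_nullspace",
    "LPResult",
]

#: LP feasibility/optimality tolerances passed to HiGHS.
LP_TOL = 1e-9

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "error"}


@dataclass
class FluxSolution:
    """A flux vector with objective value and solver status.

    ``steady_state_residual`` is max |S·v| over metabolites; for an
    optimal solution it is guaranteed ≤ 1e-6.
    """

    fluxes: dict[str, float]
    objective_value: float
    status: str
    steady_state_residual: float
    meta: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    def flux(self, rid: str) -> float:
        return self.fluxes[rid]

    def to_series(self):
        import pandas as pd

        return pd.Series(self.fluxes, name="flux")


@dataclass
class LPResult:
    x: np.ndarray | None
    fun: float | None
    status: str


def lp(
    c: np.ndarray,
    A_eq: sparse.spmatrix | np.ndarray | None,
    b_eq: np.ndarray | None,
    lb: np.ndarray,
    ub: np.ndarray,
    A_ub: sparse.spmatrix | np.ndarray | None = None,
    b_ub: np.ndarray | None = None,
) -> LPResult:
    """Solve min c·x s.t. A_eq x = b_eq, A_ub x ≤ b_ub, lb ≤ x ≤ ub."""
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options={
            "primal_feasibility_tolerance": LP_TOL,
            "dual_feasibility_tolerance": LP_TOL,
        },
    )
    status = _STATUS.get(res.status, "error")
    return LPResult(res.x if res.x is not None else None,
                    float(res.fun) if res.fun is not None else None, status)


def _apply_fixed(
    lb: np.ndarray, ub: np.ndarray, fixed: dict[int, float] | None
) -> tuple[np.ndarray, np.ndarray, str | None]:
    lb = lb.copy()
    ub = ub.copy()
    for j, value in (fixed or {}).items():
        if value < lb[j] - 1e-9 or value > ub[j] + 1e-9:
            return lb, ub, "infeasible"
        lb[j] = ub[j] = value
    return lb, ub, None


def min_norm_qp(
    S: sparse.spmatrix,
    lb: np.ndarray,
    ub: np.ndarray,
    fixed: dict[int, float] | None = None,
) -> tuple[np.ndarray | None, str]:
    """min Σ vᵢ² s.t. S v = 0, v_j = fixed_j, lb ≤ v ≤ ub (via OSQP).

    Returns ``(v, status)`` with status ``optimal`` or ``infeasible``.
    """
    import osqp

    lbw, ubw, bad = _apply_fixed(lb, ub, fixed)
    if bad:
        return None, bad
    m, n = S.shape
    # settle feasibility with one LP first: the ADMM iteration can be very
    # slow to certify borderline-infeasible points (e.g. scan points just
    # below a minimum oxygen requirement)
    probe = lp(np.zeros(n), S, np.zeros(m), lbw, ubw)
    if probe.status != "optimal":
        return None, "infeasible"
    A = sparse.vstack([S, sparse.eye(n)], format="csc")
    lo = np.concatenate([np.zeros(m), lbw])
    hi = np.concatenate([np.zeros(m), ubw])
    prob = osqp.OSQP()
    prob.setup(
        P=sparse.eye(n, format="csc") * 2.0,
        q=np.zeros(n),
        A=A,
        l=lo,
        u=hi,
        eps_abs=1e-10,
        eps_rel=1e-10,
        eps_prim_inf=1e-10,
        eps_dual_inf=1e-10,
        max_iter=200_000,
        polishing=True,
        verbose=False,
    )
    res = prob.solve(raise_error=False)
    status = res.info.status
    if status == "solved":
        return np.asarray(res.x, dtype=float), "optimal"
    if "infeasible" in status:
        return None, "infeasible"
    raise RuntimeError(f"QP solver ended with status {status!r}")


def _ldp_nnls(G: np.ndarray, h: np.ndarray) -> np.ndarray | None:
    """Least-distance program min ||z||₂ s.t. G z ≥ h, via NNLS.

    Lawson & Hanson (1974), ch. 23: solve NNLS min ||E u − f||, u ≥ 0
    with E = [Gᵀ; hᵀ] and f the last unit vector; the residual r = E u − f
    yields z_j = −r_j / r_end.  ||r|| = 0 certifies infeasibility.
    """
    m, k = G.shape
    if m == 0:
        return np.zeros(k)
    E = np.vstack([G.T, h.reshape(1, -1)])
    f = np.zeros(k + 1)
    f[-1] = 1.0
    u, _ = nnls(E, f)
    r = E @ u - f
    if np.linalg.norm(r) <= 1e-12:
        return None  # constraints inconsistent
    return -r[:k] / r[-1]


def min_norm_qp_nullspace(
    S: sparse.spmatrix,
    lb: np.ndarray,
    ub: np.ndarray,
    fixed: dict[int, float] | None = None,
    feas_tol: float = 1e-9,
) -> tuple[np.ndarray | None, str]:
    """Reference implementation of :func:`min_norm_qp` (see module
    docstring); independent of OSQP, used as a cross-check in tests.

    Fixed fluxes *and* every variable with equal bounds are eliminated
    into the equality right-hand side; the remaining equality system is
    removed by an orthonormal null-space basis (SVD).  Because the
    ``lstsq`` particular solution is the minimum-norm one it is
    orthogonal to the null space and the objective separates, leaving a
    pure least-distance program over the box constraints.
    """
    lbw, ubw, bad = _apply_fixed(lb, ub, fixed)
    if bad:
        return None, bad
    n = S.shape[1]
    A = np.asarray(S.todense(), dtype=float)

    pinned = {j: lbw[j] for j in range(n) if lbw[j] == ubw[j]}
    free_idx = np.array([j for j in range(n) if j not in pinned], dtype=int)
    v = np.zeros(n)
    b = np.zeros(A.shape[0])
    if pinned:
        cols = np.array(sorted(pinned), dtype=int)
        vals = np.array([pinned[j] for j in cols])
        v[cols] = vals
        b = b - A[:, cols] @ vals
    Af = A[:, free_idx]

    probe = lp(np.zeros(n), sparse.csr_matrix(A), np.zeros(A.shape[0]), lbw, ubw)
    if probe.status != "optimal":
        return None, "infeasible"

    if free_idx.size == 0:
        return v, "optimal"

    v0, _, _, _ = np.linalg.lstsq(Af, b, rcond=None)
    if np.linalg.norm(Af @ v0 - b) > 1e-7 * max(1.0, np.linalg.norm(b)):
        return None, "infeasible"
    N = scipy.linalg.null_space(Af)

    lo = lbw[free_idx] - v0
    hi = ubw[free_idx] - v0
    if N.shape[1] == 0:
        vf = v0
        if np.any(lo > 10 * feas_tol) or np.any(hi < -10 * feas_tol):
            return None, "infeasible"
    else:
        rows, rhs = [], []
        for i in range(free_idx.size):
            if np.isfinite(lo[i]):
                rows.append(N[i, :])
                rhs.append(lo[i])
            if np.isfinite(hi[i]):
                rows.append(-N[i, :])
                rhs.append(-hi[i])
        G = np.array(rows) if rows else np.zeros((0, N.shape[1]))
        h = np.array(rhs) if rhs else np.zeros(0)
        z = _ldp_nnls(G, h)
        if z is None:
            return None, "infeasible"
        vf = v0 + N @ z
    v[free_idx] = vf
    return v, "optimal"
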
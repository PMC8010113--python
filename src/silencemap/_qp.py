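"""Dense convex QP solver for the clustering core.

Solves   minimize   1/2 x^T P x + q^T x
         subject to l <= A x <= u

with P symmetric PSD, by a primal-dual interior-point method (Mehrotra
predictor-corrector).  Each two-sided row contributes one slack/multiplier
pair per side; the Newton system condenses to a p x p positive-definite
solve, (P + A^T D A) dx = rhs, so a problem with a few hundred sources
takes a few dozen dense Cholesky factorizations regardless of how close
the regularization drives it to a linear program.

The clustering programs always stack [I; 1^T; C] (box rows, one l1-budget
row, a few power rows); ``box_budget=p`` activates a structured path that
assembles A^T D A as diag + rank-1 + C^T D_c C and runs the constraint
matvecs in O(p * phi) instead of O(p^2).  Row equilibration keeps the
scalp-power rows (tiny physical units) well scaled next to the box rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = ["QPResult", "solve_qp", "project_box_budget"]

_BIG = 1e10
_TAU = 0.995          # fraction-to-boundary step factor
_REG = 1e-10          # static KKT regularization


@dataclass
class QPResult:
    x: np.ndarray
    y: np.ndarray           # multipliers (upper minus lower), original row scale
    objective: float
    iterations: int
    primal_residual: float
    dual_residual: float
    converged: bool


class _Rows:
    """Constraint operator: generic dense rows, or structured [I; 1^T; C]."""

    def __init__(self, A: np.ndarray, box_budget: int | None):
        self.A = A
        self.m, self.n = A.shape
        self.structured = (box_budget is not None and box_budget == self.n
                           and self.m >= self.n + 1)
        if self.structured:
            p = self.n
            self.C = np.ascontiguousarray(A[p + 1:])
            self.c_norm = np.linalg.norm(self.C, axis=1)
            self.c_norm[self.c_norm == 0] = 1.0
            self.Cn = self.C / self.c_norm[:, None]
            self.row_norm = np.concatenate(
                [np.ones(p), [np.sqrt(p)], self.c_norm])
        else:
            self.row_norm = np.linalg.norm(A, axis=1)
            self.row_norm[self.row_norm == 0] = 1.0
            self.As = A / self.row_norm[:, None]

    def matvec(self, x: np.ndarray) -> np.ndarray:
        if not self.structured:
            return self.As @ x
        return np.concatenate(
            [x, [x.sum() / np.sqrt(self.n)], self.Cn @ x])

    def rmatvec(self, v: np.ndarray) -> np.ndarray:
        if not self.structured:
            return self.As.T @ v
        p = self.n
        return v[:p] + v[p] / np.sqrt(p) + self.Cn.T @ v[p + 1:]

    def normal_matrix(self, D: np.ndarray, out: np.ndarray) -> np.ndarray:
        """out += As^T diag(D) As."""
        if not self.structured:
            out += self.As.T @ (D[:, None] * self.As)
            return out
        p = self.n
        out[np.diag_indices_from(out)] += D[:p]
        out += D[p] / p
        if self.Cn.shape[0]:
            out += self.Cn.T @ (D[p + 1:, None] * self.Cn)
        return out


def solve_qp(
    P: np.ndarray,
    q: np.ndarray,
    A: np.ndarray,
    l: np.ndarray,
    u: np.ndarray,
    x0: np.ndarray | None = None,
    eps: float = 1e-7,
    max_iter: int = 50,
    box_budget: int | None = None,
) -> QPResult:
    """Solve the two-sided inequality QP to ``eps`` relative residuals."""
    P = np.asarray(P, float)
    q = np.asarray(q, float)
    A = np.asarray(A, float)
    n = q.size
    m = A.shape[0]

    rows = _Rows(A, box_budget)
    row_norm = rows.row_norm
    ls = np.clip(np.asarray(l, float) / row_norm, -_BIG, _BIG)
    us = np.clip(np.asarray(u, float) / row_norm, -_BIG, _BIG)
    # floor the interval width (in equilibrated units): exact equalities
    # otherwise drive the side multipliers unbounded.  The relaxation is
    # ~1e-4 of the row scale, far below the statistical noise in the data
    # behind such constraints.
    center = 0.5 * (us + ls)
    half = np.maximum(0.5 * (us - ls), 5e-5)
    ls = center - half
    us = center + half

    x = np.zeros(n) if x0 is None else np.asarray(x0, float).copy()
    Ax = rows.matvec(x)
    pad = np.maximum(0.1 * (us - ls), 1e-6)
    s_u = np.maximum(us - Ax, pad)
    s_l = np.maximum(Ax - ls, pad)
    z_u = np.ones(m)
    z_l = np.ones(m)

    scale_d = max(float(np.max(np.abs(q), initial=0.0)), 1.0)
    scale_p = max(float(np.max(np.abs(us), initial=0.0)),
                  float(np.max(np.abs(ls), initial=0.0)), 1.0)

    r_prim = r_dual = np.inf
    it = 0
    Ssym = 0.5 * (P + P.T)
    reg = _REG * (1.0 + abs(np.trace(Ssym)) / n)
    best = None
    best_merit = np.inf
    stall = 0
    for it in range(1, max_iter + 1):
        Ax = rows.matvec(x)
        r_d = Ssym @ x + q + rows.rmatvec(z_u - z_l)
        r_u = Ax + s_u - us
        r_l = Ax - s_l - ls
        mu = (s_u @ z_u + s_l @ z_l) / (2 * m)

        r_prim = max(float(np.max(np.abs(r_u), initial=0.0)),
                     float(np.max(np.abs(r_l), initial=0.0)))
        r_dual = float(np.max(np.abs(r_d), initial=0.0))
        merit = max(r_prim / scale_p, r_dual / scale_d, mu / scale_d)
        if merit < best_merit:
            best_merit = merit
            best = (x.copy(), (z_u - z_l).copy(), r_prim, r_dual)
        if (r_prim <= eps * scale_p and r_dual <= eps * scale_d
                and mu <= eps * scale_d):
            break
        if stall >= 8:   # steps collapsed: (near-)infeasible or degenerate
            break

        D = z_u / s_u + z_l / s_l
        M = Ssym.copy()
        M[np.diag_indices_from(M)] += reg
        M = rows.normal_matrix(D, M)
        try:
            K = cho_factor(M, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            try:
                M[np.diag_indices_from(M)] += 1e6 * reg + 1e-8 * np.max(D)
                K = cho_factor(M, lower=True, check_finite=False)
            except np.linalg.LinAlgError:
                break  # numerical breakdown: return the best iterate

        def newton(r_cu: np.ndarray, r_cl: np.ndarray):
            w = (-r_cu + z_u * r_u) / s_u + (r_cl + z_l * r_l) / s_l
            dx = cho_solve(K, -(r_d + rows.rmatvec(w)), check_finite=False)
            Adx = rows.matvec(dx)
            ds_u = -r_u - Adx
            ds_l = Adx + r_l
            dz_u = (-r_cu - z_u * ds_u) / s_u
            dz_l = (-r_cl - z_l * ds_l) / s_l
            return dx, ds_u, ds_l, dz_u, dz_l

        def max_step(v: np.ndarray, dv: np.ndarray) -> float:
            neg = dv < 0
            if not np.any(neg):
                return 1.0
            return min(1.0, float(np.min(-v[neg] / dv[neg])))

        # predictor (affine) step
        dx, ds_u, ds_l, dz_u, dz_l = newton(s_u * z_u, s_l * z_l)
        a_p = min(max_step(s_u, ds_u), max_step(s_l, ds_l))
        a_d = min(max_step(z_u, dz_u), max_step(z_l, dz_l))
        mu_aff = ((s_u + a_p * ds_u) @ (z_u + a_d * dz_u)
                  + (s_l + a_p * ds_l) @ (z_l + a_d * dz_l)) / (2 * m)
        sigma = min((mu_aff / max(mu, 1e-300)) ** 3, 1.0)

        # corrector step
        r_cu = s_u * z_u + ds_u * dz_u - sigma * mu
        r_cl = s_l * z_l + ds_l * dz_l - sigma * mu
        dx, ds_u, ds_l, dz_u, dz_l = newton(r_cu, r_cl)
        a_p = _TAU * min(max_step(s_u, ds_u), max_step(s_l, ds_l))
        a_d = _TAU * min(max_step(z_u, dz_u), max_step(z_l, dz_l))

        x = x + a_p * dx
        s_u = s_u + a_p * ds_u
        s_l = s_l + a_p * ds_l
        z_u = z_u + a_d * dz_u
        z_l = z_l + a_d * dz_l
        stall = stall + 1 if min(a_p, a_d) < 1e-2 else 0

    if best is not None and best_merit < max(r_prim / scale_p,
                                             r_dual / scale_d):
        x, y_best, r_prim, r_dual = best
    else:
        y_best = z_u - z_l
    obj = float(0.5 * x @ (Ssym @ x) + q @ x)
    converged = bool(r_prim <= 100 * eps * scale_p
                     and r_dual <= 100 * eps * scale_d)
    return QPResult(x=x, y=y_best / row_norm, objective=obj,
                    iterations=it, primal_residual=r_prim,
                    dual_residual=r_dual, converged=converged)


def project_box_budget(g: np.ndarray, budget: float) -> np.ndarray:
    """Exact Euclidean projection onto {0 <= g <= 1, sum(g) <= budget}.

    Used to polish solver output so box and l1 constraints hold exactly.
    If the box projection already meets the budget it is returned; otherwise
    the unique shift tau with sum(clip(g - tau, 0, 1)) = budget is found by
    bisection.
    """
    gc = np.clip(g, 0.0, 1.0)
    if gc.sum() <= budget + 1e-12:
        return gc
    lo, hi = 0.0, float(np.max(g))
    for _ in range(100):
        tau = 0.5 * (lo + hi)
        s = np.clip(g - tau, 0.0, 1.0).sum()
        if s > budget:
            lo = tau
        else:
            hi = tau
    return np.clip(g - hi, 0.0, 1.0)
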
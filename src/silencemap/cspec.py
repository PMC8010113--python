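"""Convex spectral clustering (CSpeC): the silence-selection core.

The relaxed indicator g in [0, 1]^p (small entries = silent) minimizes

    beta^T (1 - g)  +  lambda (1 - g)^T L (1 - g)
    s.t.  0 <= g <= 1,   ||g||_1 <= p - k,
    and optionally per-electrode scalp-power constraints
    (1^T (Abar_i C_s_full Abar_i^T) g + sigma_z_i^2 - Var(y_i))^2 <= zeta_i.

The linear term pulls g down where the contribution measure beta is small;
the Laplacian quadratic, equal to 1/2 sum_ij w_ij (g_i - g_j)^2, penalizes
silent/active disagreement between graph neighbors and so forces the k
selected sources to form one contiguous patch (relaxed RatioCut).  The
scalar quadratic power constraints are split into linear pairs, leaving a
convex QP solved by the package's ADMM solver.

lambda is tuned by grid search on the two max-normalized objective terms;
the patch size k is tuned by matching modeled to observed scalp powers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from ._qp import QPResult, project_box_budget, solve_qp
from .estimators import ChannelStats, ContributionVector
from .geometry import NeighborGraph

__all__ = [
    "PowerConstraints",
    "CSpecSolution",
    "build_power_constraints",
    "solve_cspec",
    "default_lambda_grid",
    "tune_lambda",
    "estimate_size",
    "power_mismatch",
]


@dataclass
class PowerConstraints:
    """Linearized per-electrode power constraints for the high-res program.

    Row i encodes c_i^T g + d_i with |.| <= sqrt(zeta_i), where
    c_i = (a~_i^T C_s_full) * a~_i elementwise and d_i = sigma_z_i^2 -
    Var-hat(y_i).  zeta_i is always the squared residual of the fitted
    silence-free model at electrode i, which makes g = 1 feasible by
    construction.
    """

    C: np.ndarray      # (phi, p) linear coefficients
    d: np.ndarray      # (phi,)
    zeta: np.ndarray   # (phi,)
    electrodes: np.ndarray  # indices into the differential channels


def build_power_constraints(
    A_tilde: np.ndarray,
    C_s_full: np.ndarray,
    sigma_z2: np.ndarray,
    var_y: np.ndarray,
    electrodes: Sequence[int],
    zeta_floor_rel: float = 0.0,
) -> PowerConstraints:
    """Assemble the linearized constraints; see :class:`PowerConstraints`.

    ``zeta_floor_rel`` floors sqrt(zeta_i) at that fraction of the observed
    channel power.  When the covariance fit is nearly exact the raw
    residual can fall below the sampling noise of Var-hat(y_i) itself,
    which would demand a power match tighter than the data can support
    (and can make the program infeasible once k > 0); callers pass the
    relative standard error of the variance estimate, ~sqrt(2/T).
    """
    elec = np.asarray(list(electrodes), dtype=int)
    Ae = A_tilde[elec]                      # (phi, p)
    C = (Ae @ C_s_full) * Ae                # row i: (a_i^T C) * a_i
    d = np.asarray(sigma_z2)[elec] - np.asarray(var_y)[elec]
    zeta = (C.sum(axis=1) + d) ** 2         # residual of the full model
    if zeta_floor_rel > 0:
        zeta = np.maximum(zeta,
                          (zeta_floor_rel * np.asarray(var_y)[elec]) ** 2)
    return PowerConstraints(C=C, d=d, zeta=zeta, electrodes=elec)


@dataclass
class CSpecSolution:
    """Relaxed indicator with the silent set read off its smallest entries."""

    g: np.ndarray
    lam: float
    k: int
    silent_set: np.ndarray = field(init=False)
    objective_terms: tuple[float, float] = (0.0, 0.0)
    feasible: bool = True
    qp: QPResult | None = None

    def __post_init__(self) -> None:
        self.silent_set = smallest_k(self.g, self.k)

    @property
    def k_hat(self) -> int:
        return int(self.silent_set.size)


def smallest_k(g: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k smallest entries; ties broken by lowest index."""
    if k <= 0:
        return np.array([], dtype=int)
    order = np.lexsort((np.arange(g.size), g))
    return np.sort(order[:k])


def _objective_terms(beta: np.ndarray, L: np.ndarray,
                     g: np.ndarray) -> tuple[float, float]:
    u = 1.0 - g
    return float(beta @ u), float(u @ (L @ u))


def solve_cspec(
    beta: ContributionVector | np.ndarray,
    L: np.ndarray | NeighborGraph,
    k: int,
    lam: float,
    power_constraints: PowerConstraints | None = None,
    warm: CSpecSolution | None = None,
    eps: float = 1e-7,
) -> CSpecSolution:
    """Solve the CSpeC program at fixed (lambda, k) to solver tolerance.

    The solution is polished by exact projection onto the box and l1
    constraints, so those hold to machine precision.  With power
    constraints, infeasibility (possible only for user-corrupted zeta)
    is flagged rather than raised.
    """
    b = beta.values if isinstance(beta, ContributionVector) else np.asarray(beta, float)
    Lm = L.L if isinstance(L, NeighborGraph) else np.asarray(L, float)
    p = b.size
    if not 0 <= k < p:
        raise ValueError("k must satisfy 0 <= k < p")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")

    # objective in g: beta^T 1 - beta^T g + lam g^T L g   (L @ 1 = 0)
    P = 2.0 * lam * Lm
    q = -b

    rows = [np.eye(p), np.ones((1, p))]
    lo = [np.zeros(p), np.array([0.0])]
    hi = [np.ones(p), np.array([float(p - k)])]
    if power_constraints is not None and power_constraints.C.size:
        pc = power_constraints
        rows.append(pc.C)
        root = np.sqrt(pc.zeta)
        lo.append(-root - pc.d)
        hi.append(root - pc.d)
    A = np.vstack(rows)
    l = np.concatenate(lo)
    u = np.concatenate(hi)

    res = solve_qp(P, q, A, l, u,
                   x0=None if warm is None else warm.g,
                   eps=eps, box_budget=p)
    g = project_box_budget(res.x, float(p - k))

    feasible = True
    if power_constraints is not None and power_constraints.C.size:
        viol = np.abs(power_constraints.C @ g + power_constraints.d) - np.sqrt(
            power_constraints.zeta)
        scale = max(float(np.sqrt(power_constraints.zeta).max()), 1.0)
        feasible = bool(np.max(viol, initial=0.0) <= 1e-5 * scale)

    sol = CSpecSolution(g=g, lam=lam, k=k,
                        objective_terms=_objective_terms(b, Lm, g),
                        feasible=feasible, qp=res)
    return sol


def default_lambda_grid(beta: np.ndarray, L: np.ndarray,
                        n_points: int = 16,
                        span: tuple[float, float] = (1e-4, 1e2)) -> np.ndarray:
    """Log-spaced lambda grid scaled by the beta-to-Laplacian magnitude ratio
    so the two objective terms compete over the grid."""
    b = beta.values if isinstance(beta, ContributionVector) else np.asarray(beta)
    Lm = L.L if isinstance(L, NeighborGraph) else np.asarray(L)
    scale = (np.mean(np.abs(b)) + 1e-300) / (np.mean(np.diag(Lm)) + 1e-300)
    return scale * np.geomspace(span[0], span[1], n_points)


def _tune_lambda(beta, L, k, lambda_grid, power_constraints=None
                 ) -> tuple[float, dict[float, CSpecSolution]]:
    grid = np.asarray(lambda_grid, float)
    if grid.size == 0:
        raise ValueError("lambda grid must be nonempty")
    sols: dict[float, CSpecSolution] = {}
    warm = None
    for lam in grid:
        warm = solve_cspec(beta, L, k, float(lam),
                           power_constraints=power_constraints, warm=warm)
        sols[float(lam)] = warm
    lin = np.array([sols[float(l)].objective_terms[0] for l in grid]) ** 2
    quad = np.array([sols[float(l)].objective_terms[1] for l in grid]) ** 2
    lin_n = lin / max(lin.max(), 1e-300)
    quad_n = quad / max(quad.max(), 1e-300)
    total = lin_n + quad_n
    if np.allclose(total, 0.0):
        return float(grid[0]), sols
    return float(grid[int(np.argmin(total))]), sols


def tune_lambda(beta, L, k, lambda_grid,
                power_constraints: PowerConstraints | None = None) -> float:
    """Grid-searched lambda minimizing the sum of the two squared objective
    terms, each normalized by its maximum over the grid."""
    lam, _ = _tune_lambda(beta, L, k, lambda_grid, power_constraints)
    return lam


@dataclass
class SizeEstimate:
    k_hat: int
    costs: dict[int, float]
    solutions: dict[int, CSpecSolution]
    lambdas: dict[int, float]


def _lowres_power_cost(A_tilde: np.ndarray, silent: np.ndarray,
                       stats: ChannelStats) -> float:
    """Max-normalized scalp-power mismatch for uncorrelated sources: modeled
    power of electrode i is sum_{j not silent} a~_ij^2 (up to sigma_s^2,
    which the normalization removes)."""
    active = np.setdiff1d(np.arange(A_tilde.shape[1]), silent)
    modeled = np.sum(A_tilde[:, active] ** 2, axis=1)
    observed = stats.var_y - stats.sigma_z2
    m = modeled / max(modeled.max(), 1e-300)
    o = observed / max(observed.max(), 1e-300)
    return float(np.sum((m - o) ** 2))


def _highres_power_cost(A_tilde: np.ndarray, C_s_k: np.ndarray,
                        stats: ChannelStats) -> float:
    """Absolute scalp-power mismatch with the fitted covariance model."""
    modeled = np.einsum("ij,jk,ik->i", A_tilde, C_s_k, A_tilde)
    resid = modeled + stats.sigma_z2 - stats.var_y
    return float(np.sum(resid**2))


def estimate_size(
    beta,
    L: np.ndarray | NeighborGraph | Callable[[int], NeighborGraph],
    k_grid: Sequence[int],
    A_tilde: np.ndarray,
    stats: ChannelStats,
    cs_builder: Callable[[np.ndarray], np.ndarray] | None = None,
    lambda_grid: np.ndarray | Mapping[int, np.ndarray] | None = None,
    power_constraints: PowerConstraints | None = None,
) -> SizeEstimate:
    """Estimate the silence size k by scalp-power matching.

    For each k on the grid: build the k-NN graph (when ``L`` is a callable
    of k, matching the z = k convention), tune lambda, solve, take the k
    smallest entries of g as the candidate set, and score the mismatch
    between modeled and observed channel powers — max-normalized
    lead-field powers when sources are uncorrelated (``cs_builder`` None),
    or the fitted covariance model via ``cs_builder(silent_set) -> C_s(k)``.
    Returns the argmin k with per-k diagnostics.
    """
    ks = [int(k) for k in k_grid]
    if not ks:
        raise ValueError("k grid must be nonempty")
    costs: dict[int, float] = {}
    sols: dict[int, CSpecSolution] = {}
    lams: dict[int, float] = {}
    for k in ks:
        Lk = L(k) if callable(L) else L
        grid = (lambda_grid[k] if isinstance(lambda_grid, Mapping)
                else lambda_grid)
        if grid is None:
            grid = default_lambda_grid(beta, Lk)
        lam, per_lambda = _tune_lambda(beta, Lk, k, grid,
                                       power_constraints=power_constraints)
        sol = per_lambda[lam]
        silent = sol.silent_set
        if cs_builder is None:
            cost = _lowres_power_cost(A_tilde, silent, stats)
        else:
            cost = _highres_power_cost(A_tilde, cs_builder(silent), stats)
        costs[k], sols[k], lams[k] = cost, sol, lam
    k_hat = min(ks, key=lambda k: (costs[k], k))
    return SizeEstimate(k_hat=k_hat, costs=costs, solutions=sols,
                        lambdas=lams)


def power_mismatch(A_tilde: np.ndarray, C_s_khat: np.ndarray,
                   stats: ChannelStats) -> float:
    """Reference-selection score: total squared error between the
    max-normalized modeled and observed noise-free channel powers."""
    modeled = np.einsum("ij,jk,ik->i", A_tilde, C_s_khat, A_tilde)
    if not np.any(modeled > 0):
        raise ValueError("modeled scalp power is identically zero")
    observed = stats.var_y - stats.sigma_z2
    m = modeled / modeled.max()
    o = observed / max(observed.max(), 1e-300)
    return float(np.sum((m - o) ** 2))
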
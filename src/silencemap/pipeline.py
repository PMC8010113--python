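"""The full silence-localization pipeline.

Two passes per candidate reference electrode:

1.  **Low resolution.**  On a coarse (decimated) grid the sources are far
    enough apart to be treated as uncorrelated.  The contribution measure
    beta (optionally mirrored into the hemispheric ratio beta~) feeds the
    CSpeC program; lambda and the patch size k are grid-tuned, and the
    center of mass (COM) of the selected patch seeds the second pass.

2.  **High resolution, iterative.**  Starting from the single source
    nearest the low-res COM, each iteration (a) fits the source-covariance
    parameters (gamma, sigma_s) by least squares on the phi electrodes
    least affected by the current silence estimate, (b) recomputes the
    normalized contribution beta_high, (c) re-solves CSpeC with
    per-electrode scalp-power constraints, and (d) updates the patch; it
    stops when the COM moves less than delta over two consecutive
    iterations, or after R iterations.

The reference whose final model gives the smallest scalp power mismatch
(Delta-Pow) wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .cspec import (build_power_constraints, default_lambda_grid,
                    estimate_size, power_mismatch)
from .estimators import (ChannelStats, contribution_highres,
                         contribution_lowres, estimate_channel_stats,
                         hemispheric_ratio)
from .forward import LeadField, Recording, make_reference_scheme
from .geometry import NeighborGraph, SourceGrid, build_graph, decimate_grid

__all__ = [
    "SilenceMapConfig",
    "SilenceMapResult",
    "fit_covariance_params",
    "run_silencemap",
]


@dataclass
class SilenceMapConfig:
    """Tunables of the two-pass algorithm (all config-exposed)."""

    use_baseline: bool = True
    low_res_fraction: float = 0.15      # decimation fraction for pass 1
    phi: int | None = None              # electrodes for the covariance fit;
                                        # default ceil((n-1)/4)
    max_iterations: int = 10            # R
    delta: float | None = None          # COM convergence (mm); default one
                                        # grid spacing
    lambda_points: int = 16
    lambda_span: tuple[float, float] = (1e-4, 1e2)
    k_grid_low: Sequence[int] | None = None    # default 8 pts in [2, p/4]
    k_grid_high: Sequence[int] | None = None
    n_k_points: int = 8
    gamma_bounds: tuple[float, float] = (1e-5, 10.0)  # mm^-2 search range
    stats_method: str = "sample"
    qp_eps: float = 1e-7

    def resolve_phi(self, n_channels: int) -> int:
        phi = self.phi if self.phi is not None else int(np.ceil(n_channels / 4))
        return max(2, min(phi, n_channels))

    def default_k_grid(self, p: int) -> list[int]:
        hi = max(3, p // 4)
        return sorted(set(np.geomspace(2, hi, self.n_k_points).round()
                          .astype(int).tolist()))


@dataclass
class ReferenceResult:
    """Per-reference outcome of the two-pass run."""

    ref: str
    silent_set: np.ndarray
    k_hat: int
    delta_pow: float
    com_trajectory: list[np.ndarray]
    gamma_path: list[float]
    sigma_s_path: list[float]
    converged: bool
    iterations_used: int
    low_res_set: np.ndarray


@dataclass
class SilenceMapResult:
    """Final estimate for the winning reference, with diagnostics."""

    silent_set: np.ndarray
    k_hat: int
    chosen_ref: str
    delta_pow_by_ref: dict[str, float]
    com_trajectory: list[np.ndarray]
    gamma_hat: float
    sigma_s_hat: float
    converged: bool
    iterations_used: int
    per_reference: dict[str, ReferenceResult] = field(default_factory=dict)


def _pairwise_sq(positions: np.ndarray) -> np.ndarray:
    diff = positions[:, None, :] - positions[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def _cov_full(d2: np.ndarray, gamma: float, sigma_s2: float) -> np.ndarray:
    return sigma_s2 * np.exp(-gamma * d2)


def _silenced(C_full: np.ndarray, silent: np.ndarray) -> np.ndarray:
    C = C_full.copy()
    if silent.size:
        C[silent, :] = 0.0
        C[:, silent] = 0.0
    return C


def fit_covariance_params(
    stats: ChannelStats,
    A_tilde: np.ndarray,
    grid: SourceGrid,
    silent_prev: np.ndarray,
    phi: int,
    gamma_prev: float = 1.0,
    sigma_s_prev: float = 1.0,
    gamma_bounds: tuple[float, float] = (1e-5, 10.0),
    d2: np.ndarray | None = None,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """One covariance-refinement step: electrode selection + (gamma, sigma_s).

    The power ratio h_i = (A~ C_s A~^T)_ii / (A~ C_s_full A~^T)_ii in [0, 1]
    ranks electrodes by how little the current silence estimate dims them;
    the top-phi electrodes anchor the least-squares fit of the silence-free
    power model sigma_s^2 (A~ e^{-gamma d^2} A~^T)_ii + sigma_z_i^2 to the
    observed Var-hat(y_i).  For fixed gamma the optimal sigma_s^2 is a
    nonnegative linear least-squares solution, leaving a bounded 1-D search
    over gamma.

    Returns (gamma, sigma_s, selected electrode indices, h).
    """
    if phi < 2:
        raise ValueError("phi must be at least 2")
    silent_prev = np.asarray(silent_prev, dtype=int)
    if d2 is None:
        d2 = _pairwise_sq(grid.positions)
    C_full_prev = _cov_full(d2, gamma_prev, sigma_s_prev**2)
    C_prev = _silenced(C_full_prev, silent_prev)
    denom = np.einsum("ij,jk,ik->i", A_tilde, C_full_prev, A_tilde)
    numer = np.einsum("ij,jk,ik->i", A_tilde, C_prev, A_tilde)
    h = np.where(denom > 0, numer / denom, 0.0)

    order = np.lexsort((np.arange(h.size), -h))
    elec = np.sort(order[:phi])

    Ae = A_tilde[elec]
    target = stats.var_y[elec] - stats.sigma_z2[elec]

    def sigma2_for(gamma: float) -> tuple[float, float]:
        m = np.einsum("ij,jk,ik->i", Ae, np.exp(-gamma * d2), Ae)
        mm = float(m @ m)
        s2 = max(float(m @ target) / mm, 0.0) if mm > 0 else 0.0
        cost = float(np.sum((s2 * m - target) ** 2))
        return s2, cost

    # the cost is not unimodal in log gamma (it flattens once the modeled
    # covariance is effectively diagonal), so bracket the minimum with a
    # coarse grid scan before the bounded 1-D refinement
    lo, hi = np.log10(gamma_bounds[0]), np.log10(gamma_bounds[1])
    try:
        grid_t = np.linspace(lo, hi, 17)
        costs = [sigma2_for(10.0**t)[1] for t in grid_t]
        i0 = int(np.argmin(costs))
        t_lo = grid_t[max(i0 - 1, 0)]
        t_hi = grid_t[min(i0 + 1, grid_t.size - 1)]
        res = minimize_scalar(lambda t: sigma2_for(10.0**t)[1],
                              bounds=(t_lo, t_hi), method="bounded",
                              options={"xatol": 1e-4})
        t_best = res.x if res.fun <= costs[i0] else grid_t[i0]
        gamma = float(10.0**t_best)
        sigma_s2, _ = sigma2_for(gamma)
        if not np.isfinite(gamma) or sigma_s2 <= 0:
            raise RuntimeError
    except Exception:
        gamma, sigma_s2 = gamma_prev, sigma_s_prev**2  # keep previous iterate
    return gamma, float(np.sqrt(sigma_s2)), elec, h


def _graph_cache(grid: SourceGrid) -> "dict[int, NeighborGraph]":
    cache: dict[int, NeighborGraph] = {}

    def get(z: int) -> NeighborGraph:
        z = max(1, min(int(z), grid.p - 1))
        if z not in cache:
            cache[z] = build_graph(grid, z)
        return cache[z]

    get.cache = cache  # type: ignore[attr-defined]
    return get


def _run_one_reference(
    rec: Recording,
    A: np.ndarray,
    M: np.ndarray,
    grid_high: SourceGrid,
    grid_low: SourceGrid,
    low_idx: np.ndarray,
    C_z: np.ndarray,
    config: SilenceMapConfig,
    d2_high: np.ndarray,
) -> ReferenceResult:
    A_high = M @ A
    A_low = A_high[:, low_idx]
    C_z_diff = M @ C_z @ M.T

    # ---- pass 1: low resolution --------------------------------------
    stats_low = estimate_channel_stats(rec.Y, A_low, C_z_diff,
                                       method=config.stats_method,
                                       fs=rec.sampling_rate)
    beta = contribution_lowres(stats_low)
    score = hemispheric_ratio(beta, grid_low) if config.use_baseline else beta

    graphs_low = _graph_cache(grid_low)
    k_grid_low = (list(config.k_grid_low) if config.k_grid_low is not None
                  else config.default_k_grid(grid_low.p))
    lam_grids_low = {
        k: default_lambda_grid(score, graphs_low(k), config.lambda_points,
                               config.lambda_span)
        for k in k_grid_low
    }
    est_low = estimate_size(score, graphs_low, k_grid_low, A_low, stats_low,
                            lambda_grid=lam_grids_low)
    low_set = est_low.solutions[est_low.k_hat].silent_set
    f_com_low = grid_low.com(low_set)

    # ---- pass 2: high resolution, iterative --------------------------
    stats_high = estimate_channel_stats(rec.Y, A_high, C_z_diff,
                                        method=config.stats_method,
                                        fs=rec.sampling_rate)
    d0 = np.linalg.norm(grid_high.positions - f_com_low, axis=1)
    S_prev = np.array([int(np.argmin(d0))])
    com_traj = [grid_high.positions[S_prev[0]].copy()]
    gamma, sigma_s = 1.0, 1.0
    gamma_path: list[float] = []
    sigma_path: list[float] = []
    phi = config.resolve_phi(rec.Y.shape[0])
    delta = config.delta if config.delta is not None else grid_high.spacing()
    graphs_high = _graph_cache(grid_high)
    k_grid_high = (list(config.k_grid_high) if config.k_grid_high is not None
                   else config.default_k_grid(grid_high.p))

    converged = False
    displacements: list[float] = []
    est_high = None
    for r in range(1, config.max_iterations + 1):
        gamma, sigma_s, elec, _h = fit_covariance_params(
            stats_high, A_high, grid_high, S_prev, phi,
            gamma_prev=gamma, sigma_s_prev=sigma_s,
            gamma_bounds=config.gamma_bounds, d2=d2_high)
        gamma_path.append(gamma)
        sigma_path.append(sigma_s)
        C_full = _cov_full(d2_high, gamma, sigma_s**2)

        beta_h = contribution_highres(stats_high, C_full)
        score_h = (hemispheric_ratio(beta_h, grid_high)
                   if config.use_baseline else beta_h)
        pc = build_power_constraints(A_high, C_full, stats_high.sigma_z2,
                                     stats_high.var_y, elec,
                                     zeta_floor_rel=np.sqrt(2.0 / rec.T))
        lam_grids = {
            k: default_lambda_grid(score_h, graphs_high(k),
                                   config.lambda_points, config.lambda_span)
            for k in k_grid_high
        }
        est_high = estimate_size(
            score_h, graphs_high, k_grid_high, A_high, stats_high,
            cs_builder=lambda silent: _silenced(C_full, silent),
            lambda_grid=lam_grids, power_constraints=pc)
        S_prev = est_high.solutions[est_high.k_hat].silent_set
        com = grid_high.com(S_prev)
        displacements.append(float(np.linalg.norm(com - com_traj[-1])))
        com_traj.append(com)
        if r >= 2 and displacements[-1] <= delta and displacements[-2] <= delta:
            converged = True
            break

    k_hat = int(S_prev.size)
    C_final = _silenced(_cov_full(d2_high, gamma, sigma_s**2), S_prev)
    dpow = power_mismatch(A_high, C_final, stats_high)
    return ReferenceResult(ref=rec.ref_name, silent_set=S_prev, k_hat=k_hat,
                           delta_pow=dpow, com_trajectory=com_traj,
                           gamma_path=gamma_path, sigma_s_path=sigma_path,
                           converged=converged,
                           iterations_used=len(gamma_path),
                           low_res_set=low_set)


def run_silencemap(
    recordings_by_ref: Mapping[str, Recording],
    leadfield: LeadField,
    grid_high: SourceGrid,
    C_z: np.ndarray,
    config: SilenceMapConfig | None = None,
    grid_low: SourceGrid | None = None,
    low_idx: np.ndarray | None = None,
) -> SilenceMapResult:
    """Run the two-pass algorithm over candidate references and pick the one
    with minimum scalp power mismatch.

    ``C_z`` is the n x n sensor-noise covariance at the raw electrodes
    (known in simulation, externally estimated otherwise).  A low-res grid
    is derived by symmetric farthest-point decimation unless supplied.
    """
    if not recordings_by_ref:
        raise ValueError("need at least one referenced recording")
    config = config or SilenceMapConfig()
    layout = leadfield.layout
    if grid_low is None or low_idx is None:
        grid_low, low_idx = decimate_grid(grid_high, config.low_res_fraction)
    d2_high = _pairwise_sq(grid_high.positions)

    per_ref: dict[str, ReferenceResult] = {}
    for ref, rec in recordings_by_ref.items():
        if ref not in layout.names:
            raise KeyError(f"reference electrode {ref!r} not in montage")
        scheme = make_reference_scheme(layout.n, layout.index_of(ref) + 1, ref)
        per_ref[ref] = _run_one_reference(
            rec, leadfield.A, scheme.M, grid_high, grid_low, low_idx,
            np.asarray(C_z, float), config, d2_high)

    converged_refs = {r: res for r, res in per_ref.items() if res.converged}
    pool = converged_refs or per_ref  # fall back if nothing converged
    chosen = min(pool, key=lambda r: pool[r].delta_pow)
    best = per_ref[chosen]
    return SilenceMapResult(
        silent_set=best.silent_set, k_hat=best.k_hat, chosen_ref=chosen,
        delta_pow_by_ref={r: res.delta_pow for r, res in per_ref.items()},
        com_trajectory=best.com_trajectory,
        gamma_hat=best.gamma_path[-1] if best.gamma_path else 1.0,
        sigma_s_hat=best.sigma_s_path[-1] if best.sigma_s_path else 1.0,
        converged=best.converged, iterations_used=best.iterations_used,
        per_reference=per_ref)
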
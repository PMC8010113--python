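"""Modified source-localization comparators: MNE, MUSIC, sLORETA.

Each classical method produces a per-source score in which silent sources
should look extreme; the shared silence-selection tail then (i) ranks
sources per time point, (ii) accumulates a normalized membership histogram
beta~, (iii) estimates the patch size k-hat at the knee of the sorted-score
curve (closest point to the origin of (score, rank/p)), and (iv) returns the
k-hat nearest neighbors of the center of mass of the top 2 k-hat sources —
so the output is always a contiguous patch comparable to the main
algorithm's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimators import ContributionVector
from .geometry import SourceGrid

__all__ = [
    "KneeCurve",
    "mne_inverse",
    "lcurve_lambda",
    "knee_point",
    "histogram_localize",
    "music_contribution",
    "sloreta_standardize",
    "modified_mne_localize",
    "modified_music_localize",
    "modified_sloreta_localize",
]


# ---------------------------------------------------------------------------
# inverse operators


def mne_inverse(A_tilde: np.ndarray, Y: np.ndarray,
                lam: float | None = None) -> np.ndarray:
    """Minimum-norm estimate S-hat = A~^T (A~ A~^T + lam I)^-1 Y.

    ``lam`` defaults to the L-curve corner over a log grid.
    """
    A_tilde = np.asarray(A_tilde, float)
    Y = np.asarray(Y, float)
    if lam is None:
        lam = lcurve_lambda(A_tilde, Y)
    if lam <= 0:
        raise ValueError("lambda must be positive")
    G = A_tilde @ A_tilde.T
    K = np.linalg.solve(G + lam * np.eye(G.shape[0]), Y)
    return A_tilde.T @ K


def lcurve_lambda(A_tilde: np.ndarray, Y: np.ndarray,
                  n_grid: int = 20) -> float:
    """L-curve corner: maximum curvature of the log-log residual-vs-norm
    curve over a log-spaced lambda grid anchored at the eigenvalue range of
    A~ A~^T."""
    G = A_tilde @ A_tilde.T
    ev = np.linalg.eigvalsh(G)
    lo = max(ev.max() * 1e-8, 1e-12)
    grid = np.geomspace(lo, ev.max() * 10, n_grid)
    evec, U = np.linalg.eigh(G)
    Yt = U.T @ Y
    rY = np.sum(Yt**2, axis=1)
    res = np.empty(n_grid)
    nrm = np.empty(n_grid)
    for i, lam in enumerate(grid):
        f = lam / (evec + lam)
        res[i] = float(np.sum(f**2 * rY))               # ||Y - A S||_F^2
        nrm[i] = float(np.sum(evec * (1 - f) ** 2 / np.maximum(evec + lam,
                                                               1e-300) * rY))
    x = np.log(np.maximum(res, 1e-300))
    y = np.log(np.maximum(nrm, 1e-300))
    # discrete curvature of the parametric log-log curve
    dx, dy = np.gradient(x), np.gradient(y)
    ddx, ddy = np.gradient(dx), np.gradient(dy)
    curv = np.abs(dx * ddy - dy * ddx) / np.maximum(
        (dx**2 + dy**2) ** 1.5, 1e-300)
    return float(grid[int(np.argmax(curv))])


def sloreta_standardize(A_tilde: np.ndarray, Y: np.ndarray,
                        lam: float | None = None) -> np.ndarray:
    """sLORETA standardized source power: s-hat^2 = s~^2 / (C_s^sLORETA)_ii,
    with C_s^sLORETA = A~^T (A~ A~^T + lam I)^-1 A~, for a fixed (non-average)
    reference."""
    A_tilde = np.asarray(A_tilde, float)
    if lam is None:
        lam = lcurve_lambda(A_tilde, Y)
    if lam <= 0:
        raise ValueError("lambda must be positive")
    G = A_tilde @ A_tilde.T
    Ginv_A = np.linalg.solve(G + lam * np.eye(G.shape[0]), A_tilde)
    resolution_diag = np.einsum("iq,iq->q", A_tilde, Ginv_A)
    S = mne_inverse(A_tilde, Y, lam)
    bad = resolution_diag <= 0
    denom = np.where(bad, 1.0, resolution_diag)
    out = S**2 / denom[:, None]
    out[bad] = 0.0  # invisible sources are flagged silent-agnostic
    return out


def music_contribution(A_tilde: np.ndarray, Y: np.ndarray,
                       rho: float = 95.0) -> ContributionVector:
    """MUSIC silence score beta_q = ||P-perp a~_q||^2 / ||a~_q||^2 in [0, 1].

    The signal subspace U_s collects left singular vectors of Y up to rho %
    of the total energy; a source orthogonal to it (no contribution to Y)
    scores 1.
    """
    if not 0 < rho <= 100:
        raise ValueError("rho must be in (0, 100]")
    A_tilde = np.asarray(A_tilde, float)
    Y = np.asarray(Y, float)
    U, sv, _ = np.linalg.svd(Y, full_matrices=False)
    energy = sv**2
    total = energy.sum()
    if total == 0:
        return ContributionVector(np.ones(A_tilde.shape[1]), "beta_music")
    ncomp = int(np.searchsorted(np.cumsum(energy) / total, rho / 100.0) + 1)
    Us = U[:, :ncomp]
    proj = A_tilde - Us @ (Us.T @ A_tilde)   # P-perp applied columnwise
    num = np.sum(proj**2, axis=0)
    den = np.maximum(np.sum(A_tilde**2, axis=0), 1e-300)
    return ContributionVector(np.clip(num / den, 0.0, 1.0), "beta_music")


# ---------------------------------------------------------------------------
# shared silence-selection tail


@dataclass
class KneeCurve:
    """Sorted scores with the distance-to-origin knee statistic."""

    sorted_scores: np.ndarray
    d_origin: np.ndarray
    k_hat: int


def knee_point(scores: np.ndarray) -> KneeCurve:
    """Knee of the sorted (descending) score curve.

    d_q = score_q^2 + (q/p)^2 with 1-based rank q; the knee is the argmin
    (ties to the lowest rank), estimating how many leading scores stand out.
    """
    s = np.asarray(scores, float)
    if s.size == 0:
        raise ValueError("scores must be nonempty")
    s = np.sort(s)[::-1]
    q = np.arange(1, s.size + 1, dtype=float)
    d = s**2 + (q / s.size) ** 2
    return KneeCurve(sorted_scores=s, d_origin=d, k_hat=int(np.argmin(d)) + 1)


def _membership_histogram(power: np.ndarray, k0: int) -> np.ndarray:
    """Fraction of time points at which each source ranks among the k0
    smallest-power sources."""
    p, T = power.shape
    k0 = min(max(k0, 1), p)
    part = np.argpartition(power, k0 - 1, axis=0)[:k0]
    counts = np.bincount(part.ravel(), minlength=p).astype(float)
    return counts / counts.max() if counts.max() > 0 else counts


def _contiguous_from_scores(scores: np.ndarray, grid: SourceGrid,
                            k_hat: int) -> np.ndarray:
    """Top-2k sources -> COM -> the k nearest grid sources to that COM."""
    order = np.lexsort((np.arange(scores.size), -scores))
    top = order[: min(2 * k_hat, scores.size)]
    com = grid.positions[top].mean(axis=0)
    d = np.linalg.norm(grid.positions - com, axis=1)
    near = np.lexsort((np.arange(d.size), d))
    return np.sort(near[:k_hat])


def histogram_localize(power: np.ndarray, grid: SourceGrid,
                       k0: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Silence-selection tail shared by the MNE/sLORETA comparators.

    ``power`` is a p x T matrix of estimated per-source powers.  Returns
    (silent set, normalized membership histogram beta~, k-hat).  With T = 1
    the histogram degenerates to a single ranking, which is accepted.
    """
    beta = _membership_histogram(power, k0)
    knee = knee_point(beta)
    return _contiguous_from_scores(beta, grid, knee.k_hat), beta, knee.k_hat


def _two_pass(power_fn, grid_low: SourceGrid, low_idx: np.ndarray,
              grid_high: SourceGrid, k0: int) -> np.ndarray:
    """Low-res pass fixes nothing but mirrors the main algorithm's two-grid
    structure; the high-res pass yields the final contiguous patch."""
    _set_low, _beta, _k = histogram_localize(power_fn(low_idx), grid_low, k0)
    set_high, _beta_h, _k_h = histogram_localize(power_fn(None), grid_high,
                                                  k0)
    return set_high


def modified_mne_localize(A_tilde: np.ndarray, Y: np.ndarray,
                          grid_high: SourceGrid, grid_low: SourceGrid,
                          low_idx: np.ndarray,
                          k0: int | None = None,
                          lam: float | None = None) -> np.ndarray:
    """Silence localization from the minimum-norm estimate."""
    p = A_tilde.shape[1]
    k0 = k0 or max(1, p // 20)

    def power(idx):
        Asub = A_tilde if idx is None else A_tilde[:, idx]
        return mne_inverse(Asub, Y, lam) ** 2

    return _two_pass(power, grid_low, low_idx, grid_high, k0)


def modified_sloreta_localize(A_tilde: np.ndarray, Y: np.ndarray,
                              grid_high: SourceGrid, grid_low: SourceGrid,
                              low_idx: np.ndarray,
                              k0: int | None = None,
                              lam: float | None = None) -> np.ndarray:
    """Silence localization from standardized (sLORETA) source power."""
    p = A_tilde.shape[1]
    k0 = k0 or max(1, p // 20)

    def power(idx):
        Asub = A_tilde if idx is None else A_tilde[:, idx]
        return sloreta_standardize(Asub, Y, lam)

    return _two_pass(power, grid_low, low_idx, grid_high, k0)


def modified_music_localize(A_tilde: np.ndarray, Y: np.ndarray,
                            grid_high: SourceGrid, grid_low: SourceGrid,
                            low_idx: np.ndarray,
                            rho: float = 95.0) -> np.ndarray:
    """Silence localization from the MUSIC noise-subspace score.

    beta_MUSIC is already a static per-source score (large = silent), so the
    per-time-point histogram step collapses: the knee/COM selection is
    applied to it directly on the high-resolution grid.
    """
    beta = music_contribution(A_tilde, Y, rho).values
    knee = knee_point(beta)
    return _contiguous_from_scores(beta, grid_high, knee.k_hat)
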
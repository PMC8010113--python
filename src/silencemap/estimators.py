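"""Channel statistics and per-source contribution measures.

The silence statistic is built from the cross-correlation coefficient
mu_qt = a~_q^T y_t, the projection of each differential sample onto source
q's lead-field column.  Its variance,

    Var(mu_qt) = sum_{i not silent} (a~_q^T a~_i)^2 sigma_s^2
                 + a~_q^T C_z a~_q,

drops when sources near q are silent.  Subtracting the noise term and
normalizing by the silence-free value yields the contribution measures:

* beta   (low-res, uncorrelated sources): Var-hat(mu_q) minus noise, over
  sum_j (a~_q^T a~_j)^2 -- ranges over [0, sigma_s^2];
* beta_high (high-res, correlated sources): same numerator over
  a~_q^T (A~ C_s_full A~^T) a~_q -- ranges over [0, 1];
* beta_ratio (hemispheric baseline): min(beta_q / beta_{q_m}, 1) against
  the mirror source q_m, 1 on the midline strip -- ranges over [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import welch

from .geometry import STRIP, SourceGrid

__all__ = [
    "ChannelStats",
    "ContributionVector",
    "estimate_channel_stats",
    "contribution_lowres",
    "contribution_highres",
    "hemispheric_ratio",
    "analytic_mu_variance",
]

#: safeguard for the baseline ratio denominator (fraction of max beta)
RATIO_EPS = 1e-6


@dataclass
class ContributionVector:
    """Per-source contribution measure with its flavor-specific bounds."""

    values: np.ndarray
    flavor: str  # beta_low | beta_high | beta_ratio | beta_music | beta_mne

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def p(self) -> int:
        return self.values.size


@dataclass
class ChannelStats:
    """Estimated second-order statistics of one referenced recording."""

    var_y: np.ndarray        # (n-1,) per-channel variances Var-hat(y_i)
    var_mu: np.ndarray       # (p,) Var-hat(mu_qt)
    C_z_hat: np.ndarray      # (n-1, n-1) differential noise covariance
    A_tilde: np.ndarray      # (n-1, p) referenced lead field

    def __post_init__(self) -> None:
        if np.any(self.var_y < 0):
            raise ValueError("channel variances must be nonnegative")

    @property
    def sigma_z2(self) -> np.ndarray:
        """Per-channel noise variances (diagonal of C_z_hat)."""
        return np.diag(self.C_z_hat)


def _welch_band_variance(Y: np.ndarray, fs: float,
                         band: tuple[float, float]) -> np.ndarray:
    """Per-row variance via Welch PSD integrated over ``band`` (Hz).

    2 s Hann segments with 50% overlap; equals the sample variance for
    signals whose power lies inside the band.
    """
    nperseg = min(int(2 * fs), Y.shape[1])
    if Y.shape[1] < 2 * nperseg:
        raise ValueError("insufficient data for Welch variance estimation")
    freqs, psd = welch(Y, fs=fs, nperseg=nperseg, axis=1)
    lo, hi = band
    sel = (freqs >= lo) & (freqs <= hi)
    return np.trapezoid(psd[:, sel], freqs[sel], axis=1)


def estimate_channel_stats(
    Y: np.ndarray,
    A_tilde: np.ndarray,
    C_z: np.ndarray,
    method: str = "sample",
    fs: float = 512.0,
    band: tuple[float, float] = (1.0, 100.0),
) -> ChannelStats:
    """Estimate Var(y_i) and Var(mu_qt) from a referenced recording.

    ``method="sample"`` uses exact sample moments: Var(mu_q) = a~_q^T C-hat_y
    a~_q with C-hat_y = Y Y^T / T (the recording is zero-mean by
    construction).  ``method="welch"`` integrates Welch periodograms over
    the passband, which discards out-of-band noise for band-limited data.
    C_z is the known (simulation) or externally estimated differential noise
    covariance; a vector is interpreted as its diagonal.
    """
    Y = np.asarray(Y, float)
    A_tilde = np.asarray(A_tilde, float)
    C_z = np.asarray(C_z, float)
    if C_z.ndim == 1:
        C_z = np.diag(C_z)
    T = Y.shape[1]
    if method == "sample":
        Cy = (Y @ Y.T) / T
        var_y = np.diag(Cy).copy()
        var_mu = np.einsum("iq,ij,jq->q", A_tilde, Cy, A_tilde)
    elif method == "welch":
        var_y = _welch_band_variance(Y, fs, band)
        Mu = A_tilde.T @ Y
        var_mu = _welch_band_variance(Mu, fs, band)
    else:
        raise ValueError("method must be 'sample' or 'welch'")
    return ChannelStats(var_y=var_y, var_mu=var_mu, C_z_hat=C_z,
                        A_tilde=A_tilde)


def analytic_mu_variance(A_tilde: np.ndarray, C_s: np.ndarray,
                         C_z: np.ndarray) -> np.ndarray:
    """Exact Var(mu_qt) = a~_q^T (A~ C_s A~^T + C_z) a~_q for a known model.

    Serves as the closed-form oracle against which the empirical estimates
    converge at rate 1/sqrt(T).
    """
    C_y = A_tilde @ C_s @ A_tilde.T + C_z
    return np.einsum("iq,ij,jq->q", A_tilde, C_y, A_tilde)


def _noise_quadratic(stats: ChannelStats) -> np.ndarray:
    return np.einsum("iq,ij,jq->q", stats.A_tilde, stats.C_z_hat,
                     stats.A_tilde)


def contribution_lowres(stats: ChannelStats,
                        A_tilde: np.ndarray | None = None) -> ContributionVector:
    """Low-resolution contribution beta_q in [0, sigma_s^2].

    beta_q = (Var-hat(mu_q) - a~_q^T C_z a~_q) / sum_j (a~_q^T a~_j)^2.
    Negative numerators (noise over-subtraction) are clipped to 0.  Sources
    whose denominator vanishes are invisible to the array; their beta is 0.
    """
    A = stats.A_tilde if A_tilde is None else np.asarray(A_tilde, float)
    G = A.T @ A
    denom = np.sum(G**2, axis=1)
    num = np.clip(stats.var_mu - _noise_quadratic(stats), 0.0, None)
    values = np.zeros_like(num)
    ok = denom > 0
    values[ok] = num[ok] / denom[ok]
    return ContributionVector(values=values, flavor="beta_low")


def contribution_highres(stats: ChannelStats, C_s_full: np.ndarray,
                         A_tilde: np.ndarray | None = None) -> ContributionVector:
    """High-resolution contribution beta_high_q in [0, 1].

    Same numerator as beta, but normalized by the silence-free variance
    a~_q^T (A~ C_s_full A~^T) a~_q under the correlated-source model.
    """
    A = stats.A_tilde if A_tilde is None else np.asarray(A_tilde, float)
    S_full = A @ C_s_full @ A.T
    denom = np.einsum("iq,ij,jq->q", A, S_full, A)
    num = np.clip(stats.var_mu - _noise_quadratic(stats), 0.0, None)
    values = np.zeros_like(num)
    ok = denom > 0
    values[ok] = np.clip(num[ok] / denom[ok], 0.0, 1.0)
    return ContributionVector(values=values, flavor="beta_high")


def hemispheric_ratio(beta: ContributionVector, grid: SourceGrid,
                      baseline: ContributionVector | None = None
                      ) -> ContributionVector:
    """Baseline-relative contribution beta~_q = min(beta_q / beta_base_q, 1).

    With no explicit baseline the mirror source's beta is the baseline
    (hemispheric baseline); midline-strip sources get exactly 1.  The
    denominator is safeguarded by eps * max(beta) so doubly silent mirrored
    pairs resolve to ratio 1 instead of 0/0.
    """
    b = beta.values
    floor = RATIO_EPS * max(float(b.max()), 1e-300)
    out = np.ones(beta.p)
    if baseline is not None:
        base = np.maximum(baseline.values, floor)
        out = np.minimum(b / base, 1.0)
    else:
        if grid.p != beta.p:
            raise ValueError("grid and beta disagree in p")
        for q in range(beta.p):
            if grid.hemisphere[q] == STRIP:
                continue
            m = grid.mirror_map[q]
            if m < 0:
                continue
            if b[q] <= floor and b[m] <= floor:
                out[q] = 1.0  # doubly silent pair: 0/0 resolves to 1
            else:
                out[q] = min(b[q] / max(b[m], floor), 1.0)
    return ContributionVector(values=out, flavor="beta_ratio")
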
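"""Evaluation metrics for silence localization.

Delta-COM (mm) — Euclidean distance between the unweighted centers of mass
of the estimated and ground-truth patches; JI — Jaccard overlap of the two
index sets; Delta-k = |k - k-hat| / k — relative size error; CR — fraction
of runs whose COM trajectory converged; MAD — hemispheric mean absolute
difference of electrode powers, the scalp-level symmetry statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import ElectrodeLayout
from .geometry import SourceGrid

__all__ = ["PerformanceReport", "evaluate", "mad_symmetry",
           "convergence_rate"]


@dataclass
class PerformanceReport:
    delta_com: float
    jaccard: float
    delta_k: float
    converged: bool = True
    meta: dict = field(default_factory=dict)


def evaluate(est, truth, grid: SourceGrid, converged: bool = True,
             **meta) -> PerformanceReport:
    """Compare an estimated silent set against ground truth on one grid."""
    est = set(int(i) for i in est)
    truth = set(int(i) for i in truth)
    if not truth:
        raise ValueError("ground truth set must be nonempty")
    if not est:
        raise ValueError("estimated set is empty; Delta-COM is undefined")
    com_e = grid.com(sorted(est))
    com_t = grid.com(sorted(truth))
    ji = len(est & truth) / len(est | truth)
    dk = abs(len(truth) - len(est)) / len(truth)
    return PerformanceReport(
        delta_com=float(np.linalg.norm(com_e - com_t)),
        jaccard=float(ji), delta_k=float(dk), converged=converged,
        meta=dict(meta))


def mad_symmetry(var_y: np.ndarray, layout: ElectrodeLayout,
                 excluded_midline: int = 10) -> float:
    """Hemispheric mean absolute difference of electrode powers.

    MAD = 2/(n - 10) * sum over mirror pairs |Var(y_R) - Var(y_L)|, with the
    midline electrodes excluded.  ``var_y`` is indexed like the montage
    (reference channels may carry 0).
    """
    var_y = np.asarray(var_y, float)
    pairs = layout.mirror_pairs()
    n = layout.n
    if n - excluded_midline != 2 * len(pairs):
        raise ValueError("montage pairing inconsistent with electrode count")
    total = sum(abs(var_y[r] - var_y[l]) for l, r in pairs)
    return float(2.0 * total / (n - excluded_midline))


def convergence_rate(reports: list[PerformanceReport]) -> float:
    """Fraction of runs flagged converged."""
    if not reports:
        raise ValueError("need at least one report")
    return float(np.mean([r.converged for r in reports]))
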
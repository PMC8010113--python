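"""Source grids, nearest-neighbor graphs, and contiguous-region sampling.

The cortex is discretized into ``p`` current sources.  For the hemispheric
baseline each source in one hemisphere needs a mirror partner obtained by
reflection across the midsagittal plane (x = 0); sources inside a narrow
midline strip straddling the longitudinal fissure have no partner.  The
contiguity prior used by the clustering step is expressed through a
z-nearest-neighbor graph with Gaussian edge weights and its Laplacian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csgraph
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SourceGrid",
    "NeighborGraph",
    "build_symmetric_grid",
    "build_graph",
    "sample_contiguous_region",
    "decimate_grid",
]

#: hemisphere labels
LEFT, RIGHT, STRIP = "L", "R", "strip"

#: above this source count, theta is estimated from a seeded subsample of pairs
_THETA_EXACT_P = 3000
_THETA_SUBSAMPLE = 2_000_000


@dataclass
class SourceGrid:
    """Discretized cortex: positions (mm), hemisphere labels, mirror pairing.

    ``mirror_map[q]`` is the index of the mirror partner of source ``q`` or
    ``-1`` for strip sources.  The pairing is an involution on paired sources.
    """

    positions: np.ndarray          # (p, 3), mm; +x toward the right ear
    hemisphere: np.ndarray         # (p,) array of {"L", "R", "strip"}
    mirror_map: np.ndarray         # (p,) int, -1 for strip sources
    resolution_tag: str = "high"
    scalp_radius: float = 92.0     # mm, used for depth computations

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.hemisphere = np.asarray(self.hemisphere, dtype=object)
        self.mirror_map = np.asarray(self.mirror_map, dtype=int)
        p = self.positions.shape[0]
        if p < 2:
            raise ValueError("a source grid needs at least two sources")
        if self.positions.shape != (p, 3):
            raise ValueError("positions must be (p, 3)")
        if self.hemisphere.shape != (p,) or self.mirror_map.shape != (p,):
            raise ValueError("hemisphere and mirror_map must have length p")
        self._validate_mirror()

    def _validate_mirror(self) -> None:
        for q, m in enumerate(self.mirror_map):
            if self.hemisphere[q] == STRIP:
                if m != -1:
                    raise ValueError(f"strip source {q} has a mirror partner")
                continue
            if m < 0:
                continue
            if self.mirror_map[m] != q:
                raise ValueError("mirror_map is not an involution")

    @property
    def p(self) -> int:
        return self.positions.shape[0]

    @property
    def n_pairs(self) -> int:
        return int(np.sum(self.mirror_map >= 0)) // 2

    def hemisphere_indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.hemisphere == label)

    def depth(self) -> np.ndarray:
        """Distance of each source from the scalp surface (mm)."""
        return self.scalp_radius - np.linalg.norm(self.positions, axis=1)

    def spacing(self) -> float:
        """Median nearest-neighbor distance (mm), the grid resolution."""
        d = squareform(pdist(self.positions))
        np.fill_diagonal(d, np.inf)
        return float(np.median(d.min(axis=1)))

    def com(self, idx) -> np.ndarray:
        """Unweighted center of mass of a set of sources."""
        idx = np.asarray(list(idx), dtype=int)
        if idx.size == 0:
            raise ValueError("center of mass of an empty set is undefined")
        return self.positions[idx].mean(axis=0)


@dataclass
class NeighborGraph:
    """z-nearest-neighbor graph with Gaussian weights and its Laplacian."""

    W: np.ndarray
    z: int
    theta: float
    D: np.ndarray = field(init=False)
    L: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.D = np.diag(self.W.sum(axis=1))
        self.L = self.D - self.W

    @property
    def p(self) -> int:
        return self.W.shape[0]


def _fibonacci_cap(n: int, radius: float, cap_fraction: float) -> np.ndarray:
    """Quasi-uniform points on the upper cap of a sphere (Fibonacci lattice).

    ``cap_fraction`` is the fraction of the full sphere's area covered,
    measured from the +z pole downward.
    """
    i = np.arange(n, dtype=float) + 0.5
    # area-uniform in z over [1 - 2*cap_fraction, 1]
    zfrac = 1.0 - 2.0 * cap_fraction * i / n
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    phi = 2.0 * np.pi * i / golden
    r_xy = np.sqrt(np.clip(1.0 - zfrac**2, 0.0, None))
    pts = np.column_stack([r_xy * np.cos(phi), r_xy * np.sin(phi), zfrac])
    return radius * pts


def build_symmetric_grid(
    p_target: int,
    resolution_tag: str = "high",
    strip_width: float = 0.0,
    seed: int = 0,
    radius: float = 79.0,
    cap_fraction: float = 0.5,
    scalp_radius: float = 92.0,
) -> SourceGrid:
    """Build a mirror-symmetric synthetic cortex on an upper spherical cap.

    Points are placed quasi-uniformly with a Fibonacci lattice; points in the
    right half (x >= strip_width/2) are kept and reflected across x = 0 to
    produce exactly mirrored left-hemisphere partners.  Points with
    ``|x| < strip_width/2`` form the midline strip and have no partner.

    Parameters
    ----------
    p_target : requested total source count (``>= 4``).
    strip_width : width (mm) of the midline strip along the longitudinal
        fissure; 0 gives a fully paired grid.
    seed : rotates the lattice about z so that distinct seeds give distinct
        (but statistically equivalent) grids.
    """
    if p_target < 4:
        raise ValueError("p_target must be at least 4")
    if strip_width < 0:
        raise ValueError("strip_width must be nonnegative")

    rng = np.random.default_rng(seed)
    rot = rng.uniform(0.0, 2.0 * np.pi)
    half = strip_width / 2.0

    n_lattice = p_target
    for _ in range(60):
        pts = _fibonacci_cap(n_lattice, radius, cap_fraction)
        c, s = np.cos(rot), np.sin(rot)
        pts = pts @ np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]]).T
        strip_mask = np.abs(pts[:, 0]) < half if half > 0 else np.zeros(len(pts), bool)
        right_mask = pts[:, 0] >= half
        n_strip_lattice = int(strip_mask.sum())
        # scale the strip count down to the target total
        n_strip = min(n_strip_lattice, p_target - 2)
        n_pair = (p_target - n_strip) // 2
        if right_mask.sum() >= n_pair and n_pair >= 1:
            break
        n_lattice = int(n_lattice * 1.3) + 8
    else:  # pragma: no cover - defensive
        raise ValueError("p_target too small to place at least one mirrored pair")

    right = pts[right_mask][:n_pair]
    strip = pts[strip_mask][:n_strip]
    strip[:, 0] = 0.0  # snap strip sources onto the midsagittal plane
    left = right * np.array([-1.0, 1.0, 1.0])

    positions = np.vstack([right, left, strip])
    hemisphere = np.array(
        [RIGHT] * n_pair + [LEFT] * n_pair + [STRIP] * n_strip, dtype=object
    )
    mirror = np.full(len(positions), -1, dtype=int)
    mirror[:n_pair] = np.arange(n_pair) + n_pair
    mirror[n_pair : 2 * n_pair] = np.arange(n_pair)
    return SourceGrid(positions, hemisphere, mirror, resolution_tag,
                      scalp_radius=scalp_radius)


def _theta(positions: np.ndarray, seed: int = 0) -> float:
    """Gaussian-kernel scale: theta^2 is the spread of all pairwise
    inter-source distances, with the 1/(N-1) normalization applied to both
    moments (subsampled above ``_THETA_EXACT_P`` sources; exact otherwise).
    """
    p = positions.shape[0]
    if p <= _THETA_EXACT_P:
        d = pdist(positions)
    else:
        rng = np.random.default_rng(seed)
        i = rng.integers(0, p, _THETA_SUBSAMPLE)
        j = rng.integers(0, p, _THETA_SUBSAMPLE)
        keep = i != j
        d = np.linalg.norm(positions[i[keep]] - positions[j[keep]], axis=1)
    N = d.size
    if N < 2:
        raise ValueError("need at least two inter-source distances")
    dbar = d.sum() / (N - 1)
    theta2 = float(np.sum((d - dbar) ** 2) / (N - 1))
    if theta2 <= 0.0:
        raise ValueError("degenerate geometry: all sources coincide")
    return float(np.sqrt(theta2))


def _knn_indices(dist: np.ndarray, z: int) -> np.ndarray:
    """Boolean (p, p) matrix: entry [j, i] True iff i is among the z nearest
    neighbors of j.  Distance ties are broken by lowest index."""
    p = dist.shape[0]
    d = dist.copy()
    np.fill_diagonal(d, np.inf)
    # lexicographic (distance, index) sort makes tie-breaking deterministic
    order = np.lexsort((np.tile(np.arange(p), (p, 1)), d), axis=1)
    nn = order[:, :z]
    out = np.zeros((p, p), dtype=bool)
    np.put_along_axis(out, nn, True, axis=1)
    return out


def build_graph(grid: SourceGrid, z: int) -> NeighborGraph:
    """z-nearest-neighbor graph over the sources with Gaussian edge weights.

    ``w_ij = exp(-||f_i - f_j||^2 / (2 theta^2))`` when i is among the z
    nearest neighbors of j or vice versa, else 0; theta^2 is the variance of
    all inter-source distances.  ``L = D - W`` is the (PSD) graph Laplacian.
    """
    p = grid.p
    if not 1 <= z < p:
        raise ValueError("z must satisfy 1 <= z < p")
    if p < 3:
        raise ValueError("need at least 3 sources to estimate theta")
    dist = squareform(pdist(grid.positions))
    theta = _theta(grid.positions)
    nn = _knn_indices(dist, z)
    mask = nn | nn.T
    W = np.where(mask, np.exp(-(dist**2) / (2.0 * theta**2)), 0.0)
    np.fill_diagonal(W, 0.0)
    return NeighborGraph(W=W, z=z, theta=theta)


def region_is_contiguous(grid: SourceGrid, region, z: int) -> bool:
    """True iff ``region`` is a connected subgraph of the z-NN graph."""
    region = np.asarray(sorted(region), dtype=int)
    if region.size <= 1:
        return region.size == 1
    g = build_graph(grid, z)
    sub = g.W[np.ix_(region, region)] > 0
    ncomp, _ = csgraph.connected_components(sub, directed=False)
    return ncomp == 1


def sample_contiguous_region(
    grid: SourceGrid,
    k: int,
    seed: int = 0,
    depth_limit: float | None = None,
) -> np.ndarray:
    """Draw a random contiguous k-source patch inside one hemisphere.

    A seed node is chosen uniformly among eligible sources (non-strip, and no
    deeper than ``depth_limit`` mm below the scalp surface if given); the
    patch is the seed plus its k-1 nearest neighbors within the same
    hemisphere.
    """
    if k < 1:
        raise ValueError("k must be positive")
    if not k < grid.p / 2:
        raise ValueError("k must be small relative to p (k < p/2)")
    eligible = np.flatnonzero(grid.hemisphere != STRIP)
    if depth_limit is not None:
        depth = grid.depth()
        eligible = eligible[depth[eligible] <= depth_limit]
    if eligible.size == 0:
        raise ValueError("no eligible seed node for the requested region")
    rng = np.random.default_rng(seed)
    root = int(rng.choice(eligible))
    same = np.flatnonzero(grid.hemisphere == grid.hemisphere[root])
    if same.size < k:
        raise ValueError("hemisphere too small to hold a region of size k")
    d = np.linalg.norm(grid.positions[same] - grid.positions[root], axis=1)
    order = np.lexsort((same, d))
    return np.sort(same[order[:k]])


def decimate_grid(grid: SourceGrid, fraction: float = 0.15,
                  seed: int = 0) -> tuple[SourceGrid, np.ndarray]:
    """Symmetric farthest-point decimation: a coarse copy of ``grid``.

    Farthest-point sampling runs on the right-hemisphere sources; each kept
    source brings its mirror partner, so the coarse grid stays symmetric.
    Strip sources are decimated by the same fraction independently.

    Returns the low-resolution grid and the indices of the kept sources in
    the parent grid (so lead-field columns can be subset consistently).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    right = grid.hemisphere_indices(RIGHT)
    strip = grid.hemisphere_indices(STRIP)
    n_keep_r = max(2, int(round(fraction * right.size)))
    n_keep_s = int(round(fraction * strip.size))

    def fps(candidates: np.ndarray, n_keep: int) -> np.ndarray:
        if candidates.size == 0 or n_keep == 0:
            return candidates[:0]
        pos = grid.positions[candidates]
        start = 0  # deterministic: start from the first candidate
        chosen = [start]
        d = np.linalg.norm(pos - pos[start], axis=1)
        for _ in range(min(n_keep, candidates.size) - 1):
            nxt = int(np.argmax(d))
            chosen.append(nxt)
            d = np.minimum(d, np.linalg.norm(pos - pos[nxt], axis=1))
        return candidates[np.sort(np.array(chosen, dtype=int))]

    keep_r = fps(right, n_keep_r)
    keep_s = fps(strip, n_keep_s)
    keep_l = grid.mirror_map[keep_r]
    keep = np.sort(np.concatenate([keep_r, keep_l, keep_s]))

    old_to_new = {int(o): i for i, o in enumerate(keep)}
    mirror = np.array(
        [old_to_new.get(int(grid.mirror_map[o]), -1) if grid.mirror_map[o] >= 0
         else -1 for o in keep],
        dtype=int,
    )
    sub = SourceGrid(
        grid.positions[keep], grid.hemisphere[keep], mirror,
        resolution_tag="low", scalp_radius=grid.scalp_radius,
    )
    return sub, keep
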
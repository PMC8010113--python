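"""Forward model: lead field, differential referencing, scalp projection.

The forward model maps source amplitudes to scalp potentials, Y = M(AS + E):
``A`` is the n x p gain (lead-field) matrix, ``M`` the (n-1) x n differential
referencing matrix that subtracts one electrode's potential from all others,
``S`` the source time courses and ``E`` the per-electrode sensor noise.

The synthetic lead field is the exact closed form for a radial current
dipole inside a homogeneous conducting sphere with an insulating boundary:
for a dipole of moment m at eccentricity f = b/R and an electrode at angular
distance alpha from the dipole axis,

    V(alpha) = m / (4 pi sigma R^2) * [ 2 (cos a - f) / g^3 + (1/g - 1)/f ],

with g = sqrt(1 - 2 f cos a + f^2); the f -> 0 limit is 3 m cos a /
(4 pi sigma R^2).  Only ratios of gains matter anywhere in the method, so
the source unit is arbitrary (sigma_s = 1 a.u.).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import SourceGrid

__all__ = [
    "LeadField",
    "ReferenceScheme",
    "Recording",
    "ElectrodeLayout",
    "MIDLINE_LABELS",
    "build_symmetric_montage",
    "make_reference_scheme",
    "synth_lead_field",
    "project_scalp",
]

#: the ten 10-5 reference candidates along the longitudinal fissure,
#: front to back
MIDLINE_LABELS = ("Fpz", "AFz", "Fz", "FCz", "Cz", "CPz", "Pz", "POz", "Oz", "Iz")


@dataclass
class ElectrodeLayout:
    """Scalp electrode montage: labels and 3D positions (mm)."""

    names: list[str]
    positions: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.names) != self.positions.shape[0]:
            raise ValueError("names and positions disagree in length")

    @property
    def n(self) -> int:
        return len(self.names)

    def index_of(self, label: str) -> int:
        try:
            return self.names.index(label)
        except ValueError:
            raise KeyError(f"electrode {label!r} not in montage") from None

    def mirror_pairs(self) -> list[tuple[int, int]]:
        """(left, right) index pairs, matched by reflecting labels L<->R."""
        pairs = []
        for i, name in enumerate(self.names):
            if name.endswith("L"):
                j = self.index_of(name[:-1] + "R")
                pairs.append((i, j))
        if not pairs:
            raise ValueError("montage has no mirror-paired electrodes")
        return pairs


@dataclass
class LeadField:
    """Gain matrix A (n x p) with the montage it was computed for."""

    A: np.ndarray
    electrode_names: list[str]
    electrode_positions: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.electrode_positions = np.asarray(self.electrode_positions, float)
        if not np.all(np.isfinite(self.A)):
            raise ValueError("lead field contains non-finite entries")
        if self.A.shape[0] < 2:
            raise ValueError("need at least two electrodes")
        if np.any(np.all(self.A == 0.0, axis=0)):
            raise ValueError("lead field has an all-zero column "
                             "(source invisible to the whole array)")

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def p(self) -> int:
        return self.A.shape[1]

    @property
    def layout(self) -> ElectrodeLayout:
        return ElectrodeLayout(list(self.electrode_names),
                               self.electrode_positions)

    def subset_sources(self, idx: np.ndarray) -> "LeadField":
        return LeadField(self.A[:, np.asarray(idx, int)],
                         list(self.electrode_names), self.electrode_positions)


@dataclass
class ReferenceScheme:
    """Differential referencing matrix M ((n-1) x n) for one reference."""

    M: np.ndarray
    ref_name: str
    ref_index: int

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)


@dataclass
class Recording:
    """Differential scalp recording Y ((n-1) x T, microvolts)."""

    Y: np.ndarray
    sampling_rate: float
    ref_name: str

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 2 or self.Y.shape[1] < 2:
            raise ValueError("Y must be (n-1) x T with T >= 2")

    @property
    def T(self) -> int:
        return self.Y.shape[1]


def make_reference_scheme(n: int, ref_index: int,
                          ref_name: str | None = None) -> ReferenceScheme:
    """Referencing matrix for electrode ``ref_index`` (1-based).

    For the canonical last-electrode reference, M = [I | -1]; any other
    reference is the column-permuted form.  Rows are ordered by electrode
    index, one row per non-reference electrode: row for electrode i has +1
    in column i and -1 in the reference column.  M @ 1 = 0 (common-mode
    rejection).
    """
    if n < 2:
        raise ValueError("need at least two electrodes")
    if not 1 <= ref_index <= n:
        raise ValueError("ref_index out of range")
    r = ref_index - 1
    keep = [i for i in range(n) if i != r]
    M = np.zeros((n - 1, n))
    for row, i in enumerate(keep):
        M[row, i] = 1.0
        M[row, r] = -1.0
    return ReferenceScheme(M=M, ref_name=ref_name or f"E{ref_index}",
                           ref_index=ref_index)


def build_symmetric_montage(n: int = 64, scalp_radius: float = 92.0,
                            cap_fraction: float = 0.5) -> ElectrodeLayout:
    """Exactly mirror-symmetric synthetic scalp montage.

    Ten midline electrodes carry the standard 10-5 labels used as reference
    candidates (Fpz ... Iz, front to back on the x = 0 arc); the remaining
    (n - 10)/2 lateral pairs are labeled ``E<i>L`` / ``E<i>R`` and placed
    quasi-uniformly over each half of the upper scalp cap.
    """
    if n < 12 or (n - 10) % 2:
        raise ValueError("n must be >= 12 with n - 10 even")
    n_pairs = (n - 10) // 2

    # midline arc: from front (+y) over the vertex to the back (-y)
    ang = np.linspace(np.radians(-75), np.radians(75), len(MIDLINE_LABELS))
    midline = scalp_radius * np.column_stack(
        [np.zeros_like(ang), np.sin(-ang), np.cos(ang)]
    )

    # lateral right-half positions: Fibonacci points on the cap with x > gap
    from .geometry import _fibonacci_cap

    m = 4 * n_pairs + 16
    for _ in range(40):
        pts = _fibonacci_cap(m, scalp_radius, cap_fraction)
        right = pts[pts[:, 0] > 0.12 * scalp_radius]
        if right.shape[0] >= n_pairs:
            break
        m = int(m * 1.4) + 8
    # spread the kept pairs evenly over the cap (the lattice is ordered by
    # height, so taking a prefix would crowd electrodes at the vertex)
    pick = np.unique(np.linspace(0, right.shape[0] - 1,
                                 n_pairs).round().astype(int))
    if pick.size < n_pairs:  # rounding collisions: fall back to a prefix
        pick = np.arange(n_pairs)
    right = right[pick]
    left = right * np.array([-1.0, 1.0, 1.0])

    names = list(MIDLINE_LABELS)
    pos = [midline]
    for i in range(n_pairs):
        names += [f"E{i + 1}L", f"E{i + 1}R"]
    lateral = np.empty((2 * n_pairs, 3))
    lateral[0::2] = left
    lateral[1::2] = right
    pos.append(lateral)
    return ElectrodeLayout(names, np.vstack(pos))


def _radial_dipole_potential(cos_a: np.ndarray, f: float) -> np.ndarray:
    """Bracketed geometric factor of the homogeneous-sphere closed form."""
    if f < 1e-9:
        return 3.0 * cos_a
    g = np.sqrt(np.clip(1.0 - 2.0 * f * cos_a + f * f, 1e-30, None))
    return 2.0 * (cos_a - f) / g**3 + (1.0 / g - 1.0) / f


def synth_lead_field(
    grid: SourceGrid,
    electrode_layout: ElectrodeLayout,
    conductivity: float = 0.33,
    moment: float = 1.0,
) -> LeadField:
    """Analytic lead field: radial dipoles in a homogeneous conducting sphere.

    Sources are radially oriented (dipoles normal to the spherical cortex
    surface).  ``conductivity`` (S/m) acts as a global attenuation knob so
    conductivity-robustness experiments can be emulated; it rescales all
    gains identically and cancels from every ratio the method uses.
    """
    epos = electrode_layout.positions
    spos = grid.positions
    R = np.linalg.norm(epos, axis=1)
    b = np.linalg.norm(spos, axis=1)
    if np.any(b >= R.min()):
        raise ValueError("all sources must lie inside the electrode sphere")
    Rs = float(R.mean())  # scalp sphere radius; montages are spherical here
    f = b / Rs
    e_unit = epos / R[:, None]
    s_unit = np.where(b[:, None] > 0, spos / np.maximum(b, 1e-12)[:, None], 0.0)
    cos_a = np.clip(e_unit @ s_unit.T, -1.0, 1.0)  # (n, p)
    factor = moment / (4.0 * np.pi * conductivity * Rs**2)
    A = factor * np.stack(
        [_radial_dipole_potential(cos_a[:, q], f[q]) for q in range(grid.p)],
        axis=1,
    )
    return LeadField(A, list(electrode_layout.names), epos)


def project_scalp(A: np.ndarray, M: np.ndarray, S: np.ndarray,
                  E: np.ndarray, sampling_rate: float = 512.0,
                  ref_name: str = "") -> Recording:
    """Project sources and sensor noise to a differential recording,
    Y = M (A S + E)."""
    A, M, S, E = (np.asarray(x, float) for x in (A, M, S, E))
    n, p = A.shape
    if M.shape != (n - 1, n) or S.shape[0] != p or E.shape != (n, S.shape[1]):
        raise ValueError("shape mismatch between A, M, S, E")
    Y = M @ (A @ S + E)
    return Recording(Y=Y, sampling_rate=sampling_rate, ref_name=ref_name)


def rereference(Y: np.ndarray, old: ReferenceScheme,
                new: ReferenceScheme) -> np.ndarray:
    """Transform differential data from one reference electrode to another.

    Differential data determine the ideal potentials up to a common offset,
    so any re-referencing is an exact linear map: append a zero row for the
    old reference, reorder to raw electrode order, and apply the new M.
    """
    n = old.M.shape[1]
    X = np.zeros((n, Y.shape[1]))
    keep = [i for i in range(n) if i != old.ref_index - 1]
    X[keep] = Y
    return new.M @ X
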
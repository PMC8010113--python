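"""File I/O: run containers (HDF5), grid/montage text formats, run configs.

One hierarchical container per simulated run holds everything a localization
needs: ``/Y/<ref>`` differential recordings, ``/A`` the lead field,
``/M/<ref>`` referencing matrices, ``/grid/*`` the source grid, ``/truth``
the ground-truth silent indices and ``/meta`` scalar attributes (seed,
gamma, sigma_s, SNR, k).  Small tables (grids, montages) use delimited
text; configs are JSON and round-trip exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .forward import ElectrodeLayout, LeadField, Recording
from .geometry import SourceGrid
from .pipeline import SilenceMapConfig

__all__ = [
    "RunConfig",
    "save_grid_text",
    "load_grid_text",
    "save_leadfield",
    "load_leadfield",
    "save_montage",
    "load_montage",
    "write_simulation",
    "read_simulation",
    "read_recording",
]


@dataclass
class RunConfig:
    """Serializable snapshot of a full run's settings."""

    # simulation
    p: int = 500
    n_electrodes: int = 64
    k: int = 20
    T: int = 20_000
    gamma: float = 0.12
    sigma_s: float = 1.0
    snr_db: float = 9.0
    psd_mode: str = "flat"
    strip_width: float = 0.0
    references: tuple[str, ...] = ("Cz",)
    seed: int = 0
    # pipeline
    pipeline: SilenceMapConfig = field(default_factory=SilenceMapConfig)

    def to_json(self) -> str:
        d = asdict(self)
        d["references"] = list(self.references)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        pl = d.pop("pipeline", {})
        for key in ("lambda_span", "gamma_bounds"):
            if pl.get(key) is not None:
                pl[key] = tuple(pl[key])
        d["references"] = tuple(d.get("references", ("Cz",)))
        cfg = cls(**{k: v for k, v in d.items()
                     if k in {f.name for f in dataclasses.fields(cls)}})
        cfg.pipeline = SilenceMapConfig(**pl)
        return cfg

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# text formats


def save_grid_text(path, grid: SourceGrid) -> None:
    """Columns: x y z hemisphere mirror_index (mm; -1 = no partner)."""
    with open(path, "w") as fh:
        fh.write("# x y z hemisphere mirror_index\n")
        for q in range(grid.p):
            x, y, z = grid.positions[q]
            fh.write(f"{x:.6f} {y:.6f} {z:.6f} {grid.hemisphere[q]} "
                     f"{grid.mirror_map[q]}\n")


def load_grid_text(path, resolution_tag: str = "high",
                   scalp_radius: float = 92.0) -> SourceGrid:
    pos, hemi, mirror = [], [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        x, y, z, h, m = line.split()
        pos.append([float(x), float(y), float(z)])
        hemi.append(h)
        mirror.append(int(m))
    return SourceGrid(np.array(pos), np.array(hemi, dtype=object),
                      np.array(mirror), resolution_tag,
                      scalp_radius=scalp_radius)


def save_leadfield(path, lead: LeadField) -> None:
    """Matrix container with datasets A, electrode_names,
    electrode_positions."""
    with h5py.File(path, "w") as f:
        f.create_dataset("A", data=lead.A)
        f.create_dataset("electrode_names",
                         data=np.array(lead.electrode_names, dtype="S"))
        f.create_dataset("electrode_positions",
                         data=lead.electrode_positions)


def load_leadfield(path) -> LeadField:
    with h5py.File(path, "r") as f:
        names = [s.decode() for s in f["electrode_names"][()]]
        return LeadField(f["A"][()], names, f["electrode_positions"][()])


def save_montage(path, layout: ElectrodeLayout) -> None:
    """Whitespace-delimited montage: label x y z (mm)."""
    with open(path, "w") as fh:
        for name, (x, y, z) in zip(layout.names, layout.positions):
            fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


def load_montage(path) -> ElectrodeLayout:
    names, pos = [], []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"malformed montage line: {line!r}")
        names.append(parts[0])
        pos.append([float(v) for v in parts[1:]])
    return ElectrodeLayout(names, np.array(pos))


# ---------------------------------------------------------------------------
# run containers


def write_simulation(path, sim) -> None:
    """Write a SimulationResult to one HDF5 container (schema in module
    docstring)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("A", data=sim.leadfield.A)
        f.create_dataset("electrode_positions",
                         data=sim.leadfield.electrode_positions)
        f.create_dataset("electrode_names", data=np.array(
            sim.leadfield.electrode_names, dtype="S"))
        g = f.create_group("grid")
        g.create_dataset("positions", data=sim.grid.positions)
        g.create_dataset("hemisphere", data=np.array(
            [str(h) for h in sim.grid.hemisphere], dtype="S"))
        g.create_dataset("mirror_map", data=sim.grid.mirror_map)
        g.attrs["resolution_tag"] = sim.grid.resolution_tag
        g.attrs["scalp_radius"] = sim.grid.scalp_radius
        f.create_dataset("truth", data=np.asarray(sim.ground_truth, int))
        f.create_dataset("sigma_z", data=sim.noise_model.sigma_z)
        yg = f.create_group("Y")
        mg = f.create_group("M")
        for ref, rec in sim.recordings.items():
            d = yg.create_dataset(ref, data=rec.Y)
            d.attrs["sampling_rate"] = rec.sampling_rate
            mg.create_dataset(ref, data=sim.schemes[ref].M)
        meta = f.create_group("meta")
        for key, val in sim.meta.items():
            meta.attrs[key] = val


def read_simulation(path):
    """Read a run container back into a SimulationResult."""
    from .forward import ReferenceScheme
    from .simulate import (NoiseModel, SimulationResult,
                           build_source_covariance)

    with h5py.File(path, "r") as f:
        names = [s.decode() for s in f["electrode_names"][()]]
        lead = LeadField(f["A"][()], names, f["electrode_positions"][()])
        g = f["grid"]
        grid = SourceGrid(
            g["positions"][()],
            np.array([s.decode() for s in g["hemisphere"][()]], dtype=object),
            g["mirror_map"][()], g.attrs["resolution_tag"],
            scalp_radius=float(g.attrs["scalp_radius"]))
        truth = f["truth"][()]
        noise = NoiseModel(f["sigma_z"][()])
        meta = dict(f["meta"].attrs)
        recordings, schemes = {}, {}
        for ref in f["Y"]:
            d = f["Y"][ref]
            recordings[ref] = Recording(d[()], float(d.attrs["sampling_rate"]),
                                        ref)
            M = f["M"][ref][()]
            idx = names.index(ref) + 1
            schemes[ref] = ReferenceScheme(M=M, ref_name=ref, ref_index=idx)
    model = build_source_covariance(grid, gamma=float(meta.get("gamma", 0.12)),
                                    sigma_s2=float(meta.get("sigma_s", 1.0))**2,
                                    silent_set=truth)
    return SimulationResult(recordings=recordings, schemes=schemes,
                            leadfield=lead, grid=grid, source_model=model,
                            noise_model=noise, ground_truth=truth, meta=meta)


def read_recording(path, montage_path) -> tuple[Recording, ElectrodeLayout]:
    """Read a raw or referenced recording plus its montage, with validation.

    The container must hold ``/Y`` ((n-1) x T differential data) with attrs
    ``sampling_rate`` and ``ref_name``; the montage must contain the
    reference label and exactly n electrodes.
    """
    layout = load_montage(montage_path)
    with h5py.File(path, "r") as f:
        if "Y" not in f:
            raise ValueError("container lacks a /Y dataset")
        d = f["Y"]
        Y = d[()]
        fs = float(d.attrs.get("sampling_rate", 512.0))
        ref = str(d.attrs.get("ref_name", ""))
    if not np.all(np.isfinite(Y)):
        raise ValueError("recording contains NaN or infinite samples")
    if ref and ref not in layout.names:
        raise ValueError(f"montage is missing the reference channel {ref!r}")
    if Y.shape[0] != layout.n - 1:
        raise ValueError(
            f"recording has {Y.shape[0]} channels but the montage implies "
            f"{layout.n - 1} differential channels")
    return Recording(Y=Y, sampling_rate=fs, ref_name=ref), layout
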
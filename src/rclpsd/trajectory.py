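"""Trajectory containers and interchange formats.

Two on-disk formats are supported with lossless round trips:

- extended XYZ text: one block per frame, a comment line carrying
  ``time=... box=...`` and per-atom columns
  ``species x y z ix iy iz [bound_site]`` (positions wrapped into the box,
  ``i*`` the periodic image flags). Extra trailing columns from external
  tools are ignored with a warning.
- HDF5 container with groups ``/positions`` (unwrapped), ``/times``,
  ``/species``, ``/registry``, ``/topology`` and ``/params``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .params import SimulationParameters
from .topology import Topology


@dataclass
class TrajectoryEnsemble:
    """Time-ordered unwrapped frames of one production run.

    ``frames`` has shape (n_frames, n_particles, 3); ``registry`` holds the
    per-frame molecule->site bond registry (-1 = unbound), shape
    (n_frames, n_mol).
    """

    frames: np.ndarray
    times: np.ndarray
    box: float
    topology: Topology
    params: SimulationParameters | None = None
    registry: np.ndarray | None = None
    seed: int | None = None
    realization_id: int | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, N, 3)")
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def monomer_frames(self) -> np.ndarray:
        return self.frames[:, : self.topology.n_mon]

    def molecule_frames(self) -> np.ndarray:
        return self.frames[:, self.topology.n_mon :]

    def center_of_mass(self) -> np.ndarray:
        """Per-frame unwrapped polymer center of mass, shape (n_frames, 3)."""
        return self.monomer_frames().mean(axis=1)


# ---------------------------------------------------------------- extended XYZ


def write_xyz(ens: TrajectoryEnsemble, path: str | Path) -> None:
    species = ens.topology.species()
    n_mon = ens.topology.n_mon
    L = ens.box
    with open(path, "w") as fh:
        for k in range(ens.n_frames):
            pos = ens.frames[k]
            img = np.floor(pos / L).astype(np.int64)
            wrapped = pos - L * img
            fh.write(f"{len(pos)}\n")
            fh.write(
                f'time={ens.times[k]:.17g} box={L:.17g} n_mon={n_mon} '
                f'properties=species:S:1:pos:R:3:image:I:3:bound_site:I:1\n'
            )
            for i in range(len(pos)):
                bs = -1
                if ens.registry is not None and i >= n_mon:
                    bs = int(ens.registry[k, i - n_mon])
                fh.write(
                    f"{species[i]} {wrapped[i,0]:.9f} {wrapped[i,1]:.9f} {wrapped[i,2]:.9f} "
                    f"{img[i,0]} {img[i,1]} {img[i,2]} {bs}\n"
                )


def read_xyz(path: str | Path, topology: Topology | None = None) -> TrajectoryEnsemble:
    """Read an extended-XYZ trajectory written by this package or compatible tools.

    Requires species + positions; image flags and bound_site columns are used
    when present, surplus columns are ignored with a warning.  A malformed or
    truncated frame raises with the index of the last good frame.
    """
    text = Path(path).read_text().splitlines()
    frames, times, regs, species = [], [], [], None
    box = None
    ln = 0
    n_frame = 0
    warned = False
    while ln < len(text):
        if not text[ln].strip():
            ln += 1
            continue
        try:
            nat = int(text[ln].strip())
        except ValueError as exc:
            raise ValueError(f"bad atom count before frame {n_frame} (last good frame {n_frame - 1})") from exc
        if ln + 1 + nat >= len(text) + 1 and ln + 1 + nat > len(text):
            raise ValueError(f"truncated file in frame {n_frame} (last good frame {n_frame - 1})")
        comment = text[ln + 1]
        meta = dict(
            tok.split("=", 1) for tok in comment.split() if "=" in tok and not tok.startswith("properties")
        )
        t = float(meta.get("time", n_frame))
        box = float(meta.get("box", box if box is not None else 0.0))
        spec, pos, img, bs = [], [], [], []
        for a in range(nat):
            cols = text[ln + 2 + a].split()
            if len(cols) < 4:
                raise ValueError(f"malformed atom line in frame {n_frame} (last good frame {n_frame - 1})")
            spec.append(cols[0])
            pos.append([float(c) for c in cols[1:4]])
            if len(cols) >= 7:
                img.append([int(float(c)) for c in cols[4:7]])
            else:
                img.append([0, 0, 0])
            bs.append(int(float(cols[7])) if len(cols) >= 8 else -1)
            if len(cols) > 8 and not warned:
                warnings.warn("extra per-atom columns ignored")
                warned = True
        pos = np.array(pos) + box * np.array(img, dtype=float)
        frames.append(pos)
        times.append(t)
        species = spec
        regs.append(bs)
        ln += 2 + nat
        n_frame += 1
    if not frames:
        raise ValueError("no frames found")
    frames = np.array(frames)
    if topology is None:
        n_mon = sum(1 for s in species if s in ("M", "S"))
        sites = np.array([i for i, s in enumerate(species) if s == "S"], dtype=np.int64)
        topology = Topology(
            n_mon=max(n_mon, 1),
            n_mol=len(species) - n_mon,
            binding_sites=sites,
        )
    registry = np.array(regs, dtype=np.int64)[:, topology.n_mon :]
    return TrajectoryEnsemble(
        frames=frames,
        times=np.array(times),
        box=float(box),
        topology=topology,
        registry=registry if registry.size else None,
    )


# ------------------------------------------------------------------ HDF5


def write_h5(ens: TrajectoryEnsemble, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("positions", data=ens.frames, compression="gzip", compression_opts=1)
        f.create_dataset("times", data=ens.times)
        f.create_dataset("species", data=np.char.encode(ens.topology.species()))
        if ens.registry is not None:
            f.create_dataset("registry", data=ens.registry)
        g = f.create_group("topology")
        g.attrs["n_mon"] = ens.topology.n_mon
        g.attrs["n_mol"] = ens.topology.n_mol
        g.create_dataset("cross_links", data=ens.topology.cross_links)
        g.create_dataset("binding_sites", data=ens.topology.binding_sites)
        f.attrs["box"] = ens.box
        if ens.seed is not None:
            f.attrs["seed"] = ens.seed
        if ens.realization_id is not None:
            f.attrs["realization_id"] = ens.realization_id
        if ens.params is not None:
            f.attrs["params_json"] = json.dumps(ens.params.to_dict())


def read_h5(path: str | Path) -> TrajectoryEnsemble:
    with h5py.File(path, "r") as f:
        topo = Topology(
            n_mon=int(f["topology"].attrs["n_mon"]),
            n_mol=int(f["topology"].attrs["n_mol"]),
            cross_links=f["topology/cross_links"][...],
            binding_sites=f["topology/binding_sites"][...],
        )
        params = None
        if "params_json" in f.attrs:
            params = SimulationParameters(**json.loads(f.attrs["params_json"]))
        return TrajectoryEnsemble(
            frames=f["positions"][...],
            times=f["times"][...],
            box=float(f.attrs["box"]),
            topology=topo,
            params=params,
            registry=f["registry"][...] if "registry" in f else None,
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
            realization_id=int(f.attrs["realization_id"]) if "realization_id" in f.attrs else None,
        )


def read_trajectory(path: str | Path) -> TrajectoryEnsemble:
    """Dispatch on extension: .h5/.hdf5 container, anything else extended XYZ."""
    p = Path(path)
    if p.suffix.lower() in (".h5", ".hdf5"):
        return read_h5(p)
    return read_xyz(p)


def write_trajectory(ens: TrajectoryEnsemble, path: str | Path) -> None:
    p = Path(path)
    if p.suffix.lower() in (".h5", ".hdf5"):
        write_h5(ens, p)
    else:
        write_xyz(ens, p)
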
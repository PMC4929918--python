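"""Writers and readers for meshes, tables, checkpoints and run manifests.

Meshes are exchanged as OFF and legacy-ASCII VTK polydata (coordinates
written with 17 significant digits, so round-trips are exact well beyond
the 9-digit contract).  Numeric tables are TSV with ``#`` header lines
naming units; simulation state checkpoints use a single HDF5 container.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .mesh import TriMesh

_FMT = "%.17g"


# ----------------------------------------------------------------------
# OFF
# ----------------------------------------------------------------------
def write_off(mesh: TriMesh, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("OFF\n")
        if mesh.box is not None:
            fh.write(f"# periodic-box {_FMT % mesh.box}\n")
        fh.write(f"{mesh.n_vertices} {mesh.n_triangles} {mesh.n_links}\n")
        for p in mesh.positions:
            fh.write(" ".join(_FMT % x for x in p) + "\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def read_off(path) -> TriMesh:
    path = Path(path)
    box = None
    tokens = []
    with path.open() as fh:
        header = fh.readline().strip()
        if header != "OFF":
            raise ValueError(f"{path}: not an OFF file")
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                if "periodic-box" in line:
                    box = float(line.split()[-1])
                continue
            if line:
                tokens.extend(line.split())
    nv, nf = int(tokens[0]), int(tokens[1])
    idx = 3
    pos = np.array(tokens[idx: idx + 3 * nv], dtype=float).reshape(nv, 3)
    idx += 3 * nv
    tris = []
    for _ in range(nf):
        k = int(tokens[idx])
        tris.append([int(x) for x in tokens[idx + 1: idx + 1 + k]])
        idx += 1 + k
    return TriMesh(pos, np.array(tris, dtype=np.int64), box=box)


# ----------------------------------------------------------------------
# legacy ASCII VTK polydata
# ----------------------------------------------------------------------
def write_vtk(mesh: TriMesh, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        box = mesh.box if mesh.box is not None else -1.0
        fh.write(f"membrane mesh periodic-box {_FMT % box}\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for p in mesh.positions:
            fh.write(" ".join(_FMT % x for x in p) + "\n")
        fh.write(f"POLYGONS {mesh.n_triangles} {4 * mesh.n_triangles}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def read_vtk(path) -> TriMesh:
    path = Path(path)
    lines = path.read_text().splitlines()
    box = None
    if "periodic-box" in lines[1]:
        b = float(lines[1].split()[-1])
        box = None if b < 0 else b
    i = next(k for k, l in enumerate(lines) if l.startswith("POINTS"))
    nv = int(lines[i].split()[1])
    vals = []
    j = i + 1
    while len(vals) < 3 * nv:
        vals.extend(float(x) for x in lines[j].split())
        j += 1
    pos = np.array(vals).reshape(nv, 3)
    i = next(k for k, l in enumerate(lines) if l.startswith("POLYGONS"))
    nf = int(lines[i].split()[1])
    tris = []
    for l in lines[i + 1: i + 1 + nf]:
        parts = [int(x) for x in l.split()]
        tris.append(parts[1:4])
    return TriMesh(pos, np.array(tris, dtype=np.int64), box=box)


# ----------------------------------------------------------------------
# TSV tables with unit headers
# ----------------------------------------------------------------------
def write_table(df: pd.DataFrame, path, units: dict | None = None,
                meta: dict | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        if units:
            fh.write("# units: " + " ".join(f"{c}={u}" for c, u in units.items())
                     + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ----------------------------------------------------------------------
# HDF5 checkpoints
# ----------------------------------------------------------------------
def save_checkpoint(system, path, chunk_index: int = 0, seed: int = 0,
                    step_sizes=(2.0, 4.0, 0.3)) -> None:
    from .system import AdhesionSystem  # noqa: F401 (documentation import)

    path = Path(path)
    m = system.mesh
    with h5py.File(path, "w") as f:
        f.attrs["chunk_index"] = chunk_index
        f.attrs["seed"] = seed
        f.attrs["step_sizes"] = step_sizes
        f.attrs["box"] = m.box if m.box is not None else -1.0
        f.attrs["box_height"] = system.box_height
        g = f.create_group("mesh")
        g.create_dataset("positions", data=m.positions)
        g.create_dataset("triangles", data=m.triangles)
        g.create_dataset("pinned", data=system.pinned)
        # adjacency layout verbatim: the kernel addresses these by index
        g.create_dataset("links", data=m.links)
        g.create_dataset("link_opp", data=m.link_opp)
        g.create_dataset("link_tri", data=m.link_tri)
        g.create_dataset("neighbors", data=m.neighbors)
        g.create_dataset("vertex_links", data=m.vertex_links)
        g.create_dataset("degree", data=m.degree)
        g = f.create_group("receptors")
        g.create_dataset("vertex", data=system.rec_vertex)
        g.create_dataset("theta", data=system.rec_theta)
        g.create_dataset("phi", data=system.rec_phi)
        g.create_dataset("bond", data=system.rec_bond)
        g = f.create_group("params")
        for name, val in (("kappa", system.membrane.kappa),
                          ("sigma", system.membrane.sigma),
                          ("a0", system.membrane.a0),
                          ("L", system.membrane.L),
                          ("link_max_factor", system.membrane.link_max_factor),
                          ("link_min_factor", system.membrane.link_min_factor),
                          ("rec_length", system.receptors.length),
                          ("kappa_f", system.receptors.kappa_f),
                          ("H0", system.bonds.H0),
                          ("kappa_b", system.bonds.kappa_b),
                          ("d_star", system.bonds.d_star)):
            g.attrs[name] = val
        if system.carrier is not None:
            c = f.create_group("carrier")
            c.create_dataset("center", data=system.carrier.center)
            c.create_dataset("quaternion", data=system.carrier.quaternion)
            c.create_dataset("ligand_dirs", data=system.carrier.ligand_dirs)
            c.attrs["radius"] = system.carrier.radius
            c.attrs["ligand_length"] = system.carrier.ligand_length


def load_checkpoint(path):
    from .mesh import MembraneParams
    from .molecules import BondParams, Carrier, ReceptorParams
    from .system import AdhesionSystem

    path = Path(path)
    with h5py.File(path, "r") as f:
        box = float(f.attrs["box"])
        mesh = TriMesh.from_state(
            f["mesh/positions"][...], f["mesh/triangles"][...],
            None if box < 0 else box,
            f["mesh/links"][...], f["mesh/link_opp"][...],
            f["mesh/link_tri"][...], f["mesh/neighbors"][...],
            f["mesh/vertex_links"][...], f["mesh/degree"][...])
        p = f["params"].attrs
        membrane = MembraneParams(
            kappa=float(p["kappa"]), sigma=float(p["sigma"]),
            a0=float(p["a0"]), L=float(p["L"]),
            link_max_factor=float(p["link_max_factor"]),
            link_min_factor=float(p["link_min_factor"]))
        receptors = ReceptorParams(length=float(p["rec_length"]),
                                   kappa_f=float(p["kappa_f"]))
        bonds = BondParams(H0=float(p["H0"]), kappa_b=float(p["kappa_b"]),
                           d_star=float(p["d_star"]))
        carrier = None
        if "carrier" in f:
            c = f["carrier"]
            carrier = Carrier(
                center=c["center"][...],
                quaternion=c["quaternion"][...],
                ligand_dirs=c["ligand_dirs"][...],
                radius=float(c.attrs["radius"]),
                ligand_length=float(c.attrs["ligand_length"]))
        system = AdhesionSystem(
            mesh=mesh, membrane=membrane, receptors=receptors, bonds=bonds,
            carrier=carrier, box_height=float(f.attrs["box_height"]),
            rec_vertex=f["receptors/vertex"][...],
            rec_theta=f["receptors/theta"][...],
            rec_phi=f["receptors/phi"][...],
            rec_bond=f["receptors/bond"][...],
            pinned=f["mesh/pinned"][...].astype(np.bool_))
        meta = {
            "chunk_index": int(f.attrs["chunk_index"]),
            "seed": int(f.attrs["seed"]),
            "step_sizes": tuple(float(x) for x in f.attrs["step_sizes"]),
        }
    return system, meta


# ----------------------------------------------------------------------
# trajectory container
# ----------------------------------------------------------------------
def save_trajectory(traj, path) -> None:
    """Write a TrajectoryRecord to one HDF5 container."""
    with h5py.File(Path(path), "w") as f:
        for name in ("n_b", "delta_r", "quaternions", "nc_center", "energy",
                     "move_stats", "bound_moments", "nc_moments"):
            f.create_dataset(name, data=getattr(traj, name))
        f.attrs["cadence"] = traj.cadence
        f.attrs["cadence_slow"] = traj.cadence_slow
        f.attrs["seed"] = traj.seed
        f.attrs["final_energy"] = traj.final_energy
        f.attrs["final_delta_r"] = traj.final_delta_r


def load_trajectory(path):
    from .engine import TrajectoryRecord

    with h5py.File(Path(path), "r") as f:
        return TrajectoryRecord(
            n_b=f["n_b"][...], delta_r=f["delta_r"][...],
            quaternions=f["quaternions"][...], nc_center=f["nc_center"][...],
            energy=f["energy"][...], move_stats=f["move_stats"][...],
            bound_moments=f["bound_moments"][...],
            nc_moments=f["nc_moments"][...],
            cadence=int(f.attrs["cadence"]),
            cadence_slow=int(f.attrs["cadence_slow"]),
            seed=int(f.attrs["seed"]),
            final_energy=float(f.attrs["final_energy"]),
            final_delta_r=float(f.attrs["final_delta_r"]))


# ----------------------------------------------------------------------
# run manifest
# ----------------------------------------------------------------------
@dataclass
class RunManifest:
    """Provenance record tying every output file to its configuration."""

    command: str
    seed: int
    config: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    started: str = ""
    finished: str = ""
    version: str = ""

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__

            self.version = __version__
        if not self.started:
            self.started = time.strftime("%Y-%m-%dT%H:%M:%S")

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def write(self, path) -> None:
        self.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
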
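"""Combined NC-membrane system state.

Bundles the triangulated membrane, the mobile receptors, the rigid
carrier and all interaction parameters, and provides full-recomputation
energies and the adhesion order parameter used to cross-check the
incremental bookkeeping of the compiled MC kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .mesh import MembraneParams, TriMesh, helfrich_vertex_energies
from .molecules import (
    BondParams,
    Carrier,
    ReceptorParams,
    bound_bond_energy,
    receptor_tip,
)


class StateCorruptionError(RuntimeError):
    """Inconsistent bond bookkeeping or cached-energy drift."""


@dataclass
class AdhesionSystem:
    """Mutable simulation state (arrays are shared with the MC kernel)."""

    mesh: TriMesh
    membrane: MembraneParams
    receptors: ReceptorParams = field(default_factory=ReceptorParams)
    bonds: BondParams = field(default_factory=BondParams)
    carrier: Carrier | None = None
    box_height: float = 500.0  # L_z, nm (0.5 um simulation height)
    rec_vertex: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    rec_theta: np.ndarray = field(default_factory=lambda: np.empty(0, np.float64))
    rec_phi: np.ndarray = field(default_factory=lambda: np.empty(0, np.float64))
    rec_bond: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    pinned: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.mesh.n_vertices
        if self.pinned is None:
            self.pinned = np.zeros(n, dtype=np.bool_)
        self.occupied = np.full(n, -1, dtype=np.int64)
        for r, v in enumerate(self.rec_vertex):
            if self.occupied[v] >= 0:
                raise StateCorruptionError(f"two receptors on vertex {v}")
            self.occupied[v] = r
        if self.carrier is not None:
            self.lig_bond = np.full(self.carrier.n_ligands, -1, np.int64)
            for r, j in enumerate(self.rec_bond):
                if j >= 0:
                    self.lig_bond[j] = r
        else:
            self.lig_bond = np.full(1, -1, np.int64)

    # ------------------------------------------------------------------
    @classmethod
    def place_receptors(
        cls,
        mesh: TriMesh,
        membrane: MembraneParams,
        n_receptors: int,
        seed: int = 0,
        **kwargs,
    ) -> "AdhesionSystem":
        """Receptors on uniformly random distinct vertices, unflexed."""
        rng = np.random.default_rng(seed)
        if n_receptors > mesh.n_vertices:
            raise ValueError("more receptors than vertices")
        verts = rng.choice(mesh.n_vertices, size=n_receptors, replace=False)
        return cls(
            mesh=mesh,
            membrane=membrane,
            rec_vertex=np.sort(verts).astype(np.int64),
            rec_theta=np.zeros(n_receptors),
            rec_phi=np.zeros(n_receptors),
            rec_bond=np.full(n_receptors, -1, np.int64),
            **kwargs,
        )

    # ------------------------------------------------------------------
    @property
    def n_receptors(self) -> int:
        return len(self.rec_vertex)

    @property
    def n_bonds(self) -> int:
        return int((self.rec_bond >= 0).sum())

    def validate_bonds(self) -> None:
        """Bond bookkeeping must form a partial matching."""
        seen = {}
        for r, j in enumerate(self.rec_bond):
            if j >= 0:
                if j in seen:
                    raise StateCorruptionError(
                        f"ligand {j} bound to receptors {seen[j]} and {r}")
                seen[j] = r
                if self.lig_bond[j] != r:
                    raise StateCorruptionError(
                        f"asymmetric bond bookkeeping for pair ({r}, {j})")
        for j, r in enumerate(self.lig_bond):
            if r >= 0 and self.rec_bond[r] != j:
                raise StateCorruptionError(
                    f"asymmetric bond bookkeeping for ligand {j}")

    # ------------------------------------------------------------------
    def receptor_tips(self) -> np.ndarray:
        from .mesh import vertex_normals

        vn = vertex_normals(self.mesh)
        tips = np.empty((self.n_receptors, 3))
        for r in range(self.n_receptors):
            v = self.rec_vertex[r]
            tips[r] = receptor_tip(
                self.mesh.positions[v], vn[v], self.rec_theta[r],
                self.rec_phi[r], self.receptors)
        return tips

    def _min_image(self, d: np.ndarray) -> np.ndarray:
        box = self.mesh.box
        if box is not None:
            d = d.copy()
            d[..., :2] -= box * np.round(d[..., :2] / box)
        return d

    def total_energy(self) -> float:
        """Full recomputation: H_t = H_m + sum H_f + sum bonded H_b (k_B T)."""
        e = float(helfrich_vertex_energies(self.mesh, self.membrane).sum())
        e += float(0.5 * self.receptors.kappa_f * (self.rec_theta**2).sum())
        if self.carrier is not None and self.n_bonds:
            tips = self.receptor_tips()
            lig_tips = self.carrier.ligand_tips()
            for r, j in enumerate(self.rec_bond):
                if j >= 0:
                    d = np.linalg.norm(self._min_image(tips[r] - lig_tips[j]))
                    e += bound_bond_energy(d, self.bonds)
        return e

    def delta_r(self) -> float:
        """Order parameter |R_CM - R_NC| (nm)."""
        if self.carrier is None:
            raise ValueError("no carrier in the system")
        box = self.mesh.box if self.mesh.box is not None else -1.0
        return float(_kernels.compute_delta_r(
            self.mesh.positions, self.carrier.center, box,
            2.0 * self.carrier.radius))

    def check_excluded_volume(self) -> bool:
        """No vertex strictly inside the NC sphere."""
        if self.carrier is None:
            return True
        d = self._min_image(self.mesh.positions - self.carrier.center)
        return bool((np.linalg.norm(d, axis=1) >= self.carrier.radius - 1e-9).all())

    # ------------------------------------------------------------------
    def kernel_arrays(self) -> dict:
        """Array bundle shared with the compiled kernel (mutated in place)."""
        m = self.mesh
        if self.carrier is not None:
            car = self.carrier
            center = car.center
            quat = car.quaternion
            lig_dirs = car.ligand_dirs
            lig_tip = car.ligand_tips()
            r_nc = car.radius
            lig_len = car.ligand_length
        else:
            center = np.zeros(3)
            quat = np.array([1.0, 0.0, 0.0, 0.0])
            lig_dirs = np.zeros((1, 3))
            lig_dirs[0, 2] = 1.0
            lig_tip = np.zeros((1, 3))
            r_nc = 0.0
            lig_len = 0.0
        return dict(
            pos=m.positions, nbr=m.neighbors, nlink=m.vertex_links,
            deg=m.degree, links=m.links, link_opp=m.link_opp,
            link_tri=m.link_tri, tris=m.triangles,
            pinned=self.pinned,
            rec_vertex=self.rec_vertex, rec_theta=self.rec_theta,
            rec_phi=self.rec_phi, rec_bond=self.rec_bond,
            occupied=self.occupied,
            center=center, quat=quat, lig_dirs=lig_dirs, lig_tip=lig_tip,
            lig_bond=self.lig_bond,
            box=m.box if m.box is not None else -1.0,
            kappa=self.membrane.kappa, sigma=self.membrane.sigma,
            a0=self.membrane.l_min, lmax=self.membrane.l_max,
            rec_len=self.receptors.length, kappa_f=self.receptors.kappa_f,
            H0=self.bonds.H0, kb=self.bonds.kappa_b, dstar=self.bonds.d_star,
            r_nc=r_nc, lig_len=lig_len, L_z=self.box_height,
        )
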
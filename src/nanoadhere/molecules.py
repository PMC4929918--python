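"""Receptors, the functionalized nanocarrier, and molecular energy terms.

Receptors are rigid rods of length ``L_an`` anchored at mesh vertices; their
orientation is given by flexural angles (theta, phi) measured from the local
membrane normal, with flexural energy ``H_f = kappa_f theta^2 / 2``.

The nanocarrier (NC) is a rigid sphere carrying ``N_ab`` radial ligand rods
of length ``L_ab``.  A receptor-ligand pair interacts through the Bell
potential

    H_b(d) = H0 + kappa_b (d - d*)^2 / 2   for d <= d*,   0 otherwise,

where ``d`` is the tip-tip distance and ``d*`` the reaction range.  Bound
pairs (the discrete matching maintained by the bond move) interact through
the harmonic branch at any ``d``; the piecewise form defines the reaction
range for bond formation.

Internally all energies are k_B T and all lengths nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .units import UnitSystem


@dataclass
class ReceptorParams:
    """Receptor rod geometry and stiffness.

    length : rod length L_an, nm (ICAM-1 ectodomain scale, default 19).
    kappa_f : flexural rigidity, k_B T / rad^2.  The literature value
        7000 pN nm converts to ~1690 k_B T/rad^2 at 300 K.
    """

    length: float = 19.0
    kappa_f: float = UnitSystem(300.0).pN_nm_to_kBT(7000.0)

    def __post_init__(self) -> None:
        if self.length <= 0 or self.kappa_f < 0:
            raise ValueError("receptor length must be > 0 and kappa_f >= 0")


@dataclass
class BondParams:
    """Bell-potential parameters (internal units).

    H0 : bond depth, k_B T (negative).
    kappa_b : bond spring constant, k_B T / nm^2.
    d_star : reaction range, nm.
    """

    H0: float = UnitSystem(300.0).joule_to_kBT(-7.98e-20)
    kappa_b: float = UnitSystem(300.0).N_per_m_to_kBT_per_nm2(1.0)
    d_star: float = 1.0

    def __post_init__(self) -> None:
        if self.H0 >= 0:
            raise ValueError(f"H0 must be negative, got {self.H0}")
        if self.d_star <= 0:
            raise ValueError(f"d_star must be positive, got {self.d_star}")


@dataclass
class Carrier:
    """Rigid spherical nanocarrier with radial rod ligands.

    center : (3,) position of the sphere centre, nm.
    quaternion : (4,) unit quaternion (w, x, y, z) body->world.
    radius : NC radius, nm (default 50: a 100 nm carrier).
    ligand_dirs : (N_ab, 3) unit vectors in the body frame.
    ligand_length : L_ab, nm (default 15: antibody scale).
    """

    center: np.ndarray
    radius: float = 50.0
    ligand_length: float = 15.0
    n_ligands: int = 162
    quaternion: np.ndarray = field(default_factory=lambda: np.array([1.0, 0, 0, 0]))
    ligand_dirs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=np.float64)
        self.quaternion = np.asarray(self.quaternion, dtype=np.float64)
        if self.ligand_dirs is None:
            self.ligand_dirs = fibonacci_sphere(self.n_ligands)
        else:
            self.ligand_dirs = np.asarray(self.ligand_dirs, dtype=np.float64)
            self.n_ligands = len(self.ligand_dirs)

    def ligand_tips(self) -> np.ndarray:
        """World-frame tip positions, on the sphere of radius r_NC + L_ab."""
        world = quat_rotate(self.quaternion, self.ligand_dirs)
        return self.center + (self.radius + self.ligand_length) * world

    def ligand_bases(self) -> np.ndarray:
        world = quat_rotate(self.quaternion, self.ligand_dirs)
        return self.center + self.radius * world


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic near-uniform unit vectors (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


# ----------------------------------------------------------------------
# quaternion helpers (w, x, y, z convention)
# ----------------------------------------------------------------------
def quat_mul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = a
    w2, x2, y2, z2 = b
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def quat_from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    h = 0.5 * angle
    return np.concatenate([[math.cos(h)], math.sin(h) * axis])


def quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) v by unit quaternion q."""
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return np.asarray(v) @ R.T


def quat_to_euler_zxz(q: np.ndarray) -> tuple[float, float, float]:
    """Euler angles (phi, theta, psi) in the ZXZ convention."""
    w, x, y, z = q / np.linalg.norm(q)
    R = quat_rotate(np.array([w, x, y, z]), np.eye(3)).T
    theta = math.acos(min(1.0, max(-1.0, R[2, 2])))
    if abs(R[2, 2]) > 1.0 - 1e-12:
        phi = math.atan2(R[1, 0], R[0, 0])
        psi = 0.0
    else:
        phi = math.atan2(R[0, 2], -R[1, 2])
        psi = math.atan2(R[2, 0], R[2, 1])
    return phi, theta, psi


# ----------------------------------------------------------------------
# energies
# ----------------------------------------------------------------------
def flexural_energy(theta: float, params: ReceptorParams) -> float:
    """H_f = kappa_f theta^2 / 2, k_B T; independent of phi."""
    if not 0.0 <= theta <= math.pi:
        raise ValueError(f"theta = {theta} outside [0, pi]")
    return 0.5 * params.kappa_f * theta * theta


def bond_energy(d: float, params: BondParams) -> float:
    """Bell potential at tip-tip distance d (nm), k_B T."""
    if d < 0:
        raise ValueError(f"distance must be >= 0, got {d}")
    if d > params.d_star:
        return 0.0
    return params.H0 + 0.5 * params.kappa_b * (d - params.d_star) ** 2


def bound_bond_energy(d: float, params: BondParams) -> float:
    """Energy of an *established* bond: harmonic branch at any d."""
    return params.H0 + 0.5 * params.kappa_b * (d - params.d_star) ** 2


def tangent_frame(normal: np.ndarray):
    """Deterministic orthonormal tangent frame (t1, t2) for a unit normal."""
    n = np.asarray(normal, dtype=float)
    ref = np.array([1.0, 0.0, 0.0])
    t1 = ref - n * (ref @ n)
    if np.linalg.norm(t1) < 1e-8:
        ref = np.array([0.0, 1.0, 0.0])
        t1 = ref - n * (ref @ n)
    t1 = t1 / np.linalg.norm(t1)
    t2 = np.cross(n, t1)
    return t1, t2


def receptor_tip(
    base: np.ndarray,
    normal: np.ndarray,
    theta: float,
    phi: float,
    params: ReceptorParams,
) -> np.ndarray:
    """Tip position of a rigid receptor rod.

    theta tilts the rod away from the vertex normal; phi rotates the tilt
    axis within the tangent plane.  theta = phi = 0 reproduces the normal
    direction exactly.
    """
    n = np.asarray(normal, dtype=float)
    nn = np.linalg.norm(n)
    if nn < 1e-8:
        raise ValueError("degenerate vertex normal")
    n = n / nn
    t1, t2 = tangent_frame(n)
    direction = (
        math.cos(theta) * n
        + math.sin(theta) * (math.cos(phi) * t1 + math.sin(phi) * t2)
    )
    return np.asarray(base, dtype=float) + params.length * direction


def receptor_count(density_per_um2: float, Ap_nm2: float) -> int:
    """round(density * Ap); densities are per projected area."""
    return int(round(density_per_um2 * Ap_nm2 / 1.0e6))
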
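"""Deterministic synthetic fixtures with embedded analytic ground truth.

Every oracle test in the suite draws its inputs from here: closed meshes
with known curvature (icosphere, cylinder), sinusoidally displaced patches
with quadrature excess area, Gaussian height fields synthesized directly
from the Helfrich fluctuation spectrum, a 1-D umbrella-sampling toy, and a
two-state binding toy with a quadrature association constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import trimesh as _trimesh

from .mesh import MeshError, TriMesh, build_flat_patch

KNOWN_KINDS = (
    "icosphere",
    "cylinder",
    "sinusoid-patch",
    "gaussian-field",
    "toy-1d-umbrella",
    "toy-binding",
)


@dataclass
class FixtureSpec:
    """Declarative fixture request; generation is deterministic per spec."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KNOWN_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; "
                             f"expected one of {KNOWN_KINDS}")


# ----------------------------------------------------------------------
# closed analytic meshes
# ----------------------------------------------------------------------
def icosphere(radius: float = 100.0, subdivisions: int = 3) -> TriMesh:
    """Closed icosphere; every vertex has c1 = c2 = 1/radius."""
    ico = _trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriMesh(np.asarray(ico.vertices), np.asarray(ico.faces), box=None)


def closed_cylinder(
    radius: float = 50.0,
    height: float = 400.0,
    n_sections: int = 24,
    n_rows: int = 20,
) -> TriMesh:
    """Closed cylinder with fan caps; lateral vertices have (1/radius, 0).

    Curvature oracles should be evaluated at rows away from the caps.
    """
    phis = 2.0 * np.pi * np.arange(n_sections) / n_sections
    ring = np.column_stack([radius * np.cos(phis), radius * np.sin(phis)])
    zs = np.linspace(0.0, height, n_rows + 1)
    verts = [np.array([0.0, 0.0, 0.0])]
    for z in zs:
        verts.extend(np.column_stack([ring, np.full(n_sections, z)]))
    verts.append(np.array([0.0, 0.0, height]))
    verts = np.vstack(verts)
    bot, top = 0, len(verts) - 1

    def rid(row, i):
        return 1 + row * n_sections + (i % n_sections)

    tris = []
    for i in range(n_sections):  # caps, oriented outward (-z / +z)
        tris.append((bot, rid(0, i + 1), rid(0, i)))
        tris.append((top, rid(n_rows, i), rid(n_rows, i + 1)))
    for r in range(n_rows):  # lateral quads
        for i in range(n_sections):
            a, b = rid(r, i), rid(r, i + 1)
            c, d = rid(r + 1, i + 1), rid(r + 1, i)
            tris.append((a, b, c))
            tris.append((a, c, d))
    return TriMesh(verts, np.array(tris, dtype=np.int64), box=None)


def cylinder_lateral_vertices(mesh: TriMesh, height: float, margin: float = 0.25):
    """Vertex ids on the lateral wall, at least ``margin*height`` from caps."""
    z = mesh.positions[:, 2]
    r = np.linalg.norm(mesh.positions[:, :2], axis=1)
    return np.flatnonzero((z > margin * height) & (z < (1 - margin) * height) & (r > 1e-6))


# ----------------------------------------------------------------------
# sinusoid patch: analytic excess area oracle
# ----------------------------------------------------------------------
def sinusoid_patch(L: float = 500.0, a0: float = 10.0, h0: float = 25.0) -> TriMesh:
    """Flat patch with h(x, y) = h0 sin(2 pi x / L) imposed on the vertices."""
    m = build_flat_patch(L, a0)
    m.positions[:, 2] = h0 * np.sin(2.0 * np.pi * m.positions[:, 0] / L)
    return m


def sinusoid_excess_area_exact(L: float, h0: float, n_quad: int = 20001) -> float:
    """Excess area of the continuum sinusoid sheet by 1-D quadrature.

    A = L * int_0^L sqrt(1 + h_x^2) dx with h_x = (2 pi h0 / L) cos(2 pi x/L).
    """
    x = np.linspace(0.0, L, n_quad)
    hx = (2.0 * np.pi * h0 / L) * np.cos(2.0 * np.pi * x / L)
    A = L * np.trapezoid(np.sqrt(1.0 + hx * hx), x)
    Ap = L * L
    return 100.0 * (A - Ap) / A


# ----------------------------------------------------------------------
# Gaussian field drawn from the Helfrich spectrum (generator-estimator closure)
# ----------------------------------------------------------------------
def helfrich_mode_grid(grid_n: int, L: float):
    """Wavevector magnitudes |q| for an FFT grid over an L x L box."""
    q1 = 2.0 * np.pi * np.fft.fftfreq(grid_n, d=L / grid_n)
    qx, qy = np.meshgrid(q1, q1, indexing="ij")
    return np.sqrt(qx * qx + qy * qy)


def gaussian_helfrich_field(
    grid_n: int,
    L: float,
    kappa: float,
    sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Real height field whose Fourier coefficients h_q = FFT(h)/N^2 satisfy
    <|h_q|^2> = kBT / (Ap (kappa q^4 + sigma q^2)) with kBT = 1 (energies in
    thermal units).  The q = 0 mode is suppressed."""
    q = helfrich_mode_grid(grid_n, L)
    Ap = L * L
    S = np.zeros_like(q)
    nz = q > 0
    S[nz] = 1.0 / (Ap * (kappa * q[nz] ** 4 + sigma * q[nz] ** 2))
    w = rng.standard_normal((grid_n, grid_n))
    h = np.fft.ifft2(grid_n * np.sqrt(S) * np.fft.fft2(w)).real
    return h


# ----------------------------------------------------------------------
# 1-D umbrella toy: exact window sampling by inverse-CDF
# ----------------------------------------------------------------------
@dataclass
class ToyUmbrella:
    """A particle on a 1-D potential, sampled exactly per biased window.

    ``potential`` maps position (nm) to energy (k_B T).  Draws from the
    biased Boltzmann density use inverse-CDF sampling on a fine grid, so
    window histograms carry no Markov-chain error.
    """

    potential: Callable[[np.ndarray], np.ndarray]
    x_min: float
    x_max: float
    n_grid: int = 20001

    def sample_window(self, x0: float, k_bias: float, n: int,
                      rng: np.random.Generator) -> np.ndarray:
        x = np.linspace(self.x_min, self.x_max, self.n_grid)
        u = self.potential(x) + 0.5 * k_bias * (x - x0) ** 2
        u -= u.min()
        p = np.exp(-u)
        cdf = np.cumsum(p)
        cdf /= cdf[-1]
        return np.interp(rng.random(n), cdf, x)


def harmonic_toy(k: float = 0.5) -> ToyUmbrella:
    """V(x) = k x^2 / 2 over a generous range."""
    return ToyUmbrella(lambda x: 0.5 * k * x * x, -30.0, 30.0)


def well_toy(depth: float = 5.0, x0: float = 10.0, width: float = 3.0,
             x_max: float = 60.0) -> ToyUmbrella:
    """Gaussian well of known depth centred at x0, flat (zero) far away."""
    return ToyUmbrella(
        lambda x: -depth * np.exp(-0.5 * ((x - x0) / width) ** 2), 0.0, x_max
    )


# ----------------------------------------------------------------------
# two-state binding toy with a quadrature association-constant oracle
# ----------------------------------------------------------------------
@dataclass
class ToyBinding:
    """Single carrier in a box, harmonic well along the separation axis.

    W(r) = -w0 + k_w (r - r0)^2 / 2 for r < r_star, 0 beyond; the bound
    carrier is laterally confined to an area ``A_N_b`` and the unbound one
    roams a slab of lateral area numerically equal to ``L_z`` (the
    normalization convention of the avidity formula).
    """

    w0: float = 8.0
    r0: float = 20.0
    k_w: float = 0.1
    r_star: float = 60.0
    L_z: float = 500.0
    A_N_b: float = 400.0

    def pmf(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        w = -self.w0 + 0.5 * self.k_w * (r - self.r0) ** 2
        return np.where(r < self.r_star, w, 0.0)

    def pmf_grid(self, n: int = 2001):
        r = np.linspace(0.0, self.r_star, n)
        return r, self.pmf(r)

    def ka_oracle(self, n_samples: int = 400_000, seed: int = 12345) -> float:
        """Brute-force Monte Carlo integration of Z_bound / Z_unbound.

        Independent of the avidity module: samples the 3-D carrier
        coordinate uniformly and averages indicator-weighted Boltzmann
        factors.
        """
        rng = np.random.default_rng(seed)
        S_lat = self.L_z  # lateral area of the reference slab
        half = math.sqrt(S_lat) / 2.0
        x = rng.uniform(-half, half, n_samples)
        y = rng.uniform(-half, half, n_samples)
        z = rng.uniform(0.0, self.L_z, n_samples)
        r_conf = math.sqrt(self.A_N_b / math.pi)
        bound = (z < self.r_star) & (x * x + y * y < r_conf * r_conf)
        zb = np.where(bound, np.exp(-self.pmf(z)), 0.0).mean() * S_lat * self.L_z
        zu = float((z >= self.r_star).mean()) * S_lat * self.L_z
        return float(zb / zu)


# ----------------------------------------------------------------------
# dispatcher
# ----------------------------------------------------------------------
def generate_fixture(spec: FixtureSpec):
    """Build the fixture object described by ``spec`` (deterministic)."""
    p = dict(spec.params)
    if spec.kind == "icosphere":
        return icosphere(**p)
    if spec.kind == "cylinder":
        return closed_cylinder(**p)
    if spec.kind == "sinusoid-patch":
        return sinusoid_patch(**p)
    if spec.kind == "gaussian-field":
        rng = np.random.default_rng(spec.seed)
        return gaussian_helfrich_field(rng=rng, **p)
    if spec.kind == "toy-1d-umbrella":
        return well_toy(**p) if "depth" in p else harmonic_toy(**p)
    if spec.kind == "toy-binding":
        return ToyBinding(**p)
    raise ValueError(spec.kind)
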
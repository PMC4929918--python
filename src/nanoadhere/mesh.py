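"""Dynamically triangulated membrane patch.

The membrane is a triangulated surface with ``N_m`` vertices, ``T_m``
triangles and ``L_m`` links.  Production meshes are periodic in-plane
(torus topology, so ``N_m + T_m - L_m = 0``); closed meshes (sphere,
cylinder) are supported as analytic test fixtures.

Self-avoidance follows the tether-and-bead construction: every link length
is constrained to ``[a0, link_max_factor * a0]``.  The default
``link_max_factor = sqrt(3)`` keeps the diagonal links of the initial
square grid (length ``a0*sqrt(2)``) admissible without rescaling.

Curvature is estimated per vertex with the cotangent discretization of the
Laplace-Beltrami operator (mean curvature) plus the angle-deficit formula
(Gaussian curvature); the vertex area ``A_v`` is one third of the incident
triangle areas.  The bending + tension energy is

    H_m = sum_v [ kappa/2 * (c1_v + c2_v)^2 * A_v + sigma * A_v ].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

SQRT3 = math.sqrt(3.0)

#: maximum vertex degree supported by the fixed-width adjacency tables
MAX_DEGREE = 32


class MeshError(ValueError):
    """Raised for invalid or degenerate mesh configurations."""


@dataclass
class MembraneParams:
    """Elastic and discretization parameters of the membrane patch.

    kappa : bending rigidity, k_B T.
    sigma : surface tension, k_B T / nm^2 (may be negative to pump excess
            area into the patch; the ensemble is constant (T, Ap, sigma)).
    a0 : tether discretization length, nm.
    L : projected box side, nm (must be a multiple of a0 for flat patches).
    temperature : K.
    link_max_factor : ratio l_max / a0 of the self-avoidance tether.
    """

    kappa: float = 20.0
    sigma: float = 0.0
    a0: float = 10.0
    L: float = 250.0
    temperature: float = 300.0
    link_max_factor: float = SQRT3
    link_min_factor: float = 0.75

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise MeshError(f"kappa must be >= 0, got {self.kappa}")
        if self.a0 <= 0:
            raise MeshError(f"a0 must be > 0, got {self.a0}")
        if not 0.0 < self.link_min_factor < self.link_max_factor:
            raise MeshError("need 0 < link_min_factor < link_max_factor")

    @property
    def l_max(self) -> float:
        return self.link_max_factor * self.a0

    @property
    def l_min(self) -> float:
        """Hard-core tether minimum.  The regular grid is built at spacing
        a0, which is the *lower edge* of the printed self-avoidance window;
        a hard minimum exactly at a0 would jam the initial lattice, so the
        excluded-volume core sits at link_min_factor * a0 (< 1)."""
        return self.link_min_factor * self.a0


@dataclass
class CurvatureResult:
    """Per-vertex principal curvatures (1/nm) and vertex areas (nm^2)."""

    c1: np.ndarray
    c2: np.ndarray
    A_v: np.ndarray

    @property
    def total_area(self) -> float:
        return float(self.A_v.sum())


@dataclass
class PinningConfig:
    """Cytoskeletal pinning: a fraction of vertices held immobile.

    The pinning fraction mimics a cortical mesh size of roughly
    150-500 nm; by default it is validated to lie in [0, 0.12].
    """

    pinning_fraction: float = 0.0
    seed: int = 0
    max_fraction: float = 0.12
    pinned_vertex_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.pinning_fraction <= self.max_fraction):
            raise MeshError(
                f"pinning fraction {self.pinning_fraction} outside "
                f"[0, {self.max_fraction}]"
            )

    def choose(self, n_vertices: int) -> np.ndarray:
        """Uniformly random pinned vertex set (deterministic per seed)."""
        if self.pinned_vertex_ids is not None:
            return np.asarray(self.pinned_vertex_ids, dtype=np.int64)
        n_pin = int(round(self.pinning_fraction * n_vertices))
        rng = np.random.default_rng(self.seed)
        ids = rng.choice(n_vertices, size=n_pin, replace=False)
        self.pinned_vertex_ids = np.sort(ids).astype(np.int64)
        return self.pinned_vertex_ids


class TriMesh:
    """Triangulated surface with periodic in-plane boundaries.

    Parameters
    ----------
    positions : (N, 3) float array, nm.
    triangles : (T, 3) int array of vertex ids, consistently oriented.
    box : float or None
        In-plane periodic box side (nm); ``None`` for closed fixture meshes.
    """

    def __init__(self, positions, triangles, box: float | None):
        self.positions = np.ascontiguousarray(positions, dtype=np.float64)
        self.triangles = np.ascontiguousarray(triangles, dtype=np.int64)
        self.box = box
        self._build_adjacency()

    @classmethod
    def from_state(cls, positions, triangles, box, links, link_opp, link_tri,
                   neighbors, vertex_links, degree) -> "TriMesh":
        """Restore a mesh with its adjacency arrays verbatim.

        The MC kernel addresses links and neighbour slots by array index,
        so checkpoint restoration must preserve the evolved layout exactly
        (a canonical rebuild would change RNG-addressed orderings).
        """
        m = cls.__new__(cls)
        m.positions = np.ascontiguousarray(positions, dtype=np.float64)
        m.triangles = np.ascontiguousarray(triangles, dtype=np.int64)
        m.box = box
        m.links = np.ascontiguousarray(links, dtype=np.int64)
        m.link_opp = np.ascontiguousarray(link_opp, dtype=np.int64)
        m.link_tri = np.ascontiguousarray(link_tri, dtype=np.int64)
        m.neighbors = np.ascontiguousarray(neighbors, dtype=np.int64)
        m.vertex_links = np.ascontiguousarray(vertex_links, dtype=np.int64)
        m.degree = np.ascontiguousarray(degree, dtype=np.int64)
        return m

    # ------------------------------------------------------------------
    # construction of adjacency tables
    # ------------------------------------------------------------------
    def _build_adjacency(self) -> None:
        n = len(self.positions)
        edge_tris: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for t, (a, b, c) in enumerate(self.triangles):
            for u, v, w in ((a, b, c), (b, c, a), (c, a, b)):
                key = (u, v) if u < v else (v, u)
                edge_tris.setdefault(key, []).append((t, w))
        for key, tl in edge_tris.items():
            if len(tl) != 2:
                raise MeshError(
                    f"link {key} belongs to {len(tl)} triangles; mesh is "
                    "not edge-manifold/closed"
                )
        links = np.array(sorted(edge_tris), dtype=np.int64)
        self.links = links
        self.link_tri = np.array(
            [[tl[0][0], tl[1][0]] for tl in (edge_tris[tuple(l)] for l in links)],
            dtype=np.int64,
        )
        self.link_opp = np.array(
            [[tl[0][1], tl[1][1]] for tl in (edge_tris[tuple(l)] for l in links)],
            dtype=np.int64,
        )
        # fixed-width neighbour / incident-link tables
        self.degree = np.zeros(n, dtype=np.int64)
        self.neighbors = np.full((n, MAX_DEGREE), -1, dtype=np.int64)
        self.vertex_links = np.full((n, MAX_DEGREE), -1, dtype=np.int64)
        for li, (u, v) in enumerate(self.links):
            for a, b in ((u, v), (v, u)):
                d = self.degree[a]
                if d >= MAX_DEGREE:
                    raise MeshError(f"vertex {a} exceeds max degree {MAX_DEGREE}")
                self.neighbors[a, d] = b
                self.vertex_links[a, d] = li
                self.degree[a] = d + 1

    # ------------------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.positions)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @property
    def n_links(self) -> int:
        return len(self.links)

    @property
    def euler_sum(self) -> int:
        """N_m + T_m - L_m (0 for a torus, 2 for a closed sphere)."""
        return self.n_vertices + self.n_triangles - self.n_links

    def copy(self) -> "TriMesh":
        return TriMesh(self.positions.copy(), self.triangles.copy(), self.box)

    # ------------------------------------------------------------------
    # geometry with minimum-image convention in the plane
    # ------------------------------------------------------------------
    def edge_vector(self, i, j) -> np.ndarray:
        """Vector(s) from vertex i to vertex j (minimum image in x, y)."""
        d = self.positions[j] - self.positions[i]
        if self.box is not None:
            d[..., :2] -= self.box * np.round(d[..., :2] / self.box)
        return d

    def link_lengths(self) -> np.ndarray:
        d = self.edge_vector(self.links[:, 0], self.links[:, 1])
        return np.linalg.norm(d, axis=1)

    def triangle_geometry(self):
        """Per-triangle (area, unit normal) with minimum-image edges."""
        a, b, c = self.triangles.T
        e1 = self.edge_vector(a, b)
        e2 = self.edge_vector(a, c)
        cr = np.cross(e1, e2)
        nrm = np.linalg.norm(cr, axis=1)
        bad = np.flatnonzero(nrm < 1e-12)
        if bad.size:
            raise MeshError(f"degenerate (zero-area) triangle(s): {bad.tolist()}")
        return 0.5 * nrm, cr / nrm[:, None]

    def total_area(self) -> float:
        areas, _ = self.triangle_geometry()
        return float(areas.sum())

    def validate(self, params: MembraneParams | None = None) -> None:
        """Assert all structural invariants; raise MeshError on violation."""
        expected = 0 if self.box is not None else 2
        if self.euler_sum != expected:
            raise MeshError(
                f"Euler sum {self.euler_sum} != {expected} "
                f"(N={self.n_vertices}, T={self.n_triangles}, L={self.n_links})"
            )
        if (self.degree < 3).any():
            raise MeshError("vertex with fewer than 3 incident links")
        if params is not None and self.box is not None:
            ll = self.link_lengths()
            lo, hi = params.l_min, params.l_max
            if ll.min() < lo - 1e-9 or ll.max() > hi + 1e-9:
                raise MeshError(
                    f"link lengths [{ll.min():.3f}, {ll.max():.3f}] outside "
                    f"[{lo}, {hi:.3f}]"
                )


# ----------------------------------------------------------------------
# constructors
# ----------------------------------------------------------------------
def build_flat_patch(L: float, a0: float = 10.0) -> TriMesh:
    """Regular n x n periodic grid of squares, each split into two triangles.

    Yields N_m = n^2, T_m = 2 n^2, L_m = 3 n^2 with all heights zero.
    """
    ratio = L / a0
    n = int(round(ratio))
    if abs(ratio - n) > 1e-9:
        raise MeshError(f"L/a0 = {ratio} is not an integer")
    if n < 4:
        raise MeshError(f"grid size n = {n} < 4 gives a degenerate mesh")
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    pos = np.zeros((n * n, 3))
    pos[:, 0] = (ii * a0).ravel()
    pos[:, 1] = (jj * a0).ravel()

    def vid(i, j):
        return (i % n) * n + (j % n)

    tris = []
    for i in range(n):
        for j in range(n):
            v00, v10 = vid(i, j), vid(i + 1, j)
            v01, v11 = vid(i, j + 1), vid(i + 1, j + 1)
            tris.append((v00, v10, v11))
            tris.append((v00, v11, v01))
    return TriMesh(pos, np.array(tris, dtype=np.int64), box=float(L))


# ----------------------------------------------------------------------
# curvature and energy
# ----------------------------------------------------------------------
def vertex_normals(mesh: TriMesh) -> np.ndarray:
    """Area-weighted vertex normals (unit vectors)."""
    areas, tnorm = mesh.triangle_geometry()
    vn = np.zeros_like(mesh.positions)
    w = areas[:, None] * tnorm
    for k in range(3):
        np.add.at(vn, mesh.triangles[:, k], w)
    nrm = np.linalg.norm(vn, axis=1)
    if (nrm < 1e-12).any():
        raise MeshError("degenerate vertex normal")
    return vn / nrm[:, None]


def vertex_areas(mesh: TriMesh) -> np.ndarray:
    """One-third of the incident triangle areas per vertex, nm^2."""
    areas, _ = mesh.triangle_geometry()
    A_v = np.zeros(mesh.n_vertices)
    for k in range(3):
        np.add.at(A_v, mesh.triangles[:, k], areas / 3.0)
    return A_v


def mean_curvature(mesh: TriMesh):
    """Cotangent-Laplacian mean curvature sum (c1+c2) and vertex areas.

    This is the estimator used by the energy paths (Python and the
    compiled MC kernels use identical arithmetic).  Sign convention:
    positive for a sphere with outward normals.
    """
    n = mesh.n_vertices
    tri = mesh.triangles
    A_v = vertex_areas(mesh)

    lap = np.zeros((n, 3))
    pos_idx = [tri[:, 0], tri[:, 1], tri[:, 2]]
    ev = {}
    for i in range(3):
        for j in range(3):
            if i != j:
                ev[(i, j)] = mesh.edge_vector(pos_idx[i], pos_idx[j])
    for k in range(3):  # corner k is opposite the edge (k+1, k+2)
        i, j = (k + 1) % 3, (k + 2) % 3
        u = ev[(k, i)]
        v = ev[(k, j)]
        cosang = np.einsum("ij,ij->i", u, v)
        sinang = np.linalg.norm(np.cross(u, v), axis=1)
        cot = cosang / np.maximum(sinang, 1e-12)
        e_ij = ev[(i, j)]
        contrib = cot[:, None] * e_ij
        np.add.at(lap, tri[:, i], -contrib)
        np.add.at(lap, tri[:, j], contrib)

    mean_vec = lap / (4.0 * A_v[:, None])  # = H * n_hat, H = (c1+c2)/2
    vn = vertex_normals(mesh)
    c_sum = 2.0 * np.einsum("ij,ij->i", mean_vec, vn)
    return c_sum, A_v


def vertex_curvature(mesh: TriMesh, params: MembraneParams | None = None) -> CurvatureResult:
    """Principal curvatures per vertex from a local quadric fit.

    A paraboloid ``z' = (a x'^2 + 2 b x' y' + c y'^2)/2 + d x' + e y'`` is
    fitted over each vertex's one-ring in the frame of its area-weighted
    normal; principal curvatures are the eigenvalues of the Weingarten map
    built from the fitted first/second fundamental forms.  Rotationally and
    translationally invariant; positive for a sphere with outward normals.
    """
    n = mesh.n_vertices
    A_v = vertex_areas(mesh)
    vn = vertex_normals(mesh)
    c1 = np.zeros(n)
    c2 = np.zeros(n)
    for v in range(n):
        nb = mesh.neighbors[v, : mesh.degree[v]]
        d = mesh.edge_vector(np.full(len(nb), v), nb)
        nrm = vn[v]
        # orthonormal tangent frame
        t1 = np.cross(nrm, [1.0, 0.0, 0.0])
        if np.linalg.norm(t1) < 1e-6:
            t1 = np.cross(nrm, [0.0, 1.0, 0.0])
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(nrm, t1)
        x = d @ t1
        y = d @ t2
        z = d @ nrm
        M = np.column_stack([0.5 * x * x, x * y, 0.5 * y * y, x, y])
        coef, *_ = np.linalg.lstsq(M, z, rcond=None)
        a, b, c, dd, ee = coef
        g = 1.0 + dd * dd + ee * ee
        II = np.array([[a, b], [b, c]]) / math.sqrt(g)
        I = np.array([[1.0 + dd * dd, dd * ee], [dd * ee, 1.0 + ee * ee]])
        S = np.linalg.solve(I, II)
        # height measured along the outward normal: sphere gives a, c < 0
        ev_ = np.linalg.eigvalsh(0.5 * (S + S.T))
        c1[v], c2[v] = -ev_[0], -ev_[1]
    return CurvatureResult(c1=c1, c2=c2, A_v=A_v)


def helfrich_vertex_energies(mesh: TriMesh, params: MembraneParams) -> np.ndarray:
    """Per-vertex bending + tension energies, k_B T.

    Uses the magnitude of the cotangent mean-curvature vector, so the
    result is identical (to rounding) to the compiled MC kernel's
    accumulation and independent of the vertex-normal sign convention.
    """
    n = mesh.n_vertices
    tri = mesh.triangles
    A_v = vertex_areas(mesh)
    lap = np.zeros((n, 3))
    pos_idx = [tri[:, 0], tri[:, 1], tri[:, 2]]
    ev = {}
    for i in range(3):
        for j in range(3):
            if i != j:
                ev[(i, j)] = mesh.edge_vector(pos_idx[i], pos_idx[j])
    for k in range(3):
        i, j = (k + 1) % 3, (k + 2) % 3
        u = ev[(k, i)]
        v = ev[(k, j)]
        cosang = np.einsum("ij,ij->i", u, v)
        sinang = np.linalg.norm(np.cross(u, v), axis=1)
        cot = cosang / np.maximum(sinang, 1e-12)
        contrib = cot[:, None] * ev[(i, j)]
        np.add.at(lap, tri[:, i], -contrib)
        np.add.at(lap, tri[:, j], contrib)
    lap2 = np.einsum("ij,ij->i", lap, lap)
    A_v = np.maximum(A_v, 1e-12)
    return params.kappa * lap2 / (8.0 * A_v) + params.sigma * A_v


def helfrich_energy(mesh: TriMesh, params: MembraneParams) -> float:
    """Discrete bending + tension energy H_m, k_B T.

    H_m = sum_v [kappa/2 (c1+c2)^2 A_v + sigma A_v] with the curvature sum
    evaluated by the cotangent operator (exactly the quantity the energy
    needs; the principal split of ``vertex_curvature`` is not required).
    """
    return float(helfrich_vertex_energies(mesh, params).sum())


def bending_energy(mesh: TriMesh, params: MembraneParams) -> float:
    """Bending part only (sigma = 0), k_B T."""
    p0 = MembraneParams(kappa=params.kappa, sigma=0.0, a0=params.a0,
                        L=params.L, temperature=params.temperature,
                        link_max_factor=params.link_max_factor)
    return float(helfrich_vertex_energies(mesh, p0).sum())


def excess_area(mesh: TriMesh) -> float:
    """Excess area Aex = 100 * (A - Ap) / A, percent."""
    if mesh.box is None:
        raise MeshError("excess area requires a periodic (projected) patch")
    A = mesh.total_area()
    Ap = mesh.box * mesh.box
    return 100.0 * (A - Ap) / A
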
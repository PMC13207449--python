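"""Linear-elastic voxel finite elements: assembly, solves, homogenization.

Every element is a fully integrated (2x2x2 Gauss) trilinear hexahedron of
edge ``h``; the grid is solid (all three phases carry a modulus), so the
global stiffness couples all ``3*(N+1)^3`` degrees of freedom.  Units are
mm / MPa / N throughout.  Two boundary-value problems are provided:

* uniaxial compression -- bottom face pinned, top face driven downward by a
  fraction of the edge length, lateral faces traction free; and
* periodic homogenization -- opposite faces tied through a macroscopic
  strain, six unit macro-strain cases yielding the effective moduli.

Systems are solved with Jacobi-preconditioned conjugate gradients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from tpmsbone.geometry import VoxelRVE

#: Element corner order (unit cube offsets); DOFs are (ux, uy, uz) per node.
CORNERS = np.array(
    [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
     [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=int
)

#: Voigt order used throughout: (xx, yy, zz, xy, yz, zx), engineering shear.
VOIGT = ("xx", "yy", "zz", "xy", "yz", "zx")


def elastic_matrix(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic elasticity matrix in Voigt notation (engineering shear)."""
    if E <= 0:
        raise ValueError("Young's modulus must be positive")
    if not 0 <= nu < 0.5:
        raise ValueError("Poisson ratio must lie in [0, 0.5)")
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.full((6, 6), 0.0)
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] = lam + 2 * mu
    C[3, 3] = C[4, 4] = C[5, 5] = mu
    return C


def _shape_gradients(xi: np.ndarray, h: float) -> np.ndarray:
    """(8, 3) physical gradients of the trilinear shape functions at local
    coordinate ``xi`` in the unit cube."""
    dN = np.zeros((8, 3))
    for a, (cx, cy, cz) in enumerate(CORNERS):
        sx = cx * xi[0] + (1 - cx) * (1 - xi[0])
        sy = cy * xi[1] + (1 - cy) * (1 - xi[1])
        sz = cz * xi[2] + (1 - cz) * (1 - xi[2])
        dN[a] = ((2 * cx - 1) * sy * sz,
                 sx * (2 * cy - 1) * sz,
                 sx * sy * (2 * cz - 1))
    return dN / h


def _b_matrix(dN: np.ndarray) -> np.ndarray:
    """6x24 strain-displacement matrix from shape gradients."""
    B = np.zeros((6, 24))
    for a in range(8):
        gx, gy, gz = dN[a]
        B[0, 3 * a] = gx
        B[1, 3 * a + 1] = gy
        B[2, 3 * a + 2] = gz
        B[3, 3 * a] = gy
        B[3, 3 * a + 1] = gx
        B[4, 3 * a + 1] = gz
        B[4, 3 * a + 2] = gy
        B[5, 3 * a] = gz
        B[5, 3 * a + 2] = gx
    return B


_GAUSS = (np.array([-1.0, 1.0]) / np.sqrt(3.0) + 1.0) / 2.0  # on [0, 1]


def hex_element_stiffness(E: float, nu: float, spacing: float) -> np.ndarray:
    """24x24 stiffness of a cube voxel element, full 2x2x2 quadrature.

    Symmetric positive-semidefinite with exactly six rigid-body zero modes.
    Scales linearly in ``E`` and linearly in ``spacing``.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    C = elastic_matrix(E, nu)
    K = np.zeros((24, 24))
    w = spacing**3 / 8.0
    for gx in _GAUSS:
        for gy in _GAUSS:
            for gz in _GAUSS:
                B = _b_matrix(_shape_gradients(np.array([gx, gy, gz]), spacing))
                K += B.T @ C @ B * w
    return 0.5 * (K + K.T)


def average_b_matrix(spacing: float) -> np.ndarray:
    """Strain-displacement matrix averaged over the quadrature points."""
    B = np.zeros((6, 24))
    for gx in _GAUSS:
        for gy in _GAUSS:
            for gz in _GAUSS:
                B += _b_matrix(_shape_gradients(np.array([gx, gy, gz]), spacing))
    return B / 8.0


def element_dofs(n: int) -> np.ndarray:
    """(n^3, 24) global DOF indices per element on an n^3 grid, C order."""
    nn = n + 1
    i, j, k = np.meshgrid(np.arange(n), np.arange(n), np.arange(n),
                          indexing="ij")
    nodes = np.stack(
        [((i + c[0]) * nn + (j + c[1])) * nn + (k + c[2]) for c in CORNERS],
        axis=-1,
    ).reshape(-1, 8)
    return (3 * nodes[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 24)


def node_coordinates(n: int, spacing: float) -> np.ndarray:
    """((n+1)^3, 3) node coordinates in mm, C order matching element_dofs."""
    c = np.arange(n + 1) * spacing
    g = np.meshgrid(c, c, c, indexing="ij")
    return np.stack(g, axis=-1).reshape(-1, 3)


def assemble(
    rve: VoxelRVE,
    modulus: np.ndarray,
    nu: float = 0.3,
    edofs: np.ndarray | None = None,
) -> sp.csr_matrix:
    """Global stiffness for a fully solid voxel grid.

    ``modulus`` carries one Young's modulus per element (any shape with
    ``rve.element_count`` entries, C order).  A shared unit-modulus element
    matrix is scaled per element, so assembly cost is dominated by the
    sparse summation.
    """
    n = rve.resolution
    E = np.asarray(modulus, dtype=float).reshape(-1)
    if E.size != rve.element_count:
        raise ValueError("one modulus per element required")
    if np.any(E <= 0):
        raise ValueError("all element moduli must be positive")
    k1 = hex_element_stiffness(1.0, nu, rve.spacing)
    if edofs is None:
        edofs = element_dofs(n)
    rows = np.repeat(edofs, 24, axis=1).ravel().astype(np.int32)
    cols = np.tile(edofs, (1, 24)).ravel().astype(np.int32)
    vals = (E[:, None] * k1.ravel()[None, :]).ravel()
    ndof = 3 * (n + 1) ** 3
    return sp.coo_matrix((vals, (rows, cols)), shape=(ndof, ndof)).tocsr()


def solve_dirichlet(
    K: sp.csr_matrix,
    fixed_dofs: np.ndarray,
    fixed_values: np.ndarray,
    rtol: float = 1e-8,
    x0: np.ndarray | None = None,
    maxiter: int = 50000,
) -> np.ndarray:
    """Solve ``K u = 0`` subject to prescribed DOF values (CG, Jacobi)."""
    ndof = K.shape[0]
    u = np.zeros(ndof)
    u[fixed_dofs] = fixed_values
    free = np.ones(ndof, dtype=bool)
    free[fixed_dofs] = False
    f = -(K @ u)[free]
    Kff = K[free][:, free]
    M = sp.diags(1.0 / Kff.diagonal())
    guess = x0[free] if x0 is not None else None
    x, info = spla.cg(Kff, f, x0=guess, M=M, rtol=rtol, maxiter=maxiter)
    if info != 0:
        raise RuntimeError(f"CG failed to converge (info={info})")
    u[free] = x
    return u


@dataclass
class SolveResult:
    """Converged displacement field with recovered per-element stresses."""

    displacements: np.ndarray      # (ndof,) mm
    stress: np.ndarray             # (ne, 6) MPa, Voigt order
    principal: np.ndarray          # (ne, 3) MPa, sorted descending
    von_mises: np.ndarray          # (ne,) MPa
    reaction_force: float          # N, on the loaded face
    applied_strain: float
    edge_length: float

    @property
    def apparent_modulus(self) -> float:
        return apparent_modulus_uniaxial(self)


def recover_stress(
    displacements: np.ndarray,
    rve: VoxelRVE,
    modulus: np.ndarray,
    nu: float = 0.3,
    edofs: np.ndarray | None = None,
) -> np.ndarray:
    """Per-element stress: elasticity applied to the quadrature-averaged strain."""
    n = rve.resolution
    if edofs is None:
        edofs = element_dofs(n)
    Bavg = average_b_matrix(rve.spacing)
    eps = displacements[edofs] @ Bavg.T          # (ne, 6)
    C1 = elastic_matrix(1.0, nu)
    E = np.asarray(modulus, dtype=float).reshape(-1)
    return (eps @ C1.T) * E[:, None]


def principal_stresses(stress: np.ndarray) -> np.ndarray:
    """Sorted (descending) principal values of Voigt stress rows."""
    s = np.asarray(stress)
    T = np.zeros(s.shape[:-1] + (3, 3))
    T[..., 0, 0] = s[..., 0]
    T[..., 1, 1] = s[..., 1]
    T[..., 2, 2] = s[..., 2]
    T[..., 0, 1] = T[..., 1, 0] = s[..., 3]
    T[..., 1, 2] = T[..., 2, 1] = s[..., 4]
    T[..., 0, 2] = T[..., 2, 0] = s[..., 5]
    return np.linalg.eigvalsh(T)[..., ::-1]


def von_mises(principal: np.ndarray) -> np.ndarray:
    """Equivalent stress sqrt(1/2 [(s1-s2)^2 + (s2-s3)^2 + (s3-s1)^2])."""
    p = np.asarray(principal, dtype=float)
    s1, s2, s3 = p[..., 0], p[..., 1], p[..., 2]
    return np.sqrt(0.5 * ((s1 - s2) ** 2 + (s2 - s3) ** 2 + (s3 - s1) ** 2))


def von_mises_voigt(stress: np.ndarray) -> np.ndarray:
    """Equivalent stress directly from Voigt components."""
    s = np.asarray(stress, dtype=float)
    sx, sy, sz, txy, tyz, tzx = (s[..., i] for i in range(6))
    return np.sqrt(
        0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
        + 3.0 * (txy**2 + tyz**2 + tzx**2)
    )


def _face_nodes(n: int):
    nn = n + 1
    idx = np.arange(nn**3).reshape(nn, nn, nn)
    return idx[:, :, 0].ravel(), idx[:, :, n].ravel()  # bottom, top (z axis)


def solve_uniaxial(
    rve: VoxelRVE,
    modulus: np.ndarray,
    nu: float = 0.3,
    applied_strain: float = 0.10,
    rtol: float = 1e-8,
    K: sp.csr_matrix | None = None,
    x0: np.ndarray | None = None,
    edofs: np.ndarray | None = None,
) -> SolveResult:
    """Uniaxial compression along z: bottom pinned, top driven down.

    The bottom-face nodes are fixed in all three translations (hinged =
    pinned for rotation-free voxel nodes); top-face nodes are prescribed
    ``-applied_strain * edge_length`` vertically with in-plane motion free;
    lateral faces are traction free.
    """
    if applied_strain <= 0:
        raise ValueError("applied strain must be positive")
    n = rve.resolution
    if K is None:
        K = assemble(rve, modulus, nu, edofs=edofs)
    bottom, top = _face_nodes(n)
    fixed = np.concatenate([3 * bottom, 3 * bottom + 1, 3 * bottom + 2,
                            3 * top + 2])
    vals = np.zeros(fixed.size)
    vals[-top.size:] = -applied_strain * rve.edge_length
    u = solve_dirichlet(K, fixed, vals, rtol=rtol, x0=x0)
    stress = recover_stress(u, rve, modulus, nu, edofs=edofs)
    principal = principal_stresses(stress)
    reaction = float((K @ u)[3 * top + 2].sum())
    return SolveResult(u, stress, principal, von_mises(principal), reaction,
                       applied_strain, rve.edge_length)


def apparent_modulus_uniaxial(result: SolveResult) -> float:
    """Face-averaged reaction stress over applied strain, in MPa."""
    if result.applied_strain == 0:
        raise ValueError("zero applied strain")
    area = result.edge_length**2
    return abs(result.reaction_force) / area / result.applied_strain


@dataclass(frozen=True)
class HomogenizationResult:
    """Effective engineering constants of the periodic RVE."""

    E11: float
    E22: float
    E33: float
    G12: float
    G13: float
    G23: float
    stiffness: np.ndarray  # 6x6 effective C in Voigt order

    @property
    def moduli(self) -> tuple[float, float, float]:
        return (self.E11, self.E22, self.E33)


_MACRO_CASES = {  # Voigt index -> macroscopic strain tensor (unit amplitude)
    0: np.array([[1, 0, 0], [0, 0, 0], [0, 0, 0]], float),
    1: np.array([[0, 0, 0], [0, 1, 0], [0, 0, 0]], float),
    2: np.array([[0, 0, 0], [0, 0, 0], [0, 0, 1]], float),
    3: np.array([[0, 0.5, 0], [0.5, 0, 0], [0, 0, 0]], float),
    4: np.array([[0, 0, 0], [0, 0, 0.5], [0, 0.5, 0]], float),
    5: np.array([[0, 0, 0.5], [0, 0, 0], [0.5, 0, 0]], float),
}


def periodic_projector(n: int) -> sp.csr_matrix:
    """Maps master (N^3 node) periodic DOFs onto the full (N+1)^3 grid."""
    nn = n + 1
    i, j, k = np.meshgrid(np.arange(nn), np.arange(nn), np.arange(nn),
                          indexing="ij")
    master = (((i % n) * n + (j % n)) * n + (k % n)).ravel()
    ndof = 3 * nn**3
    cols = (3 * master[:, None] + np.arange(3)[None, :]).ravel()
    return sp.coo_matrix(
        (np.ones(ndof), (np.arange(ndof), cols)),
        shape=(ndof, 3 * n**3),
    ).tocsr()


def homogenize_pbc(
    rve: VoxelRVE,
    modulus: np.ndarray,
    nu: float = 0.3,
    cases: str = "normal",
    rtol: float = 1e-8,
    K: sp.csr_matrix | None = None,
) -> HomogenizationResult:
    """Periodic homogenization of the voxel RVE.

    The displacement is split into an affine part ``E_mac . x`` and a
    periodic fluctuation shared by opposite faces (master-slave projection
    onto the N^3 master nodes; face/edge/corner over-constraints resolve
    automatically because all slaves map to the same master).  Each macro
    strain case yields one column of the effective stiffness from the
    volume-averaged stress; engineering moduli follow from the compliance.

    ``cases="normal"`` solves the three normal cases (enough for E11, E22,
    E33 when normal/shear coupling vanishes by symmetry); ``"full"`` adds
    the three shear cases and fills in G12, G13, G23.
    """
    n = rve.resolution
    E = np.asarray(modulus, dtype=float).reshape(-1)
    edofs = element_dofs(n)
    if K is None:
        K = assemble(rve, E, nu, edofs=edofs)
    T = periodic_projector(n)
    Kr = (T.T @ K @ T).tocsr()
    nred = Kr.shape[0]
    free = np.ones(nred, dtype=bool)
    free[:3] = False  # pin one master node: kills rigid translations
    Kf = Kr[free][:, free]
    M = sp.diags(1.0 / Kf.diagonal())
    coords = node_coordinates(n, rve.spacing)
    Bavg = average_b_matrix(rve.spacing)
    C1 = elastic_matrix(1.0, nu)
    case_ids = (0, 1, 2) if cases == "normal" else (0, 1, 2, 3, 4, 5)
    C_eff = np.zeros((6, 6))
    for ci in case_ids:
        ua = (coords @ _MACRO_CASES[ci].T).ravel()
        f = -(T.T @ (K @ ua))[free]
        x, info = spla.cg(Kf, f, M=M, rtol=rtol, maxiter=50000)
        if info != 0:
            raise RuntimeError(f"PBC case {ci}: CG failed (info={info})")
        up = np.zeros(nred)
        up[free] = x
        u = ua + T @ up
        eps = u[edofs] @ Bavg.T
        sig = (eps @ C1.T) * E[:, None]
        C_eff[:, ci] = sig.mean(axis=0)
    Cn = C_eff[:3, :3]
    Sn = np.linalg.inv(Cn)
    E11, E22, E33 = 1 / Sn[0, 0], 1 / Sn[1, 1], 1 / Sn[2, 2]
    if cases == "normal":
        G12 = G13 = G23 = float("nan")
    else:
        G12, G23, G13 = C_eff[3, 3], C_eff[4, 4], C_eff[5, 5]
    return HomogenizationResult(E11, E22, E33, G12, G13, G23, C_eff)


def reuss_voigt_bounds(modulus: np.ndarray) -> tuple[float, float]:
    """Harmonic (Reuss) and arithmetic (Voigt) bounds on the modulus."""
    E = np.asarray(modulus, dtype=float).reshape(-1)
    return float(1.0 / np.mean(1.0 / E)), float(np.mean(E))
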
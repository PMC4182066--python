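"""Flat-facet triangular thin-shell finite elements.

Each triangle superposes a constant-strain membrane (CST) with a discrete
Kirchhoff plate-bending triangle (DKT) in its own local frame, plus a small
penalty stiffness tying the drilling rotation (about the shell normal) to
the in-plane rotation of the membrane field, which removes the spurious
zero-energy drilling mode without disturbing rigid-body motion.

Each node carries six generalized displacements: three translations and
three right-handed rotations about the global axes.  The internal unit
system is mm-N-tonne-s, so stresses come out in MPa and assembled matrix
entries stay well scaled; densities given in kg/m^3 are converted at the
boundary (1 kg/m^3 = 1e-12 tonne/mm^3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import ShellMesh

#: drilling penalty, as a fraction of the smallest bending rotational diagonal
DRILL_FRACTION = 1e-4

KG_M3_TO_TONNE_MM3 = 1e-12
PA_TO_MPA = 1e-6


class ElementError(ValueError):
    """Raised for a degenerate or invalid element, carrying its id."""


class SingularSystemError(RuntimeError):
    """Raised when a static solve meets an insufficiently constrained system."""


@dataclass(frozen=True)
class Material:
    """Linear elastic isotropic material with optional Rayleigh damping.

    Parameters
    ----------
    youngs_modulus : float, Pa
        Default 1.2 GPa, the mean extensometer value measured on human
        orbital-wall bone samples.
    poisson_ratio : float
        Default 0.3, typical for cortical bone.
    density : float, kg/m^3
        Default 1900, cortical bone.
    rayleigh_alpha : float, 1/s
        Mass-proportional damping coefficient (default 0, undamped).
    rayleigh_beta : float, s
        Stiffness-proportional damping coefficient (default 0).
    """

    youngs_modulus: float = 1.2e9
    poisson_ratio: float = 0.3
    density: float = 1900.0
    rayleigh_alpha: float = 0.0
    rayleigh_beta: float = 0.0

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError("youngs_modulus must be positive")
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise ValueError("poisson_ratio must lie in [0, 0.5)")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.rayleigh_alpha < 0 or self.rayleigh_beta < 0:
            raise ValueError("damping coefficients must be non-negative")

    @property
    def E_mpa(self) -> float:
        return self.youngs_modulus * PA_TO_MPA

    @property
    def rho_tonne_mm3(self) -> float:
        return self.density * KG_M3_TO_TONNE_MM3

    def plane_stress_matrix(self, thickness_scale: float = 1.0) -> np.ndarray:
        """Plane-stress constitutive matrix in MPa."""
        E, nu = self.E_mpa * thickness_scale, self.poisson_ratio
        return (E / (1.0 - nu * nu)) * np.array(
            [[1.0, nu, 0.0], [nu, 1.0, 0.0], [0.0, 0.0, 0.5 * (1.0 - nu)]]
        )


@dataclass
class GlobalSystem:
    """Assembled shell system: 6 dofs per node, mm-N-tonne-s units."""

    stiffness: sp.csr_matrix
    mass: np.ndarray  # diagonal, one entry per dof
    constrained_dofs: np.ndarray
    num_nodes: int

    @property
    def num_dofs(self) -> int:
        return 6 * self.num_nodes

    @property
    def free_dofs(self) -> np.ndarray:
        mask = np.ones(self.num_dofs, dtype=bool)
        mask[self.constrained_dofs] = False
        return np.flatnonzero(mask)

    def damping_diagonal_alpha(self, material: Material) -> np.ndarray:
        return material.rayleigh_alpha * self.mass


def dof_indices(nodes: np.ndarray) -> np.ndarray:
    """All 6 dof indices of the given nodes, flattened."""
    nodes = np.atleast_1d(np.asarray(nodes, dtype=np.int64))
    return (6 * nodes[:, None] + np.arange(6)[None, :]).ravel()


# ---------------------------------------------------------------------------
# element kinematics


def local_frame(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Local orthonormal frame of a facet; rows of R are (e1, e2, n).

    Returns (R, xy) where xy are the 2D coordinates of the three vertices
    in the local frame (vertex 1 at the origin, edge 1-2 along e1).
    """
    e1 = p[1] - p[0]
    l1 = np.linalg.norm(e1)
    n = np.cross(p[1] - p[0], p[2] - p[0])
    a2 = np.linalg.norm(n)
    if l1 <= 0.0 or a2 <= 1e-12 * l1 * l1:
        raise ElementError("degenerate triangle")
    e1 = e1 / l1
    n = n / a2
    e2 = np.cross(n, e1)
    R = np.vstack([e1, e2, n])
    xy = (p - p[0]) @ R[:2].T
    return R, xy


def _cst_b_matrix(xy: np.ndarray) -> tuple[np.ndarray, float]:
    """Constant membrane strain-displacement matrix (3x6) and the area."""
    x, y = xy[:, 0], xy[:, 1]
    area = 0.5 * ((x[1] - x[0]) * (y[2] - y[0]) - (x[2] - x[0]) * (y[1] - y[0]))
    if area <= 0.0:
        raise ElementError("triangle has non-positive local area")
    b = np.array([y[1] - y[2], y[2] - y[0], y[0] - y[1]])
    c = np.array([x[2] - x[1], x[0] - x[2], x[1] - x[0]])
    B = np.zeros((3, 6))
    B[0, 0::2] = b
    B[1, 1::2] = c
    B[2, 0::2] = c
    B[2, 1::2] = b
    return B / (2.0 * area), area


# DKT shape machinery: quadratic shape functions of the 6-node triangle and
# the rotation-interpolation coefficient tables of Batoz's element.


def _quad_shape_derivs(xi: float, eta: float) -> tuple[np.ndarray, np.ndarray]:
    lam = 1.0 - xi - eta
    dN_dxi = np.array([1.0 - 4.0 * lam, 4.0 * xi - 1.0, 0.0, 4.0 * eta, -4.0 * eta, 4.0 * (lam - xi)])
    dN_deta = np.array([1.0 - 4.0 * lam, 0.0, 4.0 * eta - 1.0, 4.0 * xi, 4.0 * (lam - eta), -4.0 * xi])
    return dN_dxi, dN_deta


def _dkt_coefficient_tables(xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gx, Gy (9x6) with beta_x = N(xi,eta) @ Gx.T acting on the bending dofs.

    The rotation field beta = -grad(w) is interpolated quadratically over
    the 6-node triangle.  Corner values come straight from the nodal
    rotations; at each midside the edge-normal component varies linearly
    between the corners while the edge-tangential component is set by the
    discrete Kirchhoff condition, i.e. the midpoint slope of the Hermite
    cubic deflection along the edge.  Bending dofs per node are
    (w, theta_x, theta_y) with theta = right-handed rotations about the
    local axes, so beta_x = theta_y and beta_y = -theta_x at the corners.
    """
    Gx = np.zeros((9, 6))
    Gy = np.zeros((9, 6))
    # corner rotations
    for i in range(3):
        Gx[3 * i + 2, i] = 1.0  # beta_x = theta_y
        Gy[3 * i + 1, i] = -1.0  # beta_y = -theta_x
    # midside k=4,5,6 on edges (2,3), (3,1), (1,2)
    pairs = ((1, 2), (2, 0), (0, 1))
    for k, (i, j) in enumerate(pairs):
        edge = xy[j] - xy[i]
        length = np.hypot(*edge)
        s = edge / length
        n = np.array([-s[1], s[0]])
        bi_x, bi_y = Gx[:, i], Gy[:, i]
        bj_x, bj_y = Gx[:, j], Gy[:, j]
        # tangential: discrete Kirchhoff condition, beta_s = -dw/ds of the
        # Hermite cubic along the edge evaluated at
        # the midpoint; corner slopes satisfy dw/ds = -(s . beta)
        bs_i = s[0] * bi_x + s[1] * bi_y
        bs_j = s[0] * bj_x + s[1] * bj_y
        bs_mid = -0.25 * (bs_i + bs_j)
        bs_mid = bs_mid.copy()
        bs_mid[3 * i] += 1.5 / length  # -3/(2l) * (w_j - w_i)
        bs_mid[3 * j] -= 1.5 / length
        # normal component: linear between corners
        bn_mid = 0.5 * (n[0] * (bi_x + bj_x) + n[1] * (bi_y + bj_y))
        Gx[:, 3 + k] = s[0] * bs_mid + n[0] * bn_mid
        Gy[:, 3 + k] = s[1] * bs_mid + n[1] * bn_mid
    return Gx, Gy


def _dkt_curvature_matrix(xy: np.ndarray, xi: float, eta: float) -> np.ndarray:
    """Curvature-displacement matrix (3x9) at a point of the unit triangle.

    Rows are (kappa_xx, kappa_yy, kappa_xy) of the Kirchhoff plate, columns
    the nodal (w, theta_x, theta_y) with theta = right-handed rotations
    about the local in-plane axes.
    """
    x, y = xy[:, 0], xy[:, 1]
    x21, y21 = x[1] - x[0], y[1] - y[0]
    x31, y31 = x[2] - x[0], y[2] - y[0]
    twoA = x21 * y31 - x31 * y21
    Gx, Gy = _dkt_coefficient_tables(xy)
    dN_dxi, dN_deta = _quad_shape_derivs(xi, eta)
    Hx_xi, Hx_eta = Gx @ dN_dxi, Gx @ dN_deta
    Hy_xi, Hy_eta = Gy @ dN_dxi, Gy @ dN_deta
    Bb = np.empty((3, 9))
    Bb[0] = (y31 * Hx_xi - y21 * Hx_eta) / twoA
    Bb[1] = (-x31 * Hy_xi + x21 * Hy_eta) / twoA
    Bb[2] = (-x31 * Hx_xi + x21 * Hx_eta + y31 * Hy_xi - y21 * Hy_eta) / twoA
    return Bb


_DKT_GAUSS = ((0.5, 0.0), (0.5, 0.5), (0.0, 0.5))

# local per-node dof order within the 18-vector: (u, v, w, tx, ty, tz)
_MEMBRANE_DOFS = np.array([0, 1, 6, 7, 12, 13])
_BENDING_DOFS = np.array([2, 3, 4, 8, 9, 10, 14, 15, 16])
_DRILL_DOFS = np.array([5, 11, 17])


def element_stiffness(
    p: np.ndarray, thickness: float, material: Material, element_id: int | None = None
) -> np.ndarray:
    """18x18 element stiffness in global coordinates (N/mm, N, N*mm).

    Dof order: node-major, per node (ux, uy, uz, rx, ry, rz) in the global
    frame.  Membrane energy scales with t, bending with t^3.
    """
    try:
        R, xy = local_frame(np.asarray(p, dtype=float))
        if thickness <= 0.0:
            raise ElementError("thickness must be positive")
        C = material.plane_stress_matrix()
        Bm, area = _cst_b_matrix(xy)
        Km = thickness * area * Bm.T @ C @ Bm

        D = C * thickness**3 / 12.0
        Kb = np.zeros((9, 9))
        for xi, eta in _DKT_GAUSS:
            Bb = _dkt_curvature_matrix(xy, xi, eta)
            Kb += (2.0 * area / 6.0) * Bb.T @ D @ Bb

        K = np.zeros((18, 18))
        K[np.ix_(_MEMBRANE_DOFS, _MEMBRANE_DOFS)] += Km
        K[np.ix_(_BENDING_DOFS, _BENDING_DOFS)] += Kb

        # drilling stabilization: penalize theta_z,i minus the membrane
        # in-plane rotation 0.5*(dv/dx - du/dy); rows of g sum consistently
        # so all six rigid-body motions stay at zero energy.  The penalty is
        # scaled from the membrane stiffness E*t*A: tying it to the bending
        # diagonal makes the spurious mode numerically indistinguishable
        # from a rigid mode on thin shells.
        k_drill = DRILL_FRACTION * material.E_mpa * thickness * area
        x, y = xy[:, 0], xy[:, 1]
        b = np.array([y[1] - y[2], y[2] - y[0], y[0] - y[1]]) / (2.0 * area)
        c = np.array([x[2] - x[1], x[0] - x[2], x[1] - x[0]]) / (2.0 * area)
        omega = np.zeros(18)
        omega[_MEMBRANE_DOFS[1::2]] = 0.5 * b  # dv/dx
        omega[_MEMBRANE_DOFS[0::2]] = -0.5 * c  # -du/dy
        for i in range(3):
            gvec = -omega.copy()
            gvec[_DRILL_DOFS[i]] += 1.0
            K += k_drill * np.outer(gvec, gvec)
    except ElementError as err:
        raise ElementError(
            f"element {element_id}: {err}" if element_id is not None else str(err)
        ) from None

    T = np.zeros((18, 18))
    for blk in range(6):
        T[3 * blk : 3 * blk + 3, 3 * blk : 3 * blk + 3] = R
    return T.T @ K @ T


def element_membrane_strain(p: np.ndarray, u_global: np.ndarray) -> np.ndarray:
    """Constant membrane strain (eps_xx, eps_yy, gamma_xy) in the local frame
    from the element's 18 global generalized displacements."""
    R, xy = local_frame(np.asarray(p, dtype=float))
    Bm, _ = _cst_b_matrix(xy)
    u_loc = _to_local(u_global, R)
    return Bm @ u_loc[_MEMBRANE_DOFS]


def element_curvature(p: np.ndarray, u_global: np.ndarray) -> np.ndarray:
    """Centroid curvature (kappa_xx, kappa_yy, kappa_xy) in the local frame."""
    R, xy = local_frame(np.asarray(p, dtype=float))
    Bb = _dkt_curvature_matrix(xy, 1.0 / 3.0, 1.0 / 3.0)
    u_loc = _to_local(u_global, R)
    return Bb @ u_loc[_BENDING_DOFS]


def _to_local(u_global: np.ndarray, R: np.ndarray) -> np.ndarray:
    u_loc = np.empty(18)
    for blk in range(6):
        u_loc[3 * blk : 3 * blk + 3] = R @ u_global[3 * blk : 3 * blk + 3]
    return u_loc


# ---------------------------------------------------------------------------
# assembly


def assemble(mesh: ShellMesh, material: Material) -> GlobalSystem:
    """Assemble global stiffness and lumped mass with the mesh's fixed nodes
    applied as homogeneous constraints (all six dofs of each fixed node)."""
    n_dof = 6 * mesh.num_nodes
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for e, tri in enumerate(mesh.triangles):
        Ke = element_stiffness(
            mesh.nodes[tri], float(mesh.thickness[e]), material, element_id=e
        )
        edofs = dof_indices(tri)
        rr, cc = np.meshgrid(edofs, edofs, indexing="ij")
        rows.append(rr.ravel())
        cols.append(cc.ravel())
        vals.append(Ke.ravel())
    K = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_dof, n_dof),
    ).tocsr()
    K = 0.5 * (K + K.T)  # enforce exact symmetry against round-off

    M = lumped_mass(mesh, material)
    constrained = dof_indices(mesh.fixed_nodes) if len(mesh.fixed_nodes) else np.empty(0, dtype=np.int64)
    return GlobalSystem(
        stiffness=K, mass=M, constrained_dofs=constrained, num_nodes=mesh.num_nodes
    )


def lumped_mass(mesh: ShellMesh, material: Material) -> np.ndarray:
    """Diagonal mass vector (tonne, tonne*mm^2), one entry per dof.

    Each element's translational mass rho*A*t is split equally over its
    three nodes.  Rotational entries use the common explicit-dynamics
    lumping I = m_node * A / 6, i.e. the nodal mass times a length^2 of the
    order of the element size; this keeps rotational dofs from dominating
    the stable time step while adding negligible inertia to the structural
    bending modes of meshes much larger than one element.
    """
    rho = material.rho_tonne_mm3
    areas = mesh.element_areas()
    m_elem = rho * areas * mesh.thickness
    M = np.zeros(6 * mesh.num_nodes)
    for e, tri in enumerate(mesh.triangles):
        m_node = m_elem[e] / 3.0
        inertia = m_node * areas[e] / 6.0
        for n in tri:
            M[6 * n : 6 * n + 3] += m_node
            M[6 * n + 3 : 6 * n + 6] += inertia
    return M


def static_solve(
    system: GlobalSystem,
    load: np.ndarray,
    prescribed: dict[int, float] | None = None,
) -> np.ndarray:
    """Solve K u = f with the system's constraints (and optional prescribed
    non-zero dof values).  Returns the full displacement vector; raises
    :class:`SingularSystemError` with near-rigid-mode diagnostics if the
    constrained operator is singular."""
    n = system.num_dofs
    u = np.zeros(n)
    fixed = set(int(d) for d in system.constrained_dofs)
    if prescribed:
        for d, v in prescribed.items():
            u[d] = v
            fixed.add(int(d))
    fixed_idx = np.array(sorted(fixed), dtype=np.int64)
    mask = np.ones(n, dtype=bool)
    mask[fixed_idx] = False
    free = np.flatnonzero(mask)
    K = system.stiffness
    rhs = load[free] - K[np.ix_(free, fixed_idx)] @ u[fixed_idx]
    Kff = K[np.ix_(free, free)].tocsc()
    try:
        lu = spla.splu(Kff)
        uf = lu.solve(rhs)
    except RuntimeError as err:
        raise SingularSystemError(_rigid_mode_report(Kff)) from err
    if not np.all(np.isfinite(uf)):
        raise SingularSystemError(_rigid_mode_report(Kff))
    resid = np.linalg.norm(Kff @ uf - rhs)
    scale = np.linalg.norm(rhs)
    if scale > 0 and resid > 1e-6 * scale:
        raise SingularSystemError(
            f"static residual {resid:.3e} exceeds tolerance; "
            + _rigid_mode_report(Kff)
        )
    u[free] = uf
    return u


def _rigid_mode_report(Kff: sp.spmatrix) -> str:
    try:
        k = min(6, Kff.shape[0] - 1)
        vals = spla.eigsh(Kff, k=k, sigma=0.0, return_eigenvectors=False)
        near_zero = int(np.sum(np.abs(vals) < 1e-8 * np.abs(vals).max()))
        return (
            "singular system: insufficient constraints "
            f"(~{near_zero} near-zero stiffness eigenvalues: {vals})"
        )
    except Exception:
        return "singular system: insufficient constraints"


def export_matrix_market(system: GlobalSystem, path: str) -> None:
    """Dump the global stiffness to a MatrixMarket file for debugging."""
    from scipy.io import mmwrite

    mmwrite(path, system.stiffness)
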
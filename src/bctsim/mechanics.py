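"""Plane-strain Neo-Hookean finite-element mechanics of the breast.

Quasi-incompressible Neo-Hookean hyperelasticity with strain energy

    W = mu/2 (J^(-2/3) I1 - 3) + K/2 (J - 1)^2

solved natively in 2D plane strain (the out-of-plane stretch is fixed at
one, so I1 = tr(F2d^T F2d) + 1 and J = det F2d) on quadratic (six-node)
triangles with a displacement-only penalty formulation.  Loads are gravity
as a dead body force and seroma pressure as a follower traction on the
cavity wall; the chest wall is clamped.  Newton iterations use the exact
consistent tangent (including the follower-pressure term) with load
stepping and a backtracking line search.

Units: lengths mm, moduli kPa, densities kg/L, pressures Pa (converted
internally), forces mN.  Body force density in kPa/mm is
1e-3 * rho[kg/L] * g[m/s^2].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .mesh import BreastMesh, FAT, GLANDULAR, SKIN, SCAR, INFLAMED

__all__ = ["Material", "LoadCase", "MechanicalState", "MechanicsError",
           "derive_moduli", "strain_energy", "material_table",
           "solve_equilibrium", "solve_linear", "evaluate_state",
           "estimate_unloaded", "normalized_stress", "outer_contour",
           "GRAVITY_SEATED", "GRAVITY_PRONE", "export_state_vtk"]

#: Standard gravity magnitude, m/s^2.
G = 9.81
#: Seated posture: gravity points inferior (down the chest wall).
GRAVITY_SEATED = (0.0, -G)
#: Prone posture: gravity points anterior (away from the chest wall).
GRAVITY_PRONE = (G, 0.0)


class MechanicsError(RuntimeError):
    """Raised on Newton divergence; carries the last residual norm."""

    def __init__(self, msg: str, residual: float = np.nan):
        super().__init__(msg)
        self.residual = residual


def derive_moduli(E: float, nu: float) -> tuple[float, float]:
    """Shear and bulk moduli (kPa) from Young modulus (kPa) and Poisson ratio."""
    if E <= 0:
        raise ValueError("Young modulus must be positive")
    if not (0.0 <= nu < 0.5):
        raise ValueError("Poisson ratio must lie in [0, 0.5); nu = 0.5 is "
                         "the incompressible limit")
    mu = E / (2.0 * (1.0 + nu))
    K = E / (3.0 * (1.0 - 2.0 * nu))
    return mu, K


def strain_energy(I1, J, mu: float, K: float):
    """Neo-Hookean strain-energy density (kPa); J must be positive."""
    J = np.asarray(J, dtype=float)
    if np.any(J <= 0):
        raise ValueError("J must be positive (element inversion)")
    return mu / 2 * (J ** (-2.0 / 3.0) * np.asarray(I1) - 3.0) \
        + K / 2 * (J - 1.0) ** 2


@dataclass(frozen=True)
class Material:
    """Isotropic Neo-Hookean tissue parameters."""

    E: float                 # Young modulus, kPa
    nu: float = 0.49
    rho: float = 1.0         # density, kg/L

    @property
    def mu(self) -> float:
        return derive_moduli(self.E, self.nu)[0]

    @property
    def K(self) -> float:
        return derive_moduli(self.E, self.nu)[1]


def material_table(E_fat: float, E_glandular: float, E_skin: float,
                   E_scar: float | None = None,
                   E_inflamed: float = 80.0, nu: float = 0.49,
                   rho_fat: float = 0.9, rho_glandular: float = 1.0,
                   rho_skin: float = 1.0) -> dict[int, Material]:
    """Material dictionary keyed by tissue code, with literature densities."""
    table = {FAT: Material(E_fat, nu, rho_fat),
             GLANDULAR: Material(E_glandular, nu, rho_glandular),
             SKIN: Material(E_skin, nu, rho_skin),
             INFLAMED: Material(E_inflamed, nu, 1.0)}
    if E_scar is not None:
        table[SCAR] = Material(E_scar, nu, 1.0)
    return table


@dataclass(frozen=True)
class LoadCase:
    """Gravity direction/magnitude (m/s^2) and cavity pressure (Pa)."""

    gravity: tuple[float, float] = GRAVITY_SEATED
    pressure: float = 0.0

    def __post_init__(self):
        if self.pressure < 0:
            raise ValueError("cavity pressure must be >= 0")


@dataclass
class MechanicalState:
    """Equilibrium solution on a BreastMesh (P2 displacement field)."""

    mesh: BreastMesh
    u: np.ndarray               # (N2, 2) nodal displacements, mm (P2 nodes)
    n_p1: int                   # number of corner (P1) nodes
    J: np.ndarray               # per-element det F (quadrature mean)
    I1: np.ndarray              # per-element first invariant
    W: np.ndarray               # per-element strain-energy density, kPa
    residual: float
    load: LoadCase
    converged: bool = True

    @property
    def deformed_nodes(self) -> np.ndarray:
        """Deformed corner-node coordinates (mm)."""
        return self.mesh.nodes + self.u[:self.n_p1]


# ---------------------------------------------------------------------------
# P2 discretisation
# ---------------------------------------------------------------------------

_QP = np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]])
_QW = np.full(3, 1 / 6)


def _tri6_shape(xi, eta):
    l1, l2, l3 = 1 - xi - eta, xi, eta
    N = np.array([l1 * (2 * l1 - 1), l2 * (2 * l2 - 1), l3 * (2 * l3 - 1),
                  4 * l1 * l2, 4 * l2 * l3, 4 * l3 * l1])
    dl = np.array([[-1, -1], [1, 0], [0, 1]], dtype=float)
    dN = np.vstack([(4 * l1 - 1) * dl[0], (4 * l2 - 1) * dl[1],
                    (4 * l3 - 1) * dl[2],
                    4 * (l2 * dl[0] + l1 * dl[1]),
                    4 * (l3 * dl[1] + l2 * dl[2]),
                    4 * (l1 * dl[2] + l3 * dl[0])])
    return N, dN


_SHAPE_N = np.stack([_tri6_shape(*qp)[0] for qp in _QP])      # (Q, 6)
_SHAPE_dN = np.stack([_tri6_shape(*qp)[1] for qp in _QP])     # (Q, 6, 2)

# 1D quadratic edge shape functions (nodes: end a, end b, midside)
_EQP = np.array([0.5 - 0.5 / np.sqrt(3), 0.5 + 0.5 / np.sqrt(3)])
_EQW = np.array([0.5, 0.5])


def _edge_shape(t):
    M = np.array([(1 - t) * (1 - 2 * t), t * (2 * t - 1), 4 * t * (1 - t)])
    dM = np.array([4 * t - 3, 4 * t - 1, 4 - 8 * t])
    return M, dM


class _P2Grid:
    """Quadratic-triangle discretisation derived from a P1 BreastMesh."""

    def __init__(self, mesh: BreastMesh):
        self.mesh = mesh
        tris = mesh.tris
        self.n_p1 = len(mesh.nodes)
        edges = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]],
                                tris[:, [2, 0]]])
        key = np.sort(edges, axis=1)
        uniq, inv = np.unique(key, axis=0, return_inverse=True)
        self.n_nodes = self.n_p1 + len(uniq)
        mid_ids = (self.n_p1 + inv).reshape(3, -1).T       # (M, 3)
        self.conn = np.hstack([tris, mid_ids])             # (M, 6)
        self.coords = np.vstack([mesh.nodes,
                                 mesh.nodes[uniq].mean(axis=1)])
        self._edge_key = {tuple(k): self.n_p1 + i
                          for i, k in enumerate(map(tuple, uniq))}

        # affine geometry per element: J_ij = dx_i/dxi_j (columns = edges)
        p = mesh.nodes[tris]
        J2 = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]], axis=2)
        self.detJ = np.linalg.det(J2)
        invJ = np.linalg.inv(J2)
        # physical shape gradients g[e, q, a, i] = dN_a/dxi_j dxi_j/dx_i
        self.g = np.einsum("qaj,eji->eqai", _SHAPE_dN, invJ)

        # scatter indices for assembly
        dof = np.stack([2 * self.conn, 2 * self.conn + 1], axis=2)  # (M,6,2)
        self.edof = dof.reshape(len(tris), 12)
        self.rows = np.repeat(self.edof, 12, axis=1).ravel()
        self.cols = np.tile(self.edof, (1, 12)).ravel()

        # boundary edge connectivity (a, b, mid) per marker
        self.bedges = {}
        for marker, ed in mesh.boundary.items():
            if len(ed) == 0:
                continue
            mids = [self._edge_key[tuple(sorted(e))] for e in ed]
            self.bedges[marker] = np.column_stack([ed, mids])

    def clamped_dofs(self) -> np.ndarray:
        nodes = set()
        for e in self.bedges.get("chest_wall", []):
            nodes.update(int(n) for n in e)
        nodes = np.array(sorted(nodes), dtype=int)
        return np.concatenate([2 * nodes, 2 * nodes + 1]) if len(nodes) else \
            np.empty(0, dtype=int)


def _material_arrays(mesh: BreastMesh, materials: dict[int, "Material"]):
    mu = np.empty(len(mesh.tris))
    K = np.empty(len(mesh.tris))
    rho = np.empty(len(mesh.tris))
    for code in np.unique(mesh.material):
        mat = materials.get(int(code))
        if mat is None:
            raise KeyError(f"no material for tissue code {int(code)} "
                           f"({code!r})")
        sel = mesh.material == code
        mu[sel], K[sel], rho[sel] = mat.mu, mat.K, mat.rho
    return mu, K, rho


def _kinematics(grid: _P2Grid, u: np.ndarray):
    ue = u[grid.conn]                                       # (M, 6, 2)
    H = np.einsum("eai,eqaj->eqij", ue, grid.g)             # grad u
    F = H + np.eye(2)
    J = np.linalg.det(F)
    return F, J


def _stress_and_tangent(F, J, mu, K, want_tangent=True):
    """First Piola stress and tangent dP/dF for plane-strain Neo-Hooke."""
    B = np.linalg.inv(F).swapaxes(-1, -2)                   # F^{-T}
    I1 = np.einsum("...ij,...ij->...", F, F) + 1.0
    Jm23 = J ** (-2.0 / 3.0)
    mu_ = mu[:, None]
    K_ = K[:, None]
    P = mu_[..., None, None] * Jm23[..., None, None] * (
        F - (I1 / 3.0)[..., None, None] * B) \
        + (K_ * (J - 1.0) * J)[..., None, None] * B
    W = mu_ / 2 * (Jm23 * I1 - 3.0) + K_ / 2 * (J - 1.0) ** 2
    if not want_tangent:
        return P, W, I1, None
    d = np.eye(2)
    BB1 = np.einsum("...ia,...jb->...iajb", B, B)
    BB2 = np.einsum("...ib,...ja->...iajb", B, B)
    FB = np.einsum("...ia,...jb->...iajb", F, B)
    BF = np.einsum("...ia,...jb->...iajb", B, F)
    dd = np.einsum("ij,ab->iajb", d, d)
    c1 = (mu_ * Jm23)[..., None, None, None, None]
    I1e = I1[..., None, None, None, None]
    A = c1 * (dd - (2.0 / 3.0) * (FB + BF) + (2.0 / 9.0) * I1e * BB1
              + (I1e / 3.0) * BB2) \
        + (K_ * (2 * J - 1.0) * J)[..., None, None, None, None] * BB1 \
        - (K_ * (J - 1.0) * J)[..., None, None, None, None] * BB2
    return P, W, I1, A


def _internal_force(grid, P):
    # f[e, a, i] = sum_q w detJ P[e,q,i,j] g[e,q,a,j]
    return np.einsum("q,e,eqij,eqaj->eai", _QW, grid.detJ, P, grid.g)


def _stiffness_values(grid, A):
    K = np.einsum("q,e,eqac,eqicjd,eqbd->eaibj", _QW, grid.detJ, grid.g,
                  A, grid.g, optimize=True)
    return K.reshape(len(grid.conn), 12, 12)


def _gravity_force(grid, rho, gravity):
    b = 1e-3 * rho                                          # kPa/mm per m/s^2
    w = np.einsum("q,e,qa->ea", _QW, grid.detJ, _SHAPE_N)   # int N_a
    f = np.zeros((grid.n_nodes, 2))
    for i, gi in enumerate(gravity):
        np.add.at(f[:, i], grid.conn.ravel(), (w * b[:, None]).ravel() * gi)
    return f


_G_EDGE = None


def _edge_G():
    """G_ab = int_0^1 M_a M'_b dt (exact by 2-pt Gauss)."""
    global _G_EDGE
    if _G_EDGE is None:
        G_ = np.zeros((3, 3))
        for t, w in zip(_EQP, _EQW):
            M, dM = _edge_shape(t)
            G_ += w * np.outer(M, dM)
        _G_EDGE = G_
    return _G_EDGE


def _pressure_force(grid, x_current, p_kpa):
    """Follower cavity-pressure nodal forces and tangent triplets."""
    f = np.zeros((grid.n_nodes, 2))
    rows, cols, vals = [], [], []
    edges = grid.bedges.get("cavity_wall")
    if edges is None or p_kpa == 0.0:
        return f, (np.empty(0, int), np.empty(0, int), np.empty(0))
    Gab = _edge_G()
    for conn in edges:
        xe = x_current[conn]                               # (3, 2)
        for t, w in zip(_EQP, _EQW):
            M, dM = _edge_shape(t)
            dx = dM @ xe                                   # tangent * |J|
            # traction = -P * outward normal; n|J| = (y', -x')
            f[conn, 0] += -p_kpa * w * M * dx[1]
            f[conn, 1] += +p_kpa * w * M * dx[0]
        # exact tangent of f_ext wrt x: df_ax/dy_b = -P G_ab, df_ay/dx_b = +P G_ab
        for a in range(3):
            for b in range(3):
                rows += [2 * conn[a], 2 * conn[a] + 1]
                cols += [2 * conn[b] + 1, 2 * conn[b]]
                # K = d(residual)/du = -d f_ext/du
                vals += [+p_kpa * Gab[a, b], -p_kpa * Gab[a, b]]
    return f, (np.array(rows), np.array(cols), np.array(vals))


def _assemble(grid, u, mu, K_mod, f_grav, p_kpa, factor, want_tangent=True):
    F, J = _kinematics(grid, u)
    if np.any(J <= 0):
        return None
    P, W, I1, A = _stress_and_tangent(F, J, mu, K_mod, want_tangent)
    fe = _internal_force(grid, P)
    f_int = np.zeros(2 * grid.n_nodes)
    np.add.at(f_int, grid.edof.ravel(),
              fe.reshape(len(grid.conn), 12).ravel())
    f_int = f_int.reshape(-1, 2)
    x_cur = grid.coords + u
    f_pres, (pr, pc, pv) = _pressure_force(grid, x_cur, p_kpa * factor)
    f_ext = factor * f_grav + f_pres
    r = (f_int - f_ext).ravel()
    Kmat = None
    if want_tangent:
        kv = _stiffness_values(grid, A).ravel()
        rows = np.concatenate([grid.rows, pr])
        cols = np.concatenate([grid.cols, pc])
        vals = np.concatenate([kv, pv])
        n = 2 * grid.n_nodes
        Kmat = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return r, Kmat, f_ext, (F, J, W, I1)


def _newton(grid, u, mu, K_mod, f_grav, p_kpa, factor, free, tol, max_iter):
    """Damped Newton with a nonmonotone safeguard.

    Full steps are taken unless they invert an element or blow the
    residual up by orders of magnitude — transient residual growth is
    normal for Newton on hyperelasticity and must not trigger damping.
    """
    res = _assemble(grid, u, mu, K_mod, f_grav, p_kpa, factor,
                    want_tangent=False)
    if res is None:
        raise MechanicsError("element inversion in initial state")
    r, _, f_ext, kin = res
    ref = max(1.0, np.linalg.norm(f_ext.ravel()[free]))
    rn = np.linalg.norm(r[free])
    r_floor = rn
    lu = None                     # reused Jacobian factorisation
    fresh = False
    for _ in range(max_iter):
        if rn <= tol * ref:
            return u, rn, kin
        if lu is None:
            full = _assemble(grid, u, mu, K_mod, f_grav, p_kpa, factor)
            Kff = full[1][free][:, free].tocsc()
            lu = sparse.linalg.splu(Kff)
            fresh = True
        du = np.zeros_like(r)
        du[free] = lu.solve(-r[free])
        alpha, accepted = 1.0, None
        for _ls in range(12):
            trial = u + alpha * du.reshape(-1, 2)
            res = _assemble(grid, trial, mu, K_mod, f_grav, p_kpa, factor,
                            want_tangent=False)
            if res is not None and np.isfinite(res[0]).all():
                # transient residual overshoot is normal for Newton on
                # hyperelasticity: only element inversion forces damping
                accepted = (trial, np.linalg.norm(res[0][free]))
                break
            alpha *= 0.5
        if accepted is None:
            if not fresh:
                lu = None          # retry once with a fresh Jacobian
                continue
            raise MechanicsError("line search failed", rn)
        u, r2 = accepted
        if r2 > 1e6 * max(ref, r_floor):
            raise MechanicsError("Newton divergence", r2)
        # stale Jacobians are kept while convergence stays fast
        if r2 > 0.25 * rn:
            lu = None
        fresh = False
        rn = r2
        r_floor = min(r_floor, rn)
        r, _, f_ext, kin = res
    if rn <= tol * ref:
        return u, rn, kin
    raise MechanicsError(f"Newton did not converge (residual {rn:.3e}, "
                         f"ref {ref:.3e})", rn)


def solve_equilibrium(mesh: BreastMesh, materials: dict[int, Material],
                      load: LoadCase, tol: float = 1e-8,
                      max_newton: int = 30, n_steps: int | None = None,
                      u0: np.ndarray | None = None) -> MechanicalState:
    """Static equilibrium under gravity and cavity pressure.

    Load is ramped in up to 10 increments for robustness (one increment
    when a good initial guess ``u0`` from a neighbouring solve is given);
    each increment runs damped Newton with the analytic tangent until the
    free-dof residual drops below ``tol`` relative to the external load.
    """
    grid = _P2Grid(mesh)
    mu, K_mod, rho = _material_arrays(mesh, materials)
    f_grav = _gravity_force(grid, rho, load.gravity)
    p_kpa = load.pressure / 1000.0
    clamped = grid.clamped_dofs()
    free = np.setdiff1d(np.arange(2 * grid.n_nodes), clamped)

    zero = np.zeros((grid.n_nodes, 2))
    if u0 is not None and len(u0) == grid.n_nodes:
        # a far-off warm start can be worse than ramping from rest, so the
        # fallback schedules always restart from zero
        schedules = [(u0, [1.0]), (zero, [1.0]),
                     (zero, list(np.linspace(0.25, 1.0, 4))),
                     (zero, list(np.linspace(0.1, 1.0, 10)))]
    else:
        schedules = [(zero, [1.0]),
                     (zero, list(np.linspace(0.25, 1.0, 4))),
                     (zero, list(np.linspace(0.1, 1.0, 10)))]
    if n_steps is not None:
        schedules = [(zero, list(np.linspace(1.0 / n_steps, 1.0, n_steps)))]

    last_err = None
    for u_start, factors in schedules:
        try:
            uk = u_start.copy()
            # fail fast on the optimistic single-step attempt
            iters = min(max_newton, 12) if len(factors) == 1 else max_newton
            for fac in factors:
                uk, rn, kin = _newton(grid, uk, mu, K_mod, f_grav, p_kpa,
                                      fac, free, tol, iters)
            F, J, W, I1 = kin
            return MechanicalState(
                mesh=mesh, u=uk, n_p1=grid.n_p1,
                J=J.mean(axis=1), I1=I1.mean(axis=1), W=W.mean(axis=1),
                residual=rn, load=load)
        except MechanicsError as err:
            last_err = err
    raise MechanicsError(f"equilibrium solve failed: {last_err}",
                         getattr(last_err, "residual", np.nan))


def p2_coordinates(mesh: BreastMesh) -> np.ndarray:
    """Coordinates of all quadratic nodes (corners then edge midpoints)."""
    return _P2Grid(mesh).coords


def evaluate_state(mesh: BreastMesh, materials: dict[int, Material],
                   u: np.ndarray, load: LoadCase | None = None
                   ) -> MechanicalState:
    """Kinematics and energies of a given (not necessarily equilibrium)
    P2 displacement field — used for objectivity and energy checks."""
    grid = _P2Grid(mesh)
    mu, K_mod, _ = _material_arrays(mesh, materials)
    F, J = _kinematics(grid, u)
    if np.any(J <= 0):
        raise ValueError("element inversion")
    P, W, I1, _ = _stress_and_tangent(F, J, mu, K_mod, want_tangent=False)
    return MechanicalState(mesh=mesh, u=u, n_p1=grid.n_p1,
                           J=J.mean(axis=1), I1=I1.mean(axis=1),
                           W=W.mean(axis=1), residual=np.nan,
                           load=load or LoadCase(), converged=False)


def solve_linear(mesh: BreastMesh, materials: dict[int, Material],
                 load: LoadCase) -> np.ndarray:
    """Small-strain linear-elastic solve (oracle for the nonlinear solver).

    Uses the Neo-Hookean tangent at the undeformed state, i.e. isotropic
    linear elasticity with lambda = K - 2 mu / 3; pressure is applied on
    the reference cavity geometry.
    """
    grid = _P2Grid(mesh)
    mu, K_mod, rho = _material_arrays(mesh, materials)
    u0 = np.zeros((grid.n_nodes, 2))
    F, J = _kinematics(grid, u0)
    _, _, _, A = _stress_and_tangent(F, J, mu, K_mod)
    kv = _stiffness_values(grid, A).ravel()
    n = 2 * grid.n_nodes
    Kmat = sparse.coo_matrix((kv, (grid.rows, grid.cols)),
                             shape=(n, n)).tocsr()
    f = _gravity_force(grid, rho, load.gravity)
    fp, _ = _pressure_force(grid, grid.coords, load.pressure / 1000.0)
    f = (f + fp).ravel()
    clamped = grid.clamped_dofs()
    free = np.setdiff1d(np.arange(n), clamped)
    u = np.zeros(n)
    u[free] = spsolve(Kmat[free][:, free].tocsc(), f[free])
    return u.reshape(-1, 2)


def estimate_unloaded(mesh_observed: BreastMesh,
                      materials: dict[int, Material],
                      observed_load: LoadCase, tol: float = 0.05,
                      max_cycles: int = 30) -> BreastMesh:
    """Stress-free geometry whose loaded shape matches the observed mesh.

    Fixed-point ("inverse gravity") iteration: starting from the observed
    geometry, repeatedly subtract the forward-load displacement until
    loading the candidate reproduces the observed node positions within
    ``tol`` (max nodal error, mm).
    """
    target = mesh_observed.nodes.copy()
    cand = mesh_observed
    for _ in range(max_cycles):
        # no warm start: the reference geometry changes between cycles
        state = solve_equilibrium(cand, materials, observed_load)
        err = np.abs(state.deformed_nodes - target).max()
        if err <= tol:
            return cand
        cand = replace(cand, nodes=cand.nodes - (state.deformed_nodes - target))
    raise MechanicsError(f"unloaded-state iteration did not contract below "
                         f"{tol} mm in {max_cycles} cycles (err {err:.3g})")


def normalized_stress(state: MechanicalState) -> np.ndarray:
    """Per-element strain-energy density normalised to [0, 1].

    The healing model's mechanical stimulus: element W divided by the
    maximum W over the mesh (zero field if nothing is stressed).
    """
    wmax = float(state.W.max(initial=0.0))
    if wmax <= 1e-300:
        return np.zeros_like(state.W)
    return np.clip(state.W / wmax, 0.0, 1.0)


def outer_contour(state_or_mesh, deformed: bool = True) -> np.ndarray:
    """Ordered closed polyline of the outer boundary (skin + chest wall).

    For a MechanicalState the deformed coordinates are used — this is the
    simulated counterpart of a side-view photograph silhouette.
    """
    if isinstance(state_or_mesh, MechanicalState):
        mesh = state_or_mesh.mesh
        coords = state_or_mesh.deformed_nodes if deformed else mesh.nodes
    else:
        mesh, coords = state_or_mesh, state_or_mesh.nodes
    edges = [mesh.boundary.get(m, np.empty((0, 2), int))
             for m in ("skin_surface", "chest_wall")]
    edges = np.vstack([e for e in edges if len(e)])
    nxt = {int(a): int(b) for a, b in edges}
    start = int(edges[0, 0])
    loop, cur = [start], nxt[start]
    while cur != start and len(loop) <= len(edges) + 1:
        loop.append(cur)
        cur = nxt.get(cur)
        if cur is None:
            raise ValueError("outer boundary is not a closed loop")
    return coords[np.array(loop)]


def export_state_vtk(path, state: MechanicalState) -> None:
    """Write displacements and J / W / normalised-stress fields as VTK."""
    from .mesh import write_vtk
    write_vtk(path, state.mesh,
              point_data={"displacement": state.u[:state.n_p1]},
              cell_data={"J": state.J, "W": state.W,
                         "E_hat": normalized_stress(state)})
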
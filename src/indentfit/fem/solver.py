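"""Quasi-static large-deformation solver for rigid hemispherical indentation.

Total-Lagrangian axisymmetric formulation on the graded Q8 mesh: Green-
Lagrange strain with the hoop component ``E_theta = (lambda_theta**2 - 1)/2``,
second Piola-Kirchhoff stress from the uncoupled Ogden law, 3x3 Gauss
quadrature, Newton iterations with a consistent tangent (material part by
central differences of the stress at each Gauss point, geometric part
analytic) globalized by an Armijo line search on the elastic energy.

Contact with the rigid indenter (analytic hemisphere of radius 10 mm plus a
20 mm cylindrical shank) is frictionless and enforced exactly by an
active-set elimination: for every active top-surface node the coordinate
most aligned with the surface normal is a slave DOF tied to the analytic
indenter surface, so the reaction acts along the true surface normal and
the converged penetration is zero.  Nodes are activated when they
penetrate and released when their nodal normal force turns tensile.
Constraint violations enter the linearized system as nonhomogeneous terms,
so fresh penetrations are resolved through the depth of the mesh rather
than by crushing the surface elements.

Everything is displacement driven: the indenter is lowered in uniform
steps (with automatic bisection on Newton failure) and the report depths
are forced onto the step grid.  The reaction force is the total vertical
contact reaction (full 360 degrees), recovered from the nodal residuals of
the active nodes.  Because ``kappa = 2000 c``, the converged displacement
field is independent of ``c`` and the reaction is exactly proportional to
it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from indentfit.fem.mesh import Mesh, MeshSpec, build_mesh
from indentfit.fem.ogden import OgdenParams, pk2_voigt, small_strain_moduli, strain_energy_voigt

__all__ = [
    "FEModel",
    "IndentationSolution",
    "NonConvergenceError",
    "solve_indentation",
    "surface_profile",
    "hertz_force",
    "interpolate_state",
]

R_TIP = 10.0  # mm
WALL_HEIGHT = 20.0  # mm cylindrical shank above the hemisphere equator

_GP1D = np.array([-np.sqrt(3.0 / 5.0), 0.0, np.sqrt(3.0 / 5.0)])
_GW1D = np.array([5.0 / 9.0, 8.0 / 9.0, 5.0 / 9.0])


class NonConvergenceError(RuntimeError):
    """Newton failed below the minimum step size; identifies (c, m, delta)."""


class _StepDiverged(RuntimeError):
    pass


def _shape_q8(xi: float, eta: float):
    """Q8 serendipity shape functions and parent derivatives."""
    N = np.array([
        0.25 * (1 - xi) * (1 - eta) * (-1 - xi - eta),
        0.25 * (1 + xi) * (1 - eta) * (xi - eta - 1),
        0.25 * (1 + xi) * (1 + eta) * (xi + eta - 1),
        0.25 * (1 - xi) * (1 + eta) * (-xi + eta - 1),
        0.5 * (1 - xi * xi) * (1 - eta),
        0.5 * (1 + xi) * (1 - eta * eta),
        0.5 * (1 - xi * xi) * (1 + eta),
        0.5 * (1 - xi) * (1 - eta * eta),
    ])
    dN = np.array([
        [0.25 * (1 - eta) * (2 * xi + eta), 0.25 * (1 - xi) * (xi + 2 * eta)],
        [0.25 * (1 - eta) * (2 * xi - eta), 0.25 * (1 + xi) * (2 * eta - xi)],
        [0.25 * (1 + eta) * (2 * xi + eta), 0.25 * (1 + xi) * (2 * eta + xi)],
        [0.25 * (1 + eta) * (2 * xi - eta), 0.25 * (1 - xi) * (2 * eta - xi)],
        [-xi * (1 - eta), -0.5 * (1 - xi * xi)],
        [0.5 * (1 - eta * eta), -eta * (1 + xi)],
        [-xi * (1 + eta), 0.5 * (1 - xi * xi)],
        [-0.5 * (1 - eta * eta), -eta * (1 - xi)],
    ])
    return N, dN


@dataclass
class IndentationSolution:
    """Forward-model output: reaction history and surface snapshots."""

    params: OgdenParams
    mesh_spec: MeshSpec
    delta_history: np.ndarray  # mm, solved step targets
    reaction_history: np.ndarray  # N
    energy_history: np.ndarray  # N*mm, total elastic energy per step
    snapshots: dict = field(default_factory=dict)  # delta -> snapshot dict
    diagnostics: dict = field(default_factory=dict)

    def reaction_at(self, delta: float) -> float:
        """Reaction force at a solved depth (interpolated along the history)."""
        return float(np.interp(delta, self.delta_history, self.reaction_history))

    def snapshot(self, delta: float) -> dict:
        for key, snap in self.snapshots.items():
            if abs(key - delta) < 1e-9:
                return snap
        raise KeyError(f"no snapshot at delta={delta} mm")


class FEModel:
    """Precomputed assembly operators for one mesh, reusable across materials."""

    def __init__(self, mesh: Mesh | MeshSpec):
        if isinstance(mesh, MeshSpec):
            mesh = build_mesh(mesh)
        self.mesh = mesh
        X = mesh.nodes
        conn = mesh.conn
        nel = mesh.n_elems

        gp = [(xi, eta) for eta in _GP1D for xi in _GP1D]
        gw = np.array([wx * we for we in _GW1D for wx in _GW1D])
        ngp = len(gp)
        Nsh = np.empty((ngp, 8))
        dNxi = np.empty((ngp, 8, 2))
        for g, (xi, eta) in enumerate(gp):
            Nsh[g], dNxi[g] = _shape_q8(xi, eta)

        Xe = X[conn]  # (nel, 8, 2)
        # J0[e,g,i,j] = dX_i/dxi_j
        J0 = np.einsum("eai,gaj->egij", Xe, dNxi)
        detJ0 = J0[..., 0, 0] * J0[..., 1, 1] - J0[..., 0, 1] * J0[..., 1, 0]
        if np.any(detJ0 <= 0):
            raise ValueError("mesh contains inverted elements")
        inv = np.empty_like(J0)
        inv[..., 0, 0] = J0[..., 1, 1] / detJ0
        inv[..., 1, 1] = J0[..., 0, 0] / detJ0
        inv[..., 0, 1] = -J0[..., 0, 1] / detJ0
        inv[..., 1, 0] = -J0[..., 1, 0] / detJ0
        # dN/dX_i = dN/dxi_j * dxi_j/dX_i
        self.dNdX = np.einsum("gaj,egji->egai", dNxi, inv)
        self.Nsh = Nsh
        self.Rgp = np.einsum("ga,ea->eg", Nsh, Xe[:, :, 0])
        self.wdet = gw[None, :] * detJ0 * self.Rgp  # per-radian measure
        self.conn = conn
        self.Xe = Xe
        self.n_dof = 2 * mesh.n_nodes

        edof = np.empty((nel, 16), dtype=int)
        edof[:, 0::2] = 2 * conn
        edof[:, 1::2] = 2 * conn + 1
        self.edof = edof
        self.k_rows = np.repeat(edof, 16, axis=1).ravel()
        self.k_cols = np.tile(edof, (1, 16)).ravel()

        # boundary conditions: axis u_r = 0, bottom face fully clamped
        free = np.ones(self.n_dof, dtype=bool)
        free[2 * mesh.node_sets["axis"]] = False
        free[2 * mesh.node_sets["bottom"]] = False
        free[2 * mesh.node_sets["bottom"] + 1] = False
        self.free = free
        self.top_nodes = mesh.node_sets["top"]
        # precomputed shape-function outer products for the hoop stiffness
        self._NN = Nsh[:, :, None] * Nsh[:, None, :]
        # gap closed per Newton iteration is capped at half the height of the
        # top element row: larger jumps crush the surface elements
        z_vals = np.unique(np.round(X[:, 1], 9))
        self.gap_ramp = 0.5 * float(z_vals[-1] - z_vals[-3])

    # ------------------------------------------------------------------ bulk
    def _kinematics(self, u: np.ndarray):
        ue = u.reshape(-1, 2)[self.conn]  # (nel, 8, 2)
        F = np.einsum("eai,egaj->egij", ue, self.dNdX)
        F[..., 0, 0] += 1.0
        F[..., 1, 1] += 1.0
        ur = np.einsum("ga,ea->eg", self.Nsh, ue[:, :, 0])
        lam_t = 1.0 + ur / self.Rgp
        C11 = F[..., 0, 0] ** 2 + F[..., 1, 0] ** 2
        C22 = F[..., 0, 1] ** 2 + F[..., 1, 1] ** 2
        C12 = F[..., 0, 0] * F[..., 0, 1] + F[..., 1, 0] * F[..., 1, 1]
        Cth = lam_t**2
        return F, lam_t, (C11, C22, C12, Cth)

    def _bmatrix(self, F, lam_t):
        nel, ngp = F.shape[:2]
        B = np.zeros((nel, ngp, 8, 2, 4))
        dN = self.dNdX
        for i in range(2):
            B[..., i, 0] = F[..., i, 0, None] * dN[..., 0]
            B[..., i, 1] = F[..., i, 1, None] * dN[..., 1]
            B[..., i, 2] = (
                F[..., i, 0, None] * dN[..., 1] + F[..., i, 1, None] * dN[..., 0]
            )
        B[..., 0, 3] = (lam_t / self.Rgp)[..., None] * self.Nsh[None, :, :]
        return B

    def internal_force(self, u: np.ndarray, params: OgdenParams):
        """Global internal force vector (gradient of elastic energy), N."""
        with np.errstate(all="ignore"):
            F, lam_t, C = self._kinematics(u)
            c, m, kappa = params.c_mpa, params.m, params.kappa_mpa
            S = np.stack(pk2_voigt(*C, c, m, kappa), axis=-1)  # (nel, ngp, 4)
            B4 = self._bmatrix(F, lam_t).reshape(*S.shape[:2], 16, 4)
            wS = (self.wdet[..., None] * S)[..., None]
            fe = (B4 @ wS)[..., 0].sum(axis=1) * (2 * np.pi)
        fvec = np.zeros(self.n_dof)
        np.add.at(fvec, self.edof, fe)
        return fvec

    def elastic_energy(self, u: np.ndarray, params: OgdenParams) -> float:
        with np.errstate(all="ignore"):
            _, _, C = self._kinematics(u)
            psi = strain_energy_voigt(*C, params.c_mpa, params.m, params.kappa_mpa)
            e = float(np.sum(self.wdet * psi) * 2 * np.pi)
        return e if np.isfinite(e) else np.inf

    def volume_ratio_range(self, u: np.ndarray):
        """(min J, max J) over all Gauss points for the current state."""
        F, lam_t, _ = self._kinematics(u)
        det2 = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
        J = det2 * lam_t
        return float(J.min()), float(J.max())

    def assemble(self, u: np.ndarray, params: OgdenParams):
        """Internal force and consistent tangent stiffness."""
        with np.errstate(all="ignore"):
            F, lam_t, C = self._kinematics(u)
            c, m, kappa = params.c_mpa, params.m, params.kappa_mpa
            C11, C22, C12, Cth = C
            S = np.stack(pk2_voigt(C11, C22, C12, Cth, c, m, kappa), axis=-1)
            B = self._bmatrix(F, lam_t)

            # material tangent dS/dE by central differences on C per GP
            h = 1e-6
            D = np.empty(S.shape[:2] + (4, 4))
            perturb = [
                (2 * h, 0.0, 0.0, 0.0),
                (0.0, 2 * h, 0.0, 0.0),
                (0.0, 0.0, h, 0.0),
                (0.0, 0.0, 0.0, 2 * h),
            ]
            for w, (d1, d2, d3, d4) in enumerate(perturb):
                Sp = np.stack(
                    pk2_voigt(C11 + d1, C22 + d2, C12 + d3, Cth + d4, c, m, kappa),
                    axis=-1,
                )
                Sm = np.stack(
                    pk2_voigt(C11 - d1, C22 - d2, C12 - d3, Cth - d4, c, m, kappa),
                    axis=-1,
                )
                D[..., :, w] = (Sp - Sm) / (2 * h)
            D = 0.5 * (D + np.swapaxes(D, -1, -2))

            B4 = B.reshape(*S.shape[:2], 16, 4)
            fvec = np.zeros(self.n_dof)
            fe = (B4 @ ((self.wdet[..., None] * S)[..., None]))[..., 0].sum(axis=1)
            np.add.at(fvec, self.edof, fe * (2 * np.pi))

            wB4 = self.wdet[..., None, None] * B4
            Ke16 = ((wB4 @ D) @ B4.transpose(0, 1, 3, 2)).sum(axis=1)
            # geometric part
            S2 = np.empty(S.shape[:2] + (2, 2))
            S2[..., 0, 0] = S[..., 0]
            S2[..., 1, 1] = S[..., 1]
            S2[..., 0, 1] = S2[..., 1, 0] = S[..., 2]
            dN = self.dNdX
            geo = (
                (dN @ S2 @ dN.transpose(0, 1, 3, 2)) * self.wdet[..., None, None]
            ).sum(axis=1)
            hoop = np.tensordot(
                self.wdet * S[..., 3] / self.Rgp**2, self._NN, axes=([1], [0])
            )
            Ke = Ke16.reshape(-1, 8, 2, 8, 2)
            Ke[:, :, 0, :, 0] += geo + hoop
            Ke[:, :, 1, :, 1] += geo
            Ke *= 2 * np.pi
        K = sp.coo_matrix(
            (Ke.reshape(-1), (self.k_rows, self.k_cols)),
            shape=(self.n_dof, self.n_dof),
        ).tocsr()
        return fvec, K

    # --------------------------------------------------------------- contact
    @staticmethod
    def _gap(x: np.ndarray, zc: float):
        """Signed gap to the indenter (sphere + shank) and outward normal."""
        r, z = x[..., 0], x[..., 1]
        on_sphere = z <= zc
        dz = z - zc
        d = np.sqrt(r * r + dz * dz)
        d = np.maximum(d, 1e-12)
        g = np.where(
            on_sphere,
            d - R_TIP,
            np.where(z <= zc + WALL_HEIGHT, r - R_TIP, 1e6),
        )
        n = np.empty_like(x)
        n[..., 0] = np.where(on_sphere, r / d, 1.0)
        n[..., 1] = np.where(on_sphere, dz / d, 0.0)
        return g, n

    def _constraints(self, u: np.ndarray, active: np.ndarray, zc: float):
        """Slave/master DOF pairs, coefficients and gap-closing offsets.

        For each active top node the DOF most aligned with the local surface
        normal becomes the slave: on the flat part of the hemisphere the
        vertical DOF is tied to ``z = zc - sqrt(rt^2 - r^2)`` (master: the
        node's radial DOF), near the equator and on the shank the radial DOF
        is tied to the surface (master: the vertical DOF), avoiding the
        singular slope at the contact edge.

        Returns (slave_dofs, master_dofs, coefs, offsets).
        """
        nodes = self.top_nodes[active]
        if nodes.size == 0:
            e = np.empty(0)
            return (np.empty(0, int), np.empty(0, int), e, e, e)
        pos = self.mesh.nodes[nodes] + u.reshape(-1, 2)[nodes]
        r, z = pos[:, 0], pos[:, 1]
        on_sphere = z <= zc
        # z-elimination where the normal is mostly vertical (r < rt/sqrt(2))
        z_elim = on_sphere & (r <= R_TIP / np.sqrt(2.0))
        slaves = np.where(z_elim, 2 * nodes + 1, 2 * nodes)
        masters = np.where(z_elim, 2 * nodes, 2 * nodes + 1)
        root_z = np.sqrt(np.maximum(R_TIP**2 - np.minimum(r, 0.999 * R_TIP) ** 2, 1e-9))
        dzs = np.clip(z - zc, None, 0.999 * R_TIP)
        root_r = np.sqrt(np.maximum(R_TIP**2 - dzs**2, 1e-9))
        target = np.where(
            z_elim,
            zc - root_z,  # surface height at the node radius
            np.where(on_sphere, root_r, R_TIP),  # surface radius at node height
        )
        current = np.where(z_elim, z, r)
        coef = np.where(
            z_elim,
            np.minimum(r, 0.999 * R_TIP) / root_z,
            np.where(on_sphere, -dzs / root_r, 0.0),
        )
        # constraint curvature d2(slave)/d(master)2 for the exact Newton term
        curv = np.where(
            z_elim,
            R_TIP**2 / root_z**3,
            np.where(on_sphere, -(R_TIP**2) / root_r**3, 0.0),
        )
        offsets = target - current
        return slaves, masters, coef, offsets, curv

    def contact_reaction(self, f_int: np.ndarray, active: np.ndarray) -> float:
        """Total vertical contact reaction from nodal residuals, N."""
        nodes = self.top_nodes[active]
        return float(-np.sum(f_int[2 * nodes + 1]))

    def _update_active_set(self, u, f_int, active, zc, release_tol,
                           allow_release: bool = True):
        """Activate penetrating nodes; release nodes with tensile normal force."""
        nodes = self.top_nodes
        pos = self.mesh.nodes[nodes] + u.reshape(-1, 2)[nodes]
        g, n = self._gap(pos, zc)
        new_active = active.copy()
        # activation: penetration beyond a tiny slack
        new_active |= g < -1e-6
        if allow_release:
            # contact force on the tissue is f_int at the node; it must push
            # along +n (compression).  Tensile -> release.
            fn = f_int[2 * nodes] * n[:, 0] + f_int[2 * nodes + 1] * n[:, 1]
            scale = max(float(np.abs(fn[active]).max()) if active.any() else 0.0, 1e-30)
            new_active &= ~(active & (fn < -release_tol * scale))
        return new_active

    # ---------------------------------------------------------------- newton
    def _newton(self, u, params, active, zc, tol_rel, max_iter):
        """Newton iteration with in-loop contact activation and LU reuse.

        The constraint linearization (slave/master pairing, slopes, gap
        offsets) is rebuilt each iteration from the current positions.
        Nodes penetrating the indenter are activated on the fly (the set
        only grows here; tensile release happens between converged solves
        in the driver).  During pure equilibration (gaps closed) the
        factorized tangent is reused until progress stalls, which cuts the
        dominant assembly/factorization cost severalfold.
        Returns ``(u, f_int, active, n_iter)``.
        """
        free = self.free
        f_int = self.internal_force(u, params)
        if not np.all(np.isfinite(f_int)):
            raise _StepDiverged("non-finite state")
        lu = None
        rnorm_at_factor = np.inf
        for it in range(max_iter):
            grown = self._update_active_set(u, f_int, active, zc, 0.0, allow_release=False)
            if not np.array_equal(grown, active):
                active = grown
                lu = None
            slaves, masters, coef, offsets, curv = self._constraints(u, active, zc)

            is_slave = np.zeros(self.n_dof, dtype=bool)
            is_slave[slaves] = True
            solve_mask = free & ~is_slave

            # transformation u_full = T u_red + b (slave tied to master)
            keep = np.arange(self.n_dof)
            data = np.ones(self.n_dof)
            data[slaves] = 0.0
            T = sp.coo_matrix(
                (
                    np.concatenate([data, coef]),
                    (np.concatenate([keep, slaves]), np.concatenate([keep, masters])),
                ),
                shape=(self.n_dof, self.n_dof),
            ).tocsr()
            gapnorm = float(np.abs(offsets).max()) if offsets.size else 0.0
            closing = gapnorm > 1e-6
            b = np.zeros(self.n_dof)
            # ramp the gap closure: crushing surface elements by more than
            # half their height in one linearized move is unrecoverable
            b[slaves] = offsets * min(1.0, self.gap_ramp / max(gapnorm, 1e-30))

            refresh = lu is None or closing
            if refresh:
                f_int, K = self.assemble(u, params)
                if not np.all(np.isfinite(f_int)):
                    raise _StepDiverged("non-finite residual")
                K_full = T.T @ K @ T
                if slaves.size:
                    # second-order constraint term: slave force times the
                    # curvature of the indenter surface along the master DOF
                    K_full = K_full + sp.coo_matrix(
                        (f_int[slaves] * curv, (masters, masters)),
                        shape=K_full.shape,
                    )
                try:
                    lu = spla.splu(K_full[solve_mask][:, solve_mask].tocsc())
                except Exception as exc:  # singular tangent
                    raise _StepDiverged(str(exc)) from exc
                lu_mask = solve_mask
                r_red = T.T @ (f_int + K @ b)
                rnorm_at_factor = np.inf
            else:
                r_red = T.T @ f_int

            rnorm = float(np.abs(r_red[solve_mask]).max())
            scale = max(float(np.abs(f_int[free]).max()), 1e-9 * params.c_mpa)
            if rnorm <= tol_rel * scale + 1e-13 and gapnorm <= 1e-8:
                return u, f_int, active, it
            if not refresh and rnorm > 0.3 * rnorm_at_factor:
                # stalled on the frozen tangent: force a fresh factorization
                lu = None
                continue
            rnorm_at_factor = min(rnorm_at_factor, rnorm)

            du_red = lu.solve(-r_red[lu_mask])
            if not np.all(np.isfinite(du_red)):
                raise _StepDiverged("non-finite Newton update")
            du = np.zeros(self.n_dof)
            du[lu_mask] = du_red
            du = T @ du + b

            # trust radius: exponential stress growth makes large linearized
            # moves meaningless.  While gaps close, cap the update at the
            # ramp scale; during pure equilibration the monotone line search
            # already rejects overshoots, so only a loose cap is needed.
            b_norm = float(np.abs(b).max()) if slaves.size else 0.0
            if closing:
                du_cap = max(1.5 * b_norm, 0.5 * self.gap_ramp)
            else:
                du_cap = max(1.0, 4.0 * self.gap_ramp)
            du_norm = float(np.abs(du).max())
            if du_norm > du_cap:
                du *= du_cap / du_norm

            alpha, accepted = 1.0, None
            best_u, best_f, best_tn = None, None, np.inf
            for _ in range(14):
                u_try = u + alpha * du
                f_try = self.internal_force(u_try, params)
                if np.all(np.isfinite(f_try)):
                    tn = float(np.abs((T.T @ f_try)[solve_mask]).max())
                    if tn < best_tn:
                        best_u, best_f, best_tn = u_try, f_try, tn
                    if closing:
                        # stress must be allowed to grow while gaps close
                        if tn <= 3.0 * max(rnorm, scale):
                            accepted, f_int = u_try, f_try
                            break
                    elif tn < rnorm * (1.0 - 1e-4 * alpha):
                        accepted, f_int = u_try, f_try
                        break
                alpha *= 0.5
            if accepted is None:
                # monotone fallback: take the best strictly improving trial
                if best_u is not None and best_tn < rnorm:
                    accepted, f_int = best_u, best_f
                else:
                    raise _StepDiverged("line search failed")
            u = accepted
        raise _StepDiverged("Newton iteration limit")

    def _relax_interior(self, u, params, tol_rel=1e-6, max_iter=30):
        """Equilibrate the interior with all top-surface nodes frozen.

        Used to clean up the volumetric residual of an interpolated warm
        start before the contact logic sees the state: with the surface held
        fixed this is plain hyperelasticity and converges quadratically.
        """
        mask = self.free.copy()
        mask[2 * self.top_nodes] = False
        mask[2 * self.top_nodes + 1] = False
        for _ in range(max_iter):
            f_int, K = self.assemble(u, params)
            if not np.all(np.isfinite(f_int)):
                raise _StepDiverged("non-finite warm state")
            rnorm = float(np.linalg.norm(f_int[mask]))
            scale = max(float(np.abs(f_int[self.free]).max()), 1e-9 * params.c_mpa)
            if float(np.abs(f_int[mask]).max()) <= tol_rel * scale + 1e-13:
                return u
            du = spla.spsolve(K[mask][:, mask].tocsc(), -f_int[mask])
            if not np.all(np.isfinite(du)):
                raise _StepDiverged("interior relaxation diverged")
            alpha, accepted = 1.0, None
            for _ in range(14):
                u_try = u.copy()
                u_try[mask] += alpha * du
                f_try = self.internal_force(u_try, params)
                if np.all(np.isfinite(f_try)) and float(
                    np.linalg.norm(f_try[mask])
                ) < rnorm * (1 - 1e-4 * alpha):
                    accepted = u_try
                    break
                alpha *= 0.5
            if accepted is None:
                raise _StepDiverged("interior relaxation stalled")
            u = accepted
        raise _StepDiverged("interior relaxation iteration limit")

    def equilibrate(
        self,
        params: OgdenParams,
        delta: float,
        state: np.ndarray,
        newton_tol: float = 1e-6,
        max_newton: int = 40,
        release_tol: float = 0.01,
    ) -> dict:
        """Re-equilibrate an approximate state at a fixed indentation depth.

        Warm-start primitive for continuation in material parameters or mesh
        resolution: hyperelastic equilibrium is path independent, so the
        converged result does not depend on the supplied guess.  Nodes
        resting on the indenter (gap ~ 0) start constrained.  Raises
        :class:`NonConvergenceError` if the state cannot be equilibrated;
        callers then fall back to smaller continuation steps or a cold walk.

        Returns a snapshot dict (``state``, ``reaction``, ``r``, ``uz``,
        ``ur``, ``active``).
        """
        height = self.mesh.spec.height
        zc = height + R_TIP - delta
        u = np.asarray(state, dtype=float).copy()
        try:
            u = self._relax_interior(u, params)
        except _StepDiverged:
            pass  # best effort; the contact attempt may still work
        pos = self.mesh.nodes[self.top_nodes] + u.reshape(-1, 2)[self.top_nodes]
        g, _ = self._gap(pos, zc)
        active = g < 1e-4
        try:
            for _ in range(8):
                u, f_int, active, _its = self._newton(
                    u, params, active, zc, newton_tol, max_newton
                )
                released = self._update_active_set(u, f_int, active, zc, release_tol)
                if np.array_equal(released, active):
                    break
                active = released
            else:
                raise _StepDiverged("active set did not settle")
        except _StepDiverged as exc:
            raise NonConvergenceError(
                f"equilibration failed at c={params.c_kpa} kPa, m={params.m}, "
                f"delta={delta:.3f} mm ({exc})"
            ) from exc
        top = self.top_nodes
        return {
            "state": u,
            "reaction": self.contact_reaction(f_int, active),
            "r": self.mesh.nodes[top, 0].copy(),
            "ur": u.reshape(-1, 2)[top, 0].copy(),
            "uz": u.reshape(-1, 2)[top, 1].copy(),
            "active": active,
        }

    # ----------------------------------------------------------------- drive
    def solve(
        self,
        params: OgdenParams,
        delta_max: float,
        n_steps: int = 24,
        snapshots=None,
        newton_tol: float = 1e-6,
        max_newton: int = 25,
        release_tol: float = 0.01,
        initial_states: dict | None = None,
    ) -> IndentationSolution:
        """Drive the indenter to ``delta_max`` and record snapshot profiles.

        Adaptive stepping: the step size halves when a solve fails and grows
        again (up to ``delta_max / n_steps``) after successes; snapshot
        depths are always landed on exactly.  Per accepted depth the contact
        set is re-equilibrated (activate penetrating nodes, release tensile
        ones) until it settles.
        """
        mesh = self.mesh
        height = mesh.spec.height
        snapshots = sorted(set(float(s) for s in (snapshots or [])))
        milestones = sorted(set(np.round(snapshots + [delta_max], 12)))
        dd_max = delta_max / n_steps
        min_dd = dd_max / 1024.0

        u = np.zeros(self.n_dof)
        active = np.zeros(len(self.top_nodes), dtype=bool)
        delta_prev = 0.0
        hist_d, hist_f, hist_e = [0.0], [0.0], [0.0]
        snaps = {}
        n_newton = 0
        dd = dd_max

        def _attempt(u, active, delta):
            """One depth increment: Newton (activation in-loop) + release."""
            zc = height + R_TIP - delta
            its_total = 0
            for _ in range(8):
                u, f_int, active, its = self._newton(
                    u, params, active, zc, newton_tol, max_newton
                )
                its_total += its
                released = self._update_active_set(u, f_int, active, zc, release_tol)
                if np.array_equal(released, active):
                    return u, f_int, active, its_total
                active = released
            raise _StepDiverged("active set did not settle")

        for milestone in milestones:
            # warm start: jump straight to the milestone from a supplied
            # approximate state (e.g. interpolated from a coarser mesh or a
            # neighboring material parameter); equilibrium is path
            # independent, so a successful re-equilibration is exact
            warm = None
            if initial_states:
                for key, state in initial_states.items():
                    if abs(key - milestone) < 1e-9:
                        warm = np.asarray(state, dtype=float).copy()
                        break
            if warm is not None:
                try:
                    snap = self.equilibrate(
                        params, milestone, warm,
                        newton_tol=newton_tol, max_newton=max_newton,
                        release_tol=release_tol,
                    )
                    u, active = snap["state"], snap["active"]
                    delta_prev = milestone
                    hist_d.append(milestone)
                    hist_f.append(snap["reaction"])
                    hist_e.append(self.elastic_energy(u, params))
                except NonConvergenceError:
                    pass  # fall back to the incremental walk below
            while delta_prev < milestone - 1e-12:
                delta = min(delta_prev + dd, milestone)
                try:
                    u_new, f_int, act_new, its = _attempt(u.copy(), active.copy(), delta)
                except _StepDiverged as exc:
                    dd = (delta - delta_prev) / 2.0
                    if dd < min_dd:
                        raise NonConvergenceError(
                            f"no convergence at c={params.c_kpa} kPa, m={params.m}, "
                            f"delta={delta:.3f} mm ({exc})"
                        ) from exc
                    continue
                u, active = u_new, act_new
                n_newton += its
                delta_prev = delta
                dd = min(dd * 1.5, dd_max)
                reaction = self.contact_reaction(f_int, active)
                hist_d.append(delta)
                hist_f.append(reaction)
                hist_e.append(self.elastic_energy(u, params))
            if any(abs(delta_prev - s) < 1e-9 for s in snapshots):
                top = self.top_nodes
                snaps[float(delta_prev)] = {
                    "r": mesh.nodes[top, 0].copy(),
                    "ur": u.reshape(-1, 2)[top, 0].copy(),
                    "uz": u.reshape(-1, 2)[top, 1].copy(),
                    "reaction": hist_f[-1],
                    "active": active.copy(),
                    "state": u.copy(),
                }

        jmin, jmax = self.volume_ratio_range(u)
        # residual penetration of the converged final state
        pos = mesh.nodes[self.top_nodes] + u.reshape(-1, 2)[self.top_nodes]
        g, _ = self._gap(pos, height + R_TIP - delta_prev)
        return IndentationSolution(
            params=params,
            mesh_spec=mesh.spec,
            delta_history=np.asarray(hist_d),
            reaction_history=np.asarray(hist_f),
            energy_history=np.asarray(hist_e),
            snapshots=snaps,
            diagnostics={
                "newton_iterations": n_newton,
                "max_penetration_mm": float(max(0.0, -g.min())),
                "J_range_final": (jmin, jmax),
                "final_state": u,
            },
        )


def interpolate_state(coarse_mesh: Mesh, u_coarse: np.ndarray, fine_mesh: Mesh) -> np.ndarray:
    """Transfer a displacement state between meshes of the same domain.

    Consistent FE interpolation: each target node is located in its source
    element (the structured mesh is axis-aligned, so lookup is a pair of
    ``searchsorted`` calls) and the quadratic Q8 field is evaluated there.
    This preserves the smooth strain field of the source solution — scattered
    linear interpolation would inject spurious volumetric strain that the
    near-incompressible material amplifies ~kappa-fold.
    """
    uc = np.asarray(u_coarse, dtype=float).reshape(-1, 2)
    rb, zb = coarse_mesh.r_breaks, coarse_mesh.z_breaks
    nr = len(rb) - 1
    pts = fine_mesh.nodes
    out = np.empty((fine_mesh.n_nodes, 2))
    ie = np.clip(np.searchsorted(rb, pts[:, 0], side="right") - 1, 0, nr - 1)
    je = np.clip(np.searchsorted(zb, pts[:, 1], side="right") - 1, 0, len(zb) - 2)
    xi = 2.0 * (pts[:, 0] - rb[ie]) / (rb[ie + 1] - rb[ie]) - 1.0
    eta = 2.0 * (pts[:, 1] - zb[je]) / (zb[je + 1] - zb[je]) - 1.0
    elems = je * nr + ie
    ue = uc[coarse_mesh.conn[elems]]  # (n_fine, 8, 2)
    for k, (x, e) in enumerate(zip(xi, eta)):
        N, _ = _shape_q8(float(x), float(e))
        out[k] = N @ ue[k]
    # honor the hard boundary conditions of the fine mesh
    out[fine_mesh.node_sets["axis"], 0] = 0.0
    out[fine_mesh.node_sets["bottom"], :] = 0.0
    return out.ravel()


def continue_in_m(
    model: FEModel,
    delta: float,
    m_start: float,
    state: np.ndarray,
    m_target: float,
    c_kpa: float = 1.0,
    dm0: float = 2.0,
    dm_max: float = 10.0,
    dm_min: float = 0.05,
):
    """Continuation in the Ogden exponent at a fixed indentation depth.

    Walks ``m`` from ``m_start`` to ``m_target`` by adaptive warm
    re-equilibration steps (halved on failure, regrown on success) and
    returns the snapshot dict at ``m_target``.  Because the displacement
    field is independent of ``c``, one chain serves the whole ``c`` axis.
    """
    m = float(m_start)
    sign = 1.0 if m_target >= m else -1.0
    dm = min(dm0, abs(m_target - m)) * sign
    snap = None
    while abs(m - m_target) > 1e-12:
        trial = m + dm
        if (m_target - trial) * sign < 0:
            trial = m_target
        try:
            snap = model.equilibrate(OgdenParams(c_kpa, trial), delta, state)
        except NonConvergenceError:
            dm *= 0.5
            if abs(dm) < dm_min:
                raise
            continue
        m, state = trial, snap["state"]
        dm = sign * min(abs(dm) * 1.5, dm_max)
    if snap is None:  # m_target == m_start: one equilibration
        snap = model.equilibrate(OgdenParams(c_kpa, m_target), delta, state)
    return snap


def solve_indentation(
    mesh: Mesh | MeshSpec,
    params: OgdenParams,
    delta_max: float,
    n_steps: int = 24,
    snapshots=None,
    **kwargs,
) -> IndentationSolution:
    """Solve rigid frictionless hemispherical indentation to ``delta_max`` mm.

    ``snapshots`` lists depths at which the reaction and the top-surface
    displacement profile are recorded exactly (they are merged into the load
    step grid).  See :meth:`FEModel.solve` for solver controls.
    """
    if snapshots is None:
        snapshots = [delta_max]
    return FEModel(mesh).solve(
        params, delta_max, n_steps=n_steps, snapshots=snapshots, **kwargs
    )


def surface_profile(solution: IndentationSolution, delta: float):
    """Top-surface ``(initial radius, vertical displacement)`` at a snapshot."""
    snap = solution.snapshot(delta)
    return snap["r"], snap["uz"]


def hertz_force(params: OgdenParams, delta: float, r_tip: float = R_TIP) -> float:
    """Hertzian small-strain contact force ``F = 4/3 E* sqrt(R) delta^1.5`` (N)."""
    e_star = small_strain_moduli(params)["E_star"]  # MPa
    return 4.0 / 3.0 * e_star * np.sqrt(r_tip) * delta**1.5
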
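"""Quasi-static finite-element solver for cardiomyocyte contraction.

Discretizes the total-Lagrangian weak form

    int_O (S_eff(u) + K (J-1) J C^-1) : d_eps(v) dV
        + int_G0 alpha u . v dG = 0   for all v,

with S_eff = S_pas + S_act, on linear (P1) triangles.  For P1 elements all
volume integrands are element-wise constant, so one-point quadrature is
exact; the Robin surface term uses the consistent edge mass matrix.  The
model has no rate terms, so a beat is a sequence of independent
equilibria at the activation values A(t, x), warm-started in time.

Element residuals are evaluated in vectorized numpy (complex-capable), and
the Newton tangent is the exact Jacobian obtained by complex-step
differentiation of the element residual (machine-precision, includes the
active-tension strain dependence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .activation import ActivationModel, ActiveTensionParameters, activation_on_elements
from .geometry import CellMesh
from .materials import DEFAULT_POISSON, C01_RATIO

_CS_H = 1e-30  # complex-step size


class SolverError(RuntimeError):
    pass


@dataclass
class BoundaryConditionSpec:
    """Robin coefficient (kPa/um) and Dirichlet anchor nodes."""

    alpha: float = 1e-2
    anchor_nodes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        self.anchor_nodes = np.asarray(self.anchor_nodes, dtype=int)


@dataclass
class SolverSettings:
    """Newton and time-stepping controls."""

    dt: float = 3.2e-3          # s
    t_end: float = 1.0          # s (one beat at 1 Hz pacing)
    newton_rtol: float = 1e-8
    newton_atol: float = 1e-10
    max_newton_iter: int = 25
    max_substep_levels: int = 8
    embedding: str = "c33"      # "c33" | "isochoric"

    def time_grid(self) -> np.ndarray:
        n = int(round(self.t_end / self.dt))
        return np.linspace(0.0, self.t_end, n + 1)


@dataclass
class StrainProfile:
    """Engineering strain (lambda - 1) vs line-scan position at one time."""

    positions: np.ndarray
    strain: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float)
        self.strain = np.asarray(self.strain, float)
        if self.positions.shape != self.strain.shape:
            raise ValueError("positions and strain must be congruent")


@dataclass
class SimulationResult:
    """Observables of a simulated beat."""

    times: np.ndarray
    linescan: np.ndarray
    profiles: np.ndarray          # (nt, n_line) engineering strain
    mean_strain: np.ndarray       # (nt,)
    shortening: np.ndarray        # (nt,) % of initial length
    J_minmax: np.ndarray          # (nt, 2)
    displacements: np.ndarray | None = None   # (nt, n_nodes, 2)

    @property
    def i_max_contraction(self) -> int:
        return int(np.argmin(self.mean_strain))

    @property
    def t_max_contraction(self) -> float:
        return float(self.times[self.i_max_contraction])

    def profile_at(self, i: int) -> StrainProfile:
        return StrainProfile(self.linescan, self.profiles[i])

    @property
    def max_contraction_profile(self) -> StrainProfile:
        return self.profile_at(self.i_max_contraction)

    @property
    def peak_shortening(self) -> float:
        return float(self.shortening.max())


# ---------------------------------------------------------------------------
# Static problem: precomputation + residual/tangent + Newton
# ---------------------------------------------------------------------------

class StaticProblem:
    """Precomputed equilibrium problem on a fixed mesh.

    Material heterogeneity enters as a per-element Young's modulus array
    (converted internally to Mooney-Rivlin constants at fixed nu), the
    activation as a per-element array A >= 0.
    """

    def __init__(self, mesh: CellMesh, bc: BoundaryConditionSpec,
                 act_params: ActiveTensionParameters | None = None,
                 settings: SolverSettings | None = None,
                 nu: float = DEFAULT_POISSON):
        mesh.validate()
        if len(bc.anchor_nodes) == 0 and len(mesh.anchor_nodes) > 0:
            bc = BoundaryConditionSpec(alpha=bc.alpha,
                                       anchor_nodes=mesh.anchor_nodes)
        if len(bc.anchor_nodes) == 0:
            raise SolverError("anchor_nodes must be non-empty (the problem "
                              "is otherwise only Robin-constrained)")
        self.mesh = mesh
        self.bc = bc
        self.act = act_params or ActiveTensionParameters()
        self.settings = settings or SolverSettings()
        self.nu = nu

        nodes, tris = mesh.nodes, mesh.triangles
        self.ne = len(tris)
        self.nn = len(nodes)
        p = nodes[tris]                     # (ne, 3, 2)
        v1 = p[:, 1] - p[:, 0]
        v2 = p[:, 2] - p[:, 0]
        det = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
        self.area = 0.5 * det
        # gradients of P1 shape functions (ne, 3, 2)
        g = np.empty((self.ne, 3, 2))
        g[:, 1, 0] = v2[:, 1] / det
        g[:, 1, 1] = -v2[:, 0] / det
        g[:, 2, 0] = -v1[:, 1] / det
        g[:, 2, 1] = v1[:, 0] / det
        g[:, 0] = -g[:, 1] - g[:, 2]
        self.gradN = g
        self.d = mesh.fiber_direction       # (ne, 2)

        # dof bookkeeping
        dofs = np.empty((self.ne, 6), dtype=int)
        for i in range(3):
            dofs[:, 2 * i] = 2 * tris[:, i]
            dofs[:, 2 * i + 1] = 2 * tris[:, i] + 1
        self.elem_dofs = dofs
        fixed = np.zeros(2 * self.nn, dtype=bool)
        fixed[2 * bc.anchor_nodes] = True
        fixed[2 * bc.anchor_nodes + 1] = True
        self.free = ~fixed
        self.free_idx = np.nonzero(self.free)[0]
        self._glob2free = -np.ones(2 * self.nn, dtype=int)
        self._glob2free[self.free_idx] = np.arange(len(self.free_idx))

        self.M_robin = self._robin_matrix()
        self._K_pattern = None
        self._transfer = {}

        # material constant factors per unit E (nu fixed)
        mu_perE = 1.0 / (2.0 * (1.0 + nu))
        self.c10_perE = mu_perE / (2.0 * (1.0 + C01_RATIO))
        self.c01_perE = self.c10_perE * C01_RATIO
        self.K_perE = 1.0 / (3.0 * (1.0 - 2.0 * nu))

    # -- matrices ----------------------------------------------------------

    def _robin_matrix(self) -> sp.csr_matrix:
        """Consistent boundary mass matrix of the Robin term (unit alpha)."""
        e = self.mesh.boundary_edges
        L = np.linalg.norm(self.mesh.nodes[e[:, 0]] - self.mesh.nodes[e[:, 1]], axis=1)
        rows, cols, vals = [], [], []
        for (w_aa, w_ab) in [(2.0 / 6.0, 1.0 / 6.0)]:
            for comp in (0, 1):
                a = 2 * e[:, 0] + comp
                b = 2 * e[:, 1] + comp
                rows += [a, b, a, b]
                cols += [a, b, b, a]
                vals += [w_aa * L, w_aa * L, w_ab * L, w_ab * L]
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        return sp.csr_matrix((vals, (rows, cols)), shape=(2 * self.nn, 2 * self.nn))

    # -- element mechanics (vectorized, complex-capable) --------------------

    def _element_forces(self, u_elem, E, A, fmax, split=False):
        """Internal nodal forces per element.

        u_elem : (ne, 3, 2) displacements (real or complex)
        E, A   : per-element Young's modulus (kPa) and activation
        Returns (ne, 3, 2) forces, or (passive+volumetric, active) if split.
        """
        g = self.gradN
        F = np.repeat(np.eye(2)[None, :, :], self.ne, axis=0).astype(u_elem.dtype)
        F = F + np.einsum("eia,eib->eab", u_elem, g)
        C = np.einsum("eab,eac->ebc", F, F)       # F^T F
        c00, c01, c11 = C[:, 0, 0], C[:, 0, 1], C[:, 1, 1]
        detC = c00 * c11 - c01 * c01
        Cinv = np.empty_like(C)
        Cinv[:, 0, 0] = c11 / detC
        Cinv[:, 1, 1] = c00 / detC
        Cinv[:, 0, 1] = -c01 / detC
        Cinv[:, 1, 0] = -c01 / detC

        emb = self.settings.embedding
        if emb == "c33":
            J = np.sqrt(detC)
            C33 = np.ones_like(detC)
        elif emb == "isochoric":
            J = np.ones_like(detC)
            C33 = 1.0 / detC
        else:
            raise SolverError(f"unknown embedding {emb!r}")
        Jm23 = J ** (-2.0 / 3.0)
        tr3 = c00 + c11 + C33
        trC2_3 = c00 ** 2 + 2.0 * c01 ** 2 + c11 ** 2 + C33 ** 2

        C10 = self.c10_perE * E
        C01 = self.c01_perE * E
        K = self.K_perE * E

        I2 = np.eye(2)[None, :, :]
        S = (2.0 * C10 * Jm23)[:, None, None] * (I2 - (tr3 / 3.0)[:, None, None] * Cinv)
        S = S + (2.0 * C01 * Jm23 ** 2)[:, None, None] * (
            tr3[:, None, None] * I2 - C
            - ((tr3 ** 2 - trC2_3) / 3.0)[:, None, None] * Cinv
        )
        S_vol = (K * (J - 1.0) * J)[:, None, None] * Cinv
        S_pv = S + S_vol

        d = self.d
        dCd = np.einsum("ea,eab,eb->e", d, C, d)
        eps_f = 0.5 * (Jm23 * dCd - 1.0)
        T_act = A * fmax * np.exp(-(((eps_f - self.act.eps_opt) / self.act.s) ** 2))
        S_act = T_act[:, None, None] * np.einsum("ea,eb->eab", d, d)

        def forces(S_):
            P = np.einsum("eab,ebc->eac", F, S_)
            return self.area[:, None, None] * np.einsum("eac,eic->eia", P, g)

        if split:
            return forces(S_pv), forces(S_act)
        return forces(S_pv + S_act)

    def _gather(self, u_flat):
        return u_flat.reshape(self.nn, 2)[self.mesh.triangles]

    def residual(self, u_flat, E, A, fmax, alpha, split=False):
        """Global residual vector (length 2*nn); Dirichlet rows not zeroed."""
        fe = self._element_forces(self._gather(u_flat), E, A, fmax, split=split)
        if split:
            r_pv = np.zeros(2 * self.nn, dtype=fe[0].dtype)
            r_act = np.zeros_like(r_pv)
            np.add.at(r_pv, self.elem_dofs, fe[0].reshape(self.ne, 6))
            np.add.at(r_act, self.elem_dofs, fe[1].reshape(self.ne, 6))
            return r_pv + alpha * (self.M_robin @ u_flat), r_act
        r = np.zeros(2 * self.nn, dtype=fe.dtype)
        np.add.at(r, self.elem_dofs, fe.reshape(self.ne, 6))
        return r + alpha * (self.M_robin @ u_flat)

    def tangent(self, u_flat, E, A, fmax, alpha) -> sp.csc_matrix:
        """Exact Jacobian dR/du by complex-step on element residuals."""
        ue = self._gather(u_flat).astype(complex)
        Ke = np.empty((self.ne, 6, 6))
        for j in range(6):
            i, a = divmod(j, 2)
            ue[:, i, a] += 1j * _CS_H
            fe = self._element_forces(ue, E, A, fmax)
            ue[:, i, a] -= 1j * _CS_H
            Ke[:, :, j] = fe.imag.reshape(self.ne, 6) / _CS_H
        rows = np.repeat(self.elem_dofs, 6, axis=1).ravel()
        cols = np.tile(self.elem_dofs, (1, 6)).ravel()
        K = sp.csr_matrix((Ke.ravel(), (rows, cols)),
                          shape=(2 * self.nn, 2 * self.nn))
        K = K + alpha * self.M_robin
        return K

    # -- Newton ------------------------------------------------------------

    def _newton(self, u, E, A, fmax, alpha, lu0=None, exact_lu=True):
        """Newton with optional Jacobian reuse (chord iterations).

        ``lu0`` seeds the iteration with a previously factored tangent;
        it is refreshed whenever a chord step stalls.  With ``exact_lu``
        the returned factor is re-assembled at the converged state (needed
        when the factor feeds an adjoint solve)."""
        free = self.free
        settings = self.settings
        lu = lu0
        fresh = False           # lu assembled at the current iterate
        for it in range(settings.max_newton_iter):
            r_pv, r_act = self.residual(u, E, A, fmax, alpha, split=True)
            r = (r_pv + r_act)[free]
            f_ref = max(np.linalg.norm(r_act[free]), np.linalg.norm(r_pv[free]))
            rnorm = np.linalg.norm(r)
            if not np.isfinite(rnorm):
                return None, None, it
            if rnorm <= settings.newton_rtol * f_ref + settings.newton_atol:
                if exact_lu:
                    K = self.tangent(u, E, A, fmax, alpha)
                    lu = splu(K[free][:, free].tocsc())
                return u, lu, it
            if lu is None:
                K = self.tangent(u, E, A, fmax, alpha)
                lu = splu(K[free][:, free].tocsc())
                fresh = True
            du = lu.solve(-r)
            # damped update if the full step grows the residual badly
            step = 1.0
            accepted = False
            for _ in range(6):
                u_try = u.copy()
                u_try[free] += step * du
                r_try = self.residual(u_try, E, A, fmax, alpha)[free]
                rt = np.linalg.norm(r_try)
                if np.isfinite(rt) and (rt < rnorm or (fresh and step < 0.2)):
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                if fresh:
                    return None, None, it
                lu = None       # stale factor stalled: rebuild and retry
                continue
            if not fresh and rt > 0.2 * rnorm:
                lu = None       # slow chord convergence: rebuild next pass
            u = u_try
            fresh = False
        # check final state
        r = self.residual(u, E, A, fmax, alpha)[free]
        if np.isfinite(np.linalg.norm(r)):
            r_pv, r_act = self.residual(u, E, A, fmax, alpha, split=True)
            f_ref = max(np.linalg.norm(r_act[free]), np.linalg.norm(r_pv[free]))
            if np.linalg.norm(r) <= 10 * (self.settings.newton_rtol * f_ref
                                          + self.settings.newton_atol):
                if exact_lu:
                    K = self.tangent(u, E, A, fmax, alpha)
                    lu = splu(K[free][:, free].tocsc())
                return u, lu, settings.max_newton_iter
        return None, None, settings.max_newton_iter

    def solve(self, E_elem, A_elem, fmax: float | None = None,
              alpha: float | None = None, u0: np.ndarray | None = None,
              lu0=None, exact_lu: bool = True):
        """Solve one equilibrium; returns (u_flat, lu_factor).

        ``lu0`` warm-starts the Newton iteration with a previously factored
        tangent; with ``exact_lu=False`` the returned factor may be stale
        (cheaper, fine when no adjoint solve follows).  On Newton failure
        the activation increment is halved recursively (load substepping)
        up to ``max_substep_levels`` before raising.
        """
        E = np.broadcast_to(np.asarray(E_elem, float), (self.ne,))
        A_target = np.broadcast_to(np.asarray(A_elem, float), (self.ne,)).copy()
        fmax = self.act.f_max if fmax is None else float(fmax)
        alpha = self.bc.alpha if alpha is None else float(alpha)
        u = np.zeros(2 * self.nn) if u0 is None else np.asarray(u0, float).ravel().copy()
        u[~self.free] = 0.0

        u_sol, lu, _ = self._newton(u, E, A_target, fmax, alpha,
                                    lu0=lu0, exact_lu=exact_lu)
        if u_sol is not None:
            return u_sol, lu
        # substepping from zero activation
        frac_done = 0.0
        u = np.zeros(2 * self.nn)
        step = 0.5
        level = 0
        lu = None
        while frac_done < 1.0 - 1e-12:
            frac = min(1.0, frac_done + step)
            last = frac >= 1.0 - 1e-12
            u_try, lu_try, _ = self._newton(u.copy(), E, frac * A_target,
                                            fmax, alpha,
                                            exact_lu=exact_lu and last)
            if u_try is None:
                step *= 0.5
                level += 1
                if level > self.settings.max_substep_levels:
                    raise SolverError(
                        f"Newton diverged at activation fraction {frac:.4f} "
                        f"after {level} substepping levels "
                        f"(max |A| = {np.abs(A_target).max():.4g})")
            else:
                u, lu = u_try, lu_try
                frac_done = frac
                step = min(2 * step, 1.0 - frac_done) if frac_done < 1 else step
        return u, lu

    # -- observables ---------------------------------------------------------

    def deformation_gradients(self, u_flat):
        ue = self._gather(u_flat)
        F = np.repeat(np.eye(2)[None, :, :], self.ne, axis=0)
        return F + np.einsum("eia,eib->eab", ue, self.gradN)

    def element_J(self, u_flat):
        F = self.deformation_gradients(u_flat)
        detF = F[:, 0, 0] * F[:, 1, 1] - F[:, 0, 1] * F[:, 1, 0]
        if self.settings.embedding == "c33":
            return detF
        return np.ones_like(detF)

    def element_fiber_green_strain(self, u_flat, modified: bool = True):
        """Green strain along the fiber per element.

        ``modified=True`` uses Cbar (drives the tension law);
        ``modified=False`` uses the unmodified C (comparable to measured
        sarcomere strain)."""
        F = self.deformation_gradients(u_flat)
        Fd = np.einsum("eab,eb->ea", F, self.d)
        dCd = np.einsum("ea,ea->e", Fd, Fd)
        if not modified:
            return 0.5 * (dCd - 1.0)
        if self.settings.embedding == "c33":
            detF = F[:, 0, 0] * F[:, 1, 1] - F[:, 0, 1] * F[:, 1, 0]
            return 0.5 * (detF ** (-2.0 / 3.0) * dCd - 1.0)
        return 0.5 * (dCd - 1.0)

    def element_engineering_strain(self, u_flat):
        """lambda - 1 along the fiber (sarcomere-length-based strain)."""
        F = self.deformation_gradients(u_flat)
        Fd = np.einsum("eab,eb->ea", F, self.d)
        return np.sqrt(np.einsum("ea,ea->e", Fd, Fd)) - 1.0

    def linescan_transfer(self, positions) -> sp.csr_matrix:
        """Sparse matrix mapping element fields to line-scan samples.

        Element values are area-averaged to nodes, then barycentrically
        interpolated at the sample points (piecewise-linear recovery)."""
        key = (len(positions), float(positions[0]), float(positions[-1]))
        if key in self._transfer:
            return self._transfer[key]
        mesh = self.mesh
        # node averaging N (nn x ne)
        rows = mesh.triangles.ravel()
        cols = np.repeat(np.arange(self.ne), 3)
        w = np.repeat(self.area, 3)
        N = sp.csr_matrix((w, (rows, cols)), shape=(self.nn, self.ne))
        wsum = np.asarray(N.sum(axis=1)).ravel()
        N = sp.diags(1.0 / wsum) @ N

        # sample points on the longitudinal mid-axis
        perp = np.array([-mesh.long_axis[1], mesh.long_axis[0]])
        c_perp = float(np.mean(mesh.nodes @ perp))
        pts = (np.asarray(positions)[:, None] * mesh.long_axis[None, :]
               + c_perp * perp[None, :])
        tri_idx, bary = self._locate(pts)
        rows = np.repeat(np.arange(len(pts)), 3)
        cols = mesh.triangles[tri_idx].ravel()
        P = sp.csr_matrix((bary.ravel(), (rows, cols)),
                          shape=(len(pts), self.nn))
        T = (P @ N).tocsr()
        self._transfer[key] = T
        return T

    def _locate(self, pts):
        """Containing triangle + barycentric coordinates for each point."""
        from matplotlib.tri import Triangulation
        mesh = self.mesh
        mtri = Triangulation(mesh.nodes[:, 0], mesh.nodes[:, 1], mesh.triangles)
        finder = mtri.get_trifinder()
        idx = finder(pts[:, 0], pts[:, 1])
        missing = idx < 0
        if np.any(missing):
            cent = mesh.element_centroids()
            from scipy.spatial import cKDTree
            _, near = cKDTree(cent).query(pts[missing])
            idx[missing] = near
        p = mesh.nodes[mesh.triangles[idx]]
        v0 = p[:, 1] - p[:, 0]
        v1 = p[:, 2] - p[:, 0]
        v2 = pts - p[:, 0]
        den = v0[:, 0] * v1[:, 1] - v1[:, 0] * v0[:, 1]
        l1 = (v2[:, 0] * v1[:, 1] - v1[:, 0] * v2[:, 1]) / den
        l2 = (v0[:, 0] * v2[:, 1] - v2[:, 0] * v0[:, 1]) / den
        l1 = np.clip(l1, 0.0, 1.0)
        l2 = np.clip(l2, 0.0, 1.0)
        l0 = np.clip(1.0 - l1 - l2, 0.0, 1.0)
        bary = np.column_stack([l0, l1, l2])
        bary /= bary.sum(axis=1, keepdims=True)
        return idx, bary

    def strain_profile(self, u_flat, positions) -> StrainProfile:
        T = self.linescan_transfer(positions)
        e_el = self.element_engineering_strain(u_flat)
        return StrainProfile(np.asarray(positions, float), T @ e_el)

    def total_potential(self, u_flat, E_elem, A_elem, fmax=None, alpha=None):
        """Approximate potential: passive energy + Robin energy + active
        pseudo-potential (Gaussian tension integrated over fiber strain)."""
        from scipy.special import erf
        fmax = self.act.f_max if fmax is None else fmax
        alpha = self.bc.alpha if alpha is None else alpha
        E = np.broadcast_to(np.asarray(E_elem, float), (self.ne,))
        A = np.broadcast_to(np.asarray(A_elem, float), (self.ne,))
        ue = self._gather(u_flat)
        # passive + volumetric energy densities
        F = self.deformation_gradients(u_flat)
        C = np.einsum("eab,eac->ebc", F, F)
        detC = C[:, 0, 0] * C[:, 1, 1] - C[:, 0, 1] ** 2
        if self.settings.embedding == "c33":
            J = np.sqrt(detC)
            C33 = np.ones_like(detC)
        else:
            J = np.ones_like(detC)
            C33 = 1.0 / detC
        Jm23 = J ** (-2.0 / 3.0)
        tr3 = C[:, 0, 0] + C[:, 1, 1] + C33
        trC2 = (C[:, 0, 0] ** 2 + 2 * C[:, 0, 1] ** 2 + C[:, 1, 1] ** 2 + C33 ** 2)
        I1b = Jm23 * tr3
        I2b = 0.5 * Jm23 ** 2 * (tr3 ** 2 - trC2)
        W = (self.c10_perE * E * (I1b - 3.0) + self.c01_perE * E * (I2b - 3.0)
             + 0.5 * self.K_perE * E * (J - 1.0) ** 2)
        eps = self.element_fiber_green_strain(u_flat, modified=False)
        s_, eo = self.act.s, self.act.eps_opt
        psi_act = A * fmax * s_ * np.sqrt(np.pi) / 2.0 * (
            erf((eps - eo) / s_) - erf((0.0 - eo) / s_))
        robin = 0.5 * alpha * float(u_flat @ (self.M_robin @ u_flat))
        return float(np.sum(self.area * (W + psi_act))) + robin


# ---------------------------------------------------------------------------
# Functional interface
# ---------------------------------------------------------------------------

def solve_equilibrium(mesh: CellMesh, E_elem, A_elem,
                      bc: BoundaryConditionSpec,
                      settings: SolverSettings | None = None,
                      act_params: ActiveTensionParameters | None = None,
                      u0=None) -> np.ndarray:
    """One quasi-static equilibrium; returns nodal displacements (nn, 2)."""
    prob = StaticProblem(mesh, bc, act_params, settings)
    u, _ = prob.solve(E_elem, A_elem, u0=u0)
    return u.reshape(-1, 2)


def simulate_beat(mesh: CellMesh, E_elem, model: ActivationModel,
                  bc: BoundaryConditionSpec,
                  settings: SolverSettings | None = None,
                  act_params: ActiveTensionParameters | None = None,
                  linescan=None, store_displacements: bool = False,
                  problem: StaticProblem | None = None) -> SimulationResult:
    """Simulate one beat as a sequence of warm-started equilibria."""
    prob = problem or StaticProblem(mesh, bc, act_params, settings)
    settings = prob.settings
    times = settings.time_grid()
    positions = np.asarray(linescan if linescan is not None else mesh.linescan, float)
    if len(positions) == 0:
        raise SolverError("no line-scan positions available")
    cent_x = mesh.element_centroids() @ mesh.long_axis
    T = prob.linescan_transfer(positions)

    E = np.broadcast_to(np.asarray(E_elem, float), (prob.ne,))
    x_node = mesh.nodes @ mesh.long_axis
    L0 = x_node.max() - x_node.min()

    nt = len(times)
    profiles = np.empty((nt, len(positions)))
    mean_strain = np.empty(nt)
    shortening = np.empty(nt)
    J_minmax = np.empty((nt, 2))
    disp = np.empty((nt, prob.nn, 2)) if store_displacements else None

    u = np.zeros(2 * prob.nn)
    lu = None
    for k, t in enumerate(times):
        A = activation_on_elements(model, float(t), cent_x)
        u, lu = prob.solve(E, A, u0=u, lu0=lu, exact_lu=False)
        e_el = prob.element_engineering_strain(u)
        profiles[k] = T @ e_el
        mean_strain[k] = profiles[k].mean()
        xdef = (mesh.nodes + u.reshape(-1, 2)) @ mesh.long_axis
        shortening[k] = 100.0 * (L0 - (xdef.max() - xdef.min())) / L0
        J = prob.element_J(u)
        J_minmax[k] = (J.min(), J.max())
        if store_displacements:
            disp[k] = u.reshape(-1, 2)

    return SimulationResult(times=times, linescan=positions, profiles=profiles,
                            mean_strain=mean_strain, shortening=shortening,
                            J_minmax=J_minmax, displacements=disp)


def fiber_green_strain(C2d, d, J=None, modified: bool = True) -> float:
    """Green strain along a unit fiber d from an in-plane C (2x2).

    With ``modified=True`` the modified tensor Cbar = J^(-2/3) C is used
    (J = sqrt(det C) under the default embedding if not given)."""
    C2d = np.asarray(C2d, float)
    d = np.asarray(d, float)
    if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-9):
        raise ValueError("fiber direction must be a unit vector")
    dCd = float(d @ C2d @ d)
    if modified:
        if J is None:
            J = np.sqrt(np.linalg.det(C2d))
        dCd = J ** (-2.0 / 3.0) * dCd
    return 0.5 * (dCd - 1.0)


def linescan_strain_profile(result: SimulationResult, t: float) -> StrainProfile:
    """Strain profile at the grid time closest to ``t``."""
    i = int(np.argmin(np.abs(result.times - t)))
    if not np.isclose(result.times[i], t, atol=1e-9):
        raise ValueError(f"t={t} is not on the simulation time grid")
    return result.profile_at(i)


# ---------------------------------------------------------------------------
# Contractile observables
# ---------------------------------------------------------------------------

def contractile_observables(result_or_times, mean_strain=None):
    """(eps_l_max, tau_sl, max strain rate) from a mean-strain trace.

    eps_l_max is the most negative mean line-scan strain; the strain rate
    is by central differences; tau_sl is the monoexponential time constant
    eps(t) = eps_inf + a * exp(-(t - t_min)/tau) fitted over the whole
    re-lengthening phase (from the minimum to the end of the beat), the
    standard relaxation-time estimate for sarcomere re-lengthening traces.
    tau_sl is None when the trace does not recover (fewer than four samples
    after the minimum, or less than half of the contraction recovered).
    """
    if mean_strain is None:
        times, eps = result_or_times.times, result_or_times.mean_strain
    else:
        times = np.asarray(result_or_times, float)
        eps = np.asarray(mean_strain, float)
    i_min = int(np.argmin(eps))
    eps_max = float(eps[i_min])
    rate = np.gradient(eps, times)
    rate_max = float(np.max(np.abs(rate)))

    tau = None
    recovered = eps[-1] - eps_max
    if eps_max < 0 and len(eps) - i_min >= 4 and recovered > 0.5 * (-eps_max):
        tseg = times[i_min:] - times[i_min]
        yseg = eps[i_min:]
        span = max(tseg[-1], 1e-6)
        from scipy.optimize import least_squares

        def residual(p):
            a, e_inf, log_tau = p
            return e_inf + a * np.exp(-tseg / np.exp(log_tau)) - yseg

        res = least_squares(
            residual, x0=[eps_max - eps[-1], eps[-1], np.log(0.3 * span)],
            bounds=([-np.inf, -np.inf, np.log(span * 1e-3)],
                    [np.inf, np.inf, np.log(span * 1e2)]))
        if res.success:
            tau = float(np.exp(res.x[2]))
    return eps_max, tau, rate_max
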
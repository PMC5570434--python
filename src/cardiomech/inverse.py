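"""Inverse estimation of the local Young's modulus from a strain profile.

The estimator minimizes the RMSE between the simulated and measured
longitudinal strain profiles at the maximum-contraction time frame, over
log E (positivity and the log-linear parameterization come for free), in
two steps:

1. coarse: ~20 regions, log E piecewise-linear between region boundaries,
   bound-constrained quasi-Newton (L-BFGS-B) with multistart from
   log-uniform random initial fields;
2. fine: ~200 segments with piecewise-constant E, initialized from the
   coarse field evaluated at segment midpoints, optionally estimating
   f_max and the Robin coefficient alpha jointly.

Because the quasi-static model is history-free, the objective needs a
single equilibrium solve at the activation field of the measured time
frame.  Gradients are exact adjoints: every residual term is linear in
its parameter (passive + volumetric stress in the element's E, active
stress in f_max, the Robin term in alpha), so dR/d(theta) costs one
element-residual evaluation and the adjoint one transposed backsolve with
the already-factorized Newton tangent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import pearsonr

from .fem import (BoundaryConditionSpec, SolverSettings, StaticProblem,
                  StrainProfile)
from .materials import ElasticityField
from .activation import ActiveTensionParameters


@dataclass
class InverseProblemConfig:
    coarse_regions: int = 20
    fine_segments: int = 200
    bounds: tuple = (0.1, 100.0)        # kPa
    stop_threshold: float = 1e-6        # on ||theta_n - theta_{n+1}||
    multistart: int = 5
    include_fmax: bool = False
    include_alpha: bool = False
    fmax_bounds: tuple = (20.0, 120.0)  # kPa
    alpha_bounds: tuple = (1e-4, 1.0)   # kPa/um
    seed: int = 0
    max_passes: int = 8
    lbfgs_maxiter: int = 60
    fine_step: bool = True
    # Curvature regularization of log E.  The strain->E map is badly
    # conditioned near working strains (the slope of the actin-myosin
    # overlap function nearly cancels the passive stiffness), so measurement
    # noise must not be fitted exactly.  "auto" picks the penalty weight by
    # the discrepancy principle: the largest weight whose data misfit stays
    # within ``discrepancy_eta`` times the noise level estimated from the
    # measured profile's second differences.  "none" disables it; a float
    # fixes the weight (strain^2 um^4 units).
    regularization: str | float = "auto"
    discrepancy_eta: float = 1.05
    # Candidate weights are factor * sigma_hat^2; zero is deliberately not a
    # candidate once noise is detected, so a noisy profile is never fitted
    # with an unregularized (noise-amplifying) objective.
    reg_factors: tuple = (3e5, 3e4, 3e3, 3e2)

    def __post_init__(self):
        if self.coarse_regions >= self.fine_segments:
            raise ValueError("coarse_regions must be < fine_segments")
        if self.bounds[0] <= 0 or self.bounds[1] <= self.bounds[0]:
            raise ValueError("bounds must be positive and increasing")
        if self.stop_threshold <= 0:
            raise ValueError("stop_threshold must be positive")


@dataclass
class InverseProblemResult:
    field: ElasticityField
    objective: float                     # final RMSE (strain units)
    fmax: float | None = None
    alpha: float | None = None
    restart_objectives: list = field(default_factory=list)
    selected_restart: int = 0
    coarse_field: ElasticityField | None = None
    coarse_objective: float | None = None


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def objective_rmse(simulated: StrainProfile, measured: StrainProfile) -> float:
    """RMSE between profiles after linear resampling onto measured positions."""
    ps, pm = simulated.positions, measured.positions
    if pm.min() < ps.min() - 1e-9 or pm.max() > ps.max() + 1e-9:
        overlap = (min(ps.max(), pm.max()) - max(ps.min(), pm.min()))
        if overlap <= 0:
            raise ValueError("profiles cover disjoint position ranges")
    sim = np.interp(pm, ps, simulated.strain)
    return float(np.sqrt(np.mean((sim - measured.strain) ** 2)))


def estimate_noise_sd(measured: StrainProfile) -> float:
    """RMS noise level of a strain profile from its second differences.

    For white noise Var(y[i-1] - 2 y[i] + y[i+1]) = 6 sigma^2, while the
    smooth strain signal contributes only O(h^2) curvature at the line-scan
    pixel spacing, so this is a nearly signal-free noise estimate.
    """
    y = np.asarray(measured.strain, float)
    if len(y) < 3:
        return 0.0
    d2 = y[:-2] - 2.0 * y[1:-1] + y[2:]
    return float(np.sqrt(np.mean(d2 ** 2) / 6.0))


def correlate_E_strain(field_values, profile_values):
    """Pearson correlation (and p-value) between local E and local strain."""
    a = np.asarray(field_values, float)
    b = np.asarray(profile_values, float)
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan"), float("nan")
    r, p = pearsonr(a, b)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

class _Engine:
    """Value-and-gradient of the half-MSE objective for one parameterization.

    theta = [log E at breakpoints] (+ log f_max) (+ log alpha).
    ``W`` maps breakpoint log-moduli to element log-moduli.
    """

    def __init__(self, prob: StaticProblem, A_elem, measured: StrainProfile,
                 W, include_fmax=False, include_alpha=False,
                 breakpoint_spacing: float = 1.0):
        self.prob = prob
        self.A = np.asarray(A_elem, float)
        self.y = measured.strain
        self.T = prob.linescan_transfer(measured.positions)
        self.W = W                      # (ne, n_bp)
        self.include_fmax = include_fmax
        self.include_alpha = include_alpha
        self.u_warm = None
        self.n_solves = 0
        self.weights = None             # optional per-point misfit weights
        # curvature penalty operator on log E (per um^2, spacing-invariant)
        n_bp = W.shape[1]
        h2 = breakpoint_spacing ** 2
        if n_bp >= 3:
            D2 = np.zeros((n_bp - 2, n_bp))
            idx = np.arange(n_bp - 2)
            D2[idx, idx] = 1.0 / h2
            D2[idx, idx + 1] = -2.0 / h2
            D2[idx, idx + 2] = 1.0 / h2
        else:
            D2 = np.zeros((0, n_bp))
        self.D2 = D2
        self.lam = 0.0                  # strain^2 um^4

    def split(self, theta):
        n_bp = self.W.shape[1]
        thE = theta[:n_bp]
        k = n_bp
        fmax = alpha = None
        if self.include_fmax:
            fmax = float(np.exp(theta[k])); k += 1
        if self.include_alpha:
            alpha = float(np.exp(theta[k])); k += 1
        return thE, fmax, alpha

    def value_and_grad(self, theta):
        prob = self.prob
        thE, fmax, alpha = self.split(np.asarray(theta, float))
        E = np.exp(self.W @ thE)
        fmax_v = prob.act.f_max if fmax is None else fmax
        alpha_v = prob.bc.alpha if alpha is None else alpha
        u, lu = prob.solve(E, self.A, fmax=fmax_v, alpha=alpha_v,
                           u0=self.u_warm)
        self.u_warm = u.copy()
        self.n_solves += 1

        # profile and misfit
        F = prob.deformation_gradients(u)
        Fd = np.einsum("eab,eb->ea", F, prob.d)
        nFd = np.sqrt(np.einsum("ea,ea->e", Fd, Fd))
        e_el = nFd - 1.0
        p = self.T @ e_el
        r = p - self.y
        n = len(self.y)
        wr = r if self.weights is None else self.weights * r
        J_data = 0.5 * float(wr @ r) / n
        self.last_data_rmse = float(np.sqrt(np.mean(r ** 2)))
        self.last_weighted_rmse = float(np.sqrt(2.0 * J_data))
        J = J_data
        pen_grad = 0.0
        if self.lam > 0.0 and len(self.D2):
            c = self.D2 @ thE
            J = J + 0.5 * self.lam * float(c @ c) / len(c)
            pen_grad = self.lam * (self.D2.T @ c) / len(c)

        # dJ/du: scatter  w_e * d(e_el)/du  with  w = T^T (weights*r) / n
        w = (self.T.T @ wr) / n                          # (ne,)
        coef = (w / nFd)[:, None, None] * (
            np.einsum("eib,eb->ei", prob.gradN, prob.d)[:, :, None]
            * Fd[:, None, :])                            # (ne, 3, 2)
        g_u = np.zeros(2 * prob.nn)
        np.add.at(g_u, prob.elem_dofs, coef.reshape(prob.ne, 6))

        # adjoint solve  K_ff^T lambda = g_u|free
        lam = np.zeros(2 * prob.nn)
        lam[prob.free_idx] = lu.solve(g_u[prob.free_idx], trans="T")

        # dR/dtheta contractions
        f_pv, f_act = prob._element_forces(prob._gather(u), E, self.A,
                                           fmax_v, split=True)
        lam_e = lam[prob.elem_dofs]                      # (ne, 6)
        q_pv = np.einsum("ek,ek->e", f_pv.reshape(prob.ne, 6), lam_e)
        grad = [-(self.W.T @ q_pv) + pen_grad]
        if self.include_fmax:
            grad.append([-float(np.einsum("ek,ek->",
                                          f_act.reshape(prob.ne, 6), lam_e))])
        if self.include_alpha:
            r_rob = alpha_v * (prob.M_robin @ u)
            grad.append([-float(lam @ r_rob)])
        return J, np.concatenate(grad)

    def rmse(self, theta) -> float:
        """Data-misfit RMSE (excludes the regularization penalty)."""
        self.value_and_grad(theta)
        return self.last_data_rmse


def _loglinear_weights(x_elem, breakpoints):
    """(ne, n_bp) weights: log E_elem = W @ log E_breakpoints (clamped)."""
    bp = np.asarray(breakpoints, float)
    x = np.clip(np.asarray(x_elem, float), bp[0], bp[-1])
    idx = np.clip(np.searchsorted(bp, x) - 1, 0, len(bp) - 2)
    t = (x - bp[idx]) / (bp[idx + 1] - bp[idx])
    W = np.zeros((len(x), len(bp)))
    W[np.arange(len(x)), idx] = 1.0 - t
    W[np.arange(len(x)), idx + 1] = t
    return W


def _segment_weights(x_elem, midpoints):
    """(ne, n_seg) indicator weights: nearest segment midpoint."""
    mp = np.asarray(midpoints, float)
    edges = 0.5 * (mp[1:] + mp[:-1])
    idx = np.clip(np.searchsorted(edges, x_elem), 0, len(mp) - 1)
    W = np.zeros((len(x_elem), len(mp)))
    W[np.arange(len(x_elem)), idx] = 1.0
    return W


def _optimize(engine: _Engine, theta0, bounds, config: InverseProblemConfig):
    """L-BFGS-B passes with the iterate-change stopping rule."""
    theta = np.asarray(theta0, float).copy()
    for _ in range(config.max_passes):
        res = minimize(engine.value_and_grad, theta, jac=True,
                       method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": config.lbfgs_maxiter,
                                "ftol": 1e-14, "gtol": 1e-12})
        delta = float(np.linalg.norm(res.x - theta))
        theta = res.x
        if delta < config.stop_threshold or res.status == 0:
            break
    return theta, engine.rmse(theta)


def _reg_weights(config: InverseProblemConfig, measured: StrainProfile):
    """Descending penalty-weight candidates and the target data misfit."""
    if isinstance(config.regularization, (int, float)):
        return [float(config.regularization)], None
    if config.regularization == "none":
        return [0.0], None
    if config.regularization != "auto":
        raise ValueError(f"unknown regularization {config.regularization!r}")
    sigma = estimate_noise_sd(measured)
    if sigma <= 1e-9:
        return [0.0], None
    lams = sorted({sigma ** 2 * f for f in config.reg_factors}, reverse=True)
    return list(lams), config.discrepancy_eta * sigma


def _fit_regularized(engine: _Engine, theta0, bounds,
                     config: InverseProblemConfig, lams, target_rmse):
    """Descend the penalty weights, keeping the largest (smoothest) weight
    whose data misfit reaches the noise level (discrepancy principle)."""
    theta = np.asarray(theta0, float)
    best = None
    for lam in lams:
        engine.lam = lam
        theta, rmse = _optimize(engine, theta, bounds, config)
        best = (theta, rmse, lam)
        if target_rmse is None or rmse <= target_rmse:
            break
    return best


# ---------------------------------------------------------------------------
# Two-step estimation
# ---------------------------------------------------------------------------

def coarse_estimate(prob: StaticProblem, A_elem, measured: StrainProfile,
                    config: InverseProblemConfig):
    """Coarse step: multistart bound-constrained fit of ~20 log-linear
    breakpoint moduli.  Returns (ElasticityField, rmse, restart_rmses)."""
    x_el = prob.mesh.element_centroids() @ prob.mesh.long_axis
    bp = np.linspace(x_el.min(), x_el.max(), config.coarse_regions + 1)
    W = _loglinear_weights(x_el, bp)
    engine = _Engine(prob, A_elem, measured, W,
                     breakpoint_spacing=bp[1] - bp[0])
    lb, ub = np.log(config.bounds[0]), np.log(config.bounds[1])
    bounds = [(lb, ub)] * len(bp)
    rng = np.random.default_rng(config.seed)
    lams, target_rmse = _reg_weights(config, measured)

    # multistart at the heaviest (smoothest, most convex) penalty weight
    engine.lam = lams[0]
    best = None
    restart_rmses = []
    for k in range(config.multistart):
        theta0 = rng.uniform(lb, ub, size=len(bp))
        engine.u_warm = None
        theta, rmse = _optimize(engine, theta0, bounds, config)
        restart_rmses.append(rmse)
        if best is None or rmse < best[1]:
            best = (theta, rmse, k)
    theta, rmse, k_sel = best
    # descend the remaining weights from the selected basin
    if len(lams) > 1:
        theta, rmse, _ = _fit_regularized(engine, theta, bounds, config,
                                          lams, target_rmse)
    fld = ElasticityField(bp, np.exp(theta), mode="log-linear",
                          bounds=config.bounds)
    return fld, rmse, restart_rmses, k_sel


def fine_estimate(prob: StaticProblem, A_elem, measured: StrainProfile,
                  coarse_field: ElasticityField,
                  config: InverseProblemConfig,
                  coarse_rmse: float | None = None,
                  restart_rmses=None, selected_restart: int = 0
                  ) -> InverseProblemResult:
    """Fine step: per-segment E (piecewise-constant), seeded by the coarse
    field; optional joint estimation of f_max and alpha."""
    x_el = prob.mesh.element_centroids() @ prob.mesh.long_axis
    edges = np.linspace(x_el.min(), x_el.max(), config.fine_segments + 1)
    mid = 0.5 * (edges[1:] + edges[:-1])

    if not config.fine_step:
        vals = np.clip(coarse_field(mid), *config.bounds)
        fld = ElasticityField(mid, vals, mode="constant", bounds=config.bounds)
        return InverseProblemResult(
            field=fld, objective=coarse_rmse if coarse_rmse is not None
            else float("nan"),
            restart_objectives=list(restart_rmses or []),
            selected_restart=selected_restart,
            coarse_field=coarse_field, coarse_objective=coarse_rmse)

    W = _segment_weights(x_el, mid)
    engine = _Engine(prob, A_elem, measured, W,
                     include_fmax=config.include_fmax,
                     include_alpha=config.include_alpha,
                     breakpoint_spacing=mid[1] - mid[0])
    lb, ub = np.log(config.bounds[0]), np.log(config.bounds[1])
    theta0 = list(np.log(np.clip(coarse_field(mid), *config.bounds)))
    bounds = [(lb, ub)] * len(mid)
    if config.include_fmax:
        theta0.append(np.log(prob.act.f_max))
        bounds.append(tuple(np.log(config.fmax_bounds)))
    if config.include_alpha:
        theta0.append(np.log(prob.bc.alpha))
        bounds.append(tuple(np.log(config.alpha_bounds)))

    lams, target_rmse = _reg_weights(config, measured)
    theta, rmse, _ = _fit_regularized(engine, np.asarray(theta0), bounds,
                                      config, lams, target_rmse)
    thE, fmax, alpha = engine.split(theta)
    fld = ElasticityField(mid, np.exp(thE), mode="constant",
                          bounds=config.bounds)
    return InverseProblemResult(
        field=fld, objective=rmse, fmax=fmax, alpha=alpha,
        restart_objectives=list(restart_rmses or []),
        selected_restart=selected_restart,
        coarse_field=coarse_field, coarse_objective=coarse_rmse)


def estimate_elasticity(mesh, A_elem, measured: StrainProfile,
                        config: InverseProblemConfig | None = None,
                        bc: BoundaryConditionSpec | None = None,
                        settings: SolverSettings | None = None,
                        act_params: ActiveTensionParameters | None = None,
                        problem: StaticProblem | None = None
                        ) -> InverseProblemResult:
    """Full two-step inverse estimation on a mesh.

    ``A_elem`` is the per-element activation at the measured (maximum
    contraction) time frame; the quasi-static model needs no other time
    information.
    """
    config = config or InverseProblemConfig()
    prob = problem or StaticProblem(mesh, bc or BoundaryConditionSpec(),
                                    act_params, settings)
    coarse_field, c_rmse, restarts, k_sel = coarse_estimate(
        prob, A_elem, measured, config)
    return fine_estimate(prob, A_elem, measured, coarse_field, config,
                         coarse_rmse=c_rmse, restart_rmses=restarts,
                         selected_restart=k_sel)
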
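import numpy as np
import pytest

from cardiomech.activation import ActiveTensionParameters
from cardiomech.fem import (BoundaryConditionSpec, SolverSettings,
                            StaticProblem, StrainProfile,
                            contractile_observables, fiber_green_strain,
                            simulate_beat, solve_equilibrium)


@pytest.fixture(scope="module")
def problem(small_mesh):
    bc = BoundaryConditionSpec(anchor_nodes=small_mesh.anchor_nodes)
    return StaticProblem(small_mesh, bc, ActiveTensionParameters(),
                         SolverSettings(dt=8e-3, t_end=0.8))


def test_zero_activation_zero_displacement(problem):
    u, _ = problem.solve(36.0, np.zeros(problem.ne))
    assert np.allclose(u, 0.0, atol=1e-12)


def test_anchor_displacement_exactly_zero(problem, small_mesh):
    u, _ = problem.solve(36.0, 0.3 * np.ones(problem.ne))
    disp = u.reshape(-1, 2)[small_mesh.anchor_nodes]
    assert np.all(disp == 0.0)


def test_residual_vanishes_at_solution(problem):
    A = 0.25 * np.ones(problem.ne)
    u, _ = problem.solve(30.0, A)
    r = problem.residual(u, np.full(problem.ne, 30.0), A,
                         problem.act.f_max, problem.bc.alpha)
    assert np.linalg.norm(r[problem.free_idx]) < 1e-7


def test_tangent_matches_directional_fd(tiny_mesh, rng):
    bc = BoundaryConditionSpec(anchor_nodes=tiny_mesh.anchor_nodes)
    prob = StaticProblem(tiny_mesh, bc, ActiveTensionParameters(),
                         SolverSettings())
    E = np.full(prob.ne, 30.0)
    A = 0.2 * np.ones(prob.ne)
    u = 1e-2 * rng.standard_normal(2 * prob.nn)
    K = prob.tangent(u, E, A, prob.act.f_max, prob.bc.alpha).toarray()
    h = 1e-7
    for _ in range(4):
        v = rng.standard_normal(2 * prob.nn)
        rp = prob.residual(u + h * v, E, A, prob.act.f_max, prob.bc.alpha)
        rm = prob.residual(u - h * v, E, A, prob.act.f_max, prob.bc.alpha)
        fd = (rp - rm) / (2 * h)
        assert np.allclose(K @ v, fd, rtol=1e-5,
                           atol=1e-6 * np.linalg.norm(fd))


def test_contraction_shortens_cell(problem, small_mesh):
    u, _ = problem.solve(36.0, 0.3 * np.ones(problem.ne))
    prof = problem.strain_profile(u, small_mesh.linescan)
    assert prof.strain.mean() < -0.01          # net shortening
    J = problem.element_J(u)
    assert np.all(J > 0.8) and np.all(J < 1.2)  # near-incompressible


def test_stiffer_cell_contracts_less(problem, small_mesh):
    A = 0.3 * np.ones(problem.ne)
    means = []
    for E in (15.0, 36.0, 80.0):
        u, _ = problem.solve(E, A)
        means.append(problem.strain_profile(u, small_mesh.linescan).strain.mean())
    assert means[0] < means[1] < means[2] < 0.0


def test_chord_and_exact_newton_agree(problem):
    A = 0.3 * np.ones(problem.ne)
    u_exact, _ = problem.solve(36.0, A, exact_lu=True)
    u_chord, _ = problem.solve(36.0, A, exact_lu=False)
    assert np.allclose(u_exact, u_chord, atol=1e-8)


def test_linescan_transfer_partition_of_unity(problem, small_mesh):
    T = problem.linescan_transfer(small_mesh.linescan)
    assert np.allclose(np.asarray(T.sum(axis=1)).ravel(), 1.0)
    # constant elementwise field maps to the same constant on the line
    assert np.allclose(T @ np.full(problem.ne, 3.7), 3.7)


def test_solve_equilibrium_wrapper(small_mesh):
    bc = BoundaryConditionSpec(anchor_nodes=small_mesh.anchor_nodes)
    disp = solve_equilibrium(small_mesh, 36.0, np.zeros(small_mesh.n_elements),
                             bc)
    assert disp.shape == (small_mesh.n_nodes, 2)
    assert np.allclose(disp, 0.0)


def test_simulate_beat_shapes_and_peak(small_mesh, activation_model):
    bc = BoundaryConditionSpec(anchor_nodes=small_mesh.anchor_nodes)
    beat = simulate_beat(small_mesh, 36.0, activation_model, bc,
                         settings=SolverSettings(dt=8e-3, t_end=0.8))
    assert beat.profiles.shape == (len(beat.times), len(small_mesh.linescan))
    assert beat.mean_strain[0] == pytest.approx(0.0, abs=1e-12)
    assert beat.peak_shortening > 0.5          # the cell visibly contracts
    assert beat.t_max_contraction == beat.times[beat.i_max_contraction]
    # relaxed again by the end of the beat
    assert abs(beat.mean_strain[-1]) < 0.3 * abs(beat.mean_strain.min())


def test_fiber_green_strain_identity():
    assert fiber_green_strain(np.eye(2), np.array([1.0, 0.0])) == pytest.approx(0.0)
    lam = 1.1
    unmod = fiber_green_strain(np.diag([lam ** 2, 1.0]), np.array([1.0, 0.0]),
                               modified=False)
    assert unmod == pytest.approx(0.5 * (lam ** 2 - 1.0))
    with pytest.raises(ValueError):
        fiber_green_strain(np.eye(2), np.array([1.0, 1.0]))


def test_contractile_observables_oracle():
    """Exponential recovery with known tau is recovered exactly."""
    t = np.linspace(0.0, 1.0, 201)
    t0, tau, amp = 0.2, 0.15, -0.1
    eps = np.where(t < t0, amp * t / t0, amp * np.exp(-(t - t0) / tau))
    eps_max, tau_fit, rate = contractile_observables(t, eps)
    assert eps_max == pytest.approx(amp)
    assert tau_fit == pytest.approx(tau, rel=1e-3)
    assert rate >= abs(amp) / t0 * 0.9


def test_contractile_observables_non_recovering():
    t = np.linspace(0.0, 1.0, 50)
    eps = -0.1 * np.ones(50)
    eps_max, tau_fit, _ = contractile_observables(t, eps)
    assert tau_fit is None


def test_strain_profile_validation():
    with pytest.raises(ValueError):
        StrainProfile(np.array([0.0, 1.0]), np.zeros(3))
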
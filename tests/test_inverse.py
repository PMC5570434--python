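import numpy as np
import pytest

from cardiomech.activation import ActiveTensionParameters
from cardiomech.fem import (BoundaryConditionSpec, SolverSettings,
                            StaticProblem, StrainProfile)
from cardiomech.inverse import (InverseProblemConfig, _Engine,
                                _loglinear_weights, _segment_weights,
                                correlate_E_strain, estimate_elasticity,
                                estimate_noise_sd, objective_rmse)


@pytest.fixture(scope="module")
def problem(small_mesh):
    bc = BoundaryConditionSpec(anchor_nodes=small_mesh.anchor_nodes)
    return StaticProblem(small_mesh, bc, ActiveTensionParameters(),
                         SolverSettings())


@pytest.fixture(scope="module")
def activation_field(problem):
    return 0.3 * np.ones(problem.ne)


def test_config_validation():
    with pytest.raises(ValueError):
        InverseProblemConfig(coarse_regions=50, fine_segments=40)
    with pytest.raises(ValueError):
        InverseProblemConfig(bounds=(-1.0, 10.0))
    with pytest.raises(ValueError):
        InverseProblemConfig(stop_threshold=0.0)


def test_objective_rmse_oracle():
    a = StrainProfile(np.linspace(0, 10, 11), -0.05 * np.ones(11))
    b = StrainProfile(np.linspace(0, 10, 11), -0.07 * np.ones(11))
    assert objective_rmse(a, a) == pytest.approx(0.0)
    assert objective_rmse(a, b) == pytest.approx(0.02)
    c = StrainProfile(np.linspace(20, 30, 11), -0.05 * np.ones(11))
    with pytest.raises(ValueError):
        objective_rmse(a, c)


def test_noise_sd_estimator(rng):
    x = np.linspace(0, 100, 400)
    smooth = -0.1 * np.sin(x / 18.0) ** 2
    sigma = 0.012
    prof = StrainProfile(x, smooth + rng.normal(0, sigma, x.shape))
    est = estimate_noise_sd(prof)
    assert est == pytest.approx(sigma, rel=0.15)
    assert estimate_noise_sd(StrainProfile(x, smooth)) < 1e-4
    assert estimate_noise_sd(StrainProfile(x[:2], smooth[:2])) == 0.0


def test_correlate_E_strain():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    r, p = correlate_E_strain(a, -2.0 * a)
    assert r == pytest.approx(-1.0)
    r, _ = correlate_E_strain(a, np.ones(4))
    assert np.isnan(r)


def test_parameterization_weights():
    x = np.linspace(0, 10, 50)
    bp = np.linspace(0, 10, 6)
    W = _loglinear_weights(x, bp)
    assert np.allclose(W.sum(axis=1), 1.0)
    # exact interpolation of a linear function of x
    assert np.allclose(W @ bp, x)
    Ws = _segment_weights(x, 0.5 * (bp[1:] + bp[:-1]))
    assert np.all(Ws.sum(axis=1) == 1.0)
    assert set(np.unique(Ws)) <= {0.0, 1.0}


def test_engine_gradient_matches_fd(problem, activation_field, small_mesh):
    measured = StrainProfile(small_mesh.linescan,
                             -0.05 * np.ones(len(small_mesh.linescan)))
    bp = np.linspace(0.0, 60.0, 5)
    x_el = problem.mesh.element_centroids() @ problem.mesh.long_axis
    eng = _Engine(problem, activation_field, measured,
                  _loglinear_weights(x_el, bp), include_fmax=True,
                  breakpoint_spacing=bp[1] - bp[0])
    eng.lam = 1e-4
    theta = np.concatenate([np.log(30.0) * np.ones(5), [np.log(54.33)]])
    J0, g = eng.value_and_grad(theta)
    h = 1e-6
    for i in range(len(theta)):
        tp = theta.copy(); tp[i] += h
        tm = theta.copy(); tm[i] -= h
        Jp, _ = eng.value_and_grad(tp)
        Jm, _ = eng.value_and_grad(tm)
        fd = (Jp - Jm) / (2 * h)
        assert g[i] == pytest.approx(fd, rel=2e-4, abs=1e-10)


def test_homogeneous_truth_recovery(problem, activation_field, small_mesh):
    """Noiseless homogeneous truth is recovered within 1%."""
    E_true = 36.0
    u, _ = problem.solve(E_true, activation_field)
    measured = problem.strain_profile(u, small_mesh.linescan)
    config = InverseProblemConfig(coarse_regions=4, fine_segments=10,
                                  multistart=3, seed=0)
    result = estimate_elasticity(small_mesh, activation_field, measured,
                                 config, problem=problem)
    E_est = result.field(small_mesh.linescan)
    assert np.max(np.abs(E_est - E_true)) / E_true < 0.01
    # monotone up to the discrepancy-principle stopping tolerance
    assert result.objective <= 1.05 * result.coarse_objective + 1e-9
    lo, hi = config.bounds
    assert np.all(result.field.values >= lo)
    assert np.all(result.field.values <= hi)


def test_fixed_and_disabled_regularization(problem, activation_field,
                                           small_mesh):
    u, _ = problem.solve(36.0, activation_field)
    measured = problem.strain_profile(u, small_mesh.linescan)
    for reg in ("none", 1e-5):
        config = InverseProblemConfig(coarse_regions=3, fine_segments=8,
                                      multistart=1, regularization=reg)
        result = estimate_elasticity(small_mesh, activation_field, measured,
                                     config, problem=problem)
        assert result.objective < 5e-3
    with pytest.raises(ValueError):
        cfg = InverseProblemConfig(coarse_regions=3, fine_segments=8,
                                   regularization="bogus")
        estimate_elasticity(small_mesh, activation_field, measured, cfg,
                            problem=problem)
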
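import numpy as np
import pytest

from cardiomech import materials
from cardiomech.materials import (ElasticityField, KinematicState,
                                  MaterialParameters, elastic_to_mooney,
                                  passive_pk2, strain_energy,
                                  total_passive_pk2, volumetric_pk2)


def test_elastic_to_mooney_roundtrip():
    mat = elastic_to_mooney(36.0, 0.49)
    assert mat.E == pytest.approx(36.0, rel=1e-12)
    assert mat.nu == pytest.approx(0.49, rel=1e-12)
    assert mat.C01 == pytest.approx(mat.C10 / 50.0)


def test_elastic_to_mooney_validation():
    with pytest.raises(ValueError):
        elastic_to_mooney(-1.0)
    with pytest.raises(ValueError):
        elastic_to_mooney(10.0, 0.5)


def test_identity_state_is_stress_free():
    mat = elastic_to_mooney(36.0)
    state = KinematicState.from_C2d(np.eye(2))
    assert strain_energy(state, mat) == pytest.approx(0.0, abs=1e-14)
    assert np.allclose(total_passive_pk2(state, mat), 0.0, atol=1e-12)


def test_pk2_is_energy_derivative():
    """S = 2 dW/dC checked by central differences in random directions."""
    rng = np.random.default_rng(7)
    mat = elastic_to_mooney(25.0)
    F = np.eye(2) + 0.05 * rng.standard_normal((2, 2))
    C0 = F.T @ F

    def W(C2d):
        return strain_energy(KinematicState.from_C2d(C2d), mat)

    S = total_passive_pk2(KinematicState.from_C2d(C0), mat)[:2, :2]
    h = 1e-6
    for _ in range(5):
        H = rng.standard_normal((2, 2))
        H = 0.5 * (H + H.T)
        dW = (W(C0 + h * H) - W(C0 - h * H)) / (2 * h)
        assert dW == pytest.approx(0.5 * np.sum(S * H), rel=1e-6, abs=1e-10)


def test_volumetric_pk2_vanishes_at_unit_volume():
    mat = elastic_to_mooney(36.0)
    # isochoric embedding forces J = 1
    state = KinematicState.from_C2d(np.diag([1.1, 1.0 / 1.1]),
                                    embedding="isochoric")
    assert np.allclose(volumetric_pk2(state, mat), 0.0, atol=1e-14)


def test_small_strain_uniaxial_recovers_young_modulus():
    E = 36.0
    mat = elastic_to_mooney(E)
    eps = 1e-5
    sigma = materials.plane_stress_uniaxial_response(mat, eps)
    assert sigma / eps == pytest.approx(E, rel=0.01)


def test_embedding_invariants():
    C2d = np.diag([1.2, 0.9])
    c33 = KinematicState.from_C2d(C2d, embedding="c33")
    iso = KinematicState.from_C2d(C2d, embedding="isochoric")
    assert c33.J == pytest.approx(np.sqrt(1.2 * 0.9))
    assert iso.J == pytest.approx(1.0)
    assert iso.C[2, 2] == pytest.approx(1.0 / (1.2 * 0.9))
    with pytest.raises(ValueError):
        KinematicState.from_C2d(C2d, embedding="bogus")
    with pytest.raises(ValueError):
        KinematicState.from_C2d(np.diag([1.0, -0.5]))


def test_material_parameter_relations():
    mat = MaterialParameters(C10=5.0, C01=0.1, D1=100.0)
    assert mat.mu == pytest.approx(2 * 5.1)
    assert mat.K == pytest.approx(200.0)


def test_elasticity_field_loglinear_and_clamping():
    f = ElasticityField([0.0, 10.0, 20.0], [10.0, 40.0, 10.0])
    assert f(10.0) == pytest.approx(40.0)
    assert f(5.0) == pytest.approx(np.exp(0.5 * (np.log(10) + np.log(40))))
    assert f(-5.0) == pytest.approx(10.0)     # clamped
    assert f(25.0) == pytest.approx(10.0)


def test_elasticity_field_constant_mode():
    f = ElasticityField([0.0, 10.0, 20.0], [10.0, 40.0, 20.0],
                        mode="constant")
    assert f(1.0) == pytest.approx(10.0)
    assert f(9.0) == pytest.approx(40.0)      # nearest midpoint
    assert f(19.0) == pytest.approx(20.0)


def test_elasticity_field_spline_clipped():
    x = np.linspace(0, 100, 8)
    vals = np.array([1.0, 90.0, 1.0, 90.0, 1.0, 90.0, 1.0, 90.0])
    f = ElasticityField(x, vals, mode="spline", bounds=(0.1, 100.0))
    E = f(np.linspace(0, 100, 500))
    assert np.all(E >= 0.1) and np.all(E <= 100.0)
    assert np.allclose(f(x), np.clip(vals, 0.1, 100.0))


def test_elasticity_field_validation():
    with pytest.raises(ValueError):
        ElasticityField([0.0, 0.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        ElasticityField([0.0, 1.0], [1.0, -2.0])
    with pytest.raises(ValueError):
        ElasticityField([0.0, 1.0], [1.0, 2.0], mode="bogus")
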
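import numpy as np
import pytest

from cardiomech import geometry
from cardiomech.activation import (ActivationModel, CalciumTransientFit,
                                   TnCKinetics)


@pytest.fixture(scope="session")
def small_mesh():
    """Coarse stadium cell (~60 um) used by fast solver tests."""
    outline = geometry.build_synthetic_outline(60.0, 20.0, 0.4)
    mesh = geometry.mesh_outline(outline, 4.0)
    mesh.anchor_nodes = geometry.default_anchor(mesh, band_width=3.0)
    mesh.linescan = geometry.sample_linescan(mesh, 40)
    return mesh


@pytest.fixture(scope="session")
def tiny_mesh():
    """Very coarse cell for gradient/tangent checks."""
    outline = geometry.build_synthetic_outline(40.0, 16.0, 0.4)
    mesh = geometry.mesh_outline(outline, 6.0)
    mesh.anchor_nodes = geometry.default_anchor(mesh, band_width=5.0)
    mesh.linescan = geometry.sample_linescan(mesh, 20)
    return mesh


@pytest.fixture(scope="session")
def nominal_fit():
    """Calcium transient with peak ~10.8 F/F0, tau_fall 80 ms."""
    return CalciumTransientFit(a=12.0, b=1.0, k_fall=12.5, k_rise=40.0)


@pytest.fixture(scope="session")
def activation_model(nominal_fit):
    tnc = TnCKinetics(tau_c=0.03, tau_r=0.30, beta=1.5, t_p=0.10, t_b=0.0)
    return ActivationModel(global_fit=nominal_fit, tnc=tnc)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
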
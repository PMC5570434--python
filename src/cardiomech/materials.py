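"""Passive constitutive model of the cardiomyocyte.

The cell interior is treated as a nearly-incompressible isotropic
Mooney-Rivlin medium with strain energy

    W = C10 (I1bar - 3) + C01 (I2bar - 3) + D1 (J - 1)^2

where I1bar, I2bar are invariants of the modified right Cauchy-Green
tensor Cbar = J^(-2/3) C, and J the local volume change.  C01 = C10/50,
K = 2 D1 is the finite bulk modulus, mu = 2 (C10 + C01) the initial shear
modulus, and (E, nu) follow the usual isotropic relations with default
nu = 0.49 (near incompressibility).

The 2D kinematics embed the in-plane C (2x2) into 3D.  Two embeddings are
supported:

* ``"c33"`` (default): out-of-plane stretch fixed at 1, so J = det(F_2D)
  and the in-plane volumetric penalty K(J-1) J C^-1 of the weak form acts
  on the in-plane volume change.  This matches the printed weak form.
* ``"isochoric"``: the out-of-plane stretch absorbs all volume change
  (C33 = 1/det C_2D, J = 1), the plane-stress/constant-volume idealization.

All stresses are in kPa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_POISSON = 0.49
C01_RATIO = 1.0 / 50.0  # C01 = C10 / 50


# ---------------------------------------------------------------------------
# Material parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaterialParameters:
    """Mooney-Rivlin constants (kPa) with derived elastic moduli."""

    C10: float
    C01: float
    D1: float

    @property
    def mu(self) -> float:
        """Initial shear modulus, mu = 2 (C10 + C01)."""
        return 2.0 * (self.C10 + self.C01)

    @property
    def K(self) -> float:
        """Finite bulk modulus, K = 2 D1."""
        return 2.0 * self.D1

    @property
    def E(self) -> float:
        """Initial Young's modulus, E = 9 K mu / (3 K + mu)."""
        return 9.0 * self.K * self.mu / (3.0 * self.K + self.mu)

    @property
    def nu(self) -> float:
        """Initial Poisson's ratio, nu = (3K - 2mu) / (2 (3K + mu))."""
        return (3.0 * self.K - 2.0 * self.mu) / (2.0 * (3.0 * self.K + self.mu))


def elastic_to_mooney(E: float, nu: float = DEFAULT_POISSON) -> MaterialParameters:
    """Convert (E, nu) to Mooney-Rivlin constants with C01 = C10/50."""
    if E <= 0:
        raise ValueError("E must be positive")
    if not (0.0 < nu < 0.5):
        raise ValueError("nu must lie in (0, 0.5); the incompressible limit "
                         "is unsupported by the penalty formulation")
    mu = E / (2.0 * (1.0 + nu))
    K = E / (3.0 * (1.0 - 2.0 * nu))
    C10 = mu / (2.0 * (1.0 + C01_RATIO))
    return MaterialParameters(C10=C10, C01=C10 * C01_RATIO, D1=K / 2.0)


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------

@dataclass
class KinematicState:
    """3D-embedded kinematic quantities built from an in-plane C (2x2)."""

    C: np.ndarray       # 3x3 right Cauchy-Green (block-diagonal embedding)
    J: float            # volume change
    embedding: str = "c33"

    @classmethod
    def from_C2d(cls, C2d, embedding: str = "c33") -> "KinematicState":
        C2d = np.asarray(C2d, dtype=float)
        _check_spd(C2d)
        det2 = C2d[0, 0] * C2d[1, 1] - C2d[0, 1] * C2d[1, 0]
        if embedding == "c33":
            C33 = 1.0
            J = np.sqrt(det2)
        elif embedding == "isochoric":
            C33 = 1.0 / det2
            J = 1.0
        else:
            raise ValueError(f"unknown embedding {embedding!r}")
        C = np.zeros((3, 3))
        C[:2, :2] = C2d
        C[2, 2] = C33
        return cls(C=C, J=float(J), embedding=embedding)

    @classmethod
    def from_F2d(cls, F2d, embedding: str = "c33") -> "KinematicState":
        F2d = np.asarray(F2d, dtype=float)
        return cls.from_C2d(F2d.T @ F2d, embedding=embedding)

    @property
    def Cbar(self) -> np.ndarray:
        """Modified right Cauchy-Green tensor J^(-2/3) C."""
        return self.J ** (-2.0 / 3.0) * self.C

    @property
    def I1bar(self) -> float:
        return float(np.trace(self.Cbar))

    @property
    def I2bar(self) -> float:
        Cb = self.Cbar
        return 0.5 * float(np.trace(Cb) ** 2 - np.trace(Cb @ Cb))

    @property
    def green_strain(self) -> np.ndarray:
        """Green strain tensor 0.5 (C - I)."""
        return 0.5 * (self.C - np.eye(3))


def _check_spd(C2d):
    if not np.allclose(C2d, C2d.T, atol=1e-10):
        raise ValueError("C must be symmetric")
    ev = np.linalg.eigvalsh(C2d)
    if np.any(ev <= 0):
        raise ValueError("C must be positive definite")


# ---------------------------------------------------------------------------
# Energy and stress
# ---------------------------------------------------------------------------

def strain_energy(state: KinematicState, mat: MaterialParameters) -> float:
    """Mooney-Rivlin strain energy density W (kPa)."""
    return float(
        mat.C10 * (state.I1bar - 3.0)
        + mat.C01 * (state.I2bar - 3.0)
        + mat.D1 * (state.J - 1.0) ** 2
    )


def passive_pk2(state: KinematicState, mat: MaterialParameters) -> np.ndarray:
    """Isochoric second Piola-Kirchhoff stress (3x3, kPa).

    The volumetric response K(J-1) J C^-1 enters the equilibrium weak form
    as a separate penalty term (see :func:`volumetric_pk2`), keeping a 1:1
    correspondence with the printed stress expression.
    """
    C = state.C
    J = state.J
    Cinv = np.linalg.inv(C)
    I = np.eye(3)
    trC = np.trace(C)
    trC2 = np.trace(C @ C)
    S1 = 2.0 * mat.C10 * J ** (-2.0 / 3.0) * (I - trC / 3.0 * Cinv)
    S2 = 2.0 * mat.C01 * J ** (-4.0 / 3.0) * (
        trC * I - C - (trC ** 2 - trC2) / 3.0 * Cinv
    )
    return S1 + S2


def volumetric_pk2(state: KinematicState, mat: MaterialParameters) -> np.ndarray:
    """Volumetric penalty stress K (J - 1) J C^-1 (3x3, kPa)."""
    return mat.K * (state.J - 1.0) * state.J * np.linalg.inv(state.C)


def total_passive_pk2(state: KinematicState, mat: MaterialParameters) -> np.ndarray:
    return passive_pk2(state, mat) + volumetric_pk2(state, mat)


def plane_stress_uniaxial_response(mat: MaterialParameters, strain: float) -> float:
    """Cauchy stress sigma_11 for uniaxial stress at small strain ``strain``.

    Solves the 3D material point problem sigma_22 = sigma_33 = 0 over the
    transverse stretches (true plane stress with free thickness), using the
    full passive + volumetric response.  Used to verify that the model
    reproduces Hooke's law with modulus E in the small-strain limit.
    """
    from scipy.optimize import brentq

    lam1 = 1.0 + strain

    def sigma(lams):
        lam2, lam3 = lams
        C = np.diag([lam1 ** 2, lam2 ** 2, lam3 ** 2])
        J = lam1 * lam2 * lam3
        state = KinematicState(C=C, J=J)
        S = passive_pk2(state, mat) + volumetric_pk2(state, mat)
        F = np.diag([lam1, lam2, lam3])
        return (F @ S @ F.T) / J  # Cauchy stress

    def resid_lat(lam_t):
        s = sigma((lam_t, lam_t))
        return s[1, 1]  # = s[2,2] by symmetry

    lam_t = brentq(resid_lat, 0.5, 2.0, xtol=1e-14)
    return float(sigma((lam_t, lam_t))[0, 0])


# ---------------------------------------------------------------------------
# Heterogeneous elasticity field
# ---------------------------------------------------------------------------

class ElasticityField:
    """Young's modulus E(x) along the cell's longitudinal axis.

    ``mode="log-linear"`` interpolates log E piecewise-linearly between the
    breakpoints (the parameterization of the coarse inverse step);
    ``mode="spline"`` passes a natural cubic interpolating spline through
    the control values (the synthetic-cell ground truth);
    ``mode="constant"`` holds E piecewise-constant on the segments whose
    midpoints are the breakpoints (the fine inverse step).
    Evaluation outside the breakpoints clamps to the nearest breakpoint
    value, and spline values are clipped to ``bounds``.
    """

    MODES = ("log-linear", "spline", "constant")

    def __init__(self, breakpoints, values, mode: str = "log-linear",
                 bounds=(0.1, 100.0)):
        self.x = np.asarray(breakpoints, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.values.shape:
            raise ValueError("breakpoints and values must be 1D and congruent")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if np.any(self.values <= 0):
            raise ValueError("E values must be positive")
        if mode not in self.MODES:
            raise ValueError(f"mode must be one of {self.MODES}")
        self.mode = mode
        self.bounds = (float(bounds[0]), float(bounds[1]))
        if mode == "spline":
            from scipy.interpolate import make_interp_spline
            self._spline = make_interp_spline(self.x, self.values, k=3,
                                              bc_type="natural")

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        xc = np.clip(x, self.x[0], self.x[-1])
        if self.mode == "log-linear":
            E = np.exp(np.interp(xc, self.x, np.log(self.values)))
        elif self.mode == "spline":
            E = np.clip(self._spline(xc), self.bounds[0], self.bounds[1])
        else:  # constant per segment, nearest breakpoint
            idx = np.clip(np.searchsorted(
                0.5 * (self.x[1:] + self.x[:-1]), xc), 0, len(self.x) - 1)
            E = self.values[idx]
        return E if E.shape else float(E)

    def to_table(self):
        import pandas as pd
        return pd.DataFrame({"x_um": self.x, "E_kPa": self.values})


def eval_E_field(field: ElasticityField, x):
    """Evaluate the elasticity field at position(s) x (um) -> E (kPa)."""
    return field(x)
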
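"""Monte-Carlo sensitivity of contractile outputs to model parameters.

Six inputs are sampled (calcium peak Z_max, calcium decay constant
tau_fall, homogeneous Young's modulus E, and the tension-law parameters
f_max, eps_opt, s), a full beat is simulated per sample on a homogeneous
cell, and the three contractile outputs (maximum longitudinal contraction
eps_l_max, re-lengthening time constant tau_sl, maximum strain rate) are
regressed on the z-scored inputs by ordinary least squares.

Nominal values: Z_max = 10.79 F/F0, tau_fall = 0.08 s, f_max = 54.33 kPa,
eps_opt = 0.23, s = 0.24; all +/- 10 % uniform except E, uniform on
[10, 100] kPa.  The Hill midpoint Z50 is held at the reference value
computed from the nominal transient (only then does the transient
amplitude influence the activation at all; if Z50 were recomputed per
sample the Hill prefactor would be amplitude-invariant).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .activation import (ActivationModel, CalciumTransientFit, TnCKinetics,
                         ActiveTensionParameters, compute_Z50)
from .fem import (BoundaryConditionSpec, SolverSettings, StaticProblem,
                  simulate_beat, contractile_observables)

PARAMS = ("Z_max", "tau_fall", "E", "f_max", "eps_opt", "s")
OUTPUTS = ("eps_l_max", "tau_sl", "strain_rate_max")

NOMINALS = {
    "Z_max": 10.79,     # F/F0
    "tau_fall": 0.08,   # s
    "f_max": 54.33,     # kPa
    "eps_opt": 0.23,
    "s": 0.24,
}


@dataclass
class SensitivityDesign:
    n_samples: int = 625
    variation: float = 0.10
    E_range: tuple = (10.0, 100.0)       # kPa
    nominals: dict = dc_field(default_factory=lambda: dict(NOMINALS))
    seed: int = 0
    baseline: float = 1.0                # F/F0
    k_rise: float = 40.0                 # 1/s
    tnc: TnCKinetics = dc_field(default_factory=lambda: TnCKinetics(
        tau_c=0.03, tau_r=0.30, beta=1.5, t_p=0.10, t_b=0.0))

    def __post_init__(self):
        if self.n_samples <= len(PARAMS):
            raise ValueError("n_samples must exceed the number of regressors")


@dataclass
class SensitivityResult:
    design: pd.DataFrame
    outputs: pd.DataFrame
    coefficients: pd.DataFrame           # standardized betas (inputs x outputs)
    pvalues: pd.DataFrame
    n_failed: int = 0


def sample_design(design: SensitivityDesign, seed: int | None = None) -> pd.DataFrame:
    """Seeded uniform sampling within the per-parameter ranges."""
    rng = np.random.default_rng(design.seed if seed is None else seed)
    n = design.n_samples
    cols = {}
    for name in ("Z_max", "tau_fall", "f_max", "eps_opt", "s"):
        nom = design.nominals[name]
        lo, hi = nom * (1 - design.variation), nom * (1 + design.variation)
        cols[name] = rng.uniform(lo, hi, size=n)
    cols["E"] = rng.uniform(*design.E_range, size=n)
    return pd.DataFrame(cols)[list(PARAMS)]


def _amplitude_for_peak(z_peak, b, k_fall, k_rise):
    """Biexponential amplitude a giving max Z = z_peak."""
    t_star = np.log(k_rise / k_fall) / (k_rise - k_fall)
    shape = np.exp(-k_fall * t_star) - np.exp(-k_rise * t_star)
    return (z_peak - b) / shape


def reference_Z50(design: SensitivityDesign) -> float:
    """Z50 of the nominal transient (held fixed across samples)."""
    k_fall = 1.0 / design.nominals["tau_fall"]
    a = _amplitude_for_peak(design.nominals["Z_max"], design.baseline,
                            k_fall, design.k_rise)
    fit = CalciumTransientFit(a=a, b=design.baseline, k_fall=k_fall,
                              k_rise=design.k_rise)
    return compute_Z50(fit)


def run_design(mesh, design: SensitivityDesign,
               samples: pd.DataFrame | None = None,
               bc: BoundaryConditionSpec | None = None,
               settings: SolverSettings | None = None) -> SensitivityResult:
    """Simulate a beat per sample and collect contractile observables.

    Each sample uses a homogeneous modulus and a homogeneous (global)
    activation built from the sampled transient.  Failed samples are
    dropped (their count is reported and must stay below 5 %).
    """
    if samples is None:
        samples = sample_design(design)
    bc = bc or BoundaryConditionSpec(anchor_nodes=mesh.anchor_nodes)
    settings = settings or SolverSettings(dt=8e-3)
    z50 = reference_Z50(design)

    rows = []
    failed = 0
    for _, row in samples.iterrows():
        k_fall = 1.0 / row["tau_fall"]
        a = _amplitude_for_peak(row["Z_max"], design.baseline, k_fall,
                                design.k_rise)
        fit = CalciumTransientFit(a=a, b=design.baseline, k_fall=k_fall,
                                  k_rise=design.k_rise)
        model = ActivationModel(global_fit=fit, tnc=design.tnc, Z50=z50)
        act = ActiveTensionParameters(f_max=row["f_max"],
                                      eps_opt=row["eps_opt"], s=row["s"])
        prob = StaticProblem(mesh, bc, act, settings)
        try:
            beat = simulate_beat(mesh, row["E"], model, bc, problem=prob)
            eps_max, tau_sl, rate = contractile_observables(beat)
            if tau_sl is None:
                raise RuntimeError("non-recovering strain trace")
            rows.append((eps_max, tau_sl, rate))
        except Exception:
            failed += 1
            rows.append((np.nan, np.nan, np.nan))
    outputs = pd.DataFrame(rows, columns=list(OUTPUTS))
    ok = outputs.notna().all(axis=1)
    if failed > 0.05 * len(samples):
        raise RuntimeError(f"{failed}/{len(samples)} sensitivity samples failed")
    coef, pval = regress(samples[ok], outputs[ok])
    return SensitivityResult(design=samples, outputs=outputs,
                             coefficients=coef, pvalues=pval, n_failed=failed)


def regress(X: pd.DataFrame, Y: pd.DataFrame, standardize: bool = True):
    """OLS of each output on the inputs; standardized coefficients.

    Inputs and outputs are z-scored (unless ``standardize=False``), so the
    coefficients are standardized betas comparable across parameters.
    Returns (coefficients, pvalues) DataFrames indexed by input name.
    """
    import statsmodels.api as sm

    Xv = X.to_numpy(float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(Xv)), Xv])) < Xv.shape[1] + 1:
        corr = np.corrcoef(Xv, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"design matrix is rank deficient (collinear columns "
            f"{X.columns[i]!r} and {X.columns[j]!r})")
    if standardize:
        Xv = (Xv - Xv.mean(axis=0)) / Xv.std(axis=0, ddof=0)
    Xd = sm.add_constant(Xv)
    coefs, pvals = {}, {}
    for name in Y.columns:
        y = Y[name].to_numpy(float)
        if standardize:
            sd = y.std(ddof=0)
            if sd == 0:
                raise ValueError(f"output {name!r} has zero variance")
            y = (y - y.mean()) / sd
        fit = sm.OLS(y, Xd).fit()
        coefs[name] = fit.params[1:]
        pvals[name] = fit.pvalues[1:]
    coef = pd.DataFrame(coefs, index=list(X.columns))
    pval = pd.DataFrame(pvals, index=list(X.columns))
    return coef, pval
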
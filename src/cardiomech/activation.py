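"""Excitation-contraction coupling.

The cytosolic calcium transient (fluorescence F/F0 from a line-scan) is
fitted with a biexponential

    Z(t) = a (exp(-k_fall t) - exp(-k_rise t)) + b,

troponin-C binding/unbinding is described by a unit-peak double-exponential
envelope f_TCa(t), and the activation driving contraction is

    A(t) = Zmax^nH / (Z50^nH + Zmax^nH) * Z(t)/Zmax * f_TCa(t),

a Hill saturation prefactor times the normalised transient times the TnC
envelope.  The sarcomere tension follows the length-dependent law

    T_act = A f_max exp(-((eps - eps_opt)/s)^2)

with eps the Green strain along the fiber direction, and the active stress
is the rank-1 tensor S_act = T_act d (x) d.

Defaults: nH = 2.6, f_max = 54.33 kPa, eps_opt = 0.23, s = 0.24,
resting sarcomere length SL0 = 1.9 um.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

DEFAULT_NH = 2.6
DEFAULT_FMAX = 54.33      # kPa
DEFAULT_EPS_OPT = 0.23
DEFAULT_S = 0.24
DEFAULT_SL0 = 1.9         # um
DEFAULT_K_RISE = 40.0     # 1/s, reference upstroke rate constant


class FitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Calcium transient
# ---------------------------------------------------------------------------

@dataclass
class CalciumTrace:
    """A measured F/F0 transient at one line-scan position (or global)."""

    times: np.ndarray          # s
    values: np.ndarray         # F/F0
    position: float | str = "global"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values <= 0):
            raise ValueError("F/F0 values must be positive")


@dataclass
class CalciumTransientFit:
    """Biexponential fit parameters of a calcium transient."""

    a: float                   # amplitude (F/F0 units)
    b: float                   # baseline (F/F0 units)
    k_fall: float              # 1/s
    k_rise: float              # 1/s
    position: float | str = "global"
    residual_rms: float = 0.0

    def __post_init__(self):
        if self.a <= 0 or self.k_fall <= 0 or self.k_rise <= 0:
            raise ValueError("a, k_fall, k_rise must be positive")
        if self.k_rise <= self.k_fall:
            raise ValueError("k_rise must exceed k_fall (upstroke faster than decay)")

    @property
    def tau_fall(self) -> float:
        return 1.0 / self.k_fall

    @property
    def tau_rise(self) -> float:
        return 1.0 / self.k_rise

    @property
    def t_peak(self) -> float:
        """Analytic peak time ln(k_rise/k_fall) / (k_rise - k_fall)."""
        return np.log(self.k_rise / self.k_fall) / (self.k_rise - self.k_fall)

    @property
    def z_max(self) -> float:
        """Maximum of Z(t) over t >= 0."""
        return float(eval_Z(self, self.t_peak))


def eval_Z(fit: CalciumTransientFit, t):
    """Evaluate the biexponential transient Z(t) for t >= 0."""
    t = np.asarray(t, dtype=float)
    Z = fit.a * (np.exp(-fit.k_fall * t) - np.exp(-fit.k_rise * t)) + fit.b
    return Z if Z.shape else float(Z)


def align_to_onset(trace: CalciumTrace, frac: float = 0.1) -> CalciumTrace:
    """Shift times so t = 0 is the upstroke onset.

    Onset is the first crossing of baseline + ``frac`` * amplitude, where
    the baseline is the pre-upstroke minimum level.
    """
    v = trace.values
    base = np.percentile(v, 5)
    amp = v.max() - base
    if amp <= 0:
        raise FitError("trace has no upstroke")
    thresh = base + frac * amp
    above = np.nonzero(v >= thresh)[0]
    i0 = above[0] if len(above) else 0
    t0 = trace.times[i0]
    return CalciumTrace(times=trace.times - t0, values=v, position=trace.position)


def fit_calcium(trace: CalciumTrace, align: bool = False,
                n_starts: int = 5, seed: int = 0) -> CalciumTransientFit:
    """Least-squares fit of the biexponential transient to a trace.

    Multistart (``n_starts`` perturbed initial guesses) guards against the
    k_fall/k_rise exchange ambiguity; the best solution with
    k_rise > k_fall is returned.
    """
    if len(trace.times) < 10:
        raise FitError("need at least 10 samples spanning upstroke and decay")
    if align:
        trace = align_to_onset(trace)
    t, y = trace.times, trace.values
    b0 = float(np.percentile(y, 5))
    amp = float(y.max() - b0)
    t_pk = float(t[np.argmax(y)])
    k_fall0 = 1.0 / max(0.3 * (t.max() - t_pk), 1e-3)
    k_rise0 = max(3.0 / max(t_pk, 1e-3), 3.0 * k_fall0)

    def model(p):
        a, b, kf, kr = p
        return a * (np.exp(-kf * t) - np.exp(-kr * t)) + b - y

    rng = np.random.default_rng(seed)
    best = None
    for i in range(n_starts):
        jitter = 1.0 if i == 0 else rng.uniform(0.5, 2.0, size=4)
        p0 = np.array([max(amp * 1.2, 1e-3), max(b0, 1e-3), k_fall0, k_rise0]) * jitter
        try:
            sol = least_squares(
                model, p0,
                bounds=([1e-6, 1e-6, 1e-4, 1e-3], [np.inf] * 4),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        a, b, kf, kr = sol.x
        if kr <= kf:  # exchanged roles: same model with swapped rates
            kf, kr, a = kr, kf, -a
        if a <= 0 or kr <= kf:
            continue
        rms = float(np.sqrt(np.mean(sol.fun ** 2)))
        if best is None or rms < best[0]:
            best = (rms, (a, b, kf, kr))
    if best is None:
        raise FitError("calcium fit did not converge for any start")
    rms, (a, b, kf, kr) = best
    return CalciumTransientFit(a=a, b=b, k_fall=kf, k_rise=kr,
                               position=trace.position, residual_rms=rms)


def compute_Z50(global_fit: CalciumTransientFit) -> float:
    """Half-maximal F/F0 level of the global transient.

    Defined as the midpoint between baseline and peak,
    Z50 = b + (Zmax - b)/2.
    """
    zmax = global_fit.z_max
    if zmax <= global_fit.b:
        raise ValueError("transient peak must exceed baseline")
    return global_fit.b + 0.5 * (zmax - global_fit.b)


# ---------------------------------------------------------------------------
# Troponin-C envelope
# ---------------------------------------------------------------------------

@dataclass
class TnCKinetics:
    """Parameters of the TnC binding/unbinding envelope f_TCa."""

    tau_c: float               # s, contraction time constant
    tau_r: float               # s, relaxation time constant
    beta: float = 1.5          # exponent in [1, 2]
    t_p: float = 0.15          # s, time to peak (f_TCa(t_p) = 1)
    t_b: float = 0.0           # s, offset of the relaxation exponential

    def __post_init__(self):
        if self.tau_c <= 0 or self.tau_r <= 0:
            raise ValueError("tau_c and tau_r must be positive")
        if not (1.0 <= self.beta <= 2.0):
            raise ValueError("beta must lie in [1, 2]")


def _signed_pow(x, beta):
    return np.sign(x) * np.abs(x) ** beta


def eval_fTCa(tnc: TnCKinetics, t):
    """TnC envelope: rise times relaxation, normalised so f(t_p) = 1.

    For t < t_b the relaxation exponent uses the sign-preserving power
    sign(x)|x|^beta so the expression stays real for non-integer beta.
    """
    t = np.asarray(t, dtype=float)
    rise = 1.0 - np.exp(-(t / tnc.tau_c) ** tnc.beta)
    relax = np.exp(-_signed_pow((t - tnc.t_b) / tnc.tau_r, tnc.beta))
    num = rise * relax
    den = (1.0 - np.exp(-(tnc.t_p / tnc.tau_c) ** tnc.beta)) * np.exp(
        -_signed_pow((tnc.t_p - tnc.t_b) / tnc.tau_r, tnc.beta))
    out = num / den
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# Activation
# ---------------------------------------------------------------------------

@dataclass
class ActivationModel:
    """Time- and position-dependent activation A(t, x).

    ``fits`` holds one transient fit per line-scan position (heterogeneous
    mode) or a single global fit (homogeneous mode).  Z50 is computed from
    the global transient; Zmax is the peak of the governing (local or
    global) fit.
    """

    global_fit: CalciumTransientFit
    tnc: TnCKinetics
    nH: float = DEFAULT_NH
    Z50: float | None = None
    local_fits: list = field(default_factory=list)
    local_positions: np.ndarray | None = None

    def __post_init__(self):
        if self.Z50 is None:
            self.Z50 = compute_Z50(self.global_fit)
        if self.local_fits:
            if self.local_positions is None:
                self.local_positions = np.array(
                    [f.position for f in self.local_fits], dtype=float)
            else:
                self.local_positions = np.asarray(self.local_positions, float)

    @property
    def mode(self) -> str:
        return "heterogeneous" if self.local_fits else "homogeneous"

    def hill_prefactor(self, fit: CalciumTransientFit) -> float:
        zm = fit.z_max
        return zm ** self.nH / (self.Z50 ** self.nH + zm ** self.nH)

    def _fit_at(self, x) -> CalciumTransientFit:
        if not self.local_fits:
            return self.global_fit
        i = int(np.argmin(np.abs(self.local_positions - x)))
        return self.local_fits[i]

    def __call__(self, t, x=None):
        return eval_activation(self, t, x)


def eval_activation(model: ActivationModel, t, x=None):
    """A(t, x): Hill prefactor x normalised transient x TnC envelope."""
    fit = model.global_fit if x is None else model._fit_at(x)
    pref = model.hill_prefactor(fit)
    zm = fit.z_max
    A = pref * (eval_Z(fit, t) / zm) * eval_fTCa(model.tnc, t)
    return A


def activation_on_elements(model: ActivationModel, t: float,
                           element_x: np.ndarray) -> np.ndarray:
    """Vectorised A(t, x) at element centroids (nearest line-scan fit)."""
    if not model.local_fits:
        return np.full(len(element_x), eval_activation(model, t))
    idx = np.argmin(
        np.abs(element_x[:, None] - model.local_positions[None, :]), axis=1)
    f_t = eval_fTCa(model.tnc, t)
    out = np.empty(len(element_x))
    for j in np.unique(idx):
        fit = model.local_fits[j]
        pref = model.hill_prefactor(fit)
        out[idx == j] = pref * eval_Z(fit, t) / fit.z_max * f_t
    return out


# ---------------------------------------------------------------------------
# Active tension
# ---------------------------------------------------------------------------

@dataclass
class ActiveTensionParameters:
    """Length-dependent sarcomere tension law parameters."""

    f_max: float = DEFAULT_FMAX     # kPa
    eps_opt: float = DEFAULT_EPS_OPT
    s: float = DEFAULT_S
    SL0: float = DEFAULT_SL0        # um

    def __post_init__(self):
        if self.f_max <= 0 or self.s <= 0:
            raise ValueError("f_max and s must be positive")


def active_tension(params: ActiveTensionParameters, eps, A):
    """T_act = A f_max exp(-((eps - eps_opt)/s)^2), kPa."""
    eps = np.asarray(eps, dtype=float)
    A = np.asarray(A, dtype=float)
    T = A * params.f_max * np.exp(-(((eps - params.eps_opt) / params.s) ** 2))
    return T if T.shape else float(T)


def active_pk2(T_act: float, d: np.ndarray) -> np.ndarray:
    """Rank-1 active stress S_act = T_act d (x) d for a unit fiber vector."""
    d = np.asarray(d, dtype=float)
    if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-9):
        raise ValueError("fiber direction must be a unit vector")
    return T_act * np.outer(d, d)


def sl_to_green_strain(SL, SL0: float = DEFAULT_SL0):
    """Sarcomere length -> fiber Green strain, eps = ((SL/SL0)^2 - 1)/2."""
    lam = np.asarray(SL, dtype=float) / SL0
    eps = 0.5 * (lam ** 2 - 1.0)
    return eps if eps.shape else float(eps)


def fit_steady_state(pCa, SL, tension, nH: float = DEFAULT_NH,
                     SL0: float = DEFAULT_SL0, seed: int = 0,
                     n_starts: int = 5):
    """Fit (f_max, eps_opt, s, pCa50) to steady-state tension data.

    The steady-state model is

        T = [Ca]^nH / (Ca50^nH + [Ca]^nH) * f_max * exp(-((eps-eps_opt)/s)^2)

    with eps the fiber Green strain from the sarcomere length.  Requires at
    least three distinct SL values, otherwise eps_opt and s are not
    identifiable.
    """
    pCa = np.asarray(pCa, float)
    SL = np.asarray(SL, float)
    tension = np.asarray(tension, float)
    if len(np.unique(np.round(SL, 9))) < 3:
        raise ValueError("need at least 3 distinct SL values to identify "
                         "eps_opt and s")
    eps = sl_to_green_strain(SL, SL0)

    def model(p):
        fmax, eps_opt, s, pca50 = p
        # Ca^n / (Ca50^n + Ca^n) with Ca = 10^-pCa, computed via pCa for
        # numerical stability at micromolar concentrations
        hill = 1.0 / (1.0 + 10 ** (nH * (pCa - pca50)))
        return hill * fmax * np.exp(-(((eps - eps_opt) / s) ** 2)) - tension

    rng = np.random.default_rng(seed)
    best = None
    p0_base = np.array([max(tension.max(), 1.0), 0.2, 0.25,
                        float(np.median(pCa))])
    lb = [1e-3, -0.5, 1e-3, pCa.min() - 2.0]
    ub = [1e4, 1.0, 2.0, pCa.max() + 2.0]
    for i in range(n_starts):
        jit = 1.0 if i == 0 else rng.uniform(0.7, 1.4, size=4)
        p0 = np.clip(p0_base * jit, lb, ub)
        try:
            sol = least_squares(model, p0, bounds=(lb, ub),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        rms = float(np.sqrt(np.mean(sol.fun ** 2)))
        if best is None or rms < best[0]:
            best = (rms, sol.x)
    if best is None:
        raise FitError("steady-state fit failed")
    rms, (fmax, eps_opt, s, pca50) = best
    params = ActiveTensionParameters(f_max=fmax, eps_opt=eps_opt, s=s, SL0=SL0)
    return params, float(pca50), rms


def fit_fTCa_to_deformation(times, observed_shortening, forward_model,
                            beta_bounds=(1.0, 2.0), seed: int = 0):
    """Fit TnC kinetics so the forward model reproduces a shortening curve.

    ``forward_model(tnc) -> normalised shortening curve on ``times``; the
    observed curve is normalised to its own peak.  Returns (TnCKinetics,
    residual_rms, at_beta_bound_flag).
    """
    y = np.asarray(observed_shortening, float)
    t = np.asarray(times, float)
    if np.allclose(y, 0.0):
        raise FitError("no contraction detected in deformation input")
    y = y / np.max(np.abs(y))
    t_pk0 = float(t[np.argmax(np.abs(y))])

    def resid(p):
        tau_c, tau_r, beta, t_p, t_b = p
        tnc = TnCKinetics(tau_c=tau_c, tau_r=tau_r, beta=beta,
                          t_p=t_p, t_b=t_b)
        sim = np.asarray(forward_model(tnc), float)
        return sim / max(np.max(np.abs(sim)), 1e-12) - y

    span = max(t.max(), 1e-2)
    p0 = np.array([0.3 * t_pk0 + 0.01, 0.3 * span, 1.5, max(t_pk0, 0.02), 0.0])
    lb = [1e-3, 1e-3, beta_bounds[0], 1e-3, 0.0]
    ub = [span, 2 * span, beta_bounds[1], span, span]
    sol = least_squares(resid, np.clip(p0, lb, ub), bounds=(lb, ub),
                        xtol=1e-12, ftol=1e-12, diff_step=1e-4)
    tau_c, tau_r, beta, t_p, t_b = sol.x
    # enforce t_b <= t_p by construction of the fit window
    tnc = TnCKinetics(tau_c=tau_c, tau_r=tau_r, beta=beta, t_p=t_p,
                      t_b=min(t_b, t_p))
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    at_bound = bool(np.isclose(beta, beta_bounds[0]) or
                    np.isclose(beta, beta_bounds[1]))
    return tnc, rms, at_bound
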
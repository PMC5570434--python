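import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiomech import activation as act
from cardiomech.activation import (ActivationModel, ActiveTensionParameters,
                                   CalciumTrace, CalciumTransientFit,
                                   TnCKinetics, active_pk2, active_tension,
                                   activation_on_elements, compute_Z50,
                                   eval_activation, eval_fTCa, eval_Z,
                                   fit_calcium, fit_steady_state,
                                   sl_to_green_strain)


def test_Z_limits_and_peak(nominal_fit):
    assert eval_Z(nominal_fit, 0.0) == pytest.approx(nominal_fit.b)
    assert eval_Z(nominal_fit, 1e3) == pytest.approx(nominal_fit.b, abs=1e-9)
    t = np.linspace(0, 1, 20001)
    assert nominal_fit.z_max == pytest.approx(eval_Z(nominal_fit, t).max(),
                                              rel=1e-6)


@settings(max_examples=50, derandomize=True)
@given(a=st.floats(0.5, 30.0), b=st.floats(0.2, 3.0),
       kf=st.floats(1.0, 20.0), ratio=st.floats(1.5, 20.0),
       t=st.floats(0.0, 5.0))
def test_Z_never_below_baseline(a, b, kf, ratio, t):
    fit = CalciumTransientFit(a=a, b=b, k_fall=kf, k_rise=kf * ratio)
    assert eval_Z(fit, t) >= b - 1e-12


def test_fit_calcium_recovers_known_parameters():
    truth = CalciumTransientFit(a=12.0, b=1.0, k_fall=4.0, k_rise=40.0)
    t = np.linspace(0.0, 1.2, 240)
    trace = CalciumTrace(times=t, values=eval_Z(truth, t))
    fit = fit_calcium(trace)
    assert fit.a == pytest.approx(truth.a, rel=1e-4)
    assert fit.b == pytest.approx(truth.b, rel=1e-4)
    assert fit.k_fall == pytest.approx(truth.k_fall, rel=1e-4)
    assert fit.k_rise == pytest.approx(truth.k_rise, rel=1e-4)
    assert fit.residual_rms < 1e-8


def test_fit_calcium_with_noise(rng):
    truth = CalciumTransientFit(a=10.0, b=1.0, k_fall=5.0, k_rise=35.0)
    t = np.linspace(0.0, 1.0, 300)
    y = eval_Z(truth, t) + rng.normal(0, 0.05, t.shape)
    trace = CalciumTrace(times=t, values=np.clip(y, 1e-3, None))
    fit = fit_calcium(trace)
    assert fit.k_fall == pytest.approx(truth.k_fall, rel=0.1)
    assert fit.z_max == pytest.approx(truth.z_max, rel=0.05)


def test_align_to_onset_locates_upstroke(rng):
    truth = CalciumTransientFit(a=10.0, b=1.0, k_fall=5.0, k_rise=35.0)
    t = np.linspace(0.0, 1.0, 500)
    delayed = eval_Z(truth, np.clip(t - 0.2, 0.0, None))
    shifted = act.align_to_onset(CalciumTrace(times=t, values=delayed))
    # onset (10% of amplitude) sits just after the 0.2 s delay
    assert shifted.times[0] == pytest.approx(-0.2, abs=0.02)


def test_fit_calcium_requires_enough_samples():
    t = np.linspace(0, 1, 5)
    with pytest.raises(act.FitError):
        fit_calcium(CalciumTrace(times=t, values=np.ones(5)))


def test_transient_fit_validation():
    with pytest.raises(ValueError):
        CalciumTransientFit(a=1.0, b=1.0, k_fall=10.0, k_rise=5.0)
    with pytest.raises(ValueError):
        CalciumTransientFit(a=-1.0, b=1.0, k_fall=1.0, k_rise=5.0)


def test_Z50_midpoint(nominal_fit):
    z50 = compute_Z50(nominal_fit)
    assert z50 == pytest.approx(
        nominal_fit.b + 0.5 * (nominal_fit.z_max - nominal_fit.b))


def test_hill_prefactor_half_at_Z50(nominal_fit, activation_model):
    model = ActivationModel(global_fit=nominal_fit,
                            tnc=activation_model.tnc,
                            Z50=nominal_fit.z_max)
    assert model.hill_prefactor(nominal_fit) == pytest.approx(0.5)


def test_fTCa_unit_peak():
    tnc = TnCKinetics(tau_c=0.06, tau_r=0.30, beta=1.5, t_p=0.15)
    assert eval_fTCa(tnc, tnc.t_p) == pytest.approx(1.0)
    assert eval_fTCa(tnc, 0.0) == pytest.approx(0.0, abs=1e-12)


def test_fTCa_real_before_offset():
    tnc = TnCKinetics(tau_c=0.06, tau_r=0.30, beta=1.5, t_p=0.25, t_b=0.1)
    vals = eval_fTCa(tnc, np.linspace(0.0, 1.0, 50))
    assert np.all(np.isfinite(vals))


def test_tnc_validation():
    with pytest.raises(ValueError):
        TnCKinetics(tau_c=-0.1, tau_r=0.3)
    with pytest.raises(ValueError):
        TnCKinetics(tau_c=0.1, tau_r=0.3, beta=3.0)


def test_activation_bounded_by_prefactor(activation_model, nominal_fit):
    t = np.linspace(0.0, 1.0, 400)
    A = eval_activation(activation_model, t)
    pref = activation_model.hill_prefactor(nominal_fit)
    envelope = eval_fTCa(activation_model.tnc, t)
    assert np.all(A >= -1e-12)
    # Z/Zmax <= 1, so A is bounded by the prefactor times the TnC envelope
    assert np.all(A <= pref * envelope + 1e-9)
    assert A[0] == pytest.approx(0.0, abs=1e-12)


def test_activation_on_elements_matches_scalar(activation_model):
    xs = np.array([1.0, 5.0, 9.0])
    A = activation_on_elements(activation_model, 0.12, xs)
    expect = [eval_activation(activation_model, 0.12, x) for x in xs]
    assert np.allclose(A, expect)


def test_active_tension_peak_value():
    p = ActiveTensionParameters()
    assert active_tension(p, p.eps_opt, 1.0) == pytest.approx(54.33)
    # symmetric Gaussian falloff
    lo = active_tension(p, p.eps_opt - p.s, 1.0)
    hi = active_tension(p, p.eps_opt + p.s, 1.0)
    assert lo == pytest.approx(hi)
    assert lo == pytest.approx(54.33 * np.exp(-1.0))


def test_active_pk2_rank_one():
    d = np.array([1.0, 0.0])
    S = active_pk2(10.0, d)
    assert np.allclose(S, [[10.0, 0.0], [0.0, 0.0]])
    with pytest.raises(ValueError):
        active_pk2(10.0, np.array([1.0, 1.0]))


def test_sl_to_green_strain():
    assert sl_to_green_strain(1.9) == pytest.approx(0.0)
    assert sl_to_green_strain(2.2, 1.9) == pytest.approx(
        0.5 * ((2.2 / 1.9) ** 2 - 1.0))


def test_fit_steady_state_recovers_truth(rng):
    truth = ActiveTensionParameters(f_max=54.33, eps_opt=0.23, s=0.24)
    pca50 = 6.0
    SL = np.repeat([1.8, 2.0, 2.2, 2.3], 8)
    pCa = np.tile(np.linspace(7.0, 5.0, 8), 4)
    eps = sl_to_green_strain(SL)
    hill = 1.0 / (1.0 + 10 ** (2.6 * (pCa - pca50)))
    T = hill * truth.f_max * np.exp(-(((eps - truth.eps_opt) / truth.s) ** 2))
    params, pca50_fit, rms = fit_steady_state(pCa, SL, T)
    assert params.f_max == pytest.approx(truth.f_max, rel=1e-3)
    assert params.eps_opt == pytest.approx(truth.eps_opt, abs=1e-3)
    assert params.s == pytest.approx(truth.s, abs=1e-3)
    assert pca50_fit == pytest.approx(pca50, abs=1e-3)


def test_fit_steady_state_needs_three_lengths():
    SL = np.repeat([1.9, 2.1], 5)
    pCa = np.tile(np.linspace(7, 5, 5), 2)
    with pytest.raises(ValueError):
        fit_steady_state(pCa, SL, np.ones(10))
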
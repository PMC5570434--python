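# Methods

This note documents the model equations, numerical methods, and estimator
definitions implemented in `cardiomech`, together with the reasoning behind
the main numerical choices.

## Geometry and discretization

The cell is a 2D domain in the `(x, y)` plane with `x` the longitudinal
axis; all lengths are in micrometres and stresses in kPa.  The synthetic
cell outline is a stadium-like polygon of bounding box `length x width`
(default 117 x 32 um) with rounded corners (corner radius = 0.4 x width).
The interior is triangulated by resampling the boundary at the target edge
length, filling the interior with a hexagonal point lattice, and Delaunay
triangulation of the combined point cloud (valid because the outline is
convex).  Meshes are plain conforming P1 triangulations with per-element
unit fiber directions (longitudinal by default) and can be read/written as
Gmsh MSH v2.2 ASCII; fields can be exported to legacy ASCII VTK.

A confocal-style line-scan along the longitudinal mid-axis (default pixel
spacing 0.28 um) defines both the strain-profile observable and the
attachment points of position-dependent calcium transients.

## Passive mechanics

The cytosol is a nearly incompressible isotropic Mooney-Rivlin medium,

```
W = C10 (I1bar - 3) + C01 (I2bar - 3) + D1 (J - 1)^2
```

with `I1bar`, `I2bar` invariants of the modified right Cauchy-Green tensor
`Cbar = J^(-2/3) C` and `C01 = C10 / 50`.  The constants map to initial
elastic moduli by `mu = 2 (C10 + C01)`, `K = 2 D1`, and the usual isotropic
relations; heterogeneous stiffness is specified as a Young's modulus field
`E(x)` along the long axis at fixed Poisson ratio `nu = 0.49`.

The isochoric second Piola-Kirchhoff stress is the analytic derivative of
the two Mooney-Rivlin terms; the volumetric response enters the weak form
as the separate penalty stress `K (J - 1) J C^-1`.

Two 3D embeddings of the in-plane kinematics are supported:

* `c33` (default): out-of-plane stretch fixed at 1, so `J = det F_2D` and
  the volumetric penalty acts on the in-plane area change;
* `isochoric`: the out-of-plane stretch absorbs all volume change
  (`C33 = 1 / det C_2D`, `J = 1`), the constant-volume idealization.

A plane-stress uniaxial material-point solve (`materials.
plane_stress_uniaxial_response`) verifies that the small-strain response
reproduces Hooke's law with modulus `E` to better than 1%.

## Excitation-contraction coupling

Measured calcium fluorescence transients (F/F0) are fitted with the
biexponential

```
Z(t) = a (exp(-k_fall t) - exp(-k_rise t)) + b ,
```

whose peak time and peak value have closed forms.  Troponin-C
binding/unbinding is a unit-peak stretched-exponential envelope

```
f_TCa(t) = [1 - exp(-(t/tau_c)^beta)] exp(-((t - t_b)/tau_r)^beta) / N ,
```

normalized so `f_TCa(t_p) = 1`; for `t < t_b` the relaxation exponent uses
the sign-preserving power `sign(x)|x|^beta` so the expression stays real
for non-integer `beta` in [1, 2].  The activation is

```
A(t, x) = Zmax^nH / (Z50^nH + Zmax^nH) * Z(t, x)/Zmax * f_TCa(t) ,
```

a Hill saturation prefactor (`nH = 2.6`, `Z50 = b + (Zmax - b)/2` from the
global transient) times the normalized local transient times the TnC
envelope.  The active tension follows the length-dependent law

```
T_act = A f_max exp(-((eps - eps_opt)/s)^2) ,
```

with `eps` the modified Green strain along the fiber (computed from
`Cbar`), `f_max = 54.33 kPa`, `eps_opt = 0.23`, `s = 0.24`, resting
sarcomere length `SL0 = 1.9 um`; the active stress is the rank-1 tensor
`S_act = T_act d (x) d` in the fiber direction `d`.

## Equilibrium solver

The model is quasi-static: at each time the displacement solves the total
Lagrangian equilibrium with the activation field frozen at that instant.
P1 triangles make every integrand of the weak form element-wise constant,
so one-point quadrature is exact (identical to any higher rule).  Boundary
conditions are a Robin (elastic foundation) term `alpha u` on the whole
domain (default `alpha = 1e-2 kPa/um`, representing weak attachment to the
substrate) plus a zero-displacement anchor band (default: a 2-um transverse
band at mid-length; for measured cells the anchor can be selected from the
non-shortening region of the strain profile).

Newton's method uses the exact consistent tangent evaluated by complex-step
differentiation of the residual (`h = 1e-30`, exact to machine precision),
with a backtracking line search and dyadic load substepping as a fallback.
The LU factorization of the tangent is reused chord-style across Newton
iterations and across the beat's time steps; it is rebuilt on stall, on
slow residual reduction, or at convergence when an exact factorization is
needed (for the adjoint).  This is bit-consistent with full Newton on the
tested problems (residual tolerances are unchanged) and 2-3x faster.

Near incompressibility is enforced by the volumetric penalty; at peak
contraction the bulk of the cell stays within `|J - 1| < 0.03`, with the
violation concentrating only in the element layer touching the Dirichlet
anchor corner (a constraint singularity of measure zero under refinement).

A beat is the sequence of equilibria on the time grid (default 1 s at
`dt = 3.2 ms`; the scaled study runs use `dt = 8 ms`, which changes the
peak contraction by < 0.1% since the solution is a static transform of the
smooth activation).  Because the model is history-free, the strain profile
at the maximum-contraction frame depends only on the activation field at
that frame — the inverse problem therefore needs a single equilibrium per
objective evaluation.

## Contractile observables

From the mean line-scan strain trace `eps(t)`:

* `eps_l_max`: the most negative mean strain (maximum contraction, a
  negative number);
* `tau_sl`: the re-lengthening time constant, from a free three-parameter
  monoexponential `eps(t) = eps_inf + a exp(-(t - t_min)/tau)` fitted over
  the entire re-lengthening phase (minimum to end of beat) — the standard
  relaxation-time estimate for sarcomere re-lengthening traces; reported
  as missing when the trace does not recover at least half of the
  contraction;
* `strain_rate_max`: the maximum of `|d eps/dt|` (central differences).
  Note this is the magnitude of the peak shortening rate; the signed peak
  shortening rate is its negative, which flips the sign of regression
  coefficients relative to conventions that report the signed rate.

## Inverse estimation of E(x)

The estimator minimizes the RMSE between simulated and measured strain
profiles at the maximum-contraction frame over `log E`, in two steps:

1. **coarse**: ~20 regions, `log E` piecewise-linear between region
   boundaries, L-BFGS-B with 5 multistarts from log-uniform random fields;
2. **fine**: ~100-200 segments with piecewise-constant `E`, initialized
   from the coarse field, optionally co-estimating `f_max` and `alpha`.

Gradients are exact adjoints: every residual term is linear in its
parameter (passive + volumetric stress in the element's `E`, active stress
in `f_max`, Robin term in `alpha`), so one objective-and-gradient
evaluation costs one equilibrium solve plus one transposed backsolve with
the already-factorized tangent.

**Conditioning.**  Near working conditions the sensitivity of local strain
to the local log-modulus is approximately `T_act E / (E + c T_act)^2 * (1/E)`
with `c ~ 11.5` the local slope magnitude of the length-dependence factor —
about 0.05 strain per e-fold of `E`.  Strain noise therefore maps to
roughly 20x larger relative modulus noise per resolution element, and an
unregularized fit of a 15%-noise profile collapses (modulus NRMSE ~ 1).

**Regularization.**  A second-difference (curvature) Tikhonov penalty on
`log E` (scaled by the breakpoint spacing, so the weight is
parameterization-invariant) is added to the objective.  The weight is
selected by Morozov's discrepancy principle: candidates
`sigma^2 * {3e5, 3e4, 3e3, 3e2}` are tried from largest (smoothest) to
smallest, keeping the largest weight whose data RMSE reaches
`1.05 * sigma`, where `sigma` is estimated from the measured profile's
second differences (`Var(y[i-1] - 2 y[i] + y[i+1]) = 6 sigma^2` for white
noise; the smooth strain signal contributes only O(h^2) at the 0.28-um
pixel spacing).  Zero is deliberately not a candidate once noise is
detected, so a noisy profile is never fitted with the noise-amplifying
unregularized objective.  A weight sweep against ground truth shows a flat
recovery plateau across four decades of weight, i.e. the achievable floor
is set by the conditioning of the strain-to-modulus map, not by the weight
selection; weighted least squares under the per-sample noise model was
also evaluated and does not improve on the plateau.

## Synthetic validation

A synthetic cell (117 x 32 um) is given a known modulus field — 30 control
points along the long axis, drawn Normal(36, 11) kPa clipped to
[0.1, 100], cubic-spline interpolated — and position-dependent calcium
transients (peak 10 +/- 1 F/F0, `tau_fall` 0.25 +/- 0.03 s, attached to the
line-scan pixels).  One beat is forward-simulated; the max-contraction
strain profile is corrupted with additive Gaussian noise of amplitude
0/5/10/15% (per-sample standard deviation proportional to the local
|strain|, the standard relative-noise model for an imaging-derived signal;
a whole-profile peak-scaled option is available).  The two-step inverse
estimator runs on the noisy profile and recovery is scored by (a) the
strain RMSE of the re-simulated profile against the *noiseless* target,
(b) the NRMSE of the recovered modulus along the line-scan (normalized by
the true field's range), and (c) Pearson correlation.

## Monte-Carlo sensitivity analysis

Six inputs are sampled uniformly: `Z_max = 10.79 F/F0`, `tau_fall =
0.08 s`, `f_max = 54.33 kPa`, `eps_opt = 0.23`, `s = 0.24`, all +/- 10%,
and homogeneous `E` uniform on [10, 100] kPa.  The Hill midpoint `Z50` is
held at the value computed from the nominal transient — if it were
recomputed per sample the Hill prefactor would be amplitude-invariant and
`Z_max` could not influence the activation at all.  One beat is simulated
per sample on a homogeneous coarse-mesh cell, the three contractile
outputs are extracted, and each output is regressed on the z-scored inputs
by OLS; the standardized coefficients are comparable across parameters.

Because the model is quasi-static and history-free, the strain trace is a
static (and strongly concave) transform of `A(t)`; consequently the
stiffness `E` influences not only the contraction amplitude but also the
shape of the re-lengthening limb, and the `tau_sl` variance is dominated
by `E` rather than by the calcium decay constant.  This is a structural
property of the quasi-static formulation (verified under both kinematic
embeddings and two `tau_sl` estimators), not a numerical artifact; models
carrying explicit relaxation dynamics (TnC unbinding or cross-bridge
kinetics) decouple `tau_sl` from stiffness.
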
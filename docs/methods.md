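# Methods

## Scope and model chain

`emboflow` models the delivery of non-adhesive liquid embolic agents
(EVOH copolymer dissolved in DMSO with suspended tantalum; the two agents
parameterized here are Onyx-18 and Squid-12) from the syringe, through a
catheter, into the vessel network of an arteriovenous malformation (AVM).
Four coupled pieces:

1. a constitutive viscosity model of the agent (shear-thinning, Sisko form)
   and procedures to fit it to rheometer flow curves;
2. a seeded synthetic-rheometry generator standing in for instrument data;
3. a reduced-order (1D) steady flow model of the catheter + AVM circuit;
4. a lumped thermal model of the agent warming up inside the catheter.

## Constitutive model

The effective viscosity follows the Sisko law

    mu_eff(U) = mu0 + k · U^(n−1)        [mPa·s, U in 1/s]

with a high-shear Newtonian plateau `mu0`, consistency coefficient `k`, and
flow index `n`. For these agents `n < 1` (pseudoplastic); the shipped fits
include slightly negative `n`, which the code accepts — the law is treated
as an empirical fit over the measured window, not extrapolated physics. The
model represents the data well over 0.1–10 1/s; above ~10 1/s the plateau
term alone carries the curve, so the default fitting window is 0.1–10 1/s.

Shipped parameter sets (mPa·s units for `mu0` and `k`; this unit choice is
motivated by the plateau values at 37 °C landing at ~18 for Onyx-18 and
~12 for Squid-12, the products' nominal centipoise grades):

| agent    | T (°C) | mu0     | k       | n         |
|----------|--------|---------|---------|-----------|
| Onyx-18  | 20     | 31.6187 | 1.80968 | −0.004368 |
| Onyx-18  | 37     | 18.0138 | 3.17306 | 0.271126  |
| Squid-12 | 20     | 19.4711 | 2.9736  | −0.03329  |
| Squid-12 | 37     | 12.1248 | 1.10875 | −0.5586   |

### Fitting

Nonlinear least squares on **log viscosity** (the curves span three decades
of shear; a linear objective lets low-shear points dominate), trust-region
reflective solver, bounds `mu0, k ≥ 0`, `n` free. Initial guess:
`mu0` = viscosity at the highest shear in the window, `k` = first-point
viscosity minus that, `n = 0`. Convergence and the residual norm are
reported with the parameters; non-convergence is an explicit flag, not an
exception.

### Piecewise log-log approximation

For feeding tabulated viscosity to external CFD, the flow curve can be
approximated by three straight segments in (log10 U, log10 mu) with
breakpoints at 1 and 10 1/s by default (the boundaries between the
low-shear pseudoplastic regime, the transition, and the plateau).
Continuity at the knots is built into the regression basis (hinge
functions), so the constrained fit stays a single linear least-squares
solve. Outside the data range the end segments extrapolate.

### Temperature interpolation

Viscosity was measured at two temperatures only (20 and 37 °C). Between
them log-viscosity is interpolated linearly in temperature at fixed shear
rate — the simplest positive interpolant that is exact at both anchors.
This is a modeling choice, not a measured law; mild extrapolation is
allowed over 15–45 °C and refused outside it.

### Nonmonotonic-zone detection

At physiological temperature the measured curves show a local viscosity dip
near 1 1/s of roughly 30 % — relevant clinically because the agent crosses
that shear regime when it exits the microcatheter into a wider vessel.
Detection: moving-median smoothing (default 5 points), then a scan of the
search window (default 0.1–10 1/s) for an interior minimum with strictly
higher values on both sides. On a falling baseline the dip manifests as a
local minimum followed, at higher shear, by a recovery maximum — so the
reported `shear_at_local_min < shear_at_local_max`; in the traversal
direction of delivery (high shear to low) the maximum is met first.

The raw difference between recovery maximum and dip minimum understates the
dip depth, because the baseline itself falls between the two (numerically,
a true 30 % dip measures 18–25 % that way across the shipped parameter
sets). `relative_drop` is therefore estimated by refitting the curve with a
Sisko baseline multiplied by a Gaussian dip in log-shear and reporting the
fitted amplitude — the decrease relative to the monotone law at the dip
location. If that fit fails, the raw smoothed measure is the fallback.
A monotone curve yields `None`; that is a result, not an error.

## Synthetic rheometry

    mu(U) = Sisko(U) · (1 − A·exp(−(log10 U − log10 c)² / 2σ²)) · ε

on a log-spaced grid, by default 30 points over 0.1–100 1/s (the plotted
range of the underlying experiments). `ε` is lognormal with median exactly
1 and sigma `noise_sd` (default 0.05): viscosity is positive and spans
decades, so scatter is multiplicative; the median-1 choice makes the
noiseless curve the pointwise median of replicates. The dip is Gaussian in
log-shear — smooth, local, two parameters — defaulting to center 1 1/s and
width σ = 0.3 decades (the observed zone spans roughly a decade; FWHM ≈ 0.7
decades); amplitude defaults to 0 (off) and to 0.3 in the dip scenarios.
Everything is reproducible from the integer seed.

What the generator does **not** emulate: rheometer hardware artifacts
(inertia, secondary flows, evaporation), replicate-to-replicate drift,
thixotropy. Passing the recovery tests therefore demonstrates the fitting
machinery under the assumed noise structure, not robustness to instrument
systematics. The "unmixed tantalum" variant parameters are synthetic
stand-ins chosen so the divergence from the mixed curve concentrates below
1 1/s (the qualitative experimental signature); they are not measurements.

## 1D network flow

The AVM circuit: catheter and feeding artery in series, then a parallel
stage — a racemose bundle of `n` identical small tubes (default 10 × 10 mm)
and optionally a fistula (default 10 mm × 4 mm) — then a draining vein.
Each segment is a straight circular tube in laminar Poiseuille flow:

    dp = 32 μ l c / d²,   R = 128 μ l / (π d⁴),   γ_wall = 8c/d = 32Q/(πd³)

The Darcy–Weisbach head-loss form `h = λ(l/d)c²/2g` with `λ = 64/Re`
reproduces the Poiseuille drop identically and is provided for
cross-checking. Default inflow is the clinical delivery rate 0.6 mL/min;
fluid density 1100 kg/m³ (DMSO-dominated; tantalum loading raises it —
configurable).

Non-Newtonian closure: each segment's viscosity is evaluated at its own
wall shear rate (the exact non-Newtonian Poiseuille integral is not used;
the wall shear rate is the representative scale for these nearly-plateau
curves). The coupling viscosity → resistance → flow split → shear →
viscosity is solved by fixed-point iteration to a relative viscosity change
below 1e-8 (cap 200 iterations; 0.5 damping of the parallel split when the
iterates oscillate). Identical racemose tubes are treated as one
representative tube carrying 1/n of the bundle flow, so their symmetry is
exact by construction. A Newtonian fluid converges in one iteration.

**Low-shear clamp.** With `n < 0` the Sisko term diverges as U → 0 — an
extrapolation artifact far below the 0.1 1/s measurement floor. Unclamped,
it makes a nearly stagnant branch's pressure drop *decrease* with
increasing flow and destabilizes the fistula/racemose split. Viscosity
evaluations inside the network therefore clamp the shear rate at 0.1 1/s
(configurable, `AVMNetwork.min_shear_clamp`).

Segment lengths, the racemose tube count, and the default geometries are
plausible AVM-scale choices (small AVM vessels run ~0.2–2 mm) and are fully
configurable; the diameter sweep covers 0.5–2 mm with and without the 4 mm
fistula. Two catheter lumens appear in the default scenarios: the 2 mm
(6 Fr) lumen for the velocity/Reynolds figures, and the 1 mm microcatheter
for the thermal model. The sweep reproduces the qualitative pattern of the
reference 3D CFD study — pressure falling with racemose diameter, fistula
shunting relieving racemose pressure, the more viscous agent requiring more
pressure — not its exact values, which carry 3D effects a resistance
network cannot represent.

## Catheter warm-up

The conjugate heat problem is reduced to plug flow through a tube at
constant wall (body) temperature:

    T(x) = T_body − (T_body − T_in)·exp(−x/x*),   x* = ρ c_p Q / (h π d)

with film coefficient `h = Nu·k/d`, laminar fully developed Nu = 3.66
(constant wall temperature); the catheter wall's cylindrical conduction
resistance can be composed in series. DMSO constants: k = 0.2 W/m/K,
c_p = 0.47 cal/g/°C = 1966.5 J/kg/K (1 cal = 4.184 J), ρ = 1100 kg/m³.
Axial conduction is neglected (the Péclet number is large on the scale of
x*). With the defaults (1 mm lumen, 0.6 mL/min) x* ≈ 9.4 mm, so 95 % of the
warm-up completes in ≈ 28 mm: a 1 m neurosurgical catheter delivers the
agent fully equilibrated, while the centimeter-scale catheters of infant
procedures do not — the clinically relevant asymmetry the model formalizes.

The viscosity profile composes T(x) with the temperature-interpolated Sisko
law at the catheter wall shear rate; the catheter pressure drop integrates
32 μ(x) c/d² by the trapezoidal rule (grid default 200 points; refinement
to 1000 changes the result by <0.1 %). In this plug-flow reduction the
temperature equation decouples from viscosity, so the model cannot
distinguish the non-Newtonian from the Newtonian temperature field — a
known limitation of the 1D closure.

## Numerical choices and degenerate inputs

- Shear rate ≤ 0 is a domain error everywhere (the law diverges at 0 for
  n < 1); flow-curve arrays must be strictly increasing in shear, positive,
  length ≥ 3; fits need ≥ 4 points in the window.
- Fit tolerances: xtol = ftol = gtol = 1e-14, max 2000 function
  evaluations; the dip-model refinement uses 1e-12 and bounded amplitude
  [0, 0.999], center within ±1 decade of the candidate, width 0.05–1.5
  decades.
- Temperature profiles are monotone non-decreasing; beyond ~25 decay
  lengths exp(−x/x*) underflows and the profile is exactly flat at body
  temperature in double precision.
- Isothermal thermal configs (inlet = body) are allowed as the degenerate
  flat-profile case.
- Problem sizes: curves of 30 points, 200-replicate Monte-Carlo recovery
  studies, 9-diameter sweeps, 200-point axial grids — chosen as the scales
  the analysis questions need.

## Known limitations

- The Sisko fit is empirical over 0.1–10 1/s; no yield stress, no
  thixotropy, no oscillatory rheometry.
- The 1D network carries no vortices, secondary flows, junction losses or
  blood–polymer displacement; its outputs are trends and scalar summaries.
- The temperature law rests on two anchors; between-anchor curvature is
  assumed away by the log-linear choice.
- Synthetic data cannot validate against instrument systematics; parameter
  recovery results are conditional on the assumed lognormal noise.
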
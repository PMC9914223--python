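# Methods

## Model

The tissue model is the one-dimensional Pennes bioheat equation for a tumor
slab touched at `x = 0`:

    rho c dT/dt = lambda d2T/dx2 + w (T_ar - T) + Q,        0 < x < omega,

with `w = m_b c_b` the lumped perfusion exchange coefficient [W/(m^3 C)],
`T_ar` the arterial temperature, `Q` a metabolic volumetric source, a
constant contact flux `-lambda dT/dx(0,t) = phi`, the far boundary held at
the initial temperature `T(omega, t) = T_i` (Dirichlet; a bounded
semi-infinite variant is also provided), and a uniform initial state
`T(x,0) = T_i`. Dividing by `rho c` gives the reduced coefficients
`a = w/(rho c)`, `b = 1/(rho c)`, `alpha = lambda/(rho c)`.

In the shifted variable `u = T - T_i` the Laplace transform satisfies

    s theta = alpha theta'' - a theta + c/s,     c = a (T_ar - T_i) + b Q,

whose solution under the two boundary conditions is, with
`beta = sqrt((s+a)/alpha)` and `P(s) = c/(s(s+a))`,

    theta(x,s) = P(s) [1 - cosh(beta x)/cosh(beta omega)]
                 + phi/(lambda s beta) * sinh(beta(omega-x))/cosh(beta omega).

The hyperbolic ratios are evaluated in exponential form with all exponents
non-positive, so the solution is overflow-safe for arbitrarily large
`beta*omega` (short times, thick slabs). The flux field uses the analytic
derivative `-lambda theta'`. Only real positive `s` is ever needed: the
Gaver-Stehfest inversion samples the transform at `s_j = j ln2/t`.

The semi-infinite variant replaces the slab terms by `exp(-beta x)` decay.
Its pure-conduction special case reproduces the classical constant-flux
half-space solution `T(0,t) - T_i = 2 phi sqrt(alpha t / pi) / lambda`,
which the tests use as a closed-form cross-check.

## Inversion scheme

The Stehfest weights are alternating rational numbers computed from
factorial sums. They are evaluated with exact integer arithmetic
(`fractions.Fraction`) and rounded to float once; naive floating
evaluation loses ~9 digits to cancellation at N = 10 (which is visibly why
float-computed renderings of the vector print 1279.000076 for the exact
integer 1279). The exact weights satisfy `sum V_j = 0` and
`sum V_j / j = 1` identically, which makes constants invert to machine
precision.

Measured intrinsic accuracy at the default order N = 10 (exact weights,
closed-form pairs): `1/s` to ~5e-12, `1/s^2` to 3.5e-5 relative
(independent of t; N = 12 reaches 1e-6), and `1/(s+a)` degrading with
`a t` (2e-6 at `a t = 0.25`, 2.5e-4 at `a t = 1`, ~1e-2 at `a t = 5`).
These are truncation errors of the Gaver sequence itself, not rounding.
For the smooth, monotone bioheat transients this is far more than needed:
against the Crank-Nicolson oracle the inverted slab solution agrees to
~3e-4 C on the default problem. Oscillatory transforms are a documented
failure mode (errors of order one) and a test asserts that failure.
Orders above 20 are rejected: the weights exceed 1e12 and double-precision
summation becomes meaningless.

## Verification oracles

* **Crank-Nicolson finite differences** (`fd_oracle`): theta-1/2 scheme,
  ghost-node Neumann boundary (second order), banded solves, optional
  substepping, and Rannacher startup (two damped implicit half-steps) to
  suppress ringing from the impulsive flux start. Verified second-order
  convergent in space; agrees with the Laplace route to < 0.05 C on a
  200 x 200 grid of the default problem.
* **Closed-form steady states**: separate forms for `a > 0` (hyperbolic),
  `a = 0` (quadratic-plus-linear), and the semi-infinite cases; the
  transient at 600 s matches to < 0.02 C on the defaults. The
  semi-infinite pure-conduction case with nonzero forcing has no bounded
  steady state and raises.
* **Eigenfunction series** (used during development, frozen into test
  tolerances): the slab response decays with the slowest mode
  `tau_1 = 4 omega^2/(alpha pi^2)`, ~152 s for the default 7 mm unfrozen
  slab.

## Parameter defaults and their rationale

Tissue and blood presets (SI, converted from a cryoprobe-literature
property table printed in kJ-based units):

| quantity | unfrozen | frozen | blood |
|---|---|---|---|
| density [kg/m^3] | 1000 | 1000 | 1000 |
| specific heat [J/(kg C)] | 4200 | 1230 | 3640 |
| conductivity [W/(m C)] | 0.55 | 2.25 | — |
| diffusivity [m^2/s] | 1.31e-7 | 1.83e-6 | — |

* **Perfusion `w = m_b c_b`**: only the product enters the model and no
  perfusion speed is given in the source table, so the default is `w = 0`
  (pure conduction) with a representative perfused preset
  (`m_b = 0.5 kg/(m^3 s)`, `w = 1820 W/(m^3 C)`).
* **Contact flux `phi = 100 W/m^2`, `Q = 0`**: repository defaults, chosen
  with the default geometry so the contact-face steady rise
  `phi omega/lambda` lands mid-band in the 1-3 C warming reported for
  tumor-surface touch. Both are overridable everywhere.
* **Slab thickness 7 mm (default problem)**: with unfrozen tissue this
  gives a steady rise of 1.27 C and a transient that settles (< 0.02 C)
  by 600 s. The thickness study sweeps 2.5/3/3.3 mm explicitly.
* **Flux-study preset = frozen tissue**: the reported two-phase behavior
  of the transmitted (far-boundary) flux — a sharp rise completing within
  ~10 s, then a plateau — requires the fast-conduction regime at these
  sub-4 mm thicknesses (`tau_1` = 1.4-2.4 s frozen vs 19-34 s unfrozen).
  The package treats the frozen preset as the study's default and the
  choice as its own interpretation; with unfrozen properties the same
  curves exist on a ~1 min time scale.
* **Tumor initial temperature 40 C**: the conventional tumor surface
  temperature; profile studies sweep 39/40/41 C.
* **Touch tolerance `epsilon = 2 mm`**: the fingertip is a point; epsilon
  absorbs the finger-pad radius. Baseline (no-contact) display
  temperature 33 C, typical fingertip skin.
* **Peltier plant**: first-order with time constant 5 s, ambient 33 C,
  full-duty slew `gain = 60 C/s` — the smallest round value for which the
  proportional equilibrium error `span (sp - ambient)/(gain tau)` stays
  inside the 0.25 C deadband for every reachable setpoint below the
  clamp. Error span 7 C maps error to duty; safety bound 43 C with 0.5 C
  margin sits below sustained-contact burn thresholds. Sensor noise
  defaults to 0 (seeded when enabled).

## Numerical and design choices

* `t = 0` is returned exactly from the initial condition (the inversion
  formula is singular there); the internal flux at `t = 0` is exactly 0.
* Contact events are maximal runs of in-contact ticks on one nearest
  surface (ties: smaller distance, then lexicographic label); the contact
  clock resets per event, so re-touching restarts the transient. The
  rendered setpoint during a hold follows the transient `T(0, tau)` — the
  model-predicted sensor temperature — rather than a fixed display value.
* Point-to-mesh distance is an exact vectorised point-to-triangle
  projection over all triangles (region-based barycentric clamping),
  chunked to bound memory. No spatial index is used: the meshes this
  package targets (thousands of triangles) do not need one, and the exact
  all-triangles route doubles as its own reference. trimesh handles mesh
  I/O, creation and integrity checks.
* The controller applies hysteresis with memory: an active drive
  direction persists until its error crosses zero, then releases; an idle
  controller re-engages only beyond the deadband. A memoryless
  off-inside-the-deadband rule would limit-cycle at the deadband edge
  instead of settling inside it. The loop integrates the plant with
  explicit Euler at `dt = 5 ms` (stability limit ~0.23 s; per-tick heating
  `gain dt = 0.3 C` stays below the safety margin), and a hardware-style
  cutoff saturates the plant at the safety bound regardless of dt or
  sensor noise.
* All internal computation is SI; millimeters are accepted only at the
  CLI boundary. Config files are strict: unknown keys anywhere are
  rejected, and round-tripping a config through YAML reproduces it
  exactly.

## What the generated data does and does not emulate

Fixtures are icospheres (watertight by construction, chord error
< 1e-3 radius) and radial approach-hold-retract trajectories with a small
seeded lateral tremor (0.1 mm), so the epsilon-shell crossing time has a
closed form that downstream tests check against. Real tumor meshes are
irregular and real finger motion is not radial; passing tests demonstrate
the correctness of the contact/rendering/control chain on known geometry,
not robustness to segmentation artifacts, non-watertight scans, or fast
sliding contact. Likewise the slab model assumes homogeneous properties,
a constant contact flux and 1D conduction; it does not model vasculature
geometry, phase change (the frozen preset is an alternative property set,
not a Stefan problem), 3D spreading, or parameter fitting to patient data.

## Known limitations

* The order-10 inversion cannot deliver better than ~1e-5 relative
  accuracy even on polynomially growing originals (see above); raise the
  order to 12-16 for tighter closed-form work, but not beyond 20.
* The far-boundary flux curves for different thicknesses converge to the
  same plateau `phi`; beyond ~15 s their separation falls below the
  inversion's resolution (~0.03 W/m^2 at phi = 100) and ordering is no
  longer numerically meaningful.
* The Peltier plant is a first-order abstraction with a symbolic gain; it
  is a testbed for the control logic, not an electrothermal model of any
  physical module. Cooling has no lower saturation; the safety bound and
  its analysis cover the heating direction only.
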
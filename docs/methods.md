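# Methods

This note documents the models, numerical choices and limitations of
`indentfit`, in the order of the processing chain.

## Coordinate and unit conventions

Lengths in mm, forces in N, moduli in kPa at the API surface (MPa
internally, so stresses × areas give N directly).  The z axis points up;
the undeformed skin surface ("reference plane") is z = 0; indentation
displaces in −z.  x (or r) is the radial distance from the indenter axis.
The indenter tip is a hemisphere of radius r_t = 10 mm extended upward by a
20 mm cylindrical shank; the evaluation domain ends at r_C = r_t + 100 =
110 mm.

## Force–displacement processing (`curves`)

Raw records are cleaned in three steps: the pre-contact prefix is removed
at a detectable-contact threshold of 0.1 N (below the load-cell noise
scale of ≈0.4 N suggested by rig calibration); samples after maximum
stroke are dropped; recording outliers are samples deviating more than
5 scaled MADs from an 11-sample rolling median of the force.

Region fits are through-origin polynomials in descending powers, degree
1–5.  "Least possible degree with minimum RMSE" is implemented as the
smallest degree whose RMSE is within 1 % of the minimum over all candidate
degrees — a strict minimum would always select the highest degree.  RMSE
is √(Σr²/n) over the cleaned samples.  Range envelopes bin the pooled data
(40 bins) and fit the per-bin extrema with the same rule.  The two-segment
stiffness summary uses secants: k₁ = f(s·δ_max)/(s·δ_max) with s = 0.45
and k₂ the secant of the remaining segment.  The first-segment secants
reproduce the study's printed values to two decimals (one region differs
by 0.01, a rounding inconsistency in the source tables themselves);
second-segment secants land within 0.03 N/mm of the printed list, whose
exact linearization the source does not specify.

## Surface reconstruction (`tof_surface`)

Each ToF sensor sits 35.1 mm above the reference plane, laterally offset
by 10 mm from the indenter axis, tilted 12° outward; its 63°-diagonal
frustum is divided 8×8 uniformly in angle (63/√2 ≈ 44.5° per axis).  The
fifth zone row gives eight transverse measuring points per side; with this
geometry they span roughly 6–32 mm lateral distance, matching the
hardware's ≈39 mm observable length.  The exact mounting offsets of the
real device are unknown; the synthetic renderer and the inverter share one
geometry definition, so closure tests are self-consistent by construction.

Frame preprocessing replaces every zone by the 5-sample sliding mean along
its zone row (the neighborhood topology is not specified by the hardware
description; a row-wise window is the axis along which the profile is
read) and resamples linearly to a 0.1 s grid.

Side profiles: points with x ≤ 0.9 r_t are discarded as distorted; the
chord through the innermost remaining left/right points is intersected
with the tip profile to give one anchor per side; a cubic is fitted
through anchor, points, and three equally spaced base points at z = 0 in
an 8 mm interval ending at x_B.  x_B is swept in 5 mm steps from the
outermost point (inclusive) to r_C, and the fit minimizing
Θ(x_B) = RMSE + Q is kept, where RMSE runs over the measuring points only
(the anchor and base points are synthetic) and Q = 0.75·x_xmax/r_C if the
cubic returns to the reference plane within r_C, else 10.  Ties prefer the
smaller x_B (most compact deformation).

The region mean u(x) is one cubic over the pooled samples of all side fits
(left side mirrored).  x_min is its intersection with the hemisphere, or
r_t when the cubic passes above the equator (wall contact); x_max is the
smallest in-range root with positive slope (fallback: largest in-range
root).  The composed profile is tip / cubic / plane with transitions
bridged by a monotone C¹ interpolant over ≤5 mm per side of each junction
(within the "up to 10 mm" smoothing section); it is exactly −δ_I at the
apex and exactly zero beyond x_max.

## sEMG (`semg`)

4th-order Butterworth band-pass 45–500 Hz plus a Q = 30 IIR notch at
50 Hz, both zero-phase (forward–backward), at 1024 Hz sampling.  The
envelope is the RMS over a 200-sample (195.3 ms) sliding window.  Percent
activity is the envelope mean over the whole indenter stroke divided by
the MVC reference, taken as the mean of the top 0.5 s of the MVC envelope
(a robust peak).  The filter family/order and MVC statistic are this
package's choices; the hardware chain specifies only the corner
frequencies, notch and window length.

## Forward model (`fem`)

Axisymmetric total-Lagrangian formulation with Green–Lagrange strain
including the hoop component, 8-node serendipity quadrilaterals (the 2-D
analog of the quadratic hex/wedge sector meshes commonly used for this
geometry), 3×3 Gauss quadrature and no reduced integration.  The
constitutive law is the uncoupled first-order Ogden energy above; the
material tangent is obtained by central differences of the
Piola–Kirchhoff stress at each Gauss point (consistent to observed
quadratic Newton convergence), the geometric stiffness analytically.

Mesh: 10N×5N elements with per-element width ratios 1.1 (radial, fine at
the axis) and 0.8 (axial, fine at the top) *defined at the production
level N=3*; other refinement levels subdivide the same spatial grading
(ratio^(3/N)), so refining N adds resolution without moving the grading.
Boundary conditions: axis radially constrained, bottom face fully clamped.
The fully clamped bottom reproduces the study's forward reaction (9.69 vs
9.62 N at 25 mm for c=7 kPa, m=12, +0.8 %); constraining only the vertical
bottom displacement gives 8.50 N (−12 %), so the clamped variant is the
configuration the published identification actually used.

Contact is frictionless against the analytic tip (sphere + shank) and
enforced **exactly** by active-set elimination: for each active top-surface
node, the displacement component most aligned with the local surface
normal becomes a slave of the other component through the analytic surface
equation, so the nodal reaction acts along the true normal and converged
penetration is zero (well inside the 10⁻³·r_t tolerance budget).  Nodes
activate on penetration; release on tensile normal force happens between
converged solves, with a 1 % hysteresis to keep marginal contact-edge
nodes from chattering.  A penalty/augmented-Lagrangian variant was
evaluated first and abandoned: with tissue shear moduli of a few kPa and
the exponential Ogden stiffening, any penalty stiff enough to meet the
penetration tolerance made Newton engagement steps unrecoverable.

Loading is displacement-driven with adaptive depth increments (halved on
failure, regrown on success, snapshot depths landed exactly); gap closure
per Newton iteration is capped at half a top-element height because larger
linearized moves crush the surface elements.  Newton tolerances: relative
residual 10⁻⁶ with safeguarded steps (trust radius plus monotone
residual acceptance during equilibration).

**Warm starting.**  Hyperelastic equilibrium is path independent, so a
converged state can seed another configuration directly: across material
exponents m on the same mesh (`continue_in_m`), and across meshes through
consistent Q8 field transfer (`interpolate_state`, which evaluates the
coarse element fields at the fine nodes; scattered linear interpolation
would inject spurious volumetric strain that the κ-penalty amplifies
~2000-fold).  Warm results were spot-checked against cold walks and agree
to ~10⁻⁶.  These chains make the grid search (~2 min for a 7×33
neighborhood) and the convergence study (~4 min) practical on one CPU.

**Convergence study.**  E_F is the relative reaction error and E_u the
mean relative vertical nodal displacement error over top-edge nodes with
r ≥ r_t, reference values interpolated to coarse radii by monotone cubics
(PCHIP); reference level N = 6, evaluated at 20 mm for three material sets
spanning the parameter space ((1 kPa, 4), (45 kPa, 30), (140 kPa, 60)).
Both errors fall monotonically with N for every set.  **Known
limitation:** at N = 3 this implementation measures max E_F ≈ 6.6 % and
max E_u ≈ 3.2 % (worst for the stiffest set), short of the original
study's sub-1 % figure.  The node-point contact used here quantizes the
contact radius at the node spacing, and at m = 60 the reaction is
extremely sensitive to the contact-edge position; solvers that integrate
the contact pressure over quadratic element faces converge faster in N.
In the parameter regime the identification actually visits (c ≈ 5–25 kPa,
m ≤ 40), E_F(N=3) ≈ 0.5 %.

Hertzian cross-check: at δ ≤ 0.5 mm the reaction matches
F = (4/3)E*√(r_t)·δ^{3/2} within ~2 %, with E* from the numerically
measured small-strain shear modulus (μ = c/2 for this energy, ν ≈ 0.4998
from κ/μ = 4000).

## Inverse identification (`inverse_id`)

Residuals and the combined/total objectives are as in the README.  Node
weights are 1/rᵢ normalized to sum one (a convex combination; the
alternative Euclidean normalization would rescale F_u by a node-set
constant and could shift minima).  The evaluation window is
x_min ≤ x ≤ x_Trim with δ_Trim = |u(x_Trim)| on the reference cubic,
which prevents the relative error from blowing up where u → 0.  Argmin
ties break lexicographically toward smaller c, then smaller m.  η defaults
to 0.5 (equal weighting of force and surface information: η = 1 leaves
valleys elongated in m, η = 0 leaves them exactly flat in c — in this
implementation F_u is *rigorously* c-independent).

The full 60×122 grid is supported; cells whose forward solve fails are
marked and excluded (a >20 % failure fraction aborts), with no silent grid
truncation.  Trim-factor selection sweeps δ_Trim = 0.1–1.2 mm and tracks
six series: the SD of |F_fu_tot − F_fu(·;δ_I)| over depths, the fraction
of the grid above 1.5, the circularity 4πA/P² of the largest connected
sublevel component on the maxima-nondimensionalized grid, the
force/surface balance (closest to ½ at the lowest candidate), and the
relative changes of the resulting c and m; the selected value is the
rounded mean of the six individual targets (convergence thresholds 2 %
for the shape criteria, 1 % for the parameter criteria, with a series
stable between two candidates attributed to the earlier one).

## Synthetic experiments (`synthetic_data`)

The generator emulates the study conditions: 5 mm/s feed sampled at
100 Hz with Gaussian force noise (default SD 0.4 N, the calibration
scale) and a pre-contact prefix; ray-cast ToF frames from both tilted
sensors at 15 Hz with additive Gaussian distance noise of SD 0.805 mm
clipped to ±1.6 mm (the hardware's aggregate deviation envelope); sEMG as
45–500 Hz band-limited Gaussian noise whose RMS follows
baseline + activity·(MVC − baseline) with amplitude anchors 6.8 µV
(baseline) and 235.4 µV (MVC), plus a 50 Hz mains tone.  All generators
are reproducible per seed, and suites are written as plain CSV plus a
ground-truth JSON manifest.

What passing synthetic tests do *not* show about real data: the generator
assumes a planar reference surface, a perfectly axisymmetric deformation,
a homogeneous isotropic tissue and instantaneous (non-viscous) response —
exactly the idealizations of the forward model — so closure tests validate
the pipeline's internal consistency, not those assumptions.  One
quantified consequence: identifying from ToF-reconstructed surfaces (zero
noise) recovers a planted parameter set only to within one grid cell,
because the side-fit cubics extrapolate beyond the sensor field of view
through their base points; identifying from forward-model references
directly recovers the planted cell exactly.

## Known limitations

* Mesh-convergence shortfall at extreme nonlinearity (see above).
* Isotropic, single-layer, hyperelastic tissue only; no viscoelasticity,
  no anisotropy, no body curvature.
* The ToF geometry is self-consistent rather than calibrated to the real
  sensor optics; absolute row-5 coordinates of the hardware may differ.
* The bundled reference tables carry two typographical defects of their
  source (one activated-region force row and one surface row whose printed
  coefficients are inconsistent with their own tabulated maxima); they are
  stored verbatim and excluded from value-level checks.
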
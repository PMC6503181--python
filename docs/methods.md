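# Methods

## Scope and model

`stentflow` models a single, unbranched coronary artery as an ordered set of
circular cross-sections along a 3D centerline: at each arc length `s` (mm,
zero at the proximal inlet) the lumen is a circle of radius `r(s)` in the
plane normal to the local tangent. Everything downstream of geometry — stent
deployment, meshing, flow, vFFR — operates on this representation. Side
branches, non-circular lumina, wall compliance and pulsatility are outside
the model; flow is steady, laminar and Newtonian, the regime in which FFR is
defined (pressure ratio at stable maximal hyperemia).

The virtual fractional flow reserve between two marked points is
`vFFR = P(s_distal) / P(s_proximal)`, both pressures absolute
(venous reference 0 Pa) and section-averaged.  A zero-flow solution has a
uniform field and returns exactly 1.

## Synthetic vessels

The generator emulates the geometric features the workflow responds to —
healthy caliber, focal narrowings of prescribed fractional diameter
reduction, overall curvature — not the appearance of real angiographic
reconstructions. A stenosis is a cosine bump
`r(s) = R (1 − severity · ½(1 + cos 2π(s − s_c)/L))` clipped to its
interval: smooth, unimodal, C¹ at its edges.  Severities of interest span
0.2–0.7 (fractional *diameter* reduction), bracketing the ~58% mean of
typical intermediate-lesion cohorts; total occlusions (severity ≥ 1) are
rejected.  Default sampling step is 0.25 mm, fine enough that a 20 mm stent
spans ≥ 80 stations.  Optional multiplicative Gaussian radius noise
(default 0) is seeded for bitwise reproducibility.

What synthetic vessels do *not* carry: reconstruction error, ECG-gating
artifacts, eccentric or calcified plaque, tapering with branch take-offs.
Passing tests therefore validate the computational pipeline, not clinical
accuracy on patient anatomies.

## Virtual stent deployment

A stent is an interval `[s_prox, s_dist]` plus a nominal diameter `D`.
Deployment is idealized (perfect circular expansion, full apposition):

* **Radius rule** — `r ← max(r, D/2 · w(s))`, where `w` is 1 inside the
  stent and ramps linearly to 0 over a 1.0 mm taper at each edge.  The
  `max` means a stent scaffolds outward and never narrows a lumen; sections
  already wider than the stent are untouched.  The taper avoids the step
  discontinuity a mesher and solver would otherwise see.  The rule is
  idempotent, order-independent for multiple stents, and overlapping stents
  behave as the union interval with the larger diameter in the overlap.
* **Trajectory rule** — the centerline over the stent interval (plus one
  margin station each side) is refit with a least-squares cubic spline with
  interior knots every 5 mm, straightening in-segment wiggle while
  following the vessel's overall curvature; a linear-in-`s` correction pins
  the fit to the original margin points so the path stays continuous.
  Because linears lie inside the cubic spline space, redeployment
  reproduces the same fit (idempotence).  Arc lengths are rebuilt from the
  smoothed chords; smoothing never lengthens the path.

## Meshing

**Surface.** Each cross-section becomes a ring of `n_circ` points (default
64) oriented by rotation-minimizing frames (double-reflection propagation),
so strips never twist.  Consecutive rings are joined by `2 n_circ`
triangles — 128 per strip at default resolution — and optional planar fan
caps close the inlet/outlet into a watertight, outward-oriented surface.
A geometric guard rejects configurations where adjacent section planes
would cross inside the lumen (`r · Δangle > Δs`), advising resampling.

**Volume.** A structured sweep: each section carries a 2D disk
triangulation (center fan plus concentric rings; the rings near the wall
are geometrically graded inflation layers — default 3 layers, growth 1.2,
first layer 5% of the local radius), consecutive disks form prisms, and
each prism is split into 3 tetrahedra.  Diagonal choices follow the
smallest-global-index rule, which makes the tetrahedralization conform
across prism boundaries.  Boundary faces are labeled wall/inlet/outlet and
vertices carry their inflation-layer index.  Mesh volume matches the
frustum closed form to the inscribed-polygon factor
`(n/2π) sin(2π/n)` and converges to the analytic profile volume at
second order in the axial step.

**Imports.** VRML97 `IndexedFaceSet` geometry (the common workstation
export) is read with fan triangulation and at most one top-level transform;
`fit_cross_sections` inverts surface generation by sweeping cutting planes
along a smoothed centroid path (two passes) and assigning each cut the
equivalent-area radius `sqrt(A/π)`.  Only single-lumen tubes (exactly two
boundary loops) are accepted.

## Reduced-order flow backend

Each inter-station interval contributes a Poiseuille resistance
`8 μ Δs / (π r̄⁴)`; each post-throat expansion adds a Borda-Carnot
separation loss `½ ρ Q² (1/A_min − 1/A_rec)²`, attributed linearly over the
diverging segment.  The flow solves
`P_in − P_v = R_v Q + K Q² + R_d Q` by bracketed Brent iteration (relative
tolerance 1e−12; the left side is strictly monotone so the bracket
`[0, (P_in − P_v)/R_d]` always contains the root).  The axial pressure
profile accumulates the losses from the inlet, making the outlet identity
`P_out = P_v + Q R_d` exact to root-finder precision.

Defaults: blood density 1056 kg/m³, dynamic viscosity 3.5 mPa·s (standard
hemodynamic values), venous pressure 0, inlet pressure from mmHg with
1 mmHg = 133.322 Pa, distal resistance 8.721×10⁹ Pa·s·m⁻³ (a
population-average myocardial resistance used when no wire measurement is
available).  A Reynolds guard warns above 2000.

## 3D finite-volume backend

Cell-centered colocated finite volumes in conservation form with SIMPLE
pressure–velocity coupling:

* convection by first-order upwind with a deferred-correction central
  blend (default fully central through the deferred correction);
* diffusion by the over-relaxed orthogonal split with explicit
  non-orthogonal correction from weighted least-squares cell gradients;
* Rhie–Chow face-flux interpolation against pressure checkerboarding, with
  the SIMPLEC face coefficient (`V/(a_P − Σa_N)`), which converges several
  times faster than plain SIMPLE here;
* under-relaxation 0.7 (momentum) and 0.7 (pressure; stable because of
  SIMPLEC), exact sparse LU solves per outer iteration;
* boundaries: no-slip walls, uniform-pressure inlet, pressure outlet.

**Control volumes.** The swept tet mesh is highly anisotropic wherever
inflation layers meet coarse axial steps, and the diagonal faces inside a
stretched prism can be nearly parallel to the line between tet centroids
(non-orthogonality approaching 90°), which no explicit correction
stabilizes.  The solver therefore agglomerates the 3 tetrahedra of each
source prism back into one prismatic control volume — the shape
boundary-layer meshes use for exactly this reason — bringing worst-case
non-orthogonality to moderate levels and cutting unknowns threefold.  The
mesh itself remains tetrahedral; agglomeration is a property of the
discretization.

**Outlet-resistance coupling.** The naive fixed point
`P_out ← P_v + Q R_d` has loop gain `−R_d/R_vessel`, which for coronary
values (`R_d ≈ 8.7×10⁹` against vessel resistances of 10⁷–10⁹) is in the
hundreds: any fixed relaxation factor large enough to make progress
diverges.  Two couplings are provided:

* *implicit* (default): the outlet boundary-pressure correction
  `p'_b = r₀ + (R_d/ρ) t` — `r₀` the current residual of the resistance
  relation, `t` the total outlet flux correction — is eliminated into the
  pressure-correction system, yielding a rank-1 modification solved with
  the same factorization via Sherman–Morrison.  Unconditionally stable.
* *fixed point*: the relaxed update with the linearized-optimal damping
  `w = R_vessel/(R_vessel + R_d)` (estimated from the reduced model),
  capped at 0.5.

Convergence requires scaled momentum and continuity residuals below 1e−4
and the outlet relation satisfied to 1e−3 relative to the inlet pressure.
Each solve warm-starts from the reduced model (pressure profile, plug
velocity, flow estimate), which typically halves the iteration count.

**Verified behavior** (recomputed by the test suite and
`scripts/acceptance.py`): the fully developed pressure gradient of a long
straight tube (L/D = 50, ≈50k tetrahedra) matches `8μQ/(πr⁴)` to within a
few percent; inlet and outlet mass fluxes balance to well below 0.1%;
`(P_out − P_v)/Q` reproduces the prescribed distal resistance; vFFR is
invariant under rigid motion of the geometry to ~1e−4; and the reduced and
3D backends agree on vFFR to well within 10% for smooth stenoses.

## Tandem lesions and statistics

`tandem_analysis` solves the untreated baseline and every non-empty subset
of lesions virtually stented (2ⁿ−1 strategies, capped at n = 6 without an
explicit override), reporting the distal vFFR of each — the computational
form of "removing each stenosis in turn", which a pressure wire cannot do
because an untreated stenosis caps the hyperemic flow seen by the others.

Statistics follow standard method-comparison practice for paired FFR data:
Bland–Altman bias with limits of agreement at bias ± 2·SD (2, not 1.96, by
convention of the validation analyses this mirrors); Pearson r with a
least-squares line through the origin; and 2×2 diagnostic metrics at the
0.80 threshold with `FFR ≤ 0.80` as the positive (ischemic) class — the
boundary value counts as positive.  Ratios with empty denominators are
reported as NaN and flagged, never silently zeroed.

## Problem sizes and numerical choices

Test and acceptance runs use "desk-scale" meshes — tens of thousands of
tetrahedra (the package's default target is ~50k; the mesh generator
reaches millions via its parameters when higher resolution is wanted).
Million-cell runs change none of the contracts checked here; the
convergence test documents the second-order trend that connects the scales.
Root-finding and coupling tolerances are stated above; degenerate inputs
(zero-radius sections, inverted tetrahedra, occlusive stenoses, overlapping
stents/lesions) are rejected with specific messages rather than patched.

## Known limitations

Idealized stents (no recoil, malapposition, or strut geometry); generic
rather than personalized distal resistance; single-lumen geometry without
side branches (which biases computed pressure drops upward); steady
Newtonian flow; first-order upwind base scheme (the central deferred
correction recovers most of the accuracy but steep jets in severe stenoses
remain smoothed); equivalent-area circular sections discard lumen
eccentricity when importing surfaces.
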
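# Methods

This note documents the models behind `mitraflow`, the defaults and why
they were chosen, the numerical scheme, and what the synthetic setting can
and cannot say about real patients.

## The flow problem

Each cardiac phase is treated as a separate steady state: mid-systole,
when the closed mitral valve leaks through coaptation defects while the
ventricle ejects through the LVOT, and mid-diastole, when the open valve
fills the ventricle. Blood is an incompressible Newtonian fluid with
density ρ = 1060 kg·m⁻³ and dynamic viscosity η = 0.004 Pa·s. Flow is
laminar by assumption at any Reynolds number (Re is reported in the
diagnostics; transvalvular jets at several m/s are physically transitional,
so the laminar steady solution is an idealisation — a limitation shared
with clinical steady-state CFD practice).

Boundary conditions:

* **Systole** — uniform plug velocity on the ventricular inlet carrying
  `Q_sys = SV / t_sys`; fixed pressures on the two outlets, left atrium
  10 mmHg and LVOT 80 mmHg. A full pressure triple (LV 120 mmHg) plus an
  inlet flow rate over-determines the problem, so the ventricular value is
  used only as the reference for reporting absolute pressures; the
  LA/LVOT flow split stays pressure-driven, which is what the two-outlet
  topology requires.
* **Diastole** — plug inlet on the atrial cap carrying `Q_dia = SV /
  t_dia`; a single gauge-zero pressure outlet on the ventricular side.
  Only pressure *differences* are meaningful in diastole.
* 1 mmHg = 133.322 Pa throughout.

## Geometry model

The flow cavity is built from a handful of parameters instead of a
segmented CT surface:

* **Annulus**: a planar ellipse whose semi-axes are solved from the
  (area, perimeter) pair via Ramanujan's perimeter approximation — two
  printed quantities determine two axes. The pair is validated for mutual
  consistency: a perimeter below the equal-area circle's circumference is
  geometrically impossible and is clamped to the circle when within the
  5% consistency band (the default 1595 mm² / 141 mm pair is 0.4% inside
  that band), rejected otherwise.
* **Leaflets**: a straight-walled funnel whose cross-section morphs from
  the annulus ellipse (superellipse exponent 2) to a rounded rectangle at
  the coaptation line (exponent 6), over the leaflet length (default
  10 mm). In systole the funnel is sealed except for rectangular slit
  channels — one per coaptation defect, `width × gap_height`, giving
  analytically checkable orifice areas. In diastole it opens into one
  rectangular channel of area `0.65 × diastolic annulus area` by default
  (the open fraction is configurable; anatomic opening, not effective
  flow area).
* **Chambers and LVOT**: elliptical-cylinder atrial and ventricular
  chambers truncated at configurable depths (25 mm default for single
  cases, 20 mm for sampled cohorts), and a circular LVOT tube beside the
  annulus, open only in systole. How far the chambers should extend is
  not constrained by the anatomy measurements, so the extents are exposed
  as parameters.
* Axis convention: +z toward the atrium, annulus plane at z = 0,
  coaptation line along x; all geometry in mm.

One continuous level-set function defines the cavity; marching cubes
triangulates it into a watertight surface (STL import/export supported)
and voxelization samples the same function at cell centers, so the two
routes agree by construction. Imported surfaces are voxelized by z-column
ray parity with jittered grid lines. Ties at the boundary resolve toward
solid (conservative walls).

Topology note: with n open slit channels the closed cavity surface has
genus n − 1 (Euler characteristic 2 − 2(n − 1)); a sealed valve splits
into two genus-0 shells connected only through no flow path.

## Virtual edge-to-edge repair

A device grasps the coaptation line over
`[position − width/2, position + width/2]` and seals every defect there,
splitting wide defects into residual slits (the classic double orifice for
a central grasp) — and changes nothing else about the valve; annular
remodeling ("annuloplasty effect") is deliberately not modelled. The
grasped interval is solid tissue in *both* phases, so it also blocks the
same stretch of the diastolic opening: this is the mechanism that raises
the diastolic gradient and can produce iatrogenic mitral stenosis.
Implantation is idempotent and monotone (post-implant orifice area never
exceeds pre-implant). Grasping widths per device family (NT/NTr and
PascalAce 4 mm; XT/XTr/XTw and Pascal 6 mm) are configuration defaults,
assumptions rather than manufacturer dimensions. The grasped interval
equals the device width exactly — no closure "halo" beyond the arms.

## Numerical scheme

Pseudo-transient Chorin projection on a staggered (MAC) Cartesian grid:

* first-order upwind convection, central diffusion; tangential ghost
  velocities mirrored across walls (sign −1) give no-slip walls located
  exactly on cell faces; selected box-wall orientations can be declared
  free-slip (symmetry), used by the plane-channel benchmark;
* pressure Poisson equation solved exactly each pseudo-step by sparse LU
  (domains are a few 10⁴ cells), with Dirichlet pressure at outlet faces
  (half-cell one-sided gradient) and zero normal gradient at walls and
  velocity inlets — discrete divergence after projection is at solver
  precision, so mass conservation is structural;
* adaptive pseudo-time step from the convective (3-component worst case)
  and diffusive stability limits, CFL 0.4 by default; boundary values are
  ramped over the first 50 steps;
* convergence: relative per-step velocity change < `rtol` (10⁻⁵ default;
  2×10⁻⁴ in the coarse pipeline profile) *and* global |inflow − outflow|
  imbalance ≤ 1%. Jets at moderate Reynolds numbers may settle into a
  small limit cycle instead of a fixed point; the solver then detects
  stationarity of windowed means (velocity scale and outflow drifting
  < 0.5% per 100-step window) and returns the window-averaged field,
  flagged `stationary_cycle` in the diagnostics. Fields that meet neither
  criterion are returned flagged non-converged, never silently accepted.
* fluid components without a pressure outlet (e.g. the atrial cavity of a
  sealed valve in systole) are frozen at zero velocity; a component with
  prescribed inflow but no pressure outlet is an error.

Verification (in the test suite): plane Poiseuille to 0.1% (the parabola
is exact for the stencil, so refinement convergence is shown on the
rectangular duct against its Fourier-series solution: 4.6% → 1.2% → 0.3%
over three refinements); orifice-jet peak velocity within ~4% of
√(2Δp/ρ); endpoint invariance under a quarter-turn of the grid.

## Endpoints

* `Q_reg`: flux integral over the left-atrial outlet patch (systole).
* `RV = Q_reg · t_sys`; the same phase durations used to derive the inlet
  rates (defaults t_sys 0.35 s, t_dia 0.65 s — heart rate 60 min⁻¹; the
  durations matter only through these products).
* `EROA = Q_reg / V_max`: continuity definition, matching the
  echocardiographic semantics it is compared against and robust on coarse
  grids; a geometric vena-contracta extraction would be meaningless at
  2 mm resolution.
* Diastolic gradient: area-averaged pressure difference between planes
  5 mm (configurable) from the leaflet tips on either side.
* PISA: the isovelocity radius is read along the ventricular-side jet
  axis from the orifice centroid — the converging side of an MR jet —
  and fed to the hemispheric formulas `Q = 2πr²·V_a`, `EROA = Q/V_max`,
  `RV = Q·t_sys` (aliasing velocity default 0.35 m/s). On the ideal
  point-sink field the inversion is exact by construction; on real
  (simulated or clinical) geometries the hemispheric assumption is
  violated and PISA is biased — reproducing that bias is the point of
  emulating it.
* Simplified Bernoulli: `MPG = 4v²` with the mean transmitral velocity by
  continuity, `v = Q_dia / A_orifice`.
* Decision flags: `stenosis_risk` at diastolic MPG ≥ 5 mmHg (the
  post-TEER favorability cutoff used clinically), `residual_MR` at
  RV ≥ 15 ml; both configurable.

## Synthetic cohorts

The population model reproduces the measured cohort statistics: systolic
annulus area ~ truncated normal (1595, 379) mm² (floored at mean − 3 SD or
a physiologic minimum), diastolic/systolic area ratio (1.022, 0.010), and
a per-patient annulus axis ratio k ~ U(0.75, 1) from which the perimeter
follows via Ramanujan — sampling area and perimeter *independently* from
their printed marginals would make roughly half the draws geometrically
impossible (perimeter below the circle bound), whereas the derived
perimeter reproduces the printed moments (mean 141.2 mm vs 141, SD ~17 vs
16) while keeping every anatomy self-consistent. Stroke volume
(70, 15) ml, leaflet length (10, 2) mm, LVOT diameter (20, 2) mm,
coaptation line = 1.7 × the systolic semi-major axis. Each patient gets
one coaptation defect, width (8, 3) mm and gap (5, 1.5) mm truncated at
physiologic floors — severe-MR scale (median anatomic orifice ~40 mm²).
Implanted device families follow the observed frequency table
(Pascal 3 : PascalAce 6 : XTw 6 : XTr 2 : XT 1 : NT 1 : NTr 2), centred on
the defect. Sampling is bit-reproducible under a fixed seed.

What the cohort does *not* emulate: atrial fibrillation beat-to-beat
stroke-volume variation, saddle-shaped 3D annulus dynamics, leaflet
mechanics/FSI, chordae, image-acquisition noise, and inter-observer echo
variability. Agreement statistics on these cohorts therefore test the
*pipeline's* self-consistency (CFD vs echo-emulation on the same fields),
not clinical accuracy; the clinical correlation coefficients from real
patient data are not reproducible in this setting and are not targets of
the test suite.

## Problem sizes and numerical profiles

Default case resolution is 1.5 mm with 0.5 mm (the shrinkwrap-scale net
size) available via config for high-fidelity runs; the test suite and the
cohort examples run at 2–2.5 mm with truncated chambers (12–15 mm) and a
relaxed residual (2–3×10⁻⁴), which resolves a 5 mm coaptation gap by only
2–3 cells — adequate for flux-scale endpoints and monotonicity properties,
coarse for local jet structure. The diastolic-stenosis examples use a
reduced diastolic open fraction (0.2) so that transvalvular velocities sit
in the clinically interesting 0.3–1 m/s range where gradient differences
are well resolved on coarse grids.

## Known limitations

* Steady single-phase snapshots; no pulsatility, no velocity-time
  integrals, no valve motion, no FSI.
* Stairstep immersed walls on a uniform grid (no boundary layers or
  body-fitted refinement); first-order upwind convection is diffusive, so
  coarse-grid jets underestimate peak velocity and overestimate EROA.
* The funnel/slit leaflet parametrization is a stand-in chosen for
  analytic checkability, not an inferred anatomical truth.
* The simplified Bernoulli relation is applied exactly as stated
  (`4v²`); its interaction with continuity-derived mean velocities makes
  the emulated gradient a lower-variance proxy, not an independent
  measurement.
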
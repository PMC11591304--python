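# Methods

## Scope and intent

`dissectflow` is a desk-scale idealization of pulsatile flow in a dissected
descending aorta, built to compare **re-entry-tear locations** against an
entry-only baseline.  The product is the *comparative* behavior — tear-flux
directions, regional pressure/WSS ordering, recirculation extent versus tear
location — not absolute patient-specific values, which depend on 3D anatomy
this model deliberately does not represent.

## Geometry

The aorta is reduced to a 2D axial plane:

* an undissected proximal channel (default 60 mm × 20 mm) carrying three
  branch outflow slots (centers 15/30/45 mm, width 6 mm, 5% of inlet flow
  each) on one wall;
* a dissected segment (default 225 mm, long enough for the most proximal
  re-entry case at 202.3 mm): true lumen (20 mm) and false lumen (12.8 mm
  short axis) in parallel, separated by a 2 mm septum; the FL is sealed at
  its distal floor;
* a short distal channel (20 mm) to the pressure outlet.

Tears are gaps in the septum.  The entry tear (width 6.4 mm) is centered
5 mm into the dissected segment — the source text does not specify its size
or exact position, so these are declared assumptions.  Re-entry tears take
their center distance from the FL floor from the 11-case table and their
width from the sizing rule (50% of the FL short axis).  The dissected
segment is partitioned into 6 equal-length regions; the anatomical
landmarks used for regions in the source study are not quantified there, so
equal division is the only reproducible choice.

Rasterization is cell-centered stair-step masking at uniform spacing; a
run refuses to start if any lumen or tear spans fewer than 3 cells or if
the septum vanishes from the mask.  The distal channel is extended by less
than one cell so the outlet plane coincides with a grid face.

## Boundary signals

The published inlet/outlet curves exist only as figures, so the package
ships documented parametric stand-ins (all config-overridable, PCHIP
interpolation between control points so positivity and extrema are
preserved):

* inlet velocity: half-sine systolic pulse over phases 0.05–0.45 s of a
  1.0 s cycle, peak 1.0 m/s at 0.25 s, zero diastolic baseline, spatially
  flat profile;
* outlet pressure: two-phase arterial wave between 10.6 and 16.0 kPa
  (≈80–120 mmHg) peaking at phase 0.30 s;
* branch outflow: prescribed negative normal velocity carrying exactly 5%
  of the instantaneous inlet volumetric flow per slot.  The split is exact
  by construction on the *discrete* slot widths, so a flow audit recovers
  5.000% at every instant.  A `branches: off` switch instead scales the
  inlet to 85%.

The cardiac period (1.0 s) is inferred from the sampling instants
t = 3.25 s / 3.47 s lying in the fourth of four cycles.

## Solver

MAC staggered grid; u on x-faces, v on y-faces, p at cell centers.
Convection is second-order upwind with a first-order fallback wherever the
second upwind node lies outside the fluid; viscous terms are central, with
antisymmetric (linear) wall ghosts for tangential components — on plane
Poiseuille this ghost yields a uniform O(h²) offset, i.e. clean second-order
behavior.  Time integration is explicit (forward Euler) with an incremental
fractional-step projection and **two** pressure-correction sweeps per step,
mirroring a PISO predictor/multi-corrector; with an explicit predictor the
second sweep only scrubs the first solve's residual, and is retained for
structural fidelity at negligible cost.  The pressure Poisson matrix (5-point
Laplacian over fluid cells; Neumann on walls and prescribed faces, Dirichlet
*on the face* at pressure boundaries) is factorized once per grid with
SuperLU, making every step a deterministic direct solve.

Stability.  Forward Euler with second-order upwind is linearly stable only
up to a Courant number of about 0.46 (the amplification factor leaves the
unit disk near θ ≈ 2π/3 for c > 2·Re λ/|λ|² ≈ 0.46).  The default CFL
safety is therefore 0.3, and the advective and diffusive limits are
combined harmonically, dt = 1/(1/dt_adv + 1/dt_diff), capped at 1 ms.
Snapshots land exactly on their target times by clipping dt.

Initial condition: rest, pressure at the outlet's t = 0 value.  Four cycles
are run so the reported cycle is quasi-periodic; the diagnostics record the
relative L2 velocity difference between the last two cycles at the first
snapshot phase, the per-step maximum discrete divergence (direct solve:
~1e-13 1/s), the global mass imbalance relative to gross boundary flux
(~1e-15), the maximum CFL, and Re_max = ρ·U_max·D_h/μ with D_h twice the
proximal channel width.  Re_max exceeds the configured critical value
(2300) at the default peak velocity; per the laminar modeling assumption
this logs a warning and nothing else.

### Validation

* **Plane Poiseuille** (pressure-driven channel): max error relative to the
  analytic parabola 0.25% at 1.0 mm and 0.06% at 0.5 mm spacing; observed
  L2 convergence order 2.00.  The benchmark fluid is 10× more viscous than
  blood so the start-up transient (time constant w²/νπ²) settles in seconds
  of simulated time; the discretization error measured is independent of
  that choice.
* **Oscillatory channel** (planar Womersley, α = 3, 1 Hz): cycle-averaged
  L2 error 0.45% at 0.5 mm.

## Post-processing

* **WSS**: μ × |one-sided quadratic fit of the tangential velocity gradient
  at the wall| through the no-slip point and the two nearest cell centers,
  q′(0) = (9q₁ − q₂)/(3h) — exact for quadratic profiles, matching the
  solver's order.  Walls with fewer than two interior cells across are
  flagged unreliable and excluded from summaries.
* **Regional summaries**: per (region 1–6 × lumen) median pressure (kPa),
  median/max WSS (Pa), peak speed; always 12 rows per phase, NaN markers
  for empty combinations.  Median is used for both pressure and WSS for
  coherence (the source analysis states medians only for WSS).
* **Tear flux**: septum-normal velocity integrated across the tear gap at
  the TL ceiling; positive = FL→TL, so "return to the true lumen" reads
  positive.
* **Recirculation**: over FL cells distal to the re-entry tear (whole FL
  for the entry-only case), two readings: the fraction/area with axial
  velocity below −0.01 × the inlet peak (a noise-robust *vigorous*
  recirculation measure) and the plain sign-based reversed-flow area.  The
  distinction matters: below a proximal tear the FL is a long dead-end
  column creeping backwards at <1 cm/s — large reversed-flow area, tiny
  thresholded area.  Trend reports and the location-comparison use the
  sign-based area; the thresholded fraction quantifies eddy vigor.
* **Mesh study**: one simulation per spacing (default 2 cycles — the max
  systolic WSS is insensitive to cycles 3–4 at the comparison precision,
  and every level is compared at identical settings), max *reliable* WSS
  over the **dissected segment** at each phase, relative change referenced
  to the finer level (both conventions emitted).  The undissected inlet
  region is excluded because the flat inlet profile meets the no-slip wall
  in a corner whose pointwise WSS is singular (grows ≈ h^(−1/2) under
  refinement) — an artifact of the idealized inlet, not lesion
  hemodynamics.  The study defaults to a shortened geometry (dissected
  length 100 mm) so four levels down to 0.7 mm finish in minutes on one
  CPU; the full-length variant is a CLI flag.

## Default problem sizes

The default sweep resolution is 1.0 mm (~11,000 cells, ~7,000–9,500 steps
per 4-cycle case, ~35 s/case on one CPU), with 0.5 mm as the documented
fine profile for publication-quality fields.  The branch audit runs one
cycle at 2.0 mm; the mesh study uses 2.0/1.4/1.0/0.7 mm on the shortened
geometry.  These are the package's standard desk-scale settings; all are
config-exposed.

## What the idealization shows — and what it cannot

Robust on this model at default settings:

* tear-flux reversal: FL→TL through the re-entry tear at peak systole,
  TL→FL at early diastole, with the entry flux equal and opposite (the
  sealed FL enforces this to machine precision);
* the reversed-flow area below the re-entry tear is non-zero whenever there
  is space below the tear and shrinks strongly as the tear moves distally
  (case 2: 115 mm² vs case 11: 1331 mm² at peak systole, sign-based);
* branch flow split and the mesh-convergence criterion.

Known limitations, found and kept honest rather than patched:

* **Cycle periodicity.**  The cycle-3 vs cycle-4 velocity difference at
  peak systole is 0.2–1.6% for most cases but 2.15% for case 2, whose
  entry→re-entry path spans the whole FL and carries the slowest-decaying
  start-up transient (the error decays geometrically, ~3× per cycle, and is
  below 0.7% by cycle 5).  The four-cycle protocol is part of the study
  conditions, so the marginal case is reported as-is.
* **FL decompression.**  On this idealization the entry-only FL equilibrates
  to the *proximal TL static pressure* — the tangential septum slot
  produces no ram pressurization of the dead-end FL — while re-entry cases
  back pressure up on the FL side of the re-entry orifice to drive the
  jet.  Distal-region FL systolic pressure is therefore *not* lower in
  re-entry cases here (case 2: 15.87 kPa vs entry-only 15.57 kPa), unlike
  in the patient-specific geometry, where the entry jet faces the FL
  frontally.  This is a fidelity limit of the 2D side-slot tear model.
* Rigid walls, no FSI; Newtonian rheology; laminar model despite Re_max
  above the nominal critical value; branches as flow-split slots, not
  vessels; no curvature or spiral FL course.  Absolute pressures/WSS are
  therefore not comparable to patient values and are excluded from any
  numeric claims.
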
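# Methods

## Model and assumptions

`mnph` solves the Pennes bioheat equation on an idealized human torso to
study magnetic nanoparticle hyperthermia (MNPH) dose planning.  The
modeling assumptions are deliberate simplifications, held constant across
all studies:

* **Constant, per-tissue properties.**  Thermal and electrical properties
  are homogeneous within each tissue and independent of temperature; blood
  perfusion is constant in time (no thermoregulatory feedback).  The
  perfusion term sinks heat toward a fixed arterial temperature
  (default 37 C).
* **Homogeneous AMF.**  The coil field is uniform over the torso, so the
  eddy-current source depends only on tissue conductivity and radial
  distance from the coil axis.  `Q_eddy = (sigma/2)(pi mu0 r f H)^2` uses
  the *peak* amplitude H; peak-to-peak hardware specs are halved at the
  config boundary (`AMFExposure.from_peak_to_peak`), since confusing the
  two silently scales `Q_eddy` by 4.
* **Uniform nanoparticle loading.**  The iron dose is deposited uniformly
  in the MION core sphere (radius = half the tumor radius, i.e. 1/8 of the
  tumor volume; the fill region is configurable).  The local rate is
  normalized by the *voxelized* fill volume, so total deposited power
  equals `SLP(H) * m_Fe` exactly at any grid spacing.
* **Worst-case tumor placement.**  The tumor sits at the torso center on
  the coil axis, where the eddy contribution vanishes — the least help
  nanoparticle heating can get from nonspecific heating.

## Geometry and voxelization

The torso is a set of concentric cylinders along Y (muscle 0.109 m, fat
0.1244 m, skin 0.126 m outer radii; 0.55 m tall) with a pancreas cylinder
along X (0.075 m radius, 0.10 m long) and a central tumor sphere
(0.005–0.03 m radius).  Regions are painted onto a regular isotropic voxel
grid by precedence (innermost wins), ownership decided at voxel centers.

The skin shell is only 1.6 mm thick.  At spacings above 1.5 mm the fat and
skin shells are merged into a single `fat_skin` region with
shell-volume-weighted average properties (the merge is logged; it can be
disabled, in which case a warning flags the unresolved skin layer).  The
superficial-heating readout is dominated by muscle in all shipped
scenarios, so the merge does not move the reported peaks.

## Tissue properties

Defaults ship in `src/mnph/data/tissue_properties.yaml`: representative
values transcribed from the IT'IS Foundation database (thermal tables,
low-frequency conductivities near 155 kHz), unit-converted to SI
(perfusion in 1/s, metabolic heat in W/m^3).  The pancreatic tumor reuses
normal-pancreas properties with configurable perfusion and metabolic
ratios; the defaults (0.2 and 1.0) describe a hypovascular adenocarcinoma
and are package choices, not database values.  Everything is overridable
per run.

## Specific loss power

Measured SLP curves are nanoparticle-specific, so `SLPModel` is fully
config-driven (ascending polynomial coefficients, validity range, no
extrapolation; SLP(0)=0 and monotonicity are enforced).  The shipped
default, `SLP(H) = 3.2e-7 H^2` W/g Fe at 155 kHz, is a **synthetic
placeholder**: a monotone quadratic through the origin, calibrated once so
that the standard scenario (5 mg Fe/cm^3 dose, AMF at the clinical H*f
limit, 2 cm tumor) reaches hyperthermic tumor temperatures (41–46 C; the
shipped value yields 42.5 C).  Absolute temperatures therefore track the
placeholder, and only structural conclusions (monotonicities, spreads,
scalings) should be read quantitatively unless a measured SLP curve is
supplied.

## Pulse schedules and the duty-cycle study

`duty% = on/(on+off) * 100`.  Schedules start ON at t=0 and deliver a
fixed cumulative on-time (default 20 min), so elapsed time scales as
`100/duty` (80 min at 25%).  The 33.3% arm is an exact 1:2 on:off ratio.
The clinical exposure check `H*f < 4.85e8 A/(m s)` is a strict inequality.

The pulse block length matters physically.  Two thermal time constants
govern the sweep: the MION-loaded tumor core (perfusion + conduction,
~3 min for the default 2 cm tumor) and the outer muscle shell (~15–25 min).
If on-blocks are short against *both*, every tissue integrates the
duty-averaged power and pulsing helps nothing it doesn't also cost the
tumor.  The duty study therefore defaults to 10 min on-blocks: long enough
that the tumor core saturates to its full-power temperature within each
block (its peak becomes nearly duty-independent), short enough that the
slow muscle shell still averages, so its peak falls steeply with duty.
`schedule_from_duty` itself defaults to 30 s blocks for generic use; both
are configurable, and the time step must divide the on-block so on/off
edges land on step boundaries (the power factor is sampled at the left
edge of each step, making delivered on-time exact).

## Solver numerics

* Conservative 7-point finite volumes on the voxel grid; harmonic-mean
  conductivity at faces between different tissues (an arithmetic-mean
  variant was considered and rejected as non-conservative across strong
  contrasts).  Exterior voxels are excluded from the unknowns.
* Boundary conditions are applied per face axis on tissue faces without a
  tissue neighbor: default convective air exposure on the lateral (X/Z)
  surface, h = 10 W/(m^2 K) toward 25 C, and adiabatic Y end caps
  (approximating continuation of the body).  Fixed-temperature faces
  accept a callable ambient for verification against analytic far fields.
  The exterior air is not meshed; the domain truncates at the skin
  surface.
* Backward-Euler time stepping: unconditionally stable, first order in
  time, so 80-minute pulsed treatments at dt = 1 s are routine.  Each step
  solves one SPD system by Jacobi-preconditioned conjugate gradients
  (relative tolerance 1e-8 by default, 1e-10 for steady states), warm
  started from the previous step.  The system matrix is constant in time.
* Initial condition: the sourceless steady state (perfusion + metabolism
  vs boundary losses), giving a physiological baseline (~37.4 C tumor
  core, skin graded toward ambient).

### Verification

* **Manufactured solution** `T* = T_b + A exp(-lambda t) prod cos(k_i x_i)`
  with the forcing that makes it exact; with `k_i = n_i pi / L_i` it
  satisfies the adiabatic (mirror) boundaries.  Observed spatial order at
  4→2→1 mm is 1.97–1.99.  The leading h^4 correction of the discrete
  Laplacian eigenvalue is negative, so the observed order of this (exactly
  second-order) scheme approaches 2 from below; tests assert [1.9, 2.1].
  Time order is measured against a small-dt reference (time-only
  Richardson) because the fixed spatial error floor otherwise contaminates
  the estimate; observed ~1.0.
* **Closed forms.**  Uniform perfused heating matches
  `T_b + (Q/g)(1 - exp(-gt/rho c))` within 0.25% at dt = tau/200; the
  conduction-only heated-sphere profile matches within 0.5% inside twice
  the source radius on a 48^3 grid with analytic far-field Dirichlet data.
* **Bookkeeping.**  Insulated, unperfused bodies conserve energy to the
  linear-solver tolerance; sourceless relaxation obeys the discrete
  maximum principle; halving both spacing and dt moves the tumor peak of a
  full treatment by < 0.2 C.

## Dosimetry

CEM43 uses the Sapareto–Dewey rule with R = 0.5 at/above the 43 C
breakpoint and 0.25 below; breakpoint and R values are parameters.  Doses
are computed on per-region maximum- and minimum-temperature traces to
bracket spatial heterogeneity (an intratumoral probe at the hottest point
approximates the max-trace dose).  Reported regions include `tumor_all`,
the union of the tumor shell and the MION core.  The t=0 baseline sample
carries no exposure time, so an N-minute constant trace scores exactly its
equivalent minutes.

## Study defaults and problem sizes

Sweeps default to 4 mm spacing (radius study: dt = 10 s, ~550k voxels;
duty study: 5 mm, dt = 1 s, ~290k voxels, four arms up to 80 simulated
minutes) — sizes chosen so a full study runs in minutes on one CPU while
the mesh/time-step independence check above bounds the discretization
error of the reported peaks.  A `--fine`/1 mm rerun path exists for
convergence checks.  The radius study runs at the clinical exposure limit;
the duty study models a deliberately unfavorable case at 1.5x the limit
(config-exposed choice).  All drivers are deterministic; rerunning a
config reproduces byte-identical tables.

## Synthetic cohorts: scope

`generate_cohort` emulates two-arm mouse studies — tumor volumes normal
within arms (0.15 ± 0.03 and 0.30 ± 0.06 cm^3), truncated below 0.1 cm^3
where intratumor injection becomes unreliable, with caliper triples
back-derived at a fixed 1.2:1:0.8 aspect ratio and the full dosing chain
(5.5 mg Fe/cm^3; 23.6 mg Fe/ml stock).  It does *not* model measurement
error, tumor growth, probe placement, or biological response; passing
cohort tests demonstrates the dosing arithmetic and reproducibility, not
in-vivo realism.  Survival/growth-delay statistics are out of scope.

## Known limitations

* No discrete vasculature: large-vessel (> 3 mm) convective cooling is
  ignored, which matters for tumors abutting major vessels.
* Idealized cylinder/sphere anatomy; no patient image-based phantoms.
* Uniform nanoparticle distribution; real intratumor distributions are
  heterogeneous and shift both the dose and its spatial pattern.
* The shipped SLP curve is a placeholder (above); absolute temperatures
  are scenario-calibrated, not nanoparticle-specific.
* Simple duty-cycle modulation only; no temperature-feedback power
  control.
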
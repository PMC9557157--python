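# Methods

This note documents the models, the numerical choices, and the limits of the
desk-scale surrogate. Units throughout: mmHg, mL, s for the circulation;
mm, mm/s, Pa for the flow domain.

## Closed-loop circulation model

An eight-compartment 0-D loop: elastance chambers LA, LV, RA, RV; systemic
arterial and venous and pulmonary arterial and venous compartments, each a
linear compliance with a series outflow resistance; four diode valves with
small series resistances; a continuous-flow pump from LV to the systemic
arterial node.

**Chamber law.** `P(V,t) = e(t)·P_iso·(V−V0)/(V_ref−V0) + α·(exp(β(V−V0))−1)`.
The activation `e(t)` is a squared-sine pulse over a fixed fraction of the
cycle (ventricles: onset 0.0, duration 0.40; atria: onset 0.85, duration
0.17), so `e` vanishes at the chamber's end-diastole and peaks at 1. The
exponential term is the end-diastolic pressure–volume relation (EDPVR).
Atrial fibrillation is modelled as the LA activation identically zero —
the atrium becomes a passive conduit; no further parameter changes.

**Pump.** Static quadratic head–flow curve at fixed speed,
`H(Q) = c0 + c1·Q + c2·Q²` (mmHg, Q in L/min), monotone decreasing on
0–10 L/min, continued linearly for retrograde flow so an operating point
exists above the shut-off head. No inertance: only cycle-resolved, not
intra-step pump dynamics, are needed downstream.

**Mean circulatory pressure (MCP)** fixes total blood volume:
stressed volume = MCP × (sum of vessel compliances), chambers initialised at
their unstressed volumes. The 12.5 → 10 mmHg scenario adjustment therefore
acts by removing stressed volume.

**Scenario adjustments** (the LVAD-patient arm): heart rate 80 bpm; LV peak
isovolumic pressure 100 → 80 mmHg; RV 80 → 50 mmHg; MCP 12.5 → 10 mmHg;
systemic arterial resistance −6 %; LV EDPVR α × 1.70 (the E/A knob — E/A
rises monotonically with α in this model family, which the test suite
asserts over a ±50 % sweep).

**Calibration.** The targets (pump flow 5.2 L/min, mean arterial pressure
83.8 mmHg, E/A 1.2) are clinical operating-point values, not parameter
listings, so three baseline knobs — pump zero-flow head, systemic arterial
resistance, LV EDPVR α — were fitted once by deterministic least squares on
the converged post-adjustment solution (`laaoflow.calibrate`) and committed
as the package defaults. The residuals at the committed values are below
1e-9 on all three targets.

**Integration.** Classical fixed-step RK4 at Δt = cycle/750 (Δt = 1 ms
available via the `dt` argument); periodic steady state declared when every
compartment volume changes < 0.5 % cycle-to-cycle (typically 16 cycles);
one further cycle is recorded at full resolution. Blood volume is conserved
to round-off by construction; halving Δt moves the cycle-mean pump flow by
< 1e-4 %.

## Parametric mitral valve

The open, rigid valve surface is swept between the circular annulus (s = 0)
and the free edge (s = 1):

    x = R cosθ (1 − s cosφ) − εRs cosφ
    y = R sinθ (1 − s k cosφ)
    z = −(s/2) [(1+k²) + ε cosθ + (1−k²) cos2θ] R sinφ

Defaults ε = 0.35, k = 0.6, φ = 60°, sampled 100 × 40 in (θ, s). The grouping
of the z equation is ambiguous as commonly typeset; the committed reading
(superscripts as squares, leading factor s/2) is the only one that uses every
typeset token and keeps z linear in s with z = 0 at the annulus. The
alternative "(1+k)/2, (1−k)/2" reading stays available behind
`z_convention="half-k"` and neither reading is treated as ground truth.
R has no reference value; the default 14 mm is the mitral orifice radius of
the synthetic domain.

## Synthetic flow domain

**3-D voxel mode** (geometry fidelity): atrium = sphere capped at the mitral
plane, ventricle = prolate half-ellipsoid (aspect 1.9), appendage = 12.9 mm
sphere joined by a 12 mm neck cylinder, two pulmonary-vein (PV) inlet patches,
apical cannula outlet. The atrial sphere radius and ventricular semi-axis are
set by bisection against the voxel-summed volumes so the reference end-systolic
values (atrium + appendage 169 cm³, ventricle 295 cm³) are met to ≲0.1 %;
capped-sphere/ellipsoid closed forms serve as the voxelizer oracle. The pouch
(~9 mL) follows the order of magnitude of blood reported to enter an
appendage per cycle; it is a scale choice, not a fitted value.

**2-D working mode** (flow solve): rectangular atrium (60 × 50 mm), square
appendage pouch (15 × 15 mm) behind a 10 mm neck on the atrial wall beside the
left PV — the appendage's anatomical neighbour, so the left-vein inflow
sweeps the neck — mitral channel, half-elliptical ventricle tapering into the
outlet (a box ventricle leaves artificial corner-stagnation cells; the
rounded apex removes them). One out-of-plane depth (≈52 mm) converts areas to
volumes and is chosen so the atrial volume matches 169 cm³; the 2-D
ventricular volume is then not 295 cm³ — matching both chambers with a single
depth is impossible, and volume fidelity for both is the 3-D mode's contract.
Grid spacing 1.0 mm (≥4 cells across the neck enforced); occlusion deletes
every appendage cell, sealing the neck plane, and leaves the rest of the
domain bit-identical.

**Flux-equivalent boundary program.** The study geometry has moving
endocardial walls; re-implementing dynamic-mesh machinery is out of scope, so
the domain is rigid and the wall motion is pushed to the boundaries — the
single largest deviation in this package, and the one to keep in mind when
reading any absolute number:

* PV inflow(t) = pump flow + d(V_LA+V_LV)/dt from the circulation model (its
  physical pulmonary-vein return, including the flow reversal at the atrial
  kick), split exactly 55/45 right/left;
* the pouch's far end-wall carries the appendage's share of atrial wall
  motion, −(V_LAA/V_atrium)·dV_LA/dt ≈ 7 % of the atrial volume-change rate.
  Without this term the pouch exchanges marker only by numerical diffusion
  and the SR/AF comparison degenerates to noise; with it, the atrial kick
  flushes the pouch in SR exactly as the mechanism under study prescribes.
  It vanishes in the occluded arms and in AF retains only the passive swing;
* the outlet carries the instantaneous sum of all inflows, so net boundary
  flux is zero at every instant (rigid domain) while its cycle mean equals
  the cycle-mean pump flow.

## Flow solver

Chorin fractional-step on a staggered (MAC) grid: first-order explicit time
stepping, first-order upwind advection, second-order centred diffusion,
tangential no-slip via reflected ghosts. Inlets and outlet impose plug
velocities from the flux program (signed; PV backflow reverses the plug).
The pressure Poisson problem (pure Neumann, compatible because the program
closes mass exactly) is factorised once (sparse LU, one pinned cell); the
discrete divergence after projection sits at round-off (~1e-13 1/s), far
inside the 1e-8 contract. The advective CFL condition is kept ≤ 0.5 by
automatic sub-stepping. Defaults: 12 cycles, Δt = 1 ms, first 4 cycles
flagged as initialisation, 50 stored snapshots per cycle. Laminar, Newtonian
(ρ = 1060 kg/m³, μ = 0.0035 Pa·s). Verification: mid-channel
plane-Poiseuille profile and wall shear within 2 % of the analytic solution;
unforced fields decay monotonically in kinetic energy; halving the grid
spacing moves the cycle-averaged appendage mean velocity by < 2 % (10 % is
the asserted bound).

Per-step residual reporting follows steady-solver convention (normalised
continuity plus per-component velocity change, acceptance threshold 1e-3):
meaningful for steady runs; in pulsatile runs the momentum entries simply
track physical acceleration and are reported, not enforced.

The solver is deliberately 2-D. The 3-D voxel mode exists for volume-faithful
geometry; nothing in this package claims 3-D flow fidelity.

## Thrombosis-related metrics

* **Stagnation volume**: cells whose *time-averaged velocity magnitude* over
  the evaluation window (cycles 5–12 by default) is below 1 mm/s.  Averaging
  the magnitude (not the vector) means oscillating-but-moving blood is not
  counted as stagnant; the vector reading is available via
  `average="vector"` and both are tested.
* **WSS bands**: per wall face, time-averaged `τ = 2μ·u_t/h` (the one-sided
  gradient consistent with the reflected-ghost wall; second-order against
  the discrete channel solution), binned into 0–0.2 Pa (low,
  non-physiological), 0.2–9 Pa (physiological) and >9 Pa; the three areas
  partition the wall exactly.
* **Velocity statistics**: volume-weighted time-averaged speed, and the
  volume-weighted mean of the *per-cell temporal* standard deviation —
  computed per cell first so spatial structure is not laundered into
  temporal variation.
* **Recirculation pocket**: over the diastasis window (detected from the
  mitral waveform between the E and A waves, or after the single AF wave),
  the phasic-mean appendage flow is classified as a pocket when mean speed
  < 20 mm/s and the swirl fraction about the vorticity-weighted vortex core
  exceeds 0.3 — slow but coherently rotating blood.

## Virtual-ink washout

Pure advection of a bounded marker (fresh = 1 at the PV inlets, initial
state 0 everywhere) by first-order upwind finite volumes on the stored
snapshots, CFL sub-stepped, clipped to [0,1]; the appendage-wall flux
boundary is zero-gradient (wall motion displaces marker, it does not create
or destroy it). Transport starts after the initialisation cycles and runs 8
cycles; all series are sampled at cycle boundaries. "Old blood entering the
appendage in the first cycle" is operationalised as the pouch's old-blood
content at the end of transport cycle 1 — the only construction available to
an Eulerian marker (Lagrangian tracking is a non-goal).

Two caveats are inherent and should temper quantitative readings: upwind
numerical diffusion (no physical diffusivity is modelled) smears fronts and
*lowers* apparent residence, while the rigid-wall surrogate (only ~7 % of
atrial wall motion reaches the pouch, and none of the three-dimensional
jet impingement) *raises* it. The net effect is appendage residence around
78–82 % after 8 cycles, far above what moving-wall 3-D CFD reports; the
orderings between arms, not the magnitudes, are the meaningful output.

## Reporting conventions

Percent changes between arms: increases round to the nearest integer
percent; reductions truncate toward zero (never overstated) — e.g.
4.2 → 6.5 cm³ is +55 %, 4.2 → 1.4 cm³ is −66 %. Raw values are always kept
beside the rounded changes. The pipeline is seed-free and deterministic:
identical configurations give byte-identical JSON/CSV, and cached stage
outputs are keyed by a configuration digest.

## Problem sizes

Defaults used throughout tests and examples: 750 circulation steps per
cycle; 2-D grid 79 × 132 at 1 mm (≈5.6k fluid cells); 12 flow cycles at
Δt = 1 ms with 50 stored snapshots per cycle; 8 washout cycles. One scenario
runs in ~30 s on one core, the four-arm experiment in ~2 min.

## What the synthetic data does not emulate

Patient-specific anatomy (single-lobe pouch only; Cactus/Chicken-wing/
Cauliflower morphologies out of scope), true moving meshes,
three-dimensional flow structures (the 2-D vortex is a planar surrogate),
non-Newtonian rheology, turbulence transition, baroreflex control, suction
events, and any platelet/coagulation biology. Passing tests demonstrate
internal consistency and directional agreement of the surrogate — not
patient-level quantitative prediction.
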
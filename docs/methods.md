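# Methods

`cardiotwin` is a desk-scale, multi-physics model of the failing human
heart: a synthetic bi-ventricular anatomy with rule-based fibers, monodomain
electrophysiology with a phenomenological two-variable cell model, 12-lead
pseudo-ECG synthesis, co-rotational soft-tissue mechanics coupled to a
lumped circulation, inverse-problem personalization loops, and a
virtual-cohort statistics pipeline. This note documents the models, their
assumptions, the defaults and why, the numerical choices, and what the
synthetic data can and cannot show.

Internal units are mm, ms, kPa, mN and mg (1 kPa·mm² = 1 mN; tissue density
1.06 mg/mm³). Interfaces report ml and mmHg; Windkessel resistances are
stored as printed (mmHg per mm³) with a per-second flow convention, the only
one that closes the ODE dimensionally with flows in mm³/s.

## Synthetic anatomy

Patient anatomies in clinical practice come from image segmentation; this
package instead generates a parametric stand-in that preserves the topology,
surface labels and tagged regions the downstream solvers need. The LV is a
thick-walled truncated ellipsoid (default endocardial semi-axes 20/20/40 mm,
wall 9 mm); the RV is a crescent formed by an offset ellipsoidal cavity
wrapped around the LV epicardium with a thin free wall built as the exact
3 mm Euclidean offset of the RV endocardial surface (vectorized bisection
projection onto the ellipsoid), so the canonical thin-RV-wall assumption
holds by construction, not calibration. The base is an open plane orthogonal
to the long axis; the four valve annuli are represented as node rings on
that plane (anterior/posterior split per ventricle), since no imaging
defines their true geometry here. Outflow tracts are deliberately omitted.

Meshing samples the analytic surfaces in quasi-uniform rings (with seeded
in-surface jitter that regularizes the Delaunay triangulation while keeping
every sample exactly on its surface), tetrahedralizes the combined cloud,
and keeps tetrahedra whose centroid lies inside the implicit myocardium.
Boundary facets therefore lie on the analytic surfaces and chamber volumes
converge to the analytic values under refinement (measured: −1.2% at 4 mm
edges, −0.4% at 2.2 mm). Poor-quality sliver elements are retained rather
than deleted — deleting them punches holes in the boundary — and the
solvers are built to tolerate them (implicit diffusion; invertible-FEM
rotations in the beat loop). Boundary labels are assigned by nearest
analytic surface, with the RV surfaces valid only outside the LV epicardium
(the analytic RV ellipsoid dives through the LV cavity near the apex).

The transmural coordinate solves a Laplace problem (P1 FEM): 1 on the
endocardial surfaces, 0 on the epicardium *and on the RV-facing septal
surface*, natural on the base. The septal choice makes the coordinate vary
across the septum — where both faces are endocardial — so the fiber rule
has a meaningful gradient there; the maximum principle keeps the coordinate
in [0, 1].

The fast-conduction sub-endocardial layer (Purkinje surrogate) tags
elements whose centroid lies within 1 mm (default) of an endocardial
surface, measured by exact point-to-triangle distance against the labeled
boundary facets. At 3.5 mm edges this yields a one-element-deep, slightly
patchy layer; patchiness is immaterial for the global features (QRS
duration, axis) the model targets.

## Fibers

Per-element elevation angle is linear in the transmural coordinate: LV
−60° (epi) → 0° (mid-wall) → +60° (endo); RV −80° → +80°. Septal elements
on the RV side of the septal mid-surface (transmural coordinate < 0.5 with
a septal outer face) follow the RV rule. The fiber is the local
circumferential direction (long axis × transmural gradient) rotated by the
elevation angle in the wall tangent plane, hence exactly unit length and
orthogonal to the transmural direction. Near the apex the circumferential
frame degenerates; those elements fall back to a radial frame and are
counted in `FiberField.n_apex_fallback`. Sheet directions are not generated
(no component uses them).

## Electrophysiology

Monodomain reaction-diffusion with the two-variable Mitchell–Schaeffer
cell model (normalized potential u, gate h; tau_in 0.3 ms, tau_out 6 ms,
tau_open 120 ms, u_gate 0.13 at their standard values, tau_close
personalized, default 150 ms). Conductivities are per-tag along-fiber
diffusivities in mm²/s — c_myo 413 (cohort mean), c_lv 1600, c_rv 2200
(values of a personalized example case) — with cross-fiber diffusivity
smaller by the anisotropy ratio 9, i.e. conduction three times faster along
fibers.

Numerics: P1 FEM with lumped mass and IMEX time stepping — implicit
diffusion (one sparse LU, reused every step) and explicit reaction, which
bounds dt at tau_in/3 (0.1 ms default); exceeding it raises with the bound.
This replaces a Lattice–Boltzmann scheme in the original workflow; the
contract is the monodomain solution, not the discretization. Stimuli are
saturating currents (amplitude × (1 − u)), so the potential never leaves
[0, 1] by more than the reaction overshoot; stimulated node sets must span
the liminal length (~ wavefront width) to ignite. On the unstructured
anatomy the P1 diffusion operator is not monotone (sliver and obtuse
elements), so the potential is clamped at the resting bound 0 after each
diffusion solve; structured slab results are unaffected by the clamp. Activation time is the
first upward 0.5-crossing (linearly interpolated), repolarization the last
downward crossing. The sinus protocol stimulates the upper third of both
septal endocardial surfaces (His-bundle surrogate; the exact sites are not
anatomically specified and are exposed as configuration). CRT protocols add
lead stimuli at the mesh nodes nearest user coordinates: biventricular
(LV lead first, RV after a 20 ms LV–RV delay), RV-only, and LV-triggered
(sensed intrinsic activation plus an LV stimulus after a 40 ms delay).

A note on the action potential duration: the closed form
APD ≈ tau_close·ln(tau_out/(4·tau_in)) describes the gate collapse exactly
(validated to <0.2%), but the potential lingers near the quasi-static fold
after the gate closes (slow passage), so the APD measured at the 0.5
threshold exceeds the formula by ~16 ms (~6–7% at default parameters).
Unit tests therefore assert against a fine-tolerance ODE oracle; the formula
is used where only its *slope* in tau_close matters (the QT personalization
step), which is accurate to ~2.5%.

Slab conduction-velocity studies use grid spacing proportional to the local
wavefront width (dz = 3·dx for a 9:1 tensor with fibers along z), so
discretization bias cancels in velocity ratios; measured along/cross ratio
2.90 on the 20×20×60-node reference slab.

## ECG

The default forward model is the infinite-homogeneous-medium pseudo-ECG:
electrode potential = −Σ_elements V·(D∇u)·∇(1/r). A bounded-torso boundary
element model is not included: the targeted features (QRS duration, QT
interval, electrical axis) are timing/direction features that are largely
insensitive to torso conductivity structure, and T-wave morphology is
explicitly not a fidelity target. The torso is a parametric ellipsoid
containing the heart, electrodes at fixed fractional surface coordinates in
clinical arrangement; leads follow the standard Einthoven/Goldberger/Wilson
algebra (I + III = II holds to round-off).

Feature extraction: QRS onset/offset are threshold crossings (5% of peak)
of the RMS-over-leads temporal derivative; the T-wave end uses an adaptive
threshold (10% of the post-QRS derivative peak) because repolarization is
an order of magnitude slower than depolarization — a fixed global threshold
misses it. A post-QRS peak below 0.5% of the global peak means
repolarization was not simulated and QT is reported as NaN. The electrical
axis is atan2(net aVF area, net lead-I area) over the QRS window, degrees,
0° along lead I and positive toward aVF; this convention is a design
decision, not a reconstruction of any particular clinical algorithm.

## Mechanics

Two-element Hill arrangement: isotropic linear elastic passive tissue
(E personalized, default 590 kPa = cohort mean; Poisson ratio 0.48 for
near-incompressibility) in parallel with an active fiber stress. The
co-rotational formulation extracts each element's rotation by polar
decomposition (batched SVD) and evaluates the linear element stiffness in
the rotated frame, so rigid motions are exactly force-free. Active stress
rises as sigma0·(1 − e^(−k_atp·(t − t_act))) between the element's
activation and repolarization times (from the EP solution) and decays
value-continuously at rate k_rs afterwards (defaults k_atp = k_rs =
0.02/ms, sigma0 = 295 kPa = cohort mean); it is applied as a rank-one
stress along the rotated fiber. The parallel-coupling reading of the
"two-element Hill model" is an interpretation; the cited rheology does not
fix the arrangement beyond passive + active in parallel at this level.

Boundary conditions: valve-annulus springs anchor the base rings;
the pericardium is a one-sided penalty toward the end-diastolic epicardial
bag along its outward normals (activating only for outward motion). The
input anatomy is taken as the end-diastolic state with no unloading step —
a common simplification; consequently EDV ≈ the generated cavity volume.

Time integration is a damped backward-Euler velocity update (Rayleigh
damping, alpha 0.1/ms, beta 0.02 ms — stabilization, the tissue damping is
not a fitted quantity). The tangent factorization is refreshed every 5
steps or whenever a step moves any node more than 2 mm (quasi-Newton with
an adaptive refresh); a step that still moves more than 25 mm with a fresh
tangent raises a divergence error naming the time and suggesting a smaller
dt. Momentarily inverted sliver elements are handled with sign-corrected
rotations (invertible FEM) inside the beat loop, while the standalone
passive-force operator keeps the strict inverted-element error.

## Hemodynamics and the coupled beat

Afterload per artery is the 3-element Windkessel (C dp_d/dt = Q − (p_d −
Pr)/Rp; p_prox = p_d + Rc·Q) with aortic defaults C 2269 mm³/mmHg,
Rp 3.64e-4, Rc 4.72e-5 mmHg·s/mm³, Pr 52 mmHg and pulmonary counterparts
(2757, 1.51e-4, 2.91e-5, 15) — the cohort means. The semi-implicit update
is exact for piecewise-constant flow; because the ODE is linear, the
periodic orbit under a sampled flow waveform is also available in closed
form (used by the Windkessel estimator; the time-stepping loop serves as
its independent cross-check in tests). Preload is a constant atrial
pressure (8 mmHg) plus a timed half-sinusoid contraction bump (4 mmHg,
100 ms, late diastole) — a documented surrogate for a full lumped atrium
whose published parameterization is not reproduced here. There is no
closed-loop circulation and the two ventricles are not hemodynamically
connected, mirroring the modeling scope this package emulates.

The four phases are switched by valve logic (filling → isovolumetric
contraction when ventricular pressure exceeds atrial; → ejection at
arterial pressure; → isovolumetric relaxation when forward flow would
reverse; → filling below atrial pressure). During the isovolumetric phases
the cavity pressure is found by prediction–correction: within each step the
factorized tangent is reused, so each pressure trial is a single triangular
solve, and a secant iteration holds the volume at its phase-entry value
(measured drift < 1% of stroke volume). During ejection the ventricular
pressure and Windkessel output pressure are made consistent by a damped
fixed-point iteration on p = p_distal + Rc·Q. A standalone
`isovolumetric_pressure` operator exposes the same correction as bracketed
root finding (brentq) for direct use and testing.

Default beat scales: LV-only test anatomy ≈ 660 nodes / 2900 tets, dt
2.5 ms, cycle 700 ms → ≈ 8–10 s per beat; the default bi-ventricular
anatomy at 3 mm edges is ≈ 4500 nodes and proportionally slower. These
sizes were chosen as the smallest that keep the physiology (phase sequence,
EF monotonicity in sigma0 and E, volume conservation) intact.

## Personalization

Exposed as model objects whose `fit()` returns a results object
(estimates, per-target residuals, iteration counts, convergence flag,
`summary()` table).

**EP (three steps, iterated).** (1) c_myo from the QRS duration: conduction
velocity scales with the square root of diffusivity, so a multiplicative
secant c ← c·(cQRSd/mQRSd)² converges in 2–4 depolarization-only forward
runs without derivatives. (2) (c_lv, c_rv) from the electrical axis: short
Nelder–Mead in log space on the absolute axis error (absolute rather than
signed — a design choice; the loop only needs a scalar merit), ≤ 14 runs,
skipped when the axis already matches half the tolerance. (3) tau_close
directly from the QT mismatch through the closed-form APD slope
ln(tau_out/(4·tau_in)), verified by one full-length run. The outer loop
repeats until |ΔQRSd| ≤ 5 ms and |ΔEA| ≤ 10° (configurable), normally
within two or three passes on self-consistent targets. QRS-only steps run
170 ms of simulation; QT steps run to full repolarization.

**Windkessel.** Nelder–Mead in log-parameter space on the RMSE between the
measured pressure cycle and the closed-form periodic response to the
measured flow; initialization uses Rp + Rc = (mean p − Pr)/mean Q with
Pr ≈ 0.7·min(p). Self-consistent recovery reaches RMSE ≈ 0.03 mmHg. Note
the classic compensation between C and (Rp, Pr): the pressure curve
constrains combinations of parameters more tightly than each parameter.

**Mechanics (E, sigma0).** Nelder–Mead over (log E, sigma0) of the
normalized squared mismatch Σ((computed − measured)/measured)² over the
present targets among EF/SV/EDV/ESV/EDP/ESP (unit weights by default;
missing targets are dropped from the objective). Each evaluation is a full
beat; a budget of ~16–25 evaluations recovers EF to well under one EF point
on self-consistent targets. sigma0 is parameterized linearly so a zero
lower/upper bound degenerates gracefully to the no-contraction case.

A Nelder–Mead simplex is used wherever the original workflow used a
NEWUOA-class optimizer; the contract is "derivative-free local optimizer
with bound support", and the loop logic, not the optimizer brand, carries
the method.

## Virtual cohort and statistics

Parameters are drawn from truncated normals at the published population
statistics (c_myo 413 ± 232 mm²/s, E 590 ± 135 kPa, sigma0 295 ± 100 kPa,
the aortic/pulmonary Windkessel rows, anatomy scale 1 ± 0.1); distribution
*shape* is a choice (only histograms were published), truncation bounds are
generous physiological ranges. Covariates (NT-proBNP-like biomarker, heart
rate, systolic pressures at rest/exercise, a survival-type outcome score in
[0, 1]) are statistical surrogates drawn through a Gaussian copula with
configured Pearson effect sizes against sigma0 (−0.5, −0.5, +0.5, +0.5,
+0.77). Because truncated marginals attenuate copula correlations, the
copula parameter is de-attenuated by the marginals' linearity coefficients
(Gauss–Hermite quadrature; NORTA-style matching), so the configured effect
sizes are realized as Pearson correlations (verified to ±0.01 at n = 4000).
The covariates are *not* biophysical outputs — the outcome score in
particular is a generated variable, which is exactly what lets the
statistics layer be tested against known ground truth.

Observations per virtual patient: `"full"` runs the 3-D forward model
(mesh → EP → ECG → beat); `"ep"` runs only the electrophysiology chain;
`"fast"` uses a documented 0-D emulator (QRSd ∝ scale/√c_myo, QT = QRSd +
plateau duration, axis ∝ log(c_lv/c_rv), EF from a saturating force
balance, systolic pressure from the Windkessel steady relation) for
large-n statistics studies where the PDE content is irrelevant. Seeded
Gaussian noise (QRSd 10 ms, EA 20°, QT 15 ms, EF 3 points, SV/volumes
8 ml, pressures 5 mmHg) is added afterwards; volume identities
(EF = 100·SV/EDV, ESV = EDV − SV) are restored after noising.

Statistics: Pearson r with the two-sided t-distribution p-value
(t = r·√((n−2)/(1−r²))); the two-sided single-outlier Grubbs test
(G = max|x − x̄|/s against the t-based critical value, at most one flag per
call); mean ± sample SD (n−1) summary tables. Type-I error calibration of
both tests is asserted at nominal α over seeded replicates.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the study — parameter
distributions, effect sizes, observation noise, the personalization loops —
but not real hearts: anatomies are smooth ellipsoid composites without
outflow tracts, trabeculation or regional disease; the tissue is globally
parameterized (no infarct scars, no bundle-branch blocks), which is exactly
the regime where axis personalization is easy and global features dominate;
ECG morphology (notching, T-wave shape) is out of scope. Passing tests
therefore demonstrate internal consistency, correct physics scaling laws,
and identifiability of the global parameters under the model's own forward
map — not clinical accuracy on patient data.

## Known limitations

* Linear isotropic passive tissue; real myocardium is orthotropic and
  hyperelastic. EF values at extreme sigma0/E should be read as model
  behavior, not physiology. The linear volumetric law is exact only at
  small strains: the wall stays within 3% of its volume in
  moderate-contraction beats, but at cohort-mean contractility on the small
  test anatomy (systolic strains ~ 25%) it leaks ~6–7% — inherent to the
  co-rotational *linear* formulation, not to the time integration.
* No pre-stress/unloading: the input anatomy is the end-diastolic state.
* The fast layer is a diffusivity surrogate for the Purkinje network; no
  retrograde coupling or discrete conduction tree.
* The atrial model is a pressure waveform, not a contracting chamber.
* Axis sensitivity to (c_lv, c_rv) is modest on smooth synthetic anatomies;
  the step-2 search is correspondingly shallow.
* Sliver tetrahedra from the Delaunay construction are tolerated, not
  removed; mechanics accuracy on the bi-ventricular mesh is coarser than on
  the structured test meshes used for the elasticity oracles.
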
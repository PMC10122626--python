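# Methods

`embryoheart` implements the biomechanical analysis of the HH25 chick
embryonic ventricle — the developmental stage at which left-atrial-ligation
(LAL) hearts, a surgical model of hypoplastic left heart syndrome, first
show mechanical differences from controls.  The package covers the whole
chain from 4D ultrasound cine processing to the calibrated finite-element
cardiac cycle, and provides synthetic generators for every input so the
pipeline is testable end to end without animal data.

## Models

### Passive myocardium

The wall is a transversely isotropic Fung-type hyperelastic solid,

    W = C (exp(Q) − 1),
    Q = b_ff E_ff² + b_xx (E_ss² + E_nn² + E_sn² + E_ns²)
        + b_fx (E_fn² + E_nf² + E_fs² + E_sf²),

with the Green–Lagrange strain E expressed in the local
fiber/sheet/sheet-normal frame.  Defaults: exponents b_ff = 29.9,
b_xx = 13.3, b_fx = 26.6 (dimensionless); scaling stress C = 19.7 Pa for
control and 27.6 Pa for LAL tissue — the stiffnesses micropipette
aspiration yields for HH25 myocardium of each group.  The second Piola–Kirchhoff stress
and the consistent material tangent are analytic; a finite-difference
oracle in the test suite verifies both.

Near-incompressibility is enforced by a volumetric penalty
U(J) = κ/2 (ln J)², κ = 2×10⁵ Pa by default.  At physiological loads
(cavity pressures of a few hundred Pa, active stresses of a few kPa) this
keeps |J − 1| below 1%; the solver exposes the attained range so tests can
assert the 2% contract.

### Active contraction

Active stress is the Guccione length- and time-dependent model: a rank-one
Cauchy stress of magnitude

    σ = T_max · Ca₀² / (ECa₅₀² + Ca₀²) · C_t

along the current (pushed-forward) fiber direction, with

    ECa₅₀ = (Ca₀)_max / sqrt(exp(B(l − l₀)) − 1),
    l = sqrt(e_f0 · C_V e_f0) · l_r,
    C_t = (1 − cos ω)/2,  ω rising over [0, t₀), falling over [t₀, t₀+t_r),
    t_r = m·l + b.

Defaults: Ca₀ = (Ca₀)_max = 4.35 µM, B = 4.75 µm⁻¹, l₀ = 1.7 µm,
l_r = 2.2 µm, t₀ = 110 ms.  Two parameterization notes:

* The printed form of the active stress couples the current and reference
  fiber directions ambiguously; we implement the standard Guccione
  reading, σ · e_f ⊗ e_f in the current configuration (pulled back to
  S = J σ/(e_f0·C e_f0) e_f0 ⊗ e_f0 for assembly).  A
  `formulation="second-piola"` flag provides the alternative
  reference-direction form.
* The relaxation-time constants m, b are not published; the defaults make
  t_r at the relaxed sarcomere length span 45% of the 164 bpm cycle, with
  the same relative length sensitivity (d ln t_r / d ln l ≈ 2.6) as the
  canonical adult parameterization.  A transient this long covers systole
  and early relaxation, which keeps end-systolic pressures positive, as
  measured embryonic pressure–volume loops do; tuning these constants to
  shape end-systole and early diastole is exactly what they exist for.
  Both are ordinary config parameters.

Calcium concentrations only enter through the ratio Ca₀²/(ECa₅₀²+Ca₀²),
so their absolute units cancel; the parameter table's "µm" for Ca₀ is
treated as µM.

### Finite elements

Total-Lagrangian displacement formulation on tetrahedra, quadratic
(10-node, 4-point quadrature) by default, linear allowed for fast tests.
Cavity pressure is applied through the enclosed-volume potential: the
endocardial surface is closed by a fan to the centroid of its basal ring,
making the volume a cubic polynomial of the nodal coordinates whose
gradient is the consistent follower nodal force and whose (symmetric)
Hessian is the load stiffness — pressure loading of a closed cavity is
conservative, which the external-work/strain-energy test exploits.
Volume-constrained steps treat the pressure as a Lagrange multiplier and
solve the bordered Newton system by block elimination.

Newton uses exact tangents, a best-of backtracking line search, adaptive
load continuation with step halving, factorization reuse while convergence
is fast, and a tangent predictor (du/dp from the previous converged bordered
solve) that makes sequential cycle steps cheap.  Linear solves use
SuperLU in symmetric mode with a relaxed pivot threshold plus one step of
iterative refinement — an order of magnitude faster on these
symmetric-pattern matrices than the default ordering.

Boundary conditions on the ventricle: basal nodes fixed along the long
axis only (in-plane free), plus two basal nodes pinned in-plane to remove
the remaining rigid modes.

### Micropipette aspiration

The aspiration experiment (60 µm lumen radius, 0 to −60 mmHg) is
idealized as a cylindrical tissue slab: radius six pipette radii,
thickness 0.24 mm (ventricular wall scale), lateral and bottom boundaries
fixed, vertical displacement blocked under a 30 µm-wide rigid pipette rim,
suction applied over the lumen disc through the same enclosed-volume
machinery.  This replaces full sliding contact with a fixed annular
support — the standard desk-scale MPA idealization.  The aspirated length
is the axial displacement of the lumen-centre surface point, solved
sequentially over the pressure steps.  The inverse fit minimizes the
summed squared length residuals over C alone (exponents held at their
published values) by bounded 1-D minimization in log C, terminating at a
relative tolerance of 10⁻³.

### Load-free geometry and the cardiac cycle

The unloaded configuration is back-computed by the fixed-point scheme:
inflate the current guess to the end-diastolic pressure, subtract the
displacement from the ED coordinates, repeat until the re-inflated
endocardial surface matches ED (mean node distance < 0.5% of the cavity
radius); updates are damped when they would invert the thin wall.  The
end-diastolic pressures used are 0.38 mmHg (control) and 0.28 mmHg (LAL);
the source text labels these "end-systolic" but uses them with
end-diastolic volumes for exactly this unloading step, so they are
treated as EDP.

The cycle is driven by a volume-time waveform (the stand-in for
image-derived volume curves) with constant-volume segments inserted at ED
and ES — 8% of the period each by default, the remainder uniformly
rescaled so stroke volume and period are preserved.  At each of the time
steps the cavity volume is imposed and the pressure is the reported
output while C_t(t) evolves.  T_max is calibrated by secant iteration
until the peak cycle pressure matches the group target (3.1 mmHg control,
2.6 mmHg LAL) within 1%; sweep cycles are truncated shortly after the
systolic peak and the final run uses the full cycle on the same step
grid.  Stress summaries report the Frobenius norm of the Cauchy tensor
and its projection along a direction field (the minimum-principal strain
directions when cine data exist, else the mesh fiber field).

## Synthetic data

* **Geometry** — thick-walled truncated ellipsoid, endocardial semi-axes
  (0.72, 0.72, 1.0) mm by default: the 1.44 mm width matches the imaged
  end-diastolic hearts; the 1.4:1 aspect ratio is a convention, since no
  full dimension set is published.  Wall thickness 0.18 mm (normal LV)
  or 0.24 mm (LAL LV).  The base is cropped flat at 30% of the long
  axis.  A structured shell grid is split into conforming tets through
  cell centres; boundary midside nodes are projected onto the analytic
  surfaces (with a blending fallback where projection would invert coarse
  apex elements).  Uniform refinement is isoparametric — children are
  placed through the parent's quadratic map — so it preserves the
  geometry exactly and ships a prolongation operator for warm-starting
  the refined solve.

* **Motion** — the ground-truth displacement scales every normalized
  ellipsoidal shell by ρ → (ρ³ + k(t))^{1/3}, which is exactly volume
  preserving and produces equibiaxial in-plane strain on each shell; k is
  calibrated by secant so the layer-mean minimum-principal strain at peak
  contraction equals the prescribed value (−0.139 control LV, −0.198 LAL
  LV in the recovery tests) to 2×10⁻⁴.  On an ellipsoid, the
  constant-offset analysis layer is not a constant-ρ surface, so the
  pointwise strain spreads by about ±0.01 around that mean; on a sphere
  it is exact.  The "random-uniform" mode composes the shell map with a
  seeded superposition of divergence-free Fourier modes, giving the local
  contraction direction a near-uniform angle distribution while the
  volume error stays second order (|J−1| < 0.005 at the default
  anisotropy of 0.05); its strain contract holds on spatial average.

* **Cine** — tissue is rendered as Gaussian speckles advected by the
  motion field (with a Gaussian slice-thickness weight of 30 µm), the
  blood pool as per-frame decorrelated noise inside the deformed cavity;
  this reproduces the contrast mechanism the ensembles exploit (quadratic
  ensemble bright in blood, arithmetic ensemble bright in tissue) without
  any ultrasound physics (no attenuation, shadowing, or speckle
  statistics of real scatterers).  Planes are 50 µm apart; ≥ 20 cycles
  are rendered; per-plane acquisition offsets emulate the sequential
  plane-by-plane protocol.

* **Waveform** — V(t) = EDV − SV·(1 − cos 2πt/T)/2 at 164 bpm
  (T = 365.85 ms).  The default stroke volume is 30% of the EDV: within
  the modest ejection fractions of the early embryonic ventricle, and
  chosen so end-systole sits near the load-free cavity volume of the very
  soft HH25 wall — ejecting far below the unloaded volume puts the thin
  shell deep into a numerically hostile buckling regime that the study
  conditions give no reason to enter.

* **Aspiration records** — generated by the forward slab model at the
  true C with optional Gaussian length noise; recovery tests are
  noise-free by construction ("inverse crime" deliberately, since the
  target is the inverse loop, not model error).

## Kinematics pipeline

Displacement fields (from the analytic truth in tests; from cine block
matching on real data) are regularized by a global motion model — a
truncated Fourier series in time (3 harmonics) times a tensor-product
cubic B-spline lattice in space (6–7 cells per axis by default; the
lattice is the resolution-limiting choice and the defaults keep the
recovered layer-mean strain within 0.003 of truth at the test sampling
density).  When all phases share sample points the normal equations
factor into a single spatial solve (Kronecker structure).  Control points
without data support are zeroed and recorded; evaluation through them
raises.  Strain on the 35 µm sub-epicardial layer is computed relative to
end-diastole, projected onto the circumferential–longitudinal tangent
plane *before* eigen-decomposition (the 3D-eigenvector alternative is not
the default); eigenvalue ties set a degeneracy flag and report the
circumferential direction.  Wall thickness is measured by area-uniform
seeded sampling of epicardial triangles with smooth (vertex-interpolated)
inward normals, ray-cast against the endocardial surface.

## Numerical choices and limitations

* Tolerances: Newton relative residual 10⁻⁶ against the external load
  norm; cavity-volume constraint 10⁻⁴ relative; C-fit bracket 10⁻³
  relative; unloading 0.5% of cavity radius; T_max 1% of target pressure.
* Degenerate inputs raise: aperiodic cine, empty phase bins, rank-deficient
  motion fits, non-positive Jacobians, unreachable volume targets,
  non-positive relaxation times where tension is possible.
* Problem sizes: ventricle ≈ 3000 quadratic tets (the resolution at which
  the refinement check shows < 2% stress change; the refinement study
  itself starts from the lower edge of that window so its 8×-refined
  counterpart stays tractable), aspiration slab ≈ 1650, 16–20 cycle
  steps; the test suite uses 700–1500-tet meshes, which the calibration
  contracts do not depend on.
* The LAL stiffness default follows the parameter table (27.6 Pa); the
  running text reports 29.3 ± 7.8 Pa for the same fits.  Both are within
  one standard deviation; the table value is used because it is the one
  propagated into the published simulations.
* Single-chamber idealization: LV/RV distinction enters only through
  wall thickness and parameter sets; no trabeculation, no transmural
  strain variation (single analysis layer), no fluid–structure
  interaction, no viscoelasticity, quasi-static (no inertia).
* Passing the synthetic recovery tests demonstrates the correctness of
  the inverse loops and strain pipeline under the stated generators; it
  does not validate the constitutive model against real tissue, nor the
  tracking against real speckle statistics.
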
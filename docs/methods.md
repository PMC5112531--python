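# Methods

## The model

A flat bilayer stands in for a small piece of developing brain: a thin
cortical plate (default 2 mm) bonded to a thick, non-growing core (subplate
+ intermediate + ventricular zones lumped together). Geometry is chosen
flat on purpose — the question is what heterogeneous growth and stiffness
do, not what curvature does.

**Kinematics.** The deformation gradient decomposes multiplicatively,
F = A·G. The growth tensor G = g·I is isotropic, stress-free, and
prescribed (independent of stress); only the cortex grows (g = 1 in the
core). The elastic tensor A = F·G⁻¹ carries all stress. In the default 2D
plane-strain model tensors are 2×2 and the out-of-plane elastic stretch
is 1; det G = g^d with d the kinematic dimension.

**Constitutive law.** Both layers are neo-Hookean with identical shear
modulus μ = 330 Pa (gray and white matter moduli are experimentally
indistinguishable, and the folded pattern depends only on the ratio).
The strain energy per unit grown volume is

    W(A) = μ/2 (λ₁² + λ₂² + λ₃² − 3) − μ ln J + K/2 (J − 1)²,  J = det A.

The −μ ln J term makes the reference state stress-free; the volumetric
penalty pressure p = K (J − 1) stands in for the incompressibility
Lagrange multiplier. The Cauchy stress is σ = (μ/J)(A·Aᵀ − I) + p·I.
K = 400 μ keeps |J − 1| ≤ 0.02 everywhere, including the dynamic
transient when a fold snaps through (100 μ, a common default, does not).

**Discretization.** Structured bilinear quads (2D) or trilinear hexes
(3D), uniform in-plane at the cortex resolution (1.25 mm default) and
graded through depth so core elements are ≥ 2× coarser; ≥ 2 element layers
through the cortex. Selective reduced integration: the isochoric term at
the full Gauss set, the volumetric penalty at the element center — no
volumetric locking at high K, no hourglassing, and nodal forces are the
exact gradient of the discrete energy (verified against finite
differences). Growth enters the reference-volume integral through the
factor g^(d−1) on the first Piola stress ∂W/∂A·G⁻ᵀ.

**Quasi-static relaxation.** Damped central-difference (explicit)
dynamics with mass-proportional damping; density is a free mass-scaling
parameter (only the quasi-static limit matters), and the stable step comes
from the penalized P-wave speed and the smallest element edge (safety
0.6). Baseline cortical growth ramps linearly to g_max = 2.2 over 150 time
units. With equal moduli the flat state stays linearly stable until the
in-plane elastic compression approaches the surface-instability threshold,
so folding starts around g ≈ 1.6–1.7; g_max = 2.2 guarantees the ramp
crosses it. The kinetic/strain-energy ratio is monitored throughout.

**Instability handling.** Fold formation at equal moduli is subcritical:
once triggered it releases stored compression violently. When the
detrended surface amplitude reaches 1× cortex thickness, growth (and the
stiffness schedule) is frozen and the pattern relaxes under stronger
damping (3 vs 0.6) until the kinetic/strain ratio falls below 2%, the
relaxation budget is exhausted, or non-adjacent surface points approach
within 0.5 mm (the self-contact guard — late-stage contact mechanics is
out of scope, so runs stop there). Seeded perturbations (uniform in
±0.05 mm = 2.5% of cortex thickness, de-meaned) are built into the
*reference* geometry: a stress-free imperfection, so t = 0 is an exact
equilibrium. Boundary conditions are the minimal confinement that forces
cortical compression: bottom fixed normally, lateral faces on rollers.

**Growth modes.**
* `homogeneous` — whole cortex at the baseline rate;
* `fast_patch` — the special area's growth *rate* is 1.2× the baseline
  (g_patch − 1 = 1.2 (g − 1), so g(0) = 1 holds; the 1.2 mirrors the
  observed gyral/sulcal thickness ratio);
* `stiff_patch` — homogeneous growth, but the special area's modulus
  ramps linearly from 1× to its final multiplier (2, 4 or 8×). The ramp
  completes by half the growth ramp, i.e. by instability onset: growth is
  frozen at folding, and the folded state is meant to carry the full final
  multiplier.

**Special area.** A centered cortex patch, full cortex thickness, default
width 10 mm ≈ 0.7× the homogeneous fold wavelength (~14.5 mm at default
settings). The width is a genuinely free parameter and the stiff-patch
outcome is sensitive to it: patches wider than about one wavelength act as
stiff plates that arch *outward* instead of sinking. The default sits well
inside the regime where a stiffening patch robustly forms a sulcus and a
fast-growing patch a gyrus.

## Fold-outcome classification

The center region of a folded profile is classified from geometry alone:
detrend the profile in a ±15 mm window (≈ one fold wavelength), rank the
center height among the window samples, and call percentile ≥ 75 a gyrus,
≤ 25 a sulcus, anything between a bank. Profiles whose detrended window
amplitude is below 10% of cortex thickness raise "no instability" instead
of being classified. Batch ensembles report per-mode counts with exact
(Clopper–Pearson) binomial CIs on the gyrus proportion. Per-run seeds are
derived by hashing (base seed, mode, run index), so batches are
reproducible and resumable from a cache.

## Surface metrics

* **Thickness** — for each white-surface vertex, the Euclidean distance to
  the nearest pial *vertex* (the measurement's own definition;
  a vertex-to-triangle projection variant would be smoother but is a
  different quantity).
* **MPC** — a quadric height function is fit over the 2-ring neighborhood
  in the tangent frame of the outward vertex normal; the shape operator's
  eigenvalue of larger magnitude, signed so convex is positive, is the
  maximal principal curvature ("larger signed value" available via
  `magnitude_rule='signed'`). Isolated or under-determined vertices are
  NaN and excluded downstream.
* **Growth rate** — per-vertex OLS of thickness against week; R² of a
  zero-variance trajectory is defined as 0; the reliability filter keeps
  R² ≥ 0.6 (inclusive; a strict flag exists).
* **Grouping and tests** — vertices split by the strict sign of MPC (zeros
  and NaNs in neither group); pooled-variance Student t-test with
  dof = n₁ + n₂ − 2, computed from the textbook formula with only the
  Student-t CDF delegated to scipy; right tail tests gyral > sulcal.

## Synthetic longitudinal surfaces

The generator emulates the *structure* of a longitudinal fetal surface
series, not its anatomy: a corrugated sheet (primary sinusoid of 50 mm
wavelength and 5 mm amplitude plus a small second harmonic, phase-offset
so curvature zeros avoid grid lines), 60×60 vertices on 200×200 mm, seven
timepoints labelled weeks 25–31 sharing one topology so cross-time vertex
correspondence is the identity — the stand-in for spherical registration.
Ridge vertices (positive analytic curvature) thicken at 0.35 mm/week,
valley vertices at 0.10, with i.i.d. Gaussian residuals (sd 0.26 mm) per
vertex per timepoint, floored at 0.1 mm; the pial surface is the white
surface offset along outward vertex normals, with a guard raising an error
if thickness approaches the concave radius of curvature (offset
self-intersection).

Two geometry choices matter and were fixed once, by analysis:

* **Vertex spacing ≈ 3.4 mm.** Closest-vertex thickness across a *step*
  in thickness (binary gyral/sulcal slopes) is undercut whenever spacing
  < √(t_g² − t_s²) (~3.2 mm by week 31): the nearest pial vertex to a
  thick-side vertex is then a thin-side neighbor. At 3.4 mm spacing the
  measurement is exact for every vertex in the noise-free case, and wrong
  for < 1% of vertices (always an underestimate) with noise.
* **Wavelength 50 mm.** At this spacing, shorter wavelengths degrade the
  MPC sign near inflection lines; at 50 mm the estimated-MPC grouping
  agrees with the generative ridge/valley labels for ≈ 99.9% of vertices.

**What passing on these surfaces does and does not show.** The generator
has no registration error, no spatially correlated noise, no curvature-
correlated thickness, and binary rather than continuous growth rates, so
pipeline recovery here certifies the estimator chain, not robustness to
real-data artifacts.

**The R²-filter selection effect.** With slope 0.10, residual sd 0.26 and
7 timepoints, a vertex passes R² ≥ 0.6 essentially only when its *noisy*
slope estimate exceeds ≈ 0.13 in magnitude (pass fraction ≈ 1/3), so the
kept sulcal group's mean slope converges to ≈ 0.14, not 0.10 — a property
of the filter at this noise level, reproducible in closed form by
truncated-normal arithmetic, and independent of the curvature estimator
(the gyral group, slope 0.35, passes at ≈ 100% and is recovered to three
decimals). The package reports the honest post-filter value; the
gyral-vs-sulcal contrast, the pipeline's actual conclusion, is unaffected
(t ≈ 90).

## Numerical and statistical defaults

| parameter | default | units | note |
|---|---|---|---|
| μ (both layers) | 330 | Pa | pattern depends only on the modulus ratio |
| bulk penalty K | 400 μ | Pa | keeps per-point det A within 2% of 1 |
| cortex thickness | 2 | mm | pre-growth |
| plate (2D desk scale) | 100 × 25 | mm | full-plate geometry via config |
| g_max / ramp | 2.2 / 150 | — / t.u. | ramp crosses the folding threshold |
| damping (ramp / hold) | 0.6 / 3.0 | 1/t.u. | mass-proportional |
| perturbation | 0.05 | mm | 2.5% of cortex thickness, seeded |
| special-area width | 10 | mm | ≈ 0.7 homogeneous wavelength |
| classifier cuts | 75 / 25 | percentile | gyrus / sulcus vs bank |
| R² threshold | 0.6 | — | inclusive |

## Known limitations

* No contact mechanics: runs terminate at a minimum-gap threshold, so the
  deeply convoluted, self-touching late stage is out of reach.
* The 2D plane-strain cross-section captures where folds form along the
  section; 3D mode exists but is meant for small demonstration meshes.
* Fold outcomes post-instability are deterministic chaos: mirror symmetry
  and objectivity hold exactly below threshold and only statistically
  beyond it.
* The stiff-patch conclusion is robust in, but conditional on, the patch
  width regime documented above.
* Quasi-staticness is monitored, not enforced: during snap-through the
  kinetic/strain ratio transiently exceeds the 5% target before the hold
  phase drains it.
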
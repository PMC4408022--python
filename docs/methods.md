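# Methods

## Scope and geometry

`bctsim` models one sagittal slice of a breast in 2D. Coordinates are in
mm with `x` anterior (away from the chest wall) and `y` superior; the
chest band occupies `0 ≤ x ≤ 3 mm` and is clamped in every mechanical
solve (the pectoral wall is orders of magnitude stiffer than breast
tissue). Gravity is `(0, −9.81)` m/s² seated and `(+9.81, 0)` m/s²
prone. Working units are mm / kPa / kg·L⁻¹ / mN, with cavity pressures
accepted in Pa.

## Synthetic phantom

The phantom emulates the data a single-patient BCT study acquires. The
breast outline is a half-ellipse on a vertical chest wall (default
protrusion 65 mm over a 120 mm wall) with a smooth low-order Fourier
radial perturbation (relative amplitude 0.02, windowed by cos²θ so the
chest attachments stay fixed) to break symmetry the way a real profile
does. Tissue composition: a 1 mm skin band along the silhouette;
glandular tissue as a thresholded smoothed Gaussian random field
(correlation length 4 mm) biased toward the retro-areolar region, with
the threshold set by quantile so glandular pixels occupy exactly the
requested fraction of the interior (default 0.25 — no quantitative
distribution is available for the study patient, so this is a
representative mammographic density); the rest is fat. The tumor bed is
a 12 × 9 mm ellipse centred 47 mm deep from the skin, above the nipple.
Label maps are rasterised at the MRI pitch of 0.7031 mm.

MRI-like images assign class-mean intensities (background 20, fat 100,
glandular 180; skin and chest share the fat intensity, matching the
three-class appearance the segmentation stage expects) plus iid Gaussian
noise clipped to [0, 255]. Observed contours are produced by the forward
model at known true parameters, divided by an "aspect ratio" emulating
the unknown photograph scale, and perturbed along local normals by
circularly smoothed Gaussian offsets rescaled to the requested RMS (the
chest-wall closure is left unperturbed). What the phantom does *not*
emulate: MRI physics (bias fields, partial volume), 3D out-of-plane
anatomy, and real inter-patient variability — passing tests demonstrate
the internal consistency of the pipeline and the identifiability of its
parameters under the model's own assumptions, not clinical validity.

Randomness: one master seed; each stage (outline, glandular field, MRI
noise, observation noise, CA) draws from an independent stream derived
by hashing the stage name into the seed sequence, so stages can be
re-run in isolation and full runs are bit-reproducible.

## Image operations

Fuzzy C-means runs on pixel intensities with fuzziness m = 2, tolerance
1e-5 on centroid movement, centroids initialised at evenly spaced
percentiles with a small seeded jitter; classes are ordered by centroid
intensity (darkest = background). The skin interface profile is smoothed
by exact second-difference (curvature) Tikhonov regularisation with
natural boundary conditions. Contours are extracted by marching squares
at the 0.5 level on a zero-padded mask, giving closed sub-pixel
polylines in mm whose enclosed area tracks the pixel-count area to
better than 1%.

## Meshing

Meshes are structured right-triangle grids (spacing `target/√2`, so no
edge exceeds the target size) restricted to cells whose centre lies in
breast tissue, with all outer boundary nodes snapped onto the marching-
squares silhouette and cavity nodes snapped onto the exact cavity
ellipse / wound polyline. Each snap is accepted only if every incident
element keeps positive orientation and a minimum angle ≥ 20°; this keeps
total area within ~0.5% of the label-map area while guaranteeing element
quality. Element materials come from the label at the centroid; boundary
edges are classified by probing the label just outside (chest vs air)
or a polygon test (cavity), and are oriented tissue-on-left.

The virtual lumpectomy removes the elliptical tumor bed plus the
surgical negative margin. The margin is added radially to each semi-axis
(12 × 9 mm bed + 5 mm margin → 22 × 19 mm cavity): the convention
matches how surgical margins are quoted, as tissue thickness around the
bed. Remeshing after healing rebuilds the same base grid, carves the
current wound polygon, and labels elements inside the original cavity
but outside the wound as scar, so total area is conserved and scar
bookkeeping is exact up to element size.

## Mechanics

Compressible Neo-Hookean energy `W = μ/2 (J^{-2/3} I₁ − 3) + K/2 (J−1)²`
with `μ = E/2(1+ν)`, `K = E/3(1−2ν)` and ν = 0.49 for all tissues
(penalty-type quasi-incompressibility; |J−1| stays below 5% at
physiological stiffness under seated gravity). Plane strain replaces the
extruded-slice trick used with 3D solvers: the out-of-plane stretch is
fixed at 1, so `I₁ = tr(F₂ᵈᵀF₂ᵈ) + 1` and `J = det F₂ᵈ`. Densities: fat
0.9, all other tissues 1.0 kg/L.

Discretisation: six-node (quadratic) triangles with straight edges,
three-point quadrature, displacement-only formulation. The first
Piola-Kirchhoff stress and its exact tangent are assembled analytically
(the tangent is verified against finite differences in the tests).
Gravity is a dead body load; cavity pressure is a follower traction on
the current cavity wall with its exact (geometry-linear) tangent.

Newton solves use an LU factorisation that is reused while the residual
is dropping fast (refactored when the reduction per step is < 4×), full
steps with damping only on element inversion (transient residual
overshoot is normal and must not trigger damping), convergence at
relative residual 1e-8, and load ramping (1 step when warm-started from
a neighbouring solve, falling back to 4 then 10 increments from rest).
A typical 2,800-element phantom solve takes ~1 s cold and ~0.3 s warm on
one CPU.

The unloaded configuration is estimated by the fixed-point ("inverse
gravity") iteration `X ← X − (φ(X) − X_obs)` with relaxation 1, which
contracts in 3–5 cycles on the phantom and reproduces the observed
geometry to < 0.05 mm. Both conventions from the study are available:
the calibration pipeline by default treats the phantom reference as the
stress-free state (self-consistent for synthetic data), while
`estimate_unloaded` provides the inverse-gravity route.

The healing stimulus `Ê` is the per-element strain-energy density
normalised by its maximum (the scalar the coupling diagram calls the
normalised stress; the exact scalar is not pinned down in the source
material, and W-based normalisation is the natural energetic choice).

## Wound healing

The CA lives on a hexagonal lattice (default spacing 1 mm) covering the
cavity plus a 15 mm tissue pad on the *unloaded* geometry. Sites inside
the wound are empty; the lattice rim is a homogeneous Dirichlet far
field for the growth factor; missing/empty neighbours give natural
no-flux conditions, in particular at the wound wall. The hexagonal
7-point Laplacian `(2/3h²)Σ(c_nb − c)` is integrated implicitly (or the
steady problem is solved directly); D = 0.05 cm²/day, Λ = 0, source
χ = 1 in an active layer of 2 lattice rings around the wound edge
(the layer width is unstated in the source material; 2 rings ≈ 2 mm).
The cut-off `F(c)` is a hard threshold at 10% of the mean steady
active-layer concentration — with the deliberately overestimated source
this makes F ≈ 1 near the wound, as intended.

Division update: each empty wound-edge site is colonised with the
division probability of its adjacent occupied active-layer tissue (the
strongest candidate parent). This empty-site-centric form has the same
edge-fill expectation `Σ_e p(e)` as parent-centric division but
guarantees that saturated division (p = 1) fills exactly one ring per
step, which the parent-centric form cannot (two parents can both pick
sibling sites and strand an empty site). Decisions are simultaneous from
the pre-step state, making trajectories bit-reproducible under a seed.

CA clock: one division sweep per 7-day coupling interval, i.e. α₀ is a
per-interval probability and the front advances ≈ α₀ · spacing per week.
A daily sweep at α₀ ≈ 0.17 would close a 22 × 19 mm cavity by week ~13,
which contradicts the multi-month healing the model is meant to capture;
the weekly sweep reproduces a cavity that is smaller but still open at
week 19.

The level-set reference (inward normal propagation by iterated negative
polygon buffering) is a cross-check oracle only. With the matched speed
defined a priori from the CA's one-step edge-fill expectation, area
curves agree to ~4% in the saturated regime; at intermediate p the
stochastic front roughens and runs ~20% faster than a constant-speed
sharp interface — a known property of Eden-like growth, documented here
as the boundary of the CA/level-set equivalence.

The weekly coupling loop solves the loaded mechanics, maps `Ê` to
lattice sites by nearest element centroid in the reference
configuration, solves the growth factor, runs the CA sweep, extracts the
wound polygon (union of empty hexagonal cells, simplified), and
remeshes. When α₁ = 0 and no mechanics recording is requested the
equilibrium solve is skipped — the stimulus would be multiplied by zero.

## Calibration

The objective rasterises both contours on a common square ROI at the
MRI pitch (cells crossed by the polyline, supersampled at a quarter
cell; the ROI origin sits half a cell below the joint minimum so
coordinates never fall exactly on cell boundaries) and counts cells
crossed by exactly one contour — the absolute-difference reading of the
per-cell norm, exposed as the symmetric-difference default. The aspect
ratio s is minimised per grid point by a coarse scan over [0.5, 2], a
fine scan around the bounding-box diagonal ratio (exact for a purely
rescaled contour), and local refinement; f is piecewise constant in s,
so scanning beats golden-section descent on plateaus.

Phase forward models (all evaluated as the seated loaded contour):

* Phase 0: intact breast, unknowns (E_fat, E_glandular, E_skin).
* Phase I: lumpectomy cavity + 5 mm inflamed ring at 80 kPa, fat and
  glandular moduli scaled by λ₁ (skin unchanged), seroma pressure P on
  the cavity wall.
* Phase II: 19 weeks of coupled healing at α₀ (pressure back to zero),
  then λ₂ scaling of fat/glandular; scar formed during healing gets base
  modulus E_glandular⁰ (granulation ≈ dense glandular tissue — the base
  scar stiffness in this phase is not stated in the source material), so
  its effective modulus is λ₂·E_glandular⁰.
* Phase III: wound closed and filled with scar of unknown modulus
  E_scar, fat/glandular scaled by λ₃.

Grids are uniform, inside the admissible bounds (E_fat 2–15,
E_glandular 5–15, E_skin 5–30 kPa, λ 1–3, P 0–500 Pa, α₀ 0–0.6), with
spacings chosen so the study's fitted values are interior grid points:
λ₁ ∈ linspace(1, 3, 11), P ∈ linspace(0, 400, 11) (Δ = 40 Pa),
λ₂ ∈ linspace(1, 3, 11), α₀ = 0.0425k, λ₃ ∈ linspace(1.2, 2.2, 11),
E_scar = 10 + 7k kPa. The "reduced" level coarsens these for quick runs
(the acceptance script uses it). Phase II's healed mesh is cached per α₀
and solver warm starts are reused along material-only axes, which is
what makes exhaustive search affordable.

`run_full_study` threads the fitted Phase-0 moduli into Phases I–III
(mirroring the quasi-steady restart from the relaxed Phase-0 state) and
reports fitted parameters, surfaces, cosmesis metrics and the week-19
cavity dimensions; identical master seeds give byte-identical reports.

## Cosmesis metrics

The nipple on a 2D profile is the most anterior contour point (ties
broken toward lower y). Metrics: absolute vertical nipple height
difference between treated and control contours (the Phase-0 baseline
serves as the control for a single simulated breast); breast area inside
a disc of fixed radius about the nipple (default 60 mm — the study's
radius is unstated); and the principal-axis extents of the (deformed)
cavity boundary. Phase boundaries in metric time series are estimated by
exhaustive two-change-point segmentation with independent linear trends
per segment; monotone or constant series are flagged degenerate.

## Problem sizes and numerical defaults

Package defaults are desk-scale: 3 mm target elements (~2,800 triangles
on the phantom; quadratic, so ~12k displacement dofs), 1 mm CA lattice
(~3,000 sites), reduced calibration grids (35–160 points per phase).
The full acceptance run completes in a few minutes on one CPU.

## Known limitations

* 2D plane strain conserves cross-section area almost exactly at
  ν = 0.49, so volume-change effects (seroma swelling) are nearly
  invisible in the silhouette: the Phase-I lateral-disc-area change on
  the phantom is slightly negative rather than the clinically observed
  swelling, and P is only weakly identified (which the sensitivity
  analysis quantifies). The nipple-elevation direction is reproduced.
* The α₀ direction of the Phase-II surface is flat only where healing
  has visibly progressed (α₀ ≳ 0.15): an entirely unhealed cavity is
  clearly visible in a 2D slice, producing a sharp wall at the low-α₀
  edge of the valley.
* The stochastic CA front is not exactly a constant-speed interface (see
  above); parameter fits treat α₀ at the weekly sweep scale.
* Chest-wall clamping and the absence of contact, anisotropy and
  viscoelasticity are deliberate simplifications of the tissue model.
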
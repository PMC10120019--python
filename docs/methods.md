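# Methods

This note documents the models and numerical choices behind
`nucleostress`, what the synthetic data emulate, and the limits of what
passing tests demonstrate.

## Synthetic nuclei and ground truth

The generator is polar: a base radius R₀ (default 8 µm, the scale of a
hepatocyte nucleus) modulated by low-order Fourier modes
r(θ) = R₀(1 + Σ aₖ cos(kθ + φₖ)), with |aₖ| < 0.3 so the shape stays
star-convex. Two droplet-induced feature types are carved in
geometrically:

- **Dents** replace the local boundary by the near arc of a droplet
  disk of the given radius, positioned so the indentation reaches the
  given depth. Because the dent is a true circular arc, the generative
  dent radius is exactly the radius of curvature a detector should
  recover — which is what makes indentation-radius recovery testable.
- **Pinches** model the envelope squeezed between large droplets: a
  small disk internally tangent at the pinch angle supplies a convex
  tip of the given radius, flanked by two deep dents (radius 3ρ, depth
  2ρ) that overlap the apex so the tip arc is the exposed boundary.

Default feature geometry in the validation fixtures: dent depth 1.5 µm
on the 8 µm nucleus. This is deliberate: much shallower dents leave
shoulder corners whose apparent radius (set by the smoothing scale, not
geometry) falls inside the 1–5 µm detector band, while much deeper
dents let the smoothing merge shoulder and trough and bias the
recovered radius. 1.5 µm sits in the physiologic indentation range and
gives clean, unique negative events for small dent radii.

Rendering is anti-aliased analytically: each pixel carries the
PSF-convolved edge profile Φ(d/σ_e) of its signed distance d to the
boundary (σ_e = 0.2 µm, the diffraction scale of a high-NA water
objective at the default 0.25 µm/px). Evaluating the smooth profile
*before* sampling means the rim does not alias on the pixel grid — a
hard or ramp edge at this pixel size sits at Nyquist and leaves
coherent, orientation-dependent boundary errors that would dominate the
irregularity floor. Chromatin texture is a seeded field of Gaussian
blobs (amplitude = contrast × background) whose centres stay ≥ 2
blob-σ inside the envelope, keeping texture and rim shape independent;
detector noise is added last. All randomness flows through one
`numpy` generator seeded per call.

What the generator does **not** emulate: realistic PSF anisotropy and
depth attenuation, shot-noise statistics, touching nuclei,
out-of-focus droplet fluorescence. Passing tests therefore demonstrate
algorithmic correctness and noise robustness at realistic SNR, not
performance on arbitrary real micrographs.

## Irregularity and its oracle

The statistic integrates |r(θ)/r̄ − 1| over θ in radians, without
normalizing by 2π; all comparisons in the package use this fixed
convention. The centre is the area centroid; r(θ) is interpolated from
vertex angles for star-convex outlines and taken as the outermost
ray–boundary intersection otherwise (flagged `star_convex=False`).

The independent oracle evaluates the same functional by dense
quadrature (≥10⁵ samples) directly on the generative polar function,
bypassing all image and contour code. It recenters analytically at the
exact polygon centroid first, because that is the statistic's centre
definition — dents shift the centroid by enough (~0.1 µm for a 1 µm
dent) to matter at the few-percent level.

Two pipeline details keep the measurement within a few percent of the
oracle through the full raster round-trip:

- `segment_nuclei` retains its smoothed image and threshold, and
  `extract_boundary` contours that continuous field (cubically
  upsampled 4×) instead of re-quantizing the binary mask, which would
  reintroduce irreducible half-pixel errors on grid-aligned stretches.
- Gaussian smoothing of an indicator shifts its mid-level set by
  σ²κ/2 along the normal (inward where convex), visibly shallowing
  indentations. `extract_boundary` undoes this first-order curvature
  bias using the known segmentation smoothing scale.

Known property limits: the "adding a dent never decreases
irregularity" monotonicity holds on near-circular baselines (the
hepatocyte regime) but can genuinely fail on strongly lobed baselines,
where the dent's centroid shift partially cancels the mode signal.
Validation sweeps use texture-free nuclei with 2% noise: blob texture
perturbs the global Otsu threshold near the rim and is exercised by the
condensation tests instead.

## Curvature and indentation events

The contour is resampled uniformly by arc length, smoothed with a
periodic Gaussian (default σ = 0.4 µm: below the 1 µm minimum feature
radius of interest, above pixel noise), re-parameterized by the
smoothed curve's own arc length (smoothing shrinks the curve
non-uniformly; without re-parameterization the turning-number integral
is biased by a few percent), and differentiated centrally. Sign
convention: positive κ = locally convex, so a CCW circle has
κ = +1/R everywhere.

Events are contiguous arcs with |κ| ≥ 1/r_max whose peak also exceeds
1.5× the global convex curvature 2π/perimeter (the factor separating
"sharp" features from overall roundness; no published threshold
exists, so it is exposed as a parameter). One event per arc at the
|κ| extremum; radii outside [r_min, r_max] = [1, 5] µm are discarded.
Recovery accuracy is smoothing-limited at roughly −10% (the Gaussian
flattens extrema), well inside the ±20% validation band.

## Segmentation and measures

DAPI segmentation is the standard recipe: Gaussian smoothing in
physical units (default 0.5 µm, resolution-stable), global Otsu
threshold (exposed; "mean" available), hole filling, 4-connected
labeling, and a 20 µm² minimum-area filter for debris. Intensity
measures operate on maximum projections by default. Area = pixel
count × pixel area; integrated density = mean × area; volume = voxel
count × voxel volume. The YZ aspect ratio reslices the stack,
maximum-projects along X, and takes the ratio of the moment-fit
ellipse's Y and Z axes in physical units, making it invariant to voxel
anisotropy; values > 1 indicate spread-induced flattening.

## Chromatin condensation parameter

CCP = fraction of nuclear pixels whose Sobel gradient magnitude clears
a threshold, measured after eroding the mask by 3 px so the envelope
step (identical in every nucleus) stays out of the statistic. The
default threshold is *relative*: 0.1 × mean in-mask intensity, in the
spirit of the edge-density method family this metric descends from. An
Otsu-over-gradients mode exists but is asymptotically scale-free in
texture amplitude: once texture gradients dominate noise, Otsu rescales
with them and CCP saturates, losing ordinal power between strongly
textured nuclei — the reason it is not the default. Only relative CCP
comparisons are meaningful; the absolute value depends on the threshold
convention.

## Phase-field model of chromatin

Chromatin is a composition field c on a disk (default radius 7 µm,
128² grid) with free energy

F[c] = ∫ [ w (c−c_eu)² (c−c_het)² + (κ_g/2)|∇c|² ] dA − γ_L ∮ c dℓ

(defaults: wells at 0.3/0.7, w = 20, κ_g = 0.08 energy·µm²), evolved by

∂c/∂t = ∇·(M ∇µ) − Γ µ,  µ = δF/δc,

i.e. conserved Cahn–Hilliard transport plus an optional first-order
interconversion of the two chromatin forms driven by the thermodynamic
potential (Cahn–Hilliard–Oono; Γ defaults to 0 so sweeps conserve
composition — the reaction is exercised separately). The lamina term
enters through the natural boundary condition κ_g ∂c/∂n = γ_L,
favouring heterochromatin at the rim (the lamina-associated-domain
analogue). The defaults put c̄₀ = 0.45 inside the spinodal
(f″ < 0 on (0.418, 0.582)) with a fastest-growing wavelength of ≈2 µm
— about a dozen domains across the nucleus.

**Compression.** Mechano-osmotic loading expels water while chromatin
stays, so a volume ratio λ = V₀/V ≥ 1 concentrates the field. Instant
mode applies c → clip(λc, 0, 1) once (nuclear-volume change treated as
an input, since it is what is measured); kinetic mode relaxes the mean
composition toward λc̄₀ at rate k_w·Δµ_w through a rim water flux,
reproducing a scalar exponential approach exactly. Both conserve total
chromatin through the volume bookkeeping. Raising λ over
{1.0, 1.1, 1.2} moves the lever-rule heterochromatin fraction from
0.38 to 0.60, merging and enlarging domains — the modeled counterpart
of droplet compression condensing chromatin.

**Numerics.** The default integrator is a linearly stabilized
semi-implicit scheme: the fourth-order term and a stabilization split
a(c^{n+1}−c^n) are implicit behind one cached sparse LU of
I + ΔtM(κ_g L² − aL), with L the masked five-point Neumann Laplacian;
the well force is explicit. Column sums of L vanish, so composition is
conserved to solver precision (observed drift ~10⁻¹¹ over 10⁴ steps),
and the scheme is energy-stable for a ≥ max|f″|/2 along the trajectory
(default a = max|f″| on [c_eu−0.1, c_het+0.1]; energy decrease is
asserted per step in the tests). Default Δt = 5×10⁻³, ~25 steps per
inverse fastest growth rate. An explicit Euler integrator with the
documented bound Δt ≤ Δx⁴/(M(16κ_g + 4 max f″ Δx²)) is kept behind a
flag and used as an independent cross-check — the two schemes agree
termwise in the linearly stable regime; in the spinodal regime the
stabilization's O(aΔt) mode retardation is exponentially amplified, so
agreement there is qualitative by design. Steady state is declared when
the free-energy change over a 500-step window falls below
10⁻⁶(|F| + 10⁻⁹).

Validation runs use 96² grids and 2–20×10³ steps (full two-domain
coarsening on a disk is a slow t^{1/3} process; the deep-quench
bimodality check runs the longest schedule). Domain statistics
threshold at (c_eu+c_het)/2 and drop components under 4 px.

The SI-level functional forms and parameter values of the published
model are not restated here; this module's forms and
dimensionless-calibrated defaults are its own declared choices, and
only directional comparisons (more compression → larger
heterochromatin domains) are claimed.

## Contractility model

A 2D plane-stress analogue of the 3D chemomechanical cell model: a
circular cell (radius 20 µm) on a Winkler foundation k_f (the
substrate-stiffness proxy; traction t = k_f·u on the adhered
cytoskeleton), cytoskeleton carrying an isotropic active prestress σ_a
(default 0.5 kPa, E_c = 1 kPa, ν = 0.3), a passive nuclear inclusion
(radius 5 µm — typical hepatocyte — modulus 4 kPa), and droplets as
soft near-incompressible inclusions (ν = 0.49, negligible shear) whose
interface carries an outward pressure p plus the balancing Laplace
membrane pretension T = p·r. The pretension matters: without it a
pressurized droplet inflates and *adds* traction; with it the droplet
is self-equilibrated and acts as what it physically is — a
non-contractile, non-adhered, shape-resisting inclusion (membrane
geometric stiffness T/L plus an elastic ring EA, default 2 kPa·µm).
An optional stress-feedback law σ_a(1 + α·trσ/2) is solved by damped
fixed-point iteration from the α = 0 solution (tolerance 10⁻⁶, ≤100
iterations); α defaults to 0.

Discretization: P1 triangles on a Delaunay mesh (default h = 0.8 µm)
whose point set samples the rim and every interface circle at ≤ h
spacing with an exclusion band keeping those edges in the
triangulation; elements are labeled by centroid. The foundation is
lumped nodally. The homogeneous disk has the closed-form solution
u = A·I₁(βr), β = √(k_f/E′), fixed by σ_rr(R) = 0 — the independent
oracle; FEM agreement is ~0.1% across two decades of k_f, and halving
h changes mean traction by < 0.1%.

Droplet sweeps array droplets of radius 2 µm on concentric rings
spanning the cytoplasmic annulus — mirroring the arrayed-inclusion
geometry of the source model and the perinuclear packing of hepatocyte
droplets (rings fill inside-out, so nucleus-adjacent droplets come
first). Seeded per-ring rotations and a small jitter randomize layouts
while preserving the ≥ mesh_h clearance; random sequential placement
jams below the 30% area fraction the sweeps need, which is why an
array, not rejection sampling, is used. Area fraction is relative to
the total cell cross-section.

Claims are directional only: mean traction decreases monotonically
with droplet loading (~7% at 30% area fraction under the defaults) and
the nucleus irregularity roughly doubles relative to the droplet-free
baseline. Absolute traction magnitudes depend on unconstrained
constitutive parameters and are out of scope, as are 3D effects,
focal-adhesion dynamics, and viscoelasticity.

## Problem sizes in validation and reproduction

The test suite and `scripts/acceptance.py` synthesize all inputs at run
time: 50-nucleus sweeps for oracle equivalence and segmentation IoU,
10-seed condensation series, phase-field runs at 96²–128² with
1.5–20×10³ steps, and mechanics sweeps of 16 solves at h = 0.8 µm.
These sizes were chosen as the smallest at which each property is
stable and well-resolved; they complete in a few minutes on one core.
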
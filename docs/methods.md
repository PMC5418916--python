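# Methods

This note documents the model implemented in `villiwave`: its assumptions,
the parameters that matter, the numerical choices, and what the synthetic
geometry does and does not capture.

## Coordinate system and discretization

Cartesian coordinates with z = 0 on the chorionic plate and +z toward the
basal plate. Voxels are isotropic with centers at ((i+0.5)v, (j+0.5)v,
(k+0.5)v); the physical volume is fixed at 34.8 × 34.8 × 24.563 mm, so the
reference resolution v = 29 µm gives 1200 × 1200 × 847 voxels (two padding
slices beyond the deepest branch at z = 24.5 mm). The default working
resolution is v = 116 µm (300 × 300 × 212), which keeps the full pipeline
— tree build, rasterization, distance transform and a 12-condition sweep —
around five minutes on one CPU while preserving every qualitative feature
of the statistics; 29 µm is a supported configuration (`pixel_size_um=29`,
raised `max_voxels`, slab streaming), not the test default.

## Stem-villi geometry

**Truncus chorii** (z = 0–2.9 mm). A single vertical branch; the radius
follows the quarter-ellipse r(z) = r_max − (r_max−r_min)/z_tr ·
√(z_tr² − (z−z_tr)²) with defaults r_max = 1.5, r_min = 0.5 mm,
z_tr = 2.9 mm, chosen so that dr/dz vanishes at the truncus–rami boundary
(smooth connection) and diverges at the plate (the basal flare).

**Rami chorii** (z = 2.9–13.5 mm). Four generations of equal, symmetric
dichotomy ending in 16 tips. The morphometric inputs are: branch points at
z = 2.9, 3.9, 4.7 and 5.8 mm; axis curvature radius 1.74 mm for the
proximal bend and 8.99 mm for the distal one; tips at z = 13.5 mm;
diameters 1.0 → 0.5 mm. These constraints interlock: an arc of radius
8.99 mm that returns to vertical at z = 13.5 mm starting at z = 5.8 mm
must start at tilt α* = asin(7.7/8.99) ≈ 59°, so every branch follows the
same tilt-vs-z schedule — bend outward from vertical on the 1.74 mm arc
until α*, run straight, then bend back on the 8.99 mm arc, landing
vertical exactly at the ramuli boundary. Bifurcations are azimuthal
(children keep the tilt schedule; their vertical planes rotate by ±45°,
±22.5°, ±11.25° per generation, and the two trunk branches leave the
truncus tip in opposite azimuths). We chose azimuthal splits over
alternating split planes because only they keep all 16 tips on the
z-station schedule with the stated curvature radii; a side effect is that
the tilt at a given z is the same for every rami branch, which makes the
per-slice φ distribution in the rami zone narrow. Diameters taper linearly
in z (monotone along every path and automatically continuous at
junctions).

**Ramuli chorii** (z = 13.5–24.5 mm). Sixteen unequally dichotomous
subtrees, one per rami tip. Topology source: 2D lattice DLA — walkers
launched on a circle of radius (cluster radius + 5), killed at 3× the
launch radius, sticking on first face contact; 400 particles per
aggregate, seeds 16·(master seed)+1 … +16. The aggregate is thinned
(morphological skeletonization), its pixel graph reduced to a chord tree
over branching points and tips (cycles — thinning artifacts — are pruned
to a minimum spanning tree; a skeleton with fewer than two branches is
regenerated with the seed advanced by 1000). The chord tree is lifted into
the slab: radial distance from the root maps linearly to depth so the
deepest tip reaches z = 24.5 mm exactly; the angular coordinate becomes
the lateral direction, scaled to 4.0 mm. The lateral scale was set from
the reported cross-section bounding rectangle (≈ 23.8 × 22.6 mm): rami tip
radius ≈ 7.3 mm plus 4.0 mm of ramuli spread reproduces it. With 400
particles the per-subtree tip generations fall in 9–16 (within the
reported 4–20) and the Strahler bifurcation ratios in ≈ 2.7–4.6 (within
the reported 2.22–6.02).

**Ordering convention.** Centripetal orders are Strahler by default
(parent = max of children, +1 only on a tie), the classical convention for
Horton/bifurcation-ratio analysis; it is what places caterpillar-like DLA
trees in the reported R_b band, whereas the max+1 (Horsfield) rule —
available as `convention="horsfield"` — drives them toward R_b → 1. The
two coincide on the complete rami tier. R_b is fitted through the origin
(ln N_u = (u_max−u) ln R_b has no intercept term), which recovers any
exact geometric series exactly.

**Rasterization.** Union of tapered capsules: a voxel is occupied iff its
center lies within the linearly interpolated radius of some axis segment.
Capsule ends are spherical, which is what guarantees watertight junctions;
volume oracles in the tests therefore use the capsule closed form
(πR²L + 4/3 πR³), not the bare cylinder.

## Contraction directions

Surface = occupied voxels with ≥ 1 of 6 face-neighbors unoccupied (volume
boundary counts as exposed). Each element maps to the branch with the
nearest sampled axis point (KD-tree over all axis samples in branch-id
order; exact ties follow the KD-tree's deterministic traversal — near-ties
are counted and logged). Truncus elements use the analytic rule
φ_o = π + atan(dr/dz) with θ_o the azimuth about the truncus axis; at
z = z_tr this gives (0,0,−1) and toward z = 0 it flattens into the plane.
Rami/ramuli elements take the local axis tangent oriented proximally
(toward the junction with the parent), i.e. minus the root-to-tip tangent.
All directions are unit vectors.

## Displacement field

The surroundings are one incompressible continuum, so only the shear wave
survives (μ = ρλ²ν²; with ρ = 1000 kg/m³ and ν = 1 Hz the three studied
wavelengths give μ = 8.41×10⁻⁵, 3.36×10⁻⁴ and 2.10×10⁻³ Pa). Each voxel
of the surroundings takes u = ξ₀ cos(Φ(r)) along the direction of its
single nearest surface element — no superposition across sources, because
the wave model is written in terms of one distance-from-surface r and the
slice statistics describe direction inherited from the local branch.
Time is frozen at t = 0 and viscoelastic attenuation is idealized as a
hard cutoff at d_max.

For the increasing-wavelength profile (0.29/0.58/1.45 mm in thirds of
d_max) the phase Φ(r) is accumulated piecewise, not evaluated as
2πr/λ(r): this keeps Φ continuous and non-decreasing, so the amplitude has
no artificial jumps at the third boundaries.

**Numerics.** Distances are exact Euclidean center-to-center values from a
cKDTree query with an upper bound of d_max (band-limited). Because each
voxel is queried independently against the same id-ordered surface tree,
the result is independent of how the volume is partitioned into z-slabs —
slab streaming (`slab_nz`) bounds memory at full resolution and is
bit-identical to a single pass (tested). Distance volumes are stored
float32; the displaced-area membership threshold |u| > 10⁻⁶ ξ₀ sits well
above the resulting rounding scale (~10⁻⁸ ξ₀ at the cosine zeros) and
well below any physical displacement, so cosine-zero voxels are excluded
as intended. A distance volume computed at the largest cutoff is shared
across conditions (cutting at each condition's d_max is exact).

## Slice statistics and characteristic positions

Polar decomposition: magnitude; φ = angle from +z in degrees [0, 180];
θ = atan2(y, x) in degrees [−180, 180) (the +180 edge maps to −180);
θ is undefined where the in-plane component is below 10⁻⁹ of the
magnitude. Statistics per z-slice over displaced voxels only; θ statistics
over θ-defined voxels only. All SDs are population SDs (divide by N), so
they are defined for every N ≥ 1, including the 360 one-degree θ-histogram
bin fractions whose SD is SD_in. The mean of θ is arithmetic, not
circular: the observed means sit near 0 with SD ≈ 90°, consistent with
arithmetic treatment, and the z_θ dip is precisely an arithmetic-mean
signature of the ramuli asymmetry.

Characteristic positions are detected on 5-slice moving-average profiles:

* **z_d** — argmax of SD/mean of the magnitude within ±2 mm of the
  truncus–rami boundary.
* **z_φ2** — the most prominent local maximum of SD(φ) (prominence ≥ 10%
  of the profile range), preferring peaks beyond the rami midpoint.
* **z_φ1** — argmax of the smoothed in-plane area fraction (φ∈[45°,135°])
  between z_t and min(z_r, z_φ2). A deliberate design choice: the
  per-slice φ distribution is a mixture of sign-flipped subpopulations
  sharing mean ≈ 90°, so the slice SD is a weighted mean of subpopulation
  variances and is monotone in the axial mixture weight — it cannot form a
  local maximum where the in-plane population dominates. Since in-plane
  dominance is the defining property of z_φ1 (the slice where the area
  fraction at φ = 45–135° is largest, > 90%), it is detected from the
  fraction profile directly; SD(φ) peak candidates are still reported.
* **z_θ** — argmin of mean θ within ±2.5 mm of the rami–ramuli boundary.

The searches are windowed by the ordering z_t < z_φ1 < z_r < z_φ2 < z_rl;
without the windows the fraction argmax lands on the degenerate
chorionic-plate slice (the thin flare band z < 0.16 mm where |dr/dz| > 1).
Flat profiles raise an `incomplete` flag instead of an error.

At the defaults, all four positions are detected in each of the 12
conditions; z_φ1 falls at 3.6–4.8 mm with in-plane fraction 0.987–1.0, and
z_φ2 at 12.7–13.1 mm where the displacement is almost purely axial.

## What the synthetic geometry does and does not capture

The generator reproduces the morphometric constraints (tier extents,
diameters, branch counts, orders, curvatures, territory size) and the
statistical character of unequal dichotomy via DLA, but not any particular
placenta: the DLA realizations are seed-dependent, so quantities tied to
individual branch shapes — notably the relative-magnitude percentiles of
the field and the exact z of the detected positions — vary between seeds
and are reported as diagnostics rather than asserted. Intermediate,
terminal and mesenchymal villi are folded into the continuum surroundings;
there is no blood-flow computation, no time dependence, no contraction
timing, and no viscoelastic attenuation beyond the hard cutoff. Passing
tests therefore demonstrate the structural claims (bounds, cutoffs,
ordering machinery, per-slice pattern of the direction statistics), not
agreement with any measured placental displacement.

## Problem sizes used by the test suite and acceptance script

Tests and the acceptance script run at the 116 µm working resolution
(300 × 300 × 212 voxels, ≈ 7×10⁴ surface elements, ≈ 6×10⁶ band voxels),
with the unit-level oracles on 20³–41³ fixtures and the slab-streaming
equality on a 150³ crop of the model. These sizes were chosen so a full
from-scratch reproduction stays in the minutes range on a single CPU.
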
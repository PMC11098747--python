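# Methods

## Data model

A specimen is the coordinate-level export of a mapped serial-section series:
per-section striatal outline polygons (µm), per-cell markers (section id,
in-plane x/y, population label, boolean phenotype flags), an optional
injection-site reference point, and the acquisition geometry. Section *i*
occupies the axial slab [i·s, i·s + t] for spacing *s* and thickness *t*
(defaults 160 µm and 20 µm, matching a 15-section sagittal series spanning a
mouse striatum); the absolute z origin is arbitrary because every downstream
quantity depends only on relative distances. Slabs must not overlap
(s ≥ t). Per-section rigid in-plane transforms may be supplied as metadata
and are applied at load time; landmark registration itself is out of scope —
it happens in the mapping software before export.

Markers lying outside their section's outline are kept for counting but
flagged as warnings: outlines alone define tissue volume, and a stray marker
usually indicates an operator slip worth surfacing, not data to delete
silently.

## Probabilistic radial counting

The depth of a mapped cell within its slab is unknown, so each cell is
represented as a vertical segment with uniform probability density
P(z) = 1/(z_u − z_l) on [z_l, z_u]. For a sphere of radius r centred at
**c**, the counted fraction of a cell at in-plane distance d from the centre
is the closed form

    f(r) = |[c_z − s, c_z + s] ∩ [z_l, z_u]| / (z_u − z_l),  s = √(r² − d²)

(0 when d > r). A shell [a, b) counts f(b) − f(a). Summing cumulative
fractions at shell edges and differencing makes every partition telescope, so
per-cell shell fractions sum to one *exactly* (up to float roundoff), and the
probability mass beyond the outermost edge is reported in an explicit
"outside" bucket. Shell edges are half-open [a, b); the boundary set has
measure zero for the integrals, the convention only fixes reproducibility.

## Exact shell volumes

The tissue volume inside a shell is the sum over sections of
(extruded outline ∩ sphere) volumes, differenced between the two shell radii.
Each prism ∩ sphere volume is computed by a z-slice construction:

1. **Polygon–disk area, exact.** For the sphere's circular cross-section at
   height z, the intersection area with the outline is the per-edge
   Green's-theorem sum: each directed edge of the counter-clockwise boundary
   is split at its circle intersections; sub-segments inside the circle
   contribute the signed triangle ½(P₁ × P₂) against the centre, sub-segments
   outside contribute the signed sector ½r²·atan2(P₁×P₂, P₁·P₂). The result
   is exact for simple polygons, non-convex included (polygons with holes are
   unsupported; mapped outlines are simple closed curves).
2. **Adaptive quadrature over z.** The disk area is integrated across the
   slab with `scipy.integrate.quad` (relative tolerance 10⁻⁶ by default,
   absolute floor 1 µm³, up to 200 subdivisions); the returned error estimate
   is carried as a certified bound on each `VolumeEstimate`. Two analytic
   shortcuts (prism entirely inside the sphere; empty overlap) return exact
   values with zero error bound.

Volumes at successive shell edges are evaluated once per section and
differenced, so a full partition of [0, ∞) telescopes exactly to the total
tissue volume. An independent Monte-Carlo oracle (rejection sampling with an
even-odd crossing test, numba-jitted, seeded, binomial standard error
reported) validates the analytic route in the test suite; the two routes
share no geometry code. The 10⁻⁶ relative tolerance is this package's
choice; it is far below every statistical uncertainty in the data.

Shells containing no tissue are reported as *undefined* (NaN density), never
as zero — a zero would fabricate signal at the edge of the mapped volume.
The analysis radius cap applies to the outer shell edge (b ≤ r_max).

## Profiles, fronts and per-section densities

`radial_density_profile` uses 125 µm increments to a 2 mm cap by default
(16 shells) around the specimen's mapped injection site; for control
specimens without their own site, `control_reference_center` averages donor
specimens' delivery-site coordinates. A section filter (`every:3`) restricts
both counts and volumes to sparser mapping cadences. `crossover_radius`
scans shells outward and returns the midpoint of the first shell where
sign(ρ_a − ρ_b) flips — with 125 µm shells this localizes a front to within
one shell width. `per_section_density` divides each section's cell count by
thickness × outline area for expansion series with no radial reference.

## Phenotype fractions and the optical fractionator

Marker fractions are exact integer ratios; an absent population yields an
undefined (not 0/0 = 0) fraction. The fractionator estimate is the standard
N̂ = ΣQ/(ssf·asf·hsf). The sampling simulator places one frame per grid cell
at a single uniform random lattice offset — systematic uniform random
sampling, giving every point inclusion probability exactly asf — rather than
independent per-cell placement, which without wrap-around is a biased point
sampler. Cells are counted with the left/bottom-inclusive half-open frame
rule. Section sampling uses a uniform random phase; ssf = 1/period refers to
the specimen's own mapped sections, which is the unbiased convention when the
truth being estimated is the specimen's marker total. Whole slabs are
counted (hsf = 1, no guard zones); "first plane of focus" sub-slab counting
has no analogue in 2D mapped coordinates and is treated as whole-slab
counting.

## Synthetic chimera generator

The generator emulates the statistical structure the estimators assume, not
a fitted biological model:

| parameter | default | meaning |
|---|---|---|
| n_sections / thickness / spacing | 15 / 20 µm / 160 µm | acquisition geometry |
| semi-axes | 1600 × 1100 µm | widest-section outline scale (≈5.5 mm² peak area, lens-profile taper across the series, smooth low-order harmonic irregularity) |
| λ_inv, λ_res | 2×10⁻⁵ µm⁻³ | plateau densities (≈2×10⁴ cells per specimen side, the scale of a densely engrafted striatum) |
| R_front / w | 750 µm / 100 µm | logistic front position and width — invader intensity λ_inv·σ(−(r−R)/w), resident mirrored; w is a free choice, documented here, since front sharpness has no quantitative anchor |
| p_ki67 invader/resident | 0.15 / 0.05 | proliferation asymmetry |
| p_tunel base/front, band | 0.02 / 0.10, 250 µm | resident apoptosis enrichment in the contact zone |

Cells are drawn by thinning a homogeneous Poisson process per section slab
restricted to the outline, using each point's true 3D radius; the z
coordinate is then discarded so markers carry exactly the information real
mapped data carry. One seed sequence drives deterministic per-section,
per-population substreams; identical spec + seed reproduces specimen files
byte for byte. `expected_shell_counts` integrates the intensities by seeded
Monte Carlo as an independent oracle for recovery tests.

What the generator does **not** emulate: temporal dynamics, cell–cell
exclusion (points are Poisson, not hard-core), mapping errors, section
distortion or registration noise, and anisotropic outlines. Passing recovery
tests therefore demonstrates correctness of the estimators under the stated
sampling model, not robustness to real-histology artefacts.

## Verification scales

The test suite and `scripts/acceptance.py` use problem sizes chosen to make
statistical checks sharp at interactive runtimes: 100 randomized
prism∩sphere configurations against a 10⁷-sample Monte-Carlo oracle (4 SE
agreement); homogeneous-density recovery at λ = 5×10⁻⁴ µm⁻³ so every
retained shell holds ≥10³ expected cells (5 % tolerance); front recovery at
R_front ∈ {500, 750, 1250} µm over 10 seeds each (±one shell width); Ki67
fractions within 99 % binomial intervals; fractionator unbiasedness as a
mean over 100 systematic samplings (5 %). Conservation residuals are exact
by construction and checked at 10⁻⁹ (counts) and 10⁻⁶ relative (volumes).

## Known limitations

- Outline polygons with holes or multiple disjoint lobes per section are not
  supported.
- The quadrature error bound is scipy's estimate, reliable in practice but
  not a formal interval-arithmetic certificate.
- `crossover_radius` reports the first sign change only; profiles that cross
  multiple times (patchy mosaics rather than a single front) need a
  different summary.
- Group-level statistics (ANOVA across specimens, multiple-comparison
  correction) are deliberately out of scope; profiles and fractions export
  to CSV/JSON for downstream statistical tools.
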
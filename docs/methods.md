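# Methods

This note documents the models, numerical choices, and known limitations of
`meristemorph`. Units are micrometres throughout; stacks are (z, y, x) with
a 0.4 µm z step and 0.5 µm lateral pixels by default.

## The 2.5D measurement model

The analysis treats the shoot apical meristem (SAM) epidermis as a height
map: one surface point per lateral position, no overhangs. This matches
top-down confocal acquisition of the L1 and keeps every quantity — cell
area, curvature, graph distance — defined on a single triangulated surface.
Inner tissue (sub-L1) is out of scope.

**Surface extraction.** For each (x, y) column the topmost voxel above an
intensity threshold defines the height (quantized at the z step); the
height map is 3×3 median-filtered and triangulated on the pixel grid with a
fixed diagonal convention, so two height maps on the same grid have 1:1
vertex correspondence. Columns with no supra-threshold voxel are filled
from their nearest valid neighbor; if more than half of all columns are
empty the stack is rejected. Quantization leaves ~0.1–0.2 µm RMS height
noise, which inflates mesh area by a few percent relative to an analytic
surface — this affects all conditions alike and cancels in stage ratios.

**Wall projection and watershed.** Wall-stain intensity is averaged 0–4 µm
below the surface along inward vertex normals (trilinear interpolation,
step = half the smallest voxel dimension). Cells are a priority-flood
watershed of that field over the mesh vertex graph — not over a flat image
— so areas are true surface areas. Markers are snapped to the nearest
vertex and then refined to the lowest wall value within 1.5 µm; a marker
left on a wall ridge would flood a degenerate basin. Without markers, seeds
are regional minima after h-minima suppression (h = 10% of the dynamic
range) of a lightly graph-smoothed copy of the field; smoothing is needed
because sampling jitter on the extracted surface ripples cell interiors.
Segments below 4 µm² (slivers, well below any epidermal cell) merge into
the neighbor with the longest shared boundary.

**Gaussian curvature.** Per vertex, all surface points within a 10 µm
Euclidean ball are expressed in the vertex tangent frame and a height
function is fit by least squares; K is the determinant of the shape
operator of the fit at the vertex. With ≥30 in-radius points the basis is
extended to degree 4 — a pure quadric underestimates |K| by ~8% on a 10 µm
cap of a 25 µm sphere, the quartic terms absorb that truncation bias
(sphere error drops to 0.4%). Dense neighborhoods are thinned to ≤80
support points by a fixed-seed uniform subsample, and the k-nearest query
is sized so the radius cut, not the k cut, selects the neighborhood (a
k-truncated set would break rigid-motion invariance). Vertices with <6
neighbors or a rank-deficient design are flagged undefined, never zeroed.
Euclidean balls stand in for geodesic neighborhoods: on the domes in scope
the chord-vs-arc discrepancy at 10 µm is <1%, far below estimator noise,
and avoids an all-pairs shortest-path computation on ~10⁵-vertex meshes.
An optional one-pass neighbor smoothing of K exists but is off by default.

**Delimitation.** Per-cell curvature is the barycentric-area-weighted mean
of defined vertex K. From the central cell (the cell containing the
highest vertex; ties broken by lowest vertex index) cells are flooded over
the adjacency graph while mean K ≥ 0; the first K < 0 cells form the
saddle boundary and are excluded from the region (a documented, togglable
choice — whether boundary saddle cells belong to the meristem is a
convention). A summit cell with negative curvature raises an error rather
than returning an empty region.

**Zonation.** Ring = breadth-first distance from the central cell within
the region; CZ = rings 0–2, PZ ring = rings 3–5 (both exposed as
parameters).

**Primordia.** Connected components of cells with mean K above
5×10⁻⁴ µm⁻² outside the region and its boundary, with area ≥ 40 µm² and
peak cell curvature ≥ 2×10⁻³ µm⁻², are primordia. The peak criterion is
needed because the fit produces shallow positive ripples (≤ ~8×10⁻⁴)
where a saddle flattens out, an order of magnitude below any organ bump
(≥ ~5×10⁻³). Age rank grows with bump area (P₁ = youngest, smallest);
incipient positions i_n extrapolate the youngest azimuth by n × 137.5°
(the divergence angle is a parameter). Curvilinear distances (e.g. between
primordia on opposite flanks, through the summit) are edge-graph shortest
paths straightened coarse-to-fine by midpoint re-projection; plain midpoint
relaxation de-slacks a polyline at a rate quadratic in its point count, so
the path is straightened at 9 points first and refined to 65.

**Signal maps.** Reporter intensity is aggregated 2–10 µm below the
surface along inward normals (mean by default, max by flag — the
aggregation is recorded in the output), then averaged per cell with vertex
area weights. Cells whose rays leave the stack are flagged NaN.

**Statistics.** One-way ANOVA over combined genotype×condition groups,
then Tukey HSD with the Tukey–Kramer standard error and adjusted p from
`scipy.stats.studentized_range`. Zero within-group variance is flagged
degenerate (separated means get p = 0). The compact letter display uses
insert-and-absorb: one letter containing all groups, split on each
significant pair, absorb subset letters; the result satisfies
"share a letter ⇔ not significantly different". Fold changes are ratios of
group means against a baseline condition, with per-apex values retained.

## The synthetic apex generator

Scenes are pure functions of (preset, seed): bit-identical on repeat.

**Geometry.** The dome is a spherical cap — constant K = 1/R², the
canonical description of a domed meristem — joined with continuous slope
at its rim circle r = σ to a quadratic moat (z′ ≤ 0, z″ = const > 0, so
K < 0 throughout) and a flat outer plateau. The cap area is exactly
π(σ² + h²), so σ derives from (cap area, dome height) and the preset's
geometry fields cannot disagree. The moat width solves
|K_moat(σ⁺)| = 1/R²: balancing curvature magnitude across the rim keeps
the 10 µm-smoothed estimate's zero crossing at σ (a much sharper moat
bleeds negative estimates several µm into the rim; a much softer one lets
the flood leak outward). Primordium bumps are Gaussian hills placed on the
plateau at golden-angle azimuths, with size and height growing ~30–35% per
age step so the detector's area-based age ranking is unambiguous; a bump
whose footprint would reach the summit raises an error.

**Epidermis.** Exactly `meristem_cell_count` tessellation seeds are placed
inside the σ-disc — those cells are the ground-truth region, making the
count calibration exact by construction. A radial target-area profile
a(r) (power ramp for right-skewed stages, smooth step — small central-zone
cells inside an enlarged periphery — for the domed stage) is solved so the
*noise-convolved* median cell area hits the preset's nominal median: the
predicted median accounts for the seeded lognormal jitter plus residual
tessellation spread, deflated by e^(s²/2) because cells must tile a fixed
total area. Seeds are blue-noise dart throws with metric-aware spacing
(2D spacing shrinks by √metric on the steep rim, where one surface cell
projects to a compressed footprint), followed by three density-weighted
Lloyd iterations (vertex weight ∝ 1/a(r)², the 2D quantizer density whose
centroidal tessellation has cell size ∝ a). An explicit pinned ring of
outside seeds just beyond σ aligns the rim cell walls with the curvature
moat; a deterministic calibration loop (≤6 passes, identical RNG stream
per pass so only profile/ring parameters change) nudges the ring offset
and the median target until the measured-on-truth region area is within
~1.5% of nominal and the median within ~3%. Across all five presets and
seeds 1–3 the realized calibration is |area| ≤ 1.4% and |median| ≤ 2.9%
(spec'd tolerances: 2% and 5%).

**Stage presets.** Vegetative (2 500 µm², 100 cells, median 19 µm²) and
domed (10 000 µm², 310 cells, median 34.2 µm²) encode the doming effect
sizes as ground truth: area ×4.0, cells ×3.1, median ×1.8. A count ratio
of exactly 3.5 is jointly unrealizable with the other two ratios — it
would force the domed median 26% above its mean, beyond what any
plausible cell-size distribution under tessellation noise can deliver —
so the count ratio sits at 3.1, inside the three-to-fourfold doming
range. Inflorescence (smaller than domed, cells back near vegetative
size, four closer primordia), `ft_tsf_like` (lateral expansion without
doming) and `narrow_meristem` (reduced width at unchanged cell size) are
qualitative stage/genotype emulations, not fits.

**Rendering.** Cell walls are drawn perpendicular to the surface
(anticlinal), by sampling 2D weight maps at each voxel's surface foot
point (first order in slope): the outer periclinal sheet occupies 0–1 µm
of normal depth everywhere, anticlinal walls 0–4 µm with a 0.5 µm Gaussian
cross-section at the true cell boundaries. Rendering walls as vertical
sheets instead would displace every downhill wall outward under
normal-band projection and bias small-meristem medians upward. Reporters
occupy a 2–10 µm normal-depth band with patterns: `pz_patches` (patches at
the incipient positions, a GA-biosynthesis-like domain),
`abaxial_primordia` (outer primordium flanks, GA-catabolism-like),
`uniform`, `none`. Noise is additive Gaussian only — no PSF, attenuation,
or bleaching — and scenes are static snapshots; no growth simulation.

## What the synthetic tests do and do not show

Passing recovery tests demonstrates that the measurement chain is
internally consistent and unbiased at realistic geometry, cell sizes,
stain contrast and modest noise. They do not exercise: uneven staining,
spectral bleed-through, segmentation errors needing manual correction,
overhanging primordia (outside the 2.5D model), or biological variation
beyond the seeded jitter. Two known, quantified method biases on synthetic
data: extraction roughness inflates all areas ~4–6%, and watershed
boundary placement inflates median cell areas slightly more where the
perimeter-to-area ratio is larger (vegetative), so the recovered
median-cell-area increase sits ~6 pp below the ground-truth 80%
(72–74% across seeds) — well within the ±15 pp acceptance band, but a
real property of the pipeline, not of the truth.

## Problem sizes and determinism

Default scenes span 93–200 µm of field at 0.5 µm pixels (3×10⁴–1.6×10⁵
vertices); a full generate-and-measure pass takes ~10 s (vegetative) to
~35 s (domed) on one CPU, and the stage-panel analyses run in minutes.
All randomness flows from `numpy.random.default_rng` seeded by the scene
seed (plus fixed stream keys per stage); estimator-internal subsampling
uses a fixed seed. Identical inputs give bit-identical scenes, identical
summary CSVs, and byte-identical PNG renders.
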
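# Methods

## Model

`mgpit` simulates pitting corrosion of an immersed Mg-alloy (AZ61)
specimen as stochastic removal of cubic voxels. The model is
*semi-autonomous*: the total corrosion rate is imposed from experiment
(a measured mass-loss rate per exposed area), while *where* the mass is
removed emerges from the interplay of two per-element attributes:

* **EA** (exposure attribute, 0–6): the number of element faces in
  contact with saline. The exterior of the bounding box is saline on
  all six sides (the specimen is suspended in solution, no mount face);
  exposure is strictly 6-face adjacency — diagonal contact does not
  expose a face. Shielded elements (`EA = 0`) cannot corrode.
* **OA** (oxide attribute, 0–1]: the element's relative corrosion
  speed. Intact Mg has `OA = 1`; the one-element-thick surface oxide
  shell has `OA = 0.07` (the shell corrodes roughly an order of
  magnitude slower than the alloy matrix — reported rate ratios for
  AZ61 are ≈ 13.7×, and 1/0.07 ≈ 14.3; we keep the conventional 0.07
  assignment and note the small discrepancy); porous film defects carry
  `OA ∈ [0.4, 0.6]`.

Per step of length `dt`:

1. `S` = current exposed area `Σ EA·a²` (or the initial `S_O` when
   `surface_mode="initial"`, the linear reference limit);
2. mass budget `ML = ml_rate · S · dt`; removal count
   `n = floor((ML + carry)/Me)` with `Me = a³ρ`, the sub-element
   remainder carried forward so cumulative removed mass tracks the
   cumulative budget to within one `Me` over arbitrarily long runs
   (plain rounding drifts);
3. corrosion attribute `CA = EA·OA`, probability `CP = n·CA/ΣCA`
   (pre-clip sum exactly `n`; values above 1 are clipped with a logged
   warning — this only happens when the corrodible population is tiny);
4. removal: `exact_count` (default) draws exactly `n` elements by
   weighted sampling without replacement — implemented with
   exponential-race keys (`k` smallest of `E_i/w_i`, `E_i ~ Exp(1)`),
   which reproduces sequential weighted draws exactly; `bernoulli`
   instead removes each element independently with probability `CP_i`
   (random count, mean `n`);
5. removed elements become void and their surviving face-neighbours
   gain exposure. Selection happens before removal within a step, so
   freshly uncovered Mg joins the corrodible population one step later.
   Newly exposed interior elements get `OA = 1` immediately and are
   never re-oxidised: there is no repassivation or corrosion-product
   protection in the model, which is what produces the characteristic
   acceleration once pits breach the shell.

If the budget exceeds the corrodible population the run removes
everything corrodible, warns, and terminates early with a flagged
truncated history.

## Parameters and defaults

| parameter | default | units | meaning |
|---|---|---|---|
| `length × width × thickness` | 15 × 15 × 2 | mm | specimen block (must be lattice multiples of `element_size`; near-misses are an error, not rounded) |
| `element_size` (a) | 0.125 | mm | voxel edge; 0.135 vs 0.125 changes 500 h MLPA by < 1.5% (mesh-refinement check) |
| `density` (ρ) | 1.7 | mg/mm³ | AZ61 bulk density; `Me = a³ρ ≈ 3.32e-3` mg |
| `ml_rate` | 3.0e-5 | mg/mm²·h | measured linear mass-loss rate (0.003 mg/cm²·h); the config takes an explicit unit string (`mg_per_mm2_h` / `mg_per_cm2_h`). The per-mm² reading of 0.003 is physically impossible for this specimen — it would dissolve ~855 mg of a 765 mg block in 500 h — so the per-cm² unit is the default |
| `dt` | 25 | h | step length (matches the scan cadence of the reference experiment) |
| `n_steps` | 20 | — | 500 h; use 120 for the 3,000 h extension |
| `surface_mode` | `current` | — | budget on the growing pitted surface (super-linear loss); `initial` freezes `S ≡ S_O` for the linear limit |
| `oxide_oa` / `intact_oa` | 0.07 / 1.0 | — | shell vs matrix corrosion-speed factors |
| `porous_oa_low..high` | 0.4–0.6 | — | OA range of film defects |
| `n_seeds` | 30 | — | synthetic porous spots; see below |
| `rng_seed` | 0 | — | governs both seed placement and removal sampling through two deterministically derived sub-streams |

## The synthetic seed map

Real studies locate pit initiators from an early-exposure (≈ 200 h)
micro-CT pit map of the specific specimen; such maps are
specimen-specific and not available here, so the generator scatters
`n_seeds` single-element spots uniformly over the exposed surface with
OA uniform in [0.4, 0.6]. The count 30 is an arbitrary but realistic
density (a few tens of visible initiation sites on a 570 mm² coupon)
and is fully configurable; measured maps can be loaded from CSV
(`i,j,k,oa`) or from a binary image stack. A patch-seeding mode
(Chebyshev radius around each spot) exists but is off by default, since
no spot-size data is assumed.

What this emulates — and does not: the generator reproduces sparse,
spatially random initiation on an otherwise uniform film. Real pit maps
are spatially correlated (rolling direction, inclusions, flow), spot
OA need not be uniform, and corrosion products partially protect real
pits. Tests passing on synthetic seeds therefore validate the
*mechanism* (budgeting, weighting, geometry evolution, quantification),
not agreement with any particular specimen's pit pattern.

## Quantification

* **Pits** are 26-connected components of *removed* voxels (material at
  build time, void now). 26-connectivity matches the visual contiguity
  of pits in sections; exposure remains 6-connected — the two
  conventions serve different physics and are configured independently.
* **Pit depth** is the inclusive z-extent `(k_max − k_min + 1)·a`, so a
  one-voxel pit has depth `a` rather than 0. Depth is measured along
  the thickness axis only; side-wall pits are still measured by their
  z-extent, a documented limitation of the convention.
* **z-planes** are measured inward from the top face: `z = 0` is the
  outermost as-built layer (`k = nz − 1`), `z = 0.125` the next, etc.
* **2D pit masks** follow the image-processing route used on micro-CT
  sections: Canny edges, contour closing, region fill. The raster is
  upsampled 4× (nearest-neighbour) and framed with one ring of material
  first, so single-pixel pits and pits touching the raster border
  produce closed contours; the filled region is intersected with the
  void pixels and downsampled. On clean rasters the result equals the
  direct voxel void mask — this equivalence is a shipped regression
  oracle (randomised sections up to 64²), i.e. the image pipeline adds
  nothing and loses nothing on noise-free input. Defaults: Gaussian
  σ = 1 upsampled pixel, automatic hysteresis thresholds.
* **Fits**: `MLPA = c·T` by closed-form least squares through the
  origin; `D(T) = A(1 − e^(−kT))` by bounded nonlinear least squares
  with `A₀ = max(D)` and `k₀ = ln2 / t_half` (the decay-form exponent
  is the only one that can produce a saturating depth curve). Constant
  or non-positive depth series are rejected as degenerate rather than
  silently fitted; non-convergence raises with diagnostics.

## Numerical and design choices

* Incremental EA updates after removal are exactly equivalent to a full
  recomputation (property-tested on randomised removal sequences), and
  the mass ledger `M_O − M_N = Me ·` (removals) is exact at every step.
* The mesh-refinement comparison at 0.135 mm uses specimen dimensions
  snapped to that element lattice (111 × 111 × 15 elements,
  14.985 × 14.985 × 2.025 mm), since 0.135 does not divide 15 or 2
  exactly; MLPA is a per-area quantity, so the ~0.1% dimension change
  is immaterial next to the 1.5% criterion.
* `ml_rate = 0` is accepted as the no-corrosion limit (useful for
  identity tests); only negative rates are rejected.
* STL export writes every exposed voxel face exactly once (two
  triangles each, outward normals); total STL area equals the exposed
  surface area by construction. Watertightness in the strict manifold
  sense holds on full blocks; corroded voxel surfaces can legitimately
  be non-manifold where removed voxels touch diagonally.
* The `.inp` deck is a minimal generic dialect (node table, 8-node
  brick elements in the counter-clockwise bottom-then-top order, one
  element set per material state) aimed at importability, not
  byte-compatibility with any vendor. Node deduplication uses integer
  lattice keys — exact, no float tolerance.
* All randomness flows from a single seed through
  `numpy.random.SeedSequence.spawn`, so enabling snapshots or supplying
  an explicit seed map cannot change the removal trajectory.

## Problem sizes in the test and acceptance runs

The bundled suites run the full 230,400-element reference specimen for
the 500 h checks and for ten 3,000 h (120-step) long runs; property
tests use randomised grids up to ~10³ elements where an independent
brute-force oracle (triple-loop exposure counts, BFS flood fill, corner
set enumeration) is affordable. A default 500 h run takes well under a
second; the entire suite runs in seconds on one CPU.

## Known limitations

* No electrochemistry: the model imposes the measured global rate and
  distributes it geometrically; it cannot predict rate changes from
  solution chemistry, temperature, or galvanic coupling.
* No repassivation or corrosion-product protection, so long-run
  acceleration is, if anything, overstated.
* No coupling from mechanical stress back into corrosion probability;
  the FE export is one-way.
* Uniform cubic voxels only; no sub-element partial corrosion states or
  curved geometries.
* Polymer degradation (PGA/PLA/PLGA-style hydrolysis) is out of scope.
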
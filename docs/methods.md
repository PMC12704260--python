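# Methods

## The model

Each hypothetical skull is a 2-D lateral-view plane-stress body defined by
its composition `(r, o, b)` on the ternary simplex (rostrum, orbital-region
and braincase fractions of skull length), its length-to-height ratio, and
its absolute length `L` (default 300 mm).  The base model sits at 60/20/20
with ratio 3, standing in for a generalized early-dinosauriform skull free
of ornamentation.  The out-of-plane thickness is `t = 0.3·H`; because `t`
scales with size, homothetic scaling combined with the area-corrected load
(below) leaves the stress field exactly invariant, which is the property the
load correction exists to provide — model comparisons isolate shape, never
size.

### Template geometry

The outline is a polygon built from a small set of named constants
(one configuration block at the top of `morphomech/template.py`):

- ventral margin from `(0, 0.05H)` to `(L, 0)`; posterior (quadrate) margin
  at `x = L` up to `0.85H`;
- a snout wedge from `(0, 0.25H)` rising to full height `H` over a span
  `(0.25 + 0.35·(r − 0.6))·L` — *partially* coupled to the rostrum
  fraction (see Design choices);
- a level skull table, then a domed braincase: the dorsal margin rises to an
  apex of height `H·(1 + 0.9·b)` over the braincase midpoint before
  dropping to the quadrate.  Braincase expansion therefore deepens the
  posterior skull rather than merely lengthening it, the planar analogue of
  an inflated braincase unit;
- an elliptical orbit (center `((r + o/2)L, 0.55H)`, semi-axes
  `(0.28·o/(o+b)·L, 0.25H)`) and an elliptical upper-temporal opening
  (center `((r + o + b/2)L, 0.78H)`, semi-axes `(0.09·b/(o+b)·L, 0.12H)`).
  Opening *widths* scale with each region's share of the postrostral skull,
  not its absolute length: a long-snouted skull keeps a fully developed
  orbit, while orbit–braincase exchange reshapes both openings strongly.
  Openings are shrunk stepwise until they keep a clearance of
  `0.05·min(H, L)` to all other boundaries, and are omitted entirely when
  their region fraction is below 0.08 (the biting scenario then refuses to
  run, since it needs the adductor chamber).

These choices were made to realize, within a 2-D idealization, the
structural logic of the 3-D box-modelled originals: orbital expansion is a
bending liability (a large mid-skull opening), braincase expansion adds
structure (dome) *and* adductor mass (larger temporal opening), and rostral
elongation is close to stress-neutral.  The partial facial-rise coupling is
the explicit compromise: rising to `rL` makes bending stress grow with
rostral length, a fully fixed span makes it shrink; the 0.35 coupling keeps
rostrum-varying transects iso-stress.  These are engineering decisions of
this package, validated by trend tests (signs and orderings), not by
absolute stress values — absolute magnitudes of a 2-D plate are not
comparable to a 3-D skull's.

### Loads

- **Bending**: quadrate nodes fixed in x and y; a dorsal (+y) point load at
  the snout-tip node, `F = F_ref·(A/A_ref)` with `F_ref = 100 N` and `A` the
  *gross envelope* planform area (holes not subtracted — fenestrae barely
  reduce a real skull's outer surface, and subtracting them couples opening
  size into the load in a way that produced spurious stress minima).
- **Biting**: quadrates fixed; the bite node (ventral margin at `0.05L`)
  fixed in y only, so its vertical reaction is the bite force; total muscle
  force `σ_m·A_temporal` (specific tension `σ_m = 0.3 N/mm²`, a standard
  vertebrate value; only relative comparisons matter) split equally over the
  dorsal temporal-margin nodes, each directed at the insertion point
  `(0.95L, −0.3H)`.  Mechanical advantage is `|R_y(bite)|/F_muscle`.
  Pterygoideus musculature is not modelled.

Material: isotropic linear elasticity, `E = 15.00 GPa`, `ν = 0.29`
(crocodilian bone).  Units are mm/N at the interface; the solver converts to
SI once during assembly.

## Meshing

`femesh.triangulate` is a DistMesh-style force-equilibrium mesher over
`scipy.spatial.Delaunay`: boundary rings are resampled (recursive halving
against a sizing field) and held fixed; interior points start on a thinned
hexagonal lattice and relax under repulsive bar forces; triangles outside
the material are discarded by a centroid point-in-polygon test.  The sizing
field is `h0` far from features and contracts to each opening's clearance
near it, so narrow necks are resolved.  A polish phase (Laplacian smoothing,
crowded-sliver deletion, Ruppert-style circumcenter insertion for slivers
whose vertices are all boundary-fixed) brings the minimum interior angle
above 20°.  Because boundary nodes lie exactly on the outline polygon, total
element area equals the outline area to round-off (enforced at 1e-6
relative).  Everything is deterministic — identical outline and size give an
identical mesh — and scale-equivariant, which is what makes the homothety
invariance exact rather than approximate.

Default resolution is `target_h = L/90` (≈ 4.8k elements on the base
model).  Halving the element size changes the median stresses by about 1%
(bending) and 0.5% (biting); the coarser `L/60` leaves grid-level trend
statistics visibly mesh-noisy, which is why the pipeline default is `L/90`.
The full 36-model × 2-scenario sweep takes ~2 minutes on one CPU.

## Solver

Constant-strain triangles, plane stress, direct sparse solve of the reduced
SPD system; constraints by row/column elimination; reactions recovered as
`K·u − f` on constrained DOFs.  Element-level (not nodal-averaged) stresses
feed the von Mises field, and the per-model summary is the unweighted
*median* over elements (the mean is also reported).  Verification battery
(also exposed as `morphomech check`):

- patch test: uniform uniaxial tension reproduced to machine precision;
- slender cantilever (10:1): tip deflection within 0.5% of `PL³/3EI`, root
  fiber stress within 0.2% of the section-modulus closed form at
  `h = 0.05`;
- rigid-lever: bite mechanical advantage equals the lever-arm ratio to 1e-10
  (statics, independent of elasticity);
- global equilibrium to 1e-6 relative on every solve;
- homothety: doubling `L` under the area-corrected load reproduces the
  metrics bit-for-bit.

## Morphospace and phylogeny layers

The theoretical grid enumerates integer compositions (36 at the default 10%
step and 10% minimum — the stated enumeration rule yields 36, and all 36 are
solved).  Occupancy is the convex-hull area of species points in ternary
plot coordinates over the simplex area (`√3/4`); an alpha-shape variant is
provided for sensitivity checks.  Species are interpolated on the surfaces
barycentrically; points outside the grid hull fall back to the nearest grid
model and are flagged.  The elongation series solves the base composition at
ratios 0.5–5.0 in 0.5 steps (the 10 printed values; a flag inserts the base
ratio as an 11th).

Ancestral states for the phylomorphospace are maximum-likelihood Brownian
motion — equivalently weighted squared-change parsimony — computed exactly
by the standard two-pass recursion on ternary plot coordinates; tips are
fixed at observed values.  The recursion is cross-checked against direct
numerical minimization of the objective in the test suite.  Trees are
pruned, never grafted; species missing from the tree are drawn unconnected.

## Synthetic dataset generator

The generator emulates the statistical structure of a comparative dinosaur
skull dataset, so the full pipeline is testable without any measurement
file.  Per clade: composition ~ Dirichlet(`concentration × mean`), skull
length and ratio lognormal, diet/epoch categorical; skull height is
`length/ratio` and region lengths are `composition × length`.  The default
preset (204 species) encodes the qualitative pattern of the target group:
theropods longirostral and elongate (ratio log-mean ln 2.6), ceratopsians
bimodal (short-rostrum basal forms and long-rostrum derived forms, ratios
near 1.3), sauropodomorphs with reduced braincases, pachycephalosaurs short
and tall, concentrations 30–50 (within-clade scatter of a few percent on the
simplex).  With seed 1 this yields rostrum fractions spanning 18–82% (the
widest of the three components), orbit 7–50%, braincase 8–52%, skull ratios
1.0–4.1 with mean 2.1, and 26% convex-hull occupancy — a narrow band of the
simplex.  What passing tests on these data show is that the *machinery*
(summaries, occupancy, interpolation, reconstruction) is correct and that
the preset's structure is recovered; they do not validate any empirical
claim about real taxa, whose measurement error, taphonomic bias and
non-Dirichlet shape the generator does not attempt to model.

Trees are clade-monophyletic pure-birth trees: within each clade, lineages
are joined pairwise with exponential waiting times; clade subtrees are then
joined by the same process.  Branch lengths are strictly positive and output
is byte-identical for a fixed seed.

## Numerical and edge-case conventions

- All randomness flows through explicit integer seeds; there is no global
  random state.
- Duplicate species rows are averaged (redundant-measurement designs);
  duplicate pairs differing by more than 20% in any measurement are logged.
- Region-length sums outside `[0.85, 1.15]×` skull length warn; outside
  `[0.5, 1.5]×` they are errors.  Ternary coordinates are normalized by the
  three-region sum (the measurement endpoints need not tile skull length);
  percentages relative to skull length are reported alongside.
- Median over an even element count is the mean of the middle two.
- Degenerate occupancy inputs (fewer than three points, collinear sets)
  return 0 rather than raising.
- Grid sweeps abort on the first model failure by default: a silent hole in
  a 36-point surface would corrupt trend statistics.

## Known limitations

- A 2-D lateral-view plate cannot reproduce 3-D stress magnitudes, torsion,
  or mediolateral load paths; all biomechanical conclusions are trends
  across models under identical conventions.
- Bending median stress scales essentially as `ratio²` for any template of
  this class (load ∝ area ∝ `L·H`, thickness ∝ `H`, section modulus ∝
  `H²`), so the elongation series has its bending minimum at the squattest
  model; it is the *biting* scenario that shows the U-shaped optimum at
  ratios 1.0–2.0 with both 0.5 and ≥ 3.5 strictly worse.
- The muscle model is a single resultant direction with equal nodal shares;
  gape, fiber architecture and the pterygoideus group are out of scope.
- Compositional back-transforms of reconstructed ancestral states are not
  claimed; reconstruction lives in plot coordinates.
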
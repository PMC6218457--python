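# Methods

This note documents the models, conventions and numerical choices behind
`projectome`, in the order data flows through the pipeline.

## SWC morphologies

A morphology is a rooted tree of 3D sample points (μm) read from 7-column
SWC. Conventions fixed here:

- Type codes 1/2/3/4 map to SOMA / AXON / DENDRITE / DENDRITE; all other
  codes are OTHER. Basal and apical dendrites are merged because no
  downstream metric separates them.
- The root is the unique node with parent −1. Additional soma nodes (a
  contour chain) are ordinary tree nodes of class SOMA.
- Arbitrary, non-consecutive ids and forward parent references are
  accepted (parsing is two-pass). Zero-length edges are legal and
  contribute zero cable.
- Morphology equality compares node content keyed by id, so any line
  permutation of a file parses to an equal morphology, while the node
  *sequence* is preserved for byte-stable writing (floats are written in
  shortest round-tripping form).
- `validate()` accepts raw node lists so broken topologies (duplicate
  ids, multiple roots, missing parents, ancestor loops) can be diagnosed
  without the constructor rejecting them; each violation names the node.

## Morphometrics

Three per-class metrics: cable length, terminal tips, branches.

- **Edge class = child-node class.** The soma→axon stem edge is axonal
  cable. This is the only unambiguous rule at class transitions.
- **Child counts are class-restricted**: an axonal node is a tip when it
  has no *axonal* children, a branch point when it has ≥ 2. Under this
  convention the identity `branches = tips + branch_points` holds exactly
  on every tree, and single-stem strictly bifurcating axons satisfy
  `branches = 2·tips − 1` — the relation observed between published tip
  and branch counts for this cell type, which is why the condensed-tree
  "branch" definition (maximal unbranched path) was adopted over counting
  compartments.
- Multifurcations count as one branch point. Lengths are computed in μm
  and reported in mm with no intermediate rounding. No soma-surface
  correction is applied to the stem (no published rule exists to copy).

## Atlas frame

- A label volume is a 3D integer grid (0 = background) with voxel size
  and origin in μm. Voxel (i,j,k) owns the half-open box
  `[origin + i·d, origin + (i+1)·d)`; a point exactly on an interior
  boundary belongs to the higher-index voxel. These conventions are fixed
  so tests can be bit-exact.
- Majority-label downsampling breaks ties toward the smallest region id
  and allows partial edge blocks; origin is unchanged, voxel size scales.
- The ontology is a parent-linked table (id, acronym, name, parent,
  hemisphere, layer, fiber-tract flag). Cortical layers are ordinary
  leaves under their area, with layers 2 and 3 assessed together as
  "2/3" (their boundary is not reliably drawable in frontal cortex).
  The layer of a soma is its region's layer tag or that of the nearest
  layer-typed ancestor.
- The midline is a config-supplied axis-aligned plane, not inferred.
- Volumes serialize to NRRD (raw or ascii encoding; first axis fastest,
  geometry in `space directions`/`space origin`). The reader/writer here
  covers exactly that subset.

## Projection quantification

Every axonal edge is subdivided into equal pieces of length ≤ step
(default: the smallest voxel edge); each piece's full length is booked to
the region and hemisphere at its midpoint.

- Total cable is conserved *by construction* — the pieces of an edge sum
  to the edge length — so `Σ_r L_r = L_total` to float precision; the
  midpoint rule converges to exact clipping as the step shrinks, and
  halving the step moves any region total by less than the
  voxel-boundary discretization bound.
- A background bucket (id 0) always carries unlabeled/outside cable and
  is included in the strength denominator, so per-neuron fractions sum
  to 1 and ipsi+contra percentages need not reach 100 %. (Denominator
  choice is configurable; total-including-background is the default and
  the conservative reading of published percentage tables.)
- "Ipsilateral" is the soma's side of the midline plane. A soma exactly
  on the plane takes LEFT as ipsilateral (deterministic tie-break).
  Mirroring a morphology about the plane swaps the LEFT/RIGHT cable
  decomposition exactly and leaves ipsi/contra invariant (the soma
  mirrors too); `side_lengths` exposes the soma-independent
  decomposition for symmetry checks.
- Dendritic cable is excluded from projection quantification; dendrites
  are only measured morphometrically.
- Aggregation to a coarser report level maps each region to its first
  self-or-ancestor in the requested region set (or ontology depth);
  regions with no ancestor at the level join the background bucket.

## Classification

- **CPN/APN**: a neuron is a callosal projection neuron iff its
  contralateral axonal cable is ≥ `min_contra_mm` (default 1.0 mm). The
  threshold exists because no published minimum is stated; 1 mm is far
  above stray crossing noise yet far below any real callosal arbor.
  Passage through the corpus-callosum label is reported separately
  (`crossed_via_cc`) rather than being definitional, so a stray
  sub-threshold crossing cannot flip the class.
- **Profile categories**: published three-way groupings of projection
  profiles are qualitative ("extends caudally…"); the pipeline replaces
  them with a deterministic stand-in — binarize each neuron's strength
  row at θ (default 0.05), then single-linkage-merge target sets with
  Jaccard similarity ≥ 0.5. Category ids follow first-member order, so
  the grouping is permutation-equivariant. This is a reproducibility
  device, not a claim about the original manual grouping.
- The signed anterior–posterior displacement of the contralateral cable
  centroid is reported as a descriptive direction-of-extension value.

## Group statistics

Mean ± s.e.m. per soma group (s.e.m. = sd(n−1)/√n, flagged undefined at
n = 1) and pooled-variance two-sided Student's t (df = n₁+n₂−2), the test
named in the source methods; Welch's variant is behind a flag. Stars:
\* p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001. No multiple-testing
correction by default (matching the original analysis); a
Benjamini–Hochberg helper is available. A zero pooled variance raises
`DegenerateVariance` instead of returning an infinite t.

## Synthetic data

The generator's defaults are the study conditions the pipeline is
validated under.

- **Atlas**: 100 × 80 × 60 voxels at 100 μm (10 × 8 × 6 mm), midline at
  x = 5000 μm, mirror-symmetric boxes for MOs/PL/ORBm (each with layer
  1, 2/3 and 5 slabs), ACA, AI, SS, VIS, RSP, ENT, CP, BLA, and a
  corpus-callosum band straddling the midline. Boxes are voxel-aligned
  so the volume equals its own reflection up to the left/right id swap.
- **Neurons**: one axonal stem leaves the soma; a shaft routes to each
  target box (contralateral targets branch from a shared
  corpus-callosum crossing); inside each box a bifurcating random-walk
  arbor consumes that target's weight share of the requested cable
  budget, minus the routing cable already spent. Dendrites grow as a
  local arbor in a ±400 μm box around the soma. Steps are 20 μm;
  per-step direction jitter sd 0.25 gives shafts a few percent of
  tortuosity overhead.
- **Ground truth is the realized allocation**, recorded by the generator
  from its own edges (midpoint rule at growth-step resolution), not the
  requested weights — so recovery tests measure quantification error
  only. Routing cable is booked to whatever regions it traverses,
  mirroring real axons' passage through white matter.
- **Regimes** are parameterized from the published group table for this
  cell type: layer-5 MOs axons are drawn from N(311.39, 60²) mm
  truncated to just inside the printed range [180.04, 318.43] mm — the
  parent mean is the value at which the *truncated* expectation equals
  the printed group mean of 270.58 mm (the truncation is asymmetric, so
  a parent centered at the group mean would realize ≈ 255 mm and
  understate the printed regime, including the six-neuron total
  exceeding 1,600 mm). Layer-2/3 regimes use means ≈ 65–70 mm; dendrites
  5.5–7.4 mm; branching rates (5.5–7.5 events per mm of axon, ≈ 10–12
  per mm of dendrite) chosen so tip counts land in the published ranges
  (≈ 1,500 axonal tips for layer 5, ≈ 400–530 for layer 2/3). Class
  mixes follow the published composition: 6 CPN layer-5, 10 CPN + 7 APN
  layer-2/3 MOs, 1 CPN + 5 APN PL, 5 CPN + 2 APN ORBm. CPN specs always
  carry ≥ 25 % contralateral weight, an order of magnitude above the
  classification threshold.
- Per-neuron growth seeds derive from the population seed via
  `SeedSequence.spawn`, so identical calls are byte-identical and each
  neuron is independent of how many follow it.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: curved region boundaries and registration
error, axon diameter/radius variation, en-passant boutons (tips are the
only target proxy), reconstruction splicing errors, truncated arbors, and
biological correlations between targets. Tests against this generator
validate the *measurement* chain (annotation, conservation, symmetry,
classification logic), not anatomical realism.

## Problem sizes and numerics

Default validation sizes: 500 random trees (≤ 500 nodes) for the
morphometry oracle battery; 20 seeded neurons for ground-truth recovery;
the 36-neuron demo population (6+17+6+7) for the end-to-end run. Strength
recovery is exact when the analysis step (voxel edge, 100 μm) is at least
the growth step (20 μm), since every growth edge then forms a single
piece with the same midpoint the generator used; tolerances in tests
(0.01 absolute on fractions, 1e−6 relative on conservation, 1e−9 on
lengths) cover the general case. Tie-breaks are all deterministic:
smallest label id in downsampling, LEFT at the midline, first-member
order for category ids.

## Known limitations

- The NRRD codec covers only the subset the atlas writes (3D integer,
  raw/ascii, diagonal space directions).
- Midline geometry is a single axis-aligned plane; curved midlines would
  need a registration step out of scope here.
- `categorize_profiles` is O(n²) in neurons — fine for tens to hundreds
  of cells, not for atlas-scale populations.
- The profile categorization is a deterministic stand-in for a manual
  grouping; its categories should not be read as biological types.
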
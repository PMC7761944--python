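# Methods

`toothwear` measures occlusal tooth wear as a volume difference between two
serial surface models of the same tooth, in the hard setting where other
crown surfaces also changed between the time points (typically because a
wire retainer was bonded lingually).  This note describes the model and the
numerical choices; everything quantitative it mentions is computed by the
test suite or by `scripts/acceptance.py`, not asserted from memory.

## Measurement model

Two triangle meshes (T0 baseline, T1 follow-up; millimetres, outward
orientation) are rigidly superimposed, sliced with identical planes, capped
identically, and the wear volume is

    wear = V(T0 part) − V(T1 part)   [mm³, positive for material loss]

Because the same planes and the same planar caps bound both parts,
everything gingival of the cut cancels exactly and the difference isolates
the occlusal change.  Volumes use the divergence theorem on watertight
parts (sum of signed tetrahedra), which is exact for a given tessellation
and translation invariant.

### Registration

The superimposition dialect is a trimmed iterative closest point scheme:

1. sample the reference-region vertices of T0 (100% sampling by default);
2. find the *exact* closest point on the T1 surface for each (faces, edges
   and vertices are all candidates; candidates come from a KD-tree over
   sub-triangle centroids with a radius certificate — any triangle that
   could beat the best candidate is provably inside the searched ball — so
   the result equals a brute-force all-triangle scan, which the tests
   verify);
3. optionally discard pairs whose closest point lies on an open boundary of
   the target ("exclude overhangs"), so structure present in only one model
   cannot bias the fit;
4. keep the fraction of best-matching pairs given by the *estimated overlap
   of meshes* (k = ⌊overlap · n⌋, ties broken by source order);
5. solve a rigid update — point-to-plane by small-angle linearisation with
   the rotation rebuilt exactly from the solved rotation vector, or
   point-to-point by orthogonal Procrustes — and compose.

Iterations stop at 50 (the protocol's cap) or when the RMS residual changes
by less than 1e-7 mm.  Eight techniques pair this dialect with a reference
area: the gold standard (GS) registers on intact adjacent teeth plus the
alveolar process at 100% overlap; the partial-crown (PC) and complete-crown
(CC) techniques register on crown subsets with 100%, 40%, 20% or an
operator-optimised ("user defined") overlap.  The user-defined value is
found by a grid search (0.05…1.00, step 0.05) scoring each candidate by the
RMS distance of known intact structures after registration — an emulation
of the operator's iterative search that is only possible in a benchmark,
where intact structures are known.

Registrations below 50% overlap are preceded by a coarse landmark
alignment (the stand-in for on-screen manual approximation; Kabsch fit of
four landmark pairs) and a full-overlap *approximation* pass.  The
approximation pass runs with a robust outlier gate: correspondences farther
than 6× the median distance are dropped before trimming.  The gate is inert
when the surfaces match everywhere (distances are then homogeneous and
nothing exceeds 6× the median, so GS-style registrations are untouched),
but it prevents a pass whose only purpose is to *approximate* the models
from being dragged by grossly changed surface — a 2 mm wear facet pulls a
converged full-overlap fit several degrees away from the correct alignment,
beyond the capture range of the final trimmed stage, whereas the final
trimmed stage converges reliably from the coarse alignment.  The final
stage always runs the predefined setting exactly (pure overlap trimming,
no gate).

### Slicing and identical hole filling

A signed distance map on the superimposed crowns (positive where T1 lies
outside the T0 surface) marks changed surface at a configurable threshold
(default 0.05 mm — the numeric stand-in for the operator's colour-coded
visual check).  The gingival plane (normal = occlusal axis) is placed
0.3 mm below the changed cluster that reaches the occlusal extreme; if the
cut line then still crosses changed surface, the plane is moved gingivally
in 0.3 mm steps until the boundary verifiably runs through unchanged
surface (both directions are checked), as an operator would reposition the
level.  If no admissible position exists inside the crown the measurement
aborts with a cannot-isolate error rather than return a biased volume.
Additional mesial/distal planes are accepted from the caller and verified
the same way; the hole-splitting and capping machinery below handles one to
three planes.  Automatic placement of proximal planes is not attempted —
the bench protocol left their placement to operator judgement, and the
generator's grinding patterns never require them.

Slicing keeps the intersection of the kept half-spaces.  Crossing triangles
are split exactly at each plane (cut vertices are projected onto the plane;
after all cuts each boundary vertex is re-projected onto every plane within
1e-6 mm, so corner vertices settle onto plane intersection lines).  Hole
boundaries spanning several planes are split into planar loops by inserting
chords along the intersection line of the two planes at each crease —
the in-silico version of connecting contralateral points across sharp
edges.  A three-plane *corner* (three planes meeting inside the hole) is
not decomposable by chords between existing vertices and raises a topology
error; the supported configurations are one plane, or two/three planes
whose creases each carry exactly two loop vertices.  Each planar loop is
capped by ear clipping in its plane (orientation follows the reversed
boundary traversal, so caps continue the outward winding); self-
intersecting loops are rejected.  Planar caps make the enclosed volume
independent of the particular cap triangulation, which the tests verify to
1e-12 mm³.

## Synthetic benchmark (what it emulates, what it does not)

The generator replays the bench validation entirely in software:

* **Teeth** are parametric superellipse-profile crowns on tapered roots:
  blade-like incisors (narrow incisal edge) and single-cusp canines, with
  deterministic anatomy (cingulum, lingual fossa, marginal and labial
  ridges) plus seeded low-frequency relief of 0.1–0.3 mm.  The anatomy is
  load-bearing: crowns close to surfaces of revolution admit spurious
  rotated registrations, and it is the ridge/fossa structure of real crowns
  that lets a crown-referenced registration constrain all six degrees of
  freedom.  Default resolution is 3000 triangles per tooth, a desk-scale
  stand-in for the 600 000–900 000-triangle arch scans of laboratory
  scanners; below ~1500 triangles the 20%-overlap trim retains too few
  points to hold that anatomy and the techniques degrade, which is a
  resolution artefact rather than a method property.
* **The arch segment** places the test tooth between two intact neighbours
  (1.4 mm gaps; optional crowding jitters rotations up to 6° and lingual
  offsets up to 0.7 mm) above a subdivided alveolar band; all components
  are disjoint closed surfaces, so the scene is watertight and the GS
  reference (neighbour crowns + band) is exactly unchanged geometry.
* **Grinding** truncates the occlusal end with a horizontal plane
  (symmetric) or a plane tilted 6–14° about the mesiodistal axis
  (asymmetric) at 0.5/1/2 mm vertical loss.  The removed solid is capped
  and measured, giving closed-form ground truth (exact for a prism:
  6 × 7 mm cross-section, 1 mm loss → 42 mm³).  Edge rounding is not
  modelled; flat facets match stone-knife grinding and keep the truth
  exact.
* **The retainer** (0.3 mm wire at 42% of crown height plus composite
  blobs ~0.7 mm proud, ~1.6 mm across, jittered per tooth) is modelled as
  the outward *envelope* the scanner would digitise: lingual crown vertices
  move outward along their normals by the wire+composite displacement
  field.  A swept tube merely concatenated onto the mesh would leave the
  original lingual surface buried inside it, and a distance query would
  still find that buried surface — the retainer would then not challenge
  crown-referenced registration at all.  The displacement form keeps every
  buccal and occlusal vertex bit-identical (asserted in tests) and yields
  the composite footprint mask on T0 by evaluating the same positional
  field on the T0 geometry (wire height anchored to the unworn crown).
* **Scanner noise** displaces vertices along their normals by zero-mean
  Gaussian offsets (SD 2 µm) hard-clamped at 5 µm, mirroring a laboratory
  scanner whose repeated scans stay within 5 µm.
* **Poses**: T1 is generated under a random rigid displacement (rotation
  5–15°, translation 2–10 mm) and the four coarse-alignment landmarks
  (incisal tip, buccal gingival midpoint, mesial/distal extremes) are
  jittered with SD 0.15 mm, the accuracy expected of expert on-screen
  landmarking, so every registration is genuinely exercised.

The benchmark (18 incisors + 18 canines, balanced over loss levels,
patterns and crowding) feeds the validation analytics: per-technique
trueness/precision against GS, Friedman + pairwise Wilcoxon with Bonferroni
adjustment, Mann–Whitney/Kruskal–Wallis covariate checks, Bland–Altman
reproducibility (repeats re-run from an independently perturbed initial
pose and re-picked landmarks on the *same* meshes — the analog of an
operator repeating the measurement after a month), and the repeated-scan
error (two independent noise realisations of a single tooth, re-posed and
superimposed with CC_C).

What passing these tests does **not** show: performance on real enamel
texture and scanner artefacts (holes, spikes, varying point density),
segmentation error of real gingival margins, erosion-like change spread
over whole surfaces (explicitly outside the method's applicability), or
behaviour at the full 600–900k-triangle scale.  The synthetic teeth are
shape-generic, not anatomical scans.

## Numerical choices and degenerate inputs

* Weld tolerance 1e-9 mm (exact duplicates only, so fine wire-scale
  geometry can never be accidentally merged); zero-area faces dropped at
  load with a logged count.
* Plane snap 1e-9 mm; loop planarity tolerance 1e-6 mm.
* Rotations validated orthonormal (det +1) to 1e-9; point-to-plane updates
  re-orthonormalised through the rotation-vector exponential.
* Rank-deficient point-to-plane systems (flat regions) fall back to the
  minimum-norm least-squares update, and to Procrustes on hard failure.
* Ties in distance trimming break by source index (stable), making every
  registration bit-reproducible for a given seed.
* The overlap grid search resolves score ties toward the largest fraction
  (an unchanged pair therefore reports 100% overlap as optimal).
* Degenerate inputs raise typed errors (configuration / invalid input /
  geometry / topology), which the CLI maps to distinct exit codes.

## Problem sizes used by the shipped validation

The acceptance script and the acceptance tests run the full 36-case
benchmark at 3000 triangles per tooth with GS and CC_C, 10-case
reproducibility repeats, and a 10-tooth repeated-scan experiment; unit and
property tests use 320–1500-triangle fixtures.  The repeated-scan
experiment uses 30 000-triangle single teeth: its volume error integrates
the surface noise over the occlusal part (σ ≈ A·sd/√N), so it is density
controlled, and a single tooth at that density approximates the per-crown
density of the laboratory arch scans while staying cheap.  These sizes are
the package's chosen desk-scale study conditions; the generator exposes
`resolution` for larger replicas.

## Known limitations

* Only the gingival plane is placed automatically; proximal planes are
  caller-supplied (verified, but not proposed).
* The retainer envelope is smooth; real composite shows sharp margins and
  occasional scanning voids.
* "User defined" overlap needs known intact structures and is therefore
  benchmark-only, exactly as in the bench study.
* The ICP dialect of the commercial tool it emulates is not publicly
  documented; the estimated-overlap trimming, boundary-contact overhang
  rule and the robust approximation gate are this package's own documented
  interpretations.
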
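# Methods

## Problem and approach

Registering a vascular point cloud reconstructed from intraoperative 3-D
ultrasound (US) to one reconstructed from preoperative CT is a cross-source
problem: the two clouds sample the same anatomy with very different density,
noise and coverage, so surface-based rigid registration is fragile. The
package instead reduces each cloud to *skeleton feature curves* — smooth
centerline segments of the vessel tree — and registers those. Homologous
features survive the source differences because they describe the vessel
axes, not the imaged surfaces.

The pipeline per cloud:

1. **Voxel downsampling** (0.8 mm grid, centroid per occupied cell).
2. **Laplacian contraction.** An umbrella Laplacian `L` is built on the
   symmetrized k-nearest-neighbour graph with inverse-distance weights
   `w_ij = 1 / max(||p_i - p_j||, 1e-6)`. Each iteration solves the stacked
   least-squares system `[w_L L; W_H] X' = [0; W_H X]` through its normal
   equations (sparse Cholesky-style factorization); `w_L` doubles per
   iteration (capped at 2048) and the per-point attraction `W_H` grows as the
   point's neighbourhood collapses (initial/current mean neighbour distance).
   The loop stops after 10 iterations or when the summed local extent changes
   by less than 0.003 between iterations. The neighbourhood graph is built
   once and kept fixed, which makes the operator — and hence the whole
   contraction — exactly equivariant under rigid motions of the input.
3. **Skeleton graph.** The contracted points are thinned on a 2 mm voxel
   grid, joined by the minimum spanning tree of their complete Euclidean
   graph (deterministic lexicographic tie-break), junction clusters closer
   than twice the mean edge length (geodesically) are collapsed to their
   centroid, and hair branches shorter than 5 mm are pruned iteratively — a
   junction left with only two chains then splices into one segment. Degree
   classifies vertices: 1 = endpoint, >= 3 = junction.
4. **Segmentation.** Each endpoint connects to its geodesically nearest
   junction by the (unique) tree path; junction-junction trunks are read off
   the remainder. Segment points are ordered along their principal direction
   (PCA over up to 20 points).
5. **Centre refinement.** Original points are assigned globally to their
   nearest skeleton point within 15 mm. Per cross-section the wall points A
   and B nearest to the centroid along the +/- second-principal ("vertical")
   direction (15-degree cones, half-space fallback) give a local diameter
   d = |A - B|; the centroid of the points within 1.25 * d/2 is the refined
   centre C'. The pass is iterated up to 3 times. The d/2 neighbourhood's
   real, measurable benefit is rejecting points of *other* vessels pulled in
   by the wide assignment radius near junctions. Guards: the disc must cover
   at least 40% of the section (otherwise the wall search failed and the
   centroid is kept — an unguarded sliver disc collapses the centre onto one
   wall), centres need >= 5 supporting points and a diameter within 3x the
   segment median, and cross-sections within one diameter of a junction are
   skipped (two merging lumens have no well-defined centre).
6. **Curve fitting.** Ordered centres are fitted per coordinate by a
   quadratic in the normalized principal-axis parameter and sampled at 25
   points. Centres farther than 2 mm from the first fit are dropped once and
   the curve refitted. A quadratic is a local model: when a segment spans
   more than 40 mm *and* the median residual exceeds 1 mm the segment is
   fitted piecewise in roughly equal spans. Fitted curves are clipped to
   imaged support — samples farther than (radius + 2.5 mm) from the original
   cloud are removed (longest supported run kept), since a curve bridging an
   unimaged region would otherwise bias the registration.
7. **Frame canonicalization.** Steps 1-6 run in the cloud's PCA-canonical
   frame (deterministic axis signs) and the curves are mapped back, so the
   voxel grids commute with rigid motions and feature extraction is
   equivariant to floating-point precision.

In human mode (portal-vein scans) terminal branch curves are additionally
thinned (every 5th sample kept) and curves carry length-proportional weights
normalized to sum to one, realized at registration time by proportional
seeded resampling.

## Registration

Feature curves from the two sources are registered in two stages.
Correspondences always run **from the US features to the CT features**: the
US sweep covers only part of the anatomy, so in this direction every source
feature has a true counterpart; the reported case transform (CT onto the
fixed US frame) is the inverse. The target side is densified along its
curves (0.5 mm) so nearest-neighbour quantization does not enter the
objective.

**Coarse stage — globally optimal search.** Both clouds are normalized by
their joint centroid and scaled into `[-1, 1]^3` (the convention under which
the translation sub-cube `+/-0.5` and the MSE threshold `0.001` of the
parameter tables are meaningful). A branch-and-bound search over the
rotation cube (axis-angle, centre `(-pi,-pi,-pi)`, width `2*pi`) and the
translation cube keeps a priority queue ordered by a lower bound on the
10%-trimmed mean-squared nearest-neighbour error: per point,
`max(0, d_i - gamma_rot,i - gamma_trans)^2` with the standard rotation
(`2 sin(min(sqrt(3) s_r, pi)/2) * ||x_i||`) and translation
(`sqrt(3) s_t`) uncertainty radii. Whichever domain currently contributes
the larger uncertainty is split into octants. Candidate poses are polished
by an inner trimmed ICP; the incumbent is warm-started from a fixed
rotation net (cube centre, octant/face/edge centres, axis half-turns), four
principal-axes pre-alignments and a roll sweep about the principal axis
(the ambiguity PCA leaves for elongated structures). The search stops when
the incumbent's trimmed MSE reaches the threshold, when the remaining bound
gap falls below `max(1e-6, 1e-3 * best)` normalized units squared, or at the
expansion budget (default 20,000; the incumbent is returned with
`converged=False`). Nearest neighbours come from exact k-d-tree queries —
at feature-cloud sizes (hundreds of points) exactness beats the customary
distance-transform grid.

**Fine stage — ICP.** Point-to-point ICP (closed-form Kabsch update, no
scale, all correspondences kept, seeded uniform subsampling only above
50,000 points) runs from the coarse pose for at most 20 iterations or until
the RMS improvement drops below 1e-6. The fine transform is adopted only if
it improves the nearest-neighbour RMSE, so the two-stage result never ends
worse than the coarse stage.

### Parameter tables (defaults)

| Stage | Parameter | Default |
|---|---|---|
| contraction | voxel edge | 0.8 mm |
| contraction | k nearest neighbours | 100 |
| contraction | initial contraction weight | 0.5 |
| contraction | initial attraction weight | 4 (phantom) / 10 (human) |
| contraction | max iterations | 10 |
| contraction | termination ratio | 0.003 |
| segmentation | PCA neighbourhood | 20 |
| segmentation | assignment radius | 15 mm |
| segmentation | end downsampling k (human) | 5 |
| coarse | rotation cube | centre (-3.1416)^3, width 6.2832 |
| coarse | translation cube | centre (-0.5)^3, width 1.0 (normalized) |
| coarse | MSE threshold | 0.001 (normalized units^2) |
| coarse | trim fraction | 0.1 |
| fine | max iterations | 20 |
| fine | adjust scale / filter farthest | off |
| fine | random sampling limit | 50,000 |
| fine | final overlap ratio | 1.0 |
| fine | max workers | 7 (resource bound; results never depend on it) |
| fine | min RMS decrease | 1e-6 |

YAML configs also accept the original tool-level spellings of these
parameters (`Goicp.MSEThresh`, `nbMaxIterations`, `rNode.a`, `Down sample
size`, ...), so published parameter listings can be pasted directly.

## Synthetic study conditions

Clinical US/CT pairs cannot be redistributed, so the package evaluates on
synthetic phantoms built to exercise the same failure modes:

- **Trees.** A 150 mm trunk bent quadratically (15 mm) with an out-of-plane
  cubic component (9 mm) — a purely quadratic trunk would be a
  mirror-symmetric parabola, which no real vessel is and which would make
  the pose ambiguous up to a flip — plus 3-8 branches (35-60 mm, 30-70
  degrees, radius 1.5 mm vs trunk 2.5 mm) sprouting at seeded positions.
  This is liver-portal-vein scale, so millimetre tolerances are meaningful.
- **CT-like render:** tube-surface sampling at 0.5 points/mm^2, isotropic
  Gaussian noise 0.15 mm.
- **US-like render:** 0.3 points/mm^2, noise 0.4 mm, 30% random dropout,
  and a coverage fan (apex 70 mm from the tree centre, half-angle 35
  degrees) that truncates roughly a quarter of the anatomy — the
  limited-scanning-range failure mode that breaks surface ICP.
- **Misalignment:** uniform random axis, rotation up to 30 degrees,
  translation uniform in a 20 mm ball. Four spherical tumours (radius
  7.5 mm) are placed 2-40 mm clear of the vessels; their centres (exact in
  both frames) score the tumor-centre TRE, and optional 1 mm voxel masks
  support Dice / volume-similarity / surface-Dice evaluation.

Everything is seeded and bit-reproducible. What the phantoms do *not*
emulate: US speckle and shadowing textures, deformable (breathing) motion,
segmentation errors of a vessel-extraction network, and anastomotic loops
(the skeleton stage assumes a tree). Passing these studies therefore shows
robustness to density/noise/coverage asymmetry under rigid motion — not to
deformation or systematic segmentation bias.

**Contraction neighbourhood at desk scale.** The synthetic studies use
k = 16 instead of the table default k = 100. The neighbourhood's *locality*
is what matters: on dense clinical reconstructions k = 100 spans a few
millimetres of vessel, while on the synthetic clouds (~0.5 points/mm^2,
1-2k points) it would span ~25 mm and collapse the tree globally. k = 16
reproduces the clinical locality at the synthetic density. The per-case
parameter adjustment mirrors practice: no single parameter set suits all
cloud densities, which is why these are configuration, not constants.

**Case-level TRE** is summarized as the mean TRE over the case's tumour
targets (the standard multi-target aggregation); per-tumour values are
reported alongside.

## Evaluation metrics

- `skeleton_rmse`: directed nearest-neighbour RMSE from the transformed
  source features to the target features — the quantity the fine stage
  minimizes. Against curve targets the distance is taken to the densified
  curve, so stored sample spacing does not inflate it.
- `target_registration_error`: `||T c_moving - c_fixed||` per tumour.
- `transform_error`: RMS discrepancy of two transforms over a reference
  cloud; used to compare against ground truth independently of any metric's
  correspondence choices.
- `dice_and_vs`: voxel overlap `2|A&B|/(|A|+|B|)` and volume similarity
  `1 - ||A|-|B||/(|A|+|B|)`; undefined (reported absent) when both masks are
  empty.
- `surface_dice` at tolerance tau (default 5 mm, the ablation margin):
  symmetric fraction of surface samples within tau of the other surface.

## Numerical choices and edge cases

- Coincident points get epsilon-floored Laplacian weights (1e-6 mm) and are
  merged before the MST; a singular contraction system falls back to a
  least-squares solve; non-finite positions abort with the parameters named.
- Voxel binning uses the absolute origin-anchored grid of half-open cells,
  which makes downsampling exactly idempotent (a cell's centroid stays in
  its cell).
- MST ties break to the lexicographically smallest vertex pair; segment
  extraction ties (equidistant junctions) break to the lowest index.
- The branch-and-bound rotation cube covers all of SO(3); sub-cubes entirely
  outside the pi-ball are discarded.
- All stochastic steps (surface sampling, dropout, transform draws, weighted
  curve resampling, ICP subsampling) flow from explicit integer seeds;
  results are independent of the worker-count setting, which is a resource
  bound only.

## Known limitations

- The coarse stage's MSE-threshold stop (table semantics) can accept a pose
  a few millimetres off in flat residual landscapes; the warm-start net
  makes this rare, and the fine stage cannot escape a wrong basin. With
  3-branch trees under harsh partial coverage, a residual 2-4 degree
  rotation error survives in roughly one case in ten (TRE at 30-40 mm lever
  arms then exceeds 2 mm).
- The centre-refinement step cannot improve a one-sidedly truncated
  cross-section (any disc around the biased centroid reaches the near wall
  first); its value is contamination rejection, while coverage robustness
  comes from the skeleton topology and curve support clipping.
- Rigid motion only: breathing-induced deformation is out of scope, as is
  real-time re-registration during probe motion.
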
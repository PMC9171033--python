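# Methods

## Model and assumptions

osteomap treats a growing bone as a time-ordered series of closed
triangulated surface models (coordinates in mm) of the *same* anatomy, with
one model per measurement instance and instances nominally one month
(4 weeks) apart.  Growth is assumed smooth in space and time at the scale
of the mesh: between consecutive instances every surface point moves by a
small displacement (typically ≤ 2–3 % of its distance to the bone center),
so a vertex's local neighborhood on the next model is geometrically similar
to its current neighborhood up to a local rigid motion plus a mild
size/shape change.  No assumption is made that growth is uniform — the
whole point of the per-vertex analysis is to map its spatial non-uniformity
— but the method cannot separate bone apposition from resorption, and it
measures surface morphology only.

## Correspondence search

For vertex *j* at instance *i*, with neighborhood point set Q_{i,j} (all
vertices within radius *r* of P_{i,j}), the matching vertex on model *i*+1
maximizes the correlation coefficient f = cov(Q_{i,j}, Q_{i+1,j}) /
(σ_{i,j} σ_{i+1,j}) subject to a local rigid transform.  Concretely:

- **Global pre-alignment.**  One rigid ICP (nearest-neighbor pairing +
  Kabsch update, converged when the RMS change < 1e-8) aligns model *i* to
  model *i*+1.  This makes the local search well-posed and supplies each
  vertex's *predicted position* on the next model.
- **Candidates.**  All target vertices within ρ of the predicted position.
  Matching is vertex-to-vertex: the winning candidate's center vertex is
  marked as vertex *j* on model *i*+1.
- **Local refinement and score.**  For each candidate, a local rigid
  transform is initialized from the pre-alignment (translated to the
  candidate) and refined by at most 5 Kabsch passes on nearest-neighbor
  pairings.  The correlation is then computed by pairing each transformed
  source-neighborhood point with its nearest point of the candidate's
  neighborhood, centering both matched lists on their own centroids, and
  taking the Pearson correlation of the two concatenated length-3m
  coordinate vectors.  This definition keeps cov and the σ's well defined
  when the two neighborhoods have different cardinalities; by
  Cauchy–Schwarz the score lies in [−1, 1], and a perfect copy scores
  exactly 1 (the variance product is computed under a single square root,
  and values within 1e-13 of ±1 are snapped to the bound).

Two properties of this score shaped the implementation:

- **Scale invariance.**  Pearson correlation is invariant to uniform
  scaling, deliberately so — a uniformly growing patch still matches its
  image perfectly.  The flip side is that the score carries almost no
  information about *which* nearby candidate is the right one: any
  candidate whose neighborhood covers the (scaled) image of the source
  patch can score ≈ 1.
- **Boundary truncation.**  With equal radii on both sides, the true
  candidate's ball clips part of the grown image of the source patch and
  loses ~1e-3..5e-3 of correlation, while an offset candidate may cover the
  image completely.  Candidate neighborhoods therefore use radius
  `r × target_radius_factor` (default 1.3); the extra target points act
  only as pairing candidates and never enter the correlation unpaired.

Consequently, score differences below `score_tol` (default 5e-3) are
treated as ties and resolved deterministically by distance to the predicted
position, then by vertex index.  Genuinely wrong placements show score
gaps well above 1e-2; differences below the tolerance are dominated by
sampling and truncation artifacts.  An exhaustive-search test confirms the
bounded search (ρ = ∞) reproduces an independently coded brute-force
selection exactly.

One theoretical note: the idealized expectation that a point-inverted
neighborhood scores exactly −1 cannot be realized under nearest-neighbor
pairing — for any point set the largest-norm point's inversion image is its
farthest target — so anti-correlation is strong but not exactly −1.

## Defaults

| parameter | default | rationale |
|---|---|---|
| r (neighborhood radius) | 5 × mean edge length | spans several vertex rings so the correlation sees shape, not noise |
| ρ (candidate radius) | 3 × mean edge length | generous bound on per-month displacement after pre-alignment |
| target_radius_factor | 1.3 | covers the grown image of the source patch (see above) |
| refine_iters | 5 | Kabsch refinement converges in 2–3 passes in practice |
| score_tol | 5e-3 | correlation discrimination floor (see above) |
| smoothing | None (GCV) | least-squares smoothing spline; see below |
| welding tolerance | 1e-6 mm | 5 orders below the 0.4 mm CBCT voxel |
| thickness cutoff | 30 mm | upper bound on plausible mandibular thickness |

## Growth rates

The monthly change of a vertex pair (mesh edge) from T_i to T_{i+1} is
100·(L(T_{i+1}) − L(T_i))/L(T_i) %/month, normalized by the *preceding*
instance's length and assigned to T_{i+1}.  A cubic spline is fitted in a
least-squares sense to the **cumulative** normalized change C(t) (C(T₁)=0)
and differentiated; fitting the cumulative curve is what gives the gradient
%/month units (a constant monthly change c returns exactly the constant
rate c).  By default the spline is a penalized least-squares cubic
smoothing spline with the penalty chosen by generalized cross-validation:
measurement noise in each instance's geometry would otherwise be amplified
by differentiating an exact interpolant, worst at the series endpoints.
Noise-free data have zero residual at zero penalty, so exact polynomial
curves are reproduced; `smoothing=0` forces exact interpolation and a
positive value is passed to FITPACK as the residual bound.

Per-vertex rates are the unweighted mean over incident edges ("adjacent
vertices" = mesh edges).  Directional components distribute each edge's
rate over the anatomical axes by squared direction cosines,
g_axis = g·(u·axis)², which sum back to g exactly; negative changes
(resorption) propagate as negative rates without clamping.  Edge directions
are taken from the first-instance geometry.

When consecutive models are *independent* reconstructions (e.g. each
instance decimated separately, as in the vertex-count sensitivity scan),
several source vertices may legitimately snap to one target vertex and a
tracked edge can collapse; `edge_length_changes(..., on_zero_length="drop")`
removes such edges, and the sensitivity scan excludes vertices left without
a surviving edge from the region means.

## Anatomy

The anatomical frame is built from landmarks only: ML is the unit vector
between the left and right lateral condylar poles, AP points from the
gonion midpoint to the genial tubercle (orthogonalized against ML),
SI = ML × AP, origin at the gonion midpoint.  The construction is a
package choice — conventions differ between laboratories — and is
equivariant under rigid motion, so directional rate components are
invariant.  Region labels are an input partition (regions are outlined
manually in practice); region summaries report mean/SD/count per region,
instance and direction, and satisfy the partition identity exactly.
Regional thickness casts a ray from each region vertex along the inward
vertex normal (Möller–Trumbore against all faces, 30 mm cutoff) and
averages the hit distances; condylar width is the Cd-lat–Cd-med distance.

## Validation

Landmarks identified on the first-instance model are snapped to their
nearest mesh vertices (snaps beyond 3 × mean edge length warn) and
propagated along the correspondence chain; position RMSE against a
gold-standard set is reported per landmark and instance over an explicit
replicate axis (the study subjects).  Inter-landmark rate RMSE compares
normalized monthly changes of landmark-pair distances.  The vertex-count
sensitivity scan decimates every instance to a decreasing count (5 % of the
start count per step), transfers labels by nearest vertex, reruns the
pipeline, and compares per-region rates to the start-count reference with a
paired two-sided t-test (α = 0.05; Wilcoxon available); the chosen count is
the last before the first significant difference.

## Synthetic generator

The generator emulates the study conditions: a closed, watertight
mandible-like surface (~653 vertices) built by sweeping a varying-radius
circular cross-section along a horseshoe centerline with two posterior
rami bearing condylar knobs; smooth low-order radial bumps give local
neighborhoods distinguishing features (real bone is feature-rich; a
perfectly smooth tube is locally rotation-symmetric and correspondence
would be ill-posed); quadric decimation to the exact vertex count followed
by shape-preserving tangential Laplacian relaxation yields near-uniform
sampling like reconstructed surfaces.  Seventeen landmark analogs and a
six-region partition are derived geometrically.

Growth displaces each vertex away from the template centroid by a smooth
per-vertex rate field (region-wise target rates diffused across region
borders by neighbor averaging), scaled per interval by a temporal profile
decaying from 1.0 to 0.3 — emulating decelerating juvenile growth with
region rates of roughly 0.3–2 %/month.  Defaults: condyle 1.9, posterior
ramus 1.5, anterior ramus 1.0, corpora 0.4 %/month; 12 instances; noise
σ = 0.2 mm applied as iid Gaussian displacement along vertex normals
(surface-measurement-like, no tangential drift, so vertex identity defines
the ground-truth correspondence).  Ground-truth rates are computed from the
noiseless coordinates through the same edge-tracking and spline machinery
with identity maps, which coincides with the closed-form edge lengths of
the displacement model.

What the generator does *not* emulate: real segmentation artifacts,
spatially correlated reconstruction error, topology changes (erupting
teeth), independent per-instance remeshing (each instance shares the
template's vertex layout), and anatomically faithful mandible shape.
Passing tests therefore demonstrate correctness of the algorithms under
controlled growth and noise, not segmentation robustness on clinical data.

## Known limitations and numerical notes

- **Endpoint rates under noise.**  Region-mean cumulative-change curves
  retain a noise floor of ~0.2–0.4 %/month per instance at the default
  study conditions (0.2 mm noise, 653 vertices, region sizes 42–171), and
  any gradient estimator amplifies this at the first and last instances.
  A scan over fixed-penalty linear smoothers with an oracle-chosen penalty
  still leaves maximum region/instance recovery errors of ~0.21–0.29
  %/month, concentrated at T1 and T12 of the fastest regions; interior
  instances recover within 0.2 %/month (mean error ~0.06–0.08).  Endpoint
  rates should be interpreted with corresponding caution.
- Decimation uses Garland–Heckbert quadrics with exact target counts;
  collapses violating the manifold link condition or flipping normals are
  rejected, preserving watertightness.
- Ties everywhere (candidate selection, nearest-neighbor pairing) are
  broken deterministically, so identical inputs give bit-identical
  outputs.
- Degenerate inputs raise typed errors: collinear point sets in ICP,
  zero-variance neighborhoods in the correlation, zero-length tracked
  edges (unless dropped), isolated vertices in rate aggregation,
  landmark-frame collinearity.
- The interval tables (T1-T2, …) report the spline gradient at the
  interval's right endpoint, matching the convention that the change from
  T_i to T_{i+1} belongs to T_{i+1}.
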
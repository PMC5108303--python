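# Methods

This note documents the models, algorithms and numerical choices behind
`hippomorph`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the design was genuinely open.

## The problem

A subcortical structure (modelled on the rodent hippocampus) is segmented as
a binary mask on a 2-D multi-slice acquisition: fine in-plane resolution
(defaults 0.187 mm, desk-scale runs 0.25 mm) but thick slices (0.5 mm).
Three treatment groups of n = 8 are compared for (a) localized *shape*
change on the structure's surface, (b) local *volume* change inside it
(TBM), and (c) overall volume post-mortem (Cavalieri stereology).

## Synthetic cohorts

No real data accompany this problem, so every stage is validated against
cohorts with planted, exactly evaluable truth.

* **Template.** A capsule around a circular arc (curvature 0.08 /mm, arc
  length 14 mm, tube radius 2 mm on the desk grid), voxelized by distance to
  the densely sampled centerline.  `curvature = length = 0` degenerates to a
  ball, which is used for analytic checks.
* **Planted effects.** A surface deformation moves the implicit surface
  along its local normal by `a · K(d/ρ)`, with `K(s) = (1−s)⁴(4s+1)` a C²
  Wendland bump (`K(0)=1`, `K(1)=0`, zero outside `ρ`).  It is applied on
  the signed distance transform and re-thresholded, so the displacement is
  controlled without any mesh in the loop, and `|a| < ρ` keeps it fold-free
  at the amplitudes used.
* **Sub-voxel calibration.** The voxel-centre EDT overstates the distance to
  the true boundary by half the local crossing spacing; uncorrected, a
  re-thresholded offset below one voxel spacing changes nothing.
  `generation_sdf` subtracts half the voxel extent projected on the local
  gradient direction (sign-preserving), after which planted offsets and
  noise express at their nominal amplitude (verified against surface-flux
  volume changes, agreement ≲ 3–8% once the amplitude spans a few voxels;
  voxel counting quantizes smaller offsets).
* **Subject noise.** A Gaussian random field smoothed to a 3-voxel
  correlation length, normalized to a chosen RMS (default 0.1 mm) over the
  near-surface band and applied as a level-set offset, i.e. normal
  displacement.  For extreme draws the thresholded mask may shed sub-voxel
  satellites; the generator keeps the largest 6-connected component iff the
  remainder is < 0.5% of the foreground, else raises.
* **Volumetric truth for TBM.** A surface bump has no unique volumetric
  extension, so TBM experiments instead warp the template by the analytic
  diffeomorphism `u(x) = s·K(|x−c|/ρ)·(x−c)` (peak Jacobian ≈ `(1+s)³`),
  giving an exactly computable ground-truth Jacobian map.  Subjects are
  textured intensity volumes (smooth random field plus structure contrast):
  binary masks carry only boundary information, while intensity texture lets
  the registration observe interior expansion, as in real TBM.
* **What is not emulated.** MRI contrast physics, intensity inhomogeneity,
  rater segmentation behaviour beyond the smooth noise field, bilateral
  anatomy, and pose differences between subjects (masks are generated in a
  common frame; the registration's rigid stage is exercised separately with
  synthetic rigid motions).  Passing tests therefore show algorithmic
  correctness and calibration under controlled truth, not performance on
  real scanner data.

## Surface building

Per-slice 2-D signed Euclidean distance transforms (negative inside) are
linearly interpolated along the slice axis onto a grid whose spacing divides
the slice thickness, so the acquired slice planes are reproduced exactly
while the surface between slices is smooth (the stair-step correction).
Meshing is marching cubes at level 0, vertices welded, orientation fixed
outward by the sign of the enclosed volume.  Decimation coarsens the
marching-cubes step, which cannot break closedness (a quadric decimation
backend is not available offline; at these mesh sizes step coarsening is an
adequate substitute).  An optional small Gaussian on the distance field
(σ = 1 voxel in the pipeline) removes voxel-quantization roughness of the
level set without touching millimetre-scale geometry.  Enclosed volume is
the divergence-theorem tetrahedron sum — exactly translation invariant and
positive for outward orientation.

## Elastic registration

The loop alternates three steps after a rigid-only initialization phase
(up to 30 iterations, early-stopped, which pins the global pose before any
elastic motion so the accumulated rigid transform is meaningful):

1. **Normal-ray correspondence.** From every source vertex a ray is cast
   along ± its outward normal with a compiled Möller–Trumbore sweep (hits
   merged within a tolerance so shared edges and on-surface vertices count
   once; at ≤ a few thousand triangles a flat compiled sweep with a
   bounding-sphere reject outperforms spatial-index traversal).  The
   candidate is the nearest distinct hit within 25% of the target's
   bounding-box diagonal; it is accepted iff the source and target normals
   agree within 60° (dot > 0.5).  An earlier non-matching sheet therefore
   blocks the match — the "no multiple intersections before the
   corresponding point" rule.  Rejected vertices get weight 0.  Ties between
   senses go to the larger normal dot product.
2. **Rigid alignment.** Weighted Kabsch/Umeyama via SVD, reflection
   corrected, requiring ≥ 3 non-collinear valid correspondences.
3. **Elastic step.** The applied displacement solves
   `(W + βL + ε(I−W)) d = W r` with `L` the combinatorial mesh Laplacian,
   `r` the correspondence residuals and `ε = 0.05`: the exact minimizer of
   the weighted data term plus `β`-weighted edge-difference penalty.  A
   constant field passes through exactly for any `β`; zero-weight vertices
   translate with their neighbours (the damping keeps that diffusion local);
   and the solve is unconditionally stable.  Iterated neighbour averaging —
   the obvious cheaper operator — is *anti-damping* for checkerboard modes
   of the residual and diverges once the stiffness schedule reaches about
   one averaging sweep, which is why the exact solve is used.

`β` decays geometrically from 10 to 0.1 over 60 iterations (the stiffness
range is a free choice; only "gradually decreasing" is prescribed).  The
registered mesh keeps the source topology; the accumulated rigid part is
inverted out of the result in cohort use, so statistics see only shape.
Vertex-redistribution ("tangential relaxation") passes were evaluated and
rejected: they preserve triangle quality but slide vertices along the
surface, destroying the anatomical correspondence (truth correlation 0.39
with vs 0.98 without on a planted-bump pair).

The population average is built in surface space: the reference surface is
registered to every subject, corresponded vertex positions are averaged, and
a second pass against the average puts every subject in dense
correspondence with it.  The reference is an explicit argument so the
average is invariant to subject order.

## Vertex statistics

Displacement vectors are `subject vertex − average vertex` (world mm).
Group differences use the two-sample Hotelling's T² on the full 3-D vectors;
the null distribution comes from subject-level relabelling (the same
relabelling at every vertex, preserving spatial structure), enumerated
exactly whenever the number of distinct relabelings is at most the requested
permutation count (for 8 vs 8, all C(16,8) = 12870), otherwise sampled with
the `(1+b)/(B+1)` estimator.  BH step-up controls FDR per contrast at
q = 0.05, with monotone q-values; an uncorrected α = 0.05 exploratory map is
always reported alongside.

Two regularization choices matter at n = 8:

* **Ridge.** The pooled covariance is stabilized with `0.1·trace(S)/3·I`.
  Normal-ray correspondence makes the tangential coordinates of a vertex
  almost deterministic functions of the geometry, so their variance is ~1%
  of the trace; with a vanishing ridge any systematic micrometre-scale
  registration response in those directions becomes "infinitely"
  significant and floods the map.  The chosen ridge caps near-null
  directions while leaving well-conditioned directions essentially
  untouched.  (Explicit `ridge` arguments override it; as the ridge → 0 the
  statistic reduces to the classical T².)
* **Normalization anchor.** Unit-volume rescaling uses one common anchor
  point for a cohort (the average's centroid).  Rescaling each subject about
  its own centroid converts a genuine group difference in centroid position
  into a uniform per-vertex offset over the whole surface, which T² detects
  everywhere — exactly the artifact volume normalization is meant to avoid.

## Statistical power at the study conditions — a real limitation

With n = 8 per group the exact permutation floor is 2/12870 ≈ 1.6·10⁻⁴.  On
the realistic mask pipeline a planted 0.4 mm deformation with 0.1 mm subject
noise yields core per-vertex effect-to-sd ratios near 4–5 (the recovered
amplitude is attenuated 25–40% and quantization/meshing variance adds to the
injected noise), so the best per-vertex exact p is ~10⁻³.  BH at q = 0.05
over ~10³ vertices then admits **zero** discoveries at any analysis mesh
size — FDR-corrected detection is structurally out of reach at these
conditions, which is why small-n studies of this design fall back to
exploratory uncorrected maps.  The package reports both maps; its
calibration is demonstrated separately (type-I error within the binomial
interval; a full null cohort through the pipeline gives zero FDR discoveries
and uniform p-values).

## TBM

The rigid template is the iterated mean after 6-d.f. alignment (SimpleITK
Euler3D, full-sampling correlation metric, moments initialization;
registration runs on lightly smoothed copies, averaging uses the original
intensities).  Nonlinear registration is multi-resolution diffeomorphic
demons (SimpleITK filter, 3 levels, Gaussian field regularization σ = 2
voxels by default, with the field checked to have strictly positive Jacobian
— fields failing the check are rejected).  This is a deliberate, simpler
stand-in for high-dimensional fluid registration with the same statistical
downstream.  Jacobians are spacing-aware central differences of
`φ(x) = x + u(x)` (one-sided at borders); statistics run on the
log-determinant (symmetric in expansion/contraction).  Field inversion is
fixed-point iteration (20 iterations, 0.1-voxel tolerance); masks propagate
to subject space by nearest-neighbour sampling through the inverse.
Voxel-wise statistics are a one-way ANOVA over the three groups plus the
three pairwise t tests on log-Jacobians inside the mask, BH-corrected per
contrast; zero-variance voxels get p = 1 and are counted in the metadata.

## Stereology

`V̂ = t·m·(a/p)·ΣPᵢ` for counts on every m-th section.  The coefficient of
error uses the Gundersen–Jensen m = 1 covariogram
(`(3(A−ΣP) − 4B + C)/240` with `A=ΣPᵢ²`, `B=ΣPᵢPᵢ₊₁`, `C=ΣPᵢPᵢ₊₂`) plus a
Poisson nugget `ΣP`; `CE = √(total)/ΣP`.  The virtual probe overlays a
square grid of spacing `√(a/p)` with uniformly random in-cell offset and
random section phase; a point counts iff its containing voxel is labelled 1.
Unbiasedness is verified against the voxel-count volume of the mask (the
probe samples the mask, so that is the estimand); agreement with the
analytic solid volume is limited only by voxelization.

## Problem sizes

Desk-scale defaults: 96×96×40 voxels at (0.25, 0.25, 0.5) mm, ~1300-vertex
analysis meshes, 60 registration iterations, exact or 5000-fold permutation,
q = 0.05; TBM uses 64×64×28 at (0.35, 0.35, 0.7) mm.  The paper-resolution
grid (0.187 mm in-plane) is a configuration option.  Full cohort runs
(24 subjects, 48 registrations, two stat variants, three contrasts) complete
in a few minutes on one core.

## Known limitations

* Surface displacement below ~half a voxel is visible to the pipeline only
  through noise dithering; single-pair experiments should mesh the deformed
  level set directly (`deformed_level_set`).
* The registration's response to a focal deformation is not perfectly local:
  micrometre-scale systematic offsets appear away from the effect.  They are
  invisible at realistic noise levels but dominate if within-group variance
  is artificially tiny.
* Demons on binary masks recovers boundary motion only; interior Jacobian
  structure requires intensity texture.
* The Cavalieri probe counts voxel centres; tissue shrinkage and section
  deformation are out of scope.
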
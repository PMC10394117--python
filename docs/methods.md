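# Methods

`livertrack` rebuilds, at desk scale, a real-time liver tumor localization
framework that combines optical surface imaging with a single on-board
cone-beam x-ray projection.  This note documents the models, the synthetic
study conditions, the numerical choices, and what the desk-scale results do
and do not demonstrate.

## Problem and approach

During radiotherapy of liver tumors, respiration moves the target by up to
~15 mm, dominantly superior-inferior (SI), while the tumor itself is nearly
invisible on x-ray projections (its attenuation differs from liver
parenchyma by only a few percent).  Real-time constraints (< 500 ms) rule
out volumetric imaging, so the framework localizes the tumor indirectly via
mesh-based deformable registration of the liver boundary:

1. **Surface stage** - a patient-specific residual CNN regresses the liver
   boundary displacement field (DVF) from an optical heightmap of the body
   surface, exploiting learned internal-external motion correlation.
2. **X-ray stage** - a graph neural network refines the surface-predicted
   boundary: a CNN backbone extracts multi-scale features from the
   projection, a perceptual pooling layer samples them bilinearly at the
   projected positions of the (surface-deformed) mesh nodes (zero features
   outside the detector FOV), and graph convolutions over the mesh
   adjacency emit a per-node correction added by a spatial-transform step.
3. **Biomechanical stage** - a population-trained 3-D U-Net propagates the
   boundary DVF into the liver interior.  The boundary field is split into
   its node-mean ("DC", rigid translation) and zero-mean residual ("AC");
   only the gridded AC enters the U-Net, and the DC is added back to the
   prediction.  The prior tumor contour is warped by the resulting interior
   field.

All stages operate on a prior liver boundary mesh whose nodes stay in
one-to-one correspondence across phases (meshes are deformed, never
re-meshed).

## Losses

With node count N, predicted and target displacements d_p, d_p^gt, mesh
coordinates x_p, Laplacian coordinates
delta_p = x_p − mean_{q in N(p)} x_q:

* surface stage:  `L_surf = (1/N) Σ_p ||d_p − d_p^gt||²`  (mm²).
* x-ray stage:  `L_tot = λ_sim L_sim + λ_lap L_lap + λ_eng L_eng` with
  `L_sim = (1/N) Σ_p [(Δx_LR)² + (Δx_AP)² + a_SI (Δx_SI)²]`, a_SI = 4
  (SI up-weighted as the motion-dominant axis),
  `L_lap = (1/N) Σ_p ||delta'_p − delta_p||²` (translation-invariant
  deformation smoothness), and
  `L_eng = (1/N) Σ_p d_p · (d_p − mean_{q in N(p)} d_q)`, the quadratic
  form of the row-normalized graph Laplacian.  Weights λ = 1 / 0.05 / 1.
* biomechanical stage: region-weighted MSE - weight 1.0 inside the 1 cm
  dilation of the prior liver contour, 0.01 outside it (where the field is
  irrelevant for tumor localization but unconstrained inference is
  discouraged).

## Reference biomechanics

Training targets for the interior-motion network come from an in-repo
linear-elastic Dirichlet solver: the homogeneous isotropic Navier-Cauchy
equations (Poisson ratio 0.45, near-incompressible soft tissue) are
discretized with central finite differences on the liver voxel grid,
boundary displacements rasterized onto the liver shell (nearest mesh node),
and solved exactly with sparse linear algebra.  This is a small-strain
substitute for nonlinear hyperelastic finite elements, adequate at the
phantom's strain levels; a hook (`train_bio` consumes plain arrays) accepts
externally computed reference fields for users with an FEM pipeline.  The
scheme is exact for rigid translations and affine fields, and in harmonic
mode each component obeys the discrete maximum principle; the suite checks
it against a dense direct solve.

## Synthetic study conditions

No patient data is used.  A phantom emulates one "patient": an ellipsoidal
torso (half-axes 110 x 85 x 120 mm) with a seeded irregular surface, an
ellipsoidal liver (162-node boundary mesh by default, configurable to 642),
and an embedded 20 mm tumor whose attenuation is +1.7 % of liver -
deliberately in the low-contrast regime so the x-ray stage
cannot see the tumor directly.  Breathing is a smooth cyclic field built
from three spatial modes driven out of phase (rank-3 structure with
hysteresis), normalized to peak liver amplitudes LR/AP/SI = 3/7/15 mm -
values in the range reported for liver tumor motion.  Phase 0 % (end of
inhale) is the zero-displacement reference; body-surface motion is driven
by the same field, so an internal-external correlation exists to be
learned.

A rank-3 PCA motion model fitted to the 10-phase fields provides
augmentation: per phase, 4/6/4/2 scaling factors for coefficients w0..w3
drawn uniformly from [0.95, 1.05], [−1.5, 3], [−1.5, 3], [−1.5, 1.5] and
combined as a full Cartesian product - 768 training cases (phases
10-40 %) and 384 validation cases (phases 70-80 %).  Rigid setup
translations within ±6 mm are added.  Held-out test phases (50/60/90 %)
are evaluated under four scenario types that deliberately exceed the
training ranges: amplitude scalings up to 5x (type 1) and single-axis
translations of −10..10 mm in 2 mm steps (types 2-4, 33 cases each).

Imaging simulation: orthographic heightmaps (the full-scale
260 x 260 px / 202 mm FOV convention is the default of the rendering API;
the study uses 64 x 64 px / 256 mm to cover the phantom), corrupted during
training by (i) a rigid shift within ±40 % of the mean surface motion,
(ii) per-pixel Gaussian noise with sd equal to the local surface motion,
floored at 5 mm ("bounded at 5 mm" is read as a floor, since the noise
exists to weaken the internal-external correlation and would otherwise
vanish for small motion), and (iii) a 50 % chance that the training target
belongs to a neighboring breathing phase.  Cone-beam projections use exact
Siddon ray tracing (SAD 1000 mm, SDD 1500 mm; full-scale detector
512 x 384 @ 0.776 mm, desk default 96 x 72 @ 4.14 mm) with on-the-fly
Poisson photon noise (I0 = 1e5 per pixel) plus 10-photon Gaussian
electronic noise.

## Training

All networks are trained with the in-repo numpy autodiff engine (float64;
gradients verified against central finite differences).  Adam throughout;
surface stage: lr 2e-4, weight decay 1e-7, plateau schedule x0.6 after 10
stagnant epochs; x-ray stage: lr 2e-4, x0.6 every 30 epochs, one model per
gantry angle, trained on the frozen surface model's predictions (the
ablation refiner is retrained from the prior mesh and zero DVFs); interior
stage: lr 2e-4, plateau x0.9 / patience 10, trained across a population of
phantoms disjoint from the test phantom, with 1 mm Gaussian noise added to
the boundary inputs to emulate upstream-model errors.  Best-validation
checkpoints are kept.  Desk-scale problem sizes (45/35/30 epochs, 120
training cases, 4 training phantoms for the population model, 16^3
liver-centered crop at 7 mm for the interior stage) were chosen so the
full study builds, trains and evaluates in roughly ten minutes on one CPU;
the full-scale architecture settings (12-feature / 5-module surface CNN,
5-level U-Net, 260 x 260 surface images, 512 x 384 detector) remain
available through the configuration dataclasses.

Desk-scale adaptations worth noting: rigid-translation augmentation is
baked per case when the projections are simulated (re-ray-tracing per epoch
is not affordable), and the surface loader adds further on-the-fly
translations by shifting the heightmap in-plane and offsetting its height -
exact under the orthographic camera; validation images are clean.

## Evaluation

Liver boundary: node-wise RMSE and the 95-percentile symmetric Hausdorff
distance (HD95) between node sets, computed on meshes refined to ≤ 2 mm
edges by midpoint subdivision (a fixed linear operator on the coarse nodes,
so correspondence is preserved).  Tumor: center-of-mass error (COME), Dice
coefficient, and mask-surface HD95 on the interior-stage grid, with ground
truth obtained by warping the prior tumor mask with the scenario's
volumetric field (backward warping via fixed-point field inversion).
Results are stratified by prior COME ≤ / > 10 mm.  Paired comparisons use
the Wilcoxon matched-pairs signed-rank test (scipy) and an in-repo
Hodges-Lehmann estimator: the median of all Walsh averages with the exact
signed-rank order-statistic confidence interval (normal approximation
beyond n = 300).

The iso-center miscalibration protocol adds a randomly oriented,
fixed-magnitude (1 or 2 mm) shift to the surface-predicted DVF before the
x-ray stage and tabulates the same metrics per offset magnitude.

## Design choices on open points

* Scenario type 1 exposes the per-phase sample count as a parameter
  (default 25) since the type-1 total is otherwise ambiguous.
* The projection image fed to the x-ray backbone is the noisy line-integral
  image, min-max normalized per image.
* Surface heightmaps are standardized by the prior image's foreground
  mean/sd; background pixels map to 0 after standardization and carry a
  recorded sentinel (-1000 mm) on disk.
* Phase-mismatch direction is ±1 phase with equal probability.
* "Spatially uniform component" of a boundary DVF is implemented as the
  per-component node mean - the simplest translation-extracting
  decomposition.
* Nearest-neighbor AC gridding is restricted to the 1 cm liver band; the
  outside region is zero (it is down-weighted 100x in the loss).
* The interior stage operates on a fixed-size liver-centered crop so one
  population model serves phantoms of different extents.
* Detector u-axis points to the patient's left at gantry 0; v points
  superior.  Gantry 0 is the AP view; 90 the left-lateral view.

## Limitations

The phantom's motion lies exactly in a rank-3 space and its
internal-external correlation is constructed, so the learning problem is
easier than patient anatomy; passing the end-to-end criteria demonstrates
that the cascade, losses, simulators and training loops are implemented
coherently - not clinical accuracy.  The linear-elastic solver ignores
material nonlinearity, heterogeneity and sliding contact.  Scatter, beam
hardening and detector response are not modelled in the projector, and the
optical camera is orthographic without calibration or speckle artifacts.
Timing figures of the original real-time system are out of scope.
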
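# livertrack

Real-time liver tumor localization from combined optical surface imaging
and a single on-board x-ray projection, rebuilt as a tested, desk-scale
Python package on a synthetic deformable liver phantom.

## The problem

Respiration moves liver tumors by up to ~15 mm (dominantly
superior-inferior), while the tumor is nearly invisible on x-ray
projections because its attenuation barely differs from liver parenchyma.
Real-time adaptive radiotherapy needs 3-D tumor positions in well under a
second, which rules out volumetric imaging.  `livertrack` implements a
deformation-driven answer: track the *liver boundary* - which both imaging
modalities constrain - and propagate its motion into the organ to localize
the tumor.

Three learned stages operate on a prior liver boundary mesh with fixed
node correspondence:

1. **Surf** - a residual CNN maps a body-surface heightmap to liver
   boundary displacements d_p (mm), trained with
   `L_surf = (1/N) Σ_p ||d_p − d_p^gt||²`.
2. **X** - a Pixel2Mesh-style refiner: CNN features of one cone-beam
   projection are pooled bilinearly at the projected mesh nodes (zero
   outside the FOV) and graph convolutions emit per-node corrections.
   Loss: `λ_sim L_sim + λ_lap L_lap + λ_eng L_eng` with SI-weighted mesh
   similarity (a_SI = 4), a Laplacian-coordinate regularizer, and a graph
   deformation energy (λ = 1 / 0.05 / 1).
3. **Bio** - the boundary field is split into its node mean (rigid "DC")
   and zero-mean residual ("AC"); a population-trained 3-D U-Net maps the
   gridded AC to the intra-liver field (supervised by an in-repo
   linear-elastic Dirichlet solver), the DC is added back, and the prior
   tumor contour is warped to its current position.

Everything around the cascade is included and tested: the breathing
phantom, the rank-3 PCA motion model with its 768/384-case augmentation
scheme, orthographic surface rendering with three noise mechanisms, exact
Siddon cone-beam ray tracing with Poisson + Gaussian photon noise, the
RMSE/HD95/COME/DSC metrics with a Hodges-Lehmann paired estimator, and the
iso-center miscalibration robustness protocol.  The networks run on an
in-repo numpy autodiff engine, so the package has no deep-learning
framework dependency.  See `docs/methods.md` for the full model account.

## Worked example

```bash
python examples/01_phantom_and_breathing.py
```

prints the phantom inventory and per-phase liver motion:

```
body mesh:  642 nodes
liver mesh: 162 nodes (fixed across phases: node correspondence)
tumor mesh: 42 nodes, attenuation +1.7% vs liver (low contrast)
grid: (32, 32, 32) voxels at 8.0 mm

phase   max |LR|   max |AP|   max |SI|  (mm, liver boundary)
   0%       0.00       0.00       0.00
  10%       0.60       0.74       1.57
  ...
  40%       2.74       7.00      15.00
  50%       1.59       5.81      13.61
  ...
```

The SI amplitude peaks at the configured 15 mm around end-of-exhale and
phase 0 % is the motionless reference - the geometry every later stage
assumes.

`examples/05_train_and_evaluate_cascade.py` trains the whole cascade at
smoke scale and compares variants; at the test-suite scale (fixed seed 1)
the evaluation table gives, averaged over all four scenario types:

```
            liver_rmse  liver_hd95  tumor_come  tumor_dsc
prior            13.54       13.02       13.82       0.24
surf-bio          2.41        2.52        2.49       0.81
x-bio             9.94       10.31       10.89       0.28
surf-x-bio        2.29        2.52        2.22       0.84
```

i.e. the combined cascade recovers ~84 % of the injected tumor motion and
clearly beats the x-ray-only ablation, whose graph refiner loses track
under large translations - the motivation for adding surface imaging.
The other examples cover the simulators, the motion model, the elastic
solver, and the robustness protocol.

A thin CLI wraps the same harness
(`livertrack phantom|simulate|train|evaluate|robustness|report`, each with
`--config/--seed/--out`).

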
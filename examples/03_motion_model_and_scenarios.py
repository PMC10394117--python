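"""Fit the PCA respiratory motion model and enumerate the augmentation.

Shows the augmentation counts (768 training / 384 validation cases from the
coefficient-rescaling scheme) and the four test scenario types that probe
beyond the training ranges.
"""

import numpy as np

from livertrack import (GridSpec, MotionParams, PhantomConfig,
                        augment_training_set, fit_pca, make_breathing_phases,
                        make_phantom, make_test_scenarios)
from livertrack.motion import TRAIN_PHASES, VALIDATION_PHASES

phantom = make_phantom(PhantomConfig(grid=GridSpec.centered(32, 8.0)), seed=7)
phases = make_breathing_phases(phantom, 10, MotionParams(), seed=3)
pca = fit_pca(phases.volumetric_dvfs, phases.phases)

print("PCA motion model: mean field + 3 principal components")
print("component orthogonality |<Di,Dj>| max off-diagonal:",
      np.abs(pca.components @ pca.components.T - np.eye(3)).max())

train = augment_training_set(pca, TRAIN_PHASES, seed=5)
val = augment_training_set(pca, VALIDATION_PHASES, seed=6)
print(f"\naugmentation: {len(train)} training cases "
      f"(4 phases x 4*6*4*2 scaling products), {len(val)} validation cases")

for t, what in [(1, "amplitude scaling beyond training range"),
                (2, "LR translation -10..10 mm"),
                (3, "AP translation -10..10 mm"),
                (4, "SI translation -10..10 mm")]:
    specs = make_test_scenarios(pca, t, seed=t)
    print(f"type {t}: {len(specs)} test cases ({what})")
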